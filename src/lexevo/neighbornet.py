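"""NeighborNet split networks.

The construction has two phases.  First, an agglomerative pass (in the style
of neighbor joining, but keeping pairs of linked nodes) produces a circular
ordering of the taxa.  Second, the n(n-1)/2 splits induced by contiguous
arcs of that ordering receive nonnegative weights by constrained least
squares against the input distances.  Reticulations in the drawn network
correspond to incompatible splits carrying positive weight; a treelike
distance matrix yields only pairwise-compatible splits.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from scipy.optimize import nnls

from .cognate import DistanceMatrix
from .errors import DataError, NumericError

WEIGHT_EPS = 1e-8  # splits below this weight are dropped


@dataclass
class SplitSystem:
    """Weighted circular split system.

    ``order`` is the circular taxa ordering; each split is stored as the
    frozenset of taxa on the side not containing ``order[-1]``.
    """

    taxa: list[str]
    order: list[str]
    splits: list[tuple[frozenset, float]]
    fit: float = 0.0

    def nontrivial(self) -> list[tuple[frozenset, float]]:
        n = len(self.taxa)
        return [(s, w) for s, w in self.splits if 2 <= len(s) <= n - 2]

    def split_distance(self, a: str, b: str) -> float:
        return sum(w for s, w in self.splits if (a in s) != (b in s))


# ---------------------------------------------------------------------------
# Phase 1: circular ordering by agglomeration


def nn_ordering(d: DistanceMatrix) -> list[str]:
    """Circular taxa ordering by the NeighborNet agglomeration.

    Repeatedly selects the pair of clusters minimizing the net-divergence
    adjusted distance, links the closest node pair between them, and reduces
    any three-node chain to two surrogate nodes; the recorded reductions are
    expanded in reverse to yield the full circular ordering.  Ties break on
    the smallest node index, and the returned order is canonicalized to
    start at the first taxon, with the orientation placing the smaller
    neighbor index second.
    """
    n = len(d.taxa)
    if n <= 3:
        return list(d.taxa)
    dist: dict[tuple[int, int], float] = {}

    def get(i, j):
        return 0.0 if i == j else dist[(min(i, j), max(i, j))]

    def put(i, j, v):
        dist[(min(i, j), max(i, j))] = v

    for i in range(n):
        for j in range(i + 1, n):
            put(i, j, d.d[i, j])
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    cluster_of: dict[int, int] = {i: i for i in range(n)}
    next_node = n
    next_cluster = n
    reductions: list[tuple[int, int, tuple[int, int, int]]] = []

    def cluster_dist(a: int, b: int) -> float:
        return float(np.mean([get(x, y) for x in clusters[a] for y in clusters[b]]))

    while sum(len(ch) for ch in clusters.values()) > 3 and len(clusters) > 1:
        cids = sorted(clusters)
        nc = len(cids)
        cd = {(a, b): cluster_dist(a, b) for a, b in combinations(cids, 2)}

        def cd_get(a, b):
            return cd[(min(a, b), max(a, b))]

        rowsum = {a: sum(cd_get(a, b) for b in cids if b != a) for a in cids}
        best, best_q = None, np.inf
        for a, b in combinations(cids, 2):
            q = (nc - 2) * cd_get(a, b) - rowsum[a] - rowsum[b]
            if q < best_q - 1e-12:
                best, best_q = (a, b), q
        ca, cb = best
        # node-pair selection: nodes of ca and cb act as singletons, the
        # remaining clusters as units
        others = [c for c in cids if c not in (ca, cb)]
        m = len(others) + len(clusters[ca]) + len(clusters[cb])
        pool = clusters[ca] + clusters[cb]

        def node_rowsum(x: int) -> float:
            s = sum(float(np.mean([get(x, y) for y in clusters[c]])) for c in others)
            s += sum(get(x, z) for z in pool if z != x)
            return s

        nbest, nbest_q = None, np.inf
        for x in clusters[ca]:
            for y in clusters[cb]:
                q = (m - 2) * get(x, y) - node_rowsum(x) - node_rowsum(y)
                if q < nbest_q - 1e-12:
                    nbest, nbest_q = (x, y), q
        x, y = nbest
        chain_a = list(clusters[ca])
        if chain_a[-1] != x:
            chain_a.reverse()
        chain_b = list(clusters[cb])
        if chain_b[0] != y:
            chain_b.reverse()
        chain = chain_a + chain_b
        del clusters[ca], clusters[cb]
        while len(chain) > 2:
            x1, x2, x3 = chain[0], chain[1], chain[2]
            u, v = next_node, next_node + 1
            next_node += 2
            live = [z for z in list({z for ch in clusters.values() for z in ch}) + chain[3:]]
            for z in live:
                put(u, z, 2 / 3 * get(x1, z) + 1 / 3 * get(x2, z))
                put(v, z, 2 / 3 * get(x3, z) + 1 / 3 * get(x2, z))
            put(u, v, (get(x1, x2) + get(x2, x3) + get(x1, x3)) / 3)
            reductions.append((u, v, (x1, x2, x3)))
            chain = [u, v] + chain[3:]
        cid = next_cluster
        next_cluster += 1
        clusters[cid] = chain
        for z in chain:
            cluster_of[z] = cid

    cycle: list[int] = []
    for cid in sorted(clusters):
        cycle.extend(clusters[cid])
    for u, v, (x1, x2, x3) in reversed(reductions):
        k = len(cycle)
        pos = seq = None
        for i in range(k):
            a, b = cycle[i], cycle[(i + 1) % k]
            if (a, b) == (u, v):
                pos, seq = i, [x1, x2, x3]
                break
            if (a, b) == (v, u):
                pos, seq = i, [x3, x2, x1]
                break
        if pos is None:
            raise NumericError("expansion failed: reduced pair not adjacent in cycle")
        rotated = [cycle[(pos + t) % k] for t in range(k)]  # starts u, v, ...
        cycle = seq + rotated[2:]
    order = [d.taxa[i] for i in cycle]
    return canonicalize_order(order)


def canonicalize_order(order: list[str]) -> list[str]:
    """Rotate/reflect so the lexicographic handling is deterministic: start
    at the minimum element, orient toward the smaller neighbor."""
    n = len(order)
    i = order.index(min(order))
    fwd = [order[(i + k) % n] for k in range(n)]
    rev = [order[(i - k) % n] for k in range(n)]
    return fwd if fwd[1] <= rev[1] else rev


# ---------------------------------------------------------------------------
# Phase 2: split weights by nonnegative least squares


def _arc_splits(order: list[str]) -> list[frozenset]:
    """All splits induced by contiguous arcs not containing order[-1]."""
    n = len(order)
    out = []
    for i in range(n - 1):
        for j in range(i, n - 1):
            out.append(frozenset(order[i : j + 1]))
    return out


def nn_split_weights(d: DistanceMatrix, order: list[str] | None = None,
                     eps: float = WEIGHT_EPS) -> SplitSystem:
    """Weight the circular splits of ``order`` by NNLS against ``d``.

    Minimizes ``||d - sum_s w_s delta_s||^2`` over ``w >= 0`` where
    ``delta_s(a,b) = 1`` iff the split separates the pair; splits with
    weight below ``eps`` are dropped.  The fit statistic is the fraction of
    squared distance reproduced, ``1 - SS_res / SS_tot``.
    """
    if order is None:
        order = nn_ordering(d)
    if set(order) != set(d.taxa):
        raise DataError("ordering does not match distance matrix taxa")
    n = len(order)
    if n == 2:
        w = d.d[0, 1] / 2
        splits = [(frozenset([order[0]]), w), (frozenset([order[1]]), w)]
        return SplitSystem(list(d.taxa), order, splits, fit=1.0)
    pairs = list(combinations(range(n), 2))
    tindex = {t: k for k, t in enumerate(d.taxa)}
    y = np.array([d.d[tindex[order[i]], tindex[order[j]]] for i, j in pairs])
    cand = _arc_splits(order)
    a = np.zeros((len(pairs), len(cand)))
    for col, s in enumerate(cand):
        member = np.array([order[i] in s for i in range(n)])
        for row, (i, j) in enumerate(pairs):
            a[row, col] = member[i] != member[j]
    try:
        w, rnorm = nnls(a, y)
    except RuntimeError as exc:  # pragma: no cover - solver failure
        raise NumericError(f"NNLS failed to converge: {exc}") from exc
    ss_tot = float(y @ y)
    fit = 1.0 - (rnorm**2 / ss_tot if ss_tot > 0 else 0.0)
    splits = [(cand[k], float(w[k])) for k in range(len(cand)) if w[k] >= eps]
    return SplitSystem(list(d.taxa), list(order), splits, fit=fit)


def neighbor_net(d: DistanceMatrix) -> SplitSystem:
    """Full NeighborNet: ordering then split weights."""
    return nn_split_weights(d, nn_ordering(d))


# ---------------------------------------------------------------------------
# Reticulation summary


def splits_compatible(s1: frozenset, s2: frozenset, taxa: set) -> bool:
    """Two splits are compatible iff some intersection of their sides is
    empty (they can coexist on one tree)."""
    a1, a2 = set(s1), taxa - set(s1)
    b1, b2 = set(s2), taxa - set(s2)
    return any(not (x & y) for x in (a1, a2) for y in (b1, b2))


def reticulation_score(s: SplitSystem) -> float:
    """Fraction of pairwise nontrivial split weight in conflict.

    Over all pairs of nontrivial splits, sums ``min(w_i, w_j)`` for the
    incompatible pairs and normalizes by the same sum over every pair:
    0 for a compatible (treelike) system, 1 when all weighted nontrivial
    splits are mutually incompatible.  The minimum weights keep low-weight
    noise splits from dominating the score.
    """
    if not s.splits:
        raise DataError("empty split system")
    taxa = set(s.taxa)
    nt = s.nontrivial()
    conflicted = total = 0.0
    for i, (si, wi) in enumerate(nt):
        for sj, wj in nt[i + 1:]:
            pair = min(wi, wj)
            total += pair
            if not splits_compatible(si, sj, taxa):
                conflicted += pair
    return conflicted / total if total > 0 else 0.0


# ---------------------------------------------------------------------------
# I/O


def write_nexus_splits(s: SplitSystem, path: str | Path) -> None:
    """SplitsTree-compatible TAXA + SPLITS blocks."""
    n = len(s.taxa)
    idx = {t: i + 1 for i, t in enumerate(s.taxa)}
    lines = [
        "#NEXUS",
        "BEGIN TAXA;",
        f"    DIMENSIONS NTAX={n};",
        "    TAXLABELS",
    ]
    lines += [f"        '{t}'" for t in s.taxa]
    lines += [
        "    ;",
        "END;",
        "BEGIN SPLITS;",
        f"    DIMENSIONS NTAX={n} NSPLITS={len(s.splits)};",
        "    FORMAT LABELS=NO WEIGHTS=YES;",
        "    CYCLE " + " ".join(str(idx[t]) for t in s.order) + ";",
        "    MATRIX",
    ]
    for side, w in s.splits:
        members = " ".join(str(idx[t]) for t in sorted(side, key=lambda t: idx[t]))
        lines.append(f"        {w:.8g}    {members},")
    lines += ["    ;", "END;", ""]
    Path(path).write_text("\n".join(lines))
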