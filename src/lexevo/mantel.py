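"""Isolation-by-barrier inference: Mantel and partial Mantel permutation
tests between lexical distances, geographic distances, and barrier
indicator matrices, plus the scree rule choosing how many barriers to keep.

A barrier indicator matrix codes a pair of sites 1 if the first *k*
barriers jointly disconnect them on the Delaunay network and 0 otherwise.
The Mantel statistic is the Pearson or Kendall tau-b correlation of the
upper-triangle entries; significance comes from jointly permuting rows and
columns of the second matrix.  The partial test residualizes both matrices
on a covariate (typically geographic distance) before correlating
(Pearson), or uses the partial-tau formula (Kendall).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics.pairwise import haversine_distances

from .barrier import Barrier, GeoNetwork
from .cognate import DistanceMatrix
from .errors import DataError

EARTH_RADIUS_KM = 6371.0088


@dataclass
class IndicatorMatrix:
    """Symmetric 0/1 matrix: 1 = pair separated by the evaluated barriers."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        if not np.array_equal(self.d, self.d.T):
            raise DataError("indicator matrix must be symmetric")
        if not set(np.unique(self.d)) <= {0.0, 1.0}:
            raise DataError("indicator entries must be 0/1")
        if np.any(np.diag(self.d) != 0):
            raise DataError("indicator diagonal must be 0")


@dataclass
class MantelResult:
    r: float
    r2: float
    p: float
    method: str
    permutations: int
    partial: bool = False


def geo_distance_matrix(ids, lonlat) -> DistanceMatrix:
    """Great-circle (haversine) distances in kilometres."""
    rad = np.radians(np.asarray(lonlat, dtype=float))[:, ::-1]  # (lat, lon)
    d = haversine_distances(rad) * EARTH_RADIUS_KM
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(ids), d)


def barrier_indicator(barriers: list[Barrier], net: GeoNetwork, k: int) -> IndicatorMatrix:
    """Indicator of separation by the first ``k`` barriers jointly.

    Removes every Delaunay edge crossed by barriers ``1..k`` and marks site
    pairs in different connected components.  ``k=0`` gives all zeros, as
    does a barrier set that cuts no graph separator (logged as a warning).
    """
    import logging

    import networkx as nx

    if k > len(barriers):
        raise DataError(f"asked for {k} barriers but only {len(barriers)} available")
    removed = {e for b in barriers[:k] for e in b.crossed}
    g = nx.Graph()
    g.add_nodes_from(range(len(net.ids)))
    g.add_edges_from(e for e in net.edges if e not in removed)
    comp = {node: ci for ci, c in enumerate(nx.connected_components(g)) for node in c}
    n = len(net.ids)
    ind = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if comp[i] != comp[j]:
                ind[i, j] = ind[j, i] = 1.0
    if k > 0 and ind.sum() == 0:
        logging.getLogger(__name__).warning(
            "first %d barriers disconnect no site pair; indicator is all zeros", k)
    return IndicatorMatrix(list(net.ids), ind)


# ---------------------------------------------------------------------------
# Mantel machinery


def _upper(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def _corr(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("constant matrix: correlation undefined")
    if method == "pearson":
        return float(np.corrcoef(x, y)[0, 1])
    if method == "kendall":
        return float(stats.kendalltau(x, y).statistic)
    raise DataError(f"unknown method {method!r}")


def _align(a, b) -> tuple[np.ndarray, np.ndarray, int]:
    if a.taxa != b.taxa:
        if set(a.taxa) != set(b.taxa):
            raise DataError("matrices cover different taxa")
        idx = [b.taxa.index(t) for t in a.taxa]
        bm = b.d[np.ix_(idx, idx)]
    else:
        bm = b.d
    return a.d, bm, len(a.taxa)


def mantel(a, b, method: str = "pearson", nperm: int = 9999,
           seed: int = 0) -> MantelResult:
    """Two-sided Mantel permutation test between two distance-like matrices.

    ``p = (1 + #{|r*| >= |r|}) / (1 + nperm)`` under joint row/column
    permutation of ``b``; deterministic given ``seed``.
    """
    if nperm < 99:
        raise DataError("nperm must be >= 99")
    am, bm, n = _align(a, b)
    x = _upper(am)
    r = _corr(x, _upper(bm), method)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(nperm):
        perm = rng.permutation(n)
        r_star = _corr(x, _upper(bm[np.ix_(perm, perm)]), method)
        if abs(r_star) >= abs(r) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + nperm)
    return MantelResult(r, r * r, p, method, nperm)


def _residualize(y: np.ndarray, c: np.ndarray) -> np.ndarray:
    beta = np.polyfit(c, y, 1)
    return y - np.polyval(beta, c)


def partial_mantel(a, b, c, method: str = "pearson", nperm: int = 9999,
                   seed: int = 0) -> MantelResult:
    """Mantel test of ``a`` vs ``b`` controlling for ``c``.

    Pearson: correlate residuals of ``a`` and ``b`` after linear regression
    on ``c``.  Kendall: partial tau,
    ``(t_ab - t_ac t_bc) / sqrt((1-t_ac^2)(1-t_bc^2))``.
    Permutations rearrange ``b`` and recompute the partial statistic.
    A constant covariate degrades gracefully to the plain test.
    """
    if nperm < 99:
        raise DataError("nperm must be >= 99")
    am, bm, n = _align(a, b)
    _, cm, _ = _align(a, c)
    x = _upper(am)
    zc = _upper(cm)
    if np.std(zc) == 0:
        res = mantel(a, b, method, nperm, seed)
        return MantelResult(res.r, res.r2, res.p, method, nperm, partial=True)

    def statistic(bmat: np.ndarray) -> float:
        y = _upper(bmat)
        if method == "pearson":
            return _corr(_residualize(x, zc), _residualize(y, zc), "pearson")
        t_ab = _corr(x, y, "kendall")
        t_ac = _corr(x, zc, "kendall")
        t_bc = _corr(y, zc, "kendall")
        denom = math_sqrt((1 - t_ac**2) * (1 - t_bc**2))
        if denom == 0:
            raise DataError("degenerate partial Kendall correlation")
        return (t_ab - t_ac * t_bc) / denom

    r = statistic(bm)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(nperm):
        perm = rng.permutation(n)
        if abs(statistic(bm[np.ix_(perm, perm)])) >= abs(r) - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + nperm)
    return MantelResult(r, r * r, p, method, nperm, partial=True)


def math_sqrt(x: float) -> float:
    return float(np.sqrt(max(x, 0.0)))


# ---------------------------------------------------------------------------
# Scree rule for the number of meaningful barriers


def select_n_barriers(pearson_r2: list[float], kendall_r2: list[float],
                      gain_frac: float = 0.01) -> int:
    """Largest k whose addition still helps both correlations.

    Keeping barrier k requires (i) the Kendall r-squared to strictly
    increase at k and (ii) the Pearson r-squared gain at k to be at least
    ``gain_frac`` of the cumulative Pearson r-squared at k.  k=1 is always
    admissible (there is no smaller model to compare against).
    """
    if len(pearson_r2) != len(kendall_r2) or not pearson_r2:
        raise DataError("need equal-length nonempty r2 sequences")
    k_star = 1
    for k in range(2, len(pearson_r2) + 1):
        p_gain = pearson_r2[k - 1] - pearson_r2[k - 2]
        k_gain = kendall_r2[k - 1] - kendall_r2[k - 2]
        cum = pearson_r2[k - 1]
        if k_gain > 0 and cum > 0 and p_gain >= gain_frac * cum:
            k_star = k
        else:
            break
    return k_star
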