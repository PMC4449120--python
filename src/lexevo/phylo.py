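"""Bayesian phylogenetics for binary cognate characters.

The model follows standard lexical-phylogenetics practice: each cognate
class is a binary character evolving along a rooted time tree under a
reversible two-state CTMC, optionally wrapped in a Tuffley-Steel covarion
whose hidden state toggles each character between an evolving ("on") and a
frozen ("off") regime.  The likelihood is conditioned on characters being
observable somewhere in the sample (ascertainment correction), because a
cognate class enters the data only if at least one variant attests it.

Branch substitution lengths are ``(parent age - child age) * mu * r_b``
where ``mu`` is the base clock rate (substitutions per character per year)
and ``r_b`` a branch rate multiplier (1 under a strict clock, i.i.d.
lognormal with mean 1 under the relaxed clock).

A compact Metropolis-Hastings sampler explores topology (narrow and wide
subtree exchange), node ages, the sampling age of dated tips, and the model
parameters.  It is meant for desk-scale data (tens of taxa, hundreds of
characters), not as a general-purpose replacement for full phylogenetics
engines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .cognate import BinaryCharacterMatrix
from .errors import DataError, NumericError

# ---------------------------------------------------------------------------
# Time tree


class TimeTree:
    """Rooted binary tree with node ages in years before present.

    Nodes ``0..n_tips-1`` are tips; internal nodes follow.  ``parent[root]``
    is -1.  ``rate_mult[v]`` is the rate multiplier of the branch above ``v``.
    """

    def __init__(self, labels, parent, children, age, rate_mult=None):
        self.labels = list(labels)
        self.n_tips = len(self.labels)
        self.parent = np.asarray(parent, dtype=int)
        self.children = [list(c) for c in children]
        self.age = np.asarray(age, dtype=float)
        self.n_nodes = len(self.parent)
        if rate_mult is None:
            rate_mult = np.ones(self.n_nodes)
        self.rate_mult = np.asarray(rate_mult, dtype=float)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise DataError(f"tree must have exactly one root, found {len(roots)}")
        self.root = int(roots[0])

    def copy(self) -> "TimeTree":
        return TimeTree(self.labels, self.parent.copy(),
                        [list(c) for c in self.children],
                        self.age.copy(), self.rate_mult.copy())

    def validate(self) -> None:
        for v in range(self.n_nodes):
            p = self.parent[v]
            if p >= 0 and not self.age[p] > self.age[v]:
                raise DataError(f"node {v}: parent age {self.age[p]} <= own age {self.age[v]}")
        if np.any(self.age < 0):
            raise DataError("negative node age")

    def postorder(self) -> list[int]:
        order, stack = [], [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        return order[::-1]

    def is_tip(self, v: int) -> bool:
        return v < self.n_tips

    def tips_below(self, v: int) -> frozenset[str]:
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if self.is_tip(u):
                out.append(self.labels[u])
            else:
                stack.extend(self.children[u])
        return frozenset(out)

    def clades(self) -> dict[frozenset[str], int]:
        """Map from each internal clade (tip-label set) to its node index."""
        below: dict[int, frozenset[str]] = {}
        for v in self.postorder():
            if self.is_tip(v):
                below[v] = frozenset([self.labels[v]])
            else:
                below[v] = frozenset().union(*(below[c] for c in self.children[v]))
        return {below[v]: v for v in range(self.n_tips, self.n_nodes)}

    def topology_key(self) -> str:
        """Canonical label-sorted newick of the unranked topology."""
        def rec(v: int) -> str:
            if self.is_tip(v):
                return self.labels[v]
            parts = sorted(rec(c) for c in self.children[v])
            return "(" + ",".join(parts) + ")"
        return rec(self.root) + ";"

    def to_newick(self, include_ages: bool = True, annotations=None) -> str:
        """Newick string with branch lengths in years; optional per-node
        ``[&key=value]`` comment annotations keyed by node index."""
        def rec(v: int) -> str:
            if self.is_tip(v):
                core = self.labels[v].replace(" ", "_")
            else:
                core = "(" + ",".join(rec(c) for c in self.children[v]) + ")"
            if annotations and v in annotations:
                meta = ",".join(f"{k}={val}" for k, val in annotations[v].items())
                core += f"[&{meta}]"
            if include_ages and self.parent[v] >= 0:
                core += f":{self.age[self.parent[v]] - self.age[v]:.6g}"
            return core
        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str, tip_ages: dict[str, float] | None = None) -> "TimeTree":
        """Parse a newick string (branch lengths in years) into a time tree.

        Node ages are reconstructed from root-to-tip path lengths; supply
        ``tip_ages`` for non-contemporaneous tips (ages are then anchored so
        the youngest tip sits at its stated age, default 0).
        """
        import dendropy

        dt = dendropy.Tree.get(data=newick, schema="newick",
                               preserve_underscores=True)
        dt.is_rooted = True
        labels = [lf.taxon.label for lf in dt.leaf_node_iter()]
        n_tips = len(labels)
        tip_idx = {lab: i for i, lab in enumerate(labels)}
        nodes = list(dt.preorder_node_iter())
        idx: dict = {}
        next_internal = n_tips
        for nd in nodes:
            if nd.is_leaf():
                idx[nd] = tip_idx[nd.taxon.label]
            else:
                idx[nd] = next_internal
                next_internal += 1
        n_nodes = next_internal
        parent = np.full(n_nodes, -1, dtype=int)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        depth = np.zeros(n_nodes)
        for nd in nodes:
            v = idx[nd]
            if nd.parent_node is not None:
                p = idx[nd.parent_node]
                parent[v] = p
                children[p].append(v)
                depth[v] = depth[p] + (nd.edge.length or 0.0)
        # convert depths to ages
        tip_ages = tip_ages or {}
        offsets = [depth[tip_idx[lab]] + tip_ages.get(lab, 0.0) for lab in labels]
        total = max(offsets)
        age = total - depth
        return cls(labels, parent, children, age)


def sample_coalescent(labels, ne: float, rng: np.random.Generator,
                      tip_ages: dict[str, float] | None = None) -> TimeTree:
    """Draw a (heterochronous) Kingman coalescent tree with population size
    ``ne`` in years; tips without an entry in ``tip_ages`` are at age 0."""
    labels = list(labels)
    n = len(labels)
    tip_ages = tip_ages or {}
    ages = np.zeros(2 * n - 1)
    for i, lab in enumerate(labels):
        ages[i] = tip_ages.get(lab, 0.0)
    parent = np.full(2 * n - 1, -1, dtype=int)
    children: list[list[int]] = [[] for _ in range(2 * n - 1)]
    pending = sorted(range(n), key=lambda i: ages[i])
    t = 0.0
    active: list[int] = []
    next_node = n
    while pending or len(active) > 1:
        while pending and ages[pending[0]] <= t:
            active.append(pending.pop(0))
        k = len(active)
        if k < 2:
            t = ages[pending[0]]
            continue
        wait = rng.exponential(ne / (k * (k - 1) / 2))
        if pending and t + wait > ages[pending[0]]:
            t = ages[pending[0]]
            continue
        t += wait
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[i], active[j]
        ages[next_node] = t
        parent[a] = parent[b] = next_node
        children[next_node] = [a, b]
        active = [x for x in active if x not in (a, b)] + [next_node]
        next_node += 1
    return TimeTree(labels, parent, children, ages)


# ---------------------------------------------------------------------------
# Substitution / clock models


@dataclass(frozen=True)
class SubstitutionModel:
    """Two-state CTMC, optionally with Tuffley-Steel covarion switching.

    ``mu`` is the base clock rate in expected substitutions per character per
    year (the visible generator is normalized to one expected substitution
    per unit of ``mu * time``).  ``switch_rate`` is the covarion on/off
    toggle rate per year; ``f_on`` the stationary frequency of the "on"
    hidden state.
    """

    kind: str = "two-state"  # or "covarion"
    pi1: float = 0.5
    mu: float = 3e-4
    switch_rate: float = 0.0
    f_on: float = 0.5

    def __post_init__(self):
        if not 0 < self.pi1 < 1:
            raise DataError(f"pi1 must be in (0,1), got {self.pi1}")
        if self.mu <= 0:
            raise DataError("mu must be positive")
        if self.switch_rate < 0:
            raise DataError("switch rate must be nonnegative")
        if self.kind not in ("two-state", "covarion"):
            raise DataError(f"unknown substitution model kind {self.kind!r}")

    @property
    def n_states(self) -> int:
        return 2 if self.kind == "two-state" else 4

    def root_freqs(self) -> np.ndarray:
        pi = np.array([1 - self.pi1, self.pi1])
        if self.kind == "two-state":
            return pi
        f = np.array([self.f_on, 1 - self.f_on])
        return np.concatenate([pi * f[0], pi * f[1]])  # (0on,1on,0off,1off)

    def generator(self) -> np.ndarray:
        """Per-(mu*year) generator for the visible or joint process."""
        pi0, pi1 = 1 - self.pi1, self.pi1
        norm = 2 * pi0 * pi1
        q = np.array([[-pi1, pi1], [pi0, -pi0]]) / norm
        if self.kind == "two-state":
            return q
        # joint 4-state generator in per-year units divided by mu so branch
        # lengths can stay mu * duration; switching therefore scales as s/mu
        s = self.switch_rate / self.mu
        f_on, f_off = self.f_on, 1 - self.f_on
        g = np.zeros((4, 4))
        g[:2, :2] = q
        g[0, 2] = g[1, 3] = s * f_off
        g[2, 0] = g[3, 1] = s * f_on
        np.fill_diagonal(g, 0)
        np.fill_diagonal(g, -g.sum(axis=1))
        return g

    def transition_matrix(self, length: float) -> np.ndarray:
        """P(length) for a branch of ``length = mu * duration * mult``."""
        if not np.isfinite(length) or length < 0:
            raise NumericError(f"bad branch length {length}")
        if self.kind == "two-state":
            pi = self.root_freqs()
            decay = math.exp(-length / (2 * pi[0] * pi[1]))
            return pi[None, :] + (np.eye(2) - pi[None, :]) * decay
        return expm(self.generator() * length)


@dataclass(frozen=True)
class ClockModel:
    """Strict clock or uncorrelated lognormal relaxed clock."""

    kind: str = "strict"  # or "relaxed-lognormal"
    log_sd: float = 0.5

    def __post_init__(self):
        if self.kind not in ("strict", "relaxed-lognormal"):
            raise DataError(f"unknown clock kind {self.kind!r}")

    def log_prior_mult(self, mult: np.ndarray) -> float:
        """Log density of branch multipliers (lognormal with real mean 1)."""
        if self.kind == "strict":
            return 0.0
        s = self.log_sd
        x = np.log(mult)
        return float(np.sum(-0.5 * ((x + s * s / 2) / s) ** 2 - x - math.log(s * math.sqrt(2 * math.pi))))


# ---------------------------------------------------------------------------
# Likelihood


def _tip_partials(m: BinaryCharacterMatrix, labels, n_states: int) -> np.ndarray:
    """(n_tips, n_states, n_chars) conditional likelihoods at the tips."""
    idx = []
    for lab in labels:
        if lab not in m.taxa:
            raise DataError(f"tip {lab!r} not in character matrix")
        idx.append(m.taxa.index(lab))
    x = m.cells[idx]  # (n_tips, n_chars)
    n_tips, n_chars = x.shape
    part = np.ones((n_tips, n_states, n_chars))  # missing: likelihood 1 everywhere
    absent = np.array([1, 0] * (n_states // 2), dtype=float)
    present = np.array([0, 1] * (n_states // 2), dtype=float)
    for s in range(n_states):
        col = part[:, s, :]
        col[x == 0] = absent[s]
        col[x == 1] = present[s]
    return part


def _pruning(tree: TimeTree, tip_part: np.ndarray, sub: SubstitutionModel) -> np.ndarray:
    """Per-character log-likelihoods by Felsenstein pruning with rescaling."""
    n_states, n_chars = tip_part.shape[1:]
    partial = np.empty((tree.n_nodes, n_states, n_chars))
    scale = np.zeros(n_chars)
    pmat = {}
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p >= 0:
            duration = tree.age[p] - tree.age[v]
            if not np.isfinite(duration):
                raise NumericError(f"non-finite branch duration above node {v}")
            pmat[v] = sub.transition_matrix(sub.mu * duration * tree.rate_mult[v])
    for v in tree.postorder():
        if tree.is_tip(v):
            partial[v] = tip_part[v]
        else:
            acc = np.ones((n_states, n_chars))
            for c in tree.children[v]:
                acc *= pmat[c] @ partial[c]
            mx = acc.max(axis=0)
            mx = np.where(mx > 0, mx, 1.0)
            scale += np.log(mx)
            partial[v] = acc / mx
    root_lik = sub.root_freqs() @ partial[tree.root]
    with np.errstate(divide="ignore"):
        return np.log(root_lik) + scale


def pruning_loglik(tree: TimeTree, m: BinaryCharacterMatrix, sub: SubstitutionModel,
                   clock: ClockModel | None = None, per_char: bool = False):
    """Log-likelihood of the binary matrix on the tree (no ascertainment).

    The clock model only documents how ``tree.rate_mult`` was generated; the
    multipliers themselves live on the tree.
    """
    tip_part = _tip_partials(m, tree.labels, sub.n_states)
    ll = _pruning(tree, tip_part, sub)
    return ll if per_char else float(ll.sum())


def allzero_log_prob(tree: TimeTree, sub: SubstitutionModel) -> float:
    """Log probability of the unobservable all-absent pattern."""
    n_states = sub.n_states
    tip = np.zeros((tree.n_tips, n_states, 1))
    for s in range(0, n_states, 2):
        tip[:, s, 0] = 1.0
    return float(_pruning(tree, tip, sub)[0])


def ascertainment_correct(tree: TimeTree, m: BinaryCharacterMatrix,
                          sub: SubstitutionModel, clock: ClockModel | None = None,
                          per_char: bool = False):
    """Log-likelihood conditioned on each character being present somewhere.

    Per character: ``log L(pattern) - log(1 - L(all-zero))``.
    """
    l0 = allzero_log_prob(tree, sub)
    denom = 1.0 - math.exp(l0)
    if denom <= 0:
        raise NumericError(f"ascertainment denominator {denom} <= 0")
    ll = pruning_loglik(tree, m, sub, clock, per_char=True) - math.log(denom)
    return ll if per_char else float(ll.sum())


# ---------------------------------------------------------------------------
# Priors and MCMC


@dataclass(frozen=True)
class TruncatedNormalPrior:
    mean: float
    sd: float
    low: float
    high: float

    def logpdf(self, x: float) -> float:
        if not self.low <= x <= self.high:
            return -np.inf
        return -0.5 * ((x - self.mean) / self.sd) ** 2


@dataclass(frozen=True)
class PriorConfig:
    """Priors for the cognate-evolution MCMC.

    Defaults encode the standard calibration for Koreanic-style data: a
    lognormal clock-rate prior with real-space mean 3e-4 substitutions per
    character per year and log-sd 0.7, and (when a dated tip is declared) a
    truncated normal sampling-age prior, mean 500 y, sd 100 y, truncated to
    [87, 870] y, reflecting the age span of the source documents.
    """

    clock_rate_mean: float = 3e-4
    clock_rate_log_sd: float = 0.7
    tip_age_priors: dict = field(default_factory=dict)  # label -> TruncatedNormalPrior
    ne_log_mean: float = math.log(1000.0)
    ne_log_sd: float = 1.5
    switch_rate_rate: float = 1000.0  # exponential prior mean 1/rate per year

    def log_clock_rate(self, mu: float) -> float:
        s = self.clock_rate_log_sd
        m = math.log(self.clock_rate_mean) - s * s / 2
        return -0.5 * ((math.log(mu) - m) / s) ** 2 - math.log(mu)

    def log_ne(self, ne: float) -> float:
        return -0.5 * ((math.log(ne) - self.ne_log_mean) / self.ne_log_sd) ** 2 - math.log(ne)


@dataclass(frozen=True)
class ChainConfig:
    n_iter: int = 20000
    burnin_frac: float = 0.1
    thin: int = 20
    max_retained: int = 10000


@dataclass
class PosteriorSample:
    """Post-burn-in MCMC output: trees, parameters, and log posteriors."""

    trees: list[TimeTree]
    params: list[dict]
    log_posts: list[float]
    seed: int
    n_iter: int
    burnin: int
    acceptance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.trees:
            raise DataError("posterior sample is empty")


def coalescent_log_density(tree: TimeTree, ne: float) -> float:
    events = sorted(
        [(tree.age[v], +1) for v in range(tree.n_tips)]
        + [(tree.age[v], -1) for v in range(tree.n_tips, tree.n_nodes)]
    )
    ll, k, t_prev = 0.0, 0, 0.0
    for t, kind in events:
        if k >= 2:
            ll -= k * (k - 1) / 2 * (t - t_prev) / ne
        if kind == -1:
            ll -= math.log(ne)
            k -= 1
        else:
            k += 1
        t_prev = t
    return ll


class _McmcState:
    def __init__(self, tree, sub, clock, ne):
        self.tree = tree
        self.sub = sub
        self.clock = clock
        self.ne = ne


def _log_prior(state: _McmcState, priors: PriorConfig) -> float:
    lp = coalescent_log_density(state.tree, state.ne) + priors.log_ne(state.ne)
    lp += priors.log_clock_rate(state.sub.mu)
    for lab, pr in priors.tip_age_priors.items():
        v = state.tree.labels.index(lab)
        lp += pr.logpdf(state.tree.age[v])
    if state.sub.kind == "covarion":
        lp += -priors.switch_rate_rate * state.sub.switch_rate
    if state.clock.kind == "relaxed-lognormal":
        lp += state.clock.log_prior_mult(state.tree.rate_mult[_branch_nodes(state.tree)])
    return lp


def _branch_nodes(tree: TimeTree) -> np.ndarray:
    return np.array([v for v in range(tree.n_nodes) if v != tree.root])


def mcmc_run(m: BinaryCharacterMatrix | None, priors: PriorConfig, chain: ChainConfig,
             seed: int, sub: SubstitutionModel | None = None,
             clock: ClockModel | None = None, labels=None) -> PosteriorSample:
    """Metropolis-Hastings sampler over trees and model parameters.

    ``m=None`` runs the chain under the prior alone (likelihood identically
    zero), which is how the calibration priors are validated.  Deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    sub = sub or SubstitutionModel()
    clock = clock or ClockModel()
    if labels is None:
        if m is None:
            raise DataError("prior-only run needs explicit labels")
        labels = list(m.taxa)
    if len(labels) < 3:
        raise DataError("need at least 3 taxa")
    tip_ages = {lab: pr.mean for lab, pr in priors.tip_age_priors.items()}
    ne0 = math.exp(priors.ne_log_mean)
    tree = sample_coalescent(labels, ne0, rng, tip_ages)
    if clock.kind == "relaxed-lognormal":
        s = clock.log_sd
        tree.rate_mult[:] = np.exp(rng.normal(-s * s / 2, s, tree.n_nodes))
        tree.rate_mult[tree.root] = 1.0
    state = _McmcState(tree, sub, clock, ne0)

    def loglik(st: _McmcState) -> float:
        if m is None:
            return 0.0
        return ascertainment_correct(st.tree, m, st.sub, st.clock)

    cur_ll = loglik(state)
    cur_lp = _log_prior(state, priors)
    dated = [labels.index(lab) for lab in priors.tip_age_priors]
    moves = ["age", "root", "narrow", "wide", "mu", "pi1", "ne"]
    weights = [4, 1, 3, 2, 1, 1, 1]
    if dated:
        moves.append("tipdate")
        weights.append(1)
    if sub.kind == "covarion":
        moves.append("switch")
        weights.append(1)
    if clock.kind == "relaxed-lognormal":
        moves.append("mult")
        weights.append(3)
    weights = np.array(weights, float) / sum(weights)
    n_acc = {mv: 0 for mv in moves}
    n_try = {mv: 0 for mv in moves}

    trees, params, lposts = [], [], []
    burnin = int(chain.n_iter * chain.burnin_frac)
    for it in range(chain.n_iter):
        mv = rng.choice(moves, p=weights)
        n_try[mv] += 1
        prop = _McmcState(state.tree.copy(), state.sub, state.clock, state.ne)
        log_hastings = 0.0
        ok = True
        t = prop.tree
        if mv == "age":
            internal = [v for v in range(t.n_tips, t.n_nodes) if v != t.root]
            if internal:
                v = int(rng.choice(internal))
                lo = max(t.age[c] for c in t.children[v])
                hi = t.age[t.parent[v]]
                t.age[v] = rng.uniform(lo, hi)
            else:
                ok = False
        elif mv == "root":
            base = max(t.age[c] for c in t.children[t.root])
            e = t.age[t.root] - base
            e2 = e * math.exp(0.5 * (rng.random() - 0.5))
            t.age[t.root] = base + e2
            log_hastings = math.log(e2 / e) if e > 0 else 0.0
        elif mv == "tipdate":
            v = int(rng.choice(dated))
            pr = priors.tip_age_priors[labels[v]]
            hi = min(pr.high, t.age[t.parent[v]])
            if hi <= pr.low:
                ok = False
            else:
                t.age[v] = rng.uniform(pr.low, hi)
        elif mv == "narrow":
            ok = _narrow_exchange(t, rng)
        elif mv == "wide":
            ok = _wide_exchange(t, rng)
        elif mv == "mu":
            f = math.exp(0.3 * (rng.random() - 0.5))
            prop.sub = replace(state.sub, mu=state.sub.mu * f)
            log_hastings = math.log(f)
        elif mv == "pi1":
            p2 = state.sub.pi1 + rng.normal(0, 0.08)
            if 0.01 < p2 < 0.99:
                prop.sub = replace(state.sub, pi1=p2)
            else:
                ok = False
        elif mv == "switch":
            f = math.exp(0.4 * (rng.random() - 0.5))
            s2 = max(state.sub.switch_rate, 1e-8) * f
            prop.sub = replace(state.sub, switch_rate=s2)
            log_hastings = math.log(f)
        elif mv == "ne":
            f = math.exp(0.6 * (rng.random() - 0.5))
            prop.ne = state.ne * f
            log_hastings = math.log(f)
        elif mv == "mult":
            v = int(rng.choice(_branch_nodes(t)))
            f = math.exp(0.3 * (rng.random() - 0.5))
            t.rate_mult[v] *= f
            log_hastings = math.log(f)
        if ok:
            try:
                new_lp = _log_prior(prop, priors)
                new_ll = loglik(prop) if np.isfinite(new_lp) else -np.inf
            except NumericError:
                new_lp = new_ll = -np.inf
            log_alpha = (new_ll + new_lp) - (cur_ll + cur_lp) + log_hastings
            if math.log(rng.random() + 1e-300) < log_alpha:
                state, cur_ll, cur_lp = prop, new_ll, new_lp
                n_acc[mv] += 1
        if it >= burnin and (it - burnin) % chain.thin == 0:
            trees.append(state.tree.copy())
            params.append({"mu": state.sub.mu, "pi1": state.sub.pi1,
                           "switch_rate": state.sub.switch_rate, "ne": state.ne,
                           "loglik": cur_ll})
            lposts.append(cur_ll + cur_lp)
    if len(trees) > chain.max_retained:
        keep = np.linspace(0, len(trees) - 1, chain.max_retained).astype(int)
        trees = [trees[i] for i in keep]
        params = [params[i] for i in keep]
        lposts = [lposts[i] for i in keep]
    acc = {mv: (n_acc[mv] / n_try[mv] if n_try[mv] else 0.0) for mv in moves}
    if all(a == 0 for a in acc.values()):
        import logging
        logging.getLogger(__name__).warning("zero acceptance across all moves: %s", acc)
    return PosteriorSample(trees, params, lposts, seed, chain.n_iter, burnin, acc)


def _narrow_exchange(t: TimeTree, rng) -> bool:
    """Swap a node's sibling with one of its children (age-valid NNI)."""
    cand = [v for v in range(t.n_tips, t.n_nodes)
            if v != t.root and not t.is_tip(v)]
    if not cand:
        return False
    c = int(rng.choice(cand))
    p = t.parent[c]
    sib = [u for u in t.children[p] if u != c][0]
    x = int(rng.choice(t.children[c]))
    if not t.age[c] > t.age[sib]:
        return False
    t.children[p] = [u if u != sib else x for u in t.children[p]]
    t.children[c] = [u if u != x else sib for u in t.children[c]]
    t.parent[sib], t.parent[x] = c, p
    return True


def _wide_exchange(t: TimeTree, rng) -> bool:
    """Swap two non-nested subtrees chosen uniformly (reject if invalid)."""
    nodes = [v for v in range(t.n_nodes) if v != t.root]
    i, j = rng.choice(len(nodes), size=2, replace=False)
    a, b = nodes[i], nodes[j]
    pa, pb = t.parent[a], t.parent[b]
    if pa == pb:
        return False
    # ancestry check
    u = pa
    while u >= 0:
        if u == b:
            return False
        u = t.parent[u]
    u = pb
    while u >= 0:
        if u == a:
            return False
        u = t.parent[u]
    if not (t.age[pa] > t.age[b] and t.age[pb] > t.age[a]):
        return False
    t.children[pa] = [u if u != a else b for u in t.children[pa]]
    t.children[pb] = [u if u != b else a for u in t.children[pb]]
    t.parent[a], t.parent[b] = pb, pa
    return True


# ---------------------------------------------------------------------------
# Posterior summaries


def clade_frequencies(sample: PosteriorSample) -> dict[frozenset[str], float]:
    counts: dict[frozenset[str], int] = {}
    for tr in sample.trees:
        for clade in tr.clades():
            counts[clade] = counts.get(clade, 0) + 1
    n = len(sample.trees)
    return {c: k / n for c, k in counts.items()}


def mcc_tree(sample: PosteriorSample) -> tuple[TimeTree, dict[frozenset[str], float]]:
    """Maximum clade credibility tree with support and median-height
    annotations.

    Returns the sampled tree maximizing the product of its clades' posterior
    frequencies, its node ages replaced by posterior median ages per clade,
    plus the clade-support map.
    """
    freqs = clade_frequencies(sample)
    heights: dict[frozenset[str], list[float]] = {}
    for tr in sample.trees:
        for clade, v in tr.clades().items():
            heights.setdefault(clade, []).append(tr.age[v])
    best, best_score = None, -np.inf
    for tr in sample.trees:
        score = sum(math.log(freqs[c]) for c in tr.clades())
        if score > best_score:
            best, best_score = tr, score
    out = best.copy()
    for clade, v in out.clades().items():
        out.age[v] = float(np.median(heights[clade]))
    # medians can violate parent>child order in pathological samples; nudge
    for v in out.postorder():
        p = out.parent[v]
        if p >= 0 and out.age[p] <= out.age[v]:
            out.age[p] = out.age[v] * (1 + 1e-9) + 1e-12
    out.support = {clade: freqs[clade] for clade in out.clades()}
    return out, freqs


def topology_table(sample: PosteriorSample) -> list[dict]:
    """Sampled-topology frequency table with per-group mean clade ages."""
    groups: dict[str, list[TimeTree]] = {}
    for tr in sample.trees:
        groups.setdefault(tr.topology_key(), []).append(tr)
    n = len(sample.trees)
    out = []
    for key, trs in sorted(groups.items(), key=lambda kv: -len(kv[1])):
        rep = trs[0].copy()
        ages: dict[frozenset[str], list[float]] = {}
        for tr in trs:
            for clade, v in tr.clades().items():
                ages.setdefault(clade, []).append(tr.age[v])
        for clade, v in rep.clades().items():
            rep.age[v] = float(np.mean(ages[clade]))
        out.append({"topology": key, "frequency": len(trs) / n, "tree": rep,
                    "count": len(trs)})
    return out


def majority_consensus_clades(sample: PosteriorSample, threshold: float = 0.5):
    return {c for c, f in clade_frequencies(sample).items() if f > threshold}
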