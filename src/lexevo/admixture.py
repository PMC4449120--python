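"""Bayesian admixture clustering of variants from binary cognate profiles.

Each language variant is treated as a haploid individual; each cognate-class
column is a biallelic locus.  Under the admixture model a variant ``i``
carries cluster proportions ``Q[i]`` on the K-simplex; the allele at each
locus is drawn from a cluster chosen from ``Q[i]``, with per-cluster
presence frequencies ``P[k, l]``.  A Gibbs sampler alternates the
conjugate updates for assignments Z, frequencies P (Beta(1,1) prior) and
proportions Q (symmetric Dirichlet(alpha)), with a Metropolis step for the
shared concentration alpha under a uniform prior on (0, 10).

Model choice across K uses the deviance-style marginal-likelihood
approximation standard in this literature: ``LnP(D|K) = mean(L) -
var(L)/2`` over the retained per-sweep log-likelihoods, with the Evanno
second-difference statistic DeltaK selecting the strongest change point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .cognate import BinaryCharacterMatrix
from .errors import DataError

ALPHA_MAX = 10.0


@dataclass
class AdmixtureState:
    """Current Gibbs-sampler state for one chain."""

    k: int
    p: np.ndarray      # (K, n_loci) presence frequencies in (0,1)
    q: np.ndarray      # (n_taxa, K) proportions, rows on the simplex
    z: np.ndarray      # (n_taxa, n_loci) cluster assignments (int)
    alpha: float

    def __post_init__(self):
        if self.alpha <= 0:
            raise DataError("alpha must be positive")
        if not np.allclose(self.q.sum(axis=1), 1.0):
            raise DataError("Q rows must sum to 1")


@dataclass
class AdmixtureRun:
    """Posterior summary of one chain at fixed K."""

    k: int
    ln_p_d: float                 # deviance-based marginal-likelihood estimate
    q_mean: np.ndarray            # (n_taxa, K)
    p_mean: np.ndarray            # (K, n_loci)
    taxa: list[str]
    seed: int
    burnin: int
    sweeps: int
    loglik_trace: np.ndarray = field(repr=False, default=None)


def _loglik(x: np.ndarray, obs: np.ndarray, p: np.ndarray, q: np.ndarray) -> float:
    """log P(X | P, Q) with Z marginalized, missing cells skipped."""
    # mix[i, l] = sum_k q[i,k] * (p[k,l] if x=1 else 1-p[k,l])
    on = q @ p                # (n, L) probability of allele 1
    lik = np.where(x == 1, on, 1.0 - on)
    return float(np.sum(np.log(np.clip(lik[obs], 1e-300, None))))


def initial_state(m: BinaryCharacterMatrix, k: int, rng: np.random.Generator) -> AdmixtureState:
    n, loci = m.shape
    p = rng.uniform(0.2, 0.8, size=(k, loci))
    q = rng.dirichlet(np.ones(k), size=n)
    z = rng.integers(0, k, size=(n, loci))
    return AdmixtureState(k, p, q, z, alpha=1.0)


def gibbs_sweep(state: AdmixtureState, m: BinaryCharacterMatrix,
                rng: np.random.Generator, sample_alpha: bool = True) -> AdmixtureState:
    """One full Gibbs sweep (Z, P, Q, then a Metropolis step on alpha).

    ``sample_alpha=False`` keeps the Dirichlet concentration fixed, which
    makes the posterior analytically enumerable on toy matrices.
    """
    x = m.cells
    obs = m.observed()
    n, loci = x.shape
    k = state.k
    p, q, z, alpha = state.p, state.q, state.z.copy(), state.alpha

    # Z | P, Q  (vectorized per taxon)
    for i in range(n):
        li = np.where(x[i] == 1, p, 1.0 - p)          # (K, L)
        w = q[i][:, None] * li
        w_sum = w.sum(axis=0)
        w_sum[w_sum <= 0] = 1.0
        cdf = np.cumsum(w / w_sum, axis=0)
        u = rng.random(loci)
        z[i] = (u[None, :] > cdf).sum(axis=0)
    # P | Z  with Beta(1,1) prior; missing cells contribute nothing
    p_new = np.empty_like(p)
    for kk in range(k):
        mask = (z == kk) & obs
        n1 = ((x == 1) & mask).sum(axis=0)
        n0 = ((x == 0) & mask).sum(axis=0)
        p_new[kk] = rng.beta(1 + n1, 1 + n0)
    # Q | Z  (Dirichlet(alpha + counts), observed cells only)
    q_new = np.empty_like(q)
    for i in range(n):
        counts = np.bincount(z[i][obs[i]], minlength=k)
        q_new[i] = rng.dirichlet(alpha + counts)
    # alpha | Q  via random-walk Metropolis, uniform prior on (0, ALPHA_MAX)
    prop = alpha + rng.normal(0, 0.25)
    if sample_alpha and 0 < prop < ALPHA_MAX:
        def ldir(a):
            return n * (math.lgamma(k * a) - k * math.lgamma(a)) + (a - 1) * float(
                np.sum(np.log(np.clip(q_new, 1e-300, None))))
        if math.log(rng.random() + 1e-300) < ldir(prop) - ldir(alpha):
            alpha = prop
    p_new = np.clip(p_new, 1e-9, 1 - 1e-9)
    return AdmixtureState(k, p_new, q_new, z, alpha)


def run_chain(m: BinaryCharacterMatrix, k: int, burnin: int, sweeps: int,
              seed: int) -> AdmixtureRun:
    """One seeded chain: ``burnin`` discarded sweeps then ``sweeps`` retained."""
    if k < 1:
        raise DataError("K must be >= 1")
    if sweeps < 1 or burnin < 0:
        raise DataError("need at least one retained sweep and nonnegative burn-in")
    rng = np.random.default_rng(seed)
    state = initial_state(m, k, rng)
    obs = m.observed()
    q_acc = np.zeros_like(state.q)
    p_acc = np.zeros_like(state.p)
    ll = np.empty(sweeps)
    for t in range(burnin + sweeps):
        state = gibbs_sweep(state, m, rng)
        if t >= burnin:
            i = t - burnin
            ll[i] = _loglik(m.cells, obs, state.p, state.q)
            q_acc += state.q
            p_acc += state.p
    mean_l = float(ll.mean())
    ln_p_d = mean_l - float(ll.var()) / 2.0
    return AdmixtureRun(k, ln_p_d, q_acc / sweeps, p_acc / sweeps,
                        list(m.taxa), seed, burnin, sweeps, ll)


def run_k(m: BinaryCharacterMatrix, k: int, n_runs: int, burnin: int,
          sweeps: int, seed: int) -> list[AdmixtureRun]:
    """Independent seeded chains at fixed K (deterministic per seed)."""
    child = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_runs)
    return [run_chain(m, k, burnin, sweeps, int(s)) for s in child]


# ---------------------------------------------------------------------------
# Evanno Delta K


def evanno_delta_k(runs_by_k: dict[int, list[AdmixtureRun]]) -> pd.DataFrame:
    """Mean/SD of LnP(D) per K and the Evanno second-difference statistic.

    ``DeltaK(K) = |L(K-1) - 2 L(K) + L(K+1)| / sd(L(K))``; undefined (NaN)
    at the endpoints of the K range and wherever sd is 0.
    """
    ks = sorted(runs_by_k)
    mean = {k: float(np.mean([r.ln_p_d for r in runs_by_k[k]])) for k in ks}
    sd = {k: float(np.std([r.ln_p_d for r in runs_by_k[k]], ddof=1))
          if len(runs_by_k[k]) > 1 else 0.0 for k in ks}
    rows = []
    for k in ks:
        dk = np.nan
        if k - 1 in mean and k + 1 in mean and sd[k] > 0:
            dk = abs(mean[k - 1] - 2 * mean[k] + mean[k + 1]) / sd[k]
        rows.append({"K": k, "mean_lnp": mean[k], "sd_lnp": sd[k],
                     "n_runs": len(runs_by_k[k]), "delta_k": dk})
    return pd.DataFrame(rows)


def select_k(table: pd.DataFrame, plateau_frac: float = 0.01) -> int:
    """Pick K* as argmax DeltaK; if DeltaK is nowhere defined fall back to
    the mean-likelihood plateau (smallest K whose gain over the previous K
    drops below ``plateau_frac`` of the mean likelihood's magnitude)."""
    valid = table.dropna(subset=["delta_k"])
    if len(valid) and valid["delta_k"].max() > 0:
        return int(valid.loc[valid["delta_k"].idxmax(), "K"])
    t = table.sort_values("K").reset_index(drop=True)
    l = t["mean_lnp"].to_numpy()
    for i in range(1, len(l)):
        if (l[i] - l[i - 1]) < plateau_frac * abs(l[i - 1]):
            return int(t.loc[i - 1, "K"])
    return int(t.loc[len(t) - 1, "K"])


# ---------------------------------------------------------------------------
# Label alignment across runs


def _permute_run(run: AdmixtureRun, perm: tuple[int, ...]) -> AdmixtureRun:
    return AdmixtureRun(run.k, run.ln_p_d, run.q_mean[:, list(perm)],
                        run.p_mean[list(perm), :], run.taxa, run.seed,
                        run.burnin, run.sweeps, run.loglik_trace)


def align_labels(runs: list[AdmixtureRun]) -> list[AdmixtureRun]:
    """Permute cluster labels of each run to match the first run's Q.

    Exact search over all K! permutations for K <= 8 (minimizing the
    Frobenius distance between Q matrices); greedy matching beyond that.
    """
    if not runs:
        return []
    k = runs[0].k
    if any(r.k != k or r.taxa != runs[0].taxa for r in runs):
        raise DataError("runs must share K and taxa")
    ref = runs[0].q_mean
    out = [runs[0]]
    for run in runs[1:]:
        if k <= 8:
            best, best_cost = None, np.inf
            for perm in permutations(range(k)):
                cost = float(np.sum((run.q_mean[:, list(perm)] - ref) ** 2))
                if cost < best_cost:
                    best, best_cost = perm, cost
        else:  # greedy column matching
            remaining = list(range(k))
            best = []
            for col in range(k):
                costs = [float(np.sum((run.q_mean[:, c] - ref[:, col]) ** 2))
                         for c in remaining]
                pick = remaining.pop(int(np.argmin(costs)))
                best.append(pick)
            best = tuple(best)
        out.append(_permute_run(run, best))
    return out


def mean_q(runs: list[AdmixtureRun]) -> pd.DataFrame:
    """Average aligned Q across runs; rows = taxa, columns = clusters."""
    aligned = align_labels(runs)
    q = np.mean([r.q_mean for r in aligned], axis=0)
    return pd.DataFrame(q, index=aligned[0].taxa,
                        columns=[f"cluster_{j + 1}" for j in range(aligned[0].k)])


def admixed_taxa(q: pd.DataFrame, threshold: float = 0.10) -> list[str]:
    """Taxa whose minority ancestry exceeds ``threshold`` (default 10%)."""
    minor = 1.0 - q.max(axis=1)
    return list(q.index[minor > threshold])
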