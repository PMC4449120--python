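"""Likelihood machinery and MCMC for the binary cognate model."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from lexevo import synth
from lexevo.cognate import MISSING, BinaryCharacterMatrix
from lexevo.errors import NumericError
from lexevo.phylo import (
    ChainConfig,
    ClockModel,
    PosteriorSample,
    PriorConfig,
    SubstitutionModel,
    TimeTree,
    TruncatedNormalPrior,
    allzero_log_prob,
    ascertainment_correct,
    majority_consensus_clades,
    mcc_tree,
    mcmc_run,
    pruning_loglik,
    sample_coalescent,
    topology_table,
)


def brute_force_loglik(tree, states, sub):
    """Sum over all internal-node state assignments (the pruning oracle).

    Tips marginalize the hidden covarion state: a visible tip state ``s``
    is compatible with joint states ``s`` (on) and ``s + 2`` (off).
    """
    pm = {}
    for v in range(tree.n_nodes):
        p = tree.parent[v]
        if p >= 0:
            pm[v] = sub.transition_matrix(
                sub.mu * (tree.age[p] - tree.age[v]) * tree.rate_mult[v])
    pi = sub.root_freqs()
    tip_states = {
        v: ([states[v]] if sub.n_states == 2 else [states[v], states[v] + 2])
        for v in range(tree.n_tips)
    }
    total = 0.0
    n_internal = tree.n_nodes - tree.n_tips
    for assign in itertools.product(range(sub.n_states), repeat=n_internal):
        st = [None] * tree.n_tips + list(assign)
        pr = pi[st[tree.root]]
        for v in range(tree.n_nodes):
            p = tree.parent[v]
            if p < 0:
                continue
            if tree.is_tip(v):
                pr *= sum(pm[v][st[p], s] for s in tip_states[v])
            else:
                pr *= pm[v][st[p], st[v]]
        total += pr
    return math.log(total)


def random_time_tree(n, rng):
    return sample_coalescent([f"t{i}" for i in range(n)], 1000.0, rng)


def tip_states_to_matrix(tree, patterns):
    cells = np.array(patterns, dtype=np.int8).T
    chars = [("m", str(j)) for j in range(cells.shape[1])]
    return BinaryCharacterMatrix(list(tree.labels), chars, cells)


class TestPruning:
    @pytest.mark.parametrize("kind", ["two-state", "covarion"])
    def test_matches_brute_force_on_random_trees(self, kind):
        """Criterion check: pruning == enumeration on <=5 taxa, 200 cases."""
        rng = np.random.default_rng(7)
        n_cases = 200
        for _ in range(n_cases):
            n = int(rng.integers(3, 6))
            tree = random_time_tree(n, rng)
            sub = SubstitutionModel(
                kind=kind, pi1=float(rng.uniform(0.2, 0.8)),
                mu=float(10 ** rng.uniform(-4.5, -3.0)),
                switch_rate=float(rng.uniform(0, 1e-3)) if kind == "covarion" else 0.0,
                f_on=float(rng.uniform(0.3, 0.7)) if kind == "covarion" else 0.5)
            pattern = rng.integers(0, 2, size=n)
            # fold covarion tip states onto visible 0/1
            vis = [int(s) for s in pattern]
            m = tip_states_to_matrix(tree, [vis])
            got = pruning_loglik(tree, m, sub)
            want = brute_force_loglik(tree, vis, sub)
            assert got == pytest.approx(want, abs=1e-8)

    def test_covarion_reduces_to_two_state(self, three_taxon_tree):
        m = tip_states_to_matrix(three_taxon_tree, [[1, 0, 1], [0, 1, 1]])
        two = SubstitutionModel(pi1=0.3, mu=2e-4)
        cov = SubstitutionModel(kind="covarion", pi1=0.3, mu=2e-4,
                                switch_rate=0.0, f_on=1 - 1e-12)
        got = pruning_loglik(three_taxon_tree, m, cov, per_char=True)
        want = pruning_loglik(three_taxon_tree, m, two, per_char=True)
        assert np.allclose(got, want, atol=1e-10)

    def test_zero_branch_lengths_limit(self):
        tree = TimeTree(["a", "b"], [2, 2, -1], [[], [], [0, 1]], [0.0, 0.0, 0.0])
        sub = SubstitutionModel(pi1=0.4)
        same = tip_states_to_matrix(tree, [[1, 1]])
        diff = tip_states_to_matrix(tree, [[1, 0]])
        assert pruning_loglik(tree, same, sub) == pytest.approx(math.log(0.4))
        assert pruning_loglik(tree, diff, sub) < -50  # underflow-guarded -inf

    def test_missing_cells_marginalized(self, three_taxon_tree):
        sub = SubstitutionModel(pi1=0.4, mu=2e-4)
        with_missing = tip_states_to_matrix(three_taxon_tree, [[1, MISSING, 0]])
        manual = np.logaddexp(
            pruning_loglik(three_taxon_tree,
                           tip_states_to_matrix(three_taxon_tree, [[1, 0, 0]]), sub),
            pruning_loglik(three_taxon_tree,
                           tip_states_to_matrix(three_taxon_tree, [[1, 1, 0]]), sub))
        assert pruning_loglik(three_taxon_tree, with_missing, sub) == pytest.approx(manual)


class TestAscertainment:
    @pytest.mark.parametrize("kind,n", [("two-state", 3), ("two-state", 4),
                                        ("covarion", 3)])
    def test_corrected_probabilities_sum_to_one(self, kind, n):
        """Conditioning on observability must renormalize the pattern law."""
        rng = np.random.default_rng(11)
        tree = random_time_tree(n, rng)
        sub = SubstitutionModel(kind=kind, pi1=0.35, mu=3e-4,
                                switch_rate=2e-4 if kind == "covarion" else 0.0)
        total = 0.0
        for pattern in itertools.product([0, 1], repeat=n):
            if not any(pattern):
                continue
            m = tip_states_to_matrix(tree, [list(pattern)])
            total += math.exp(ascertainment_correct(tree, m, sub))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_single_branch_closed_form(self):
        # two-tip star at zero duration: L(all-zero) = pi0, correction = pi1
        tree = TimeTree(["a", "b"], [2, 2, -1], [[], [], [0, 1]], [0.0, 0.0, 0.0])
        sub = SubstitutionModel(pi1=0.25)
        assert math.exp(allzero_log_prob(tree, sub)) == pytest.approx(0.75)
        m = tip_states_to_matrix(tree, [[1, 1]])
        assert ascertainment_correct(tree, m, sub) == pytest.approx(
            math.log(0.25) - math.log(1 - 0.75))

    def test_high_rate_limit_is_conditioned_bernoulli(self, three_taxon_tree):
        """mu -> infinity: tips i.i.d. Bernoulli(pi1) given >=1 presence."""
        sub = SubstitutionModel(pi1=0.3, mu=10.0)  # hundreds of expected changes
        p1, p0 = 0.3, 0.7
        for pattern in ([1, 0, 0], [1, 1, 0], [1, 1, 1]):
            m = tip_states_to_matrix(three_taxon_tree, [pattern])
            want = (p1 ** sum(pattern) * p0 ** (3 - sum(pattern))) / (1 - p0 ** 3)
            got = math.exp(ascertainment_correct(three_taxon_tree, m, sub))
            assert got == pytest.approx(want, rel=1e-6)

    def test_degenerate_denominator_raises(self, monkeypatch):
        # an all-zero probability of 1 is not reachable with pi1 in (0,1),
        # so drive the numeric guard directly
        tree = TimeTree(["a", "b"], [2, 2, -1], [[], [], [0, 1]], [0.0, 0.0, 1.0])
        m = tip_states_to_matrix(tree, [[1, 1]])
        monkeypatch.setattr("lexevo.phylo.allzero_log_prob", lambda *a, **k: 0.0)
        with pytest.raises(NumericError):
            ascertainment_correct(tree, m, SubstitutionModel())


class TestMcmc:
    def test_recovers_known_tree_clades(self):
        """Parameter recovery: >=6/7 true clades in >=90% of 20 seeded runs."""
        tree = synth.balanced_tree(8, depth=3000)
        cfg = synth.SimConfig(n_taxa=8, n_meanings=300, tree=tree,
                              replacement_rate=2.5e-4, switch_rate=0.0)
        true_clades = set(tree.clades().keys())
        good = 0
        for seed in range(20):
            lex, _ = synth.simulate_lexicon(cfg, seed)
            from lexevo.cognate import binarize

            m = binarize(lex)
            sample = mcmc_run(m, PriorConfig(), ChainConfig(n_iter=4000, thin=10),
                              seed=100 + seed)
            recovered = len(true_clades & majority_consensus_clades(sample))
            good += recovered >= 6
        assert good >= 18

    def test_prior_only_tip_age_matches_truncated_normal(self):
        """Sampling the prior alone reproduces the dated-tip calibration."""
        prior = TruncatedNormalPrior(500, 100, 87, 870)
        cfg = PriorConfig(tip_age_priors={"v8": prior})
        labels = [f"v{i + 1}" for i in range(8)]
        chain_means = []
        for seed in range(4):
            s = mcmc_run(None, cfg, ChainConfig(n_iter=30000, thin=20),
                         seed=seed, labels=labels)
            ages = [t.age[t.labels.index("v8")] for t in s.trees]
            chain_means.append(float(np.mean(ages)))
        a, b = (87 - 500) / 100, (870 - 500) / 100
        target = stats.truncnorm.mean(a, b, loc=500, scale=100)
        mc_se = np.std(chain_means, ddof=1) / math.sqrt(len(chain_means))
        assert abs(np.mean(chain_means) - target) <= 2 * mc_se + 1.0

    def test_fixed_seed_is_bit_identical(self, toy_matrix):
        m = BinaryCharacterMatrix(
            ["a", "b", "c", "d"], [("m", str(j)) for j in range(6)],
            np.array([[1, 0, 1, 0, 1, 1], [1, 0, 0, 1, 1, 0],
                      [0, 1, 1, 0, 0, 1], [0, 1, 0, 1, 0, 0]], dtype=np.int8))
        runs = [mcmc_run(m, PriorConfig(), ChainConfig(n_iter=500, thin=5), seed=9)
                for _ in range(2)]
        assert runs[0].log_posts == runs[1].log_posts
        assert [t.to_newick() for t in runs[0].trees] == \
               [t.to_newick() for t in runs[1].trees]

    def test_covarion_relaxed_chain_runs(self):
        tree = synth.balanced_tree(5, depth=2000)
        cfg = synth.SimConfig(n_taxa=5, n_meanings=60, tree=tree)
        lex, _ = synth.simulate_lexicon(cfg, 3)
        from lexevo.cognate import binarize

        s = mcmc_run(binarize(lex), PriorConfig(),
                     ChainConfig(n_iter=300, thin=10), seed=1,
                     sub=SubstitutionModel(kind="covarion", switch_rate=1e-4),
                     clock=ClockModel(kind="relaxed-lognormal"))
        assert len(s.trees) > 0
        assert all(np.isfinite(lp) for lp in s.log_posts)


class TestSummaries:
    def _sample_from(self, trees):
        return PosteriorSample(trees, [{} for _ in trees],
                               [0.0] * len(trees), seed=0, n_iter=0, burnin=0)

    def test_identical_trees_full_support(self):
        t = synth.balanced_tree(4, 1000)
        mcc, freqs = mcc_tree(self._sample_from([t.copy() for _ in range(5)]))
        assert all(f == 1.0 for f in freqs.values())
        assert mcc.topology_key() == t.topology_key()

    def test_three_to_one_topology_split(self):
        t1 = synth.balanced_tree(4, 1000, labels=list("abcd"))
        t2 = synth.balanced_tree(4, 1000, labels=list("acbd"))
        sample = self._sample_from([t1.copy(), t1.copy(), t1.copy(), t2.copy()])
        mcc, _ = mcc_tree(sample)
        assert mcc.topology_key() == t1.topology_key()
        table = topology_table(sample)
        assert [row["frequency"] for row in table] == [0.75, 0.25]

    def test_flat_posterior_support_one_third(self):
        trees = [synth.balanced_tree(4, 1000, labels=list(order))
                 for order in ("abcd", "acbd", "adbc")]
        # the three resolutions share only the root clade
        _, freqs = mcc_tree(self._sample_from(trees))
        nontrivial = [f for c, f in freqs.items() if 1 < len(c) < 4]
        assert max(nontrivial) == pytest.approx(1 / 3)

    def test_mcc_heights_are_posterior_medians(self):
        base = synth.balanced_tree(4, 1000)
        trees = []
        for scale in (0.8, 1.0, 1.2):
            t = base.copy()
            t.age[t.n_tips:] *= scale
            trees.append(t)
        mcc, _ = mcc_tree(self._sample_from(trees))
        root_ages = sorted(t.age[t.root] for t in trees)
        assert mcc.age[mcc.root] == pytest.approx(root_ages[1])
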