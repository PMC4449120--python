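# Methods

This note records the models, priors, numerical choices, and known
limitations behind each stage of the pipeline, and what the synthetic
validation does and does not establish.

## Data model and binary coding

A lexicon is a list of records `(variant, meaning, form, cognate_class)`.
Cognate-class labels are namespaced per meaning: the same label under two
meanings denotes two different characters. Binarization emits one
presence/absence column per attested `(meaning, class)` pair, ordered by
meaning order then sorted class label, so matrices are byte-stable across
runs. Three coding conventions, chosen where the literature is either
silent or split:

* a variant with *no record at all* for a meaning is coded missing (`?`)
  across that meaning's columns, not absent — coding it 0 would claim
  positive evidence of loss and would also break the ascertainment logic
  below;
* synonyms (several classes for one variant and meaning) are all coded 1;
* distances use pairwise deletion of missing cells; a pair with no
  jointly observed column is an error rather than a silent 0.

By construction no observed column is all-zero: a class exists only if
someone attests it.

## Phylogenetic likelihood

Characters evolve independently on a rooted time tree. The visible
process is a reversible two-state CTMC with stationary frequencies
(π₀, π₁); the generator is normalized to one expected substitution per
unit of μ·t, so the clock rate μ is in substitutions per character per
year. The covarion variant is the Tuffley–Steel construction: the joint
state is (visible, on/off); substitution runs only while "on", the
hidden toggle has rate s and stationary frequencies (f_on, 1−f_on),
default equal. Transition matrices are closed-form for the two-state
model and a 4×4 matrix exponential for the covarion. Tips marginalize
the hidden state; missing cells contribute likelihood 1 in every state.
Pruning rescales partials per node to avoid underflow.

Because characters are cognate classes, a character can only be sampled
if present in at least one variant. The likelihood is therefore
conditioned per character: `log L(x) − log(1 − L(0…0))`. On enumerable
trees the corrected pattern probabilities sum to one over the admissible
(non-all-zero) patterns, which is the invariant the tests assert.

## MCMC

State: tree topology and node ages, dated-tip ages, μ, π₁, covarion s,
coalescent population size Ne, and (relaxed clock) per-branch lognormal
rate multipliers with real-space mean 1.

Priors: μ ~ lognormal with real-space mean 3·10⁻⁴ and log-sd 0.7 (the
calibration standard for basic-vocabulary replacement); dated tips ~
truncated normal (for the ancient variant: mean 500 y, sd 100 y,
truncated to [87, 870] y, the age span of its source documents); tree ~
constant-size coalescent with lognormal prior on Ne; π₁ ~ uniform(0,1);
s ~ exponential; relaxed-clock log-sd fixed at 0.5 by default.

Moves: uniform node-age redraw within the bracket set by parent and
children (symmetric), multiplicative root-excess scaling, uniform
dated-tip redraw, narrow exchange (swap a node's sibling with one of its
children, age-valid NNI) and wide exchange (swap two non-nested
subtrees, rejected if ages forbid it) for topology, and multiplicative
or windowed moves for scalars. Narrow exchange alone already connects
topology space; wide exchange accelerates mixing. Burn-in defaults to
10% and retained samples are capped at 10,000.

Validation is by (i) exact agreement of the pruning likelihood with
brute-force enumeration (≤5 taxa, 200 random model/tree draws, both
model kinds, tolerance 1e-8), (ii) prior-only runs whose dated-tip
marginal reproduces the truncated-normal calibration within Monte Carlo
error (the coalescent factor integrates to one for any tip age, so the
marginal is exactly the calibration), and (iii) recovery experiments:
on data simulated from a known 8-taxon balanced tree (depth 3000 y,
replacement 2.5·10⁻⁴), the majority-rule consensus recovers ≥6 of 7 true
clades in ≥90% of seeded runs. Balanced trees are used deliberately:
random Kingman trees contain, with ~30% probability at n=8, an internal
branch too short to be identifiable from 500 meanings, which makes
"recover the whole topology" an ill-posed target for them.

The maximum clade credibility tree is the sampled tree maximizing the
product of clade posterior frequencies, re-aged with per-clade posterior
median heights (with an epsilon repair pass in the rare case medians
invert a parent/child pair). No Bayes-factor machinery is provided;
model fit across substitution/clock variants is outside this package's
scope.

## NeighborNet

The agglomeration keeps clusters of at most two linked nodes, selects
cluster pairs by the net-divergence-corrected criterion
`(m−2)·D(A,B) − ΣD(A,·) − ΣD(B,·)`, selects the node pair by the same
criterion with the members of the two clusters treated as singletons,
and reduces any three-node chain to two surrogate nodes with the
standard 2/3–1/3 distance blend. Reductions are expanded in reverse to
give the circular order, canonicalized to start at the lexicographically
first taxon with deterministic orientation; agglomeration ties break on
the smallest node index.

Split weights solve `min ‖d − Σ w_s δ_s‖², w ≥ 0` by active-set NNLS
over the n(n−1)/2 circular splits; weights below 1e-8 are dropped and
the fit statistic is `1 − SS_res/SS_tot`. Additive tree metrics are
reproduced exactly with zero conflicting weight (verified over 100
random trees, and against R/phangorn's NeighborNet ordering as an
independent implementation).

The reticulation score sums `min(w_i, w_j)` over incompatible nontrivial
split pairs, normalized by the same sum over all nontrivial pairs. The
minimum weighting keeps the score from being dominated by the many tiny
noise splits that finite data always produce; it is 0 for a compatible
system and 1 when all weighted splits are mutually incompatible, and it
increases monotonically with the simulated borrowing rate.

## Admixture clustering

Haploid STRUCTURE-style admixture model with independent allele
frequencies: `P(x_il = 1) = Σ_k Q_ik P_kl`. Gibbs updates are conjugate
for Z, P (Beta(1,1) prior, i.e. λ = 1), and Q (symmetric Dirichlet(α));
one α is shared across clusters and sampled by random-walk Metropolis
under a uniform(0, 10) prior. Missing cells are skipped, not imputed.
Chain-averaged posterior quantities match exact enumeration over all
cluster assignments of a 3×4 toy matrix to within 0.02.

Model choice uses the deviance-style estimator
`LnP(D|K) = mean(L) − var(L)/2` over the retained per-sweep
log-likelihoods. This estimator is exact only when L is normal across
sweeps; on very small data its bias is visible (about +0.7 nats against
the closed-form Beta marginal on the 3×4 toy), which is why the
corresponding test allows a 1-nat tolerance. ΔK is the absolute second
difference of mean LnP(D) across K divided by its between-run standard
deviation, undefined at the K-range endpoints and where the sd is 0; K*
is the ΔK argmax, with a mean-likelihood plateau fallback when ΔK is
nowhere defined. Because the between-run sd sits in ΔK's denominator,
too few runs per K make the statistic erratic (an accidentally tiny sd
at some K manufactures a spurious peak); ten or more runs per K keep it
stable at the data sizes used here, which is the scaled-down analogue of
the large run counts this literature uses. Cluster labels are aligned across runs by exact
permutation search (K ≤ 8) minimizing the Frobenius distance between Q
matrices, greedy column matching beyond.

## Barriers and isolation-by-barrier

Sites are projected equirectangularly (longitude scaled by cos of the
mean latitude — adequate at peninsular extent), triangulated, and each
Delaunay edge carries the Jaccard distance of its endpoints; the Voronoi
dual supplies the barrier geometry, with infinite ridges clipped to a
bounding box padded by 20% of the site extent (these clipped ends are
the "limit of the network"). Degenerate cocircular site sets fall back
to joggled qhull input. Monmonier's traversal seeds at the
largest-distance unused edge (ties to the smallest index pair) and grows
both arms, always crossing the adjacent unused, uncrossed edge with the
largest distance, stopping at the network limit or when the polyline
revisits one of its own vertices. Successive barriers exclude the edges
crossed before, so no edge is crossed twice.

The indicator matrix for k barriers marks pairs disconnected after
removing every crossed edge of barriers 1..k (cumulative semantics,
matching the scree construction). Mantel tests correlate upper-triangle
entries (Pearson or Kendall τb) with p-values from joint row/column
permutations, two-sided, 9,999 permutations by default and seeded;
partial tests residualize both matrices on the covariate (Pearson) or
use the partial-τ formula (Kendall), permuting the second matrix. The
scree rule keeps barrier k while the Kendall r² strictly increases and
the Pearson r² gain is at least 1% of the cumulative r² (the 1%
threshold operationalizes "negligible"; both thresholds are arguments).
Kendall τb carries an intrinsic ceiling once the separated pairs exceed
half of all pairs — a balanced cut maximizes τb under perfect separation
— which is what makes it a natural stopping criterion here.

## Synthetic generator and what the tests show

Each meaning carries one active cognate label per lineage; replacement
mints globally novel labels (so all homoplasy comes from contact), and
the covarion toggle freezes/unfreezes meanings at the configured switch
rate. Borrowing copies the donor's current label to a Delaunay-adjacent
recipient; the configured rate is split over several rounds so loans can
diffuse multi-hop and homogenize whole connected regions. Crossing a
planted barrier polyline multiplies an edge's contact rate by a penalty
in [0, 1]. Admixed variants redraw each meaning from one of two source
variants according to their true mixing proportions. Borrowing is
applied to the tip generation (a single contact epoch), which is the
main idealization: real loan histories are spread over time and can be
themselves overwritten by later replacement.

The study-shaped configuration (`peninsula_study_config`) emulates the
peninsular sampling design on the shipped approximate 14-site coordinate
fixture plus one ancient, unlocated variant: a recent south/north core
split (1,500 y) kept in open contact, and three old (1,900–2,100 y)
basal singleton lineages each ringed by a planted barrier (the island
strait, an east-central mountain ring, a far-northeast highland ring).
The design is deliberate on two points. First, the ringed lineages are
mutually unrelated singletons of equal depth: they elevate distances
across their own barrier without forming extra frequency pools, so the
marginal likelihood grows roughly linearly past K = 2 and the Evanno
statistic peaks at the core split. Second, open-contact borrowing
flattens the *adjacent* cross-core pairs, so the core split is visible
to the clustering model (which pools information across all taxa and
loci) but does not register as a fourth distance barrier on the edge
graph that Monmonier sees. Under these conditions the pipeline recovers
K* = 2 and retains exactly the three planted barriers in ≥80% of seeds
at the scaled schedule used in the tests (K = 1..6, 10 chains of 300
burn-in + 700 sweeps, 99 permutations).

Passing these tests shows that each stage implements its model
correctly and that the full pipeline detects a planted
two-pools-plus-three-barriers history at realistic data sizes. It does
not show that real dialect data satisfies the generator's assumptions —
single contact epoch, equal-rate meanings within the covarion classes,
one cognate per meaning per lineage, province-centroid geography — and
quantitative outputs on real data (LnP values, split weights, Mantel
r²) will depend on coding decisions and software defaults that differ
between implementations.

## Problem sizes and determinism

Test and acceptance runs use scaled-down schedules chosen as the
smallest sizes at which the targeted recoveries are stable: 246
meanings, chains of a few thousand sweeps, 99–999 permutations, 10–25
seeded replicates per property. Every stochastic component takes an
explicit seed and is bit-reproducible given it; the pipeline derives
per-stage seeds from the global seed with a CRC-based stream split so
stage toggles do not shift other stages' streams.
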