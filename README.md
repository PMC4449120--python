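# lexevo

Quantitative language-history analyses on binary cognate data, built
around the kind of question asked for the Koreanic dialect continuum:
given basic-vocabulary lexicons from a set of language variants, how
treelike is their history, how many ancestral populations do they mix,
and where do geographic barriers cut the flow of words?

The package implements five analysis stages over one data model, plus a
ground-truthed simulator so every stage can be validated end to end:

1. **Cognate coding** (`lexevo.cognate`) — long-format lexicons
   (variant, meaning, form, cognate class) are coded into a taxa ×
   characters presence/absence matrix, one column per (meaning, cognate
   class) pair; a variant with no record for a meaning is *missing*, not
   absent. Normalized Hamming and Jaccard distances with pairwise
   deletion; NEXUS character I/O.
2. **Bayesian phylogenetics** (`lexevo.phylo`) — Felsenstein pruning for
   a reversible two-state CTMC and its Tuffley–Steel covarion extension
   (visible state × evolving/frozen hidden state), with ascertainment
   correction `log L(x) − log(1 − L(all-absent))` because cognate classes
   are only collected when attested somewhere. A compact
   Metropolis–Hastings sampler moves over topology (narrow/wide subtree
   exchange), node ages, dated-tip ages (truncated-normal calibration,
   mean 500 y, sd 100 y, bounds [87, 870] y), the clock rate (lognormal,
   real-space mean 3·10⁻⁴ substitutions/character/year, log-sd 0.7), and
   relaxed-clock branch multipliers, under a constant-size coalescent
   tree prior. Summaries: maximum clade credibility tree with clade
   supports and posterior-median heights, topology frequency tables.
3. **NeighborNet** (`lexevo.neighbornet`) — agglomerative circular
   ordering plus nonnegative least-squares weights for the n(n−1)/2
   circular splits; a reticulation score measures the fraction of
   pairwise split weight in conflict (0 = treelike).
4. **Admixture clustering** (`lexevo.admixture`) — variants as haploid
   individuals, cognate classes as biallelic loci; Gibbs sampling of
   assignments Z, cluster frequencies P (Beta(1,1)), proportions Q
   (Dirichlet(α), α Metropolis-sampled on (0,10)); the deviance-style
   marginal likelihood `mean(L) − var(L)/2` per K and the Evanno ΔK
   second difference to select K*.
5. **Barriers & isolation-by-barrier** (`lexevo.barrier`,
   `lexevo.mantel`) — Delaunay triangulation of sample sites with
   Jaccard edge distances, Monmonier maximum-difference traversal of the
   Voronoi dual to extract successive barriers, indicator matrices
   (pair separated by the first k barriers), Mantel and partial-Mantel
   permutation tests (Pearson and Kendall τb), and a scree rule for the
   number of meaningful barriers.

`lexevo.synth` generates cognate lexicons with full ground truth: one
cognate label per meaning evolving down a time tree with covarion-style
freezing, globally novel labels on replacement (all homoplasy comes from
contact), multi-round borrowing between Delaunay-adjacent sites damped by
planted barrier penalties, and optional admixed variants.

## Worked example

The `analysis/` scripts run the whole study design on a synthetic
peninsula: 15 variants (14 located sites plus one ancient variant
sampled ~500 years ago), 246 meanings, two recent frequency pools in
open contact, and three old barrier-ringed lineages.

```bash
python analysis/01_simulate_dataset.py 1
python analysis/02_code_cognates.py
python analysis/03_phylogeny.py
python analysis/04_split_network.py
python analysis/05_admixture.py
python analysis/06_barriers_mantel.py
```

Selected output (seed 1):

```
binary matrix: 15 variants x 566 cognate classes
retained 540 trees; mean nontrivial clade support 0.31
50 weighted splits, fit 0.9996
reticulation score 0.124 (0 = treelike, 1 = fully conflicting)
selected K* = 2
barrier 2: 4 edges (network-limit): Jeju_1-NPyongan_12, Jeju_1-Hwanghae_10, ...
scree rule retains 3 barriers
 k  method     r2     p  partial_r2  partial_p
 3 pearson 0.5763 0.003      0.5216      0.003
 3 kendall 0.4933 0.003      0.4517      0.003
```

Read: vertical signal is weak (mean clade support 0.31; an eighth of the
split weight is in conflict) because contact keeps erasing it, the
clustering model still finds the two planted pools (K* = 2), and the
Monmonier/Mantel stage recovers exactly the three planted barriers, all
remaining significant after controlling for geographic distance
(`partial_p`). That is the qualitative signature the pipeline is built
to detect: homogenized, non-treelike variation with a small number of
real geographic breaks.

A thin `lexevo` CLI wraps the same stages (`lexevo code`, `phylo`,
`network`, `admix`, `barrier`, `ibb`, `simulate`, `run`); see
`lexevo --help`.

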