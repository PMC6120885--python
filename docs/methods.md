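# Methods

This note documents the statistical procedures implemented in `craft`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions that were genuinely open.

## Input model

Expression arrives as genes × samples matrices of already-normalized,
log-scale values (e.g. log2 FPKM); the package never recomputes
quantification or normalization. Gene identifiers are opaque,
case-sensitive strings; cross-species transfer is done only through an
explicit one-to-one ortholog map. The expression filter keeps genes with
value strictly greater than the threshold (default 0) in at least
`ceil(min_fraction × n_samples)` samples (default fraction 0.05); the
strict inequality means a log value of exactly 0 does not count as
expressed at the default threshold.

A differential-expression table (gene, direction ∈ {over, under, none},
BH q) is normally supplied by the user from a dedicated count-model fit.
The built-in `rank_sum_de` (two-sided Wilcoxon rank-sum + BH, direction
from the sign of the case-minus-control mean) is a deliberately simple
nonparametric stand-in for workflows that only need direction labels, not
a replacement for a proper DE model.

## Co-expression modules

Pairwise gene distances are d = 1 − ρ with Spearman's ρ (average ranks on
ties), so d ∈ [0, 2] and d is invariant to strictly monotone per-gene
transforms. Clustering is agglomerative Ward on the precomputed distance
matrix via the Lance–Williams recurrence — the standard convention when
only a distance matrix exists, since no Euclidean coordinates are
available.

The dendrogram is cut at every K in a scan range and scored by
R²(K) = BSS/(WSS+BSS). Because the data are distance-only, within-group
dispersion uses the pairwise identity

    WSS_c = (1 / n_c) · Σ_{i<j ∈ c} d²_ij ,

with TSS computed the same way over all genes and BSS = TSS − WSS. The
identity reduces exactly to the centroid sum of squares whenever the
distances embed in Euclidean space (unit-tested on embeddable toys); for
correlation-derived distances it is well defined without committing to an
embedding. BSS + WSS = TSS holds to 1e−9 by construction, and R² is
non-decreasing along nested cuts in all tested regimes (it is not a
theorem for arbitrary non-embeddable distances, so the scan asserts it).

Two cut-selection criteria are implemented:

* **pseudo F-index** — the Calinski–Harabasz form
  (BSS/(K−1))/(WSS/(n−K)), maximized over the scan. The cited index has no
  other standard reading; a maximum at the scan boundary is flagged as
  unstable.
* **elbow** — the smallest K after which every marginal gain ΔR²(K→K+1)
  over a look-ahead window (default 3 steps) stays below a fraction
  (default 0.01) of the scanned R² range. "Elbow" names a family of
  heuristics, so both knobs are explicit configuration rather than an
  inferred constant.
* **consensus** (default) — require the two criteria to agree within ±2
  and return the pseudo-F choice; on disagreement the error carries both
  candidates (the pipeline falls back to pseudo-F with a warning).

Genes are always assigned to some module; pooling sub-threshold clusters
into an "unclustered" catch-all is available as an optional post-hoc
relabeling (`relabel_small_modules`, off by default) because there is no
principled default for the minimum size.

A module's **eigengene** is the first right singular vector of the
row-standardized module submatrix — one score per sample, automatically
zero-mean (standardized rows are orthogonal to the constant vector), unit
norm, oriented so its inner product with the module's mean standardized
profile is non-negative, with variance explained s₁²/Σs².

## Differential co-expression

For a module of m genes the statistic is the Euclidean distance
D = ‖r_A − r_B‖₂ between the two condition-wise vectors of all C(m,2)
pairwise Spearman correlations (fixed row-major upper-triangle order).
Significance comes from a competitive null: B gene sets of size m redrawn
without replacement from the expressed-gene pool, D recomputed for each,
and

    p = (1 + #{D_null ≥ D_obs}) / (B + 1),

which can never return 0 and is BH-adjusted across the module family.
"Permuting genes in the module" admits two readings; redrawing same-size
sets is the proper competitive null for module-level co-expression and is
the default, with a condition-label shuffling variant behind
`null="shuffle"` for comparison. Default B is 1000 for routine runs;
10,000 matches the most conservative published practice.

Two properties of the competitive null are worth knowing. First, it is
*calibrated only against the pool*: when the tested module's correlation
structure differs from what a random same-size draw looks like (e.g. a
tightly coherent module in a mostly incoherent pool with equal coherence
in both conditions), the test is conservative rather than anti-
conservative. The type-I calibration check therefore uses an exchangeable
design — the module is a random subset of a single factor family — where
the null holds exactly. Second, other differentially co-expressed modules
in the pool contaminate random draws and inflate the null, which is the
realistic competitive setting; power statements below are made under that
setting.

**Conservation** in an external dataset asks a different question — is the
module coherent there at all — so its statistic is the mean absolute
pairwise Spearman correlation of the ortholog-mapped module genes,
compared against random equal-size sets from the external expressed genes
(one-sided exceedance). A cross-dataset differential test (mouse vs human
correlations) would conflate species and platform with disease; both
routes exist (`conservation_test` vs `diffcoexpr_test` after mapping) and
reports name which was run.

**Subsampling power** draws stratified column subsets per condition at
each sampling fraction (preserving the case/control ratio), reruns the
permutation test, and records the empirical p. One master seed spawns an
independent stream per (fraction, repetition) cell, so any cell is
reproducible in isolation. Fractions leaving fewer than 4 samples per
condition are skipped with a warning.

## Trait association

Trait association uses case samples only by default (the trait is
undefined in controls); this is configurable. Module-level: Spearman ρ of
each eigengene with the trait, two-sided p, BH across modules. The
reported R² is the coefficient of determination of an ordinary
least-squares fit of trait on eigengene, reported *alongside* the squared
rank correlation, because the two answer different questions (linear
variance explained vs monotone association) and neither is canonical.
Gene-level QTT analysis computes each gene's Spearman ρ with the trait
(t-approximation p, matching SciPy), with the BH family spanning all
expressed genes — genome-wide, not per-module. Module QTT enrichment is an
upper-tail hypergeometric of the module against the QTT gene set, with the
module's mean gene-level ρ as the direction summary.

## Enrichment machinery

All set enrichments are one-sided (upper tail). Fisher's one-sided exact
test equals the hypergeometric survival function on the same 2×2 table, so
both families share one implementation, which is exact and stable for
corpus populations in the millions (SciPy's log-space survival function;
cross-checked against an independent gammaln-based implementation and
against exhaustive enumeration for every universe ≤ 12). Odds ratios use a
0.5 continuity correction only when a margin is zero, and only for the
reported ratio — never for the p-value. Universes are competitive by
default: expressed genes for cell-type enrichment, expressed genes with at
least one abstract for literature module enrichment; every output names
the universe used. The literature gene test treats a gene's n abstracts as
draws from a corpus of N_total abstracts containing K_disease
disease-linked ones and asks whether the observed co-citations k are
excessive.

## Causal reasoning

The regulome has exactly two signed layers: receptor→TF (from linear
canonical pathways) and TF→target. Path depth is fixed at two hops;
regulatory cascades beyond the TF layer are out of scope because the
pathway layer already terminates at TFs. Edge endpoints are restricted to
expressed genes before any test. An edge annotated with both act and inh
(curation conflicts) keeps both signed copies so conflicting paths remain
visible downstream.

Sign composition is multiplicative by default: act·act = act,
act·inh = inh, inh·act = inh, inh·inh = act, and unk absorbs everything.
The published rule table this follows contains one cell — an inhibitory
receptor→TF edge composed with an activating TF→target edge yielding
"Activated" — that contradicts both sign multiplication and the
framework's own reversion logic. Rather than silently "correcting" it or
hard-coding a suspected typo, both behaviours are selectable
(`mode="as_printed"` reproduces the table literally) and the
multiplicative algebra, which is associative with act as identity, is the
default.

For each receptor, every two-hop path contributes its composed sign: a
gene with at least one activating path enters the activated set, one
inhibiting path the inhibited set (both allowed — such genes are flagged),
and genes reachable only through unk-composed paths form the unknown set.
A gene reached through two same-sign TFs counts once.

Sub-modules are the over-expressed ("o") and under-expressed ("u") genes
of each module; empty ones are dropped with a note. Each regulator's
activated and inhibited sets are tested separately against each sub-module
with an upper-tail hypergeometric; an empty target set is recorded as
untested, never as p = 1. The phrase "all genes under the control of the
regulator as the universe" does not parametrize a standard hypergeometric
(the draw set would equal the population), so the universe is
configurable: `regulome_targets` (default — all expressed genes appearing
as targets anywhere in the filtered regulome) or `expressed_genes`; every
report names the universe used. BH is applied across all
(regulator × sub-module × sign) tests of a run, with receptors and TFs
adjusted as separate families since they are reported separately.

Classification at FDR α (default 0.05): **act** if the positive test is
significant and the negative is untested or non-significant; **inh**
symmetrically; **uns** if both are significant; **ns** otherwise. Activity
(k/n) and weight (k/K) come from the classifying test; for uns and ns the
more significant of the pair supplies the reported metrics.

**Absolute ranking** (per sub-module): act/inh calls outrank uns; ns is
excluded. Within a stratum, regulators are ranked by activity and by
weight (descending, average ranks on ties) and sorted by the rank sum,
with ties broken by the smaller classifying q and then regulator id —
rankings are fully deterministic. **Relative ranking** greedily maximizes
sub-module coverage: pick the absolute-rank-1 regulator, remove the
sub-module genes covered by its classifying direction's target set,
recompute activity (residual overlap / target-set size) and weight
(residual overlap / residual size) for the rest, re-rank, and repeat;
regulators contributing no residual coverage are listed last. Cumulative
coverage is reported after each pick.

**Therapeutic direction** is a pure function of (class, sub-module
direction): act on o → blockade, inh on o → activation, act on u →
activation, inh on u → blockade; uns and ns give no recommendation.

## Synthetic data

The generator exists to give every stage a ground truth. Gene g in module
m is x_gs = λ_cond(m)·f_ms + δ_g·1[case] + baseline + ε_gs with one
standard-normal factor per (module, sample), noise ε ~ N(0, σ²) (default
σ = 1), and an additive log-scale shift δ (default magnitude 1) planting
DE on a configured fraction of the module. Within a condition, same-module
genes have Pearson correlation λ²/(λ²+σ²) in expectation — the closed form
the generator tests converge to. Background genes are pure noise around
the baseline (default 5, so values sit on a log2-expression-like scale).
Case traits are counts, Poisson with log-rate intercept + Σ_m β_m f_ms
(negative-binomial behind a flag); since all trait stages are rank-based,
the link is non-critical. Controls carry no trait. The regulome generator
plants a driver receptor whose activating two-hop paths cover a configured
fraction of an over-expressed sub-module (plus extra off-module targets so
its activity is not trivially 1), decoy receptors with uniformly random
signed edges, an optional fraction of signs degraded to unk, and a hub TF
pinning the target universe. Citation counts give planted disease genes a
multiplied co-citation rate over the corpus base rate. One RNG stream per
component (expression / regulome / citations) is spawned from the master
seed, so regenerating one component leaves the others unchanged.

What the generator does **not** emulate: count-level RNA-seq properties
(library size, per-gene overdispersion, mean–variance coupling),
correlated noise between modules, realistic regulatory topology
(hub-dominated degree distributions, feedback), or batch structure.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated factor model, not robustness to every artifact
of real data.

## Study conditions used by the tests and the acceptance script

Simulation sizes were chosen once to mirror a realistically-sized rodent
case/control study (of the order of 100 cases and 100 controls, an
expressed pool of order 10³ genes, modules of tens of genes) while keeping
a full run in minutes on one CPU:

* Type-I calibration: module of 50 drawn from a 350-gene single-factor
  pool (λ = 0.5 in both conditions), 60+60 samples, B = 200, 200
  replicates — exchangeable by construction, so the rejection rate is
  nominal.
* Planted differential co-expression: λ_case = 0.8 vs λ_control = 0,
  module 50, 60+60 samples.
* Subsampling power: 100+100 samples, 1000-gene pool, strong module
  (size 60, λ 0.8 vs 0) against weak (size 60, λ 0.28 vs 0), fractions
  {0.2, 0.5, 1.0}. λ = 0.28 puts the weak module's detectability right at
  the full sample size, reproducing the qualitative finding that some
  modules are only detectable with the complete cohort; rates pool 25
  independent datasets with one subsample each, since at fraction 1.0 the
  subsample is the dataset and repetitions within one dataset are not
  informative.
* Module-count recovery: six modules of 100 genes, λ = 0.9, 100 samples.
* Driver recovery: a 67-gene module with 60% of genes over-expressed
  (40-gene o-sub-module), driver coverage 0.6, 20 decoys, universe of
  1000 regulome targets, 40 seeds.

## Known limitations

* The pairwise WSS identity and Ward-on-distances are conventions, not
  uniquely implied by R² = BSS/(WSS+BSS); other conventions would shift
  absolute R² values (though typically not the selected K).
* The competitive permutation null is conservative for modules whose
  correlation structure has no counterpart in the pool (see above).
* The hypergeometric effect tests treat genes as exchangeable draws;
  co-regulation within sub-modules makes the nominal p-values optimistic
  in absolute terms, which is why decisions rest on BH-controlled
  comparisons within one run rather than on absolute p magnitudes.
* Two-hop composition cannot represent longer signalling cascades, and
  sign conflicts are preserved rather than resolved — a receptor with
  genuinely conflicting paths will tend toward uns.
* `rank_sum_de` ignores count overdispersion; supply a dedicated DE table
  for real RNA-seq.
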