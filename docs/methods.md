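# Methods

## Study design and terminology

The experimental layout the package models: a baseline group **B** of five
non-fighting fish, and two fighting groups — **D20** (five pairs sampled
after a 20-minute fight) and **D60** (five pairs after 60 minutes) — giving
25 brain RNA-seq samples. Within one fighting group of 10 fish there are
45 unordered sample pairs ("dyads"): 5 *paired* dyads (actual opponents)
and 40 *unpaired* dyads. "Synchrony" means paired dyads look more alike
than unpaired dyads, globally (profile correlations) or per gene
(expression distances).

## Normalization

Genes are kept when their CPM is ≥ 1 in ≥ 1 sample (inclusive boundary;
the filter is idempotent). TMM scaling factors follow the canonical
recipe: per sample vs a reference (chosen as the sample whose
upper-quartile CPM is closest to the mean upper-quartile), per-gene log₂
ratios M and average abundances A over genes positive in both samples;
genes in the extreme 30 % tails of M or 5 % tails of A (rank-based, ties
averaged) are discarded; the factor is 2^(weighted mean M) with inverse
delta-method binomial variances as weights; factors are rescaled to
geometric mean 1. If fewer than 20 genes survive trimming the untrimmed
weighted mean is used with a warning. A "TMM value" is CPM on the
effective library size (library size × factor); log transformation is
log₂(value + 1) with the pseudocount configurable. Because the precision
weights depend on library sizes, TMM factors are *not* exactly invariant
under rescaling one library (≈0.1 % drift at realistic scale); exact
invariance holds when all M values are equal, and the test suite checks
both facts.

## Differential expression

The default test is Welch's t on log₂ TMM values per gene
(log₂FC = mean(fighting) − mean(baseline)), BH-FDR across all tested
genes. An NB likelihood-ratio option (`nb_lrt`) with per-gene
method-of-moments dispersion and TMM-offset GLM fits is provided for
count-level inference; the empirical-Bayes dispersion machinery of
dedicated DE packages is deliberately out of scope, and DEG lists can be
injected from a file so downstream stages are method-agnostic. Two
threshold profiles are exposed: `characterization` (FDR ≤ 0.05 and
|log₂FC| > 2) and `sync_input` (FDR ≤ 0.05 and log₂FC > 0). FDR
boundaries are inclusive; fold-change boundaries strict. All-constant
genes get p = 1 by convention and are flagged.

The overlap of two DEG lists is tested with the upper-tail hypergeometric
probability P(X ≥ k), summed in log space via log-gamma so values far
below the double-precision underflow threshold remain representable (the
log₁₀ p is always reported alongside p).

## Synchrony analysis

Per gene and dyad the distance is D = |log₁₀((x₁+ε)/(x₂+ε))| on linear
TMM values. ε guards zeros; the default is half the smallest positive
value of the full TMM matrix, recorded in every output. Distances are
*not* invariant to per-sample rescaling — comparability across samples is
exactly what TMM normalization provides — so distances are always computed
after normalization.

Three permutation modes share one interface:

* `exact_rank` (default) — exact Wilcoxon rank-sum p via the
  Streitberg–Röhmel shift algorithm on doubled midranks (ties handled
  exactly, no mid-p), the convention of classical exact rank-test
  software;
* `exact_enum` — full enumeration of all C(n, n₁) assignments with the
  difference of group means as statistic (the observed assignment counts
  in numerator and denominator, so p ≥ 1/C(n, n₁); at the study scale
  C(45,5) = 1,221,759);
* `monte_carlo` — (1 + #extreme)/(1 + n_mc) over random assignments.

Sidedness defaults to the direction the synchrony hypothesis implies:
paired correlations *greater*, paired distances *less*; two-sided is
available. A gene is synchronized when its per-gene p < 0.05 (strict).
The per-gene baseline B_i is the 25th percentile of the 40 unpaired
distances under the linear-interpolation convention h = (n−1)p + 1 (so
the 25th percentile of 1…40 is 10.75), and a synchronized gene counts as
synchronized in pair j when D_ij < B_i, strictly — a tie does not count.

**Exchangeability caveat.** The 45 dyads share samples (each fish appears
in 9 dyads), so distances are positively correlated (ρ ≈ 0.22 for dyads
sharing one fish under Gaussian per-fish noise) while the permutation
tests treat them as exchangeable. Reproducing the procedure as defined
therefore yields a *conservative* per-gene test: under a no-pair-effect
null the measured rejection rate is ≈ 0.03 at nominal α = 0.05 (it matches
the attainable level ≈ 0.047 exactly when distances are made artificially
exchangeable, which the property tests verify). Synchronized-gene counts
should be read accordingly; the group-level test on 45 correlations shares
the caveat.

Pair coclustering uses average-linkage hierarchical clustering with
1 − Pearson r distance on the group's samples (top-variable gene subset by
log₂ TMM standard deviation, ties broken lexicographically, floor() for
fractional counts); the score is the fraction of fighting pairs whose two
members are sister leaves. Under random profiles the expected score is low
(each fish's nearest neighbour is roughly uniform over the 9 others); a
score of 1.0 means every pair merged first with its own opponent.

## Count simulator

Relative expression on the log₂ scale:

    log2 q_gs = log2 λ_g + F_s·[ LFC_g + w·u_{g,pair(s)} + (1−w)·e_{g,s} ]

with λ_g lognormal (log₂ mean 8, sd 2.5), F_s the fighting indicator,
LFC_g ~ N(2, 1) for responsive genes, u pair-shared effects
(sd `sigma_pair`, default 2), e fish-specific effects (sd `sigma_fish`,
default 1), and w the pair-sharing weight of the sample's group for
synchronized genes (defaults 0.2 for D20, 0.9 for D60; 0 for merely
responsive genes). Counts are NB with mean L_s·q_gs/Σq and per-gene
dispersion φ_g log-uniform on (0.02, 0.3) (variance μ + φμ²; drawn as a
gamma–Poisson mixture). Library sizes are lognormal with mean 2×10⁶ and
CV 0.1. Defaults give a desk-scale genome of 2,000 genes, 30 % of them
responsive and half of those synchronized; `n_genes` scales to the full
23,306-gene geometry when needed. The default weights put the 20-minute
group in a fish-noise-dominated (weak-synchrony) regime and the 60-minute
group in a pair-dominated (strong-synchrony) regime.

The recovery experiments (tests and the acceptance script) use
`sigma_pair = 3.0` with w = 0.9 as the strong-pair-effect regime; at that
effect size the per-gene test recovers synchronized genes with sensitivity
≈ 0.9 and specificity ≈ 0.95 among the up-regulated DEGs, and all five
pairs co-cluster in essentially every run.

What the simulator does **not** emulate: winner/loser asymmetries,
compositional library artefacts beyond the simplex renormalization,
batch/lane effects, gene–gene correlation beyond the shared pair effects,
and any temporal dynamics within the fight. Passing recovery tests on
these simulations therefore demonstrates that the pipeline detects the
signal it defines, not that real brains behave like the generator.

## Behavior simulator and metrics

Mouth-locking is an alternating renewal process shared by the dyad: onset
lognormal (mean 10.60 min, sd 1.12), episode durations lognormal (mean
1.29 min, sd 0.24, truncated at the observation end), exponential gaps
sized from the renewal-theorem expansion
E[N(t)] ≈ t/c − 1/2 + σ_c²/(2c²) so the expected episode count matches its
target (12.12 per 60 minutes) without the inspection bias a naive split
would leave. Bite/strike and surface-breath events are per-fish Poisson
processes whose log rate is modulated per 2-minute block by a pair-shared
Gaussian (sd `shared_intensity_sd`, default 0.8, mean-centred so the base
rate is the marginal mean) plus independent fish noise (sd 0.2); base
rates default to 4 bites/min and 2 breaths/min. The behavior-specific
onset (lognormal; means 0.94 and 3.49 min) *is* the pair's first
occurrence: one randomly chosen fish acts at the onset and all earlier
events are thinned, as are all events inside mouth-lock episodes — so
generated logs satisfy the gating constraint by construction. Each
mouth-lock episode is recorded once per fish. The distributional forms
(lognormal onsets/durations, exponential gaps, Poisson events) are
modelling conventions chosen for positivity and tractability, not claims
about the fish.

Analysis metrics use half-open intervals [start, start+duration)
throughout: an event at the exact end of an episode is outside it, and a
window [k·step, k·step+width) counts every event whose start falls inside
it (durations clipped to the window). With a 60-minute log, 2-minute
windows and 1-minute steps give 59 windows. Overlapping windows inflate
serial correlation of the series; the opponent-vs-opponent Pearson r is
reported exactly as the procedure defines it, with that caveat. Zero
variance in a window series raises an error rather than silently
reporting r = 0.

## Over-representation analysis

Generic hypergeometric ORA: term sizes are computed within the chosen
universe (default: all post-filter tested genes; an annotated-only
universe is a caller decision that changes p-values), terms overlapping
the test set by fewer than 2 genes are omitted, significance is p < 0.05
(strict), and BH-FDR is reported per table. A minimal pass merging terms
with identical gene sets stands in for semantic deduplication; GO-graph
propagation and curated pathway semantics are out of scope.

## Pipeline, determinism and problem sizes

`run_all` executes simulate → normalize → DE (both contrasts, both
profiles) → synchrony (both groups) → behavior → enrichment and emits a
schema-versioned JSON report carrying the config hash and seed; all
randomness flows from named seeds, and two runs with the same config are
byte-identical. The bundled analyses and the acceptance script run at
desk scale — 2,000-gene (analysis chain) or 800-gene (recovery
experiments) matrices, 1,000 null genes for calibration, 300 simulated
fights for behavioral calibration, 20 replicates for the coclustering
experiment — sizes chosen so the full chain completes in seconds while
preserving the 25-sample, 45-dyad geometry of the study design.

## Known limitations

* The dyad-exchangeability caveat above: both permutation tests inherit
  the dependence of dyads sharing samples, making them conservative under
  the null; no correction is applied because reproducing the defined
  procedure is the point.
* Welch's t on log₂ TMM is not an NB GLM; at n = 5 per group its p-values
  are approximate, which is why DEG injection and the `nb_lrt` option
  exist.
* The hypergeometric overlap test treats DEG calls as independent draws
  from the universe, ignoring the correlation induced by testing both
  contrasts on the same samples.
* The simulators are statistical caricatures (see above); they define the
  conditions under which the pipeline's operating characteristics are
  measured, nothing more.
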