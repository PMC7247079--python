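# Methods

## The measurement model

`barseqfit` analyses pooled Bar-seq competition experiments in which a
library of barcoded yeast deletion strains is grown in a
nutrient-restricted medium, enters starvation-induced quiescence when the
restricted nutrient runs out, and is sampled repeatedly through both
phases. Each strain's relative abundance is read out by sequencing its
UPTAG and DNTAG deletion-cassette barcodes. Four library backgrounds are
modeled: a neutral *HO* control (effectively single mutants) and three
kinase-query backgrounds (*TOR1*, *RIM15*, *PHO85*) whose double mutants
carry both the query deletion and an array-gene deletion.

The quantities of interest are per-strain regression slopes of
reference-normalized log abundance against scaled time:

* **Fitness, F_Pro** — slope during proliferation (default sampling at
  0, 9, 14, 18, 24 h),
* **Survival, S_Qui** — the same slope during quiescence (32, 48, 96,
  187, 368 h), when no division occurs and abundance changes reflect
  differential death,
* **Phase difference, S_Qui − F_Pro** — the time-by-growth-stage
  interaction coefficient of a single ANCOVA `F ~ T * GS`,
* **Genetic interaction score (GIS)** — the time-by-genotype interaction
  coefficient of `F ~ T * GT` over a double-mutant series and the
  matching single-mutant series, equal to `f_aq − f_a`,
* **Multiplicative ε** — `exp(f_aq) − exp(f_a)·exp(f_q)`, the deviation
  of the double mutant from the classic multiplicative null.

### Time scaling

Phases span wildly different durations (24 h vs. ~15 days), so the time
covariate is rescaled per phase by its uncentered root-mean-square with
an `n − 1` denominator: `T = t / sqrt(Σ t_i² / (n − 1))`. The scaled
vector has RMS 1, preserves the natural spacing of the sampling grid,
and is invariant to the unit of the raw times. Scaling is computed on
the *unique* time points of a phase and mapped onto replicate
observations; scaling the replicate-expanded covariate column would
change the divisor and break the canonical grid values
(0, 0.5246676, 0.8161497, 1.0493353, 1.3991137 for the proliferative
grid). Whole-course fitness across all ten time points instead uses raw
days, since a single RMS unit spanning both phases has no natural
interpretation.

### Counting and filtering

Reads are demultiplexed by sample index (Levenshtein distance ≤ 1
against an index set built with pairwise distance ≥ 2) and assigned to
strains by barcode (Levenshtein distance ≤ 2 against a catalog built
with pairwise distance ≥ 5). Ties at the minimal qualifying distance
are discarded rather than assigned arbitrarily. Note that pairwise
index distance ≥ 2 does *not* guarantee a unique radius-1 neighbor —
a substitution toward another index can tie — but it does guarantee a
corrupted index is never silently misassigned; ties are simply dropped.

Filtering applies, in order: (1) per-tag sample libraries with fewer
than 1 × 10⁵ total reads are removed; (2) count cells ≤ 4 are zeroed as
likely sequencing-error artifacts (interpreted per strain × sample
cell); (3) UPTAG and DNTAG counts are merged by summation; (4) strains
with merged coverage < 3,000 across all retained samples, or absent
from either tag entirely, are removed. Because each removal changes the
margins the other thresholds are computed on, a single pass is not
idempotent; the filter therefore iterates these passes to a fixed
point, making re-application a guaranteed no-op. On clean data the
first pass is almost always the fixed point.

### Normalization

Counts are depth-corrected with median-of-ratios size factors and
transformed as `log2(count / size_factor + 0.5)`. This is the limiting
behavior of the dispersion-fitted variance-stabilizing transformations
used for RNA-seq-like counts and is all the downstream regressions
rely on: monotone in counts, finite at zero, and approximately log2
fold-change for counts well above the pseudocount. Relative abundance
is then the *difference* on this log-like scale between each strain and
the library's reference (the wild-type-like control in the HO library,
the query single mutant in a query library), which makes the result
invariant to per-sample additive shifts and keeps the fitted slope a
log-scale rate — the only scale on which exponentiating coefficients
into multiplicative fitness is coherent. A literal-ratio mode exists
for sensitivity analysis. Slopes are in log2 units; they are
exponentiated with `exp()` in the ε formula exactly as the procedure
prescribes, so the two estimators share the same (inflated by 1/ln 2)
scale and the comparison between them is unaffected.

### Statistics

All replicates enter one OLS fit per strain as independent
observations. Fits are computed with closed-form simple-regression
algebra vectorized over strains; single-strain results match a general
OLS solver exactly (tested against statsmodels). The two-group ANCOVA
interaction coefficient is computed through the identity "interaction
coefficient = difference of the two separately fitted slopes, standard
error from the pooled residual variance with n₁ + n₂ − 4 degrees of
freedom", which is the exact OLS solution of the saturated model, not
an approximation.

For ε, the expectation's standard error propagates the single-mutant
errors as `S²_{a+q} = S²_a + S²_q`, and significance uses a Welch t
statistic with Welch–Satterthwaite degrees of freedom computed from
`S²_aq/N_aq + S²_{a+q}/N_{a+q}`. Two conventions in this formula are
not pinned down by the procedure it follows and were fixed here:
`N_{a+q} = min(N_a, N_q)` (the conservative choice for the effective
sample size behind the propagated error), and the Welch numerator is ε
itself — observed minus expected, both on the exponentiated scale — the
literal `f_aq − f^exp_aq` contrast mixes an un-exponentiated
coefficient with an exponentiated expectation and is retained only as
an explicit `literal` mode.

Multiple testing uses Benjamini–Hochberg within a (query, condition,
state) stratum, significance at q < 0.05 by default.

### Known property of the printed ε estimator

The ε formula takes `f_aq` from the double-mutant library normalized by
the query but multiplies single-mutant terms `exp(f_a)·exp(f_q)` on the
absolute (control-normalized) scale. For a non-interacting gene its
expectation is therefore `exp(f_a)(1 − exp(f_q))`, which is zero only
when the query's own phenotype `f_q` is zero. With a strongly
non-neutral query, ε acquires a spurious `exp(f_a)`-proportional spread
for null genes and its agreement with the ANCOVA score degrades. The
ANCOVA score does not have this problem — query normalization removes
`f_q` exactly — which is an additional argument for preferring it, and
it is the default estimator for all profile-level analyses.

## The synthetic-data generator

The generator is first-class, tested code that mirrors the experimental
design: libraries × conditions × replicates × ten time points, with
UPTAG and DNTAG counted as independent multinomial draws per sample.

Generative model: within each phase, strain *i*'s expected frequency is
`initial_freq_i · exp(rate_i · T)` renormalized over the pool, where
`rate_i` is the strain's log-scale effect per unit scaled time (fitness
or survival, per condition) plus its interaction term in a query
library. Because a query-background effect is shared by the entire pool
it cancels in the renormalization, so rates are specified relative to
the library reference. The regression slope of log relative abundance
therefore equals the true effect exactly, which makes
parameter-recovery and CI-calibration tests sharp.

Defaults and their rationale:

| parameter | default | why |
| --- | --- | --- |
| pool size | 2,000 strains | desk-scale stand-in for a ~4,000-strain deletion collection |
| effect SD | 0.2 / unit scaled T | typical spread of deletion fitness effects on the log scale |
| interaction fraction | 10% of pairs | sparse interactions, the regime the estimators assume |
| interaction SD | 0.2 | comparable to single-mutant effects |
| fitness–survival correlation | 0 | the decoupling of proliferation and quiescence phenotypes is the phenomenon under study; the generator must not bake in a correlation |
| query effect SD | 0 | quiescence-screen queries are selected to be dispensable for proliferation; also required for the printed ε estimator to be unbiased (see above) |
| depth | 10⁶ reads per tag per sample | 2 × 10⁶ per merged sample |
| biological noise | lognormal, SD 0.1 per strain per sample | replicate-to-replicate variability of pooled competition assays; shared between the two tags of a sample |
| reference weight | 5% of the pool, noise averaged over 96 colonies | the control is pooled from replicated colonies; a single noisy reference trajectory would impose a common-mode error on every normalized strain |
| initial frequencies | lognormal, SD 0.5 | uneven pool representation |

A global seed feeds per-stage `SeedSequence` substreams; every
stochastic operation is deterministic given its seed.

What the generator does **not** emulate: PCR amplification bias,
chimeric reads, quality-score structure, diauxic-shift kinetics within
the proliferative phase, batch effects between conditions, and
strain-specific dispersion. Passing tests therefore demonstrate that
the estimators are correct and calibrated under the stated generative
model, not that real libraries meet its assumptions. Read simulation
adds i.i.d. per-base substitutions only — sufficient to exercise the
fuzzy matcher, not a full error model.

## Numerical choices and degenerate inputs

* Slopes within 1e-10·(signal scale) of zero are snapped to exact zero
  so a perfectly constant series reports f = 0, p = 1 instead of a
  floating-point-noise t statistic.
* Fits require ≥ 3 observations and nonzero time variance; degenerate
  strains are flagged, not silently dropped.
* Size factors fall back to positive-entry ratios (with a warning) when
  no strain is zero-free; degenerate columns get factor 1.
* Hierarchical clustering uses average linkage on 1 − r (configurable);
  profiles causing undefined correlations are dropped greedily, most
  offending first.
* Replicate PCA outlier detection uses a leave-one-out Mahalanobis
  distance (threshold 3): with three replicates per library an aberrant
  replicate inflates a naively pooled covariance enough to mask itself,
  so centroid and covariance exclude the replicate being scored.
* The multiset intersection test is Monte-Carlo (≥ 10⁴ draws,
  add-one-corrected p), with the closed-form expected overlap
  `N·∏(n_i/N)` reported alongside; universe size is a required explicit
  parameter.

## Quiescence-specific gene classification

A gene is quiescence-specific in a condition when (i) it is dispensable
for proliferation, (ii) it is required for survival (S_Qui < 0,
adjusted p < 0.05), and (iii) its survival is significantly worse than
its fitness (S_Qui − F_Pro < 0, adjusted p < 0.05). Criterion (i) is
implemented as "not significantly deleterious" (estimate ≥ 0, or a
negative estimate that is not significant); a strict mode requiring
significantly *positive* fitness is available but contradicts the
meaning of "dispensable". The common set is the intersection across
conditions, restricted to genes scored in all of them.

## Problem sizes

Calibration and agreement analyses run on simulated libraries of 2,000
array genes, one query, three replicates, five time points per phase,
and 2 × 10⁶ reads per sample; false-discovery calibration averages 20
such simulations. A full scoring run at this scale takes well under a
second thanks to the vectorized fits, so these sizes are comfortable on
a laptop.

## Limitations

* The dispersion-fitted VST is approximated by a pseudocount log2
  transform; for very low-coverage strains the scales differ.
* No batch correction, spike-ins, UMI logic, or quality-aware matching.
* No per-replicate random effects; replicates are pooled as independent
  observations, so replicate-level autocorrelation would narrow CIs
  optimistically.
* Partial-correlation (conditional) networks are out of scope; the
  correlation network uses plain Pearson edges.
* Essential genes (hypomorphic alleles) and trigenic interactions are
  not handled.
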