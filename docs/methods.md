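# Methods

## The scientific question

Corticocortical connectomes obtained by retrograde tract tracing are
expensive and incomplete: only area pairs whose *target* received a tracer
injection have a known connection status. `structconn` implements a
predictive analysis that asks how far three cheap, area-level anatomical
properties can account for the wiring:

1. **architectonic similarity** — the log-ratio of the two areas' overall
   neuron densities, `log_ratio_density = ln(density_source / density_target)`,
   a quantitative proxy for relative cytoarchitectonic differentiation;
2. **spatial proximity** — the Euclidean distance between area mass
   centers (mm);
3. **thickness similarity** — the analogous log-ratio of cortical
   thicknesses.

Four analyses are chained: inter-variable correlations, binned relative
frequencies of present projections, abstention-thresholded classification
of projection existence, and the relation of architecture to laminar origin
patterns and network topology (degree, core/periphery, modules).

## The classifier

A linear support-vector machine is trained on standardized predictors.
Classes are reweighted to equal effective mass in the margin fit (the
uniform-prior assumption: the boundary is not dragged toward the prevalent
class). Margin scores are mapped to a posterior `p(present)` by a sigmoid
(Platt) calibration fitted by unweighted maximum likelihood on the training
scores.

The calibration is deliberately *not* class-reweighted. Because the sigmoid
is fitted to the raw training labels, its intercept absorbs the class
prevalence, and on data with no usable signal (for example, permuted labels)
the posterior distribution centers at the prevalence rather than at 0.5.
The procedure then degenerates to calling every classified observation
'present': sensitivity = false-positive rate = 1, Youden index
`J = sensitivity + specificity − 1 = 0` exactly, and accuracy equal to the
prevalence at every threshold — the canonical chance signature of this
pipeline. A class-reweighted calibration was evaluated and rejected: it
centers null posteriors at 0.5, so at thresholds where only a few extreme
posteriors receive calls, the fold-averaged null J inherits the well-known
negative dependence between training and test noise in cross-validated
permutation schemes (measured around −0.1 at `p(threshold)` = 0.55), i.e. a
biased null.

Decision rule at threshold `t ∈ [0.5, 1.0]` (strict inequalities; ties
abstain): 'present' if `p > t`, 'absent' if `p < 1 − t`, otherwise abstain.
Thresholds below 0.5 are rejected since the two windows would overlap.
The sweep covers 0.500, 0.525, …, 1.000 (21 thresholds). Accuracy,
precision, negative predictive value, sensitivity, specificity, FPR and J
are computed over classified observations only; metrics with a zero
denominator are NaN and excluded from averaging (the alternative
"abstentions count as errors" convention is available behind
`abstain_as_error=True`). The fraction of the test set classified is
reported relative to the whole test set and is non-increasing in the
threshold by construction.

Validation is 5-fold cross-validation with unstratified random folds of
(near-)equal size, repeated 100 rounds; degenerate partitions (a training
set missing a class) are redrawn and logged. Standardization and
calibration are refitted inside every training set. The per-round summary
`mean_youden` averages J over the seven conservative thresholds
0.850–1.000. The permutation null runs the identical pipeline with labels
randomly permuted before partitioning each round, preserving class counts.
The master seed spawns independent per-round streams
(`numpy.random.SeedSequence`), so any round is reproducible in isolation.

The SVM regularization constant defaults to C = 1 (configurable); results
on the synthetic benchmark are insensitive to it because the two-predictor
problem is low-dimensional and far from separable.

## The synthetic generator

`synthetic.SyntheticConfig` defines the study conditions the pipeline is
tested under; all downstream code consumes only the two CSV table schemas,
so real anatomy/projection tables can be substituted unchanged.

* **Design**: `n_areas = 91` cortical areas, `n_injected = 29` injection
  targets. Connection status is known exactly for ordered pairs with an
  injected target (29 × 90 = 2610 pairs), and the 29 × 28 injected block is
  edge-complete. Pairs with a non-injected target are recorded as 'unknown'
  (`unknown_fraction = 1`). `classifier_benchmark_config()` shrinks the
  cortex to 52 areas (29 injected → 1479 tested pairs), the scale used for
  the classification benchmarks.
* **Densities**: log-normal, `ln(density) ~ N(11.0, 0.35)` (median
  ≈ 6×10⁴ neurons/mm³, range spanning roughly a factor of ten across the
  cortex — the magnitude stereology reports for primate neocortex).
* **Thickness**: `2.4 ± 0.35 mm`, built as `ρ·z + sqrt(1−ρ²)·ε` on the
  standardized ln-density `z` with `ρ = thickness_coupling = −0.69`, so the
  sample correlation between ln-density and thickness converges to the
  configured anticorrelation; clipped at 0.5 mm to stay positive.
* **Positions**: uniform in a 40 mm cube. Only pairwise distances matter
  downstream; the mean inter-area distance (≈26 mm) and tail (≈60 mm)
  bracket the ranges typical of a macaque-sized cortex.
* **Presence model**: `P(present) = σ(β₀ + β_d·|Δ ln density| + β_x·d)` with
  strong-signal defaults `β_d = −4` per unit log-ratio and `β_x = −0.1` per
  mm. The intercept is calibrated numerically (Brent root-find on the
  sampled covariates) so prevalence among tested pairs equals
  `target_prevalence = 0.66`; class balance drives several null behaviors,
  so it is a first-class parameter.
* **Strength and laminar origin**: present projections draw a labeled-neuron
  count from `round(LogNormal(4.5, 2.0))`, floored at 1 neuron (counts from
  single neurons to tens of thousands, matching the orders-of-magnitude
  spread of labeled-neuron counts in tracing data). The expected
  supragranular percentage is `clip(50 + 30·log_ratio_density + ε, 0, 100)`
  with `ε ~ N(0, 20)`, and supragranular counts are binomial — denser
  (more differentiated) sources project from supragranular layers. The
  implied correlation between N_SG% and the density log-ratio on
  well-sampled projections is ≈0.5–0.6.
* **Core / modules**: the lowest-density 17/29 of the injected areas are
  flagged as the network core (a documented convention standing in for a
  topological core definition); module labels are k-means clusters (k = 5)
  of the injected areas' positions, giving spatially coherent modules.

What the generator does *not* emulate: cortical surface geometry and
hemispheres (positions are a box), measurement noise and staining-method
heterogeneity in densities, distance-dependent *strength* (counts are
independent of distance given presence), and topological structure beyond
what the pairwise presence model induces (no explicitly planted rich club).
Passing tests therefore demonstrate that the pipeline's machinery is
correct and well calibrated under the assumed generative model — not that
the anatomical claims hold in real cortex.

## Feature construction and subsets

Log-ratios are natural logarithms, oriented source-over-target for both
density and thickness. Missing densities are handled by pairwise deletion:
rows lacking a density keep distance/thickness features
(`density_available = False`) and drop out of density-based analyses only.
Laminar analyses use present projections with strictly more than
`laminar_count_threshold = 20` labeled neurons (a 10-neuron alternative is a
parameter away); `N_SG% = 100·n_supra/(n_supra+n_infra)` and the undirected
imbalance `|N_SG%| = |N_SG% − 50|·2`. Fractions of labeled neurons (FLN)
normalize each projection's count by the summed counts of its injection.

## Frequency curves

Each variable is partitioned into half-open fixed-width bins anchored at
the data minimum (last bin closed, numpy convention); relative frequency is
present/(present+absent) per bin, undefined for empty bins. Default widths
0.1 (|density log-ratio|), 5 mm (distance), 0.05 (|thickness log-ratio|)
give roughly ten bins over the plotted ranges. The monotone trend is the
Spearman ρ of the per-bin frequencies against bin order (≥3 nonempty bins;
a constant profile returns NaN — the rank correlation is 0/0 under total
ties). Trend signs are invariant to halving/doubling the width on the
synthetic benchmark.

## Statistics

Two-tailed α = 0.05 throughout. Independent-samples t-tests are
pooled-variance by default with Welch behind a flag; every t-test carries
the correlation-scale effect size `r = sqrt(t²/(t²+df))`. Partial
correlations are first-order, computed from the three pairwise
correlations, with p from `t = r·sqrt((n−3)/(1−r²))` on n−3 df; a control
variable numerically collinear with an input is an error. Kruskal–Wallis is
tie-corrected with a χ² p-value; the all-identical degenerate case returns
H = 0, p = 1. Post hoc module contrasts are Bonferroni-corrected pairwise
t-tests (α/number-of-pairs), mirroring the mixed omnibus-nonparametric /
post-hoc-parametric reporting convention of the analysis this package
reimplements; the mix is deliberate and documented rather than harmonized.

## Problem sizes and determinism

Default analysis sizes: 100 cross-validation rounds and 100 permutation
rounds on the 1479-pair benchmark (seconds to a few minutes on one core);
generator calibration checks average 100 seeds at 91 areas. Every stochastic
entry point takes an explicit integer seed; identical configuration plus
seed reproduces tables byte-for-byte.

## Known limitations

* Posterior probabilities are calibration-dependent; only the procedure,
  not exact posterior values, is reproducible across SVM/calibration
  implementations.
* The abstention metrics are undefined at high thresholds when nothing is
  classified; summaries are NaN-aware, and comparisons between feature
  combinations silently drop rounds with no conservative-threshold calls
  (reported via `rounds_defined`).
* Core and module labels are inputs (or generator conventions), not
  detected structures; no rich-club or spectral module detection is
  included.
* Real-data ingestion assumes densities already transformed to a common
  reference frame across staining methods.
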