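# structconn

Predicting corticocortical connectivity from cortical architecture.

Tract-tracing connectomes are edge-complete only on the subgraph of
injected areas; most area pairs remain untested. `structconn` is a tested,
reusable implementation of an analysis pipeline that relates — and
predicts — the existence, laminar origin and topology of inter-areal
projections from three area-level anatomical variables:

* **architectonic similarity**: the neuron-density log-ratio
  `log-ratio_density = ln(density_source / density_target)`;
* **spatial proximity**: Euclidean distance between area mass centers;
* **thickness similarity**: the analogous cortical-thickness log-ratio.

It is aimed at systems/network neuroscientists who want to run this class
of analysis on their own area and projection tables, or to study its
statistical behavior under a controlled generative model. Since
quantitative tracing data are not freely redistributable, the package
ships a synthetic-connectome generator that emulates the study design (91
areas, 29 injections, ~66% of tested pairs connected, density–thickness
anticorrelation r ≈ −0.69) so every stage is testable end to end.

## The core model

Projection existence is classified by a linear SVM on standardized
predictors with uniform class priors in the margin fit, calibrated to a
posterior p(present) by Platt scaling, and read out through a
dual-threshold **abstention rule**: at threshold *t* ∈ [0.5, 1],

&nbsp;&nbsp;call *present* if p > *t*, call *absent* if p < 1 − *t*, otherwise abstain.

Sweeping *t* = 0.500, 0.525, …, 1.000 trades coverage against accuracy.
Performance per threshold is summarized by accuracy, precision, negative
predictive value, sensitivity, specificity and the Youden index
*J* = sensitivity + specificity − 1, averaged over 100 rounds of 5-fold
cross-validation; chance behavior is established by an identical sweep with
permuted labels. Laminar origin is quantified by the supragranular fraction
N_SG% and its imbalance |N_SG%| = |N_SG% − 50|·2; topology by
afferent+efferent degree, core vs non-core density contrasts and module
comparisons. See `docs/methods.md` for the full model description.

## Worked example

```python
import numpy as np
import structconn as sc
from structconn import classifier as clf
from structconn.features import build_feature_table

cfg = sc.classifier_benchmark_config(seed=1)      # 52 areas, 29 injected
ds = sc.generate_dataset(cfg)
features, laminar = build_feature_table(ds.areas, ds.projections)

X = features[["abs_log_ratio_density", "distance"]].to_numpy()
y = features["present"].to_numpy(bool)
cv = clf.cross_validate(X, y, ("abs_log_ratio_density", "distance"),
                        rounds=100, seed=1)
null = clf.permutation_null(X, y, ("abs_log_ratio_density", "distance"),
                            rounds=100, seed=1)
```

This prints (via the obvious summaries):

```
tested pairs: 1479  prevalence: 0.651
mean J (0.85-1.00): 0.78 +/- 0.02
at p(threshold)=0.85: accuracy 0.91, fraction classified 0.29
permutation null mean J: 0.000
N_SG% ~ log-ratio density: r = 0.43, p = 1.2e-35 (n = 746)
```

Reading: on 1479 synthetic tested pairs (65% connected), the
density+distance classifier reaches a conservative-threshold mean Youden
index of 0.78 — at p(threshold) = 0.85 it classifies 29% of held-out pairs
with 91% accuracy — while the same pipeline on permuted labels sits exactly
at chance (J = 0). Among well-sampled projections, the supragranular
origin fraction rises with the source/target density ratio (r = 0.43),
the laminar signature of the architectonic model.

The same flows are available from the shell:

```sh
structconn simulate --seed 1 --out run/
structconn classify --areas run/areas.csv --projections run/projections.csv \
    --features density,distance --rounds 100 --seed 1 --out run/clf/
structconn run-all --seed 1 --out run/all/     # every analysis, one directory
```

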