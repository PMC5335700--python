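"""Probabilistic classification of projection existence with abstention.

The predictive model is a linear max-margin classifier on standardized
anatomical predictors, with scores mapped to a posterior probability of
presence by Platt (sigmoid) calibration. Uniform class priors are imposed in
the margin fit by reweighting the classes to equal effective mass; the
calibration itself is an unweighted maximum-likelihood sigmoid, so the
posterior scale reflects the training prevalence. Predictions use a
dual-threshold abstention rule on the posterior ``p(present)``:

* call **present** if ``p(present) > p_threshold``;
* call **absent**  if ``p(present) < 1 - p_threshold``;
* otherwise **abstain**.

Thresholds run from 0.50 to 1.00 in steps of 0.025 (21 values); raising the
threshold narrows the classified region of feature space, trading coverage
for accuracy. Performance metrics (accuracy, precision, negative predictive
value, sensitivity, specificity, false-positive rate, Youden index
``J = sensitivity + specificity - 1``) are computed over the classified
observations only, and the fraction of the test set that received a call is
tracked alongside. A single summary per cross-validation round is the mean
of ``J`` over the conservative thresholds 0.85-1.00.

Chance behavior is characterized by a permutation null: the identical
cross-validated sweep run on randomly permuted labels.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .stats import StatResult, kruskal_wallis, pairwise_posthoc_ttests

__all__ = [
    "THRESHOLDS",
    "CONSERVATIVE_THRESHOLDS",
    "ClassifierModel",
    "ThresholdPerformance",
    "SweepSummary",
    "train",
    "classify_with_abstention",
    "evaluate_threshold",
    "sweep_thresholds",
    "cross_validate",
    "permutation_null",
    "compare_feature_combinations",
    "predict_unknown",
    "FEATURE_SETS",
]

logger = logging.getLogger(__name__)

#: The evaluated abstention thresholds: 0.500, 0.525, ..., 1.000.
THRESHOLDS = np.round(np.arange(0.50, 1.0 + 1e-9, 0.025), 3)

#: Conservative thresholds summarized by the per-round mean Youden index.
CONSERVATIVE_THRESHOLDS = THRESHOLDS[THRESHOLDS >= 0.85 - 1e-9]

#: All 7 predictor combinations: 3 singles, 3 pairs, 1 triple.
FEATURE_SETS: tuple[tuple[str, ...], ...] = tuple(
    subset
    for k in (1, 2, 3)
    for subset in combinations(
        ("abs_log_ratio_density", "distance", "abs_log_ratio_thickness"), k
    )
)

def _nanmean(a: np.ndarray, axis=None) -> np.ndarray:
    """nanmean that stays silent (returns NaN) on all-NaN slices."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(a, axis=axis)


def _nanstd(a: np.ndarray, axis=None) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanstd(a, axis=axis)


METRICS = (
    "accuracy",
    "precision",
    "npv",
    "sensitivity",
    "specificity",
    "fpr",
    "youden_j",
    "fraction_classified",
)


@dataclass(frozen=True)
class ThresholdPerformance:
    """All performance metrics at one abstention threshold.

    Metrics whose denominator is zero (for example sensitivity when no
    classified observation is truly present) are NaN and are excluded from
    any averaging.
    """

    threshold: float
    accuracy: float
    precision: float
    npv: float
    sensitivity: float
    specificity: float
    fpr: float
    youden_j: float
    fraction_classified: float


@dataclass
class SweepSummary:
    """Cross-validated threshold sweep, aggregated across folds and rounds.

    ``per_round`` holds fold-averaged metrics with shape
    ``(rounds, n_thresholds, n_metrics)`` in the order of :data:`METRICS`;
    ``mean_youden`` is the per-round mean of ``J`` over the conservative
    thresholds (NaN if no conservative threshold produced a call).
    """

    thresholds: np.ndarray
    metric_names: tuple[str, ...]
    per_round: np.ndarray
    feature_set: tuple[str, ...]

    @property
    def mean_youden(self) -> np.ndarray:
        j = self.per_round[:, :, self.metric_names.index("youden_j")]
        cons = np.isin(np.round(self.thresholds, 3), np.round(CONSERVATIVE_THRESHOLDS, 3))
        return _nanmean(j[:, cons], axis=1)

    def mean(self, metric: str) -> np.ndarray:
        """Across-round mean of a metric at each threshold (NaN-aware)."""
        return _nanmean(self.per_round[:, :, self.metric_names.index(metric)], axis=0)

    def sd(self, metric: str) -> np.ndarray:
        return _nanstd(self.per_round[:, :, self.metric_names.index(metric)], axis=0)

    def to_frame(self) -> pd.DataFrame:
        cols = {"threshold": self.thresholds}
        for m in self.metric_names:
            cols[f"{m}_mean"] = self.mean(m)
            cols[f"{m}_sd"] = self.sd(m)
        return pd.DataFrame(cols)


@dataclass
class ClassifierModel:
    """Standardizer + linear margin + sigmoid posterior calibration."""

    feature_set: tuple[str, ...]
    scaler: StandardScaler
    svm: LinearSVC
    platt: LogisticRegression

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        return self.svm.decision_function(self.scaler.transform(np.asarray(X, float)))

    def posterior(self, X: np.ndarray) -> np.ndarray:
        """Calibrated p(present); monotone nondecreasing in the margin score."""
        scores = self.decision_scores(X)
        return self.platt.predict_proba(scores.reshape(-1, 1))[:, 1]


def train(
    X: np.ndarray,
    y: np.ndarray,
    feature_set: Sequence[str] = FEATURE_SETS[3],
    C: float = 1.0,
) -> ClassifierModel:
    """Fit the linear max-margin model with uniform class priors.

    Predictors are standardized on the training data. The uniform-prior
    assumption enters the margin fit: classes are reweighted to equal
    effective mass, so the decision boundary is not dragged toward the
    prevalent class. The score-to-posterior map is a plain maximum-
    likelihood sigmoid (Platt) fitted on the training scores, so posteriors
    reflect the training prevalence; on label-permuted data this makes the
    classifier default to 'present' calls at the observed prevalence, the
    documented chance behavior of the procedure (see docs/methods.md).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional (observations x features)")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training set contains a single class")
    if np.min(counts) < 2:
        raise ValueError("need at least 2 observations per class")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("a training feature has zero variance")

    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    svm = LinearSVC(C=C, class_weight="balanced", dual=False)
    svm.fit(Xs, y)
    scores = svm.decision_function(Xs).reshape(-1, 1)
    # near-unregularized 1-D logistic fit of label on margin score
    platt = LogisticRegression(C=1e6)
    platt.fit(scores, y)
    return ClassifierModel(tuple(feature_set), scaler, svm, platt)


def classify_with_abstention(posterior, threshold: float):
    """Apply the dual-threshold rule; returns 'present'/'absent'/'abstain'.

    Strict inequalities: a posterior equal to the threshold (or to
    ``1 - threshold``) abstains. Thresholds below 0.5 are rejected because
    the present/absent windows would overlap.
    """
    if threshold < 0.5 or threshold > 1.0:
        raise ValueError(f"threshold must lie in [0.5, 1.0], got {threshold}")
    p = np.asarray(posterior, dtype=float)
    calls = np.where(p > threshold, "present", np.where(p < 1.0 - threshold, "absent", "abstain"))
    return calls if p.ndim else str(calls)


def evaluate_threshold(
    posterior: np.ndarray,
    truth: np.ndarray,
    threshold: float,
    abstain_as_error: bool = False,
) -> ThresholdPerformance:
    """Score the abstention rule at one threshold against true labels.

    By default all rates are computed over classified (non-abstaining)
    observations only; ``fraction_classified`` is relative to the whole
    test set. With ``abstain_as_error=True`` abstentions count against
    accuracy, sensitivity and specificity (denominators include them).
    """
    p = np.asarray(posterior, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    pred_present = p > threshold
    pred_absent = p < 1.0 - threshold
    classified = pred_present | pred_absent

    nan = float("nan")
    tp = int(np.sum(pred_present & truth))
    fp = int(np.sum(pred_present & ~truth))
    tn = int(np.sum(pred_absent & ~truth))
    fn = int(np.sum(pred_absent & truth))

    if abstain_as_error:
        pos_denom = int(truth.sum())
        neg_denom = int((~truth).sum())
        acc_denom = truth.size
    else:
        pos_denom = tp + fn
        neg_denom = tn + fp
        acc_denom = int(classified.sum())

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else nan

    sensitivity = ratio(tp, pos_denom)
    specificity = ratio(tn, neg_denom)
    youden = (
        sensitivity + specificity - 1.0
        if not (math.isnan(sensitivity) or math.isnan(specificity))
        else nan
    )
    return ThresholdPerformance(
        threshold=float(threshold),
        accuracy=ratio(tp + tn, acc_denom),
        precision=ratio(tp, tp + fp),
        npv=ratio(tn, tn + fn),
        sensitivity=sensitivity,
        specificity=specificity,
        fpr=1.0 - specificity if not math.isnan(specificity) else nan,
        youden_j=youden,
        fraction_classified=classified.sum() / truth.size if truth.size else nan,
    )


def sweep_thresholds(
    posterior: np.ndarray,
    truth: np.ndarray,
    thresholds: np.ndarray = THRESHOLDS,
    abstain_as_error: bool = False,
) -> np.ndarray:
    """Metric matrix (n_thresholds x n_metrics) for one test set."""
    rows = [
        evaluate_threshold(posterior, truth, t, abstain_as_error=abstain_as_error)
        for t in thresholds
    ]
    return np.array([[getattr(r, m) for m in METRICS] for r in rows])


def _partition_folds(
    n: int, n_folds: int, y: np.ndarray, rng: np.random.Generator, max_redraws: int = 100
) -> list[np.ndarray]:
    """Random unstratified folds of (near-)equal size.

    Redraws the partition if some training set would miss a class — rare
    unless one class is tiny — and logs the event.
    """
    for attempt in range(max_redraws):
        perm = rng.permutation(n)
        folds = np.array_split(perm, n_folds)
        ok = all(np.unique(y[np.concatenate([f for j, f in enumerate(folds) if j != i])]).size == 2
                 for i in range(n_folds))
        if ok:
            if attempt:
                logger.info("redrew fold partition %d time(s): degenerate training fold", attempt)
            return folds
    raise RuntimeError("could not draw a fold partition with both classes in every training set")


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    feature_set: Sequence[str] = FEATURE_SETS[3],
    n_folds: int = 5,
    rounds: int = 100,
    seed: int = 0,
    C: float = 1.0,
    permute_labels: bool = False,
    abstain_as_error: bool = False,
) -> SweepSummary:
    """Repeated k-fold cross-validation of the full threshold sweep.

    Each round draws a fresh random partition into ``n_folds`` equal folds;
    the model (standardization, margin, calibration) is refitted on every
    training set, the held-out fold is scored at all 21 thresholds, and
    metrics are averaged across folds (NaN-aware). Per-round streams are
    spawned from the master seed so rounds are independently reproducible.

    With ``permute_labels=True`` the labels are randomly permuted before
    partitioning each round, giving the permutation null of the entire
    pipeline.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=bool)
    n = y.size
    streams = np.random.SeedSequence(seed).spawn(rounds)
    per_round = np.empty((rounds, THRESHOLDS.size, len(METRICS)))
    for r in range(rounds):
        rng = np.random.default_rng(streams[r])
        labels = y[rng.permutation(n)] if permute_labels else y
        folds = _partition_folds(n, n_folds, labels, rng)
        fold_metrics = np.empty((n_folds, THRESHOLDS.size, len(METRICS)))
        for i, test_idx in enumerate(folds):
            train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
            model = train(X[train_idx], labels[train_idx], feature_set, C=C)
            post = model.posterior(X[test_idx])
            fold_metrics[i] = sweep_thresholds(
                post, labels[test_idx], abstain_as_error=abstain_as_error
            )
        per_round[r] = _nanmean(fold_metrics, axis=0)
    return SweepSummary(
        thresholds=THRESHOLDS.copy(),
        metric_names=METRICS,
        per_round=per_round,
        feature_set=tuple(feature_set),
    )


def permutation_null(
    X: np.ndarray,
    y: np.ndarray,
    feature_set: Sequence[str] = FEATURE_SETS[3],
    n_folds: int = 5,
    rounds: int = 1000,
    seed: int = 0,
    C: float = 1.0,
) -> SweepSummary:
    """Chance-level sweep: labels permuted before each cross-validation round.

    Permutation preserves the class counts exactly, so the null reflects
    the same prevalence as the observed data.
    """
    return cross_validate(
        X, y, feature_set, n_folds=n_folds, rounds=rounds, seed=seed, C=C, permute_labels=True
    )


@dataclass
class CombinationComparison:
    """Cross-validated performance of all predictor combinations."""

    summaries: dict[tuple[str, ...], SweepSummary]
    omnibus: StatResult
    posthoc: list[tuple[str, str, StatResult]]
    ranking: pd.DataFrame  # feature_set, mean_J, sd_J sorted best-first


def compare_feature_combinations(
    features: pd.DataFrame,
    labels: np.ndarray,
    feature_sets: Iterable[tuple[str, ...]] = FEATURE_SETS,
    n_folds: int = 5,
    rounds: int = 100,
    seed: int = 0,
    C: float = 1.0,
) -> CombinationComparison:
    """Cross-validate every predictor combination and compare mean-J spreads.

    Runs the sweep for each combination, then a Kruskal-Wallis omnibus over
    the per-round mean-Youden distributions followed by Bonferroni-corrected
    pairwise t-tests. Rounds where a combination produced no call at any
    conservative threshold contribute NaN and are dropped from the tests.
    """
    labels = np.asarray(labels, dtype=bool)
    summaries: dict[tuple[str, ...], SweepSummary] = {}
    for fs in feature_sets:
        X = features.loc[:, list(fs)].to_numpy(float)
        summaries[fs] = cross_validate(
            X, labels, fs, n_folds=n_folds, rounds=rounds, seed=seed, C=C
        )
    dists = {
        "+".join(fs): s.mean_youden[np.isfinite(s.mean_youden)] for fs, s in summaries.items()
    }
    nonempty = {k: v for k, v in dists.items() if v.size >= 2}
    omnibus = kruskal_wallis(list(nonempty.values()))
    posthoc = pairwise_posthoc_ttests(nonempty)
    ranking = (
        pd.DataFrame(
            {
                "feature_set": list(dists),
                "mean_J": [float(np.mean(v)) if v.size else float("nan") for v in dists.values()],
                "sd_J": [float(np.std(v)) if v.size else float("nan") for v in dists.values()],
                "rounds_defined": [int(v.size) for v in dists.values()],
            }
        )
        .sort_values("mean_J", ascending=False, na_position="last")
        .reset_index(drop=True)
    )
    return CombinationComparison(summaries, omnibus, posthoc, ranking)


def predict_unknown(
    model: ClassifierModel,
    unknown_features: pd.DataFrame,
    threshold: float = 0.85,
) -> pd.DataFrame:
    """Score untested pairs with a trained model and apply the abstention rule.

    Rows missing a required predictor are flagged ``predictable = False``
    and carry no posterior. Output is sorted by posterior, descending.
    """
    cols = list(model.feature_set)
    out = unknown_features[["source", "target"]].copy()
    if unknown_features.empty:
        out["posterior"] = pd.Series(dtype=float)
        out["call"] = pd.Series(dtype=object)
        out["predictable"] = pd.Series(dtype=bool)
        return out
    X = unknown_features.loc[:, cols].to_numpy(float)
    predictable = np.isfinite(X).all(axis=1)
    posterior = np.full(len(out), np.nan)
    if predictable.any():
        posterior[predictable] = model.posterior(X[predictable])
    calls = np.full(len(out), "unpredictable", dtype=object)
    if predictable.any():
        calls[predictable] = classify_with_abstention(posterior[predictable], threshold)
    out["posterior"] = posterior
    out["call"] = calls
    out["predictable"] = predictable
    return out.sort_values("posterior", ascending=False, na_position="last").reset_index(drop=True)
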