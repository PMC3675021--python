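"""Model validation: cross-validated classification metrics, label
permutation testing, and PCA/Hotelling-T² outlier screening.

COPD (class code -1) is the positive class throughout.  Predicted scores
are thresholded at 0, the midpoint of the ±1 class coding; an exact tie is
classified as control (+1), an arbitrary but documented and consistent
rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemometrics import (
    cross_validated_q2,
    fit_pca,
    fit_pls,
    fit_opls,
    hotelling_t2,
    q2_score,
)
from .preprocess import BucketTable, ScaledMatrix

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "PermutationResult",
    "classification_metrics",
    "permutation_test",
    "remove_outliers",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int  # COPD predicted COPD
    fn: int  # COPD predicted control
    tn: int  # control predicted control
    fp: int  # control predicted COPD

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class MetricSet:
    """Percent sensitivity, specificity and overall classification rate.

    Sensitivity is true positives over modeled COPD samples, specificity
    true negatives over modeled control samples, and the classification
    rate the fraction of all predicted samples classified correctly.
    """

    sensitivity: float
    specificity: float
    classification_rate: float


def classification_metrics(y_true, yhat) -> tuple[ConfusionCounts, MetricSet]:
    """Confusion counts and percent metrics from out-of-fold predictions."""
    y_true = np.asarray(y_true, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y_true.shape != yhat.shape:
        raise ValueError(
            f"length mismatch: y_true {y_true.size}, predictions {yhat.size}"
        )
    if np.unique(y_true).size < 2:
        raise ValueError("y_true contains a single class")
    pred = np.where(yhat >= 0, 1.0, -1.0)  # tie (0) goes to control (+1)
    counts = ConfusionCounts(
        tp=int(np.sum((y_true == -1) & (pred == -1))),
        fn=int(np.sum((y_true == -1) & (pred == 1))),
        tn=int(np.sum((y_true == 1) & (pred == 1))),
        fp=int(np.sum((y_true == 1) & (pred == -1))),
    )
    metrics = MetricSet(
        sensitivity=100.0 * counts.tp / (counts.tp + counts.fn),
        specificity=100.0 * counts.tn / (counts.tn + counts.fp),
        classification_rate=100.0 * (counts.tp + counts.tn) / counts.n,
    )
    return counts, metrics


@dataclass
class PermutationResult:
    """Outcome of a y-scrambling validation run.

    ``correlations``, ``r2y`` and ``q2`` hold the permuted models followed
    by the original model at correlation 1.0 (last entry).  The intercepts
    come from ordinary least-squares lines of R²Y and Q² against the
    |correlation| between permuted and true labels; a valid discriminant
    model shows every permuted Q² below the original and a negative Q²
    intercept.
    """

    correlations: np.ndarray
    r2y: np.ndarray
    q2: np.ndarray
    r2y_intercept: float
    q2_intercept: float
    p_value: float
    valid: bool
    n_perm: int

    @property
    def original_q2(self) -> float:
        return float(self.q2[-1])

    @property
    def original_r2y(self) -> float:
        return float(self.r2y[-1])


def permutation_test(
    X,
    y,
    model_kind: str = "pls",
    n_comp: int = 1,
    n_perm: int = 100,
    k_folds: int = 10,
    seed: int = 0,
    scale_method: str = "unit_variance",
) -> PermutationResult:
    """Validate a supervised model by refitting under label permutations.

    Every permutation reuses the original component count and the full
    pipeline (scaling refit inside each cross-validation fold).  The
    empirical p-value uses the standard finite-sample correction
    ``p = (1 + #{Q²_perm >= Q²_orig}) / (n_perm + 1)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if np.unique(y).size < 2:
        raise ValueError("constant y cannot be permuted meaningfully")
    rng = np.random.default_rng(seed)
    fold_seed = int(rng.integers(2**31))

    def _fit_full_r2y(y_vec: np.ndarray) -> float:
        scaler = ScaledMatrix.fit(X, scale_method)
        if model_kind == "pls":
            return fit_pls(scaler.values, y_vec, n_comp).r2y
        return fit_opls(scaler.values, y_vec, n_comp).r2y

    q2_orig, _ = cross_validated_q2(
        X, y, model_kind, n_comp, k_folds=k_folds, seed=fold_seed,
        scale_method=scale_method,
    )
    r2y_orig = _fit_full_r2y(y)

    yc = y - y.mean()
    denom = float(yc @ yc)
    corr = np.empty(n_perm + 1)
    r2y = np.empty(n_perm + 1)
    q2 = np.empty(n_perm + 1)
    for i in range(n_perm):
        y_p = rng.permutation(y)
        corr[i] = abs(float((y_p - y_p.mean()) @ yc) / denom)
        r2y[i] = _fit_full_r2y(y_p)
        q2[i], _ = cross_validated_q2(
            X, y_p, model_kind, n_comp, k_folds=k_folds, seed=fold_seed,
            scale_method=scale_method,
        )
    corr[-1], r2y[-1], q2[-1] = 1.0, r2y_orig, q2_orig

    p_value = (1 + int(np.sum(q2[:-1] >= q2_orig))) / (n_perm + 1)
    r2y_slope, r2y_intercept = np.polyfit(corr, r2y, 1)
    q2_slope, q2_intercept = np.polyfit(corr, q2, 1)
    valid = (q2_intercept < 0) and bool(np.all(q2[:-1] < q2_orig))
    return PermutationResult(
        correlations=corr,
        r2y=r2y,
        q2=q2,
        r2y_intercept=float(r2y_intercept),
        q2_intercept=float(q2_intercept),
        p_value=p_value,
        valid=valid,
        n_perm=n_perm,
    )


def remove_outliers(
    b: BucketTable, pca_components: int = 2, alpha: float = 0.05
) -> tuple[BucketTable, list[str]]:
    """Single-pass PCA/Hotelling-T² outlier screen.

    Fits a mean-centered PCA, flags samples whose T² exceeds the
    F-distribution limit at level ``alpha``, and removes them.  Refuses to
    empty a class.
    """
    if b.n_samples < 3:
        raise ValueError("need at least 3 samples for outlier screening")
    A = min(pca_components, b.n_samples - 1, b.matrix.shape[1])
    scaler = ScaledMatrix.fit(b.matrix, "mean_center")
    model = fit_pca(scaler.values, A)
    _, _, flags = hotelling_t2(model, alpha)
    removed = [sid for sid, bad in zip(b.sample_ids, flags) if bad]
    if not removed:
        return b, []
    keep = ~flags
    kept_groups = {g for g, k in zip(b.groups, keep) if k}
    lost = set(b.groups) - kept_groups
    if lost:
        raise ValueError(f"outlier removal would empty class(es): {sorted(lost)}")
    return b.subset(keep), removed
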