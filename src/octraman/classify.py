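"""LDA classification with leave-one-out cross-validation and
nonparametric feature significance.

Per-sample feature vectors (12 OCT texture features, 8 Raman band
parameters, or the 20-feature combination) are z-scored and projected
by linear discriminant analysis onto n_classes - 1 axes, which doubles
as the classifier.  Performance is estimated by leave-one-out
cross-validation over samples; besides per-class one-vs-rest
sensitivity/specificity, a merged "malignant" class (MCT + STS pooled
in both truth and prediction) is scored, since confusing the two
malignant classes with each other is clinically irrelevant.

Feature significance between class pairs uses the unpaired two-sided
Mann-Whitney U test (exact for small tie-free groups, normal
approximation with tie correction otherwise), with the star convention
*** p < 0.001, ** p < 0.01, * p < 0.05, NS otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.preprocessing import StandardScaler

__all__ = [
    "CANONICAL_CLASSES",
    "MALIGNANT_CLASSES",
    "FeatureMatrix",
    "FittedLDA",
    "SensSpec",
    "fit_lda",
    "loocv",
    "merge_malignant",
    "confusion_metrics",
    "accuracy",
    "mann_whitney",
    "significance_stars",
    "mann_whitney_matrix",
]

#: fixed canonical class order; prediction ties break toward the
#: earliest class in this order
CANONICAL_CLASSES = ("skin", "lipoma", "MCT", "STS")
MALIGNANT_CLASSES = ("MCT", "STS")
MERGED_LABEL = "malignant"


@dataclass
class FeatureMatrix:
    """Samples x named features, with one class label per sample."""

    X: pd.DataFrame
    labels: pd.Series
    dataset_tag: str = ""
    #: LOOCV training folds retain one sample fewer of the held-out class
    min_per_class: int = 2

    def __post_init__(self) -> None:
        self.labels = self.labels.loc[self.X.index]
        if self.X.isna().any().any():
            bad = list(self.X.columns[self.X.isna().any()])
            raise ValueError(f"feature matrix contains missing values in {bad}")
        counts = self.labels.value_counts()
        if len(counts) < 2:
            raise ValueError("at least two classes are required")
        small = counts[counts < self.min_per_class]
        if len(small):
            raise ValueError(
                "every class needs >= 2 samples for leave-one-out refits; "
                f"too small: {dict(small)}"
            )

    @property
    def classes(self) -> tuple[str, ...]:
        present = set(self.labels)
        return tuple(c for c in CANONICAL_CLASSES if c in present) + tuple(
            sorted(present - set(CANONICAL_CLASSES))
        )


@dataclass
class FittedLDA:
    """Standardizer + discriminant model with canonical label encoding."""

    scaler: StandardScaler
    lda: LinearDiscriminantAnalysis
    classes: tuple[str, ...]

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        codes = self.lda.predict(self.scaler.transform(np.asarray(X, dtype=float)))
        return np.asarray([self.classes[int(c)] for c in codes])

    def transform(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Project onto the n_classes - 1 discriminant axes."""
        return self.lda.transform(self.scaler.transform(np.asarray(X, dtype=float)))


def fit_lda(fm: FeatureMatrix) -> FittedLDA:
    """Fit z-scoring + LDA with equal class priors.

    If the within-class scatter is singular (e.g. a feature is constant
    within classes), the degenerate features are named in a warning and
    a small shrinkage ridge is applied as fallback.
    """
    classes = fm.classes
    code = {c: i for i, c in enumerate(classes)}
    y = np.asarray([code[c] for c in fm.labels])
    scaler = StandardScaler().fit(fm.X.to_numpy(dtype=float))
    Xs = scaler.transform(fm.X.to_numpy(dtype=float))
    priors = np.full(len(classes), 1.0 / len(classes))

    degenerate = [c for c, v in zip(fm.X.columns, scaler.var_) if not np.isfinite(v) or v == 0]
    lda = LinearDiscriminantAnalysis(solver="eigen", priors=priors)
    try:
        if degenerate:
            raise np.linalg.LinAlgError(f"zero-variance features: {degenerate}")
        with warnings.catch_warnings():
            warnings.simplefilter("error", RuntimeWarning)
            lda.fit(Xs, y)
    except (np.linalg.LinAlgError, RuntimeWarning, ValueError) as exc:
        warnings.warn(
            "within-class scatter is singular "
            f"({'features ' + ', '.join(map(str, degenerate)) if degenerate else exc}); "
            "falling back to shrinkage regularization",
            RuntimeWarning,
            stacklevel=2,
        )
        lda = LinearDiscriminantAnalysis(solver="eigen", priors=priors, shrinkage=1e-3)
        lda.fit(Xs, y)
    return FittedLDA(scaler=scaler, lda=lda, classes=classes)


def loocv(fm: FeatureMatrix) -> pd.DataFrame:
    """Leave-one-out cross-validation over samples.

    Each sample is predicted by a model fitted (standardization
    included) on all other samples.  The returned prediction table has
    one row per sample with true/predicted labels plus LD coordinates
    from the full-data fit — the latter are for plotting only and are
    not cross-validated.  Predictions do not depend on sample order.
    """
    n = len(fm.X)
    full = fit_lda(fm)
    coords = full.transform(fm.X)
    n_ld = coords.shape[1]

    predicted = []
    for sid in fm.X.index:
        rest = fm.X.drop(index=sid)
        sub = FeatureMatrix(X=rest, labels=fm.labels.drop(index=sid),
                            dataset_tag=fm.dataset_tag, min_per_class=1)
        model = fit_lda(sub)
        predicted.append(model.predict(fm.X.loc[[sid]])[0])

    table = pd.DataFrame(
        {
            "sample_id": list(fm.X.index),
            "true_label": list(fm.labels),
            "predicted_label": predicted,
        }
    )
    for k in range(n_ld):
        table[f"LD{k + 1}"] = coords[:, k]
    assert len(table) == n
    return table


def merge_malignant(pred_table: pd.DataFrame) -> pd.DataFrame:
    """Pool MCT and STS into one 'malignant' class in truth and prediction."""
    out = pred_table.copy()
    mapping = {c: MERGED_LABEL for c in MALIGNANT_CLASSES}
    out["true_label"] = out["true_label"].replace(mapping)
    out["predicted_label"] = out["predicted_label"].replace(mapping)
    return out


@dataclass(frozen=True)
class SensSpec:
    class_label: str
    sensitivity: float
    specificity: float
    tp: int
    fn: int
    tn: int
    fp: int


def confusion_metrics(pred_table: pd.DataFrame, class_label: str) -> SensSpec:
    """One-vs-rest sensitivity and specificity for one class."""
    true_pos = pred_table["true_label"] == class_label
    pred_pos = pred_table["predicted_label"] == class_label
    if not true_pos.any():
        raise ValueError(f"class {class_label!r} absent from the true labels")
    tp = int((true_pos & pred_pos).sum())
    fn = int((true_pos & ~pred_pos).sum())
    tn = int((~true_pos & ~pred_pos).sum())
    fp = int((~true_pos & pred_pos).sum())
    return SensSpec(
        class_label=class_label,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        tp=tp, fn=fn, tn=tn, fp=fp,
    )


def accuracy(pred_table: pd.DataFrame) -> float:
    return float((pred_table["true_label"] == pred_table["predicted_label"]).mean())


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U of x, p).

    Exact null distribution when both groups have <= 8 observations and
    no ties; tie-corrected normal approximation otherwise.  Groups must
    have at least 3 observations each.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError(
            f"untestable pair: group sizes {len(x)} and {len(y)} (need >= 3 each)"
        )
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def mann_whitney_matrix(fm: FeatureMatrix) -> pd.DataFrame:
    """Pairwise class comparison of every feature.

    One row per (feature, class pair): U statistic, two-sided p and the
    star label.  Pairs with a group below 3 samples are reported as
    "untestable" rather than aborting.
    """
    rows = []
    groups = {c: fm.X[fm.labels == c] for c in fm.classes}
    for a, b in combinations(fm.classes, 2):
        for feat in fm.X.columns:
            try:
                u, p = mann_whitney(groups[a][feat], groups[b][feat])
                stars = significance_stars(p)
            except ValueError:
                u, p, stars = float("nan"), float("nan"), "untestable"
            rows.append(
                {
                    "dataset": fm.dataset_tag,
                    "feature": feat,
                    "class_a": a,
                    "class_b": b,
                    "U": u,
                    "p_value": p,
                    "stars": stars,
                }
            )
    return pd.DataFrame(rows)
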