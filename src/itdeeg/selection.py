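"""One-way ANOVA feature screening.

Each feature column is tested across the classes with the classical
equal-variance one-way ANOVA (between/within mean-square ratio, F
distribution with (g-1, n-g) degrees of freedom); columns with p < alpha
(0.05 by default) are kept. The screen is meant to run on the training
partition only, so the held-out rows never influence the mask; a
whole-data mode exists for comparison with analyses that did not guard
against that leakage. No multiple-testing correction is applied by
default; a Bonferroni option is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix

__all__ = [
    "AnovaResult",
    "SelectionMask",
    "one_way_anova",
    "select_features",
    "AnovaSelector",
]


@dataclass(frozen=True)
class AnovaResult:
    """Per-feature F statistics and p-values with their design sizes."""

    f_statistic: np.ndarray
    p_value: np.ndarray
    n_groups: int
    n_total: int
    feature_names: list[str]
    degenerate: np.ndarray  # zero within-group variance with unequal means

    def to_frame(self, mask: "SelectionMask | None" = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "feature": self.feature_names,
                "F": self.f_statistic,
                "p": self.p_value,
            }
        )
        if mask is not None:
            df["kept"] = mask.keep
        return df

    def to_tsv(self, path, mask: "SelectionMask | None" = None) -> None:
        self.to_frame(mask).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class SelectionMask:
    """Boolean keep flag per feature column at level alpha."""

    keep: np.ndarray
    alpha: float

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    @property
    def empty(self) -> bool:
        return not self.keep.any()


def _group_arrays(column: np.ndarray, labels: np.ndarray) -> list[np.ndarray]:
    groups = [column[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("every group needs at least 2 members")
    return groups


def one_way_anova(column, labels) -> tuple[float, float]:
    """Classical one-way ANOVA of one feature column across classes.

    Returns (F, p). Zero within-group variance with unequal group means is
    reported as (inf, 0.0) by convention; identical constant groups give
    (0.0, 1.0).
    """
    column = np.asarray(column, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.isfinite(column).all():
        raise ValueError("feature column contains non-finite values")
    groups = _group_arrays(column, labels)
    within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if within == 0.0:
        means = [g.mean() for g in groups]
        if np.ptp(means) > 0.0:
            return float("inf"), 0.0
        return 0.0, 1.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def select_features(
    matrix: FeatureMatrix,
    alpha: float = 0.05,
    correction: str | None = None,
) -> tuple[AnovaResult, SelectionMask]:
    """ANOVA screen of every feature column of a matrix.

    The mask keeps exactly the columns with p < alpha (after the optional
    Bonferroni correction). An all-drop outcome is reported with a warning
    so downstream benches can fall back to the full feature set.
    """
    x = matrix.values.to_numpy()
    labels = matrix.labels
    classes = np.unique(labels)
    g = classes.size
    n = labels.size
    if g < 2:
        raise ValueError("feature matrix labels must cover >= 2 classes")
    counts = np.array([(labels == c).sum() for c in classes])
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 trials for ANOVA")

    # vectorised sum-of-squares decomposition over all columns at once
    grand = x.mean(axis=0)
    ss_between = np.zeros(x.shape[1])
    ss_within = np.zeros(x.shape[1])
    for c, nc in zip(classes, counts):
        xc = x[labels == c]
        mc = xc.mean(axis=0)
        ss_between += nc * (mc - grand) ** 2
        ss_within += ((xc - mc) ** 2).sum(axis=0)

    df1, df2 = g - 1, n - g
    degenerate = (ss_within == 0.0) & (ss_between > 0.0)
    constant = (ss_within == 0.0) & (ss_between == 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df1) / (ss_within / df2)
    f[degenerate] = np.inf
    f[constant] = 0.0
    p = stats.f.sf(f, df1, df2)
    p[degenerate] = 0.0
    p[constant] = 1.0

    threshold = alpha / x.shape[1] if correction == "bonferroni" else alpha
    keep = p < threshold
    result = AnovaResult(
        f_statistic=f,
        p_value=p,
        n_groups=g,
        n_total=n,
        feature_names=matrix.columns,
        degenerate=degenerate,
    )
    mask = SelectionMask(keep=keep, alpha=alpha)
    if mask.empty:
        warnings.warn(
            "ANOVA selection kept no features; downstream benches fall back "
            "to the full feature set",
            stacklevel=2,
        )
    return result, mask


class AnovaSelector:
    """scikit-learn compatible transformer wrapping the ANOVA screen.

    Refit inside each CV fold so the mask is a pure function of the fold's
    training rows. Falls back to all features when nothing passes alpha.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        classes = np.unique(y)
        grand = X.mean(axis=0)
        ssb = np.zeros(X.shape[1])
        ssw = np.zeros(X.shape[1])
        for c in classes:
            xc = X[y == c]
            mc = xc.mean(axis=0)
            ssb += xc.shape[0] * (mc - grand) ** 2
            ssw += ((xc - mc) ** 2).sum(axis=0)
        df1, df2 = classes.size - 1, y.size - classes.size
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ssb / df1) / (ssw / df2)
        p = stats.f.sf(f, df1, df2)
        p[(ssw == 0.0) & (ssb > 0.0)] = 0.0
        p[(ssw == 0.0) & (ssb == 0.0)] = 1.0
        keep = p < self.alpha
        if not keep.any():
            keep = np.ones(X.shape[1], dtype=bool)
        self.keep_ = keep
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.keep_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)

    def get_params(self, deep=True):
        return {"alpha": self.alpha}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self
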