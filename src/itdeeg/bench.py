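"""Classifier benchmark under the stratified 80/20 split + 5-fold CV protocol.

Every feature matrix is first split into training (80%) and held-out test
(20%) rows, stratified by class and seeded. Variant scores are the mean
accuracy over stratified 5-fold cross-validation of the training rows,
plus the accuracy of the train-fitted model on the held-out rows; when the
ANOVA screen is enabled it is refit inside every fold (and on the full
training rows for the test model), so held-out rows never influence
feature selection. Multi-class accuracy is the confusion-matrix trace over
its grand total, the micro-averaged form of the binary
(TP+TN)/(TP+TN+FP+FN) criterion.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline

from .features import FeatureMatrix
from .registry import ClassifierSpec, all_specs, make_estimator
from .selection import AnovaSelector

__all__ = [
    "EvaluationProtocol",
    "VariantResult",
    "BenchReport",
    "split_train_test",
    "cross_validate",
    "accuracy",
    "run_bench",
]


@dataclass(frozen=True)
class EvaluationProtocol:
    """Split/CV controls: 80/20 stratified split and 5-fold CV by default."""

    test_fraction: float = 0.2
    k_folds: int = 5
    split_seed: int = 0
    cv_seed: int = 0
    scheme: str = "subject_dependent"

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.scheme not in ("subject_dependent", "subject_independent"):
            raise ValueError(f"unknown scheme {self.scheme!r}")


def split_train_test(
    matrix: FeatureMatrix, protocol: EvaluationProtocol
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified-by-class random split, deterministic per seed."""
    counts = np.bincount(matrix.labels)
    present = counts[counts > 0]
    if (present < 10).any():
        raise ValueError(
            "every class needs at least 10 trials for the 80/20 split; "
            f"got class counts {present.tolist()}"
        )
    idx = np.arange(matrix.n_trials)
    train_idx, test_idx = train_test_split(
        idx,
        test_size=protocol.test_fraction,
        stratify=matrix.labels,
        random_state=protocol.split_seed,
    )
    return matrix.take(np.sort(train_idx)), matrix.take(np.sort(test_idx))


def _pipeline(spec, n_features, seed, selection_mode, alpha):
    est = make_estimator(spec, n_features, random_state=seed)
    if selection_mode == "anova":
        return Pipeline([("anova", AnovaSelector(alpha=alpha)), ("model", est)])
    if selection_mode != "none":
        raise ValueError(f"unknown selection_mode {selection_mode!r}")
    return est


def cross_validate(
    spec: ClassifierSpec,
    train: FeatureMatrix,
    protocol: EvaluationProtocol,
    selection_mode: str = "none",
    alpha: float = 0.05,
) -> float:
    """Mean held-out-fold accuracy over stratified k-fold CV of the
    training rows; the ANOVA screen (when enabled) is refit per fold."""
    y = train.labels
    counts = np.bincount(y)
    if (counts[counts > 0] < protocol.k_folds).any():
        raise ValueError(
            f"every class needs >= k_folds={protocol.k_folds} training rows"
        )
    x = train.values.to_numpy()
    skf = StratifiedKFold(
        n_splits=protocol.k_folds, shuffle=True, random_state=protocol.cv_seed
    )
    scores = []
    for tr, va in skf.split(x, y):
        model = _pipeline(
            spec, x.shape[1], protocol.cv_seed, selection_mode, alpha
        )
        model.fit(x[tr], y[tr])
        scores.append(float(np.mean(model.predict(x[va]) == y[va])))
    return float(np.mean(scores))


def accuracy(confusion: np.ndarray) -> float:
    """Multi-class accuracy: confusion-matrix trace over grand total."""
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    return float(np.trace(confusion) / total)


@dataclass
class VariantResult:
    """Scores of one (family, variant) cell of the bench."""

    spec: ClassifierSpec
    cv_accuracy: float | None
    test_accuracy: float | None
    confusion: np.ndarray | None
    status: str = "ok"  # "ok" or "not_available"


@dataclass
class BenchReport:
    """Per-variant scores, per-family best records, and run metadata."""

    variants: list[VariantResult]
    selection_mode: str
    prc_selection: str
    protocol: EvaluationProtocol
    classes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def best_per_family(self, metric: str = "cv") -> dict[str, VariantResult]:
        attr = "cv_accuracy" if metric == "cv" else "test_accuracy"
        best: dict[str, VariantResult] = {}
        for v in self.variants:
            score = getattr(v, attr)
            if score is None:
                continue
            cur = best.get(v.spec.family)
            if cur is None or score > getattr(cur, attr):
                best[v.spec.family] = v
        return best

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": [v.spec.family for v in self.variants],
                "variant": [v.spec.variant for v in self.variants],
                "cv_accuracy": [v.cv_accuracy for v in self.variants],
                "test_accuracy": [v.test_accuracy for v in self.variants],
                "status": [v.status for v in self.variants],
            }
        )

    def to_dict(self) -> dict:
        return {
            "prc_selection": self.prc_selection,
            "selection_mode": self.selection_mode,
            "protocol": {
                "test_fraction": self.protocol.test_fraction,
                "k_folds": self.protocol.k_folds,
                "split_seed": self.protocol.split_seed,
                "cv_seed": self.protocol.cv_seed,
                "scheme": self.protocol.scheme,
            },
            "classes": self.classes.tolist(),
            "variants": [
                {
                    "family": v.spec.family,
                    "variant": v.spec.variant,
                    "cv_accuracy": v.cv_accuracy,
                    "test_accuracy": v.test_accuracy,
                    "confusion": None
                    if v.confusion is None
                    else v.confusion.astype(int).tolist(),
                    "status": v.status,
                }
                for v in self.variants
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def run_bench(
    matrix: FeatureMatrix,
    specs: list[ClassifierSpec] | None = None,
    protocol: EvaluationProtocol | None = None,
    selection_mode: str = "none",
    alpha: float = 0.05,
) -> BenchReport:
    """Train and score every requested variant on one feature matrix.

    A classifier that fails to fit (degenerate feature set, singular
    covariance, ...) is recorded as not-available for that cell and the
    bench continues.
    """
    specs = specs if specs is not None else all_specs()
    if not specs:
        raise ValueError("at least one classifier spec is required")
    protocol = protocol or EvaluationProtocol()
    if selection_mode == "anova_whole":
        # comparison mode: the screen sees all rows (train and test) before
        # the split, the optimistically-biased variant some analyses use
        from .selection import select_features

        _, mask = select_features(matrix, alpha=alpha)
        if not mask.empty:
            matrix = FeatureMatrix(
                values=matrix.values.loc[:, mask.keep],
                labels=matrix.labels,
                selection=matrix.selection,
                flags=matrix.flags[:, mask.keep],
                row_flags=matrix.row_flags,
                subject_ids=matrix.subject_ids,
            )
        selection_mode = "none"
    train, test = split_train_test(matrix, protocol)
    classes = np.unique(matrix.labels)
    x_train = train.values.to_numpy()
    x_test = test.values.to_numpy()
    results: list[VariantResult] = []
    for spec in specs:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cv = cross_validate(spec, train, protocol, selection_mode, alpha)
                model = _pipeline(
                    spec,
                    x_train.shape[1],
                    protocol.cv_seed,
                    selection_mode,
                    alpha,
                )
                model.fit(x_train, train.labels)
                pred = model.predict(x_test)
            conf = _sk_confusion(test.labels, pred, labels=classes)
            results.append(
                VariantResult(
                    spec=spec,
                    cv_accuracy=cv,
                    test_accuracy=accuracy(conf),
                    confusion=conf,
                )
            )
        except (ValueError, np.linalg.LinAlgError, FloatingPointError) as exc:
            results.append(
                VariantResult(
                    spec=spec,
                    cv_accuracy=None,
                    test_accuracy=None,
                    confusion=None,
                    status=f"not_available: {exc.__class__.__name__}",
                )
            )
    return BenchReport(
        variants=results,
        selection_mode=selection_mode,
        prc_selection=matrix.selection,
        protocol=protocol,
        classes=classes,
    )
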