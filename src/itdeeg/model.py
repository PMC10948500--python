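"""Model/Results surface for the full decoding pipeline.

:class:`MovementDecoder` is built from an :class:`~itdeeg.epochs.EpochSet`
and a choice of component-set rows (single PRCs, PRC combinations, the raw
EEG, each optionally behind the ANOVA screen), classifier specs and an
evaluation protocol. ``fit()`` decomposes each trial, builds the feature
matrices, screens and benchmarks every requested cell, and returns a
:class:`DecoderResults` carrying per-variant cross-validated and held-out
accuracies, confusion matrices and a ``summary()`` table shaped like the
component-set x subject accuracy tables this kind of study reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bench import BenchReport, EvaluationProtocol, run_bench
from .epochs import EpochSet
from .features import (
    EntropyParams,
    FeatureMatrix,
    PRC_SELECTIONS,
    build_feature_matrix,
    subset_selection,
)
from .itd import ITDParams
from .registry import ClassifierSpec, all_specs

__all__ = ["MovementDecoder", "DecoderResults", "DEFAULT_ROWS"]

# the component-set rows of the study's report tables
DEFAULT_ROWS: tuple[str, ...] = (
    "PRC1",
    "PRC2",
    "PRC3",
    "PRCs1-2",
    "PRCs1-3",
    "PRCs2-3",
    "PRCs1-to-3",
    "ANOVA+PRCs1-to-3",
    "EEG",
    "ANOVA+EEG",
)


def _parse_row(row: str) -> tuple[str, str]:
    """Split a table row name into (selection, selection_mode)."""
    if row.startswith("ANOVA+"):
        return row[len("ANOVA+") :], "anova"
    return row, "none"


class MovementDecoder:
    """Six-class finger-movement decoder benchmark over ITD feature sets.

    Parameters
    ----------
    epochs : EpochSet
        Labelled trials; multiple subjects supported.
    rows : sequence of str
        Component-set rows to evaluate; a ``"ANOVA+"`` prefix enables the
        ANOVA feature screen for that row. Defaults to the ten standard
        rows (three single PRCs, four combinations, raw EEG, and the two
        ANOVA variants).
    specs : list of ClassifierSpec, optional
        Classifier variants to run; defaults to the full 27-variant
        registry.
    protocol : EvaluationProtocol, optional
        Split/CV scheme and seeds.
    """

    def __init__(
        self,
        epochs: EpochSet,
        rows=DEFAULT_ROWS,
        specs: list[ClassifierSpec] | None = None,
        protocol: EvaluationProtocol | None = None,
        itd_params: ITDParams | None = None,
        entropy_params: EntropyParams | None = None,
        alpha: float = 0.05,
    ):
        self.epochs = epochs
        self.rows = tuple(rows)
        for row in self.rows:
            sel, _ = _parse_row(row)
            if sel not in PRC_SELECTIONS:
                raise ValueError(f"unknown component-set row {row!r}")
        self.specs = specs if specs is not None else all_specs()
        self.protocol = protocol or EvaluationProtocol()
        self.itd_params = itd_params or ITDParams()
        self.entropy_params = entropy_params or EntropyParams()
        self.alpha = alpha

    @classmethod
    def from_container(cls, path, **kwargs) -> "MovementDecoder":
        from .io import read_epoch_container

        return cls(read_epoch_container(path), **kwargs)

    # -- feature matrices ------------------------------------------------

    def _base_matrices(self, epochs: EpochSet) -> dict[str, FeatureMatrix]:
        """One decomposition pass serves every PRC row; the raw-EEG matrix
        is built separately only when requested."""
        matrices: dict[str, FeatureMatrix] = {}
        needs_prc = any(_parse_row(r)[0] != "EEG" for r in self.rows)
        if needs_prc:
            matrices["PRCs1-to-3"] = build_feature_matrix(
                epochs, "PRCs1-to-3", self.itd_params, self.entropy_params
            )
        if any(_parse_row(r)[0] == "EEG" for r in self.rows):
            matrices["EEG"] = build_feature_matrix(
                epochs, "EEG", self.itd_params, self.entropy_params
            )
        return matrices

    def _matrix_for(self, base: dict[str, FeatureMatrix], selection: str) -> FeatureMatrix:
        if selection in base:
            return base[selection]
        return subset_selection(base["PRCs1-to-3"], selection)

    # -- fitting ---------------------------------------------------------

    def fit(self) -> "DecoderResults":
        """Run the bench for every (scope, row) cell.

        Scopes follow the protocol scheme: one per subject for
        ``subject_dependent`` (columns ``S1..``), the pooled trials for
        ``subject_independent`` (column ``SI``).
        """
        scopes: list[tuple[str, EpochSet]] = []
        if self.protocol.scheme == "subject_dependent":
            for i, subject in enumerate(self.epochs.subjects, start=1):
                scopes.append((f"S{i}", self.epochs.for_subject(subject)))
        else:
            scopes.append(("SI", self.epochs))
        reports: dict[str, dict[str, BenchReport]] = {}
        for scope_name, scope_epochs in scopes:
            base = self._base_matrices(scope_epochs)
            reports[scope_name] = {}
            for row in self.rows:
                selection, mode = _parse_row(row)
                matrix = self._matrix_for(base, selection)
                reports[scope_name][row] = run_bench(
                    matrix,
                    specs=self.specs,
                    protocol=self.protocol,
                    selection_mode=mode,
                    alpha=self.alpha,
                )
        return DecoderResults(
            reports=reports,
            rows=self.rows,
            scopes=tuple(name for name, _ in scopes),
            protocol=self.protocol,
            n_trials=self.epochs.n_trials,
            n_channels=self.epochs.n_channels,
            classes=self.epochs.classes,
        )


@dataclass
class DecoderResults:
    """Fitted benchmark: per-(scope, row) reports plus rendered tables."""

    reports: dict[str, dict[str, BenchReport]]
    rows: tuple[str, ...]
    scopes: tuple[str, ...]
    protocol: EvaluationProtocol
    n_trials: int
    n_channels: int
    classes: np.ndarray

    def report(self, scope: str, row: str) -> BenchReport:
        return self.reports[scope][row]

    def accuracy_table(
        self, family: str | None = None, metric: str = "test"
    ) -> pd.DataFrame:
        """Component-set rows x scope columns of best-variant accuracy (%).

        ``family`` restricts the best-variant search to one classifier
        family; otherwise the best over all evaluated variants is shown.
        Cells whose classifiers all failed are NaN (reported as N/A).
        """
        attr = "cv_accuracy" if metric == "cv" else "test_accuracy"
        table = pd.DataFrame(index=list(self.rows), columns=list(self.scopes), dtype=float)
        for scope in self.scopes:
            for row in self.rows:
                scores = [
                    getattr(v, attr)
                    for v in self.reports[scope][row].variants
                    if getattr(v, attr) is not None
                    and (family is None or v.spec.family == family)
                ]
                table.loc[row, scope] = 100.0 * max(scores) if scores else np.nan
        return table

    def confusion(self, scope: str, row: str, family: str, variant: str) -> np.ndarray:
        for v in self.reports[scope][row].variants:
            if v.spec.family == family and v.spec.variant == variant:
                if v.confusion is None:
                    raise ValueError(f"{family}/{variant} was not available")
                return v.confusion
        raise KeyError(f"{family}/{variant} not in this bench")

    def summary(self, metric: str = "test", family: str | None = None) -> str:
        """Human-readable report: run header plus the accuracy table."""
        table = self.accuracy_table(family=family, metric=metric)
        lines = [
            "Movement decoding bench",
            "=" * 60,
            f"trials: {self.n_trials}   channels: {self.n_channels}   "
            f"classes: {self.classes.tolist()}",
            f"protocol: {int((1 - self.protocol.test_fraction) * 100)}/"
            f"{int(self.protocol.test_fraction * 100)} stratified split, "
            f"{self.protocol.k_folds}-fold CV "
            f"(seeds split={self.protocol.split_seed}, cv={self.protocol.cv_seed})",
            f"metric: {'held-out test' if metric == 'test' else 'mean CV'} "
            f"accuracy (%), best "
            + (f"{family} variant" if family else "variant overall"),
            "-" * 60,
            table.round(2).to_string(na_rep="N/A"),
            "-" * 60,
        ]
        best = table.stack(future_stack=True).dropna()
        if len(best):
            (row, scope), value = best.idxmax(), best.max()
            lines.append(f"best cell: {row} @ {scope} = {value:.2f}%")
        return "\n".join(lines)

    def plot_component_accuracies(self, family: str | None = None, metric: str = "test", ax=None):
        """Bar chart of accuracy per component-set row, one group per scope."""
        import matplotlib.pyplot as plt

        table = self.accuracy_table(family=family, metric=metric)
        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        table.plot.bar(ax=ax)
        ax.set_ylabel("accuracy (%)")
        ax.set_xlabel("component set")
        ax.axhline(100.0 / max(len(self.classes), 1), ls="--", c="k", lw=0.8)
        ax.legend(title="scope", fontsize=8)
        return ax

    def to_dict(self) -> dict:
        return {
            "rows": list(self.rows),
            "scopes": list(self.scopes),
            "n_trials": self.n_trials,
            "n_channels": self.n_channels,
            "classes": self.classes.tolist(),
            "reports": {
                scope: {row: rep.to_dict() for row, rep in per_scope.items()}
                for scope, per_scope in self.reports.items()
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
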