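"""Feature concatenation ensembles and the end-to-end experiment.

The ensemble step is feature-level: the top-k selected representations are
concatenated column-wise into one longer feature vector per sample (in
selection rank order), and every single / pair / triple combination of the
selected representations is re-evaluated with the full classifier bank —
seven ensemble rows for k = 3 (3 singles + 3 pairs + 1 triple).

The experiment is exposed statsmodels-style: :class:`FeatureEnsembleModel`
holds the data and configuration; :meth:`FeatureEnsembleModel.fit` runs
matrix building, selection, enumeration and ensemble evaluation, returning a
:class:`FeatureEnsembleResults` with the grids, the selection audit and a
``summary()`` table.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec, grid_search, reduced_specs
from .errors import InvalidInputError
from .features import FeatureTable
from .preprocessing import SplitPartition, split_dataset
from .selection import (
    EvaluationMatrix,
    SelectionResult,
    build_evaluation_matrix,
    row_summary,
    select_top_k,
)
from ._seeds import substream_seed

__all__ = [
    "EnsembleSpec",
    "concatenate_features",
    "enumerate_ensembles",
    "FeatureEnsembleModel",
    "FeatureEnsembleResults",
    "run_experiment",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """An ordered combination of extractor ids with its canonical name."""

    member_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.member_ids) < 1:
            raise InvalidInputError("an ensemble needs at least one member")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise InvalidInputError("duplicate ensemble members")

    @property
    def derived_id(self) -> str:
        if len(self.member_ids) == 1:
            return self.member_ids[0]
        return "(" + " + ".join(self.member_ids) + ")"


def concatenate_features(
    tables: list[FeatureTable], standardize_members: bool = False
) -> FeatureTable:
    """Column-wise concatenation of row-aligned tables, in member order.

    Misaligned sample ids or labels raise rather than silently reordering.
    ``standardize_members`` z-scores each member before concatenation (off by
    default; useful for scale-sensitive members such as SVMs and the ELM).
    """
    if not tables:
        raise InvalidInputError("nothing to concatenate")
    if standardize_members:
        from .features import zscore_table

        tables = [zscore_table(t) for t in tables]
    ref = tables[0]
    for t in tables[1:]:
        if list(t.sample_ids) != list(ref.sample_ids):
            raise InvalidInputError(
                f"sample ids of {t.extractor_id!r} are not aligned with {ref.extractor_id!r}"
            )
        if not np.array_equal(t.labels, ref.labels):
            raise InvalidInputError(
                f"labels of {t.extractor_id!r} are not aligned with {ref.extractor_id!r}"
            )
    if len(tables) == 1:
        return ref
    spec = EnsembleSpec(tuple(t.extractor_id for t in tables))
    return FeatureTable(
        values=np.hstack([t.values for t in tables]),
        extractor_id=spec.derived_id,
        family="+".join(t.family for t in tables),
        sample_ids=list(ref.sample_ids),
        labels=ref.labels.copy(),
    )


def enumerate_ensembles(selected: list[str]) -> list[EnsembleSpec]:
    """All non-empty combinations in size order; 7 specs for 3 members.

    Order is fixed: singles in rank order, then pairs in lexicographic index
    order, then the full combination — matching the published grid layout.
    """
    ids = list(selected)
    if len(set(ids)) != len(ids):
        raise InvalidInputError("duplicate extractor ids")
    specs = []
    for size in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, size):
            specs.append(EnsembleSpec(tuple(combo)))
    return specs


@dataclass
class FeatureEnsembleResults:
    """Estimates of one full experiment run.

    ``evaluation_matrix`` scores every candidate extractor; ``selection``
    carries the top-k choice with its audit; ``ensemble_grid`` holds the
    accuracy of every enumerated combination under every bank classifier.
    """

    model: "FeatureEnsembleModel"
    evaluation_matrix: EvaluationMatrix
    selection: SelectionResult
    ensemble_grid: pd.DataFrame
    seed: int

    def ensemble_row_means(self) -> pd.Series:
        return self.ensemble_grid.mean(axis=1)

    def summary(self) -> str:
        lines = []
        lines.append("Feature-ensemble experiment")
        lines.append("=" * 64)
        lines.append(f"seed: {self.seed}   grid-search mode: {self.model.mode}")
        lines.append(
            f"samples: {len(self.model.tables[0].sample_ids)}   "
            f"train/test: {len(self.model.partition.train_ids)}/"
            f"{len(self.model.partition.test_ids)}"
        )
        lines.append("")
        lines.append("Evaluation matrix (test accuracy per extractor x classifier)")
        df = self.evaluation_matrix.accuracies.copy()
        df["Average"] = df.mean(axis=1)
        lines.append(df.round(4).to_string())
        lines.append("")
        lines.append(f"Selected top-{len(self.selection.selected)}: "
                     + ", ".join(self.selection.selected))
        for eid, reason in self.selection.excluded:
            lines.append(f"  excluded {eid}: {reason}")
        for a, b, win, sa, sb in self.selection.tie_breaks:
            lines.append(
                f"  mean tie {a} vs {b}: winner {win} (std {sa:.4f} vs {sb:.4f})"
            )
        lines.append("")
        lines.append("Ensemble grid (test accuracy per combination x classifier)")
        eg = self.ensemble_grid.copy()
        eg["Average"] = eg.mean(axis=1)
        lines.append(eg.round(4).to_string())
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "mode": self.model.mode,
            "evaluation_matrix": self.evaluation_matrix.accuracies.to_dict(),
            "families": self.evaluation_matrix.families,
            "ranking": self.selection.ranking,
            "selected": self.selection.selected,
            "excluded": [list(e) for e in self.selection.excluded],
            "tie_breaks": [list(t) for t in self.selection.tie_breaks],
            "ensemble_grid": self.ensemble_grid.to_dict(),
        }


class FeatureEnsembleModel:
    """End-to-end feature-ensemble experiment over a bank of feature tables.

    Parameters
    ----------
    tables
        Row-aligned feature tables, one per candidate extractor.
    classifier_specs
        The bank members; defaults to the nine classifiers with desk-scale
        grids (:func:`featfuse.classifiers.reduced_specs`).
    k
        Number of representations to select (3 reproduces the study design).
    mode
        Grid-search protocol, ``"holdout"`` (default) or ``"paper_faithful"``.
    train_fraction, stratified
        Split protocol; 0.8 matches the published 80/20 splits.
    """

    def __init__(
        self,
        tables: list[FeatureTable],
        classifier_specs: list[ClassifierSpec] | None = None,
        k: int = 3,
        mode: str = "holdout",
        train_fraction: float = 0.8,
        stratified: bool = False,
        partition: SplitPartition | None = None,
    ) -> None:
        if not tables:
            raise InvalidInputError("no feature tables")
        self.tables = tables
        self.classifier_specs = classifier_specs
        self.k = k
        self.mode = mode
        self.train_fraction = train_fraction
        self.stratified = stratified
        self.partition = partition

    @classmethod
    def from_feature_bank(cls, tables: list[FeatureTable], **kwargs) -> "FeatureEnsembleModel":
        return cls(tables, **kwargs)

    def fit(self, seed: int = 0) -> FeatureEnsembleResults:
        """Run matrix -> selection -> enumeration -> ensemble evaluation."""
        specs = self.classifier_specs
        if specs is None:
            specs = reduced_specs(seed=substream_seed(seed, "classifiers"))
        if self.partition is None:
            ref = self.tables[0]
            self.partition = split_dataset(
                list(ref.sample_ids),
                list(ref.labels),
                self.train_fraction,
                seed=substream_seed(seed, "split"),
                stratified=self.stratified,
            )
        matrix = build_evaluation_matrix(self.tables, specs, self.partition, mode=self.mode)
        selection = select_top_k(matrix, k=self.k)

        by_id = {t.extractor_id: t for t in self.tables}
        grid_rows = {}
        for ens in enumerate_ensembles(selection.selected):
            table = concatenate_features([by_id[m] for m in ens.member_ids])
            X_tr, y_tr = table.rows_for(list(self.partition.train_ids))
            X_te, y_te = table.rows_for(list(self.partition.test_ids))
            row = {}
            for spec in specs:
                _, acc = grid_search(spec, X_tr, y_tr, X_te, y_te, mode=self.mode)
                row[spec.name] = acc
            grid_rows[ens.derived_id] = row
        grid = pd.DataFrame.from_dict(grid_rows, orient="index")
        grid = grid[[s.name for s in specs]]
        return FeatureEnsembleResults(
            model=self,
            evaluation_matrix=matrix,
            selection=selection,
            ensemble_grid=grid,
            seed=seed,
        )


def run_experiment(
    tables: list[FeatureTable],
    classifier_specs: list[ClassifierSpec] | None = None,
    k: int = 3,
    mode: str = "holdout",
    seed: int = 0,
    train_fraction: float = 0.8,
    stratified: bool = False,
) -> FeatureEnsembleResults:
    """Functional wrapper over :class:`FeatureEnsembleModel`."""
    model = FeatureEnsembleModel(
        tables,
        classifier_specs=classifier_specs,
        k=k,
        mode=mode,
        train_fraction=train_fraction,
        stratified=stratified,
    )
    return model.fit(seed=seed)
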