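"""Evaluation matrix construction and top-k extractor selection.

Each candidate feature representation is scored by every classifier in the
bank, producing an extractor x classifier grid of test accuracies.  Extractors
are ranked by their row mean; mean ties (at full precision, or at the
4-decimal display precision used in published grids) are broken by the lower
population standard deviation of the row; residual ties fall back to the
lexicographically smaller extractor id.  Walking down that ranking, an
extractor whose architecture family is already represented among the selected
ones is excluded ("homogeneous-family" rule: same-lineage networks such as
DenseNet-121 and DenseNet-169 yield largely redundant feature spaces) and the
next-best extractor is taken instead.  Every exclusion and tie-break is
recorded so the decision can be audited.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifiers import ClassifierSpec, grid_search
from .errors import InvalidInputError, SelectionInfeasibleError
from .features import FeatureTable, family_of
from .preprocessing import SplitPartition

__all__ = [
    "EvaluationMatrix",
    "SelectionResult",
    "build_evaluation_matrix",
    "row_summary",
    "column_summary",
    "select_top_k",
    "brute_force_select",
]

DISPLAY_DECIMALS = 4


@dataclass
class EvaluationMatrix:
    """Extractor x classifier accuracy grid with per-extractor families."""

    accuracies: pd.DataFrame  # index: extractor ids, columns: classifier names
    families: dict[str, str]

    def __post_init__(self) -> None:
        vals = self.accuracies.to_numpy(dtype=float)
        if vals.size and (np.nanmin(vals) < 0.0 or np.nanmax(vals) > 1.0):
            raise InvalidInputError("accuracies must lie in [0, 1]")
        missing = [e for e in self.accuracies.index if e not in self.families]
        if missing:
            raise InvalidInputError(f"missing family labels for {missing}")

    @property
    def extractor_ids(self) -> list[str]:
        return list(self.accuracies.index)

    @property
    def classifier_names(self) -> list[str]:
        return list(self.accuracies.columns)

    def row(self, extractor_id: str) -> np.ndarray:
        if extractor_id not in self.accuracies.index:
            raise InvalidInputError(f"unknown extractor {extractor_id!r}")
        return self.accuracies.loc[extractor_id].to_numpy(dtype=float)


@dataclass
class SelectionResult:
    """Ordered selection plus a full audit trail."""

    ranking: list[str]
    selected: list[str]
    excluded: list[tuple[str, str]] = field(default_factory=list)
    tie_breaks: list[tuple[str, str, str, float, float]] = field(default_factory=list)


def build_evaluation_matrix(
    tables: list[FeatureTable],
    specs: list[ClassifierSpec],
    partition: SplitPartition,
    mode: str = "holdout",
) -> EvaluationMatrix:
    """Grid-search and score every (extractor, classifier) pair.

    Cell (e, c) is the test accuracy of classifier c trained on extractor e's
    training rows. All tables must carry identical sample ids and labels.
    """
    if not tables:
        raise InvalidInputError("no feature tables given")
    ref = tables[0]
    for t in tables[1:]:
        if list(t.sample_ids) != list(ref.sample_ids) or not np.array_equal(t.labels, ref.labels):
            raise InvalidInputError(
                f"feature table {t.extractor_id!r} is not row-aligned with {ref.extractor_id!r}"
            )
    known = set(ref.sample_ids)
    for sid in itertools.chain(partition.train_ids, partition.test_ids):
        if sid not in known:
            raise InvalidInputError(f"partition id {sid!r} not present in feature tables")

    grid = {}
    families = {}
    for t in tables:
        X_tr, y_tr = t.rows_for(list(partition.train_ids))
        X_te, y_te = t.rows_for(list(partition.test_ids))
        row = {}
        for spec in specs:
            _, acc = grid_search(spec, X_tr, y_tr, X_te, y_te, mode=mode)
            row[spec.name] = acc
        grid[t.extractor_id] = row
        families[t.extractor_id] = t.family
    df = pd.DataFrame.from_dict(grid, orient="index")
    df = df.loc[[t.extractor_id for t in tables], [s.name for s in specs]]
    return EvaluationMatrix(df, families)


def row_summary(matrix: EvaluationMatrix, extractor_id: str) -> tuple[float, float]:
    """(mean, population std) of one extractor's accuracies over classifiers."""
    row = matrix.row(extractor_id)
    return float(np.mean(row)), float(np.std(row))


def column_summary(matrix: EvaluationMatrix, classifier_name: str) -> float:
    """Mean accuracy of one classifier over all extractors."""
    if classifier_name not in matrix.accuracies.columns:
        raise InvalidInputError(f"unknown classifier {classifier_name!r}")
    return float(matrix.accuracies[classifier_name].mean())


def _rank_key(matrix: EvaluationMatrix, extractor_id: str) -> tuple:
    """Sort key implementing the ranking rules (best first under tuple <).

    Rounding the mean to display precision makes extractors whose means agree
    at 4 decimals (a true tie in a published grid) compare equal on the first
    component, letting the std break the tie; rounding is order-preserving so
    distinct rounded means sort exactly as the full-precision means do.
    """
    mean, std = row_summary(matrix, extractor_id)
    return (-round(mean, DISPLAY_DECIMALS), std, str(extractor_id))


def _ranked_ids(matrix: EvaluationMatrix) -> tuple[list[str], list[tuple]]:
    ids = matrix.extractor_ids
    keys = {e: _rank_key(matrix, e) for e in ids}
    ranking = sorted(ids, key=keys.__getitem__)
    tie_log = []
    for a, b in zip(ranking, ranking[1:]):
        if keys[a][0] == keys[b][0]:  # display-precision mean tie
            _, std_a = row_summary(matrix, a)
            _, std_b = row_summary(matrix, b)
            tie_log.append((a, b, a if std_a <= std_b else b, std_a, std_b))
    return ranking, tie_log


def select_top_k(matrix: EvaluationMatrix, k: int = 3) -> SelectionResult:
    """Greedy top-k selection under the homogeneous-family exclusion rule."""
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    n_families = len(set(matrix.families[e] for e in matrix.extractor_ids))
    if n_families < k:
        raise SelectionInfeasibleError(
            f"need {k} distinct families, matrix has only {n_families}"
        )
    ranking, tie_log = _ranked_ids(matrix)
    selected: list[str] = []
    used_families: set[str] = set()
    excluded: list[tuple[str, str]] = []
    for e in ranking:
        if len(selected) == k:
            break
        fam = matrix.families[e]
        if fam in used_families:
            excluded.append((e, "homogeneous-family"))
            continue
        selected.append(e)
        used_families.add(fam)
    return SelectionResult(ranking=ranking, selected=selected, excluded=excluded, tie_breaks=tie_log)


def brute_force_select(matrix: EvaluationMatrix, k: int = 3) -> SelectionResult:
    """Exhaustive oracle: best family-distinct k-subset under the same rules.

    Scores every k-subset with pairwise-distinct families by the sorted tuple
    of per-extractor ranking keys and returns the lexicographic optimum, which
    for this partition-matroid constraint coincides with the greedy walk.
    Intended for tests; exponential in k.
    """
    if k < 1:
        raise InvalidInputError("k must be >= 1")
    ids = matrix.extractor_ids
    keys = {e: _rank_key(matrix, e) for e in ids}
    best_subset: tuple | None = None
    best_score: tuple | None = None
    for subset in itertools.combinations(sorted(ids, key=keys.__getitem__), k):
        fams = [matrix.families[e] for e in subset]
        if len(set(fams)) < k:
            continue
        score = tuple(sorted(keys[e] for e in subset))
        if best_score is None or score < best_score:
            best_score, best_subset = score, subset
    if best_subset is None:
        raise SelectionInfeasibleError(f"no family-distinct subset of size {k}")
    ranking, tie_log = _ranked_ids(matrix)
    chosen = sorted(best_subset, key=keys.__getitem__)
    return SelectionResult(ranking=ranking, selected=list(chosen), excluded=[], tie_breaks=tie_log)


def matrix_from_tables_layout(
    df: pd.DataFrame, families: dict[str, str] | None = None
) -> EvaluationMatrix:
    """Build an EvaluationMatrix from a published-style grid.

    Accepts a DataFrame indexed by extractor id with one column per classifier;
    an "Average" row/column, if present, is dropped and recomputed on demand.
    Families default to :func:`featfuse.features.family_of` on the ids.
    """
    df = df.drop(index=[i for i in df.index if str(i).lower() == "average"], errors="ignore")
    df = df.drop(columns=[c for c in df.columns if str(c).lower() == "average"], errors="ignore")
    fams = families or {e: family_of(str(e)) for e in df.index}
    return EvaluationMatrix(df.astype(float), fams)
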