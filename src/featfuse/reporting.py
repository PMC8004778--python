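"""Rendering experiment results to CSV grids and audit files.

The evaluation matrix is written in the published grid layout — one row per
extractor, the nine classifier columns, and an "Average" row and column —
and the ensemble grid adds a per-row best-classifier flag.  A JSON manifest
(config echo, seed, selection audit) makes the run reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .ensemble import FeatureEnsembleResults
from .errors import InvalidInputError
from .selection import EvaluationMatrix

__all__ = ["matrix_to_csv", "matrix_from_csv", "render_report"]

_AVERAGE = "Average"


def matrix_to_csv(matrix: EvaluationMatrix, path: str | Path) -> None:
    """Write the extractor x classifier grid with Average row and column."""
    df = matrix.accuracies.copy()
    df[_AVERAGE] = df.mean(axis=1)
    avg_row = df.mean(axis=0)
    df.loc[_AVERAGE] = avg_row
    df.index.name = "extractor"
    df.round(6).to_csv(path)


def matrix_from_csv(path: str | Path) -> EvaluationMatrix:
    """Read a grid written by :func:`matrix_to_csv` (Average rows dropped)."""
    from .selection import matrix_from_tables_layout

    path = Path(path)
    if not path.exists():
        raise InvalidInputError(f"no such matrix file: {path}")
    df = pd.read_csv(path, index_col=0)
    return matrix_from_tables_layout(df)


def render_report(results: FeatureEnsembleResults, out_dir: str | Path, dataset_name: str = "run") -> dict[str, Path]:
    """Write the full experiment report into a directory.

    Produces ``evaluation_matrix.csv``, ``ensemble_grid.csv`` (with per-row
    best-classifier flag), ``selection_audit.txt``, ``summary.txt`` and
    ``manifest.json``; returns the paths keyed by artifact name.
    """
    if not dataset_name:
        raise InvalidInputError("dataset_name must be non-empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["evaluation_matrix"] = out / "evaluation_matrix.csv"
    matrix_to_csv(results.evaluation_matrix, paths["evaluation_matrix"])

    grid = results.ensemble_grid.copy()
    grid[_AVERAGE] = grid.mean(axis=1)
    grid["best_classifier"] = results.ensemble_grid.idxmax(axis=1)
    grid.index.name = "ensemble"
    paths["ensemble_grid"] = out / "ensemble_grid.csv"
    grid.round(6).to_csv(paths["ensemble_grid"])

    audit_lines = [f"dataset: {dataset_name}", f"seed: {results.seed}", ""]
    audit_lines.append("ranking (best first):")
    for eid in results.selection.ranking:
        audit_lines.append(f"  {eid}")
    audit_lines.append("selected: " + ", ".join(results.selection.selected))
    for eid, reason in results.selection.excluded:
        audit_lines.append(f"excluded: {eid} ({reason})")
    for a, b, win, sa, sb in results.selection.tie_breaks:
        audit_lines.append(f"tie-break: {a} vs {b} -> {win} (std {sa:.6f} vs {sb:.6f})")
    paths["selection_audit"] = out / "selection_audit.txt"
    paths["selection_audit"].write_text("\n".join(audit_lines) + "\n")

    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text(results.summary() + "\n")

    paths["manifest"] = out / "manifest.json"
    with open(paths["manifest"], "w") as fh:
        json.dump({"dataset": dataset_name, **results.to_dict()}, fh, indent=2, default=str)
    return paths
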