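"""Metagene scoring: per-sample mean of standardized expression over a panel.

The metagene score of sample s for cell type c is

    score(s, c) = (1 / n_P) * sum_{i in P_c} x_is

where x is expression standardized to mean 0 / SD 1 per gene across the
dataset's samples and P_c is the cell type's marker panel.  Scores are
therefore comparable across samples within one dataset but not across
datasets standardized separately; the TSV writer records a dataset id so
downstream comparisons stay within one standardization.

Panels built on one platform may lose genes on another (e.g. human-derived
markers scored on a mouse array through an orthology map); the default
missing-gene policy drops absent genes and records the effective panel size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix
from .marker_selection import MarkerPanel

__all__ = ["ScoreMatrix", "SelfRecoveryResult", "score_metagenes", "self_recovery",
           "write_scores", "read_scores"]

logger = logging.getLogger(__name__)

#: largest per-gene |mean| tolerated before input is deemed unstandardized
_STANDARDIZED_TOL = 1e-6


@dataclass
class ScoreMatrix:
    """Samples x cell-types metagene scores (unitless z-score averages)."""

    data: pd.DataFrame
    sample_labels: dict[str, str] | None = None
    effective_n: dict[str, int] | None = None
    dataset_id: str | None = None

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    @property
    def cell_types(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


def score_metagenes(
    m: ExpressionMatrix, panel: MarkerPanel, missing_policy: str = "drop"
) -> ScoreMatrix:
    """Score every sample of a standardized matrix against every metagene.

    *m* must already be standardized (any gene row mean beyond 1e-6 raises).
    Under ``missing_policy='drop'`` panel genes absent from the matrix are
    excluded and the effective panel size recorded; ``'error'`` demands
    every panel gene be present.  A panel with no present genes always
    raises.
    """
    if missing_policy not in ("drop", "error"):
        raise ValueError(f"missing_policy must be 'drop' or 'error', got {missing_policy!r}")
    m.require_unique_genes()
    row_means = m.values.mean(axis=1)
    worst = float(np.max(np.abs(row_means))) if row_means.size else 0.0
    if worst > _STANDARDIZED_TOL:
        raise ValueError(
            f"input does not look standardized: a gene row mean is {worst:.3g} "
            f"(limit {_STANDARDIZED_TOL:g}); run standardize_genes first"
        )

    index = {g: i for i, g in enumerate(m.gene_ids)}
    values = m.values
    cols: dict[str, np.ndarray] = {}
    effective: dict[str, int] = {}
    for cls, genes in panel.panels.items():
        present = [g for g in genes if g in index]
        absent = [g for g in genes if g not in index]
        if absent and missing_policy == "error":
            raise ValueError(f"panel {cls!r} genes missing from matrix: {absent[:10]}")
        if not present:
            raise ValueError(f"panel {cls!r} has no genes present in the matrix")
        if absent:
            logger.info(
                "panel %s: %d of %d genes absent, scoring with effective n_p=%d",
                cls, len(absent), len(genes), len(present),
            )
        rows = [index[g] for g in present]
        cols[cls] = values[rows].mean(axis=0)
        effective[cls] = len(present)

    data = pd.DataFrame(cols, index=m.sample_ids)
    return ScoreMatrix(data, sample_labels=m.sample_labels, effective_n=effective)


@dataclass
class SelfRecoveryResult:
    """Per-class outcome of the purified-population validation.

    A cell type passes when the mean of its own metagene over its purified
    samples strictly exceeds that metagene's mean in every other class's
    samples; ``margins`` holds own-mean minus best-other-mean.
    """

    passed: dict[str, bool]
    margins: dict[str, float]

    @property
    def n_passed(self) -> int:
        return sum(self.passed.values())

    @property
    def n_classes(self) -> int:
        return len(self.passed)

    @property
    def all_passed(self) -> bool:
        return all(self.passed.values())


def self_recovery(
    scores: ScoreMatrix, labels: Mapping[str, str] | None = None
) -> SelfRecoveryResult:
    """Check that each metagene is highest in its own purified cell population."""
    if labels is None:
        if scores.sample_labels is None:
            raise ValueError("no sample labels supplied for self-recovery check")
        labels = scores.sample_labels
    missing = [s for s in scores.sample_ids if s not in labels]
    if missing:
        raise ValueError(f"unlabeled samples: {missing}")
    present_classes = {labels[s] for s in scores.sample_ids}
    absent = [c for c in scores.cell_types if c not in present_classes]
    if absent:
        raise ValueError(f"panel classes with no labeled samples: {absent}")

    by_class: dict[str, list[str]] = {}
    for s in scores.sample_ids:
        by_class.setdefault(labels[s], []).append(s)

    passed: dict[str, bool] = {}
    margins: dict[str, float] = {}
    for cls in scores.cell_types:
        column = scores.data[cls]
        own = float(column.loc[by_class[cls]].mean())
        others = [
            float(column.loc[samples].mean())
            for other, samples in by_class.items()
            if other != cls
        ]
        margin = own - max(others)
        margins[cls] = margin
        passed[cls] = margin > 0
    return SelfRecoveryResult(passed=passed, margins=margins)


def write_scores(scores: ScoreMatrix, path: str | Path) -> None:
    """Write scores as TSV (rows = samples), with a group column when labeled."""
    path = Path(path)
    df = scores.data.copy()
    if scores.sample_labels is not None:
        df.insert(0, "group", [scores.sample_labels.get(s, "") for s in scores.sample_ids])
    with path.open("w", encoding="utf-8") as fh:
        if scores.dataset_id is not None:
            fh.write(f"# dataset_id={scores.dataset_id}\n")
        df.to_csv(fh, sep="\t", index_label="sample_id", float_format="%.17g")


def read_scores(path: str | Path) -> ScoreMatrix:
    """Read a score TSV written by :func:`write_scores`."""
    path = Path(path)
    dataset_id = None
    with path.open(encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("# dataset_id="):
            dataset_id = first.strip().split("=", 1)[1]
        else:
            fh.seek(0)
        df = pd.read_csv(fh, sep="\t", index_col="sample_id")
    labels = None
    if "group" in df.columns:
        labels = {str(s): str(g) for s, g in df["group"].items()}
        df = df.drop(columns="group")
    return ScoreMatrix(df, sample_labels=labels, dataset_id=dataset_id)
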