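"""Differential infiltration: per-cell-type two-sample t-tests on scores.

Each cell type's metagene scores are compared between control and disease
samples with a two-sided t-test (Student pooled-variance by default, Welch
by flag), significance called at p <= alpha (default 0.05).  Differences
and t statistics follow the disease - control convention, so increased
infiltration is positive.  Benjamini-Hochberg q-values are emitted as a
supplementary column; the primary significance call is uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .metagene_scoring import ScoreMatrix

__all__ = ["ComparisonTable", "compare_groups"]

GROUPS = ("control", "disease")


@dataclass
class ComparisonTable:
    """Per-cell-type comparison results.

    ``data`` columns: cell_type, mean_control, mean_disease, diff, t, df, p,
    significant, bh_q.
    """

    data: pd.DataFrame
    alpha: float = 0.05
    variant: str = "student"

    def significant_types(self) -> list[str]:
        return self.data.loc[self.data["significant"], "cell_type"].tolist()

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _ttest(control: np.ndarray, disease: np.ndarray, variant: str) -> tuple[float, float, float]:
    """Two-sided t-test of disease vs control; returns (t, df, p).

    Degenerate zero-variance cases are resolved by the limit of the
    statistic: equal constant groups give t=0, p=1; distinct constant
    groups give an infinite t and p=0.
    """
    n1, n2 = len(control), len(disease)
    if variant == "student":
        pooled = ((n1 - 1) * control.var(ddof=1) + (n2 - 1) * disease.var(ddof=1)) / (
            n1 + n2 - 2
        )
        if pooled == 0:
            diff = disease.mean() - control.mean()
            if diff == 0:
                return 0.0, float(n1 + n2 - 2), 1.0
            return float(np.sign(diff) * np.inf), float(n1 + n2 - 2), 0.0
        res = stats.ttest_ind(disease, control, equal_var=True)
    elif variant == "welch":
        if control.var(ddof=1) == 0 and disease.var(ddof=1) == 0:
            diff = disease.mean() - control.mean()
            if diff == 0:
                return 0.0, float(n1 + n2 - 2), 1.0
            return float(np.sign(diff) * np.inf), float(n1 + n2 - 2), 0.0
        res = stats.ttest_ind(disease, control, equal_var=False)
    else:
        raise ValueError(f"variant must be 'student' or 'welch', got {variant!r}")
    return float(res.statistic), float(res.df), float(res.pvalue)


def compare_groups(
    scores: ScoreMatrix,
    groups: Mapping[str, str] | None = None,
    variant: str = "student",
    alpha: float = 0.05,
) -> ComparisonTable:
    """Test each cell type's scores for a disease vs control difference.

    *groups* maps sample id -> ``"control"`` or ``"disease"`` (defaults to
    the score matrix's own labels).  Both groups need >=2 samples.  Student's
    test uses the pooled variance with df = n1 + n2 - 2; Welch's uses the
    Satterthwaite df.
    """
    if groups is None:
        if scores.sample_labels is None:
            raise ValueError("no group labels supplied")
        groups = scores.sample_labels
    missing = [s for s in scores.sample_ids if s not in groups]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    unknown = sorted({groups[s] for s in scores.sample_ids} - set(GROUPS))
    if unknown:
        raise ValueError(f"unknown group labels {unknown}; expected {GROUPS}")
    control_ids = [s for s in scores.sample_ids if groups[s] == "control"]
    disease_ids = [s for s in scores.sample_ids if groups[s] == "disease"]
    for name, ids in (("control", control_ids), ("disease", disease_ids)):
        if len(ids) < 2:
            raise ValueError(f"group {name!r} has {len(ids)} sample(s); need >= 2")

    rows = []
    for cell_type in scores.cell_types:
        col = scores.data[cell_type]
        control = col.loc[control_ids].to_numpy()
        disease = col.loc[disease_ids].to_numpy()
        t, df, p = _ttest(control, disease, variant)
        rows.append(
            {
                "cell_type": cell_type,
                "mean_control": float(control.mean()),
                "mean_disease": float(disease.mean()),
                "diff": float(disease.mean() - control.mean()),
                "t": t,
                "df": df,
                "p": p,
                "significant": bool(p <= alpha),
            }
        )
    table = pd.DataFrame(rows)
    table["bh_q"] = stats.false_discovery_control(table["p"].to_numpy(), method="bh")
    return ComparisonTable(data=table, alpha=alpha, variant=variant)
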