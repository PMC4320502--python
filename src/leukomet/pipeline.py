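"""End-to-end convenience drivers tying the pipeline stages together.

These helpers run the full marker-panel / scoring / comparison chain on
simulated data and back the analysis scripts, the test suite and the
acceptance checks; each stage remains usable on its own for real matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

from .expression_io import standardize_genes
from .group_comparison import ComparisonTable, compare_groups
from .marker_selection import CentroidModel, MarkerPanel, fit_centroids, select_markers
from .metagene_scoring import ScoreMatrix, SelfRecoveryResult, score_metagenes, self_recovery
from .synthetic_data import (
    CohortSimulation,
    ReferenceSimulation,
    SimulationConfig,
    simulate_cohort,
    simulate_reference,
)

__all__ = ["ReferencePanel", "CohortStudy", "build_reference_panel", "run_cohort_study"]


@dataclass
class ReferencePanel:
    """A fitted reference: simulation truth, NSC model, panels, validation."""

    reference: ReferenceSimulation
    model: CentroidModel
    panel: MarkerPanel
    reference_scores: ScoreMatrix
    recovery: SelfRecoveryResult


@dataclass
class CohortStudy:
    """One simulated cohort scored and tested against a marker panel."""

    cohort: CohortSimulation
    scores: ScoreMatrix
    comparison: ComparisonTable


def build_reference_panel(
    cfg: SimulationConfig, seed: int | None = None, k: int = 25, rank: str = "signed"
) -> ReferencePanel:
    """Simulate a purified-leukocyte reference, fit NSC and select panels.

    Also scores the reference against its own panels and runs the
    self-recovery validation (each metagene highest in its own population).
    """
    reference = simulate_reference(cfg, seed=seed)
    model = fit_centroids(reference.matrix)
    panel = select_markers(model, k=k, rank=rank)
    scores = score_metagenes(standardize_genes(reference.matrix), panel)
    recovery = self_recovery(scores)
    return ReferencePanel(
        reference=reference,
        model=model,
        panel=panel,
        reference_scores=scores,
        recovery=recovery,
    )


def run_cohort_study(
    cfg: SimulationConfig,
    panel: MarkerPanel,
    signatures,
    seed: int | None = None,
    variant: str = "student",
    alpha: float = 0.05,
) -> CohortStudy:
    """Simulate a bulk cohort, score it with *panel* and compare the groups."""
    cohort = simulate_cohort(cfg, signatures, seed=seed)
    scores = score_metagenes(standardize_genes(cohort.matrix), panel)
    comparison = compare_groups(scores, cohort.groups, variant=variant, alpha=alpha)
    return CohortStudy(cohort=cohort, scores=scores, comparison=comparison)
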