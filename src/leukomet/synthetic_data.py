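"""Synthetic reference and cohort generators with the structure the
pipeline assumes.

Two generators cover the two kinds of input the analysis needs:

* :func:`simulate_reference` emulates purified leukocyte profiles — six
  sorted populations (monocytes, dendritic cells, NK, CD4+ T, CD8+ T and B
  cells) with two replicate arrays each.  Every class owns a disjoint block
  of marker genes elevated by ``marker_effect`` noise-SD units above a
  shared per-gene baseline; i.i.d. Gaussian noise of SD ``noise_sd`` is
  added on the log-like scale.

* :func:`simulate_cohort` emulates bulk biopsies as convex mixtures of the
  cell-type signatures plus a stromal background: each sample's cell
  fractions are drawn from a Dirichlet around its group's mean fractions,
  the disease group's means are shifted by ``fraction_shift`` (absorbed by
  the stromal remainder, so unshifted leukocyte types remain true nulls),
  and measurement noise of SD ``bulk_noise_sd`` is added per gene.

Both generators are fully determined by the config and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .expression_io import ExpressionMatrix

__all__ = [
    "LEUKOCYTE_CLASSES",
    "STROMAL",
    "SimulationConfig",
    "ReferenceSimulation",
    "CohortSimulation",
    "simulate_reference",
    "simulate_cohort",
]

LEUKOCYTE_CLASSES = ("Monocyte", "DC", "NK", "CD4T", "CD8T", "B")
STROMAL = "Stromal"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study layout the pipeline targets: a 6-class x 2
    replicate purified-leukocyte reference over 500 genes with 30 disjoint
    markers per class elevated by 3 noise-SD units, and a human-style
    cohort of 7 control vs 8 disease biopsies whose leukocyte content sits
    on a simplex with a stromal remainder of 0.5 in controls (a mouse-style
    4 vs 4 cohort is the same config with ``n_control=n_disease=4``).

    ``noise_sd`` is the per-gene profiling noise of the sorted-population
    arrays; ``bulk_noise_sd`` (default 0.3) is the smaller replicate-level
    noise of bulk hybridizations, which average far more input material.
    ``fraction_shift`` adds to the disease group's mean leukocyte fractions
    (e.g. ``{"DC": 0.15, "CD4T": 0.15}``); the stromal remainder shrinks to
    compensate.  ``dirichlet_concentration`` controls biological
    variability of per-sample fractions (larger = tighter around the group
    mean).  ``mixing`` is ``"linear"`` (mix on the log-like scale) or
    ``"lognormal"`` (mix on the linear scale, then log2).
    """

    class_names: tuple[str, ...] = LEUKOCYTE_CLASSES
    replicates_per_class: int = 2
    n_genes: int = 500
    markers_per_class: int = 30
    marker_effect: float = 3.0
    noise_sd: float = 1.0
    bulk_noise_sd: float = 0.3
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    n_control: int = 7
    n_disease: int = 8
    baseline_fractions: dict[str, float] | None = None
    stromal_fraction: float = 0.5
    fraction_shift: dict[str, float] = field(default_factory=dict)
    dirichlet_concentration: float = 50.0
    mixing: str = "linear"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.class_names = tuple(self.class_names)
        if self.markers_per_class * self.n_classes > self.n_genes:
            raise ValueError(
                f"marker capacity exceeded: {self.n_classes} classes x "
                f"{self.markers_per_class} markers > {self.n_genes} genes"
            )
        if self.mixing not in ("linear", "lognormal"):
            raise ValueError(f"mixing must be 'linear' or 'lognormal', got {self.mixing!r}")
        if not 0 <= self.stromal_fraction < 1:
            raise ValueError("stromal_fraction must lie in [0, 1)")
        for c, f in self.leukocyte_fractions().items():
            if f < 0:
                raise ValueError(f"baseline fraction for {c!r} is negative")
        total = sum(self.leukocyte_fractions().values()) + self.stromal_fraction
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"fractions plus stromal remainder sum to {total}, not 1")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def leukocyte_fractions(self) -> dict[str, float]:
        """Control-group mean fraction per leukocyte class (stromal excluded)."""
        if self.baseline_fractions is not None:
            return dict(self.baseline_fractions)
        per_class = (1.0 - self.stromal_fraction) / self.n_classes
        return {c: per_class for c in self.class_names}

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["class_names"] = list(self.class_names)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**doc)


@dataclass
class ReferenceSimulation:
    """A simulated purified-leukocyte reference and its ground truth."""

    matrix: ExpressionMatrix
    marker_map: dict[str, list[str]]
    signatures: pd.DataFrame  # genes x classes noiseless mean expression

    @property
    def labels(self) -> dict[str, str]:
        assert self.matrix.sample_labels is not None
        return self.matrix.sample_labels


@dataclass
class CohortSimulation:
    """A simulated bulk cohort, its group labels and true cell fractions."""

    matrix: ExpressionMatrix
    groups: dict[str, str]
    fractions: pd.DataFrame  # samples x (classes + stromal), rows sum to 1
    mean_fractions: pd.DataFrame  # group x (classes + stromal)


def _resolve_seed(cfg: SimulationConfig, seed: int | None) -> np.random.Generator:
    if seed is None:
        seed = cfg.seed
    return np.random.default_rng(seed)


def simulate_reference(
    cfg: SimulationConfig, seed: int | None = None
) -> ReferenceSimulation:
    """Generate purified-population profiles with known marker genes.

    Marker genes are assigned to classes by a random disjoint draw; a
    marker of class c has mean ``baseline + marker_effect * noise_sd`` in
    class-c samples and the shared baseline elsewhere.  Returns the noisy
    matrix (with cell-type labels), the true marker map and the noiseless
    per-class signature matrix used by :func:`simulate_cohort`.
    """
    rng = _resolve_seed(cfg, seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)

    perm = rng.permutation(cfg.n_genes)
    marker_map: dict[str, list[str]] = {}
    signatures = np.tile(baseline[:, np.newaxis], (1, cfg.n_classes))
    for j, cls in enumerate(cfg.class_names):
        block = perm[j * cfg.markers_per_class : (j + 1) * cfg.markers_per_class]
        block = np.sort(block)
        marker_map[cls] = [genes[i] for i in block]
        signatures[block, j] += cfg.marker_effect * cfg.noise_sd

    sample_ids: list[str] = []
    labels: dict[str, str] = {}
    columns = []
    for j, cls in enumerate(cfg.class_names):
        for r in range(cfg.replicates_per_class):
            sid = f"{cls}_{r + 1}"
            sample_ids.append(sid)
            labels[sid] = cls
            columns.append(signatures[:, j])
    values = np.column_stack(columns) + rng.normal(
        0.0, cfg.noise_sd, size=(cfg.n_genes, len(sample_ids))
    )
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids), sample_labels=labels
    )
    signature_df = pd.DataFrame(signatures, index=genes, columns=list(cfg.class_names))
    return ReferenceSimulation(matrix=matrix, marker_map=marker_map, signatures=signature_df)


def _group_mean_fractions(cfg: SimulationConfig) -> pd.DataFrame:
    """Mean fraction vectors (leukocyte classes + stromal) for both groups.

    The disease shift is added to the named leukocyte classes and absorbed
    by the stromal remainder; negative results are clipped to 0 and, should
    the leukocyte total exceed 1, fractions are renormalized onto the
    simplex (stromal 0).
    """
    unknown = sorted(set(cfg.fraction_shift) - set(cfg.class_names))
    if unknown:
        raise ValueError(
            f"fraction_shift names unknown cell types {unknown}; "
            f"known classes: {list(cfg.class_names)}"
        )
    control = cfg.leukocyte_fractions()
    disease = {
        c: max(control[c] + cfg.fraction_shift.get(c, 0.0), 0.0)
        for c in cfg.class_names
    }
    leuk_total = sum(disease.values())
    if leuk_total > 1.0:
        disease = {c: f / leuk_total for c, f in disease.items()}
        stromal_disease = 0.0
    else:
        stromal_disease = 1.0 - leuk_total
    rows = {
        "control": [control[c] for c in cfg.class_names] + [cfg.stromal_fraction],
        "disease": [disease[c] for c in cfg.class_names] + [stromal_disease],
    }
    return pd.DataFrame.from_dict(
        rows, orient="index", columns=[*cfg.class_names, STROMAL]
    )


def simulate_cohort(
    cfg: SimulationConfig,
    signatures: pd.DataFrame,
    seed: int | None = None,
    stromal_signature: pd.Series | None = None,
) -> CohortSimulation:
    """Generate bulk samples as noisy convex mixtures of cell signatures.

    *signatures* is a genes x cell-types matrix covering every configured
    class (e.g. ``ReferenceSimulation.signatures``).  The stromal signature
    defaults to the per-gene minimum of the leukocyte signatures (the
    shared baseline) plus its own random gene effects of unit SD on
    non-marker genes only — leukocyte lineage markers are at baseline in
    stroma just as they are in every other leukocyte class, which is what
    makes them markers.  Each sample's fraction vector is drawn from
    Dirichlet(concentration x group mean fractions); per-sample fractions
    sum to 1 exactly.
    """
    missing = [c for c in cfg.class_names if c not in signatures.columns]
    if missing:
        raise ValueError(f"signatures missing configured cell types: {missing}")
    rng = _resolve_seed(cfg, seed)
    genes = list(signatures.index)
    sig = signatures[list(cfg.class_names)].to_numpy(dtype=float)
    if stromal_signature is None:
        non_marker = np.ptp(sig, axis=1) == 0
        stromal = sig.min(axis=1) + non_marker * rng.normal(0.0, 1.0, size=len(genes))
    else:
        stromal = stromal_signature.reindex(genes).to_numpy(dtype=float)
        if not np.isfinite(stromal).all():
            raise ValueError("stromal signature does not cover all signature genes")
    full_sig = np.column_stack([sig, stromal])

    means = _group_mean_fractions(cfg)
    sample_ids: list[str] = []
    groups: dict[str, str] = {}
    fracs: list[np.ndarray] = []
    for group, n in (("control", cfg.n_control), ("disease", cfg.n_disease)):
        mean_vec = means.loc[group].to_numpy()
        alive = mean_vec > 0
        for i in range(n):
            sid = f"{'Ctrl' if group == 'control' else 'Dis'}_{i + 1}"
            sample_ids.append(sid)
            groups[sid] = group
            f = np.zeros_like(mean_vec)
            f[alive] = rng.dirichlet(cfg.dirichlet_concentration * mean_vec[alive])
            fracs.append(f)
    frac_matrix = np.vstack(fracs)  # samples x (K+1)

    if cfg.mixing == "linear":
        expr = full_sig @ frac_matrix.T
    else:
        expr = np.log2(np.exp2(full_sig) @ frac_matrix.T)
    expr = expr + rng.normal(0.0, cfg.bulk_noise_sd, size=expr.shape)

    matrix = ExpressionMatrix(
        pd.DataFrame(expr, index=genes, columns=sample_ids), sample_labels=dict(groups)
    )
    fractions = pd.DataFrame(
        frac_matrix, index=sample_ids, columns=[*cfg.class_names, STROMAL]
    )
    return CohortSimulation(
        matrix=matrix, groups=groups, fractions=fractions, mean_fractions=means
    )
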