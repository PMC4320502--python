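"""Nearest-shrunken-centroid statistics and marker-panel selection.

Given purified leukocyte profiles with one class per cell population, the
standard NSC statistics are computed per gene i and class k:

    d_ik = (xbar_ik - xbar_i) / (m_k * (s_i + s0))

with xbar_ik the class centroid, xbar_i the overall centroid, s_i the
pooled within-class standard deviation (denominator n - K), the class size
factor m_k = sqrt(1/n_k - 1/n) and the stabilising offset s0 = median_i s_i.
Soft-thresholding shrinks d_ik toward zero by a non-negative delta; the
shrunken class centroids are xbar_i + m_k * (s_i + s0) * d'_ik.

Marker panels ("metagenes") take, for each class, the top-k genes by signed
d_ik — markers must be elevated in their class — with disjointness across
classes enforced by a greedy round-robin so that k markers per class over K
classes always yield k*K distinct genes (150 for the default k=25, K=6).
Classification of a profile uses the shrunken-centroid discriminant

    delta_k(x) = sum_i (x_i - xbar'_ik)^2 / (s_i + s0)^2 - 2 log pi_k

predicting the class minimising delta_k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .expression_io import ExpressionMatrix, read_gmt, write_gmt

__all__ = [
    "CentroidModel",
    "MarkerPanel",
    "fit_centroids",
    "shrink",
    "select_markers",
    "classify",
]

_MODEL_FORMAT_VERSION = 1


@dataclass
class CentroidModel:
    """Fitted nearest-shrunken-centroid state.

    ``class_centroids`` and ``d_stats`` are genes x classes arrays; after
    :func:`shrink` they hold the shrunken centroids/statistics and ``delta``
    records the threshold applied.
    """

    classes: list[str]
    gene_ids: list[str]
    overall_centroid: np.ndarray
    class_centroids: np.ndarray
    pooled_sd: np.ndarray
    s0: float
    m_k: np.ndarray
    d_stats: np.ndarray
    class_sizes: np.ndarray
    priors: np.ndarray
    delta: float = 0.0

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "format_version": _MODEL_FORMAT_VERSION,
            "classes": self.classes,
            "gene_ids": self.gene_ids,
            "overall_centroid": self.overall_centroid.tolist(),
            "class_centroids": self.class_centroids.tolist(),
            "pooled_sd": self.pooled_sd.tolist(),
            "s0": self.s0,
            "m_k": self.m_k.tolist(),
            "d_stats": self.d_stats.tolist(),
            "class_sizes": self.class_sizes.tolist(),
            "priors": self.priors.tolist(),
            "delta": self.delta,
        }
        Path(path).write_text(json.dumps(doc), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "CentroidModel":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        version = doc.get("format_version")
        if version != _MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported centroid-model format version: {version}")
        return cls(
            classes=list(doc["classes"]),
            gene_ids=list(doc["gene_ids"]),
            overall_centroid=np.asarray(doc["overall_centroid"], dtype=float),
            class_centroids=np.asarray(doc["class_centroids"], dtype=float),
            pooled_sd=np.asarray(doc["pooled_sd"], dtype=float),
            s0=float(doc["s0"]),
            m_k=np.asarray(doc["m_k"], dtype=float),
            d_stats=np.asarray(doc["d_stats"], dtype=float),
            class_sizes=np.asarray(doc["class_sizes"], dtype=int),
            priors=np.asarray(doc["priors"], dtype=float),
            delta=float(doc["delta"]),
        )


@dataclass
class MarkerPanel:
    """Ordered top-k marker genes per cell type (one metagene per class)."""

    panels: dict[str, list[str]]
    k: int = field(default=0)

    def __post_init__(self) -> None:
        if self.k == 0 and self.panels:
            self.k = len(next(iter(self.panels.values())))
        seen: set[str] = set()
        for cls, genes in self.panels.items():
            if len(genes) != self.k:
                raise ValueError(
                    f"panel {cls!r} has {len(genes)} genes, expected k={self.k}"
                )
            if len(set(genes)) != len(genes):
                raise ValueError(f"panel {cls!r} contains duplicate genes")
            overlap = seen & set(genes)
            if overlap:
                raise ValueError(f"panels overlap across classes: {sorted(overlap)[:10]}")
            seen |= set(genes)

    @property
    def classes(self) -> list[str]:
        return list(self.panels)

    @property
    def all_genes(self) -> list[str]:
        return [g for genes in self.panels.values() for g in genes]

    def to_gmt(self, path: str | Path) -> None:
        write_gmt(
            self.panels,
            path,
            descriptions={c: f"top {self.k} markers" for c in self.panels},
        )

    @classmethod
    def from_gmt(cls, path: str | Path) -> "MarkerPanel":
        sets = read_gmt(path)
        sizes = {len(genes) for genes in sets.values()}
        if len(sizes) != 1:
            raise ValueError(f"GMT panels have unequal sizes: {sorted(sizes)}")
        return cls(panels={name: list(genes) for name, genes in sets.items()})


def fit_centroids(
    m: ExpressionMatrix, labels: Mapping[str, str] | None = None
) -> CentroidModel:
    """Fit per-gene NSC statistics from a labeled reference matrix.

    *labels* maps sample id -> class; when omitted the matrix's own sample
    labels are used.  Requires >=2 classes and >=2 samples per class (the
    pooled SD needs within-class degrees of freedom); every sample must be
    labeled.  Class order follows first appearance in sample order.
    """
    if labels is None:
        labels = m.labels_for()
    unlabeled = [s for s in m.sample_ids if s not in labels]
    if unlabeled:
        raise ValueError(f"unlabeled samples: {unlabeled}")

    classes: list[str] = []
    for s in m.sample_ids:
        c = labels[s]
        if c not in classes:
            classes.append(c)
    if len(classes) < 2:
        raise ValueError("fitting requires at least 2 classes")

    X = m.values
    n = m.n_samples
    K = len(classes)
    members = {c: [j for j, s in enumerate(m.sample_ids) if labels[s] == c] for c in classes}
    too_small = [c for c, idx in members.items() if len(idx) < 2]
    if too_small:
        raise ValueError(f"classes with fewer than 2 samples: {too_small}")

    class_sizes = np.array([len(members[c]) for c in classes])
    overall = X.mean(axis=1)
    centroids = np.column_stack([X[:, members[c]].mean(axis=1) for c in classes])

    within_ss = np.zeros(m.n_genes)
    for j, c in enumerate(classes):
        resid = X[:, members[c]] - centroids[:, [j]]
        within_ss += (resid**2).sum(axis=1)
    pooled_sd = np.sqrt(within_ss / (n - K))
    s0 = float(np.median(pooled_sd))
    m_k = np.sqrt(1.0 / class_sizes - 1.0 / n)

    denom = m_k[np.newaxis, :] * (pooled_sd + s0)[:, np.newaxis]
    d_stats = (centroids - overall[:, np.newaxis]) / denom

    return CentroidModel(
        classes=classes,
        gene_ids=m.gene_ids,
        overall_centroid=overall,
        class_centroids=centroids,
        pooled_sd=pooled_sd,
        s0=s0,
        m_k=m_k,
        d_stats=d_stats,
        class_sizes=class_sizes,
        priors=class_sizes / n,
    )


def shrink(model: CentroidModel, delta: float) -> CentroidModel:
    """Soft-threshold the d-statistics by *delta* and shrink the centroids."""
    if delta < 0:
        raise ValueError(f"shrinkage threshold must be non-negative, got {delta}")
    d = model.d_stats
    d_shr = np.sign(d) * np.maximum(np.abs(d) - delta, 0.0)
    scale = model.m_k[np.newaxis, :] * (model.pooled_sd + model.s0)[:, np.newaxis]
    centroids = model.overall_centroid[:, np.newaxis] + scale * d_shr
    return replace(model, class_centroids=centroids, d_stats=d_shr, delta=delta)


def _rankings(model: CentroidModel, rank: str) -> dict[str, list[int]]:
    if rank not in ("signed", "abs"):
        raise ValueError(f"rank must be 'signed' or 'abs', got {rank!r}")
    gene_ids = model.gene_ids
    out: dict[str, list[int]] = {}
    for j, cls in enumerate(model.classes):
        score = model.d_stats[:, j] if rank == "signed" else np.abs(model.d_stats[:, j])
        # descending by score, lexicographic gene id on ties
        out[cls] = sorted(range(model.n_genes), key=lambda i: (-score[i], gene_ids[i]))
    return out


def select_markers(model: CentroidModel, k: int, rank: str = "signed") -> MarkerPanel:
    """Pick the top-*k* marker genes per class, disjoint across classes.

    Genes are ranked per class by signed d_ik descending (markers are
    elevated in their class; ``rank='abs'`` ranks by magnitude instead),
    ties broken by lexicographic gene id.  Panels are made disjoint by a
    greedy round-robin: in each of k rounds every class, in class order,
    claims its best still-unclaimed gene.
    """
    if k < 1:
        raise ValueError(f"panel size k must be >= 1, got {k}")
    needed = k * model.n_classes
    if needed > model.n_genes:
        raise ValueError(
            f"cannot build disjoint panels: need {needed} genes "
            f"({model.n_classes} classes x k={k}) but only {model.n_genes} available"
        )
    rankings = _rankings(model, rank)
    cursors = {c: 0 for c in model.classes}
    claimed: set[int] = set()
    panels: dict[str, list[str]] = {c: [] for c in model.classes}
    for _ in range(k):
        for cls in model.classes:
            ranking = rankings[cls]
            pos = cursors[cls]
            while ranking[pos] in claimed:
                pos += 1
            claimed.add(ranking[pos])
            panels[cls].append(model.gene_ids[ranking[pos]])
            cursors[cls] = pos + 1
    return MarkerPanel(panels=panels, k=k)


def classify(
    model: CentroidModel, sample: Sequence[float] | np.ndarray
) -> tuple[str, np.ndarray]:
    """Assign a gene-aligned expression vector to the nearest shrunken centroid.

    Returns the winning class label and the full discriminant-score vector
    (one delta_k per class, aligned with ``model.classes``); the winner is
    the minimiser, ties resolved in class order.
    """
    x = np.asarray(sample, dtype=float)
    if x.shape != (model.n_genes,):
        raise ValueError(
            f"sample has {x.shape} values, model expects ({model.n_genes},)"
        )
    denom = (model.pooled_sd + model.s0) ** 2
    resid = (x[:, np.newaxis] - model.class_centroids) ** 2 / denom[:, np.newaxis]
    scores = resid.sum(axis=0) - 2.0 * np.log(model.priors)
    winner = int(np.argmin(scores))
    return model.classes[winner], scores
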