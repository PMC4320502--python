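"""Expression-matrix I/O and gene-level preprocessing.

The pipeline consumes normalized (log-scale) expression matrices as
tab-delimited text: row 1 is ``gene_id`` followed by sample identifiers, an
optional row 2 is ``label`` followed by per-sample labels (cell type or
study group), and every following row is a gene/probe identifier plus one
numeric value per sample.  Probe-level matrices are collapsed to one row per
gene (the probe with the highest mean), genes are z-standardized across the
samples of a dataset, and two gene-collapsed datasets can be aligned on
their shared genes for cross-platform comparisons.

Marker panels are exchanged in GMT format (set name, description, member
genes, one set per line).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ProbeGeneMap",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "read_probe_map",
    "collapse_to_genes",
    "standardize_genes",
    "align_genes",
    "read_gmt",
    "write_gmt",
]


class MatrixParseError(ValueError):
    """Raised when a tab-delimited input file violates the expected layout."""


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix on a normalized log-like scale.

    Parameters
    ----------
    data
        DataFrame with gene/probe identifiers as the index and sample
        identifiers as columns.  All values must be finite.
    sample_labels
        Optional map sample_id -> label (cell type or study group).

    Gene identifiers may repeat before probe collapse; sample identifiers
    must be unique.  Operations that require one row per gene
    (standardization checks aside, e.g. alignment and scoring) call
    :meth:`require_unique_genes`.
    """

    data: pd.DataFrame
    sample_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.data = self.data.astype(float)
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            n_bad = int((~np.isfinite(values)).sum())
            raise ValueError(f"expression matrix contains {n_bad} non-finite value(s)")
        if self.sample_labels is not None:
            missing = set(self.sample_labels) - set(self.sample_ids)
            if missing:
                raise ValueError(f"labels refer to unknown samples: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return [str(g) for g in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def require_unique_genes(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(
                f"operation requires one row per gene; duplicated gene ids: {dups[:10]}"
            )

    def labels_for(self, samples: Sequence[str] | None = None) -> dict[str, str]:
        """Return labels for the given samples (default: all), erroring on gaps."""
        if self.sample_labels is None:
            raise ValueError("expression matrix carries no sample labels")
        samples = list(samples) if samples is not None else self.sample_ids
        missing = [s for s in samples if s not in self.sample_labels]
        if missing:
            raise ValueError(f"unlabeled samples: {missing}")
        return {s: self.sample_labels[s] for s in samples}


@dataclass
class ProbeGeneMap:
    """Many-to-one probe -> gene map (e.g. derived from Unigene annotation)."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mapping = {str(p): str(g) for p, g in self.mapping.items()}

    def __contains__(self, probe: str) -> bool:
        return probe in self.mapping

    def __getitem__(self, probe: str) -> str:
        return self.mapping[probe]

    def __len__(self) -> int:
        return len(self.mapping)


def read_matrix(path: str | Path, label_row: bool | None = None) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    Layout: header ``gene_id\\t<sample ids...>``; if *label_row* is true the
    second line is ``label\\t<per-sample labels...>``; each further line is a
    gene id followed by one numeric value per sample.  With the default
    ``label_row=None`` the label row is auto-detected from a line-2 first
    field of ``label``.  Malformed lines raise :class:`MatrixParseError`
    naming the offending line (1-based) or cell.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise MatrixParseError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 2:
        raise MatrixParseError(f"{path}, line 1: header must contain at least one sample")
    sample_ids = header[1:]
    ncol = len(header)

    if label_row is None:
        label_row = len(lines) > 1 and lines[1].split("\t", 1)[0] == "label"

    labels: dict[str, str] | None = None
    body_start = 1
    if label_row:
        if len(lines) < 2:
            raise MatrixParseError(f"{path}: label row requested but file has no line 2")
        fields = lines[1].split("\t")
        if len(fields) != ncol:
            raise MatrixParseError(
                f"{path}, line 2: expected {ncol} fields, found {len(fields)}"
            )
        labels = dict(zip(sample_ids, fields[1:]))
        body_start = 2

    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for offset, line in enumerate(lines[body_start:]):
        lineno = body_start + offset + 1
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != ncol:
            raise MatrixParseError(
                f"{path}, line {lineno}: expected {ncol} fields, found {len(fields)}"
            )
        gene_ids.append(fields[0])
        row = []
        for j, cell in enumerate(fields[1:]):
            try:
                row.append(float(cell))
            except ValueError:
                raise MatrixParseError(
                    f"{path}, line {lineno}, sample {sample_ids[j]!r} "
                    f"(gene {fields[0]!r}): non-numeric value {cell!r}"
                ) from None
        rows.append(row)

    data = pd.DataFrame(rows, index=gene_ids, columns=sample_ids, dtype=float)
    return ExpressionMatrix(data, sample_labels=labels)


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write *m* in the tab-delimited layout, at full double precision."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(m.sample_ids) + "\n")
        if m.sample_labels is not None:
            fh.write(
                "label\t"
                + "\t".join(m.sample_labels.get(s, "") for s in m.sample_ids)
                + "\n"
            )
        values = m.values
        for gene, row in zip(m.gene_ids, values):
            fh.write(gene + "\t" + "\t".join(format(v, ".17g") for v in row) + "\n")


def read_probe_map(path: str | Path) -> ProbeGeneMap:
    """Read a two-column probe->gene TSV (header required)."""
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise MatrixParseError(f"{path}: empty probe map")
    mapping: dict[str, str] = {}
    for offset, line in enumerate(lines[1:]):
        lineno = offset + 2
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise MatrixParseError(
                f"{path}, line {lineno}: expected 2 fields, found {len(fields)}"
            )
        probe, gene = fields
        if probe in mapping and mapping[probe] != gene:
            raise MatrixParseError(
                f"{path}, line {lineno}: probe {probe!r} mapped to multiple genes"
            )
        mapping[probe] = gene
    return ProbeGeneMap(mapping)


def collapse_to_genes(m: ExpressionMatrix, probe_map: ProbeGeneMap) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per gene.

    For each gene the retained row is the probe with the highest mean across
    all samples; ties keep the probe occurring earlier in the input.  Output
    rows are ordered by first appearance of each gene.
    """
    unmapped = [p for p in m.gene_ids if p not in probe_map]
    if unmapped:
        raise ValueError(f"probes absent from probe map: {unmapped[:20]}")
    means = m.values.mean(axis=1)
    best: dict[str, int] = {}
    order: list[str] = []
    for i, probe in enumerate(m.gene_ids):
        gene = probe_map[probe]
        if gene not in best:
            best[gene] = i
            order.append(gene)
        elif means[i] > means[best[gene]]:
            best[gene] = i
    idx = [best[g] for g in order]
    data = pd.DataFrame(m.values[idx], index=order, columns=m.sample_ids)
    return ExpressionMatrix(data, sample_labels=m.sample_labels)


def standardize_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Z-transform each gene to mean 0 and sample SD 1 across the dataset.

    Standardization is computed over all samples of the dataset together
    (controls and disease alike), with the n-1 (sample) SD.  Genes with zero
    variance become all-zero rows and trigger a warning: they contribute
    nothing to any downstream metagene score.
    """
    if m.n_samples < 2:
        raise ValueError("standardization requires at least 2 samples")
    values = m.values
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        genes = [g for g, z in zip(m.gene_ids, flat) if z]
        warnings.warn(
            f"{flat.sum()} zero-variance gene(s) set to all-zero rows: {genes[:10]}",
            stacklevel=2,
        )
    safe_sd = np.where(sd == 0, 1.0, sd)
    out = (values - mean) / safe_sd
    out[flat, :] = 0.0
    data = pd.DataFrame(out, index=m.data.index, columns=m.data.columns)
    return ExpressionMatrix(data, sample_labels=m.sample_labels)


def align_genes(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two gene-collapsed matrices to their shared genes, same order.

    The row order of the result follows the first matrix.  Disjoint gene
    sets raise an error.
    """
    a.require_unique_genes()
    b.require_unique_genes()
    in_b = set(b.gene_ids)
    common = [g for g in a.gene_ids if g in in_b]
    if not common:
        raise ValueError("no genes shared between the two matrices")
    a_out = ExpressionMatrix(a.data.loc[common], sample_labels=a.sample_labels)
    b_out = ExpressionMatrix(b.data.loc[common], sample_labels=b.sample_labels)
    return a_out, b_out


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file, preserving set and gene order."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise MatrixParseError(
                f"{path}, line {lineno}: GMT lines need name, description and >=1 gene"
            )
        name = fields[0]
        if name in sets:
            raise MatrixParseError(f"{path}, line {lineno}: duplicate set name {name!r}")
        sets[name] = fields[2:]
    return sets


def write_gmt(
    sets: Mapping[str, Sequence[str]],
    path: str | Path,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    """Write gene sets to GMT (set name, description, member genes)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")
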