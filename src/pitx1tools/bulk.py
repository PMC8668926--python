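"""Bulk RNA-seq marker statistics: RPKM, expression floors, z-scores, log2FC.

These are the small, closed-form statistics behind marker heatmaps and
fold-change panels: RPKM normalization, removal of genes at or below an
RPKM floor in every sample of a subset, per-gene z-scoring across all
samples, and replicate-averaged log2 fold changes between sample groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "rpkm",
    "rpkm_floor_filter",
    "gene_zscore",
    "group_log2fc",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus gene/sample metadata.

    ``values`` holds raw counts (``kind="counts"``) or RPKM
    (``kind="rpkm"``); ``gene_lengths`` is in bp; ``sample_totals`` is total
    mapped reads per sample (required to compute RPKM); ``sample_groups``
    maps each sample to its replicate group.
    """

    values: pd.DataFrame
    gene_lengths: pd.Series | None = None
    sample_totals: pd.Series | None = None
    sample_groups: Mapping[str, str] = field(default_factory=dict)
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "rpkm"):
            raise ValueError("kind must be 'counts' or 'rpkm'")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.gene_lengths is not None:
            self.gene_lengths = self.gene_lengths.reindex(self.values.index)
            if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
                raise ValueError("every gene needs a positive length")
        if self.sample_totals is not None:
            self.sample_totals = self.sample_totals.reindex(self.values.columns)
            if self.sample_totals.isna().any() or (self.sample_totals <= 0).any():
                raise ValueError("every sample needs a positive total")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, group: str) -> list[str]:
        out = [s for s in self.samples if self.sample_groups.get(s) == group]
        if not out:
            raise ValueError(f"no samples in group {group!r}")
        return out


def rpkm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Reads per kilobase per million mapped reads.

    ``rpkm = count * 1e9 / (gene_length * sample_total)``.
    """
    if m.kind != "counts":
        raise ValueError("rpkm() expects raw counts")
    if m.gene_lengths is None or m.sample_totals is None:
        raise ValueError("gene lengths and sample totals are required")
    vals = (
        m.values
        .div(m.gene_lengths, axis=0)
        .div(m.sample_totals, axis=1)
        * 1e9
    )
    return replace(m, values=vals, kind="rpkm")


def rpkm_floor_filter(
    m: ExpressionMatrix,
    threshold: float = 1.0,
    sample_subset: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Drop genes at or below ``threshold`` in EVERY sample of the subset.

    The rule is inclusive: a gene with exactly ``threshold`` RPKM in all
    subset samples is removed; a single sample above the floor rescues it.
    ``sample_subset`` defaults to all samples.
    """
    if m.kind != "rpkm":
        raise ValueError("rpkm_floor_filter() expects RPKM values")
    if sample_subset is None:
        subset = list(m.samples)
    else:
        subset = list(sample_subset)
        missing = [s for s in subset if s not in m.samples]
        if missing:
            raise ValueError(f"unknown samples in subset: {missing}")
    if not subset:
        raise ValueError("sample subset must not be empty")
    low_everywhere = (m.values[subset] <= threshold).all(axis=1)
    kept = m.values.loc[~low_everywhere]
    lengths = None if m.gene_lengths is None else m.gene_lengths.loc[kept.index]
    return replace(m, values=kept, gene_lengths=lengths)


def gene_zscore(
    m: ExpressionMatrix, ddof: int = 1
) -> tuple[pd.DataFrame, list]:
    """Per-gene z-scores across all samples.

    ``z[g, s] = (x[g, s] - mean_g) / sd_g`` with the sample (n-1) standard
    deviation by default (``ddof=0`` switches to the population convention).
    Zero-variance genes are not divided: their rows are NaN and their names
    returned as the flagged list.
    """
    if m.samples.size < 2:
        raise ValueError("need at least 2 samples")
    x = m.values
    mean = x.mean(axis=1)
    sd = x.std(axis=1, ddof=ddof)
    flagged = list(x.index[sd == 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = x.sub(mean, axis=0).div(sd, axis=0)
    z.loc[flagged] = np.nan
    return z, flagged


def group_log2fc(
    m: ExpressionMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = 0.01,
) -> pd.Series:
    """Replicate-averaged log2 fold change between two sample groups.

    ``log2((mean_A + eps) / (mean_B + eps))`` per gene, with a small
    pseudocount guarding against zero means.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    mean_a = m.values[m.group_samples(group_a)].mean(axis=1)
    mean_b = m.values[m.group_samples(group_b)].mean(axis=1)
    with np.errstate(divide="ignore"):
        out = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
    return pd.Series(out, index=m.genes, name=f"log2fc_{group_a}_vs_{group_b}")
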