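"""Genomic intervals with 1-based, fully-closed coordinates.

External files and presets use the 1-based inclusive convention common in
chromosome-conformation work (``chr13:54,000,001-57,300,000``); bin indices
derived from an interval are 0-based and half-open.  The two conversions are
exact: position ``start`` always falls in bin 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

_REGION_RE = re.compile(
    r"^(?P<chrom>[\w.]+):(?P<start>[\d,]+)-(?P<end>[\d,]+)$"
)


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, inclusive genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) must be >= start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos):
        """Membership test for a position or array of positions (1-based)."""
        pos = np.asarray(pos)
        out = (pos >= self.start) & (pos <= self.end)
        return bool(out) if out.ndim == 0 else out

    def contains_interval(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and other.start >= self.start
            and other.end <= self.end
        )

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and other.start <= self.end
            and other.end >= self.start
        )

    def n_bins(self, bin_size: int) -> int:
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        return -(-self.length // bin_size)

    def bin_index(self, pos, bin_size: int):
        """0-based bin index of 1-based position(s); ``start`` maps to bin 0."""
        pos = np.asarray(pos)
        out = (pos - self.start) // bin_size
        return int(out) if out.ndim == 0 else out.astype(np.int64)

    def bin_interval(self, index: int, bin_size: int) -> "GenomicInterval":
        """Genomic interval covered by a bin (clipped at the region end)."""
        lo = self.start + index * bin_size
        hi = min(lo + bin_size - 1, self.end)
        return GenomicInterval(self.chrom, lo, hi)

    @classmethod
    def parse(cls, text: str) -> "GenomicInterval":
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
        return cls(
            m["chrom"],
            int(m["start"].replace(",", "")),
            int(m["end"].replace(",", "")),
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"
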