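"""Single-cell target-gene expression: QC, normalization, class calling.

The workflow mirrors how a highly expressed developmental gene (here the
hindlimb-identity gene *Pitx1*) is partitioned into three expression classes
from droplet scRNA-seq:

1. cells failing basic QC are removed (``qc_filter``),
2. raw target UMIs are log-normalized per cell (``log_normalize``,
   ``ln(1 + count / total * scale)`` with the conventional ``scale`` of
   10,000 counts per cell),
3. class boundaries are either taken as frozen thresholds (0.3 and 1.45 on
   the ``ln(x+1)`` scale) or re-derived as the intersection points of two
   kernel density estimates (``estimate_density`` + ``find_intersection``),
4. cells are called non/low-, intermediate- or high-expressing
   (``classify_cells``) and per-group class fractions and fold changes are
   tabulated (``class_proportions``, ``fold_change_nonlow``).

Cell tables are plain :class:`pandas.DataFrame` objects with the columns
listed in :data:`CELL_COLUMNS` (plus ``norm_expr`` and ``expr_class`` once
computed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CELL_COLUMNS",
    "CLASS_LABELS",
    "Thresholds",
    "DensityCurve",
    "IntersectionResult",
    "NoIntersectionError",
    "qc_filter",
    "log_normalize",
    "estimate_density",
    "find_intersection",
    "classify_cells",
    "class_proportions",
    "fold_change_nonlow",
    "condition_label",
]

#: Required columns of a cell table, in canonical order.
CELL_COLUMNS = (
    "cell_id",
    "genotype",
    "tissue",
    "cluster",
    "axis",
    "n_genes",
    "mito_frac",
    "target_count",
    "total_count",
)

#: The three expression classes, in increasing order of expression.
CLASS_LABELS = ("nonlow", "intermediate", "high")


class NoIntersectionError(ValueError):
    """Raised when two density curves do not cross in the search window."""


@dataclass(frozen=True)
class Thresholds:
    """Class boundaries on the log-normalized expression scale.

    ``norm_expr <= t_low`` is non/low, ``t_low < norm_expr <= t_high`` is
    intermediate, ``norm_expr > t_high`` is high (boundaries belong to the
    lower class).
    """

    t_low: float = 0.3
    t_high: float = 1.45

    def __post_init__(self) -> None:
        if not (0 < self.t_low < self.t_high):
            raise ValueError(
                f"thresholds must satisfy 0 < t_low < t_high, "
                f"got ({self.t_low}, {self.t_high})"
            )


@dataclass
class DensityCurve:
    """A Gaussian-kernel density evaluated on an even grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    n_cells: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.shape != self.density.shape:
            raise ValueError("grid and density must have the same shape")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def __call__(self, x):
        return np.interp(x, self.grid, self.density)


@dataclass
class IntersectionResult:
    """Smallest crossing of two density curves plus all crossings found."""

    x: float
    crossings: list = field(default_factory=list)

    def __float__(self) -> float:
        return float(self.x)


def _require_columns(cells: pd.DataFrame, cols: Sequence[str]) -> None:
    missing = [c for c in cols if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table is missing required columns: {missing}")


def condition_label(cells: pd.DataFrame) -> pd.Series:
    """``genotype-tissue`` label per cell, e.g. ``WT-HL``."""
    _require_columns(cells, ["genotype", "tissue"])
    return cells["genotype"].astype(str) + "-" + cells["tissue"].astype(str)


def qc_filter(
    cells: pd.DataFrame,
    min_genes: int = 200,
    mito_low: float = 0.01,
    mito_high: float = 0.15,
) -> tuple[pd.DataFrame, dict]:
    """Remove low-quality cells.

    A cell is kept iff it expresses at least ``min_genes`` genes AND its
    mitochondrial fraction lies in ``[mito_low, mito_high]``.  Cells below
    200 genes are presumed empty/damaged; above 15% mitochondrial content
    dying; below 1% they are dissection-derived blood cells.  The bounds are
    exclusive for removal, so 200 genes / 15% / 1% are all kept.

    Returns the kept table (original order) and a per-rule removal log; a
    cell violating several rules is counted under each.
    """
    _require_columns(cells, ["n_genes", "mito_frac"])
    if cells[["n_genes", "mito_frac"]].isna().any().any():
        raise ValueError("n_genes / mito_frac contain missing values")
    few_genes = cells["n_genes"] < min_genes
    high_mito = cells["mito_frac"] > mito_high
    low_mito = cells["mito_frac"] < mito_low
    keep = ~(few_genes | high_mito | low_mito)
    log = {
        "n_input": int(len(cells)),
        "removed_few_genes": int(few_genes.sum()),
        "removed_high_mito": int(high_mito.sum()),
        "removed_low_mito": int(low_mito.sum()),
        "n_kept": int(keep.sum()),
    }
    return cells.loc[keep].copy(), log


def log_normalize(cells: pd.DataFrame, scale: float = 10_000.0) -> pd.DataFrame:
    """Per-cell log normalization: ``norm_expr = ln(1 + count/total * scale)``.

    All other columns are unchanged.  Cells with ``total_count == 0`` cannot
    be normalized and are rejected.
    """
    _require_columns(cells, ["target_count", "total_count"])
    total = cells["total_count"].to_numpy(dtype=float)
    if np.any(total <= 0):
        bad = cells.loc[cells["total_count"] <= 0, "cell_id"].tolist()[:5]
        raise ValueError(
            f"cells with total_count == 0 cannot be normalized (e.g. {bad})"
        )
    count = cells["target_count"].to_numpy(dtype=float)
    if np.any(count < 0) or np.any(count > total):
        raise ValueError("target_count must satisfy 0 <= target_count <= total_count")
    out = cells.copy()
    out["norm_expr"] = np.log1p(count / total * scale)
    return out


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb, ``0.9 * min(sd, IQR/1.34) * n^(-1/5)``."""
    values = np.asarray(values, dtype=float)
    n = values.size
    sd = float(np.std(values, ddof=1))
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25)
    spread_candidates = [s for s in (sd, iqr / 1.34) if s > 0]
    if not spread_candidates:
        raise ValueError("cannot pick a bandwidth for zero-variance data")
    return 0.9 * min(spread_candidates) * n ** (-1 / 5)


def estimate_density(
    values,
    bandwidth: float | str = "auto",
    n_grid: int = 512,
) -> DensityCurve:
    """Gaussian-kernel density of expression values on an even grid.

    The grid spans ``[min - 3*bw, max + 3*bw]`` so that essentially the whole
    kernel mass is covered and the trapezoidal integral is ~1.  ``bandwidth``
    is either a positive number or ``"auto"`` (Silverman's rule).
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or not np.all(np.isfinite(values)):
        raise ValueError("need at least 2 finite values")
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    if isinstance(bandwidth, str):
        if bandwidth != "auto":
            raise ValueError(f"unknown bandwidth rule {bandwidth!r}")
        bw = silverman_bandwidth(values)
    else:
        bw = float(bandwidth)
        if bw <= 0:
            raise ValueError("bandwidth must be positive")
    grid = np.linspace(values.min() - 3 * bw, values.max() + 3 * bw, n_grid)
    # Direct kernel sum, blocked over values to bound memory.
    dens = np.zeros(n_grid)
    block = max(1, int(4_000_000 // n_grid))
    for lo in range(0, values.size, block):
        z = (grid[:, None] - values[None, lo : lo + block]) / bw
        dens += np.exp(-0.5 * z * z).sum(axis=1)
    dens /= values.size * bw * np.sqrt(2 * np.pi)
    return DensityCurve(grid=grid, density=dens, bandwidth=bw, n_cells=values.size)


def find_intersection(
    a: DensityCurve,
    b: DensityCurve,
    search: tuple[float, float],
) -> IntersectionResult:
    """Locate where two density curves cross inside ``search = (lo, hi)``.

    Curve ``b`` is re-interpolated onto ``a``'s grid; a crossing is a sign
    change of ``a(x) - b(x)``, located by linear interpolation between the
    bracketing grid points.  The smallest crossing is returned; all crossings
    found in the window are reported in ``crossings``.  Segments where the
    difference is exactly zero (e.g. identical curves) are not crossings.
    """
    lo, hi = float(search[0]), float(search[1])
    if not lo < hi:
        raise ValueError(f"search window must satisfy lo < hi, got ({lo}, {hi})")
    grid = a.grid
    diff = a.density - b(grid)
    inside = (grid >= lo) & (grid <= hi)
    idx = np.flatnonzero(inside)
    if idx.size < 2:
        raise NoIntersectionError(
            f"search window ({lo}, {hi}) covers fewer than 2 grid points"
        )
    crossings: list[float] = []
    for i in idx[:-1]:
        d0, d1 = diff[i], diff[i + 1]
        if d0 == 0.0:
            # exact zero at a grid point: a crossing only if the sign flips
            # around it
            if i > 0 and diff[i - 1] * d1 < 0:
                crossings.append(float(grid[i]))
            continue
        if d0 * d1 < 0:
            x = grid[i] + d0 * (grid[i + 1] - grid[i]) / (d0 - d1)
            crossings.append(float(x))
    if not crossings:
        raise NoIntersectionError(
            f"density curves do not intersect in ({lo}, {hi})"
        )
    return IntersectionResult(x=min(crossings), crossings=sorted(crossings))


def classify_cells(
    cells: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Call each cell non/low-, intermediate- or high-expressing.

    Boundaries belong to the lower class: ``norm_expr == t_low`` is non/low
    and ``norm_expr == t_high`` is intermediate.
    """
    _require_columns(cells, ["norm_expr"])
    if cells["norm_expr"].isna().any():
        raise ValueError("norm_expr contains missing values; run log_normalize first")
    v = cells["norm_expr"].to_numpy(dtype=float)
    calls = np.select(
        [v <= thresholds.t_low, v <= thresholds.t_high],
        [CLASS_LABELS[0], CLASS_LABELS[1]],
        default=CLASS_LABELS[2],
    )
    out = cells.copy()
    out["expr_class"] = pd.Categorical(calls, categories=CLASS_LABELS, ordered=True)
    return out


def class_proportions(cells: pd.DataFrame, group_by: str = "cluster") -> pd.DataFrame:
    """Per-(condition, group) fractions of the three expression classes.

    ``group_by`` is ``"cluster"``, ``"axis"`` or ``"condition"``; the
    condition is always ``genotype-tissue``.  Rows are indexed by
    ``(condition, group)`` with columns ``n_cells`` and one fraction per
    class; fractions sum to 1 per row.  Empty groups are omitted (with a
    warning when a grouping value is entirely NA).
    """
    if group_by not in ("cluster", "axis", "condition"):
        raise ValueError("group_by must be 'cluster', 'axis' or 'condition'")
    _require_columns(cells, ["expr_class"])
    cond = condition_label(cells)
    if group_by == "condition":
        group = cond
    else:
        _require_columns(cells, [group_by])
        group = cells[group_by].astype(str)
    if len(cells) == 0:
        warnings.warn("empty cell table: no proportion rows produced")
        return pd.DataFrame(
            columns=["n_cells"] + [f"frac_{c}" for c in CLASS_LABELS]
        )
    counts = (
        pd.crosstab([cond.rename("condition"), group.rename("group")],
                    cells["expr_class"], dropna=False)
        .reindex(columns=list(CLASS_LABELS), fill_value=0)
    )
    n = counts.sum(axis=1)
    table = counts.div(n, axis=0)
    table.columns = [f"frac_{c}" for c in CLASS_LABELS]
    table.insert(0, "n_cells", n.astype(int))
    return table[table["n_cells"] > 0]


def fold_change_nonlow(ref: pd.DataFrame, alt: pd.DataFrame) -> pd.DataFrame:
    """Per-group fold change of the non/low fraction, ``alt / ref``.

    ``ref`` and ``alt`` are proportion tables from :func:`class_proportions`
    (typically one condition each); they must carry exactly the same group
    keys.  Groups with a zero reference fraction are flagged ``undefined``
    and their fold is NaN rather than a number.
    """

    def _by_group(table: pd.DataFrame, name: str) -> pd.DataFrame:
        t = table.reset_index()
        if t["group"].duplicated().any():
            raise ValueError(
                f"{name} table has duplicated group keys; "
                "pass a single condition per table"
            )
        return t.set_index("group")

    r = _by_group(ref, "ref")
    a = _by_group(alt, "alt")
    if set(r.index) != set(a.index):
        raise ValueError(
            f"group keys differ between tables: {sorted(set(r.index) ^ set(a.index))}"
        )
    a = a.reindex(r.index)
    out = pd.DataFrame(
        {
            "ref_frac_nonlow": r["frac_nonlow"],
            "alt_frac_nonlow": a["frac_nonlow"],
        },
        index=r.index,
    )
    undefined = out["ref_frac_nonlow"] == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = out["alt_frac_nonlow"] / out["ref_frac_nonlow"]
    out["fold"] = fold.where(~undefined)
    out["undefined"] = undefined
    return out
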