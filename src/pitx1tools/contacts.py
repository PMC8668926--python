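"""Capture-HiC post-processing: binning, KR balancing, subtraction maps,
percentile truncation and virtual-4C profile extraction.

The unit of input is a list of valid mate-pair coordinates restricted to a
captured region (the shipped preset ``pitx1-mm9`` is the 3.3 Mb capture
window chr13:54,000,001-57,300,000 with the gene-promoter viewpoint
chr13:55,930,001-55,940,000).  From pairs the module builds binned symmetric
contact matrices, balances them with the Knight-Ruiz algorithm, jointly
rescales two maps along their subdiagonals so distance decay cancels,
subtracts them, and extracts one-viewpoint (virtual 4C) profiles smoothed
over fixed genomic intervals, serializable as bedGraph.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .regions import GenomicInterval

__all__ = [
    "ContactPairs",
    "ContactMatrix",
    "V4CProfile",
    "KRInfo",
    "ConvergenceError",
    "PRESETS",
    "bin_pairs",
    "kr_balance",
    "subdiagonal_scale",
    "subtract",
    "truncate_percentile",
    "virtual_4c",
    "profile_subtract",
]

#: Named viewpoint/region presets (1-based inclusive coordinates).
PRESETS = {
    "pitx1-mm9": {
        "region": GenomicInterval("chr13", 54_000_001, 57_300_000),
        "viewpoint": GenomicInterval("chr13", 55_930_001, 55_940_000),
    },
}


class ConvergenceError(RuntimeError):
    """Raised when matrix balancing fails to converge."""


@dataclass
class ContactPairs:
    """Mate-pair coordinates (1-based) within one genomic region."""

    region: GenomicInterval
    pos_a: np.ndarray
    pos_b: np.ndarray

    def __post_init__(self) -> None:
        self.pos_a = np.asarray(self.pos_a, dtype=np.int64)
        self.pos_b = np.asarray(self.pos_b, dtype=np.int64)
        if self.pos_a.shape != self.pos_b.shape:
            raise ValueError("pos_a and pos_b must have equal length")
        for name, pos in (("pos_a", self.pos_a), ("pos_b", self.pos_b)):
            bad = np.flatnonzero(~self.region.contains(pos))
            if bad.size:
                raise ValueError(
                    f"{name}[{bad[0]}] = {pos[bad[0]]} outside region {self.region}"
                )

    def __len__(self) -> int:
        return int(self.pos_a.size)


@dataclass
class ContactMatrix:
    """Binned symmetric contact matrix over one region.

    ``mask`` flags valid bins; masked rows/columns are all zero.  ``bias``
    holds the per-bin balancing vector once normalized.  Subtraction maps are
    ``signed``; ``subdiag_scaled`` records that the map went through
    :func:`subdiagonal_scale` (a precondition of :func:`subtract`).
    """

    region: GenomicInterval
    bin_size: int
    matrix: np.ndarray
    mask: np.ndarray | None = None
    normalized: bool = False
    bias: np.ndarray | None = None
    signed: bool = False
    subdiag_scaled: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = self.region.n_bins(self.bin_size)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{n} bins of {self.bin_size} bp over {self.region}"
            )
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (n,):
            raise ValueError("mask length must equal the number of bins")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-9):
            raise ValueError("contact matrix must be symmetric (atol 1e-9)")
        if not self.signed and np.any(self.matrix < 0):
            raise ValueError("contact counts must be non-negative")
        if (self.bias is not None) != self.normalized:
            raise ValueError("bias must be present iff the matrix is normalized")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def valid_entries(self) -> np.ndarray:
        """Entries whose row and column bins are both unmasked."""
        m2 = np.outer(self.mask, self.mask)
        return self.matrix[m2]

    def same_geometry(self, other: "ContactMatrix") -> bool:
        return (
            self.region == other.region
            and self.bin_size == other.bin_size
            and bool(np.array_equal(self.mask, other.mask))
        )


@dataclass
class V4CProfile:
    """Smoothed one-viewpoint contact profile over fixed intervals."""

    viewpoint: GenomicInterval
    region: GenomicInterval
    interval_size: int
    values: np.ndarray
    viewpoint_mask: np.ndarray
    n_qualifying: int
    raw_bin: int
    signed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.viewpoint_mask = np.asarray(self.viewpoint_mask, dtype=bool)
        n = self.region.n_bins(self.interval_size)
        if self.values.shape != (n,):
            raise ValueError(
                f"expected {n} interval values, got {self.values.shape}"
            )
        if self.viewpoint_mask.shape != (n,):
            raise ValueError("viewpoint_mask length must equal interval count")
        if not self.signed and np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")

    def interval(self, index: int) -> GenomicInterval:
        return self.region.bin_interval(index, self.interval_size)


def bin_pairs(pairs: ContactPairs, bin_size: int) -> ContactMatrix:
    """Accumulate mate pairs into a symmetric binned contact matrix.

    Off-diagonal pairs increment both ``M[i, j]`` and ``M[j, i]``; pairs
    whose mates share a bin increment the diagonal once, so the upper
    triangle (including the diagonal) sums to the pair count.
    """
    region = pairs.region
    n = region.n_bins(bin_size)
    i = region.bin_index(pairs.pos_a, bin_size)
    j = region.bin_index(pairs.pos_b, bin_size)
    m = np.zeros((n, n))
    np.add.at(m, (i, j), 1.0)
    off = i != j
    np.add.at(m, (j[off], i[off]), 1.0)
    marginal = m.sum(axis=1)
    return ContactMatrix(
        region=region, bin_size=bin_size, matrix=m, mask=marginal > 0
    )


@dataclass(frozen=True)
class KRInfo:
    iterations: int
    residual: float
    row_sum: float


def _kr_vector(
    a: np.ndarray, tol: float, max_outer: int
) -> tuple[np.ndarray, int, float]:
    """Knight-Ruiz balancing vector for a symmetric non-negative matrix.

    Inner-outer Newton iteration with conjugate-gradient inner solves; on
    success ``diag(x) @ a @ diag(x)`` has unit row sums within ``tol`` (in
    the residual 2-norm).
    """
    n = a.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, big_delta = 0.1, 3.0
    g, etamax = 0.9, 0.1
    eta = etamax
    stop_tol = tol * 0.5
    rt = tol**2
    v = x * (a @ x)
    rk = 1.0 - v
    rho_km1 = rk @ rk
    rho_km2 = rho_km1
    rout = rold = rho_km1
    outer = 0
    while rout > rt:
        outer += 1
        if outer > max_outer:
            raise ConvergenceError(
                f"KR balancing did not converge in {max_outer} outer "
                f"iterations (residual {np.sqrt(rout):.3e}, tol {tol:.1e})"
            )
        k = 0
        y = e.copy()
        innertol = max(eta**2 * rout, rt)
        z = p = np.zeros(n)
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                z = rk / v
                p = z.copy()
                rho_km1 = rk @ z
            else:
                beta = rho_km1 / rho_km2
                p = z + beta * p
            w = x * (a @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                neg = ap < 0
                gamma = ((delta - y[neg]) / ap[neg]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= big_delta:
                over = ynew > big_delta
                gamma = ((big_delta - y[over]) / ap[over]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            z = rk / v
            rho_km1 = rk @ z
            if k > 10 * n + 100:  # CG safeguard
                break
        x = x * y
        if np.any(x <= 0) or not np.all(np.isfinite(x)):
            raise ConvergenceError("KR balancing produced a non-positive bias")
        v = x * (a @ x)
        rk = 1.0 - v
        rho_km1 = rho_km2 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        eta_o = eta
        eta = g * rat
        if g * eta_o**2 > 0.1:
            eta = max(eta, g * eta_o**2)
        eta = max(min(eta, etamax), stop_tol / max(np.sqrt(rout), 1e-300))
    return x, outer, float(np.sqrt(rout))


def kr_balance(
    m: ContactMatrix, tol: float = 1e-8, max_iter: int = 500
) -> tuple[ContactMatrix, KRInfo]:
    """Knight-Ruiz balance a contact matrix.

    Bins that are masked or have a zero marginal are removed before
    balancing and re-inserted as masked all-zero rows.  The balanced matrix
    ``N[i, j] = M[i, j] * b[i] * b[j]`` has all unmasked row sums equal to
    the mean raw row sum of the balanced bins (so total mass is preserved).
    Failure to converge raises :class:`ConvergenceError` rather than
    returning a partial result.
    """
    if m.normalized:
        raise ValueError("matrix is already normalized")
    if m.signed:
        raise ValueError("cannot balance a signed (subtraction) matrix")
    active = m.mask & (m.matrix.sum(axis=1) > 0)
    if active.sum() < 2:
        raise ValueError("fewer than 2 balanceable bins")
    sub = m.matrix[np.ix_(active, active)]
    x, iterations, residual = _kr_vector(sub, tol=tol, max_outer=max_iter)
    row_sum = float(sub.sum(axis=1).mean())  # common target row sum
    b_active = x * np.sqrt(row_sum)
    n = m.n_bins
    bias = np.zeros(n)
    bias[active] = b_active
    balanced = np.zeros_like(m.matrix)
    balanced[np.ix_(active, active)] = sub * np.outer(b_active, b_active)
    out = ContactMatrix(
        region=m.region,
        bin_size=m.bin_size,
        matrix=balanced,
        mask=active,
        normalized=True,
        bias=bias,
    )
    return out, KRInfo(iterations=iterations, residual=residual, row_sum=row_sum)


def subdiagonal_scale(
    a: ContactMatrix, b: ContactMatrix
) -> tuple[ContactMatrix, ContactMatrix, list[int]]:
    """Jointly rescale two balanced maps along each diagonal offset.

    For every offset ``d`` the mean over unmasked entries is computed in
    both maps and each map's offset-``d`` entries are multiplied by
    ``t(d) / m_x(d)`` where ``t(d)`` is the average of the two means.  After
    scaling the two maps have identical per-offset means, so their
    difference no longer carries the distance-decay imbalance.  Offsets
    where either mean is zero (or with no unmasked entries) are left
    untouched and returned as flagged offsets.
    """
    if not a.same_geometry(b):
        raise ValueError("maps must share region, bin size and mask")
    if not (a.normalized and b.normalized):
        raise ValueError("both maps must be KR-normalized before scaling")
    n = a.n_bins
    ma = a.matrix.copy()
    mb = b.matrix.copy()
    mask = a.mask
    flagged: list[int] = []
    for d in range(n):
        i = np.arange(n - d)
        j = i + d
        sel = mask[i] & mask[j]
        if not sel.any():
            flagged.append(d)
            continue
        ii, jj = i[sel], j[sel]
        mean_a = ma[ii, jj].mean()
        mean_b = mb[ii, jj].mean()
        if mean_a == 0 or mean_b == 0:
            flagged.append(d)
            continue
        t = 0.5 * (mean_a + mean_b)
        ma[ii, jj] *= t / mean_a
        mb[ii, jj] *= t / mean_b
        if d > 0:
            ma[jj, ii] = ma[ii, jj]
            mb[jj, ii] = mb[ii, jj]
    out_a = replace(a, matrix=ma, bias=a.bias, subdiag_scaled=True)
    out_b = replace(b, matrix=mb, bias=b.bias, subdiag_scaled=True)
    return out_a, out_b, flagged


def subtract(
    a: ContactMatrix, b: ContactMatrix, require_scaled: bool = True
) -> ContactMatrix:
    """Signed subtraction map ``a - b`` of two jointly scaled maps."""
    if not a.same_geometry(b):
        raise ValueError("maps must share region, bin size and mask")
    if require_scaled and not (a.subdiag_scaled and b.subdiag_scaled):
        raise ValueError(
            "maps must be scaled together (subdiagonal_scale) before "
            "subtraction; pass require_scaled=False to override"
        )
    return ContactMatrix(
        region=a.region,
        bin_size=a.bin_size,
        matrix=a.matrix - b.matrix,
        mask=a.mask.copy(),
        signed=True,
        subdiag_scaled=a.subdiag_scaled and b.subdiag_scaled,
    )


def truncate_percentile(m: ContactMatrix, q: float = 99.0) -> ContactMatrix:
    """Clip unmasked entries above their ``q``-th percentile (display aid).

    The percentile is the linear-interpolation quantile of the unmasked
    entries; entries above it are set to it.
    """
    if not 0 < q < 100:
        raise ValueError("q must be in (0, 100)")
    vals = m.valid_entries()
    if vals.size == 0:
        raise ValueError("matrix has no unmasked entries")
    cap = float(np.percentile(vals, q))
    out = m.matrix.copy()
    m2 = np.outer(m.mask, m.mask)
    out[m2 & (m.matrix > cap)] = cap
    return replace(m, matrix=out, bias=m.bias)


def virtual_4c(
    pairs: ContactPairs,
    viewpoint: GenomicInterval | None = None,
    region: GenomicInterval | None = None,
    raw_bin: int = 1000,
    interval_size: int = 5000,
    preset: str | None = None,
    normalize: str | None = None,
) -> V4CProfile:
    """Extract a one-viewpoint contact profile from mate pairs.

    A pair qualifies iff exactly one mate lies in the viewpoint; the outside
    mate is counted in its ``raw_bin`` bin, and the profile value of each
    ``interval_size`` window is the mean of the raw-bin counts it covers
    (two-scale count-then-average smoothing).  ``normalize="per-million"``
    rescales to counts per million qualifying pairs.
    """
    if preset is not None:
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}; have {sorted(PRESETS)}")
        viewpoint = PRESETS[preset]["viewpoint"]
        region = PRESETS[preset]["region"]
    if viewpoint is None:
        raise ValueError("a viewpoint (or preset) is required")
    if region is None:
        region = pairs.region
    if not region.contains_interval(viewpoint):
        raise ValueError(f"viewpoint {viewpoint} outside region {region}")
    if interval_size % raw_bin != 0:
        raise ValueError(
            f"interval_size ({interval_size}) must be a multiple of "
            f"raw_bin ({raw_bin})"
        )
    if pairs.region != region:
        # re-anchor the pairs onto the requested region
        pairs = ContactPairs(region=region, pos_a=pairs.pos_a, pos_b=pairs.pos_b)

    in_a = viewpoint.contains(pairs.pos_a)
    in_b = viewpoint.contains(pairs.pos_b)
    qualifying = np.logical_xor(in_a, in_b)
    outside = np.where(in_a, pairs.pos_b, pairs.pos_a)[qualifying]

    n_raw = region.n_bins(raw_bin)
    raw = np.bincount(region.bin_index(outside, raw_bin), minlength=n_raw).astype(
        float
    )
    n_qualifying = int(qualifying.sum())
    if normalize == "per-million":
        if n_qualifying > 0:
            raw *= 1e6 / n_qualifying
    elif normalize is not None:
        raise ValueError("normalize must be None or 'per-million'")

    per = interval_size // raw_bin
    n_int = region.n_bins(interval_size)
    padded = np.full(n_int * per, np.nan)
    padded[:n_raw] = raw
    values = np.nanmean(padded.reshape(n_int, per), axis=1)

    vp_mask = np.array(
        [region.bin_interval(i, interval_size).overlaps(viewpoint) for i in range(n_int)]
    )
    return V4CProfile(
        viewpoint=viewpoint,
        region=region,
        interval_size=interval_size,
        values=values,
        viewpoint_mask=vp_mask,
        n_qualifying=n_qualifying,
        raw_bin=raw_bin,
    )


def profile_subtract(a: V4CProfile, b: V4CProfile) -> V4CProfile:
    """Signed elementwise subtraction of two virtual-4C profiles."""
    if (
        a.viewpoint != b.viewpoint
        or a.region != b.region
        or a.interval_size != b.interval_size
        or a.raw_bin != b.raw_bin
    ):
        raise ValueError("profiles must share viewpoint geometry and intervals")
    return V4CProfile(
        viewpoint=a.viewpoint,
        region=a.region,
        interval_size=a.interval_size,
        values=a.values - b.values,
        viewpoint_mask=a.viewpoint_mask.copy(),
        n_qualifying=a.n_qualifying - b.n_qualifying,
        raw_bin=a.raw_bin,
        signed=True,
    )
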