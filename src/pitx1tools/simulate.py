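"""Seeded generators for synthetic cell tables and contact pairs.

The cell generator emulates the statistical structure the downstream
expression-classing stages assume: cluster-structured cell populations
across genotype/tissue conditions, and a target gene whose per-cell
log-normalized expression is a three-component mixture — a zero-inflated
"off" component below the low threshold, and two truncated-normal "on"
components inside the intermediate and high class intervals — with mixing
weights that depend on (condition, cluster).  Values are drawn on the
normalized ``ln(x+1)`` scale and back-converted to integer UMI counts, so
the full input pathway (counts -> normalize -> classify) is exercised and
re-normalization recovers the latent class.  Because UMI counts quantize
the normalized scale, the reconstructed count is clamped into the count
range whose normalized value lies in the latent class's interval; without
this, boundary rounding would systematically re-label a visible fraction of
low-intermediate cells as non/low.

The contact generator samples mate pairs with power-law distance decay plus
optional viewpoint-anchor loops whose pair density is multiplied by an
enrichment factor (implemented by exact rejection sampling, so an
enrichment of 1 reduces to pure decay).

Both generators are byte-deterministic under a fixed seed and return a
:class:`TruthRecord` for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import ContactPairs
from .expression import CELL_COLUMNS, CLASS_LABELS, Thresholds
from .regions import GenomicInterval

__all__ = [
    "NonLowComponent",
    "TruncNormalComponent",
    "LibrarySizeModel",
    "QCModel",
    "ClusterSpec",
    "CellGenConfig",
    "Loop",
    "ContactGenConfig",
    "TruthRecord",
    "gen_cells",
    "gen_contacts",
    "default_cell_config",
    "default_contact_config",
]

PROXIMAL_CLUSTERS = ("PPP", "TP", "ICT", "PC")
DISTAL_CLUSTERS = ("DP", "DPP", "EDC", "LDC")


@dataclass(frozen=True)
class NonLowComponent:
    """Zero-inflated 'off' component: point mass at 0 plus a small
    positive uniform tail on ``(0, max_value]``."""

    zero_prob: float = 0.8
    max_value: float = 0.3

    def __post_init__(self) -> None:
        if not 0 <= self.zero_prob <= 1:
            raise ValueError("zero_prob must be in [0, 1]")
        if self.max_value <= 0:
            raise ValueError("max_value must be positive")


@dataclass(frozen=True)
class TruncNormalComponent:
    """Truncated normal on ``(lower, upper]`` of the ``ln(x+1)`` scale."""

    loc: float
    scale: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.upper <= self.lower:
            raise ValueError("need scale > 0 and upper > lower")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        a = (self.lower - self.loc) / self.scale
        b = (self.upper - self.loc) / self.scale
        return stats.truncnorm.rvs(
            a, b, loc=self.loc, scale=self.scale, size=size, random_state=rng
        )


@dataclass(frozen=True)
class LibrarySizeModel:
    """Log-normal total-UMI model (droplet scRNA-seq scale).

    ``min_total`` emulates the cell-calling UMI floor of droplet pipelines;
    it also guarantees that every expression-class interval contains at
    least one achievable count at the default normalization scale, so the
    count round-trip preserves latent classes exactly.
    """

    median: float = 10_000.0
    sigma: float = 0.35
    min_total: int = 3500

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        t = rng.lognormal(mean=np.log(self.median), sigma=self.sigma, size=size)
        return np.maximum(np.rint(t), self.min_total).astype(np.int64)


@dataclass(frozen=True)
class QCModel:
    """Detected-gene counts (log-normal) and mitochondrial fraction (beta)."""

    genes_median: float = 2500.0
    genes_sigma: float = 0.35
    mito_alpha: float = 2.0
    mito_beta: float = 38.0

    def sample(self, rng: np.random.Generator, size: int):
        genes = rng.lognormal(np.log(self.genes_median), self.genes_sigma, size)
        genes = np.maximum(np.rint(genes), 1).astype(np.int64)
        mito = rng.beta(self.mito_alpha, self.mito_beta, size)
        return genes, mito


@dataclass(frozen=True)
class ClusterSpec:
    """One cluster: name, proximo-distal axis, cells per condition."""

    name: str
    axis: str  # "proximal" | "distal" | "NA"
    n_cells: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.axis not in ("proximal", "distal", "NA"):
            raise ValueError(f"axis must be proximal/distal/NA, got {self.axis!r}")
        for cond, n in self.n_cells.items():
            if int(n) <= 0:
                raise ValueError(
                    f"n_cells must be > 0 (cluster {self.name}, condition {cond})"
                )


@dataclass
class CellGenConfig:
    """Full description of a synthetic single-cell experiment.

    ``class_weights[condition][cluster]`` is a (non/low, intermediate, high)
    triple on the simplex; condition labels are ``genotype-tissue``.
    """

    conditions: Sequence[tuple[str, str]]
    clusters: Sequence[ClusterSpec]
    class_weights: Mapping[str, Mapping[str, tuple[float, float, float]]]
    nonlow: NonLowComponent = NonLowComponent()
    intermediate: TruncNormalComponent = TruncNormalComponent(0.85, 0.35, 0.3, 1.45)
    high: TruncNormalComponent = TruncNormalComponent(2.2, 0.55, 1.45, 6.0)
    library_size: LibrarySizeModel = LibrarySizeModel()
    qc: QCModel = QCModel()
    scale: float = 10_000.0
    thresholds: Thresholds = Thresholds()
    seed: int | None = None

    def condition_labels(self) -> list[str]:
        return [f"{g}-{t}" for g, t in self.conditions]

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required for reproducible generation")
        if not self.conditions or not self.clusters:
            raise ValueError("need at least one condition and one cluster")
        genotypes = {"WT", "PenDel", "KO"}
        tissues = {"FL", "HL"}
        for g, t in self.conditions:
            if g not in genotypes or t not in tissues:
                raise ValueError(f"unknown condition ({g}, {t})")
        for cond in self.condition_labels():
            for cl in self.clusters:
                if cond not in cl.n_cells:
                    raise ValueError(
                        f"cluster {cl.name} has no cell count for {cond}"
                    )
                w = np.asarray(self.class_weights[cond][cl.name], dtype=float)
                if w.shape != (3,) or np.any(w < 0) or abs(w.sum() - 1) > 1e-8:
                    raise ValueError(
                        f"class weights for ({cond}, {cl.name}) must be a "
                        f"length-3 simplex vector, got {w}"
                    )
        if not (
            self.nonlow.max_value <= self.thresholds.t_low
            and self.intermediate.upper <= self.thresholds.t_high
            and self.high.lower >= self.thresholds.t_high
        ):
            raise ValueError(
                "mixture components must respect the class thresholds"
            )


@dataclass(frozen=True)
class Loop:
    """A pairwise contact enrichment between two anchors."""

    anchor_a: GenomicInterval
    anchor_b: GenomicInterval
    enrichment: float

    def __post_init__(self) -> None:
        if self.enrichment < 1:
            raise ValueError("loop enrichment must be >= 1")


@dataclass
class ContactGenConfig:
    """Synthetic contact-pair experiment over one region."""

    region: GenomicInterval
    n_pairs: int
    decay_exponent: float = -1.0
    loops: Sequence[Loop] = ()
    min_distance: int = 1000
    condition_tag: str = ""
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is required for reproducible generation")
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if not 1 <= self.min_distance < self.region.length:
            raise ValueError("min_distance must be in [1, region length)")
        for loop in self.loops:
            for anchor in (loop.anchor_a, loop.anchor_b):
                if not self.region.contains_interval(anchor):
                    raise ValueError(f"anchor {anchor} outside region {self.region}")


@dataclass
class TruthRecord:
    """Ground truth of a synthetic dataset, for recovery tests."""

    class_weights: dict | None = None
    cluster_sizes: dict | None = None
    loops: tuple = ()
    condition_tag: str = ""
    seed: int | None = None


# ---------------------------------------------------------------------------
# cell generation


def _norm_value(counts: np.ndarray, totals: np.ndarray, scale: float) -> np.ndarray:
    # same float expression as expression.log_normalize, so the class
    # boundaries computed here agree bit-for-bit with classification
    return np.log1p(counts / totals * scale)


def _class_count_bounds(
    totals: np.ndarray, scale: float, th: Thresholds
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell count boundaries of the three classes.

    ``c_low_max`` is the largest count whose normalized value stays <= t_low;
    ``c_high_min`` the smallest count normalizing strictly above t_high.
    Boundary rounding is resolved with the actual normalization predicate.
    """
    c_low_max = np.floor(np.expm1(th.t_low) * totals / scale)
    c_low_max -= _norm_value(c_low_max, totals, scale) > th.t_low
    c_low_max += _norm_value(c_low_max + 1, totals, scale) <= th.t_low
    c_high_min = np.floor(np.expm1(th.t_high) * totals / scale) + 1
    c_high_min += _norm_value(c_high_min, totals, scale) <= th.t_high
    c_high_min -= _norm_value(c_high_min - 1, totals, scale) > th.t_high
    return c_low_max, c_high_min


def _counts_for_class(
    values: np.ndarray,
    class_idx: int,
    totals: np.ndarray,
    scale: float,
    th: Thresholds,
) -> np.ndarray:
    """Round normalized values to counts, staying inside the class interval."""
    counts = np.rint(np.expm1(values) * totals / scale)
    c_low_max, c_high_min = _class_count_bounds(totals, scale, th)
    if class_idx == 0:
        counts = np.clip(counts, 0, c_low_max)
    elif class_idx == 1:
        upper = np.maximum(c_high_min - 1, c_low_max + 1)
        counts = np.clip(counts, c_low_max + 1, upper)
    else:
        counts = np.maximum(counts, c_high_min)
    return counts.astype(np.int64)


def gen_cells(config: CellGenConfig) -> tuple[pd.DataFrame, TruthRecord]:
    """Generate a synthetic cell table plus its ground truth.

    One record per cell; per (condition, cluster) block a latent class is
    drawn from the configured weights, a normalized expression value from
    that class's component, and the raw UMI count is reconstructed so that
    re-normalization (same ``scale``) recovers the value up to count
    rounding, with the latent class preserved exactly.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    th = config.thresholds
    components = (config.nonlow, config.intermediate, config.high)
    rows: list[pd.DataFrame] = []
    for (genotype, tissue) in config.conditions:
        cond = f"{genotype}-{tissue}"
        for cl in config.clusters:
            n = int(cl.n_cells[cond])
            weights = np.asarray(config.class_weights[cond][cl.name], dtype=float)
            weights = weights / weights.sum()
            classes = rng.choice(3, size=n, p=weights)
            totals = config.library_size.sample(rng, n)
            values = np.zeros(n)
            counts = np.zeros(n, dtype=np.int64)
            for ci in range(3):
                sel = classes == ci
                m = int(sel.sum())
                if m == 0:
                    continue
                if ci == 0:
                    comp: NonLowComponent = components[0]
                    v = np.where(
                        rng.random(m) < comp.zero_prob,
                        0.0,
                        rng.uniform(0.0, comp.max_value, m),
                    )
                else:
                    v = components[ci].sample(rng, m)
                values[sel] = v
                counts[sel] = _counts_for_class(
                    v, ci, totals[sel], config.scale, th
                )
            genes, mito = config.qc.sample(rng, n)
            totals = np.maximum(totals, counts)  # counts can never exceed totals
            block = pd.DataFrame(
                {
                    "cell_id": [
                        f"{cond}_{cl.name}_{i:05d}" for i in range(n)
                    ],
                    "genotype": genotype,
                    "tissue": tissue,
                    "cluster": cl.name,
                    "axis": cl.axis,
                    "n_genes": genes,
                    "mito_frac": mito,
                    "target_count": counts,
                    "total_count": totals,
                }
            )
            block["true_class"] = pd.Categorical(
                np.asarray(CLASS_LABELS, dtype=object)[classes],
                categories=CLASS_LABELS,
                ordered=True,
            )
            rows.append(block)
    cells = pd.concat(rows, ignore_index=True)[list(CELL_COLUMNS) + ["true_class"]]
    truth = TruthRecord(
        class_weights={
            cond: {cl.name: tuple(config.class_weights[cond][cl.name])
                   for cl in config.clusters}
            for cond in config.condition_labels()
        },
        cluster_sizes={
            cond: {cl.name: int(cl.n_cells[cond]) for cl in config.clusters}
            for cond in config.condition_labels()
        },
        seed=config.seed,
    )
    return cells, truth


# ---------------------------------------------------------------------------
# contact generation


def _sample_distances(
    rng: np.random.Generator, n: int, d_min: float, d_max: float, exponent: float
) -> np.ndarray:
    """Inverse-CDF sampling of a truncated power law ``p(d) ~ d^exponent``."""
    u = rng.random(n)
    if exponent == -1.0:
        return d_min * (d_max / d_min) ** u
    a1 = exponent + 1.0
    return (d_min**a1 + u * (d_max**a1 - d_min**a1)) ** (1.0 / a1)


def gen_contacts(config: ContactGenConfig) -> tuple[ContactPairs, TruthRecord]:
    """Sample mate pairs with power-law decay and optional loops.

    Candidate pairs are drawn from the pure decay model (distance from the
    truncated power law, left mate uniform given the distance) and accepted
    by rejection against the loop enrichment weights, so the output
    distribution is exactly decay times enrichment.  Output order is
    deterministic under the seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    region = config.region
    n_target = int(config.n_pairs)
    if n_target == 0:
        empty = np.empty(0, dtype=np.int64)
        return (
            ContactPairs(region=region, pos_a=empty, pos_b=empty),
            TruthRecord(loops=tuple(config.loops),
                        condition_tag=config.condition_tag, seed=config.seed),
        )
    w_max = max([loop.enrichment for loop in config.loops], default=1.0)
    acc_a: list[np.ndarray] = []
    acc_b: list[np.ndarray] = []
    n_have = 0
    while n_have < n_target:
        batch = int(1.3 * (n_target - n_have) * w_max) + 16
        d = np.rint(
            _sample_distances(
                rng, batch, config.min_distance, region.length - 1,
                config.decay_exponent,
            )
        ).astype(np.int64)
        d = np.maximum(d, 1)
        lo = region.start
        span = region.length - d  # number of valid left-mate starts
        pos_a = lo + np.floor(rng.random(batch) * span).astype(np.int64)
        pos_b = pos_a + d
        w = np.ones(batch)
        for loop in config.loops:
            hit = (
                loop.anchor_a.contains(pos_a) & loop.anchor_b.contains(pos_b)
            ) | (loop.anchor_b.contains(pos_a) & loop.anchor_a.contains(pos_b))
            w = np.where(hit, np.maximum(w, loop.enrichment), w)
        keep = rng.random(batch) * w_max < w
        acc_a.append(pos_a[keep])
        acc_b.append(pos_b[keep])
        n_have += int(keep.sum())
    pos_a = np.concatenate(acc_a)[:n_target]
    pos_b = np.concatenate(acc_b)[:n_target]
    pairs = ContactPairs(region=region, pos_a=pos_a, pos_b=pos_b)
    truth = TruthRecord(
        loops=tuple(config.loops),
        condition_tag=config.condition_tag,
        seed=config.seed,
    )
    return pairs, truth


# ---------------------------------------------------------------------------
# default study conditions


def default_cell_config(seed: int = 0) -> CellGenConfig:
    """The default four-condition limb experiment.

    Conditions: wildtype hindlimb and forelimb, enhancer-deletion hindlimb
    and full-knockout hindlimb; nine mesenchymal clusters (four proximal,
    four distal, one mixed).  Class weights are set so that condition-level
    aggregates echo the published single-cell fractions: ~21% non/low cells
    in the wildtype hindlimb rising to ~35% in the enhancer deletion, with
    a ~3.5-fold non/low increase in ICT, ~2-fold in PPP, ~2.1-fold across
    proximal and ~1.5-fold across distal clusters.  Cluster sizes shift
    progenitors (PPP, DPP) up and differentiated clusters (ICT, PC, LDC)
    down in the mutants.  The forelimb and knockout conditions do not
    express the target gene.
    """
    base_sizes = {
        "PPP": 620, "TP": 500, "ICT": 700, "PC": 470,
        "DP": 560, "DPP": 620, "EDC": 500, "LDC": 480, "Ms": 550,
    }
    pendel_sizes = dict(base_sizes, PPP=820, ICT=480)
    ko_sizes = dict(
        base_sizes, PPP=840, DPP=760, ICT=420, PC=380, Ms=460, LDC=380
    )
    sizes = {
        "WT-HL": base_sizes,
        "WT-FL": base_sizes,
        "PenDel-HL": pendel_sizes,
        "KO-HL": ko_sizes,
    }

    def axis_of(name: str) -> str:
        if name in PROXIMAL_CLUSTERS:
            return "proximal"
        if name in DISTAL_CLUSTERS:
            return "distal"
        return "NA"

    clusters = tuple(
        ClusterSpec(
            name=name,
            axis=axis_of(name),
            n_cells={cond: sizes[cond][name] for cond in sizes},
        )
        for name in base_sizes
    )

    wt_hl = {}
    for name in base_sizes:
        if name in PROXIMAL_CLUSTERS:
            wt_hl[name] = (0.13, 0.25, 0.62)
        elif name in DISTAL_CLUSTERS:
            wt_hl[name] = (0.29, 0.55, 0.16)
        else:
            wt_hl[name] = (0.20, 0.40, 0.40)
    pendel_hl = {
        "ICT": (0.455, 0.265, 0.28),
        "PPP": (0.26, 0.30, 0.44),
        "TP": (0.20, 0.30, 0.50),
        "PC": (0.20, 0.30, 0.50),
        "Ms": (0.32, 0.38, 0.30),
    }
    for name in DISTAL_CLUSTERS:
        pendel_hl[name] = (0.44, 0.45, 0.11)
    silent = {name: (0.98, 0.02, 0.0) for name in base_sizes}

    return CellGenConfig(
        conditions=(("WT", "HL"), ("WT", "FL"), ("PenDel", "HL"), ("KO", "HL")),
        clusters=clusters,
        class_weights={
            "WT-HL": wt_hl,
            "WT-FL": silent,
            "PenDel-HL": pendel_hl,
            "KO-HL": silent,
        },
        seed=seed,
    )


def default_contact_config(
    seed: int = 0,
    n_pairs: int = 100_000,
    with_loop: bool = True,
    condition_tag: str = "active",
) -> ContactGenConfig:
    """A desk-scale two-condition contact experiment.

    A 300 kb region binned at 5 kb with one 10 kb-anchor loop (enrichment 5)
    between a promoter-like viewpoint and a distal enhancer-like anchor;
    ``with_loop=False`` gives the matched inactive condition.
    """
    region = GenomicInterval("chr13", 54_000_001, 54_300_000)
    loop = Loop(
        anchor_a=GenomicInterval("chr13", 54_075_001, 54_085_000),
        anchor_b=GenomicInterval("chr13", 54_225_001, 54_235_000),
        enrichment=5.0,
    )
    return ContactGenConfig(
        region=region,
        n_pairs=n_pairs,
        decay_exponent=-1.0,
        loops=(loop,) if with_loop else (),
        min_distance=1000,
        condition_tag=condition_tag,
        seed=seed,
    )
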