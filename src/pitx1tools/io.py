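"""Plain-text readers and writers for the pipeline's data types.

Formats: cell tables and label tables as headered TSV, contact pairs as
4-column BEDPE-like TSV (1-based), contact matrices as triplet or dense
text with a self-describing comment header, virtual-4C profiles as bedGraph
(0-based half-open, as the format requires), generator configs as YAML or
JSON, and bulk expression matrices as TSV with a required ``length`` column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bulk import ExpressionMatrix
from .composition import DPAResult
from .contacts import ContactMatrix, ContactPairs, V4CProfile
from .expression import CELL_COLUMNS, CLASS_LABELS
from .regions import GenomicInterval
from .simulate import (
    CellGenConfig,
    ClusterSpec,
    ContactGenConfig,
    LibrarySizeModel,
    Loop,
    NonLowComponent,
    QCModel,
    TruncNormalComponent,
)

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "read_contact_pairs",
    "write_contact_pairs",
    "read_contact_matrix",
    "write_contact_matrix",
    "write_bedgraph",
    "write_dpa_result",
    "read_label_table",
    "load_cell_config",
    "load_contact_config",
    "read_expression_matrix",
]

_OPTIONAL_CELL_COLUMNS = ("norm_expr", "expr_class", "true_class")


def write_cell_table(cells: pd.DataFrame, path) -> None:
    cols = [c for c in CELL_COLUMNS if c in cells.columns]
    cols += [c for c in _OPTIONAL_CELL_COLUMNS if c in cells.columns]
    cells.to_csv(path, sep="\t", index=False, columns=cols)


def read_cell_table(path) -> pd.DataFrame:
    # axis uses the literal string "NA"; stop pandas from nulling it
    cells = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    for col in ("expr_class", "true_class"):
        if col in cells.columns:
            cells[col] = pd.Categorical(
                cells[col], categories=CLASS_LABELS, ordered=True
            )
    return cells


def write_contact_pairs(pairs: ContactPairs, path) -> None:
    """Headerless 4-column TSV: chrom, posA, chrom, posB (1-based)."""
    chrom = pairs.region.chrom
    with open(path, "w") as fh:
        for a, b in zip(pairs.pos_a, pairs.pos_b):
            fh.write(f"{chrom}\t{a}\t{chrom}\t{b}\n")


def read_contact_pairs(path, region: GenomicInterval) -> ContactPairs:
    table = pd.read_csv(
        path, sep="\t", header=None, names=["chrom_a", "pos_a", "chrom_b", "pos_b"]
    )
    if len(table) and not (
        (table["chrom_a"] == region.chrom).all()
        and (table["chrom_b"] == region.chrom).all()
    ):
        raise ValueError(f"pair chromosomes do not match region {region}")
    return ContactPairs(
        region=region,
        pos_a=table["pos_a"].to_numpy(np.int64),
        pos_b=table["pos_b"].to_numpy(np.int64),
    )


def write_contact_matrix(m: ContactMatrix, path, fmt: str = "triplet") -> None:
    """Write a contact matrix as triplet (upper triangle) or dense text.

    A comment header records region, bin size, masked bins and flags, so the
    file round-trips without side information.
    """
    masked = ",".join(map(str, np.flatnonzero(~m.mask)))
    header = (
        f"# region={m.region} bin_size={m.bin_size} "
        f"normalized={int(m.normalized)} signed={int(m.signed)} "
        f"subdiag_scaled={int(m.subdiag_scaled)} masked={masked}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        if m.normalized and m.bias is not None:
            fh.write("# bias=" + ",".join(f"{v:.12g}" for v in m.bias) + "\n")
        if fmt == "triplet":
            iu, ju = np.nonzero(np.triu(m.matrix != 0))
            for i, j in zip(iu, ju):
                fh.write(f"{i}\t{j}\t{m.matrix[i, j]:.12g}\n")
        elif fmt == "dense":
            np.savetxt(fh, m.matrix, fmt="%.12g", delimiter="\t")
        else:
            raise ValueError("fmt must be 'triplet' or 'dense'")


def read_contact_matrix(path) -> ContactMatrix:
    meta: dict[str, str] = {}
    bias = None
    body: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# bias="):
                bias = np.array(
                    [float(v) for v in line.split("=", 1)[1].split(",")]
                )
            elif line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        key, val = tok.split("=", 1)
                        meta[key] = val
            elif line.strip():
                body.append(line)
    region = GenomicInterval.parse(meta["region"])
    bin_size = int(meta["bin_size"])
    n = region.n_bins(bin_size)
    mask = np.ones(n, dtype=bool)
    if meta.get("masked"):
        mask[[int(i) for i in meta["masked"].split(",")]] = False
    first_fields = body[0].split("\t") if body else []
    matrix = np.zeros((n, n))
    if len(first_fields) == 3:  # triplet
        for line in body:
            i_s, j_s, v_s = line.split("\t")
            i, j, v = int(i_s), int(j_s), float(v_s)
            matrix[i, j] = v
            matrix[j, i] = v
    else:  # dense
        matrix = np.loadtxt(body, delimiter="\t").reshape(n, n)
    return ContactMatrix(
        region=region,
        bin_size=bin_size,
        matrix=matrix,
        mask=mask,
        normalized=bool(int(meta.get("normalized", "0"))),
        bias=bias,
        signed=bool(int(meta.get("signed", "0"))),
        subdiag_scaled=bool(int(meta.get("subdiag_scaled", "0"))),
    )


def write_bedgraph(profile: V4CProfile, path, track_name: str | None = None) -> None:
    """bedGraph export (0-based half-open; exact coordinate conversion)."""
    region = profile.region
    with open(path, "w") as fh:
        if track_name:
            fh.write(f'track type=bedGraph name="{track_name}"\n')
        for i, value in enumerate(profile.values):
            start0 = region.start - 1 + i * profile.interval_size
            end0 = min(start0 + profile.interval_size, region.end)
            fh.write(f"{region.chrom}\t{start0}\t{end0}\t{value:.6g}\n")


def write_dpa_result(result: DPAResult, path) -> None:
    s = result.settings
    with open(path, "w") as fh:
        fh.write(
            f"# condition_a={result.condition_a} condition_b={result.condition_b} "
            f"n_perm={s.n_perm} p_mix={s.p_mix} seed={s.seed} "
            f"statistic={s.statistic}\n"
        )
        result.table.to_csv(fh, sep="\t")


def read_label_table(path) -> pd.DataFrame:
    """TSV of (cell_id, condition, cluster) for the proportion test."""
    table = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    missing = {"cell_id", "condition", "cluster"} - set(table.columns)
    if missing:
        raise ValueError(f"label table is missing columns: {sorted(missing)}")
    return table


# ---------------------------------------------------------------------------
# generator configs


def _load_mapping(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def cell_config_from_dict(data: dict) -> CellGenConfig:
    conditions = tuple(
        (c["genotype"], c["tissue"]) if isinstance(c, dict) else tuple(c)
        for c in data["conditions"]
    )
    clusters = tuple(
        ClusterSpec(
            name=c["name"], axis=c.get("axis", "NA"),
            n_cells={k: int(v) for k, v in c["n_cells"].items()},
        )
        for c in data["clusters"]
    )
    weights = {
        cond: {cl: tuple(map(float, w)) for cl, w in by_cluster.items()}
        for cond, by_cluster in data["class_weights"].items()
    }
    kwargs = {}
    comp = data.get("components", {})
    if "nonlow" in comp:
        kwargs["nonlow"] = NonLowComponent(**comp["nonlow"])
    if "intermediate" in comp:
        kwargs["intermediate"] = TruncNormalComponent(**comp["intermediate"])
    if "high" in comp:
        kwargs["high"] = TruncNormalComponent(**comp["high"])
    if "library_size" in data:
        kwargs["library_size"] = LibrarySizeModel(**data["library_size"])
    if "qc" in data:
        kwargs["qc"] = QCModel(**data["qc"])
    if "scale" in data:
        kwargs["scale"] = float(data["scale"])
    return CellGenConfig(
        conditions=conditions,
        clusters=clusters,
        class_weights=weights,
        seed=data.get("seed"),
        **kwargs,
    )


def load_cell_config(path) -> CellGenConfig:
    return cell_config_from_dict(_load_mapping(path))


def contact_config_from_dict(data: dict) -> ContactGenConfig:
    loops = tuple(
        Loop(
            anchor_a=GenomicInterval.parse(lp["anchor_a"]),
            anchor_b=GenomicInterval.parse(lp["anchor_b"]),
            enrichment=float(lp["enrichment"]),
        )
        for lp in data.get("loops", [])
    )
    return ContactGenConfig(
        region=GenomicInterval.parse(data["region"]),
        n_pairs=int(data["n_pairs"]),
        decay_exponent=float(data.get("decay_exponent", -1.0)),
        loops=loops,
        min_distance=int(data.get("min_distance", 1000)),
        condition_tag=str(data.get("condition_tag", "")),
        seed=data.get("seed"),
    )


def load_contact_config(path) -> ContactGenConfig:
    return contact_config_from_dict(_load_mapping(path))


# ---------------------------------------------------------------------------
# bulk matrices


def read_expression_matrix(
    path, groups_path=None, totals_path=None, kind: str = "counts"
) -> ExpressionMatrix:
    """Gene x sample TSV with a required ``length`` column.

    Sample totals default to the column sums of the counts; a sidecar TSV
    (sample, total) overrides them.  ``groups_path`` is a sidecar TSV of
    (sample, group).
    """
    table = pd.read_csv(path, sep="\t", index_col=0)
    if "length" not in table.columns:
        raise ValueError("expression matrix needs a 'length' column")
    lengths = table["length"].astype(float)
    values = table.drop(columns="length").astype(float)
    if totals_path is not None:
        t = pd.read_csv(totals_path, sep="\t", index_col=0).iloc[:, 0]
        totals = t.reindex(values.columns).astype(float)
    elif kind == "counts":
        totals = values.sum(axis=0)
    else:
        totals = None
    groups: dict[str, str] = {}
    if groups_path is not None:
        g = pd.read_csv(groups_path, sep="\t", index_col=0).iloc[:, 0]
        groups = g.to_dict()
    return ExpressionMatrix(
        values=values,
        gene_lengths=lengths,
        sample_totals=totals,
        sample_groups=groups,
        kind=kind,
    )
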