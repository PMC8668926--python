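import numpy as np
import pandas as pd
import pytest

from pitx1tools.expression import CELL_COLUMNS


@pytest.fixture
def rng():
    return np.random.default_rng(20210129)


def make_cell_table(rows):
    """Build a minimal cell table from (n_genes, mito, target, total) rows."""
    records = []
    for i, (n_genes, mito, target, total) in enumerate(rows):
        records.append(
            {
                "cell_id": f"cell{i:03d}",
                "genotype": "WT",
                "tissue": "HL",
                "cluster": "ICT",
                "axis": "proximal",
                "n_genes": n_genes,
                "mito_frac": mito,
                "target_count": target,
                "total_count": total,
            }
        )
    return pd.DataFrame.from_records(records, columns=list(CELL_COLUMNS))


@pytest.fixture
def toy_cells():
    return make_cell_table(
        [(2500, 0.05, 0, 10_000), (2500, 0.05, 1, 10_000), (2500, 0.05, 50, 10_000)]
    )
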