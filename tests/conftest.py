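import numpy as np
import pandas as pd
import pytest

from eqtlweight import AssocTable, EqtlTable


@pytest.fixture
def rng():
    return np.random.default_rng(20130531)


@pytest.fixture
def small_assoc():
    return AssocTable.from_arrays(
        snp_ids=[f"rs{i}" for i in range(1, 6)],
        p=[0.02, 0.5, 1e-4, 0.9, 0.03],
        chrom=["1"] * 5,
        pos=[100, 200, 300, 400, 500],
    )


@pytest.fixture
def small_eqtl():
    return EqtlTable(
        pd.DataFrame(
            {
                "snp_id": ["rs1", "rs3"],
                "p_eqtl": [1e-4, 1e-16],
                "lod": [4.0, 16.0],
                "gene": ["GENEA", "GENEB"],
            }
        )
    )


def make_assoc(p_values, prefix="rs"):
    p_values = np.asarray(p_values, dtype=float)
    return AssocTable.from_arrays(
        snp_ids=[f"{prefix}{i}" for i in range(1, len(p_values) + 1)], p=p_values
    )
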