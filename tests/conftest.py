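import numpy as np
import pandas as pd
import pytest

from serodiff import io_tables, quantify
from serodiff.simulate import SimConfig, simulate_study


@pytest.fixture
def toy_sheet() -> pd.DataFrame:
    rows = (
        [(f"m{i}", "M", f"p{i}" if i < 3 else None) for i in range(4)]
        + [(f"s{i}", "S", f"p{i}" if i < 3 else None) for i in range(5)]
        + [(f"c{i}", "C", None) for i in range(4)]
    )
    return pd.DataFrame(rows, columns=["sample_id", "group", "pair_id"])


@pytest.fixture
def toy_peptides(toy_sheet) -> pd.DataFrame:
    """Two proteins, three peptides each, hand-enterable intensities."""
    rng = np.random.default_rng(7)
    rows = []
    for gid in (1, 2):
        for k in range(3):
            rows.append(
                {
                    "sequence": "ACDEFGHIK"[: 7 + k] + str(gid),
                    "length": 7 + k,
                    "protein_group_id": gid,
                    "is_unique": k != 2,  # third peptide shared
                }
            )
    pep = pd.DataFrame(rows)
    pep["length"] = pep["sequence"].str.len()
    for sid in toy_sheet["sample_id"]:
        vals = rng.uniform(1e3, 1e6, len(pep))
        vals[rng.random(len(pep)) < 0.2] = 0.0
        pep[sid] = vals
    return pep


@pytest.fixture
def toy_protein_groups() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "group_id": [1, 2],
            "majority_ids": [["P00001"], ["P00002", "P00002-2"]],
            "only_by_site": [False, False],
            "reverse": [False, False],
            "contaminant": [False, False],
            "n_unique_peptides": [2, 2],
            "all_ids_contaminant": [False, False],
        }
    )


@pytest.fixture(scope="session")
def small_study():
    """One modest simulated study shared by read-only tests."""
    return simulate_study(SimConfig(n_proteins=120, seed=11))


@pytest.fixture(scope="session")
def small_quant(small_study):
    pg = io_tables.apply_qc_filters(small_study.protein_groups)
    return quantify.build_quant_matrix(
        small_study.peptides, pg, small_study.sample_sheet
    )
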