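import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import panelfinder as pf

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def two_group_sim():
    """Planted two-group simulation: 50 markers shifted by 2 log2 units."""
    cfg = pf.SimConfig(
        n_per_group={"control": 20, "LGG_GT": 20},
        n_proteins=1000,
        n_markers=50,
        effect_log2=2.0,
        seed=11,
    )
    return pf.simulate_matrix(cfg)


@pytest.fixture(scope="session")
def four_group_sim():
    """Small four-group simulation with per-group marker signatures."""
    cfg = pf.SimConfig(
        n_per_group={"control": 10, "LGG_GT": 8, "EMB": 8, "other_tumor": 8},
        n_proteins=300,
        n_markers=30,
        effect_log2=2.5,
        seed=7,
    )
    return pf.simulate_matrix(cfg)


@pytest.fixture(scope="session")
def four_group_complete(four_group_sim):
    """Filtered, log2, normalized and imputed version of the 4-group sim."""
    m, sheet, truth = four_group_sim
    f, _ = pf.filter_group_validity(m, sheet)
    ml = pf.normalize_median(pf.log2_transform(f))
    mc = pf.impute_downshifted(ml, seed=13)
    return mc, sheet, truth


@pytest.fixture()
def tiny_sheet():
    return pf.SampleSheet(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(6)],
        "group": ["control"] * 3 + ["LGG_GT"] * 3,
    }))


@pytest.fixture()
def proteingroups_file(tmp_path):
    """Three-row MaxQuant-style proteinGroups table, one contaminant."""
    text = (
        "Protein IDs\tLFQ intensity A\tLFQ intensity B\tReverse\tPotential contaminant\n"
        "P1;P1b\t100\t200\t\t\n"
        "P2\t0\t300\t\t\n"
        "CON__P3\t50\t60\t\t+\n"
    )
    path = tmp_path / "proteinGroups.txt"
    path.write_text(text)
    return path
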