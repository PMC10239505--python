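import numpy as np
import pandas as pd
import pytest

import brainmetab as bm
from brainmetab import PipelineConfig, SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def null_cohort():
    """Small cohort with no planted effects (DOPA's levodopa shift excepted)."""
    cfg = SimConfig(seed=11, n_analytes_lc=6, n_analytes_fia=6)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def processed_null(null_cohort):
    table, meta, blanks, truth = null_cohort
    return bm.run_pipeline(table, meta, blanks, [],
                           PipelineConfig(expected_qc_conc=truth.expected_qc_conc))


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with known group, levodopa, and progression effects planted."""
    cfg = SimConfig(
        seed=22, n_analytes_lc=10, n_analytes_fia=0,
        named_analytes=("Hcy",),
        group_effects={("LC_001", "PD-D"): 1.0},
        levodopa_effects={("Hcy", "PD-D"): 2.0},
        score_effects={("LC_002", "updrs_m"): 0.5},
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def processed_planted(planted_cohort):
    table, meta, blanks, truth = planted_cohort
    return bm.run_pipeline(table, meta, blanks, [], None)


@pytest.fixture()
def tiny_table():
    values = pd.DataFrame(
        [[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]],
        index=["s1", "s2", "s3"], columns=["A", "B"])
    ann = pd.DataFrame({
        "method": ["LC", "FIA"],
        "analyte_type": ["measured", "measured"],
        "class_label": ["amine", "lipid"],
    }, index=pd.Index(["A", "B"], name="analyte_id"))
    return bm.AnalyteTable(values, ann)


def make_meta(groups, regions=None, plates=None, **extra):
    """Minimal SampleMeta for hand-built preprocessing instances."""
    n = len(groups)
    regions = regions or ["cortex"] * n
    plates = plates or ["P1"] * n
    idx = [f"s{i + 1}" for i in range(n)]
    df = pd.DataFrame({
        "subject_id": idx, "group": groups, "region": regions,
        "plate_id": plates,
    }, index=idx)
    for k, v in extra.items():
        df[k] = v
    return bm.SampleMeta(df)
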