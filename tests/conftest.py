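import numpy as np
import pandas as pd
import pytest

from rhfsig import synthdata


@pytest.fixture(scope="session")
def small_rat_cohort():
    """Modest rat cohort with planted 4-fold RV programs, shared across tests."""
    cfg = synthdata.RatSimConfig(
        n_genes=800, n_per_group=6, library_size=2e6,
        baseline_logmean_scale=0.8,
        planted_clusters=[({("PAB-H", "RV"): 2.0, ("PAB-F", "RV"): 2.0}, 40),
                          ({("PAB-F", "RV"): 2.0}, 30)],
        seed=42)
    return synthdata.simulate_rat_cohort(cfg)


@pytest.fixture(scope="session")
def small_human_cohort():
    """71-patient cohort with balanced planted severity-linked genes."""
    cfg = synthdata.HumanSimConfig(n_genes=1500, n_planted_pos=60,
                                   n_planted_neg=60, seed=7)
    return synthdata.simulate_human_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def condition_samples(sheet: pd.DataFrame, group: str, ventricle: str) -> list:
    by = sheet.set_index("sample_id")
    return list(by[(by["group"] == group) & (by["ventricle"] == ventricle)].index)
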