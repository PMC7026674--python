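import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, print_blob=False)
settings.load_profile("deterministic")

from dysbiota.datatypes import OtuTable, metadata_frame
from dysbiota.synthetic_cohort import CohortConfig, generate_cohort


def toy_table(counts, sample_ids=None, otu_ids=None, taxonomy=None) -> OtuTable:
    counts = np.asarray(counts)
    sample_ids = sample_ids or [f"S{i}" for i in range(counts.shape[0])]
    otu_ids = otu_ids or [f"Otu{j}" for j in range(counts.shape[1])]
    df = pd.DataFrame(counts, index=sample_ids, columns=otu_ids)
    return OtuTable(df, taxonomy or {})


def small_cohort_config(seed: int = 0, **overrides) -> CohortConfig:
    """A reduced cohort (fast) that keeps the three-cluster structure."""
    cfg = CohortConfig(seed=seed)
    cfg.n_per_group = {"CD": 5, "UC": 8, "Infection": 8, "Tumor": 7, "Other": 12, "NHC": 40}
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@pytest.fixture(scope="session")
def default_cohort():
    """One default 283-subject cohort shared across tests."""
    bact, fungi, records = generate_cohort(CohortConfig(seed=11))
    return bact, fungi, metadata_frame(records)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
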