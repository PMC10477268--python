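import warnings

import pandas as pd
import pytest

from pretermpsw import pipeline, registry_io, synthetic

# constant-column warnings from tiny designs are expected in several tests
warnings.filterwarnings("ignore", message="dropping constant design columns")


def make_raw(**overrides) -> dict:
    """One valid raw registry row; override individual fields per test."""
    row = {
        "year": 2019,
        "gestational_age": 39,
        "maternal_age": 27,
        "race": 1,
        "schooling_years": 11,
        "marital_status": 2,
        "parity": 1,
        "pregnancy_type": 1,
        "delivery_mode": 1,
        "sex": 2,
        "birthweight": 3200,
        "anc_visits": 8,
        "region": "Southeast",
    }
    row.update(overrides)
    return row


def raw_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows).astype({c: "Int64" for c in registry_io.RAW_FIELDS if c != "region"})


@pytest.fixture(scope="session")
def confounded_recoded() -> pd.DataFrame:
    """Recoded two-year synthetic registry with confounding, null period effect."""
    cfg = synthetic.null_config(n_per_year=6000, seed=42)
    return registry_io.recode(synthetic.simulate_births(cfg))


@pytest.fixture(scope="session")
def confounded_stacked(confounded_recoded) -> pipeline.StackedDataset:
    return pipeline.build_stacked(confounded_recoded, 2019, 2020)
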