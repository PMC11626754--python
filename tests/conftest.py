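import numpy as np
import pandas as pd
import pytest

from climtax import default_config, generate_climate, generate_injuries


@pytest.fixture(scope="session")
def small_config():
    """Reduced study: 60 schools, fewer cases — fast but structurally complete."""
    return default_config(seed=42, n_schools=60, injuries_per_school_year=3.0)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    climate, gt = generate_climate(small_config)
    injuries, gt = generate_injuries(small_config, gt)
    return climate, injuries, gt


@pytest.fixture()
def mixed_cases():
    """Eight hand-crafted mixed-type injury cases, two obvious blocks."""
    return pd.DataFrame(
        {
            "case_id": [f"C{i}" for i in range(8)],
            "age_group": [8, 8, 9, 8, 11, 12, 11, 12],
            "gender": ["girl", "girl", "girl", "girl", "boy", "boy", "boy", "boy"],
            "event_place": ["classroom"] * 4 + ["yard"] * 4,
            "event_term": ["lesson", "lesson", "break", "lesson", "break", "break", "break", "lesson"],
            "anatomic_place": ["hand", "foot", "hand", "hand", "head", "head", "head", "other"],
            "injury_cause": ["slipping"] * 4 + ["game"] * 4,
            "injury_type": ["superficial_incision"] * 4 + ["trauma"] * 4,
        }
    )


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: results do not depend on test order
    return np.random.default_rng(20260927)
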