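import numpy as np
import pandas as pd
import pytest

from alrisk.cohort import Cohort
from alrisk.simulate import default_config, generate_cohort, resolve_config


@pytest.fixture(scope="session")
def study_config():
    """Study-condition generator config with the intercept resolved once."""
    return resolve_config(default_config(seed=0))


@pytest.fixture(scope="session")
def study_cohort(study_config):
    return generate_cohort(study_config)


@pytest.fixture(scope="session")
def flat_config():
    """No era effects: covariate model only (for effect-recovery checks)."""
    return resolve_config(default_config(seed=0, era_boundaries=(2,), era_log_odds_shifts=(0.0,)))


def expand_counts(rows):
    """Expand (sex, location, ..., leaks, total) style count rows to a cohort frame.

    `rows` is a list of (overrides: dict, leaks: int, total: int); unspecified
    covariates take fixed reference values.
    """
    base = {
        "sex": "M",
        "age_years": 60.0,
        "bmi": 23.0,
        "asa": 2,
        "stage": 2,
        "tumor_size_cm": 4.0,
        "location": "upper",
        "op_time_min": 200.0,
        "transfusion": 0,
        "neoadjuvant_crt": 0,
        "stapler_firings": 1,
    }
    records = []
    for overrides, leaks, total in rows:
        for i in range(total):
            rec = dict(base)
            rec.update(overrides)
            rec["leak"] = 1 if i < leaks else 0
            records.append(rec)
    df = pd.DataFrame(records)
    df.insert(0, "seq", np.arange(1, len(df) + 1))
    df.insert(0, "patient_id", [f"X{i:05d}" for i in range(len(df))])
    return Cohort.from_frame(df, provenance="expanded-counts")


@pytest.fixture(scope="session")
def sex_counts_cohort():
    """The published sex cross-tabulation expanded to records:
    12/272 female leaks, 53/464 male leaks."""
    return expand_counts([({"sex": "F"}, 12, 272), ({"sex": "M"}, 53, 464)])
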