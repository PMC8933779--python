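import pandas as pd
import pytest

from cogprof import SimConfig, default_domain_map, score_cohort, simulate_cohort


@pytest.fixture(scope="session")
def default_map():
    return default_domain_map()


@pytest.fixture(scope="session")
def calibrated_cohort():
    """Synthetic 500-patient cohort under the reference loading pattern
    with per-score residual SD 5 (shared across the factor/recovery tests)."""
    return simulate_cohort(SimConfig(n_patients=500, residual_sd=5.0), seed=42)


@pytest.fixture(scope="session")
def calibrated_scored(calibrated_cohort):
    return score_cohort(calibrated_cohort.to_long())


def make_scored(rows):
    """Minimal banded score table from (patient_id, score_id, band3) rows."""
    df = pd.DataFrame(rows, columns=["patient_id", "score_id", "band3"])
    df["test_id"] = df["score_id"]
    df["t_score"] = float("nan")
    return df
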