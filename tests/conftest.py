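import numpy as np
import pandas as pd
import pytest

from kneebis import synthetic as syn


@pytest.fixture(scope="session")
def tiny_config():
    return syn.CohortConfig(
        n_participants=4,
        n_days=2,
        wear_hours=4.0,
        artifact_rate=0.05,
        disconnect_event_rate=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return syn.simulate_study(tiny_config)


@pytest.fixture(scope="session")
def study_dir(tiny_study, tmp_path_factory):
    d = tmp_path_factory.mktemp("study")
    syn.write_study(tiny_study, d)
    return d


@pytest.fixture(scope="session")
def recovery_truth():
    """Ground truth used by the model-level simulation harness."""
    return syn.GroundTruth(
        gamma00=-4.85,
        gamma01=-1.8,
        gamma10=0.007,
        gamma20=-0.05,
        gamma11=0.006,
        gamma21=0.08,
        sigma_u=1.2,
    )


@pytest.fixture(scope="session")
def reference_cohort(recovery_truth):
    """Mid-sized reduced cohort shared by the model cross-check tests."""
    return syn.simulate_reduced_cohort(100, recovery_truth, seed=11)


def make_samples(rows):
    """Build a samples frame from (ts, config, freq, R, X, battery) tuples."""
    from kneebis.ingest import phase_deg

    df = pd.DataFrame(
        rows,
        columns=["timestamp", "configuration", "frequency_khz",
                 "resistance_ohm", "reactance_ohm", "battery_v"],
    )
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["phase_deg"] = phase_deg(df["resistance_ohm"].to_numpy(),
                                df["reactance_ohm"].to_numpy())
    return df


@pytest.fixture
def samples_factory():
    return make_samples
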