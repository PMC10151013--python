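import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kneebis import qc
from kneebis.errors import ConfigError
from kneebis.ingest import DeviceLog, phase_deg, segment_sessions
from kneebis.qc import QCConfig, check_day_alignment, classify_samples, filter_call_periods


def _log(rows, reported_days=None, selftest_ok=True):
    """Log from (R, X) pairs at 2.5-min spacing, one config/frequency."""
    ts = pd.date_range("2023-01-02 08:00", periods=len(rows), freq="2.5min")
    df = pd.DataFrame({
        "timestamp": ts,
        "configuration": "long",
        "frequency_khz": 128.0,
        "resistance_ohm": [r for r, _ in rows],
        "reactance_ohm": [x for _, x in rows],
        "battery_v": 4.0,
    })
    df["phase_deg"] = phase_deg(df["resistance_ohm"].to_numpy(),
                                df["reactance_ohm"].to_numpy())
    measured = 100.0 if selftest_ok else 150.0
    selftests = pd.DataFrame({
        "session_index": [0], "frequency_khz": [128.0],
        "nominal_ohm": [100.0], "measured_ohm": [measured],
    })
    return DeviceLog("P01", df, selftests, reported_days)


def _classify(rows, **logkw):
    log = _log(rows, **logkw)
    sessions = segment_sessions(log)
    return classify_samples(log, sessions), log


def _rx_for_phase(theta_deg, magnitude=100.0):
    t = np.radians(theta_deg)
    return magnitude * np.cos(t), magnitude * np.sin(t)


class TestSampleClassification:
    def test_resistance_out_of_band(self):
        rep, _ = _classify([(250.0, -91.0)])  # theta = -20 deg
        assert not rep.sample_flags["clean"].iloc[0]
        assert rep.sample_flags["reason"].iloc[0] == qc.REASON_RESISTANCE

    def test_inside_both_bands(self):
        r, x = _rx_for_phase(-25.0, 100.0)
        rep, _ = _classify([(r, x)])
        assert rep.sample_flags["clean"].iloc[0]

    @pytest.mark.parametrize("r", [212.0, 0.0, 213.5])
    def test_resistance_boundaries_strict(self, r):
        rep, _ = _classify([(r, -10.0 if r else -0.1)])
        assert not rep.sample_flags["clean"].iloc[0]

    @pytest.mark.parametrize("theta", [-50.0, 0.0, -55.0, 10.0])
    def test_phase_boundaries_strict(self, theta):
        rep, _ = _classify([_rx_for_phase(theta, 100.0)])
        assert not rep.sample_flags["clean"].iloc[0]

    def test_phase_failure_short_circuits_resistance_reason(self):
        # out of band on both counts: the phase step runs first
        rep, _ = _classify([_rx_for_phase(-60.0, 500.0)])
        assert rep.sample_flags["reason"].iloc[0] == qc.REASON_PHASE

    def test_per_frequency_independence(self):
        ts = pd.Timestamp("2023-01-02 08:00")
        df = pd.DataFrame({
            "timestamp": [ts, ts],
            "configuration": "long",
            "frequency_khz": [40.0, 128.0],
            "resistance_ohm": [100.0, 300.0],
            "reactance_ohm": [-5.0, -5.0],
            "battery_v": 4.0,
        })
        df["phase_deg"] = phase_deg(df["resistance_ohm"].to_numpy(),
                                    df["reactance_ohm"].to_numpy())
        st_df = pd.DataFrame({"session_index": [0], "frequency_khz": [128.0],
                              "nominal_ohm": [100.0], "measured_ohm": [100.0]})
        log = DeviceLog("P01", df, st_df)
        rep = classify_samples(log, segment_sessions(log))
        flags = rep.sample_flags["clean"].tolist()
        assert flags == [True, False]

    def test_selftest_failure_drops_session(self):
        rep, _ = _classify([(100.0, -5.0)] * 3, selftest_ok=False)
        assert not rep.sample_flags["clean"].any()
        assert (rep.sample_flags["reason"] == qc.REASON_SELFTEST).all()

    def test_conservation(self, tiny_study):
        log = tiny_study.logs["P03"]
        rep = classify_samples(log, segment_sessions(log))
        assert rep.n_clean + rep.n_dropped == len(log.samples)
        dropped = rep.sample_flags[~rep.sample_flags["clean"]]
        assert (dropped["reason"] != "").all()
        kept = rep.sample_flags[rep.sample_flags["clean"]]
        assert (kept["reason"] == "").all()

    def test_idempotent_on_filtered_data(self, tiny_study):
        log = tiny_study.logs["P01"]
        rep = classify_samples(log, segment_sessions(log))
        clean = DeviceLog("P01", log.samples[rep.sample_flags["clean"]],
                          log.selftests, log.reported_wear_days)
        rep2 = classify_samples(clean, segment_sessions(clean))
        assert rep2.sample_flags["clean"].all()


class TestDayAlignment:
    def _sessions(self, n):
        return [object()] * n  # only the count matters

    def test_equal_passes(self):
        assert check_day_alignment(self._sessions(7), 7, QCConfig())

    def test_mismatch_fails(self):
        assert not check_day_alignment(self._sessions(5), 7, QCConfig())

    def test_tolerance_relaxation(self):
        cfg = QCConfig(day_alignment_tolerance=1)
        assert check_day_alignment(self._sessions(6), 7, cfg)

    def test_missing_reported_days_skips(self):
        assert check_day_alignment(self._sessions(5), None, QCConfig())

    def test_misalignment_drops_everything(self):
        rep, _ = _classify([(100.0, -5.0)] * 4, reported_days=3)
        assert not rep.sample_flags["clean"].any()
        assert (rep.sample_flags["reason"] == qc.REASON_DAY_MISALIGNMENT).all()
        assert rep.session_failures[0]["reason"] == qc.REASON_DAY_MISALIGNMENT


def _periods(fracs, day=1, config="long", n=10):
    rows = []
    for i, f in enumerate(fracs):
        rows.append({
            "participant_id": "P01", "day": day, "call_index": i + 1,
            "configuration": config, "n_samples": n, "n_clean": int(round(f * n)),
        })
    return pd.DataFrame(rows)


class TestPeriodFilter:
    def test_twenty_percent_dropped(self):
        out = filter_call_periods(_periods([0.2, 0.9, 0.9, 0.9]))
        assert not out.loc[0, "kept"]
        assert out.loc[0, "reason"] == qc.REASON_LOW_FRACTION

    def test_thirty_percent_kept(self):
        out = filter_call_periods(_periods([0.3, 0.9, 0.9, 0.9]))
        assert out["kept"].all()

    def test_two_of_four_day_drops_all(self):
        out = filter_call_periods(_periods([0.3, 0.3, 0.1, 0.1]))
        assert not out["kept"].any()
        assert set(out.loc[[0, 1], "reason"]) == {qc.REASON_DAY_RULE}
        assert set(out.loc[[2, 3], "reason"]) == {qc.REASON_LOW_FRACTION}

    def test_exactly_25_percent_is_dropped(self):
        out = filter_call_periods(_periods([0.25, 0.9, 0.9, 0.9]))
        assert not out.loc[0, "kept"]

    def test_empty_period_reason(self):
        df = _periods([0.9, 0.9, 0.9, 0.9])
        df.loc[3, ["n_samples", "n_clean"]] = 0
        out = filter_call_periods(df)
        assert out.loc[3, "reason"] == qc.REASON_EMPTY_PERIOD
        assert out.loc[[0, 1, 2], "kept"].all()

    def test_short_day_uses_answered_count(self):
        # only 2 answered periods: day rule needs min(3, 2) = 2 passes
        out = filter_call_periods(_periods([0.9, 0.9]))
        assert out["kept"].all()
        out2 = filter_call_periods(_periods([0.9, 0.1]))
        assert not out2["kept"].any()

    def test_configurations_independent(self):
        df = pd.concat([
            _periods([0.9, 0.9, 0.9, 0.9], config="long"),
            _periods([0.1, 0.1, 0.1, 0.1], config="trans"),
        ], ignore_index=True)
        out = filter_call_periods(df)
        assert out[out["configuration"] == "long"]["kept"].all()
        assert not out[out["configuration"] == "trans"]["kept"].any()

    def test_idempotence(self):
        out = filter_call_periods(_periods([0.5, 0.6, 0.7, 0.8]))
        kept = out[out["kept"]]
        again = kept[["participant_id", "day", "call_index", "configuration"]].copy()
        # after dropping artifacts the kept periods are fully clean
        again["n_samples"] = kept["n_clean"].to_numpy()
        again["n_clean"] = kept["n_clean"].to_numpy()
        out2 = filter_call_periods(again)
        assert out2["kept"].all()

    def test_validation(self):
        with pytest.raises(ConfigError, match="phase_min"):
            filter_call_periods(_periods([0.5]), QCConfig(phase_min=0, phase_max=-1))


class TestMonotonicity:
    @settings(max_examples=25, deadline=None)
    @given(
        rx=st.lists(
            st.tuples(st.floats(1.0, 400.0), st.floats(-300.0, 50.0)),
            min_size=1, max_size=40,
        ),
        widen_r=st.floats(0.0, 200.0),
        widen_p=st.floats(0.0, 40.0),
    )
    def test_widening_bands_never_drops_more(self, rx, widen_r, widen_p):
        log = _log(rx)
        sessions = segment_sessions(log)
        narrow = classify_samples(log, sessions, QCConfig())
        wide_cfg = QCConfig(resistance_max=212.0 + widen_r,
                            phase_min=-50.0 - widen_p)
        wide = classify_samples(log, sessions, wide_cfg)
        assert wide.n_clean >= narrow.n_clean
        # every sample clean under the narrow config stays clean when widened
        assert (wide.sample_flags["clean"] | ~narrow.sample_flags["clean"]).all()


class TestOracleEquivalence:
    def test_sensitivity_and_false_positive_rate(self, tiny_study):
        """Injected artifacts are beyond the bands by construction, so the
        range checks must find all of them and nothing else."""
        for pid, log in tiny_study.logs.items():
            rep = classify_samples(log, segment_sessions(log))
            truth = log.samples["injected_artifact"].to_numpy()
            pred_artifact = ~rep.sample_flags["clean"].to_numpy()
            assert pred_artifact[truth].all(), f"missed artifact in {pid}"
            assert not pred_artifact[~truth].any(), f"false positive in {pid}"

    def test_zero_artifact_rate_removes_nothing(self):
        from kneebis import synthetic as syn

        cfg = syn.CohortConfig(n_participants=1, n_days=2, wear_hours=4.0,
                               artifact_rate=0.0, disconnect_event_rate=0.0,
                               seed=13)
        study = syn.simulate_study(cfg)
        log = study.logs["P01"]
        rep = classify_samples(log, segment_sessions(log))
        assert rep.n_dropped == 0
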