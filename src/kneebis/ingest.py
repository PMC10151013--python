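"""Device-log parsing, wear-session segmentation, and self-test verification.

The on-disk dialect is plain CSV::

    timestamp,configuration,frequency_khz,resistance_ohm,reactance_ohm,battery_v

with ISO-8601 timestamps, ``configuration`` in ``{long, trans}``, UTF-8 and LF
line endings.  Self-test records live in a second CSV::

    session_index,frequency_khz,nominal_ohm,measured_ohm
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

DEVICE_LOG_COLUMNS = [
    "timestamp",
    "configuration",
    "frequency_khz",
    "resistance_ohm",
    "reactance_ohm",
    "battery_v",
]
SELFTEST_COLUMNS = ["session_index", "frequency_khz", "nominal_ohm", "measured_ohm"]
CONFIGURATIONS = ("long", "trans")

#: key that makes one physical measurement unique within a log
SAMPLE_KEY = ["timestamp", "configuration", "frequency_khz"]


def phase_deg(resistance: np.ndarray | float, reactance: np.ndarray | float):
    """Phase angle in degrees, ``atan2(X, R)``.

    Capacitive tissue (X < 0) maps to negative phase, so the physiologic
    acceptance band is an interval below zero.
    """
    return np.degrees(np.arctan2(reactance, resistance))


@dataclass
class WearSession:
    """One contiguous battery-discharge interval of a device log."""

    session_index: int
    start: pd.Timestamp
    end: pd.Timestamp
    n_epochs: int

    @property
    def duration(self) -> pd.Timedelta:
        return self.end - self.start


@dataclass
class DeviceLog:
    """A participant's full impedance log plus self-test records.

    ``samples`` is a time-ordered frame with the dialect columns and a derived
    ``phase_deg`` column; rows are unique on (timestamp, configuration,
    frequency_khz).
    """

    participant_id: str
    samples: pd.DataFrame
    selftests: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=SELFTEST_COLUMNS)
    )
    reported_wear_days: int | None = None
    n_malformed: int = 0

    def __len__(self) -> int:
        return len(self.samples)


def _empty_samples() -> pd.DataFrame:
    df = pd.DataFrame(columns=DEVICE_LOG_COLUMNS + ["phase_deg"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def read_device_log(
    path,
    participant_id: str,
    *,
    selftest_path=None,
    reported_wear_days: int | None = None,
    malformed_tolerance: float = 0.01,
) -> DeviceLog:
    """Parse a device-log CSV into a :class:`DeviceLog`.

    Malformed rows (non-numeric fields, bad timestamps, unknown configuration)
    are counted and dropped; if they exceed ``malformed_tolerance`` of all rows
    an :class:`IntegrityError` is raised instead of silently proceeding.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in DEVICE_LOG_COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"device log missing required column(s): {missing}")
    if len(raw) == 0:
        return DeviceLog(participant_id, _empty_samples(),
                         _read_selftest(selftest_path), reported_wear_days)

    ts = pd.to_datetime(raw["timestamp"], errors="coerce", format="ISO8601")
    num = {
        c: pd.to_numeric(raw[c], errors="coerce")
        for c in ("frequency_khz", "resistance_ohm", "reactance_ohm", "battery_v")
    }
    ok = ts.notna() & raw["configuration"].isin(CONFIGURATIONS)
    for col in num.values():
        ok &= col.notna()

    n_bad = int((~ok).sum())
    if n_bad / len(raw) > malformed_tolerance:
        raise IntegrityError(
            f"{n_bad}/{len(raw)} malformed rows exceeds tolerance "
            f"{malformed_tolerance:.1%}"
        )

    samples = pd.DataFrame(
        {
            "timestamp": ts[ok],
            "configuration": raw.loc[ok, "configuration"],
            **{c: v[ok] for c, v in num.items()},
        }
    ).sort_values(["timestamp", "configuration", "frequency_khz"], kind="stable")
    if samples.duplicated(SAMPLE_KEY).any():
        raise IntegrityError("duplicate (timestamp, configuration, frequency) keys")
    samples["phase_deg"] = phase_deg(
        samples["resistance_ohm"].to_numpy(), samples["reactance_ohm"].to_numpy()
    )
    samples = samples.reset_index(drop=True)
    return DeviceLog(
        participant_id,
        samples,
        _read_selftest(selftest_path),
        reported_wear_days,
        n_malformed=n_bad,
    )


def _read_selftest(path) -> pd.DataFrame:
    if path is None:
        return pd.DataFrame(columns=SELFTEST_COLUMNS)
    df = pd.read_csv(path)
    missing = [c for c in SELFTEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"self-test file missing required column(s): {missing}")
    if (df["nominal_ohm"] <= 0).any():
        raise FormatError("self-test nominal_ohm must be > 0")
    return df


def write_device_log(log: DeviceLog, path) -> None:
    """Write ``log.samples`` back out in the CSV dialect (LF, UTF-8)."""
    out = log.samples[DEVICE_LOG_COLUMNS].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    buf = io.StringIO()
    out.to_csv(buf, index=False, float_format="%.6f", lineterminator="\n")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


def write_selftest(selftests: pd.DataFrame, path) -> None:
    selftests[SELFTEST_COLUMNS].to_csv(path, index=False, float_format="%.6f",
                                       lineterminator="\n")


def epoch_table(log: DeviceLog) -> pd.DataFrame:
    """Unique epochs (timestamps) with the battery voltage recorded first."""
    return (
        log.samples.groupby("timestamp", as_index=False)["battery_v"]
        .first()
        .sort_values("timestamp")
        .reset_index(drop=True)
    )


def segment_sessions(
    log: DeviceLog,
    gap_threshold: float = 120.0,
    recharge_jump: float = 0.2,
) -> list[WearSession]:
    """Split a log into battery-discharge wear sessions.

    A new session starts when the gap between consecutive epochs exceeds
    ``gap_threshold`` minutes, or when battery voltage rises by more than
    ``recharge_jump`` volts (a recharge happened while logging resumed fast).
    """
    epochs = epoch_table(log)
    if len(epochs) == 0:
        return []
    ts = epochs["timestamp"].to_numpy()
    bat = epochs["battery_v"].to_numpy()
    gaps = np.diff(ts) > np.timedelta64(int(gap_threshold * 60), "s")
    jumps = np.diff(bat) > recharge_jump
    breaks = np.flatnonzero(gaps | jumps) + 1
    bounds = np.concatenate([[0], breaks, [len(epochs)]])
    sessions = []
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        sessions.append(
            WearSession(
                session_index=i,
                start=epochs["timestamp"].iloc[a],
                end=epochs["timestamp"].iloc[b - 1],
                n_epochs=int(b - a),
            )
        )
    return sessions


def assign_sessions(log: DeviceLog, sessions: list[WearSession]) -> pd.Series:
    """Session index for every sample row (aligned with ``log.samples``)."""
    out = pd.Series(-1, index=log.samples.index, dtype=int, name="session_index")
    for s in sessions:
        mask = (log.samples["timestamp"] >= s.start) & (log.samples["timestamp"] <= s.end)
        out[mask] = s.session_index
    return out


def check_selftest(
    log: DeviceLog,
    sessions: list[WearSession],
    tolerance: float = 0.10,
    *,
    missing: str = "fail",
) -> dict[int, bool]:
    """Per-session self-test verdicts.

    A session passes iff every tested frequency satisfies
    ``|measured - nominal| / nominal <= tolerance`` (boundary inclusive).
    Sessions without a record follow the ``missing`` policy ("fail" or "pass").
    """
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must be in (0, 1)")
    if missing not in ("fail", "pass"):
        raise ValueError("missing policy must be 'fail' or 'pass'")
    st = log.selftests
    verdicts: dict[int, bool] = {}
    for s in sessions:
        rows = st[st["session_index"] == s.session_index]
        if len(rows) == 0:
            verdicts[s.session_index] = missing == "pass"
            continue
        rel = (rows["measured_ohm"] - rows["nominal_ohm"]).abs() / rows["nominal_ohm"]
        verdicts[s.session_index] = bool((rel <= tolerance).all())
    return verdicts
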