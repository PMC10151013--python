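"""Binary decision-tree artifact classification.

The checks run in a fixed order — wear-day alignment, on-board self-test,
phase band, resistance band, per-period clean fraction, per-day period rule —
and a "no" at any step classifies the affected scope as artifact.  All four
range bounds are strict: a sample sitting exactly on a bound is an artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .ingest import DeviceLog, WearSession, assign_sessions, check_selftest

REASON_DAY_MISALIGNMENT = "day_misalignment"
REASON_SELFTEST = "selftest_fail"
REASON_PHASE = "phase_out_of_range"
REASON_RESISTANCE = "resistance_out_of_range"
REASON_NO_SESSION = "no_session"
REASON_EMPTY_PERIOD = "empty_period"
REASON_LOW_FRACTION = "low_clean_fraction"
REASON_DAY_RULE = "day_rule"


@dataclass
class QCConfig:
    """Thresholds of the decision tree; defaults follow the study protocol."""

    selftest_tolerance: float = 0.10
    phase_min: float = -50.0
    phase_max: float = 0.0
    resistance_min: float = 0.0
    resistance_max: float = 212.0
    min_period_clean_fraction: float = 0.25
    min_valid_periods_per_day: int = 3
    periods_per_day: int = 4
    require_session_day_alignment: bool = True
    day_alignment_tolerance: int = 0

    def validate(self) -> None:
        if not self.phase_min < self.phase_max:
            raise ConfigError("phase_min must be < phase_max")
        if not self.resistance_min < self.resistance_max:
            raise ConfigError("resistance_min must be < resistance_max")
        if not 0 < self.min_period_clean_fraction < 1:
            raise ConfigError("min_period_clean_fraction must be in (0, 1)")
        if not 0 < self.selftest_tolerance < 1:
            raise ConfigError("selftest_tolerance must be in (0, 1)")


@dataclass
class QCReport:
    """Decisions at every level of the tree.

    ``sample_flags`` aligns with the log's sample rows and has boolean
    ``clean`` plus a ``reason`` (empty string for kept samples).  Period and
    day decisions are produced by :func:`filter_call_periods`.
    """

    sample_flags: pd.DataFrame
    period_decisions: pd.DataFrame | None = None
    session_failures: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    @property
    def n_clean(self) -> int:
        return int(self.sample_flags["clean"].sum())

    @property
    def n_dropped(self) -> int:
        return int((~self.sample_flags["clean"]).sum())


def check_day_alignment(
    sessions: list[WearSession],
    reported_wear_days: int | None,
    config: QCConfig,
) -> bool:
    """Do distinguishable battery-discharge events match reported wear days?"""
    if reported_wear_days is None:
        return True  # check skipped (caller may warn)
    return abs(len(sessions) - reported_wear_days) <= config.day_alignment_tolerance


def classify_samples(
    log: DeviceLog,
    sessions: list[WearSession],
    config: QCConfig | None = None,
) -> QCReport:
    """Sample-level pass of the decision tree.

    Classification is per (timestamp, configuration, frequency): one
    frequency's failure never removes other frequencies at the same epoch.
    Earlier tree steps short-circuit later ones for the scope they fail.
    """
    config = config or QCConfig()
    config.validate()

    n = len(log.samples)
    clean = np.ones(n, dtype=bool)
    reason = np.full(n, "", dtype=object)

    session_failures: list[dict] = []
    session_ids = assign_sessions(log, sessions).to_numpy()

    aligned = check_day_alignment(sessions, log.reported_wear_days, config)
    if config.require_session_day_alignment and not aligned:
        clean[:] = False
        reason[:] = REASON_DAY_MISALIGNMENT
        session_failures.append(
            {"scope": "log", "reason": REASON_DAY_MISALIGNMENT,
             "n_sessions": len(sessions),
             "reported_wear_days": log.reported_wear_days}
        )
        flags = pd.DataFrame({"clean": clean, "reason": reason},
                             index=log.samples.index)
        return QCReport(flags, session_failures=session_failures,
                        summary=_summary(flags))

    selftest_ok = check_selftest(log, sessions, config.selftest_tolerance)
    for s in sessions:
        if not selftest_ok.get(s.session_index, False):
            mask = clean & (session_ids == s.session_index)
            clean[mask] = False
            reason[mask] = REASON_SELFTEST
            session_failures.append(
                {"scope": f"session:{s.session_index}", "reason": REASON_SELFTEST}
            )
    orphan = clean & (session_ids < 0)
    clean[orphan] = False
    reason[orphan] = REASON_NO_SESSION

    theta = log.samples["phase_deg"].to_numpy(dtype=float)
    bad_phase = clean & ~((theta > config.phase_min) & (theta < config.phase_max))
    clean[bad_phase] = False
    reason[bad_phase] = REASON_PHASE

    r = log.samples["resistance_ohm"].to_numpy(dtype=float)
    bad_r = clean & ~((r > config.resistance_min) & (r < config.resistance_max))
    clean[bad_r] = False
    reason[bad_r] = REASON_RESISTANCE

    flags = pd.DataFrame({"clean": clean, "reason": reason}, index=log.samples.index)
    return QCReport(flags, session_failures=session_failures, summary=_summary(flags))


def _summary(flags: pd.DataFrame) -> dict:
    counts = flags.loc[~flags["clean"], "reason"].value_counts().to_dict()
    return {
        "n_samples": int(len(flags)),
        "n_clean": int(flags["clean"].sum()),
        "n_dropped": int((~flags["clean"]).sum()),
        "dropped_by_reason": counts,
    }


def filter_call_periods(
    periods: pd.DataFrame,
    config: QCConfig | None = None,
) -> pd.DataFrame:
    """Apply the period (>25% clean) and day (3-of-4 periods) rules.

    ``periods`` needs one row per (participant_id, day, call_index,
    configuration) with ``n_samples`` and ``n_clean`` counts (per electrode
    configuration — a transverse disconnect does not invalidate longitudinal
    data).  Returns the frame plus ``clean_fraction``, ``kept`` and ``reason``
    columns.  The day rule counts only answered-call periods: a day with
    ``a`` answered periods must have at least ``min(min_valid_periods_per_day,
    a)`` periods above the fraction threshold, else the whole day is dropped.
    """
    config = config or QCConfig()
    config.validate()

    out = periods.reset_index(drop=True).copy()
    n_samples = out["n_samples"].to_numpy(dtype=float)
    n_clean = out["n_clean"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_samples > 0, n_clean / n_samples, np.nan)
    out["clean_fraction"] = frac

    empty = n_samples == 0
    passes = ~empty & (frac > config.min_period_clean_fraction)

    kept = passes.copy()
    reason = np.full(len(out), "", dtype=object)
    reason[empty] = REASON_EMPTY_PERIOD
    reason[~empty & ~passes] = REASON_LOW_FRACTION

    out["_passes"] = passes
    day_flagged = []
    for key, grp in out.groupby(["participant_id", "day", "configuration"],
                                sort=False):
        answered = len(grp)
        need = min(config.min_valid_periods_per_day, answered)
        n_pass = int(grp["_passes"].sum())
        if n_pass < need:
            idx = grp.index
            pos = out.index.get_indexer(idx)
            newly = kept[pos]
            kept[pos] = False
            reason[pos[newly]] = REASON_DAY_RULE
            day_flagged.append(key)
        if answered < config.periods_per_day:
            day_flagged.append((*key, "short_day"))
    out = out.drop(columns="_passes")
    out["kept"] = kept
    out["reason"] = reason
    out.attrs["day_rule_flags"] = day_flagged
    return out
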