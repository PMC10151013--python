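"""End-to-end orchestration: raw logs + ESM reports -> reduced metrics table.

Thin glue over the stage modules; the decision tree order is session
alignment -> self-test -> phase -> resistance -> period fraction -> day rule.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import qc as qc_mod
from . import reduction
from .ingest import DeviceLog, read_device_log, segment_sessions
from .qc import QCConfig, QCReport


def read_esm_reports(path) -> pd.DataFrame:
    """Read the ESM-report CSV, restoring dtypes."""
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df["answered"] = df["answered"].astype(bool)
    return df


def process_participant(
    log: DeviceLog,
    reports: pd.DataFrame,
    participant: dict | pd.Series,
    config: QCConfig | None = None,
    pain_mode: str = "momentary",
) -> tuple[pd.DataFrame, QCReport]:
    """Run QC + windowing + reduction for one participant.

    Windows are carved on the raw log (the day's first logged sample anchors
    the first window); the period clean fraction is the share of QC-clean
    samples among all assigned samples per electrode configuration; kept
    periods are reduced from their clean samples only.
    """
    config = config or QCConfig()
    sessions = segment_sessions(log)
    sample_report = qc_mod.classify_samples(log, sessions, config)
    clean_mask = sample_report.sample_flags["clean"]

    periods, assignment = reduction.window_samples(log.samples, reports)

    # per-(period, configuration) sample counts for the fraction rule
    count_rows = []
    for pos, period in periods.iterrows():
        for cfg in ("long", "trans"):
            in_period = (assignment == pos) & (log.samples["configuration"] == cfg)
            count_rows.append(
                {
                    "participant_id": period["participant_id"],
                    "day": period["day"],
                    "call_index": period["call_index"],
                    "configuration": cfg,
                    "period_pos": pos,
                    "n_samples": int(in_period.sum()),
                    "n_clean": int((in_period & clean_mask).sum()),
                }
            )
    if count_rows:
        decisions = qc_mod.filter_call_periods(pd.DataFrame(count_rows), config)
    else:
        decisions = pd.DataFrame(
            columns=["participant_id", "day", "call_index", "configuration",
                     "period_pos", "n_samples", "n_clean", "clean_fraction",
                     "kept", "reason"]
        )
    sample_report.period_decisions = decisions

    answered = reports[reports["answered"].astype(bool)].set_index(
        ["day", "call_index"]
    )
    L_by_config = {
        "long": float(participant["L_longitudinal"]),
        "trans": float(participant["L_transverse"]),
    }
    reduced_rows = []
    for _, d in decisions[decisions["kept"]].iterrows():
        pos = d["period_pos"]
        cfg = d["configuration"]
        mask = (
            (assignment == pos)
            & (log.samples["configuration"] == cfg)
            & clean_mask
        )
        sub = log.samples[mask]
        if len(sub) == 0:
            continue
        per_freq = reduction.reduce_period(sub, L_by_config[cfg]).set_index(
            "frequency_khz"
        )
        rep = answered.loc[(d["day"], d["call_index"])]
        pain = reduction.binarize_pain(
            rep["momentary_pain_0_4"], rep["pain_since_last_yn"], pain_mode
        )
        row = {
            "participant_id": d["participant_id"],
            "group": int(participant["group"]),
            "day": int(d["day"]),
            "call": int(d["call_index"]),
            "config": cfg,
            "pain": pain,
        }
        if 128 in per_freq.index:
            row["plr128_mean"] = per_freq.loc[128, "plr_mean"]
            row["plr128_cv"] = per_freq.loc[128, "plr_cv"]
        if 40 in per_freq.index:
            row["plx40_mean"] = per_freq.loc[40, "plx_mean"]
            row["plx40_cv"] = per_freq.loc[40, "plx_cv"]
        for f in per_freq.index:
            row[f"plr{int(f)}_mean_all"] = per_freq.loc[f, "plr_mean"]
            row[f"plr{int(f)}_cv_all"] = per_freq.loc[f, "plr_cv"]
            row[f"plx{int(f)}_mean_all"] = per_freq.loc[f, "plx_mean"]
            row[f"plx{int(f)}_cv_all"] = per_freq.loc[f, "plx_cv"]
        reduced_rows.append(row)

    reduced = (pd.DataFrame(reduced_rows) if reduced_rows
               else pd.DataFrame(columns=reduction.REDUCED_COLUMNS))
    return reduced, sample_report


def process_study_dir(
    study_dir,
    config: QCConfig | None = None,
    pain_mode: str = "momentary",
) -> tuple[pd.DataFrame, dict[str, QCReport]]:
    """Process a directory written by :func:`kneebis.synthetic.write_study`."""
    study_dir = Path(study_dir)
    participants = pd.read_csv(study_dir / "participants.csv").set_index(
        "participant_id"
    )
    reports = read_esm_reports(study_dir / "esm_reports.csv")
    wear_days = None
    gt_path = study_dir / "ground_truth.json"
    if gt_path.exists():
        import json

        with open(gt_path, encoding="utf-8") as fh:
            wear_days = json.load(fh).get("config", {}).get("n_days")
    frames = []
    qc_reports: dict[str, QCReport] = {}
    for pid, prow in participants.iterrows():
        log_path = study_dir / f"device_log_{pid}.csv"
        if not log_path.exists():
            continue
        st_path = study_dir / f"selftest_{pid}.csv"
        log = read_device_log(
            log_path, pid,
            selftest_path=st_path if st_path.exists() else None,
            reported_wear_days=wear_days,
        )
        preports = reports[reports["participant_id"] == pid]
        reduced, qrep = process_participant(log, preports, prow, config, pain_mode)
        frames.append(reduced)
        qc_reports[pid] = qrep
    reduced = (pd.concat(frames, ignore_index=True) if frames
               else pd.DataFrame(columns=reduction.REDUCED_COLUMNS))
    return reduced, qc_reports


def qc_drop_table(qc_reports: dict[str, QCReport]) -> pd.DataFrame:
    """One row per drop decision (level, scope, reason) across participants."""
    rows = []
    for pid, rep in qc_reports.items():
        for reason, count in rep.summary.get("dropped_by_reason", {}).items():
            rows.append({"participant_id": pid, "level": "sample",
                         "scope": "samples", "reason": reason, "n": count})
        if rep.period_decisions is not None:
            dropped = rep.period_decisions[~rep.period_decisions["kept"]]
            for _, d in dropped.iterrows():
                rows.append({
                    "participant_id": pid,
                    "level": "period",
                    "scope": f"day{d['day']}/call{d['call_index']}/"
                             f"{d['configuration']}",
                    "reason": d["reason"],
                    "n": int(d["n_samples"]),
                })
        for f in rep.session_failures:
            rows.append({"participant_id": pid, "level": "session",
                         "scope": f["scope"], "reason": f["reason"], "n": np.nan})
    return pd.DataFrame(rows, columns=["participant_id", "level", "scope",
                                       "reason", "n"])
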