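"""Call-period windowing, per-length transform, mean/CV reduction, and the
Spearman redundancy screen.

Each answered ESM call owns the window ``(previous answered call, this call]``;
the first window of a day is anchored at the day's first logged sample.
Samples after a day's last call stay unassigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, ReductionError

ESM_COLUMNS = [
    "participant_id",
    "day",
    "call_index",
    "timestamp",
    "answered",
    "momentary_pain_0_4",
    "pain_since_last_yn",
]

REDUCED_COLUMNS = [
    "participant_id",
    "group",
    "day",
    "call",
    "config",
    "plr128_mean",
    "plr128_cv",
    "plx40_mean",
    "plx40_cv",
    "pain",
]


def per_length(value: float | np.ndarray, L: float):
    """Per-length impedance: resistance or reactance divided by the electrode
    spacing ``L`` in meters.  Sign is preserved, so reactance stays negative."""
    if L <= 0:
        raise DomainError(f"electrode spacing L must be > 0, got {L}")
    return np.asarray(value, dtype=float) / L if np.ndim(value) else value / L


def binarize_pain(momentary_pain, pain_since_last, mode: str = "momentary"):
    """Binary pain outcome for one answered report.

    ``momentary`` (default): 1 iff the 0-4 momentary rating is >= 1.
    ``any``: additionally 1 when pain was reported between calls
    (``pain_since_last == "yes"``) even if momentary pain is 0.
    """
    if mode not in ("momentary", "any"):
        raise ValueError(f"unknown binarization mode {mode!r}")
    if momentary_pain is None or (isinstance(momentary_pain, float)
                                  and np.isnan(momentary_pain)):
        return None
    current = 1 if momentary_pain >= 1 else 0
    if mode == "momentary":
        return current
    between = 1 if str(pain_since_last).lower() in ("yes", "y", "1", "true") else 0
    return 1 if (current or between) else 0


@dataclass
class CallPeriod:
    """One answered ESM call's observation window."""

    participant_id: str
    day: int
    call_index: int
    window_start: pd.Timestamp
    window_end: pd.Timestamp
    pain_binary: int | None = None


def window_samples(
    samples: pd.DataFrame,
    reports: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign samples to answered-call windows.

    ``samples`` must carry ``timestamp`` (and belong to one participant);
    ``reports`` is an ESM frame for the same participant.  Returns
    ``(periods, assignment)`` where ``periods`` has one row per answered call
    (participant_id, day, call_index, window_start, window_end) and
    ``assignment`` maps each sample row to the positional index of its period
    in ``periods`` (−1 for unassigned).  Windows are right-closed: a sample
    stamped exactly at a call belongs to that call's period.
    """
    reports = reports.sort_values(["day", "call_index"], kind="stable")
    answered = reports[reports["answered"].astype(bool)]

    ts = samples["timestamp"]
    assignment = pd.Series(-1, index=samples.index, dtype=int)
    rows = []
    for day, day_calls in answered.groupby("day", sort=True):
        call_ts = pd.to_datetime(day_calls["timestamp"])
        day_dates = call_ts.dt.normalize()
        day_date = day_dates.iloc[0]
        day_samples = ts[ts.dt.normalize() == day_date]
        if len(day_samples):
            anchor = day_samples.min() - pd.Timedelta(microseconds=1)
        else:
            anchor = day_date  # no samples that day; windows will be empty
        prev = anchor
        for (_, call), t in zip(day_calls.iterrows(), call_ts):
            in_window = (ts > prev) & (ts <= t)
            assignment[in_window] = len(rows)
            rows.append(
                {
                    "participant_id": call["participant_id"],
                    "day": int(day),
                    "call_index": int(call["call_index"]),
                    "window_start": prev,
                    "window_end": t,
                }
            )
            prev = t
    periods = pd.DataFrame(
        rows,
        columns=["participant_id", "day", "call_index", "window_start", "window_end"],
    )
    return periods, assignment


def reduce_values(values: np.ndarray) -> tuple[float, float]:
    """Mean and CV (%) of one period's per-length series.

    CV uses the sample SD (n−1) over the absolute mean, so negative-reactance
    periods still yield non-negative percentages.  With fewer than two values
    the CV is undefined (NaN).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ReductionError("cannot reduce a period with zero clean samples")
    mean = float(np.mean(values))
    if values.size < 2:
        return mean, float("nan")
    sd = float(np.std(values, ddof=1))
    denom = abs(mean)
    cv = float("nan") if denom == 0 else 100.0 * sd / denom
    return mean, cv


def reduce_period(
    period_samples: pd.DataFrame,
    L: float,
) -> pd.DataFrame:
    """Reduce one period's clean samples (one configuration) to per-frequency
    mean/CV of per-length resistance and reactance."""
    rows = []
    for freq, grp in period_samples.groupby("frequency_khz", sort=True):
        plr = per_length(grp["resistance_ohm"].to_numpy(), L)
        plx = per_length(grp["reactance_ohm"].to_numpy(), L)
        plr_mean, plr_cv = reduce_values(plr)
        plx_mean, plx_cv = reduce_values(plx)
        rows.append(
            {
                "frequency_khz": freq,
                "plr_mean": plr_mean,
                "plr_cv": plr_cv,
                "plx_mean": plx_mean,
                "plx_cv": plx_cv,
                "n_samples": len(grp),
            }
        )
    return pd.DataFrame(rows)


def spearman_screen(
    metrics: pd.DataFrame,
    columns: list[str] | None = None,
    threshold: float = 0.9,
    prefer: tuple[str, ...] = ("plr128_mean", "plx40_mean", "plr128_cv", "plx40_cv"),
) -> tuple[pd.DataFrame, list[str]]:
    """Spearman redundancy screen over reduced metrics.

    Computes the pairwise-complete Spearman matrix (average ranks for ties)
    and collapses every cluster of metrics linked by ``|rho| > threshold`` to
    one representative.  Representatives follow ``prefer`` order — by default
    the 128 kHz resistance and 40 kHz reactance metrics survive — falling back
    to column order.  Needs at least 3 complete rows, else the screen is
    skipped with a warning and all metrics are retained.
    """
    cols = columns or [c for c in metrics.columns
                       if metrics[c].dtype.kind in "fi"]
    data = metrics[cols]
    if len(data.dropna(how="any")) < 3:
        warnings.warn("fewer than 3 complete rows; Spearman screen skipped")
        return pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols), list(cols)

    corr = data.corr(method="spearman")

    # union-find over the |rho| > threshold graph
    parent = {c: c for c in cols}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if abs(corr.loc[a, b]) > threshold:
                parent[find(a)] = find(b)

    clusters: dict[str, list[str]] = {}
    for c in cols:
        clusters.setdefault(find(c), []).append(c)

    rank = {name: i for i, name in enumerate(prefer)}
    retained = []
    for members in clusters.values():
        members.sort(key=lambda m: (rank.get(m, len(prefer)), cols.index(m)))
        retained.append(members[0])
    retained.sort(key=cols.index)
    return corr, retained


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks, pairwise complete."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    rho, _ = stats.spearmanr(x[ok], y[ok])
    return float(rho)


def reduce_participant(
    clean_samples: pd.DataFrame,
    reports: pd.DataFrame,
    participant: dict | pd.Series,
    pain_mode: str = "momentary",
) -> pd.DataFrame:
    """Full reduction for one participant: window, per-length, mean/CV, pain.

    ``clean_samples`` holds QC-passed samples for both configurations;
    ``participant`` supplies ``group``, ``L_longitudinal``, ``L_transverse``.
    Returns one row per (answered call, configuration) in the reduced-table
    layout (128 kHz resistance + 40 kHz reactance columns).
    """
    L_by_config = {
        "long": float(participant["L_longitudinal"]),
        "trans": float(participant["L_transverse"]),
    }
    periods, assignment = window_samples(clean_samples, reports)
    answered = reports[reports["answered"].astype(bool)].set_index(
        ["day", "call_index"]
    )
    out = []
    for pos, period in periods.iterrows():
        rep = answered.loc[(period["day"], period["call_index"])]
        pain = binarize_pain(
            rep["momentary_pain_0_4"], rep["pain_since_last_yn"], pain_mode
        )
        for cfg, L in L_by_config.items():
            mask = (assignment == pos) & (clean_samples["configuration"] == cfg)
            sub = clean_samples[mask]
            if len(sub) == 0:
                continue
            per_freq = reduce_period(sub, L).set_index("frequency_khz")
            row = {
                "participant_id": period["participant_id"],
                "group": int(participant["group"]),
                "day": period["day"],
                "call": period["call_index"],
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
            out.append(row)
    if not out:
        return pd.DataFrame(columns=REDUCED_COLUMNS)
    return pd.DataFrame(out)


def write_reduced(df: pd.DataFrame, path) -> None:
    cols = [c for c in REDUCED_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False, lineterminator="\n")


def read_reduced(path) -> pd.DataFrame:
    # round_trip parser: probabilities recomputed from a written/reread
    # table must be bit-identical to the in-memory ones
    return pd.read_csv(path, float_precision="round_trip")
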