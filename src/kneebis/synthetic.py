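"""Synthetic study generator with known ground truth.

Produces complete synthetic studies — participants, randomized ESM call
schedules, raw multi-frequency impedance logs with injected artifacts, and
pain reports driven by a latent random-intercept logistic process — so every
downstream stage (ingest, QC, reduction, modelling, prediction) can be tested
end-to-end without any external data.

Determinism: every stream is derived from ``(config.seed, participant index,
purpose tag)`` so regenerating with the same config is byte-identical, and
individual operations are reproducible in isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, fields, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from . import reduction
from .errors import ConfigError
from .ingest import DeviceLog, phase_deg

_TAG_SCHEDULE = 1
_TAG_DEVICE = 2
_TAG_PAIN = 3

#: per-configuration baseline resistance (ohm) by frequency (kHz).  Chosen so
#: that the transverse 128 kHz per-length resistance of a typical knee lands
#: in the high-300s to low-500s ohm/m operating band.
DEFAULT_BASELINE_R = {
    "long": {8: 62.0, 18: 58.0, 40: 54.0, 80: 50.0, 128: 47.0},
    "trans": {8: 55.0, 18: 51.0, 40: 47.0, 80: 44.0, 128: 42.0},
}
#: baseline reactance (ohm, negative: capacitive tissue)
DEFAULT_BASELINE_X = {
    "long": {8: -4.0, 18: -5.0, 40: -5.5, 80: -5.0, 128: -4.2},
    "trans": {8: -2.2, 18: -2.8, 40: -3.1, 80: -2.9, 128: -2.5},
}


@dataclass
class GroundTruth:
    """Generative parameters of the latent pain process and tissue model.

    The fixed effects mirror the two-level logistic model: log-odds of pain =
    ``gamma00 + gamma01*Group + gamma10*PLZ + gamma20*CV + gamma11*PLZ*Group
    + gamma21*CV*Group + u_j`` with ``u_j ~ N(0, sigma_u^2)``.
    """

    gamma00: float = -4.85
    gamma01: float = 1.5
    gamma10: float = 0.0
    gamma20: float = 0.0
    gamma11: float = 0.007
    gamma21: float = 0.0
    sigma_u: float = 1.2
    baseline_R: dict = field(default_factory=lambda: {
        c: dict(v) for c, v in DEFAULT_BASELINE_R.items()})
    baseline_X: dict = field(default_factory=lambda: {
        c: dict(v) for c, v in DEFAULT_BASELINE_X.items()})
    between_sd_log: float = 0.08   # lognormal SD of per-participant scale
    drift_sd: float = 0.8          # ohm, slow AR(1) drift innovations
    drift_phi: float = 0.99        # AR(1) per-sample correlation
    noise_sd: float = 0.4          # ohm, white measurement noise
    gen_config: str = "trans"      # configuration driving the pain process
    gen_frequency: int = 128       # frequency driving the pain process
    rating_weights: tuple = (0.45, 0.30, 0.15, 0.10)  # P(rating=1..4 | pain)
    between_call_pain_prob: float = 0.05

    def validate(self) -> None:
        if self.sigma_u < 0:
            raise ConfigError("sigma_u must be >= 0")
        for cfg, freqs in self.baseline_X.items():
            if any(v >= 0 for v in freqs.values()):
                raise ConfigError(f"baseline_X[{cfg!r}] central values must be < 0")
        if not math.isclose(sum(self.rating_weights), 1.0, abs_tol=1e-9):
            raise ConfigError("rating_weights must sum to 1")


@dataclass
class CohortConfig:
    """Study design of one synthetic cohort."""

    n_participants: int = 20
    oa_fraction: float = 0.5
    n_days: int = 7
    sample_interval: float = 2.5           # minutes
    frequencies: tuple = (8, 18, 40, 80, 128)
    calls_per_day: int = 4
    call_window: tuple = (8.0, 20.0)       # hours of day
    response_rate: float = 0.942
    artifact_rate: float = 0.02            # per (epoch, configuration, frequency)
    disconnect_event_rate: float = 0.5     # events / day / configuration
    wear_hours: float = 14.0
    start_date: str = "2023-01-02"
    true_params: GroundTruth = field(default_factory=GroundTruth)
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 0:
            raise ConfigError("n_participants must be >= 0")
        if not 0 <= self.oa_fraction <= 1:
            raise ConfigError("oa_fraction must be in [0, 1]")
        if not 0 <= self.response_rate <= 1:
            raise ConfigError("response_rate must be in [0, 1]")
        if self.sample_interval <= 0:
            raise ConfigError("sample_interval must be > 0")
        if list(self.frequencies) != sorted(self.frequencies) or min(
                self.frequencies, default=1) <= 0:
            raise ConfigError("frequencies must be sorted ascending and > 0")
        lo, hi = self.call_window
        if not (0 <= lo < hi <= 24):
            raise ConfigError("call_window must be an increasing range within a day")
        if self.calls_per_day <= 0 or (hi - lo) % self.calls_per_day > 1e-9:
            raise ConfigError(
                "calls_per_day must divide the call window into equal blocks")
        if not 0 <= self.artifact_rate < 1:
            raise ConfigError("artifact_rate must be in [0, 1)")
        if self.n_days <= 0:
            raise ConfigError("n_days must be > 0")
        self.true_params.validate()


@dataclass
class Participant:
    id: str
    group: int                 # control = 0, OA = 1
    age: float
    knee_circumference: float  # cm
    brace_size: int            # ordinal 1..7
    L_longitudinal: float      # meters
    L_transverse: float        # meters


def _rng(config: CohortConfig, pidx: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, pidx, tag])


def _pidx(participant: Participant) -> int:
    return int("".join(ch for ch in participant.id if ch.isdigit()))


def generate_cohort(config: CohortConfig) -> list[Participant]:
    """Sample a cohort with exactly round(n * oa_fraction) OA participants.

    Knee circumference is drawn from group-specific normals and drives the
    electrode spacings: transverse L is a fixed quarter of the circumference,
    longitudinal L is a fixed 0.10 m.
    """
    config.validate()
    n = config.n_participants
    n_oa = int(math.floor(n * config.oa_fraction + 0.5))
    rng = np.random.default_rng([config.seed, 0, 0])
    group_assign = np.array([1] * n_oa + [0] * (n - n_oa))
    rng.shuffle(group_assign)
    participants = []
    for i in range(n):
        g = int(group_assign[i])
        prng = _rng(config, i + 1, 0)
        circ_mu, circ_sd = (42.4, 4.7) if g else (39.9, 3.8)
        circ = round(float(np.clip(prng.normal(circ_mu, circ_sd), 33.0, 50.8)), 1)
        age_mu, age_sd = (75.6, 8.21) if g else (71.4, 8.18)
        age = float(np.clip(prng.normal(age_mu, age_sd), 57.0, 89.0))
        brace = int(np.clip(round((circ - 33.0) / (50.8 - 33.0) * 6) + 1, 1, 7))
        participants.append(
            Participant(
                id=f"P{i + 1:02d}",
                group=g,
                age=round(age, 1),
                knee_circumference=circ,
                brace_size=brace,
                L_longitudinal=0.10,
                L_transverse=round(circ * 0.25 / 100.0, 4),
            )
        )
    return participants


def participants_frame(participants: list[Participant]) -> pd.DataFrame:
    return pd.DataFrame([asdict(p) for p in participants]).rename(
        columns={"id": "participant_id"}
    )


def generate_esm_schedule(
    participant: Participant, config: CohortConfig
) -> pd.DataFrame:
    """Randomized call schedule: one call per equal block of the call window
    per day, each independently answered with ``response_rate``."""
    config.validate()
    rng = _rng(config, _pidx(participant), _TAG_SCHEDULE)
    lo, hi = config.call_window
    block_h = (hi - lo) / config.calls_per_day
    base = pd.Timestamp(config.start_date)
    rows = []
    for day in range(1, config.n_days + 1):
        date = base + pd.Timedelta(days=day - 1)
        for c in range(config.calls_per_day):
            offset_h = lo + c * block_h + rng.uniform(0.0, block_h)
            ts = date + pd.Timedelta(seconds=round(offset_h * 3600))
            answered = bool(rng.random() < config.response_rate)
            rows.append(
                {
                    "participant_id": participant.id,
                    "day": day,
                    "call_index": c + 1,
                    "timestamp": ts,
                    "answered": answered,
                }
            )
    return pd.DataFrame(rows)


def _ar1(rng, n, sd, phi):
    """Stationary AR(1) path with marginal SD ``sd``."""
    if n == 0:
        return np.empty(0)
    innov_sd = sd * math.sqrt(1 - phi**2)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t - 1]
    return x


def generate_device_log(
    participant: Participant,
    schedule: pd.DataFrame,
    config: CohortConfig,
) -> DeviceLog:
    """Raw impedance log for one participant's wear week.

    Each wear day is one contiguous powered session (battery discharging
    linearly 4.2 -> 3.5 V) of epochs every ``sample_interval`` minutes with
    all frequencies and both configurations.  Clean values are baseline x
    participant scale + slow AR(1) drift + white noise, kept inside the
    physiologic acceptance bands.  Injected artifacts — disconnect bursts
    (R >= 212 ohm, phase >= 0), phase excursions (theta < -50 deg) and
    isolated resistance spikes — are labelled in the ``injected_artifact``
    and ``artifact_kind`` columns for QC validation.
    """
    config.validate()
    truth = config.true_params
    rng = _rng(config, _pidx(participant), _TAG_DEVICE)
    freqs = list(config.frequencies)
    n_epochs = int(config.wear_hours * 60 / config.sample_interval)
    base_date = pd.Timestamp(config.start_date)

    pscale = {c: float(rng.lognormal(0.0, truth.between_sd_log))
              for c in ("long", "trans")}
    pscale_x = {c: float(rng.lognormal(0.0, truth.between_sd_log))
                for c in ("long", "trans")}

    frames = []
    selftest_rows = []
    for day in range(1, config.n_days + 1):
        date = base_date + pd.Timedelta(days=day - 1)
        start = date + pd.Timedelta(minutes=7 * 60 + 40 + round(rng.uniform(0, 20)))
        ts = start + pd.to_timedelta(
            np.arange(n_epochs) * config.sample_interval, unit="m"
        )
        battery = np.linspace(4.2, 3.5, max(n_epochs, 1))
        for cfg in ("long", "trans"):
            drift = _ar1(rng, n_epochs, truth.drift_sd, truth.drift_phi)
            drift_x = _ar1(rng, n_epochs, truth.drift_sd * 0.2, truth.drift_phi)
            ref_r = truth.baseline_R[cfg][max(freqs)]

            # artifact placement: isolated per (epoch, frequency) + bursts
            iso = rng.random((n_epochs, len(freqs))) < config.artifact_rate
            burst = np.zeros(n_epochs, dtype=bool)
            for _ in range(rng.poisson(config.disconnect_event_rate)):
                s = rng.integers(0, max(n_epochs, 1))
                length = 1 + rng.geometric(0.3)
                burst[s:s + length] = True
            iso_kind = rng.integers(0, 3, size=(n_epochs, len(freqs)))

            for fi, f in enumerate(freqs):
                base_r = truth.baseline_R[cfg][f] * pscale[cfg]
                base_x = truth.baseline_X[cfg][f] * pscale_x[cfg]
                r = base_r + drift * (truth.baseline_R[cfg][f] / ref_r) \
                    + rng.normal(0.0, truth.noise_sd, n_epochs)
                x = base_x + drift_x * (abs(truth.baseline_X[cfg][f]) /
                                        abs(truth.baseline_X[cfg][max(freqs)])) \
                    + rng.normal(0.0, truth.noise_sd * 0.3, n_epochs)
                r = np.clip(r, 0.5, 205.0)
                x = np.clip(x, -0.5 * r, -0.02)  # stay above the -50 deg band

                is_art = iso[:, fi] | burst
                kind = np.full(n_epochs, "", dtype=object)
                kind[burst] = "disconnect"
                only_iso = iso[:, fi] & ~burst
                kind[only_iso & (iso_kind[:, fi] == 0)] = "disconnect"
                kind[only_iso & (iso_kind[:, fi] == 1)] = "phase_excursion"
                kind[only_iso & (iso_kind[:, fi] == 2)] = "spike"

                for which, rows in (("disconnect", np.flatnonzero(kind == "disconnect")),
                                    ("phase_excursion",
                                     np.flatnonzero(kind == "phase_excursion")),
                                    ("spike", np.flatnonzero(kind == "spike"))):
                    if len(rows) == 0:
                        continue
                    if which == "disconnect":
                        r[rows] = rng.uniform(250.0, 1500.0, len(rows))
                        x[rows] = rng.uniform(0.0, 80.0, len(rows))
                    elif which == "phase_excursion":
                        theta = np.radians(rng.uniform(-85.0, -55.0, len(rows)))
                        m = rng.uniform(20.0, 120.0, len(rows))
                        r[rows] = m * np.cos(theta)
                        x[rows] = m * np.sin(theta)
                    else:  # spike: resistance out of band, phase still normal
                        r[rows] = rng.uniform(220.0, 400.0, len(rows))
                        x[rows] = -0.05 * r[rows]

                frames.append(pd.DataFrame({
                    "timestamp": ts,
                    "configuration": cfg,
                    "frequency_khz": float(f),
                    "resistance_ohm": r,
                    "reactance_ohm": x,
                    "battery_v": battery,
                    "injected_artifact": is_art,
                    "artifact_kind": kind,
                }))
        for f in freqs:
            selftest_rows.append({
                "session_index": day - 1,
                "frequency_khz": float(f),
                "nominal_ohm": 100.0,
                "measured_ohm": 100.0 * (1 + rng.uniform(-0.05, 0.05)),
            })

    samples = pd.concat(frames, ignore_index=True).sort_values(
        ["timestamp", "configuration", "frequency_khz"], kind="stable"
    ).reset_index(drop=True)
    samples["phase_deg"] = phase_deg(
        samples["resistance_ohm"].to_numpy(), samples["reactance_ohm"].to_numpy()
    )
    return DeviceLog(
        participant_id=participant.id,
        samples=samples,
        selftests=pd.DataFrame(selftest_rows),
        reported_wear_days=config.n_days,
    )


def generate_pain_reports(
    participant: Participant,
    schedule: pd.DataFrame,
    reduced_truth: pd.DataFrame,
    truth: GroundTruth,
    seed,
) -> pd.DataFrame:
    """Pain reports from the latent logistic process.

    ``reduced_truth`` must hold one row per answered call (columns ``plz``,
    ``cv``) aligned with the answered rows of ``schedule`` in order.  The
    participant's random intercept is drawn once; each answered call gets a
    Bernoulli pain indicator at the model probability, a momentary 0-4 rating
    (0 without pain, categorical 1-4 with pain) and a between-call pain flag.
    """
    rng = np.random.default_rng(seed)
    u = float(rng.normal(0.0, truth.sigma_u))
    g = participant.group

    out = schedule.copy()
    out["momentary_pain_0_4"] = np.nan
    out["pain_since_last_yn"] = ""
    out["true_pain_prob"] = np.nan

    answered_idx = out.index[out["answered"].astype(bool)]
    if len(answered_idx) != len(reduced_truth):
        raise ValueError(
            "reduced_truth must have one row per answered call "
            f"({len(reduced_truth)} != {len(answered_idx)})"
        )
    plz = reduced_truth["plz"].to_numpy(dtype=float)
    cv = reduced_truth["cv"].to_numpy(dtype=float)
    lp = (truth.gamma00 + truth.gamma01 * g + truth.gamma10 * plz
          + truth.gamma20 * cv + truth.gamma11 * plz * g
          + truth.gamma21 * cv * g + u)
    prob = expit(lp)
    pain = rng.random(len(prob)) < prob
    ratings = np.zeros(len(prob), dtype=int)
    n_pain = int(pain.sum())
    if n_pain:
        ratings[pain] = rng.choice(
            [1, 2, 3, 4], size=n_pain, p=list(truth.rating_weights)
        )
    between = rng.random(len(prob)) < truth.between_call_pain_prob
    since_last = np.where(pain | between, "yes", "no")

    out.loc[answered_idx, "momentary_pain_0_4"] = ratings.astype(float)
    out.loc[answered_idx, "pain_since_last_yn"] = since_last
    out.loc[answered_idx, "true_pain_prob"] = prob
    out.attrs["random_intercept"] = u
    return out


def simulate_reduced_cohort(
    n_participants: int,
    truth: GroundTruth,
    seed: int,
    *,
    calls_per_participant: int = 28,
    oa_fraction: float = 0.5,
    plz_center: float = 430.0,
    plz_between_sd: float = 30.0,
    plz_within_sd: float = 20.0,
    cv_mean: float = 3.0,
    cv_sd: float = 1.5,
) -> pd.DataFrame:
    """Reduced-metrics table simulated directly at the call-period level.

    Skips the raw device-log layer: per-participant metric baselines plus
    within-person variation feed the latent pain process.  This is the
    harness for model-level tests (oracle checks, parameter recovery, power),
    returning the standard reduced layout with the generation metric in the
    128 kHz resistance columns.
    """
    rng = np.random.default_rng(seed)
    n_oa = int(math.floor(n_participants * oa_fraction + 0.5))
    groups = np.array([1] * n_oa + [0] * (n_participants - n_oa))
    rng.shuffle(groups)
    rows = []
    for j in range(n_participants):
        g = int(groups[j])
        pid = f"S{j + 1:03d}"
        center = rng.normal(plz_center, plz_between_sd)
        u = rng.normal(0.0, truth.sigma_u)
        plz = rng.normal(center, plz_within_sd, calls_per_participant)
        cv = np.abs(rng.normal(cv_mean, cv_sd, calls_per_participant))
        lp = (truth.gamma00 + truth.gamma01 * g + truth.gamma10 * plz
              + truth.gamma20 * cv + truth.gamma11 * plz * g
              + truth.gamma21 * cv * g + u)
        pain = (rng.random(calls_per_participant) < expit(lp)).astype(int)
        x40 = -(plz * 0.07 + rng.normal(0.0, 2.0, calls_per_participant))
        x40cv = np.abs(rng.normal(cv_mean, cv_sd, calls_per_participant))
        for i in range(calls_per_participant):
            rows.append({
                "participant_id": pid,
                "group": g,
                "day": i // 4 + 1,
                "call": i % 4 + 1,
                "config": truth.gen_config,
                "plr128_mean": plz[i],
                "plr128_cv": cv[i],
                "plx40_mean": x40[i],
                "plx40_cv": x40cv[i],
                "pain": int(pain[i]),
                "true_prob": float(expit(lp[i])),
                "true_u": float(u),
            })
    return pd.DataFrame(rows)


@dataclass
class SimulatedStudy:
    """One complete synthetic study with its ground truth."""

    config: CohortConfig
    participants: list[Participant]
    reports: pd.DataFrame        # all participants' ESM reports
    logs: dict[str, DeviceLog]
    reduced_truth: pd.DataFrame  # per answered call: plz, cv used generatively
    random_intercepts: dict[str, float]


def _truth_reduction(
    log: DeviceLog, schedule: pd.DataFrame, participant: Participant,
    truth: GroundTruth,
) -> pd.DataFrame:
    """Ground-truth per-call metrics from the clean (pre-artifact) samples."""
    L = (participant.L_transverse if truth.gen_config == "trans"
         else participant.L_longitudinal)
    clean = log.samples[
        (~log.samples["injected_artifact"])
        & (log.samples["configuration"] == truth.gen_config)
        & (log.samples["frequency_khz"] == float(truth.gen_frequency))
    ]
    periods, assignment = reduction.window_samples(clean, schedule)
    baseline = truth.baseline_R[truth.gen_config][truth.gen_frequency] / L
    rows = []
    for pos in range(len(periods)):
        vals = clean.loc[assignment[assignment == pos].index, "resistance_ohm"]
        if len(vals) >= 2:
            mean, cv = reduction.reduce_values(vals.to_numpy() / L)
        elif len(vals) == 1:
            mean, cv = float(vals.iloc[0]) / L, 0.0
        else:
            mean, cv = baseline, 0.0  # no data in window: fall back to baseline
        rows.append({"plz": mean, "cv": cv})
    return pd.DataFrame(rows, columns=["plz", "cv"])


def simulate_study(config: CohortConfig) -> SimulatedStudy:
    """Generate a full study: cohort, schedules, device logs, pain reports."""
    config.validate()
    participants = generate_cohort(config)
    logs: dict[str, DeviceLog] = {}
    all_reports = []
    all_truth = []
    intercepts: dict[str, float] = {}
    for p in participants:
        schedule = generate_esm_schedule(p, config)
        log = generate_device_log(p, schedule, config)
        logs[p.id] = log
        truth_metrics = _truth_reduction(log, schedule, p, config.true_params)
        reports = generate_pain_reports(
            p, schedule, truth_metrics, config.true_params,
            seed=[config.seed, _pidx(p), _TAG_PAIN],
        )
        intercepts[p.id] = reports.attrs["random_intercept"]
        all_reports.append(reports)
        tm = truth_metrics.copy()
        tm.insert(0, "participant_id", p.id)
        all_truth.append(tm)
    reports = (pd.concat(all_reports, ignore_index=True)
               if all_reports else pd.DataFrame())
    truth = (pd.concat(all_truth, ignore_index=True)
             if all_truth else pd.DataFrame())
    return SimulatedStudy(config, participants, reports, logs, truth, intercepts)


def write_study(study: SimulatedStudy, outdir) -> None:
    """Write a study to disk in the pipeline's text formats.

    Emits the device-log and self-test CSVs per participant, the ESM report
    CSV, the participants CSV, and a ground-truth JSON sidecar containing the
    generative parameters, random intercepts, and artifact labels.
    """
    from pathlib import Path

    from .ingest import write_device_log, write_selftest

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    participants_frame(study.participants).to_csv(
        out / "participants.csv", index=False, lineterminator="\n"
    )
    rep = study.reports.copy()
    if len(rep):
        rep["timestamp"] = pd.to_datetime(rep["timestamp"]).dt.strftime(
            "%Y-%m-%dT%H:%M:%S")
        rep[reduction.ESM_COLUMNS].to_csv(
            out / "esm_reports.csv", index=False, lineterminator="\n")

    artifact_labels = {}
    for pid, log in study.logs.items():
        write_device_log(log, out / f"device_log_{pid}.csv")
        write_selftest(log.selftests, out / f"selftest_{pid}.csv")
        art = log.samples[log.samples["injected_artifact"]]
        artifact_labels[pid] = [
            [row.timestamp.isoformat(), row.configuration,
             float(row.frequency_khz), row.artifact_kind]
            for row in art.itertuples()
        ]

    truth = study.config.true_params
    sidecar = {
        "config": {
            f.name: getattr(study.config, f.name)
            for f in fields(CohortConfig) if f.name != "true_params"
        },
        "true_params": asdict(truth),
        "random_intercepts": study.random_intercepts,
        "artifact_labels": artifact_labels,
    }
    sidecar["config"]["frequencies"] = list(study.config.frequencies)
    with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1, default=str)


def with_params(config: CohortConfig, **kwargs) -> CohortConfig:
    """Convenience: a copy of ``config`` with fields replaced."""
    return replace(config, **kwargs)
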