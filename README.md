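# kneebis

Analysis pipeline for free-living knee bioimpedance and momentary pain:

1. **`kneebis.synthetic`** — generates complete synthetic studies
   (participants, randomized ESM call schedules, raw multi-frequency
   impedance logs with injected artifacts, latent-logistic pain reports) with
   known ground truth, so every downstream stage is testable offline.
2. **`kneebis.ingest`** — parses device-log CSVs, segments battery-discharge
   wear sessions, verifies on-board self-tests.
3. **`kneebis.qc`** — the binary decision-tree artifact classifier: wear-day
   alignment, self-test (±10%), phase band (−50° < Θ < 0°), resistance band
   (0 Ω < R < 212 Ω), >25% clean per call period, ≥3-of-4 periods per day.
4. **`kneebis.reduction`** — assigns cleaned samples to ESM call periods,
   applies the per-length transform (PLR = R/L, PLX = X/L), reduces each
   period to mean and CV, and runs the Spearman redundancy screen.
5. **`kneebis.glmm`** — from-scratch random-intercept logistic regression by
   maximum likelihood with adaptive Gauss–Hermite quadrature: null model with
   latent-threshold ICC (σ²/(σ² + π²/3)), main-effect model, interaction
   model, and the OA-subset model, with Wald inference and odds ratios.
6. **`kneebis.probability`** — conditional pain-probability curves
   (logistic(β₀ + β₁·PLZ)), per-call-period probability timelines, and
   pain/no-pain group contrasts.

## CLI

```sh
kneebis simulate --config cfg.json --seed 1 --out study/   # synthetic study
kneebis ingest --log study/device_log_P01.csv --selftest study/selftest_P01.csv --participant P01
kneebis clean --in study/ --out cleaned/                   # QC + reduction
kneebis correlate --data cleaned/reduced_metrics.csv --config trans
kneebis fit --data cleaned/reduced_metrics.csv --model 2 --metric r128 --config trans
kneebis predict --beta0 -4.850 --beta1 0.007 --metric r128 \
    --in cleaned/reduced_metrics.csv --participant P01
kneebis curve --beta0 -4.850 --beta1 0.007 --lo 300 --hi 550
```

## File formats

* Device log CSV: `timestamp,configuration,frequency_khz,resistance_ohm,reactance_ohm,battery_v`
  (ISO-8601 timestamps, configuration ∈ {long, trans}, UTF-8, LF).
* Self-test CSV: `session_index,frequency_khz,nominal_ohm,measured_ohm`.
* ESM reports CSV: `participant_id,day,call_index,timestamp,answered,momentary_pain_0_4,pain_since_last_yn`.
* Reduced metrics CSV: `participant_id,group,day,call,config,plr128_mean,plr128_cv,plx40_mean,plx40_cv,pain`.
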