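# gaitgrip

Estimation of hand grip strength (HGS) from in-shoe motion-sensor gait
waveforms, with downstream agreement statistics and an analog frailty risk
score — exercised entirely on synthetic cohorts with planted ground truth.

The pipeline:

1. **`gaitgrip.synthetic`** — seeded synthetic cohorts: per-subject raw
   9-channel foot-motion trials (3 accelerations, 3 angular velocities,
   3 sole-to-ground Euler angles at 100 Hz) with known heel-strike/toe-off
   events and a tunable linear dependence of waveform amplitude on HGS
   inside chosen gait-cycle windows.
2. **`gaitgrip.strides`** — stride segmentation, temporal normalization onto
   a 100-column %GC grid (stance 1–60, swing 61–100), neutral-posture
   (21–25%GC) bias removal, velocity normalization, the 20 spatiotemporal
   gait parameters (GP01–GP20), and within-trial/both-feet averaging.
3. **`gaitgrip.spm`** — 1D statistical parametric mapping: a node-wise
   canonical-correlation curve with a random-field-theory threshold gates
   Šidák-corrected per-channel Pearson SPM{t} curves; supra-threshold runs
   become gait phase clusters, filtered to the quadriceps-activation
   windows Q_t = {1–16, 48–70, 92–100}%GC; integral averages over clusters
   are scalar waveform predictors.
4. **`gaitgrip.selection`** — LOSO-LASSO: a 100-point geometric
   regularization path per left-out subject, per-fold support label
   matrices summed and thresholded at floor(0.95·U), candidate models
   scored by leave-one-subject-out cross-validated ICC(2,1), plus the
   nested comparison pools M1 (gait speed), M2 (+GPs), M3 (+IPAs), Mo
   (+waveform predictors).
5. **`gaitgrip.agreement`** — ICC(2,1)/ICC(2,k) from the two-way
   random-effects ANOVA, interpretation bands, Bland–Altman limits of
   agreement with outer confidence limits, and confidence bounds
   (K_AL, K_AU) on the measurement success rate.
6. **`gaitgrip.frailty`** — four-item frailty questionnaire scoring and the
   cumulative-normal performance scores P_HGS, P_GS and their equal-weight
   mean P_fr, using sex-specific population norms.
7. **`gaitgrip.pipeline` / `gaitgrip.cli`** — orchestration of the study
   replica: model construction, Test 1 (agreement on a fresh cohort) and
   Test 2 (frailty scores against a synthetic expert-rater panel).

## CLI

```sh
gaitgrip all --config config.yaml --out results/run   # full study replica
gaitgrip simulate  --config config.yaml --out cohort_dir
gaitgrip process   --cohort cohort_dir --out trial_averages.csv
gaitgrip discover  --table trial_averages.csv --out gpcs.json
gaitgrip select    --table trial_averages.csv --gpcs gpcs.json --pool Mo --out model.json
gaitgrip construct --config config.yaml --out run_dir
gaitgrip test1     --config config.yaml --run run_dir
gaitgrip test2     --config config.yaml --run run_dir
gaitgrip score --hgs 28 --gs 1.0 --sex male
```

Minimal `config.yaml`:

```yaml
seed: 1
cohort:
  n_subjects: 27
  sex: male
test_cohort:
  n_subjects: 12
```

All randomness derives from the single `seed`; reruns are bit-identical.

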