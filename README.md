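# lapskill

Automatic rating of surgical skill at a laparoscopic intracorporeal
suturing task, from instrument motion alone.

Trainees practising minimally invasive surgery need frequent, detailed
feedback, but expert OSATS rating (five domains, each scored 1–5 from a
trial video) is slow and subjective. `lapskill` implements the full
sensor-to-score pipeline for an instrumented box trainer: two tracked
laparoscopic tools and an endoscope report 6-DOF poses at ~20 Hz, and
flex sensors on the handles report grip voltages. The pipeline turns one
recorded trial into a predicted OSATS score:

1. **Calibration** — pivot (sphere-fit) calibration of each tool-tip
   offset, piecewise-linear grip voltage→angle maps, and a least-squares
   cone fit of the endoscope's field of view;
2. **Kinematics** — zero-phase 4th-order Butterworth low-pass at 6 Hz,
   resampling to exactly 20 Hz, tool-tip transformation, Euler-angle
   unwrapping, derivatives, and per-sample visibility flags;
3. **Features** — 280 motion-analysis features (MAFs): 5 time, 8
   visibility, 20 grip, 247 tip-motion (path lengths Σ|Δx|, average and
   instantaneous velocity/acceleration statistics, needle/maryland
   ratios, peak rates above fixed thresholds);
4. **Modelling** — features standardised, selected by an elastic net
   (`min_β ‖y − Xβ‖² + λ(α‖β‖₁ + (1−α)‖β‖²/2)`, α and λ by inner 5-fold
   CV) against the summed score, then one pruned regression tree per
   OSATS domain; the summed prediction is the sum of the five trees,
   clipped to [5, 25];
5. **Evaluation** — leave-one-subject-out cross-validation with six
   metrics (summed-score accuracy within ±2/±4 and Pearson r;
   rounded-average accuracy exact/±1 and Pearson r), a 5×5 confusion
   matrix, and random/median control models.

Because no recordings of the motivating study are publicly available,
the package includes a first-class synthetic cohort generator
(`lapskill.synthetic`): minimum-jerk sub-movement trajectories in a
14×19×7 cm workspace, tremor and sensor quantisation noise, jittered
sampling, skill-dependent durations, grip event trains, out-of-view
episodes, and a noisy simulated rater — so every stage is testable end
to end. See `docs/methods.md` for the models and all numeric defaults.

## Worked example

Simulate a small cohort, extract features, and evaluate with
leave-one-subject-out CV:

```sh
$ lapskill simulate --subjects 8 --trials 2 --seed 3 -o cohort
wrote 16 trials to cohort
$ lapskill validate cohort/S00_t1.csv
ok
$ lapskill features cohort/S*.csv --calib cohort/calibration.json -o features.csv
wrote features.csv (16 trials)
$ lapskill evaluate --features features.csv --ratings cohort/ratings.csv \
      --subset TMVG --seed 3 -o report.json
subset TMVG: within2 0.50  within4 0.62  r 0.68  exact 0.50  within1 1.00  r_rounded 0.77
```

The last line reports the six metrics on held-out subjects: half of the
16 trials were scored within ±2 summed points of the simulated rater,
the predicted and true summed scores correlate at r = 0.68, and every
rounded-average prediction fell within one point of the label. (A cohort
this small is noisy; the full 32-subject default cohort reaches r ≈ 0.8
for the all-sensor TMVG model.) `report.json` holds the pooled
predictions, metrics, confusion matrix, and the number of selected
features per sensor category.

The same steps are available as library calls (`simulate_cohort`,
`compute_kinematics`, `extract_mafs`, `OSATSRegressor`,
`loso_evaluate`); `OSATSRegressor` follows the scikit-learn estimator
protocol and composes with sklearn model selection.

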