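# confclust

Electrophysiological markers of confidence and error monitoring under
performance matching: a tested, reusable analysis pipeline covering

- **synth** — synthetic two-group cohorts (1-up-2-down staircase-matched
  accuracy, confidence read-out coupled to movement onset, mouse
  trajectories, 64-channel EEG epochs with calibrated ERP components plus
  1/f + white noise);
- **kinematics** — movement onsets (20%-of-peak-velocity crossing minus a
  five-frame ≈83 ms offset), change-of-mind detection (midline crossing
  after 20% of travel), and trial exclusions (early < 100 ms, late > 6 s,
  pre-/post-response changes of mind);
- **eegproc** — deterministic EEG preprocessing: 128 Hz resampling,
  zero-phase 0.5–45 Hz FIR filtering, epoching (−1 to 2 s around movement
  onset), common-average reference, EOG derivations, participant-level
  baseline (−700 to −200 ms), percentile trimming, variance-based
  participant exclusion; minimal plain-EDF I/O included;
- **massuni** — single-trial mass-univariate mixed-model scans per
  (electrode, sample) with joint Benjamini–Hochberg FDR, ROI-restricted
  cluster regressions with nested `(1|participant/electrode)` random
  intercepts, the strict > 50 ms contiguity rule, and 50 ms peak-window
  effect amplitudes (correctness and confidence-tertile contrasts);
- **bayes** — cluster-level Bayesian mixed models (Gibbs sampler with the
  protocol's Gaussian fixed-effect priors), directional evidence ratios,
  Savage–Dickey BF01, and default JZS two-sample Bayes factors;
- **metacog** — d′ / meta-d′ / M-ratio (per-participant MLE with a
  response-collapsed type-2 likelihood, plus a hierarchical Bayesian group
  model with a group-difference Bayes factor), the confidence ~ movement
  onset × correctness × group regression, the BCIS composite, and Welch
  t-tests with JZS BFs for group descriptives.

Everything runs without any external dataset: the synthetic module emulates
the study design (19 + 14 participants, ~300 trials each, ~71–74% accuracy,
correctness component peaking ≈266 ms, confidence component ≈102 ms, onset
component ≈133 ms).

## CLI

The console script is `confclust`:

```sh
confclust simulate --seed 1 --out results/run1 --trajectories
confclust kinematics --trajectories results/run1/trajectories.csv --out kin.csv
confclust preprocess --edf recording.edf --onsets onsets.csv --out epochs.h5
confclust scan     --epochs epochs.h5 --term correctness --alpha 0.05
confclust cluster  --epochs epochs.h5 --term correctness --electrodes Cz,C1,C2
confclust bayes    --epochs epochs.h5 --model 4 --electrodes Cz,C1,C2 \
                   --t-start 0.01 --t-end 0.33 --seed 1
confclust metacog  --trials results/run1/trials.csv --bins 4 --hierarchical
confclust all      --seed 1 --out results/full   # full synthetic pipeline
confclust report   --results results/full
```

`confclust all` writes a result bundle (trials, behavioral summary with
t/p/BF columns, scan grids, cluster tables with effect amplitudes, Bayesian
posterior summaries with evidence ratios and BF01, M-ratio posteriors, and a
machine-readable exclusion/retention report), every table stamped with the
config hash. A YAML `RunConfig` (see `confclust.config`) makes any run
reproducible from its config + master seed; the seed fans out to per-module
streams.

## Notes on scope

ICA + automated component classification and spherical-spline interpolation
are out of scope; artifact handling uses a documented amplitude/EOG
surrogate with hooks for plugging in an external implementation. Cluster
inference is FDR/contiguity-based (no permutation cluster-mass tests).
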