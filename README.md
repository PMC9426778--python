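# whiskeye

Analysis pipeline for coordinated whisker and eye movement in head-fixed
mice navigating a plus maze, exercised end-to-end on a synthetic session
generator with full ground truth.

The pipeline takes per-session tracked keypoints (whisker positions at
200 Hz, eight pupil-edge points per eye at 100 Hz, eyelid outlines) and
frame-indexed behavioral-state annotations, and produces:

- **geometry** — hue-masked luma-weighted centroids, circle fits turning
  whisker positions into polar angles, ellipse fits for the pupil, eyelid
  parabola fits whose intersections define the eye corners and the
  eye-width segment used to normalize pupil position;
- **kinematics** — session-median-centered, per-trial range-normalized
  whisker angles; signed whisker asymmetry; head-centered conjugate pupil
  deviation; behavioral-epoch time normalization onto [0, 1];
- **saccade_detection** — conjugate saccades from the two eyes' speed
  traces (threshold 0.1 % of eye width per frame, both eyes, same sign;
  trains of crossings closer than 250 ms discarded as artifacts), plus
  10-bin per-epoch saccade histograms split by direction;
- **turn_prediction** — per-time-bin ROC/AUC for whisker asymmetry and
  eye position with within-session label-shuffled nulls, and a
  two-variable linear-separation fidelity with shuffle-based unique
  contributions of each predictor;
- **saccade_whisker_coupling** — saccade-triggered whisker-asymmetry
  correlograms with a within-epoch shuffled-timing null and per-100-ms-bin
  Mann-Whitney statistics;
- **stats_nonparametric** — self-implemented Mann-Whitney U (exact
  enumeration for small samples), Kruskal-Wallis, Dunn's post hoc test,
  and Bonferroni correction;
- **synthetic_data** — a deterministic generator producing sessions with
  known turn-dependent whisker asymmetry, conjugate stepwise pupil
  deviation, late-backward-biased saccade timing, and a configurable
  asymmetry-before-saccade lead, together with raw keypoint tables and a
  ground-truth sidecar for recovery tests;
- **io_formats / cli_pipeline** — pose-tracker-style keypoint CSVs,
  JSON annotations (0-based, end-exclusive frames), YAML run configs,
  JSON results, and a `whiskeye` command-line interface.

## Test

```sh
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py`, which checks the analytic
fidelity anchors, exact AUC/U-statistic equivalence, zero-noise geometry
recovery, saccade-detector calibration, effect- and lead-recovery on
generator data, and type-I calibration of the shuffle-based tests.  The
calibration tests iterate over ~100 seeded generator runs and take a few
minutes on one CPU.

## CLI

```sh
# generate a synthetic session bundle (traces, annotations, ground truth)
whiskeye simulate --seed 1 --n-trials 20 --out scratch/session

# full pipeline: simulate -> saccades -> predict -> couple
whiskeye run --seed 1 --n-sessions 4 --out scratch/results
whiskeye report --results-dir scratch/results

# detect saccades in a stored session bundle
whiskeye saccades --session-dir scratch/session --out scratch/events.json
```

`whiskeye run` also accepts `--config run.yaml`; every tunable (speed
threshold, refractory interval, bin counts, shuffle counts, lag window,
generator parameters) lives in the config, with the published analysis
constants as defaults.

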