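# gaitassist

Tools for analysing manual balance assistance given by physical therapists
during overground gait training. The package detects the *timing* of
assistance events from a single sacrum-mounted 3-axis accelerometer,
characterizes the corrective *forces* recorded by two pelvis-mounted force
sensors, scores detections against ground-truth annotations (PPV/TPR with a
temporal matching tolerance), tunes the detector's two parameters by grid
search, and ships a seeded simulator of therapist–patient sessions so the
whole pipeline is testable without clinical recordings.

## Method overview

* **Detection** (`gaitassist.assist_detector`): the per-sample Euclidean norm
  of the three accelerometer axes (orientation independent) has its record
  mean removed (free acceleration), stationary head/tail periods are trimmed,
  the signal is smoothed with a centered moving average of width `δ` seconds,
  and every smoothed sample strictly above the upper Tukey fence
  `Q3 + α·IQR` (quartiles of the trimmed pre-smoothing signal) is marked.
  Contiguous marked runs become detected intervals.
* **Force characterization** (`gaitassist.force_metrics`): per channel 2nd
  order Butterworth low-pass at 5 Hz (zero phase), static-window baseline
  removal, left-minus-right net force per body axis, then per annotated event:
  peak |force| per axis (N and % body weight), duration, and the rectified
  medio-lateral impulse (trapezoidal integral, N·s).
* **Evaluation** (`gaitassist.evaluation`): greedy one-to-one matching of
  detections to annotations within ±0.5 s (overlap = distance 0), pooled
  TP/FN/FP, `PPV = TP/(TP+FP)·100`, `TPR = TP/(TP+FN)·100`, an (α, δ) grid
  search maximizing `min(PPV, TPR)` (ties: `PPV+TPR`, smaller δ, smaller α)
  reporting the full optimal plateau, and a dev/validation split workflow.
* **Simulation** (`gaitassist.synthetic_gait`): sinusoidal gait harmonics +
  noise + gravity, sparse sustained-acceleration assistance episodes, and
  matching two-hand raised-cosine force pulses (left hand dominant), all
  driven by one seed.

## Command line

The console script `gaitassist` (equivalently `python -m gaitassist.cli_app`)
exposes five subcommands:

```bash
# write session.csv (+ session_force.csv), annotations.csv, meta.json
gaitassist simulate --seed 42 --out-dir session01/

# detect assistance intervals from the accelerometer channels
gaitassist detect --input session01/session.csv --alpha 1.0 --delta 2.5 \
    --out detections.json

# score detections against the ground truth (±0.5 s tolerance)
gaitassist evaluate --detections detections.json \
    --annotations session01/annotations.csv --tol 0.5

# grid-search (α, δ) over a cohort listed in a YAML manifest
gaitassist tune --sessions manifest.yaml --alpha-step 0.1 --delta-step 0.01 \
    --out-prefix results/tune

# per-event corrective-force characteristics
gaitassist forcechars --input session01/session.csv \
    --annotations session01/annotations.csv --out forces.csv
```

The tune manifest is a YAML list of `{signals: <csv>, annotations: <csv>}`
entries with paths relative to the manifest file.

### File formats

Signal files are CSV (`t,ax,ay,az[,flx,fly,flz,frx,fry,frz]`, SI units) with
session metadata in leading `# key: value` comment lines; when the force
stream runs at a different rate it lives in a companion `<stem>_force.csv`.
Annotation files are CSV or JSON with `start_s, stop_s, location,
sensors_hit`.

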