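# nirsbci

A real-time fNIRS motor brain-computer-interface pipeline with a fully
synthetic data path, so every stage is testable without recorded data:

- **Montage** — two 4x4 checkerboard optode grids (emitters/detectors
  alternating, 25 mm separation) over left and right sensorimotor cortex;
  adjacent emitter-detector pairing forms 48 measurement channels, 24 per
  hemisphere.
- **Protocol** — block-design runs (six task blocks separated by seven rest
  blocks, balanced left/right hand labels) and the three experiment
  paradigms: ME-trained subject-dependent, MI-trained subject-dependent,
  and subject-independent classification (ME = motor execution,
  MI = motor imagery).
- **Synthetic generator** — 48-channel HbO/HbR series at 7.69 Hz with
  contralateral task-locked hemodynamic responses (double-gamma impulse
  response, phasic-plus-sustained neural drive), weaker and more anterior
  activation for imagery, physiological oscillations, white noise and slow
  drift. Fully deterministic given a seed.
- **Preprocessing** — baseline correction, HRF-kernel pre-coloring
  (unit-DC-gain low-pass) and wavelet-MDL detrending (periodized db4
  transform with a minimum-description-length trend model choice).
- **Features & selection** — per-second channel features (sum of HbO
  samples per one-second window) ranked by Parzen-window mutual information
  against the binary class label; the best 12 channels are kept, 6 per
  hemisphere.
- **Classifier** — soft-margin linear SVM; between-run adaptation (run r is
  classified by a model trained on runs r-1 and r-2); within-run rest-bias
  correction (the mean rest-block decision value is subtracted from the
  following task block).
- **Real-time loop** — per-second streaming classification, 20-level
  thermometer feedback (one level per correct/incorrect classification,
  reset at block ends), per-run accuracy, ROC with the zero-threshold
  operating point, 5-fold cross-validation, and channel-wise t-statistic
  activation maps.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (protocol
constants, hemodynamic latency, oracle equivalences, statistical
calibration, signal-regime recovery, pipeline invariants).

## CLI

```sh
# generate synthetic run files for experiment 1 (one subject)
nirsbci simulate --experiment 1 --seed 7 --out scratch/sim

# fit selector + SVM on a training run
nirsbci train scratch/sim/sub01_run1.csv --out scratch/model.json

# replay a run through the per-second online loop
nirsbci stream scratch/sim/sub01_run2.csv --model scratch/model.json --out scratch/session

# end-to-end experiment (3 = subject-independent pooling)
nirsbci experiment --experiment 3 --seed 7 --subjects 4 --out scratch/exp3

# 5-fold cross-validation of a training set
nirsbci crossval scratch/sim/sub01_run1.csv --seed 0

# decision-trace / MI-map / ROC figures
nirsbci report scratch/sim/sub01_run2.csv --model scratch/model.json --out scratch/report
```

All commands accept `--config <yaml|json>`; unknown keys are rejected and
defaults mirror the deployed system's constants (N = 12 selected channels,
7.69 Hz, 6 task + 7 rest blocks, 20 thermometer levels, 25 mm separation).

## Data format

Runs are stored as plain CSV (`time_s, block, label, ch01_hbo..ch48_hbo,
ch01_hbr..ch48_hbr`) with a JSON sidecar carrying the sampling rate,
layout geometry and hash, block schedule, task type, generator parameters
and seed; round-trips are lossless. A SNIRF export hook is a documented
extension point but out of scope here.
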