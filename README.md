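# cytoquant

Single-cell quantification of cytosolic siRNA release events and intracellular
knockdown dose-response from two-plane confocal time-lapse data.

The package turns multichannel time-lapse stacks (or precomputed per-cell
trace tables) into absolute cytosolic siRNA concentrations and molecule
counts, detects sudden release events, estimates per-event magnitudes with
confidence measures, and derives intracellular dose-response relationships
(per-timepoint 4PL IC50s and a kinetic knockdown model with bootstrap CIs).
A first-class synthetic-data module provides image sequences, trace
ensembles, and knockdown datasets with full ground truth, so the entire
pipeline is testable offline.

## Modules

| module        | role |
|---------------|------|
| `synthkit`    | synthetic traces, two-plane rendered scenes, knockdown datasets, all with ground truth |
| `imgproc`     | segmentation (Otsu + watershed), nucleus tracking, lipoplex masking across z-planes, median-intensity measurement, geometric utilities |
| `calibration` | FWHM-projected 1 µM reference image, vignetting-aware intensity→nM conversion, N = C·V·N_A molecule counts, standard curves |
| `events`      | 5-frame median filtering and persistent-shift release-event detection; sensitivity/specificity scoring against ground truth |
| `releasefit`  | exp / step / double release models, AICc model selection, R², statistical + systematic uncertainty budget |
| `knockdown`   | bleach/mitosis/apoptosis-corrected eGFP traces, magnitude quintiles, 4PL IC50 time courses, ODE knockdown kinetics with bootstrap IC50 CIs |
| `workbench`   | pipeline orchestration, YAML config, run manifests |

## CLI

```bash
# synthetic data (traces | images | knockdown), fully seeded
cytoquant simulate traces --seed 1 --out sim/

# image stacks -> per-cell trace CSV
cytoquant measure --stack sim/ --out traces.csv

# 1 µM reference + blank z-stacks -> calibration model
cytoquant calibrate --ref ref.tif --blank blank.tif --out calib/

# event detection (optional manual-QC flag CSV round-trip)
cytoquant detect --traces traces.csv --out events.csv [--qc qc_flags.csv]

# release-magnitude model fits
cytoquant fit-release --traces traces.csv --events events.csv --out releases.csv

# knockdown correction + dose grouping
cytoquant knockdown --releases releases.csv --traces traces.csv \
    --events events.csv --out results/

# full pipeline from a YAML config
cytoquant run --config pipeline.yaml
```

A minimal pipeline config:

```yaml
seed: 5
out_dir: results
input:
  simulate: {n_cells: 50, n_frames: 120, events_per_cell: 1}
detection: {fixed_offset: 0.15}
release_fit: {fit_window: 15}
```

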