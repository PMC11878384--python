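# efcpipe

Condition-specific **effective functional connectivity (EFC)** analysis for
block-design BOLD fMRI, built around psychophysiological-interaction (PPI)
regression, plus the supporting machinery to test it end to end without any
data download:

- **acoustics** — pulsed focused-ultrasound dose arithmetic: duty cycle,
  time-averaged power, cranial thermal index (TIC) and a configurable
  duration-limit advisory.
- **synth** — a seeded synthetic BOLD generator that plants the structure the
  analysis assumes: HRF-convolved block responses, two ROI subnetworks
  sharing latent signals, stimulus-gated coupling from a seed region that is
  suppressed under the combined heat+FUS condition, AR(1) noise, drift and
  motion-like nuisance regressors.
- **preprocess** — initial-volume discard, linear detrend/demean, PCA
  nuisance selection (cumulative-variance criterion), confound regression and
  zero-phase Chebyshev-II low-pass filtering.
- **hrf_glm** — canonical double-gamma HRF, design matrices, OLS GLM with t
  inference, Benjamini–Hochberg FDR, cluster-extent activation detection,
  percent-signal-change cycle averaging and a bounded two-gamma fit of
  cycle-averaged responses.
- **ppi** — seed extraction, PPI regressor construction with per-condition
  cycle masking, EFC regression, two-stage group inference and the
  Mann–Whitney–Wilcoxon test (exact for small samples).
- **clustering** — per-ROI feature vectors (two-gamma parameters, EFC beta,
  PSC samples), WPGMA hierarchical clustering under a correlation metric with
  deterministic tie-breaking, cophenetic distances/correlation, dendrogram
  cutting into subnetworks, thresholded inter-ROI correlation matrices and
  Newick export.
- **netcompare** — Dice similarity over suprathreshold edge sets with a
  correlation-difference overlap criterion, percentage correlation-power
  change, per-subnetwork statistics and weighted edge lists.
- **pipeline / cli** — configuration, text-based I/O (TSV/JSON/NIfTI) and an
  end-to-end runner producing a deterministic JSON report.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (oracle
equivalences, statistical calibration, parameter recovery, formula cases,
determinism); the remaining files are per-module unit and property tests.
Independent oracles (brute-force WPGMA, exhaustive Mann–Whitney enumeration)
live in `tests/_oracles.py`.

## Command line

```sh
# dose arithmetic
efcpipe acoustics --pulse-ms 0.5 --prf-hz 1000 --train-ms 500 --slow-hz 0.5 \
    --power-w 11.1 --efficiency 0.6 --aperture-cm 3.7

# generate a synthetic run (BOLD/events/nuisance TSV + truth JSON)
efcpipe simulate --seed 1 --out data/

# full pipeline on simulated runs (or --data <dir> for on-disk runs)
efcpipe run-all --seed 1 --n-runs 4 --out out/
```

`run-all` writes `report.json` plus per-stage artifacts (EFC beta tables,
correlation matrices, dendrograms as Newick, partitions) and is byte-
deterministic for a fixed seed. Other subcommands (`preprocess`, `glm`,
`ppi`, `cluster`, `compare`) expose the individual stages; `--config
config.yaml` overrides any stage parameter.

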