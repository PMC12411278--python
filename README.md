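# voltfield

Analysis pipeline for trial-structured voltage-imaging recordings of
hippocampal interneurons during an odor-cued delayed non-match-to-sample
(DNMS) task, plus companion extracellular procedures — driven end-to-end by
a synthetic-data generator with exact ground truth.

Each trial holds an 11-s, 1-kHz ΔF/F trace (recording starts 1 s before the
first odor), detected spike times and a locomotion signal; two 1-s odor cues
are separated by a 5-s delay.  The package implements:

- **io_model** — validated `TrialRecord` / `CellSession` data model with a
  deterministic HDF5 layout (byte-identical re-saves) and recording
  concatenation.
- **synthgen** — ground-truth generator: inhomogeneous-Poisson spiking
  (baseline × field bump × von-Mises theta modulation × onset/rebound
  envelopes, 2-ms refractory), pink-noise + theta subthreshold traces with
  spike waveforms, odor-onset hyperpolarization dips with optional theta
  phase reset, photobleaching drift, locomotion bouts, multiday ensembles
  with configurable field retention, and extracellular sessions (two unit
  classes, LFP with injected ripples).
- **preprocess** — motion segmentation (hysteresis 0.02/0.01, 20-ms merge,
  10-ms minimum), rate binning (100-ms / 5-ms), burst index, speed/odor
  scores with circular-shift chance bands, de-spiking (boundary-matched
  interpolation + AR(2)-matched noise over 25-ms windows), Kaiser-window
  periodograms and flattened spectrograms, theta phase/amplitude (zero-phase
  3rd-order Butterworth 4–10 Hz + Hilbert), spike-phase statistics.
- **hyperpol** — odor-onset hyperpolarization detection (baseline-z-scored
  trace `S`; first merged `S < −1` segment; significant iff > 50 ms with
  > 10 ms below −3) and across-trial theta phase-reset variance.
- **fields** — temporal firing-field detection over the odor-delay interval
  with a per-trial circular-shift null (1000 shuffles, 95th percentile),
  field-bin merging for two-odor cells, selectivity index
  SI = (R_A − R_B)/(R_A + R_B) with the |SI| ≥ 0.42 specificity rule and
  random-split chance distributions, and per-segment rate changes.
- **decode** — Bayesian decoding of odor-specific time on a concatenated
  two-odor template (Poisson emission, per-bin odor prior, Gaussian
  continuity constraint with σ = 3 s), with 500-surrogate circular-shift
  chance baselines for time error and odor accuracy.
- **multiday** — odor-field turnover (stable / inflow / outflow) and
  cross-day trial-pair rate correlations.
- **finescale** — 5-ms onset (30–50 ms) and rebound (200–500 ms) spiking
  metrics against the 500-ms pre-odor baseline.
- **ephys** — LFP conditioning (2.5-kHz downsample, 60/120/180-Hz
  bandstops), ripple detection (120–200 Hz binned RMS, 10/2-s.d.
  thresholds), PCA + k-means unit classification, odor-response
  quantification.
- **report** — cohort summary tables assembled from the stage CSVs.

## CLI

All stages share `--config <yaml> --seed <int> --out <dir> --log-level`.

```bash
voltfield simulate  --config cfg.yaml --seed 1 --out sessions/
voltfield preprocess --sessions sessions/ --seed 1 --out results/
voltfield hyperpol   --sessions sessions/ --seed 1 --out results/
voltfield fields     --sessions sessions/ --seed 1 --out results/
voltfield decode     --sessions sessions/ --seed 1 --out results/
voltfield multiday   --sessions sessions/ --seed 1 --out results/
voltfield finescale  --sessions sessions/ --seed 1 --out results/
voltfield ephys      --seed 1 --out results/
voltfield report     --results results/ --seed 1 --out results/
```

`simulate` config keys mirror `voltfield.synthgen.SynthConfig` fields plus
`n_cells`; e.g.

```yaml
n_cells: 4
n_trials: 20
baseline_rate_hz: 10
field: odorA
field_gain: 3.0
hyperpol_prob: 0.8
n_sessions: 3          # multiday ensemble per cell
retention_prob: 0.6
```

Outputs are CSV/JSON tables; a rerun with the same seed reproduces every
output byte-for-byte.

## Acceptance

The quantitative acceptance criteria (detector calibration/power,
hyperpolarization and ripple recovery, decoder oracle equivalence and
chance calibration, turnover and unit-classification recovery, full-pipeline
determinism) are property-based and live in `tests/test_acceptance.py`:

```bash
pytest tests/test_acceptance.py
```

`scripts/acceptance.py --seed <int> --out <path>` writes the machine-readable
acceptance report (an empty JSON object here: there are no numeric targets
tied to printed cohort statistics, since the source recordings cannot be
regenerated at desk scale).
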