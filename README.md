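# labpbpk

Whole-body physiologically based pharmacokinetic (PBPK) model of labetalol,
with disease-population extrapolation (liver cirrhosis CP-A/B/C, chronic
kidney disease), non-compartmental analysis (NCA), and model-qualification
statistics (observed/predicted fold ratios, average fold error, two-fold
criterion, percentile bands, box-whisker severity summaries).

## What it does

- **physiology** — embedded ICRP-style 70 kg reference adult (organ volumes
  and regional blood flows, `data/reference_physiology.csv`), linear
  body-weight scaling, and seeded virtual-population sampling from cohort
  descriptors (age/weight ranges, female fraction).
- **drug_model** — labetalol parameters (`data/labetalol.yaml`),
  tissue-composition partition coefficients with a global scale calibrated
  to a steady-state distribution-volume target (default 11 L/kg), and
  allocation of total body clearance (15 mL/min/kg) into renal (fu × GFR)
  and well-stirred hepatic pathways.
- **pbpk_engine** — perfusion-limited whole-body ODE system with lung in
  series, portal first pass, a gastric-emptying + 7-segment intestinal
  transit absorption chain, IV-infusion and oral dosing, an exact
  matrix-exponential propagator (stiff ODE solver retained as a
  cross-check), and a per-timepoint mass-balance ledger.
- **disease** — Child-Pugh cirrhosis modifier table (editable CSV) and the
  severe-CKD physiological values (GET 24.375 min, SITT 2.94 h, hematocrit
  0.398, protein-binding factor 0.843, GFR 11 — absolute mL/min by default,
  literal per-kg reading behind a flag); moderate CKD by midpoint
  interpolation.
- **nca** — trapezoidal AUC (linear default, lin-log flag), terminal-slope
  regression, AUC extrapolation, clearance (CL or CL/F), and a typed reader
  for the observed PK-parameter tables.
- **evaluation** — fold ratios, AFE (geometric mean), inclusive two-fold
  flags, 5th–95th percentile bands, bootstrap median CIs.
- **synthetic_data** — the eight study fixtures (designs + observed values,
  shipped as CSV transcriptions) and a seeded log-normal noise model for
  parameter-recovery experiments.
- **workflow** — end-to-end orchestration and the CLI.

## CLI

```sh
labpbpk fixtures --out fixtures/            # dump the shipped data tables
labpbpk run --scenario 8 --n 100 --seed 1 --out runs/renal
labpbpk qualify --mode simulation --n 100 --seed 1 --out qualification.csv
labpbpk qualify --mode fixture --out qualification_fixture.csv
labpbpk sweep --kind cirrhosis --route oral --n 100 --seed 1 --out sweep.csv
```

`run` writes per-subject profiles, percentile bands, population NCA
summaries, an evaluation table against the observed fixtures, and a JSON
manifest recording every parameter value, interpretation, and seed.
Scenario configs can also be given as YAML (`labpbpk run --config cfg.yaml`).

## Notes

- All randomness is seeded (`numpy.random.default_rng`); population
  sampling, noise generation, and bootstrap CIs are bitwise reproducible.
- The IV infusion duration is not reported by the source studies and is an
  explicit configuration knob (`EngineOptions.infusion_duration`, default
  1.0 h), surfaced in every run manifest.
- Cirrhosis modifier values are literature-informed defaults; claims made
  against them are ordering/trend claims, not absolute-value claims.
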