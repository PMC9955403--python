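# cghofd

Cuffless blood-pressure estimation from ECG + PPG waveforms: pulse
morphology/timing feature extraction, hybrid feature weighting, and a
Gaussian-process wrapper that decides the best feature subset by
cross-validated RMSE.

## Pipeline

1. **synthdata** — seeded generators for (a) BP-coupled ECG/PPG/ABP
   waveform triplets at 125 Hz with ground-truth fiducials and (b) feature
   tables with known sparse linear target structure, so the whole pipeline
   is testable without any clinical download.
2. **preprocess** — NaN removal across aligned channels, zero-phase Kaiser
   FIR band-limiting (35 Hz low-pass, 0.0665 Hz high-pass), PPG min-max
   normalization, 20 s non-overlapping windows, amplitude and SBP/DBP
   gating (drop SBP ≥ 180 / ≤ 80, DBP ≥ 130 / ≤ 50 mmHg).
3. **features** — ECG R-peak and PPG fiducial detection (foot, max-slope,
   systolic peak, falling-edge inflection, next foot) and 25 features per
   segment (ST, DT, PIR, HR, PAT1–3, LASI, AI, S1–S4, IPAR, PPGk,
   1st/2nd-derivative heights+widths, MXAP, MIAP, MEU, FHR) plus reference
   SBP/DBP from the ABP channel.
4. **weighting** — three interchangeable filters producing full feature
   rankings: one-way-ANOVA F-test (weight = −log10 p), robust NCA
   (bounded loss 1 − exp(−|Δy|), λ tuned by 5-fold CV), and MRMR (greedy
   mutual-information-quotient forward search).
5. **gpr** — GP regression with squared-exponential kernel, explicit
   (constant or linear) basis with closed-form profiled weights, and
   multi-start gradient maximization of the log marginal likelihood.
6. **hofd** — shrink the weight-ranked feature list one feature at a time,
   score every prefix by 5-fold-CV GP RMSE on a shared fold partition, and
   keep the prefix with minimal RMSE (ties → fewer features).
7. **evaluation** — ME/SDE, MAE, RMSE, R², AAMI pass rule (|ME| < 5 and
   SDE < 8 mmHg), BHS cumulative grading, Bland–Altman statistics, and
   one-way ANOVA across algorithms.

## CLI

```sh
cghofd synth waveforms --seed 1 --out record.csv
cghofd synth table    --seed 1 --out features.csv
cghofd preprocess --in record.csv --out segments/
cghofd extract    --segments segments/ --out features.csv
cghofd select     --features features.csv --target SBP --method ftest --out weights.json
cghofd hofd       --features features.csv --target SBP --mode rnca --folds 5 --seed 7 --out result.json
cghofd train      --features features.csv --target SBP --subset idx.json --out model.json
cghofd evaluate   --pred pred.csv --ref ref.csv --out report.json
cghofd run-all    --config demo.yaml --seed 7 --out out/
```

`run-all` writes `features.csv`, `result.json`, `report.json`, and a
`manifest.json` with SHA-256 checksums; reruns with the same config and
seed reproduce the manifest bit-for-bit.

## Python API

```python
from cghofd import (SynthFeatureConfig, generate_feature_table,
                    HOFDConfig, run_pipeline)

table, truth = generate_feature_table(SynthFeatureConfig(
    n_segments=400, n_features=10, support=(0, 1, 2),
    effect_sizes=(8.0, 6.0, 4.0), noise_sd=2.0, seed=42))
result = run_pipeline(table, HOFDConfig(hybrid_mode="ftest", seed=3))
print(result.selected_names, result.report.RMSE)
```

## Notes

- The MEU ("blood viscosity") feature has no published formula; the
  default surrogate is `ps/pm` and is pluggable via `meu_surrogate` (or
  excluded with `build_feature_table(..., include_meu=False)`).
- All randomness flows from explicit integer seeds; stage-local seeds are
  derived by hashing the global seed with the stage name.
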