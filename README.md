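# kidosim

Synthetic SPECT/CT kidney dosimetry for ¹⁷⁷Lu radiopeptide therapy, built
to quantify a specific workflow hazard: the whole kidney parenchyma (WKP)
swells transiently during treatment (amino-acid co-infusion), so reusing a
single CT delineation across all post-administration SPECT scans — a common
time-saver — biases the measured activity concentrations, the
time-integrated activity concentration (TIAC), and the absorbed dose.

The package is for medical-physics researchers who want a controlled,
fully synthetic testbed for delineation-propagation and partial-volume
correction choices, where the ground truth (anatomy, kinetics, PSF) is
known exactly.

## What it computes

* **Phantoms** — per-subject kidney/spleen shapes on a CT-like grid
  (1.1 mm in-plane / 5 mm slices) whose volumes follow the per-time-point
  multipliers {D0: 1.0877, D1: 1.1007, D2: 1.0110, D7: 1.0110} (kidneys)
  and 1.0 (spleen control); SPECT-like rendering on a 4.42 mm grid with a
  12 mm FWHM Gaussian PSF and optional Poisson noise.
* **Quantification** — CT→SPECT fractional VOI resampling, tag-matched
  (*reference*) vs single-delineation (*single_D0..D7*) propagation,
  coverage-weighted mean concentrations, optional translation alignment.
* **Kinetics** — the five-parameter tri-exponential model
  `C(t) = A1·e^(−bt) + A2·e^(−ct) − (A1+A2)·e^(−dt)` fitted to the four
  samples (≈4, 24, 48, 168 h) plus the structural zero at administration;
  TIAC in closed form `A1/b + A2/c − (A1+A2)/d`, cross-checked by
  adaptive quadrature.
* **Dose** — recovery-coefficient partial-volume correction (fixed 0.85 or
  shape-specific from the PSF-blurred delineation) and local-energy-
  deposition dose `D = TIAC × 147.9 keV / 1.05 g/mL` converted to Gy.
* **Statistics** — Bland-Altman bias ± 1.96 SD limits on percent
  differences and the paired Wilcoxon signed-rank test (exact by 2ⁿ
  enumeration for n ≤ 12).

See `docs/methods.md` for the model details, defaults and limitations.

## Worked example

```python
from kidosim import ExperimentConfig, run_experiment

cfg = ExperimentConfig(seed=1, cohort={"n_subjects": 4, "kidneys_per_subject": 1})
res = run_experiment(cfg)
print(res.volume_agreement[["tag", "bias_pct", "sd_pct"]].to_string(index=False))
print(res.concentration_agreement.query("strategy == 'single_D7'")[
    ["tag", "bias_pct"]].to_string(index=False))
```

prints

```
tag  bias_pct       sd_pct
 D0      8.77 4.298176e-08
 D1     10.07 6.958864e-08
 D2      1.10 3.823666e-08
 D7      1.10 3.823666e-08
tag  bias_pct
 D0  3.124742
 D1  3.602362
 D2  0.000000
 D7  0.000000
```

The first table is the volume analysis: the rasterised kidney volumes at
each time point, compared with baseline, recover the configured swelling
biases (8.77%, 10.07%, 1.10%, 1.10%) to rasterisation precision. The
second shows the mechanism under study: a D7 delineation (kidney almost
back to baseline size) is strictly interior to the swollen D0/D1 kidney,
so it reads the blurred activity high — a ~+3% concentration overestimate
that propagates into a positive absorbed-dose bias versus the
tag-matched reference.

## The analysis

Numbered drivers under `analysis/` run the full study and write tables to
`results/`:

```bash
python analysis/01_simulate_cohort.py --seed 1    # simulate + quantify (slow step)
python analysis/02_volume_changes.py              # volume Bland-Altman + Wilcoxon
python analysis/03_concentration_bias.py          # delineation×measurement bias matrix
python analysis/04_dose_agreement.py              # dose agreement per strategy × RC mode
```

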