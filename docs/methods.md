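# Methods

`kidosim` simulates a serial quantitative SPECT/CT dosimetry study of a
¹⁷⁷Lu-labelled radiopeptide therapy and measures how two workflow choices
bias kidney absorbed dose: (i) reusing a single CT delineation of the whole
kidney parenchyma (WKP) across all post-administration scans while the
kidney transiently swells, and (ii) correcting partial-volume losses with a
fixed guideline recovery coefficient instead of a shape-specific one.

## Anatomy and the volume time-course

Each synthetic subject carries two kidney-parenchyma organs and a spleen.
Organs are smooth convex shapes (ellipsoids by default; a "bean" variant
with a hilum indent exists) rasterised as fraction-of-voxel coverage masks
on a CT-like grid (1.105 mm in-plane, 5 mm slices). The shape scale is
solved so the rasterised volume hits the target to well under half a voxel
(coverage along the in-plane fast axis is computed by exact chord–voxel
overlap, so volume is a smooth monotone function of scale).

Baseline kidney volumes are drawn from a truncated normal, mean 130.6 mL,
SD 46.1 mL, clipped to 27.7–248.8 mL; spleens from mean 183.5 mL, SD
115.1 mL. Kidney volumes are scaled per time tag by the default multipliers

| tag | B_L | D0 (~4 h) | D1 (~24 h) | D2 (48 h) | D7 (168 h) |
|-----|-----|-----------|------------|-----------|------------|
| factor | 1.0 | 1.0877 | 1.1007 | 1.0110 | 1.0110 |

which encode the transient parenchymal swelling attributed to the
nephro-protective amino-acid co-infusion (+8.8% and +10.1% at the early
time points, back to ~+1% by 48 h). The spleen keeps factor 1 at every
tag and serves as the no-swelling control. By default every subject swells
by exactly these factors (`multiplier_jitter_sd = 0`): the multipliers are
the quantity the generator is supposed to reproduce, and adding per-subject
dispersion (an option) would only blur the round-trip check. Real cohorts
show subject scatter of ~24% SD around these biases; the default generator
deliberately does not emulate that scatter, so cohort-level significance
patterns (e.g. which tags reach p < 0.05) are not comparable to a real
study — only the bias mechanics are.

## Kinetics truth and dilution

Organ kinetics follow the five-parameter tri-exponential model

    A(t) = A1·e^(−b·t) + A2·e^(−c·t) − (A1+A2)·e^(−d·t)

which is structurally zero at the administration time. In the default
`activity_primary` mode the model is total organ activity and the true
concentration at tag *T* is A(t)/V(T): swelling dilutes concentration,
which is the hypothesised physiological mechanism. Default truth rates are
b = 0.01/h (effective half-life ≈ 69 h), c = 0.05/h, d = 0.7/h, jittered
per subject by a 15% lognormal; amplitudes are scaled to a peak
concentration of 0.3 MBq/mL (lognormal 20% across subjects), plausible for
~7.5 GBq administrations. Truth rates should not be slower than the ¹⁷⁷Lu
physical decay constant (ln 2 / 159.53 h ≈ 4.3×10⁻³/h); the defaults
respect this but the model does not enforce it.

## Image formation

The emission image is formed by painting each organ's true concentration on
the CT grid (fraction-weighted), downsampling to the 4.42 mm isotropic
SPECT grid by exact volume-weighted (box) averaging, and convolving with an
isotropic Gaussian PSF, FWHM 12 mm by default — representative of
medium-energy-collimator ¹⁷⁷Lu SPECT at 208 keV; the Gaussian is a
declared surrogate for a Monte-Carlo projection/reconstruction chain and
reproduces partial-volume spill-out but not attenuation, scatter, septal
penetration or reconstruction artefacts. Optional Poisson noise acts on
calibrated counts (default 10⁻³ counts per Bq/mL per voxel, ~200 counts in
a hot kidney voxel); the default is noise-free so that strategy biases are
measured without stochastic floor. All resampling uses exact separable
interval-overlap weights rather than point sampling, so total activity is
conserved to numerical precision for organs away from the grid edge.

## Quantification strategies

The delineation at each tag is resampled CT→SPECT as fractional coverage
and the VOI concentration is the coverage-weighted mean. The *reference*
strategy uses the tag-matched delineation at every time point; *single_Dk*
reuses the Dk delineation everywhere without geometric modification.
Optional integer-voxel translation alignment (off by default) maximises the
in-mask mean within a shift budget — a surrogate for the manual nudging of
contours onto SPECT, deliberately translation-only. Because a D7
delineation is strictly interior to the swollen D0/D1 kidney and the
blurred profile of a uniform object is highest in the interior, single-VOI
strategies overestimate concentration at the swollen tags; the converse
(delineation larger than the organ) underestimates. This sign structure is
asserted by the tests; magnitudes depend on the PSF and geometry.

## Recovery coefficients

The RC of a VOI is measured/true of the mean concentration for a uniformly
filled object, so correction divides by it. `fixed` mode uses the
guideline value 0.85. `specific` mode recovers the sharp organ surface
from the coverage mask (cubic-spline upsampling to ≈2.3 mm, re-thresholded
at coverage 0.5), paints it with unit concentration, convolves with the
PSF on the fine grid, and averages back over the shape. For spheres this
agrees with the closed-form erf-profile oracle to ~0.1%. Two numerical
facts worth knowing:

* The realized voxel measurement chain (box downsampling to 4.42 mm plus
  coverage-weighted averaging) behaves like ~0.7 mm of extra effective
  FWHM, so corrected concentrations sit ~1% below truth even with the
  shape-specific RC. This is a property of finite-grid quantification, not
  a bug; round-trip tests assert 1.5%.
* At 12 mm FWHM the kidney-sized shapes here have specific RCs near 0.79 —
  below the fixed 0.85 — so fixed-RC doses run several percent lower than
  specific-RC doses in this synthetic cohort. In a real cohort the two
  agree more closely because patient-specific RCs computed by Monte-Carlo
  for a reconstructed system cluster near 0.85; the synthetic PSF is
  sharper-edged than a reconstructed-system response.

The VOI-mean RC of a sphere obeys 1 − RC ≈ 3σ/(R√(2π)): even a 2 L sphere
only reaches RC ≈ 0.92 at 12 mm FWHM. RC → 1 holds in the infinite-volume
limit but very slowly (RC > 0.97 needs ≳17 L).

## Time-integrated activity and dose

The time–activity series per strategy consists of the four corrected
concentrations at the acquisition times plus the structural zero anchor.
The fit minimises unweighted SSE over A1, A2 ≥ 0 and rates in
[10⁻⁴, 10]/h with 16-start bounded trust-region optimisation (rate triples
log-spaced with b ≤ c ≤ d, amplitudes initialised from the peak sample,
analytic Jacobian), discarding solutions whose model dips negative on the
observed span.

Five parameters against four informative samples leave a one-dimensional
family of exact interpolants. Along this family the TIAC (closed form
A1/b + A2/c − (A1+A2)/d) is bounded tightly from below by the data but
only weakly from above, because the tail beyond the last sample admits
arbitrarily slow rates carrying arbitrarily large area. The fit therefore
reports the canonical *minimal-TIAC* member among SSE-ties (tie window
10⁻¹⁰ of the data's sum of squares; residual ties break to smaller d):
deterministic, scale-equivariant, and empirically within ~0.6% (median
~0.1%) of a generating truth under the default kinetics — the
identifiability floor of this design; no selection rule can do materially
better from these data, which is why recovery is asserted at 1% rather
than an arbitrary tighter figure. The closed form is verified against
adaptive quadrature with an analytic tail bound to 10⁻⁸ relative.

Dose uses the local-energy-deposition model: TIAC in Bq·h/mL × 3600 →
decays/mL, ÷ 1.05 g/mL → decays/g, × 147.9 keV × 1.602176634×10⁻¹⁶ J/keV
× 10³ g/kg → Gy. A `photon_self_dose_factor` (default 1.0, i.e. pure
electron LED) is available for the self-absorbed photon contribution. All
conversions live in one function to prevent silent double-conversion.

## Agreement statistics

Bland-Altman analysis reports mean (bias) and sample SD of per-pair
percent differences with limits at ±1.96 SD. Volume changes versus
baseline use the *reference* (baseline) denominator, because the
multipliers are defined as 1 + bias/100 relative to baseline; strategy
comparisons of concentration and dose use the standard pair-mean
denominator. The paired Wilcoxon signed-rank test drops zero differences,
midranks ties, computes the exact two-sided p by full 2ⁿ enumeration for
n ≤ 12 and otherwise a tie- and continuity-corrected normal approximation
(slightly conservative: null rejection ≈ 4–5% at α = 0.05, n = 18).
Kidneys are pooled across sides (n = 36 pairs for 18 subjects) by default,
matching how paired kidney volumes are usually counted; per-subject
pooling is available by filtering the tables.

## Problem sizes and determinism

The default experiment is 18 subjects × 5 tags × 3 organs on a
32×190×154-voxel CT grid and a 37×48×39 SPECT grid (≈3 min on one CPU);
tests exercise the same code on 2–3-subject cohorts and the volumetric
half of the pipeline at full n = 18. All randomness flows from one seed
through per-subject `SeedSequence` spawns; with noise off the entire
pipeline is deterministic bit-for-bit, and with Poisson noise it is
reproducible for a fixed seed.

## Known limitations

* No attenuation, scatter, collimator modelling or reconstruction; the
  Gaussian PSF is the declared resolution surrogate.
* No deformable registration or respiratory motion; alignment is integer
  translation only.
* Organ shapes are smooth and convex; real parenchyma (cortex+medulla
  minus pelvis) is concave, which lowers specific RCs further.
* The generator's default cohort has no multiplier scatter and no
  acquisition-time jitter (both available as options), so only biases —
  not cohort variances or significance patterns — are meaningful outputs.
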