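# Methods

This note documents the models, conventions and numerical choices behind the
`cestdwi` pipeline: what the synthetic study generator simulates, how each
analysis stage computes its quantity, and what the passing test suite does and
does not demonstrate about real animal data.

## The study being emulated

The pipeline targets a preclinical design: rats bearing an orthotopic C6
glioma, half receiving a single 15 Gy whole-brain X-ray dose on day 9, imaged
on days 8, 10 and 17 after implantation. Three series per animal per day:

* **T2-weighted anatomy** — 32 mm field of view, 256×256 matrix, 10 slices of
  1 mm; used only to draw the tumor ROI and measure volume.
* **CEST Z-spectrum series** — single 128×128 slice, saturation offsets
  −4.8 … +4.8 ppm in 0.3 ppm steps (33 frames) plus an unsaturated reference
  frame. The creatine-weighted readout is the MTR asymmetry at +1.8 ppm.
* **DWI** — the same single 128×128 slice at b = 0, 1000, 2000 s/mm²,
  treated as trace-weighted (direction-averaged) input.

No real acquisitions ship with the package; the phantom module generates
studies with this structure and with group/day trajectories matching the
published summary statistics, so every downstream stage is testable offline.

## Phantom generative model

**Z-spectra.** Each pixel's spectrum is a sum of Lorentzian saturation lines
on top of unity:

Z(Δω) = 1 − Σ_p A_p·(Γ_p/2)² / ((Γ_p/2)² + (Δω − δ₀ − δ_p)²)

with a water line (A=0.8, Γ=1.4 ppm, center 0), a broad symmetric semi-solid
MT line (A=0.1, Γ=20 ppm, center 0) and one solute (creatine guanidinium)
line at +1.8 ppm with Γ=1 ppm. This is a steady-state approximation chosen
over Bloch–McConnell integration deliberately: the analysis consumes only MTR
asymmetry, which the Lorentzian model reproduces with exact analytic control.
Because water and MT are symmetric, all asymmetry comes from the solute pool,
and the amplitude that yields a target asymmetry T% at the pool's own center
is available in closed form:

A = (T/100) / (1 − t),  t = (Γ/2)² / ((Γ/2)² + (2δ)²)

(the tail factor t is the pool's own mirrored-offset contribution). The
calibrate → synthesize → measure round trip is exact to ~10⁻¹² and anchors
the acceptance tests. Spectra at unscheduled positions are never needed by
the generator: a B0 error δ₀ is modelled as a rigid translation of all lines.

**Per-pixel structure.** The single CEST/DWI slice contains four
compartments: background (air), normal brain (disk of radius 12 mm), tumor
margin and tumor center (concentric disks; the center disk holds 36% of the
tumor area). Within each tumor compartment the per-pixel (ADC, MTR-target)
pair is bivariate normal with configurable SDs and correlation ρ — the knob
that generates the pixel-basis scatter couplings. Compartment means carry a
center-minus-margin contrast applied area-weighted so the tumor mean is
preserved exactly.

**Noise.** DWI magnitude noise is Rician (|S + n₁ + i·n₂|, n ~ N(0, σ²)),
the magnitude-MRI convention; CEST and T2 frames carry additive Gaussian
noise (σ = 2 and 20 on S0 ≈ 1000 and 1500 respectively, i.e. high SNR — the
per-pixel biological dispersion is injected in the ground truth, not the
thermal noise). Defaults: DWI σ=10 on S0=1000.

**Study defaults.** n = 6 animals per arm (the original report used 12 rats
total without stating arm sizes). Per-(group, day) tumor volumes, ADC means,
creatine-MTR means, animal-level and pixel-level SDs follow the published
trajectories (volumes 26.3/51.3/152.2 mm³ control and 18.6/23.0/27.3 mm³
irradiated on days 8/10/17; ADC 0.6/0.7/0.8 vs 0.6/0.6/0.7 ×10⁻³ mm²/s; MTR
5.6/5.6/5.9 vs 6.4/4.3/5.0 %). The tumor is a 4-slice cylinder; per-animal
volumes share one animal z-score across days (so individual growth curves
are monotone when the group means are). The day-17 control cell is the only
spatially contrasted one (center ADC higher by 0.2×10⁻³, center MTR lower by
1.5 points — the edematous/necrotic center described for untreated tumors at
that stage) and the only cell with positive within-compartment coupling
(ρ = +0.8); all others use ρ ≤ −0.5. These values were fixed from a
closed-form pooled-covariance budget so that pooling pixels across
compartments yields a positive day-17 control Pearson r (within-compartment
covariance ρσ_aσ_m = +0.19 against a between-compartment term
w_c·w_m·Δadc·Δmtr = −0.03) while the printed means/SDs are matched.

**Seeding.** One integer seed drives a `numpy` `SeedSequence` hierarchy
(study → animal → day → channel). Rebuilding the same spec is bit-identical;
changing the seed moves ground-truth means only within sampling error.

**Masks across grids.** The T2-grid tumor mask is the 2×2 block-upsampling
of the 128-grid truth mask, so the analysis path's 50%-majority block
downsampling recovers the truth mask exactly and compartment statistics are
not diluted by grid-boundary disagreement. The ≥2-of-4 tie-inclusive
majority rule is exercised separately on hand-built masks.

## Analysis conventions

* **Normalization**: z = S(Δω)/S0 with a dedicated unsaturated reference
  frame (the ±4.8 ppm extremes still carry MT saturation, so they are not
  used as the reference). Pixels with S0 below a floor (default 50 on the
  nominal 1000 scale in the pipeline) are flagged invalid and excluded from
  every downstream map; drop counts are logged in the run manifest.
* **B0 correction** (on by default, window ±1.0 ppm): a cubic spline locates
  the spectral minimum; the location is then polished by a least-squares fit
  of a Lorentzian plus linear baseline to the windowed points. The polish
  matters: the bare spline minimum carries a grid-phase bias of ~0.01 ppm on
  the 0.3 ppm grid, which leaks ~0.2 percentage points into the asymmetry
  through the water-line slope; after polishing, recovered shifts are
  accurate to ~0.002 ppm and the corrected asymmetry at 1.8 ppm stays within
  ~0.1 points of the unshifted value for |δ₀| ≤ 0.15 ppm. The corrected
  spectrum is resampled with a cubic spline over the full axis (linear
  resampling would contribute ~0.5 points of error near the Γ=1 ppm solute
  line). A minimum on the window boundary, or a flat window, produces a
  warning and no shift.
* **MTR asymmetry**: [z(−Δω) − z(+Δω)] × 100, percent everywhere. The
  default schedule samples ±1.8 exactly; off-grid offsets use linear
  interpolation on z. Group MTR curves default to per-animal means followed
  by across-animal mean ± SD; a pooled-pixels mode reproduces the larger
  pixel-basis dispersions.
* **ADC**: ordinary least squares of ln S on b; ADC = −slope. Non-positive
  signals are dropped per pixel (never clamped — clamping biases the slope
  with no principled floor); <2 usable points flags the pixel invalid. A
  weighted variant (weights ∝ S²) is available by flag. The log-fit of
  Rician data carries a small positive bias at low SNR; at the default noise
  levels the Monte-Carlo recovery error is well under 5%.
* **Volumetry**: pixel count × (fov/matrix)² × slice thickness, exact
  arithmetic; 0-based, row-major, pixel-center conventions.
* **Joint pixel analysis**: the ADC and MTR maps must share a grid (hard
  error otherwise; no silent resampling). Default pooling merges pixels
  across animals within (group, day) — one scatter per cell; a per-animal
  mode averages within-animal correlations for sensitivity analysis. Sign
  calls require |r| > 0.1 *and* p < 0.05 (both thresholds configurable; the
  original report states signs without criteria). Spearman ρ is reported
  alongside Pearson.
* **Group statistics**: one-way ANOVA (scipy F distribution) with
  Tukey-Kramer all-pairs post hoc; the q statistics and marshaling are
  implemented here with the studentized-range distribution delegated to
  scipy (verified against the statsmodels implementation in the tests).
  Stars use strict inequalities: *** p<0.001, ** p<0.01, * p<0.05, else ns.
  No additional correction is applied across measures. Repeated measures
  across days are treated as independent, mirroring the one-way design of
  the original analysis; this is a documented caveat, not a recommendation.

## What the tests show — and what they cannot

Passing tests demonstrate: exact inversion of the volumetry and ADC
arithmetic on printed values; closed-form calibration round trips for the
published MTR curve values; B0 inject-and-recover accuracy; sign-recovery
rates for known generative couplings (≥95/100 seeds at n=500 pixels);
type-I calibration of the ANOVA layer; and end-to-end bit-reproducibility
of the full default study in well under 15 minutes on one CPU.

They do not demonstrate performance on real 7T data: the phantom has no
motion, no partial-volume mixing at compartment boundaries beyond grid
quantization, no spatially varying B0/B1 fields (B0 is one number per
animal), no NOE or amide pools (supported by the types but absent by
default), Lorentzian rather than Bloch–McConnell saturation, and hand-drawn
ROI variability is not modelled. The positive day-17 control correlation is
a generator-level construction resolving an apparent tension in the
published description (center-high ADC with center-low MTR is a negative
between-compartment gradient, yet the pooled day-17 correlation is
positive); the phantom exposes both couplings and makes no claim about
which dominated in vivo.

## Problem sizes

Default acceptance-scale runs use the full study (36 acquisitions, 128²
single slice, ~500–4000 tumor pixels per group/day cell), 100 seeds × 3
couplings × 500 pixels for sign recovery, and 2000 null datasets (3 groups
× 10) for the type-I check.
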