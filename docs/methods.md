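# Methods

This note documents the models implemented in `hippodwi`, the default
parameter values and why they were chosen, the numerical conventions, and
what the synthetic phantom does and does not establish about real data.

## The phantom

### Geometry

One phantom is a 2D transverse hippocampal slice on a 128×102 voxel grid
(rows = dorso-ventral axis, columns = left–right axis, 0-based indexing,
angles counterclockwise from +x) at 0.04 mm in-plane voxel size and
0.1 mm slice thickness. Five regions are laid out as concentric arcs and
wedges around the grid center so that the adjacency of the real anatomy is
preserved: an outer C-shaped CA1 pyramidal band (upper arc, 30°–150°)
continuing into CA3 (150°–270°), a stratum-radiatum band (srCA1) lining
the inside of CA1, a thinner U-shaped granule cell layer (DG) near the
center opening upward (190°–350°), and the hilus filling the wedge the DG
encloses. Band widths scale with the grid (CA1 ≈ 5.5% of the short grid
dimension, srCA1 5%, GCL 4.5%); the GCL width is multiplied by a
per-condition dispersion factor (1.0 control/contralateral, 2.0
ipsilateral — granule cell dispersion). This is a stylized parametric
stand-in for manual segmentation of real slices: any geometry preserving
ROI adjacency and orientation structure suffices for the statistics under
test, and no attempt is made at anatomical rendering.

### Orientations

Each ROI carries a mean axial orientation μ and a concentration κ:
90° (dorso-ventral) for CA1 and DG (pyramidal/granule cell dendrites),
45° for CA3, 0° (left–right) for the hilus (mossy fibers) and srCA1
(Schaffer collaterals). Orientations are *axial* — defined modulo 180°,
because dendrites and axons have no polarity — so sampling uses the
standard angle-doubling construction: φ ~ vonMises(2μ, κ),
θ = (φ/2) mod 180°. κ = 0 yields exactly uniform axial orientations and
models complete loss of directional conformity. Within-ROI dispersion of
real tissue is unknown (the hypothesized orientations are approximate for
curved structures), so the defaults (κ = 7–14 per ROI) are calibration
choices that put the V-test comfortably in its operating range at the
default sample caps, not measured tissue values.

### Tensors

Per voxel, D = λ⊥I + (λ∥ − λ⊥)eeᵀ with the principal axis
e = (cos θ, sin θ, 0) in-plane at the voxel's orientation. Baseline
eigenvalues give fixed-tissue mean diffusivities of 0.5×10⁻³ mm²/s in
every ROI (e.g. CA1: λ∥ = 0.90, λ⊥ = 0.30 ×10⁻³ mm²/s, FA ≈ 0.60), the
scale observed in paraformaldehyde-fixed tissue. Background voxels get an
isotropic saline tensor (2.0×10⁻³ mm²/s). Principal axes are kept
in-plane; through-plane diffusion exists in real slices but the analysis
quantifies in-plane measures, so a λ_z tilt is not modelled.

### Conditions, severity, and density coupling

Epileptic slices draw a severity scalar s ~ Uniform[0.5, 1] (controls:
s = 0); pathological alterations are inherently variable across epileptic
animals, and this per-slice severity creates the within-group spread that
makes intra-group density–DWI correlations recoverable at n = 9.

Condition effects (all config-exposed; magnitudes are invented defaults
calibrated once so the documented significance/direction pattern is
reproduced at the 6/9/6 group sizes — directions, not effect sizes, are
the modelling target):

| condition     | ROI   | effect at severity s |
|---------------|-------|----------------------|
| ipsilateral   | CA1   | density ×(1 − 0.75 s), κ → 0 |
| ipsilateral   | CA3   | density ×(1 − 0.60 s), κ → 0 |
| ipsilateral   | DG    | density ×(1 − 0.20 s), both λ ×(1 + 0.45 s) |
| ipsilateral   | hilus | λ∥ ×(1 + 0.60 s), λ⊥ ×(1 + 0.15 s), κ → 12 |
| ipsilateral   | srCA1 | density ×(1 − 0.20 s) |
| contralateral | CA1   | density ×(1 − 0.12 s) |

Cell density is a per-voxel proxy map (arbitrary units, background 0):
ROI mean = baseline × condition factor × (1 + 5% slice jitter), voxels
add 10% multiplicative noise. Density couples to the tensors through the
affine law λ⊥ = λ⊥⁰ + b_md·(ρ₀ − ρ), λ∥ = λ∥⁰ − b_fa·(ρ₀ − ρ) with
defaults b_md = 0.25×10⁻³ and b_fa = 0.50×10⁻³ mm²/s per density unit:
cell loss (a density deficit) raises radial diffusivity and lowers axial
coherence, so higher density means lower MD and higher FA in layered
ROIs. The intercept is pinned per ROI to the control baseline — the same
affine law as a global a − b·ρ, but able to respect five different
baselines. Independent 5% per-slice jitters on λ∥ and λ⊥ provide the
biological between-slice variance without which group standard deviations
would be implausibly tiny.

The GCL width is measured from the label map as band area / centerline
length, computed via the ribbon model: area = L·w and Crofton perimeter
= 2L + 2w, so w is the smaller root of w² − (P/2)w + A = 0. This avoids
skeleton end-trimming bias on curved bands and recovers configured widths
within ~3% (half a voxel on straight bands).

## Acquisition model

Signals follow the mono-exponential tensor model
S_i = S0·exp(−b·gᵢᵀD gᵢ); b = 0 volumes equal S0 exactly. The default
scheme is 60 directions at b = 1000 s/mm² plus 6 b=0 images, generated by
electrostatic repulsion with antipodal symmetry (fixed 300 iterations,
seeded, minimum inter-line angle > 10°); real gradient tables can be read
from FSL-style `bval`/`bvec` files instead. The b-value trade-off
functions quantify the choice of b = 1000 for fixed tissue: at
D = 0.5×10⁻³ mm²/s, 100·(e^{−b₁D}/e^{−b₂D} − 1) ≈ 65% SNR gain against
b = 2000, and contrast sensitivity |∂S/∂D| = b·S0·e^{−bD} falls by
100·(1 − b₁e^{−b₁D}/(b₂e^{−b₂D})) ≈ 18%. "Contrast" here is the
sensitivity of the signal to a diffusivity change; a two-tissue signal
difference is an alternative reading that is not implemented.

Noise is Rician — magnitude data from complex Gaussian channel noise:
S_noisy = √((S + ε₁)² + ε₂²), ε ~ N(0, σ²), with σ = S0/SNR defined
against the b=0 tissue signal. The default simulation SNR of 15 sits in
the middle of the 11–22 range acceptable for slice DWI at this
resolution. Multiple b=0 volumes are averaged (mean) before ADC
computation.

## Quantification

**Tensor fit.** ADC = −ln(S/S0)/b with the signal ratio clamped to
(10⁻⁶, 1] before the log (noise-floor guard; clamped voxels are flagged,
not raised). The tensor solves B·d = y, y_i = ln(S0/S_i), with rows
b·(g_x², g_y², g_z², 2g_xg_y, 2g_xg_z, 2g_yg_z) and weights S_i² — the
standard one-pass WLS for log-transformed magnitude data, sufficient at
SNR ≥ 10; iterative reweighting and NLLS are deliberately out of scope.
Negative eigenvalues (rare at tissue diffusivities) are clamped to zero
post hoc and counted. FA uses the normalized eigenvalue-dispersion
formula; θ = atan2(e₁y, e₁x) mod 180° and is masked where λ₁ − λ₂ ≤
10⁻¹² mm²/s or the principal eigenvector has no in-plane component.
Phantom runs mask from the known label map; external data fall back to an
Otsu threshold on the mean b=0 image (real backgrounds are dark air; the
phantom's saline background is not, which is why the label mask is used
there).

**SH profile.** Per-direction ADC is fit with real even-order spherical
harmonics (orders 0..L, only even: ADC is antipodally symmetric). The
default L = 4 (15 coefficients) is the standard HARDI choice for 60
directions and can capture non-tensor profiles; L = 2 suffices for tensor
data, where the fit reproduces g↦gᵀDg exactly — the property that makes
the tensor and SH routes mutually consistent oracles in the tests. No
Laplace–Beltrami regularization by default (noise is handled by ROI
averaging); a weight is exposed in `fit_sh` callers if needed. Axis
diffusivities evaluate the expansion at (0,1,0) (dvD) and (1,0,0) (lrD);
per-voxel values are computed first and then averaged within ROI (the
alternative, fitting one profile to the ROI-mean ADC, is not the
default), and the ratio is masked where lrD < 10⁻⁶ mm²/s.

## Statistics

The unit of analysis is the slice: per-slice ROI means enter ANOVA,
paired tests and correlations. Orientation V-tests instead pool voxel
orientations per group × ROI, subsampled to at most 300 voxels (150 per
slice) so the pooled test is not driven to astronomical n — a variance
control, not a power trick; caps are config-exposed. The V-test doubles
angles (axial data), computes V = Σcos(φᵢ − φ₀), u = V√(2/n), and takes
the one-sided normal upper tail, adequate for n ≥ 5; the undoubled
variant is available via a flag for directional data. Tukey HSD uses the
studentized-range distribution via statsmodels and is cross-checked in
the tests against an independent pooled-MSE computation. No
multiple-testing correction is applied by default, mirroring a per-test
p < 0.05 workflow; `build_report(bonferroni=True)` divides α by the test
count. Paired comparisons with zero within-pair variance report p = NaN
with a degeneracy flag rather than a fabricated value; correlations of
constant columns likewise return NaN, non-significant.

## Reproducibility and problem sizes

A single master seed derives every per-slice seed as
blake2b("master:slice_id") truncated to 31 bits; phantom generation,
noise, and subsampling each consume their own derived generator, so equal
configurations are bit-identical end to end. The replicate studies in the
tests and the acceptance script use 50 cohorts of 21 slices (128×102
grid, 66 volumes, SNR 15) — a full study re-run takes roughly three
minutes on one CPU, and the per-replicate quantities are boolean pattern
flags, so this replicate count estimates the recovery rates to a few
percent.

## What passing tests do and do not show

The phantom reproduces the *statistical structure* the analysis assumes:
layered axial orientation fields, group effects of plausible direction,
severity-driven within-group covariance of density and diffusion, Rician
magnitude noise at slice-level SNR. It does not emulate curved-structure
orientation gradients within an ROI, partial-volume mixing at band
borders, through-plane fiber components, eddy-current or EPI distortion,
coregistration error between DWI and histology, or multi-compartment
(non-mono-exponential) diffusion. Consequently, passing tests validate
the estimators and the statistical workflow — not the biological effect
sizes, which are invented defaults; on real data the same pipeline
applies via `fit_external` but group-level conclusions depend on the
usual acquisition-quality caveats. Repeated slices from the same animal
are treated as independent (no mixed-effects modelling), a known
limitation of the per-slice design.

## Design choices on genuinely open points

- Tensor estimator (WLS with S² weights), masking rule, and b=0
  combination (mean) are conventions; none is dictated by the analysis
  being emulated.
- SH order (4) and zero regularization are documented defaults, both
  configurable.
- "Contrast" in the b-value trade-off is the derivative sensitivity
  |∂S/∂D| (reproduces the ~18% figure); the two-tissue difference
  definition is noted above as the alternative.
- The V-test is applied to doubled angles by default; the flag
  `axial=False` gives the undoubled test.
- `RunConfig` validates its fields directly in `__post_init__` and round
  trips losslessly through YAML; a JSON-schema layer would duplicate
  those checks without adding guarantees.
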