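# hippodwi

Quantitative diffusion MR microscopy of the epileptic mouse hippocampus,
as a tested, reusable, fully synthetic pipeline.

In the intrahippocampal kainate model of mesial temporal lobe epilepsy,
hippocampal sclerosis reshapes the microstructure of the hippocampal
subfields: CA1/CA3 pyramidal cells degenerate, the granule cell layer
(GCL) disperses, and mossy fibers sprout. High-resolution diffusion-weighted
imaging (DWI) of fixed slices can resolve these changes: the orientation and
magnitude of water diffusion track the layered dendrite/axon architecture,
and region-wise diffusion parameters correlate with histological cell
density. `hippodwi` reproduces this analysis end to end on parametric
digital phantoms, for methodologists who want a controlled test bed for
tensor metrics, spherical-harmonic ADC profiles and axial circular
statistics at realistic slice-cohort sizes.

## What it computes

Per voxel, from a HARDI acquisition (60 directions, b = 1000 s/mm², 6 b=0
images) of a 2D hippocampal slice:

- **Diffusion tensor** D from weighted least squares on log-signals
  (S_i = S0·exp(−b·gᵢᵀD gᵢ)), then **FA**, **MD** and the primary in-plane
  diffusion orientation θ ∈ [0°, 180°) from the eigendecomposition.
- **ADC profile** ADC(g) = −ln(S/S0)/b expanded in real even-order
  spherical harmonics (default order 4), evaluated along the dorso-ventral
  (dvD) and left–right (lrD) image axes, plus their ratio dvD/lrD.

Per region (CA1, CA3, DG granule cell layer, hilus, CA1 stratum radiatum)
and cohort (6 control / 9 ipsilateral / 6 contralateral slices):

- **V-test** for non-uniformity of axial orientations against hypothesized
  directions (90° for CA1/DG, 45° for CA3, 0° for hilus/srCA1), with
  angle doubling since orientations are 180°-periodic: u = V·√(2/n),
  V = Σ cos(2θᵢ − 2μ₀).
- **One-way ANOVA + Tukey HSD** across regions and across groups.
- **Paired t-tests** for within-slice ipsilateral/contralateral contrasts.
- **Pearson correlations** between diffusion parameters and the phantom's
  cell-density proxy, pooled and within the ipsilateral group.

The phantom generator is first-class, tested code: a stylized slice
geometry (arcs and wedges with the correct ROI adjacency), axial von Mises
orientation fields, per-slice lesion-severity randomization, and a
density→diffusivity coupling that makes intra-group density–DWI
correlations recoverable.

## Worked example

```python
from hippodwi import snr_gain, contrast_loss
from hippodwi.pipeline import RunConfig, run_cohort, cohort_report

# the b-value trade-off at fixed-tissue diffusivity 0.5e-3 mm^2/s
print(f"SNR gain:      {snr_gain(1000, 2000, 0.5e-3):.2f}%")
print(f"Contrast loss: {contrast_loss(1000, 2000, 0.5e-3):.2f}%")

# a full 6/9/6 cohort at SNR 15, and its statistical report
result = run_cohort(RunConfig(master_seed=1))
report = cohort_report(result)
```

which prints

```
SNR gain:      64.87%
Contrast loss: 17.56%
```

— acquiring at b = 1000 instead of 2000 s/mm² costs ~18% diffusion
contrast sensitivity but buys ~65% more SNR. The report contains, among
~190 tests (excerpts from the run above):

```
     test                            contrast  statistic       pvalue  significant
tukey[FA]     control-contralateral (roi=CA1)   0.049267 3.841855e-01        False
tukey[FA] ipsilateral-contralateral (roi=CA1)  -0.279284 3.410293e-07         True
tukey[FA]       ipsilateral-control (roi=CA1)  -0.328551 3.016480e-08         True

      test                   contrast  statistic        pvalue  significant
vtest[CA1]       group=control,mu0=90  23.251762 6.826645e-120         True
vtest[CA1]   group=ipsilateral,mu0=90   1.329626  9.182078e-02        False

                           test  statistic   pvalue  significant
pearson[FA(CA1) vs density_CA1]   0.919439 0.000451         True
```

CA1 FA drops only ipsilaterally (pyramidal cell loss); control CA1
orientations align dorso-ventrally while ipsilateral ones are uniform; and
within the ipsilateral group CA1 FA tracks the cell-density proxy
(r = 0.92) — the severity of the lesion, not just group membership.

The same experiment runs from the shell:

```bash
hippodwi run-all --out results/run1 --seed 1
hippodwi simulate --condition ipsilateral --seed 2 --out results/slice2
hippodwi fit --dwi results/slice2/dwi.nii --bval results/slice2/dwi.bval \
             --bvec results/slice2/dwi.bvec --labels results/slice2/labels.nii \
             --out results/slice2/maps
```

writing NIfTI maps, FSL-style `bval`/`bvec` tables, the tidy ROI table and
the CSV/JSON statistics report.

## Layout

- `hippodwi.phantom` — parametric slice phantoms (geometry, orientations,
  density, tensors)
- `hippodwi.dwisim` — gradient schemes, mono-exponential signals, Rician
  noise, b-value trade-offs
- `hippodwi.tensorfit` — ADC, WLS tensor fit, FA/MD/orientation maps
- `hippodwi.shprofile` — spherical-harmonic ADC profiles, dvD/lrD/ratio
- `hippodwi.stats` — V-test, ANOVA/Tukey, paired tests, correlations
- `hippodwi.pipeline` / `hippodwi.cli` — cohort orchestration and the
  `hippodwi` command
- `docs/methods.md` — model assumptions, parameter choices, limitations
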