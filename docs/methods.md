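# Methods

## Signal model and units

Diffusion-weighted signal is mono-exponential per voxel,
`S(b) = S0 · exp(−b · ADC · 10⁻⁶) + ε`, with `ε ~ N(0, σ²)` independent
across voxels and b-values. Noise is Gaussian on the magnitude signal,
not Rician: this is valid at the signal-to-noise ratios simulated here
(σ/S0 ≤ ~0.025 at b=0) and keeps the noise model exactly invertible.
Negative simulated signals are kept at generation; they are handled at
the ADC-fitting stage only.

ADC is carried everywhere in units of 10⁻⁶ mm²/s, so clinically
familiar limits (0–3000 for brain, 0–2400 for pelvis) are usable
verbatim and the decay exponent carries an explicit 10⁻⁶ factor.
b-values are s/mm²; voxel sizes mm.

Two acquisition protocols are bundled: a glioma-like multi-b protocol
(b = 0, 200, …, 1000; voxel 1.2 mm; native noise σ = 17) and a
prostate-like two-b protocol (b = 0, 800; voxel 1.625 mm; σ = 2.5).

## Phantom generator

Each synthetic ROI is an ellipsoid on a 60×60×4 grid (~2–3×10³ voxels).
The ADC texture is seeded white noise smoothed in-plane with a Gaussian
kernel (the correlation length, in voxels), then affinely mapped so the
in-ROI sample mean and standard deviation equal the requested base mean
and amplitude exactly; values are clipped at zero. Slices are smoothed
independently, matching the per-slice (2-D) GLCM construction — the
slice gap of a real multi-slice acquisition is not modelled because no
computation crosses slices.

Cohort batches draw per-ROI parameters from fixed ranges chosen to
emulate a clinical cohort's heterogeneity at desk scale: base mean
U(800, 1200), texture amplitude U(200, 400), correlation length
U(1.0, 4.0) voxels, and unattenuated amplitude S0 ~ U(700, 1400). The
S0 spread matters: inter-exam SNR varies substantially in practice
(coil loading, tumour depth, signal averaging), and without it the
noise-propagation differences between b-value subsets would be
identically sized in every ROI — an artificially coherent shift no real
cohort exhibits. Optionally a fluid-like ellipsoid (mean ADC 3000, mild
texture) is placed at a jittered position on the ROI boundary, so some
ROIs contain a thin near-fluid rim and others none, emulating tumours
near ventricles or bladder.

What the phantoms do *not* emulate: biological texture structure beyond
a single-scale Gaussian random field, EPI distortion, bias fields,
intravoxel incoherent motion (bi-exponential decay), or Rician noise at
low SNR. Passing the cohort-level tests therefore shows the *pipeline's*
sensitivities reproduce, not that any specific tissue value would.

## Pre-processing chain

* **Resampling** — the acquisition method behind coarser clinical
  resolutions is not uniquely defined; this implementation uses local
  block averaging for integer factors (mimics acquiring bigger voxels,
  including the accompanying noise averaging) and linear interpolation
  onto the coarser grid otherwise. ROI masks always use
  nearest-neighbour so they stay binary.
* **Noise injection** — variance additivity: to reach a total of
  `f · σ_native` the stage adds `σ_native·√(f²−1)`.
* **ADC fitting** — per-voxel OLS of ln S on b. Non-positive signals at
  voxels with ≥2 positive samples are clamped to 10⁻³ of the series
  maximum before the log (clamp count logged); voxels with <2 positive
  samples are set to ADC 0 and tallied. Natural log throughout.

## Quantization

Uniform bins over `[lo, hi]`: label `1 + ⌊N(v−lo)/(hi−lo)⌋`, top edge
closed so `v = hi` maps to N. Limits come from the whole ROI (AutoROI),
each slice (AutoSlice, computed before that slice's GLCM), or fixed
Manual bounds with out-of-range values clipped into the boundary bins —
clipping rather than dropping keeps the GLCM support stable when fluid
voxels enter the ROI. Degenerate (constant) regions label everything 1
with a warning. Cohort-level Manual limits follow the quartile rule:
lower quartile of per-ROI minima, upper quartile of per-ROI maxima
(linear interpolation between order statistics); on the default
synthetic cohorts this rule lands near (0, 3100), consistent with the
round limits used for the bundled designs.

## GLCM and features

Per slice, every ordered pair of 8-adjacent voxels with *both* members
inside the ROI increments the count matrix (the both-inside rule keeps
background intensities out of the texture); distance is fixed at one
voxel. Slice matrices are summed over the ROI and normalized once, so
`Σp = 1` and symmetry hold exactly. The 19 features use natural logs,
`0·log 0 = 0`, sum variance centred on the sum average, difference
variance centred on the mean of the difference distribution, and the
grand gray-level mean `μ = Σᵢ i·p_x(i)` (equal to both marginal means
for symmetric matrices). Cluster prominence uses exponent 3 and cluster
shade exponent 4 by default, with
`cluster_convention="conventional"` swapping to the more widespread
assignment. `imc2`'s radicand is clamped at zero against floating-point
negatives. Correlation (zero marginal variance) and imc1 (zero marginal
entropy) are undefined on degenerate matrices and propagate as NaN;
downstream KS tests drop them pairwise, and a pair left with fewer than
two values per side yields a missing p-value, never a silent 1.0.

## Sensitivity analysis

One parameter varies at a time; every varied list contains the
reference setting (resolution 1.0×, noise 1.0×, reference b-subset,
N = 32, AutoROI), and recurring reference rows are bit-identical
because the added-noise stream is derived from (master seed, ROI,
noise factor) only. The two-sample KS test uses the exact ECDF
sup-gap D and the classic asymptotic Kolmogorov p-value
`Q(√(n_a n_b/(n_a+n_b))·D)` — adequate for the ≥30-per-side cohort
sizes used here, and a documented limitation for small batches.
Aggregation per (parameter, feature) is the minimum pairwise p, flagged
significant when below α/n_tests; a single design corrects for its own
count (475 or 361), a joint analysis for 836, with the denominator
recorded in every output header.

The ROI-perturbation experiment dilates the ROI by one voxel in-plane
with 8-connectivity (matching the GLCM neighbourhood) and compares the
percentage feature change under AutoROI limits against fixed Manual
limits of 500–1500 × 10⁻⁶ mm²/s, the narrow-band choice that excludes
fluid and signal voids.

## Problem sizes and determinism

The bundled cohorts are 72 (multi-b) and 36 (two-b) ROIs on 60×60×4
grids — large enough that every ROI supports non-degenerate 128-level
GLCMs after 3× downsampling, small enough that the complete two-cohort
analysis runs in well under a minute. All randomness flows from master
seeds through `numpy.random.SeedSequence`; identical inputs give
bit-identical tables.

## Known limitations

* The asymptotic KS p-value is anti-conservative for very small
  cohorts; exact-method support was deliberately left out.
* Phantom prostate SNR is far higher than clinical prostate DWI, so the
  two-b cohort does not show the noise sensitivity a real low-SNR
  cohort would; the multi-b cohort does.
* Resampling via k-space truncation is not offered; the interpolation
  choice is a documented config option, not an acquisition simulation.
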