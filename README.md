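# adctexture

Sensitivity analysis of Haralick texture features computed from apparent
diffusion coefficient (ADC) maps.

## The problem

Gray-level co-occurrence matrix (GLCM) texture features are widely used
on ADC maps from diffusion-weighted MRI (DWI) to characterise tumour
heterogeneity, but their values depend not only on the tissue: they also
depend on how the image was acquired and pre-processed. This package
quantifies that dependence for five parameters — in-plane resolution,
image noise, the b-value subset used to fit the ADC map, the number of
gray levels N (the GLCM size), and the quantization method (AutoROI /
AutoSlice / Manual limits) — by varying one parameter at a time around a
reference workflow and testing whether the resulting feature
distributions over a cohort of ROIs differ.

Because clinical tumour DWI is not redistributable, the cohorts here are
synthetic: seeded phantoms with spatially correlated ADC texture inside
ellipsoidal ROIs, mono-exponential signal decay
`S(b) = S0 · exp(−b · ADC · 10⁻⁶)`, additive Gaussian noise, and
optional adjacent fluid-like structures (ADC ≈ 3000 × 10⁻⁶ mm²/s,
a CSF/urine analogue) that can overlap the ROI boundary.

## The method

Per ROI and per setting, the five-step chain is

1. resample the DWI in-plane (block averaging for integer factors),
2. add Gaussian noise so the total noise std is `factor · σ_native`
   (glioma-like protocol σ = 17, prostate-like σ = 2.5),
3. fit ADC per voxel by ordinary least squares of ln S on b,
4. choose the GLCM size N,
5. quantize the in-ROI ADC values to gray levels 1..N.

Symmetric GLCMs are built per slice from all eight in-plane neighbour
directions, summed over the ROI and normalized to a joint probability
matrix `p(i,j)` with `Σ p(i,j) = 1`. Nineteen Haralick features
(contrast `Σ(i−j)²p(i,j)`, energy `Σp²`, entropy `−Σp·ln p`,
homogeneity `Σ p/(1+(i−j)²)`, correlation, the sum/difference
statistics, the information measures of correlation, …) are evaluated
on each matrix. For every feature and every unordered pair of settings
of a varied parameter, a two-sample Kolmogorov–Smirnov test compares
the feature's distribution over ROIs between the two settings
(475 tests for the multi-b design, 361 for the two-b design, 836
jointly), each at α = 0.01 with Bonferroni correction; a parameter
significantly affects a feature if any of its setting pairs does.

## Worked example

```python
import adctexture as at

proto = at.make_protocol("glioma")       # b = 0..1000, voxel 1.2 mm, sigma 17
spec = at.PhantomSpec(seed=3)            # textured ADC field, mean 1000
adc, roi = at.generate_adc_phantom(spec)
dwi = at.simulate_dwi(adc, 1000.0, proto, noise_sigma=17.0, seed=1)
fit = at.fit_adc(dwi, proto.b_values)
q = at.quantize_roi(fit, roi, at.QuantizationScheme("AutoROI", 32))
P = at.glcm_roi(q)
f = at.compute_features(P)
print(round(P.p.sum(), 12), round(f["contrast"], 2), round(f["entropy"], 2))
```

prints `1.0 6.48 5.34`: the normalized GLCM sums to one, followed by
this phantom's 32-level contrast and entropy. Re-quantizing the same
ROI at N = 128 raises contrast roughly sixteen-fold (6.48 → 100.9) —
GLCM size is the strongest single effect in the whole analysis, which
is why comparing texture values across studies requires a fixed number
of gray levels.

The cohort-scale analysis lives in `analysis/01…04` (thin drivers over
the library that write TSV tables under `results/`), or via the CLI:

```
adctexture simulate  --protocol glioma --batch-size 72 --seed 1 --output-dir phantoms
adctexture features  phantoms --output-dir out
adctexture sensitivity out/features.tsv --output-dir out
adctexture perturb   --n-phantoms 20 --output-dir out
```

On the default 72-ROI glioma-like cohort the analysis reproduces the
expected qualitative pattern: the b-value subset changes **no** feature
(mono-exponential decay makes all subsets estimate the same ADC), while
GLCM size, quantization method, resolution and noise significantly
shift most features, including contrast, energy, entropy and
homogeneity. The one-voxel ROI-expansion experiment shows fixed Manual
limits are less sensitive than AutoROI for a majority of features when
fluid borders the ROI.

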