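"""One-at-a-time sensitivity analysis of texture features.

The experimental design varies five acquisition/pre-processing
parameters one at a time around a fixed reference setting (resolution
1.0x, noise 1.0x, the reference b-value subset, 32 gray levels,
AutoROI quantization):

* resolution factor: 1.0, 1.5, 3.0
* noise factor:      1.0, 2.0, 4.0
* b-value subset (multi-b protocols only): four combinations
* gray levels (GLCM size): 8, 16, 32, 64, 128
* quantization method: AutoROI, AutoSlice, Manual

For every ROI and every setting, the pipeline
resample -> add_noise -> fit_adc -> quantize -> GLCM -> features
produces the 19 feature values.  Per (parameter, feature), every
unordered pair of settings is compared across ROIs with a two-sample
Kolmogorov-Smirnov test; a parameter is deemed to significantly affect
a feature if any pair falls below the Bonferroni-corrected alpha.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import special

from .features import FEATURE_NAMES, compute_features
from .glcm import glcm_roi
from .preproc import ADCVolume, add_noise, fit_adc, resample, resample_mask
from .quantize import QuantizationScheme, quantize_roi
from .synthetic import ProtocolSpec, make_protocol

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineSetting",
    "ExperimentDesign",
    "run_design",
    "ks_two_sample",
    "all_pairs_tests",
    "count_tests",
    "bonferroni_threshold",
    "roi_perturbation",
    "SensitivityResult",
]

GLIOMA_B_SUBSETS: tuple[tuple[float, ...], ...] = (
    (0.0, 1000.0),
    (200.0, 1000.0),
    (0.0, 200.0, 400.0, 600.0, 800.0, 1000.0),
    (200.0, 400.0, 600.0, 800.0, 1000.0),
)


@dataclass(frozen=True)
class PipelineSetting:
    """One fully specified run of the five-step pre-processing chain."""

    resolution_factor: float
    noise_factor: float
    b_subset: tuple[float, ...]
    n_levels: int
    method: str


@dataclass(frozen=True)
class ExperimentDesign:
    """The one-at-a-time design for one protocol.

    ``manual_limits`` are the cohort-level Manual quantization bounds
    (1e-6 mm^2/s).  ``n_tests_total`` overrides the Bonferroni
    denominator (e.g. 836 when a multi-b and a two-b design are analysed
    jointly); by default a design corrects for its own test count.
    """

    protocol: ProtocolSpec
    resolution_factors: tuple[float, ...] = (1.0, 1.5, 3.0)
    noise_factors: tuple[float, ...] = (1.0, 2.0, 4.0)
    b_subsets: tuple[tuple[float, ...], ...] | None = None
    gray_levels: tuple[int, ...] = (8, 16, 32, 64, 128)
    quant_methods: tuple[str, ...] = ("AutoROI", "AutoSlice", "Manual")
    reference_b_subset: tuple[float, ...] = ()
    manual_limits: tuple[float, float] = (0.0, 3000.0)
    alpha: float = 0.01
    n_tests_total: int | None = None

    @classmethod
    def glioma(cls, **kw) -> "ExperimentDesign":
        return cls(protocol=make_protocol("glioma"),
                   b_subsets=GLIOMA_B_SUBSETS,
                   reference_b_subset=(200.0, 400.0, 600.0, 800.0, 1000.0),
                   manual_limits=(0.0, 3000.0), **kw)

    @classmethod
    def prostate(cls, **kw) -> "ExperimentDesign":
        return cls(protocol=make_protocol("prostate"),
                   b_subsets=None,
                   reference_b_subset=(0.0, 800.0),
                   manual_limits=(0.0, 2400.0), **kw)

    @property
    def reference(self) -> PipelineSetting:
        return PipelineSetting(1.0, 1.0, tuple(self.reference_b_subset), 32, "AutoROI")

    def varied_parameters(self) -> dict[str, list]:
        varied = {
            "resolution": list(self.resolution_factors),
            "noise": list(self.noise_factors),
        }
        if self.b_subsets is not None:
            varied["b_values"] = [tuple(b) for b in self.b_subsets]
        varied["gray_levels"] = list(self.gray_levels)
        varied["quantization"] = list(self.quant_methods)
        return varied

    def settings_for(self, parameter: str) -> list[tuple[str, PipelineSetting]]:
        """(label, setting) pairs for one varied parameter, others at reference."""
        ref = self.reference
        out = []
        for value in self.varied_parameters()[parameter]:
            if parameter == "resolution":
                s = PipelineSetting(value, ref.noise_factor, ref.b_subset,
                                    ref.n_levels, ref.method)
                label = f"{value:g}x"
            elif parameter == "noise":
                s = PipelineSetting(ref.resolution_factor, value, ref.b_subset,
                                    ref.n_levels, ref.method)
                label = f"{value:g}x"
            elif parameter == "b_values":
                s = PipelineSetting(ref.resolution_factor, ref.noise_factor,
                                    tuple(value), ref.n_levels, ref.method)
                label = "b=" + ",".join(f"{b:g}" for b in value)
            elif parameter == "gray_levels":
                s = PipelineSetting(ref.resolution_factor, ref.noise_factor,
                                    ref.b_subset, int(value), ref.method)
                label = f"N={value}"
            elif parameter == "quantization":
                s = PipelineSetting(ref.resolution_factor, ref.noise_factor,
                                    ref.b_subset, ref.n_levels, str(value))
                label = str(value)
            else:
                raise KeyError(parameter)
            out.append((label, s))
        return out


def _run_setting(dwi, mask, setting: PipelineSetting, design: ExperimentDesign,
                 noise_seed: int) -> dict[str, float]:
    dwi_r = resample(dwi, setting.resolution_factor)
    mask_r = resample_mask(mask, setting.resolution_factor)
    dwi_n = add_noise(dwi_r, design.protocol.native_noise_sigma,
                      setting.noise_factor, noise_seed)
    adc = fit_adc(dwi_n, setting.b_subset)
    if setting.method == "Manual":
        scheme = QuantizationScheme("Manual", setting.n_levels,
                                    manual_min=design.manual_limits[0],
                                    manual_max=design.manual_limits[1])
    else:
        scheme = QuantizationScheme(setting.method, setting.n_levels)
    q = quantize_roi(adc, mask_r, scheme)
    return compute_features(glcm_roi(q))


def run_design(phantoms, design: ExperimentDesign, seed: int = 0) -> pd.DataFrame:
    """Execute the full one-at-a-time design over a batch of ROIs.

    ``phantoms`` is a sequence of (DWISeries, mask) pairs already carrying
    their native noise.  Returns a long-format feature table with columns
    ``roi``, ``parameter``, ``setting`` and one column per feature.  The
    added-noise seed for each (ROI, noise factor) is derived from ``seed``
    only, so the reference setting is bit-identical wherever it recurs and
    a failed stage marks one row missing without stopping the run.
    """
    phantoms = list(phantoms)
    if len(phantoms) == 0:
        raise ValueError("phantom batch must be non-empty")
    ss = np.random.SeedSequence(seed)
    roi_seeds = ss.generate_state(len(phantoms)) % (2**31)
    rows = []
    for r, (dwi, mask) in enumerate(phantoms):
        cache: dict[PipelineSetting, dict[str, float]] = {}
        for parameter in design.varied_parameters():
            for label, setting in design.settings_for(parameter):
                if setting not in cache:
                    noise_seed = int((roi_seeds[r]
                                      + int(setting.noise_factor * 1000)) % (2**31))
                    try:
                        cache[setting] = _run_setting(dwi, mask, setting, design,
                                                      noise_seed)
                    except Exception:
                        logger.exception("pipeline failed for roi=%d %s=%s; "
                                         "row marked missing", r, parameter, label)
                        cache[setting] = {f: math.nan for f in FEATURE_NAMES}
                rows.append({"roi": r, "parameter": parameter, "setting": label,
                             **cache[setting]})
    return pd.DataFrame(rows)


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p-value).

    D is the supremum gap between the two empirical CDFs; the p-value is
    the classic asymptotic Kolmogorov survival function evaluated at
    sqrt(n_a*n_b/(n_a+n_b)) * D.  Missing values are dropped; fewer than
    two values on either side yields (nan, nan) and a logged warning.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = np.sort(a[np.isfinite(a)]), np.sort(b[np.isfinite(b)])
    if a.size < 2 or b.size < 2:
        logger.warning("ks_two_sample: insufficient sample (%d vs %d)", a.size, b.size)
        return (math.nan, math.nan)
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / a.size
    cdf_b = np.searchsorted(b, grid, side="right") / b.size
    d = float(np.abs(cdf_a - cdf_b).max())
    en = math.sqrt(a.size * b.size / (a.size + b.size))
    p = float(special.kolmogorov(en * d))
    return (d, p)


def count_tests(design: ExperimentDesign) -> int:
    """Number of (feature, setting-pair) KS tests implied by a design."""
    n_pairs = sum(math.comb(len(v), 2) for v in design.varied_parameters().values())
    return len(FEATURE_NAMES) * n_pairs


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise corrected per-test threshold alpha / n_tests."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class SensitivityResult:
    """All pairwise KS tests plus the parameter x feature aggregation."""

    pairwise: pd.DataFrame      # parameter, feature, setting_a, setting_b, D, p
    aggregated: pd.DataFrame    # parameter x feature minimum pairwise p
    significant: pd.DataFrame   # boolean mask, same shape as aggregated
    alpha: float
    n_tests: int
    threshold: float


def all_pairs_tests(table: pd.DataFrame, design: ExperimentDesign) -> SensitivityResult:
    """KS-test every unordered setting pair of every varied parameter.

    Aggregation per (parameter, feature) is the minimum pairwise p; the
    significance flag is set when any pair falls strictly below the
    Bonferroni threshold alpha / n_tests (n_tests defaults to this
    design's own count, or ``design.n_tests_total`` when given).
    """
    n_tests = design.n_tests_total or count_tests(design)
    threshold = bonferroni_threshold(design.alpha, n_tests)
    recs = []
    for parameter in design.varied_parameters():
        labels = [lab for lab, _ in design.settings_for(parameter)]
        sub = table[table["parameter"] == parameter]
        by_setting = {lab: sub[sub["setting"] == lab] for lab in labels}
        for la, lb in combinations(labels, 2):
            for feat in FEATURE_NAMES:
                d, p = ks_two_sample(by_setting[la][feat], by_setting[lb][feat])
                recs.append({"parameter": parameter, "feature": feat,
                             "setting_a": la, "setting_b": lb, "D": d, "p": p})
    pairwise = pd.DataFrame(recs)
    agg = (pairwise.groupby(["parameter", "feature"])["p"].min()
           .unstack("feature").reindex(columns=list(FEATURE_NAMES)))
    agg = agg.reindex(index=list(design.varied_parameters()))
    sig = agg < threshold
    return SensitivityResult(pairwise=pairwise, aggregated=agg, significant=sig,
                             alpha=design.alpha, n_tests=n_tests, threshold=threshold)


def dilate_roi(roi: np.ndarray) -> np.ndarray:
    """One-voxel in-plane dilation with 8-connectivity, slice by slice."""
    roi = np.asarray(roi, dtype=bool)
    out = np.zeros_like(roi)
    struct = np.ones((3, 3), dtype=bool)
    for z in range(roi.shape[2]):
        out[:, :, z] = ndi.binary_dilation(roi[:, :, z], structure=struct)
    return out


def roi_perturbation(adc: ADCVolume, roi: np.ndarray, *,
                     n_levels: int = 32,
                     manual_limits: tuple[float, float] = (500.0, 1500.0)
                     ) -> pd.DataFrame:
    """Feature change under a one-voxel ROI expansion, AutoROI vs Manual.

    Computes all 19 features on the original and the dilated ROI under
    both quantization schemes and reports the percentage change
    100*(f_dilated - f_orig)/f_orig per feature, plus the Manual/AutoROI
    ratio of those changes.  Features with f_orig == 0 (or undefined) are
    reported as NaN.
    """
    roi = np.asarray(roi, dtype=bool)
    big = dilate_roi(roi)
    schemes = {
        "AutoROI": QuantizationScheme("AutoROI", n_levels),
        "Manual": QuantizationScheme("Manual", n_levels,
                                     manual_min=manual_limits[0],
                                     manual_max=manual_limits[1]),
    }
    pct = {}
    for name, scheme in schemes.items():
        f0 = compute_features(glcm_roi(quantize_roi(adc, roi, scheme)))
        f1 = compute_features(glcm_roi(quantize_roi(adc, big, scheme)))
        pct[name] = {
            feat: (100.0 * (f1[feat] - f0[feat]) / f0[feat]
                   if np.isfinite(f0[feat]) and f0[feat] != 0 else math.nan)
            for feat in FEATURE_NAMES
        }
    out = pd.DataFrame({"autoroi_pct": pct["AutoROI"], "manual_pct": pct["Manual"]})
    out["manual_over_autoroi"] = out["manual_pct"] / out["autoroi_pct"]
    out.index.name = "feature"
    return out
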