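"""Pre-processing chain for diffusion-weighted MRI ahead of texture analysis.

The chain mirrors a typical ADC-map workflow: (1) resample the DWI series
in-plane, (2) inject additional Gaussian noise, (3) fit the apparent
diffusion coefficient (ADC) per voxel by log-linear regression of the
signal against the b-values.  ADC is carried internally in units of
1e-6 mm^2/s, so clinically familiar limits such as 0-3000 can be used
verbatim; the mono-exponential exponent therefore includes a 1e-6 factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

logger = logging.getLogger(__name__)

__all__ = ["DWISeries", "ADCVolume", "resample", "resample_mask", "add_noise", "fit_adc"]


@dataclass
class DWISeries:
    """A stack of 3-D signal volumes indexed by b-value.

    Parameters
    ----------
    signals : ndarray, shape (n_b, nx, ny, nz)
        Magnitude signal, one volume per b-value.
    b_values : ndarray, shape (n_b,)
        Diffusion weightings in s/mm^2, strictly increasing.
    voxel_size : float
        In-plane voxel size in mm.
    slice_thickness : float
        Through-plane thickness in mm (informational; slices are treated
        as independent planes downstream).
    """

    signals: np.ndarray
    b_values: np.ndarray
    voxel_size: float
    slice_thickness: float = 3.0

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        self.b_values = np.asarray(self.b_values, dtype=float)
        if self.signals.ndim != 4:
            raise ValueError("signals must be 4-D: (n_b, nx, ny, nz)")
        if self.signals.shape[0] != self.b_values.size:
            raise ValueError("one volume per b-value required")
        if self.b_values.size < 2 or np.any(np.diff(self.b_values) <= 0):
            raise ValueError("b_values must be strictly increasing with >= 2 entries")
        if np.any(self.b_values < 0):
            raise ValueError("b_values must be non-negative")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.signals.shape[1:]


@dataclass
class ADCVolume:
    """A 3-D apparent-diffusion-coefficient map in 1e-6 mm^2/s."""

    values: np.ndarray
    voxel_size: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ADC values must be finite")


def _is_integer(x: float) -> bool:
    return abs(x - round(x)) < 1e-9


def _out_shape(n: int, factor: float) -> int:
    return int(np.floor(n / factor + 1e-9))


def resample(dwi: DWISeries, factor: float) -> DWISeries:
    """Coarsen the in-plane resolution of a DWI series by ``factor``.

    Integer factors use local block averaging (each output voxel is the
    mean of a factor x factor block), which emulates acquiring at coarser
    resolution and the accompanying noise averaging.  Non-integer factors
    use linear interpolation onto the coarser grid.  Through-plane
    resolution is untouched.
    """
    if factor < 1:
        raise ValueError("resample factor must be >= 1 (upsampling not supported)")
    if _is_integer(factor) and round(factor) == 1:
        return DWISeries(dwi.signals.copy(), dwi.b_values.copy(),
                         dwi.voxel_size, dwi.slice_thickness)
    nb, nx, ny, nz = dwi.signals.shape
    if _is_integer(factor):
        f = int(round(factor))
        ox, oy = nx // f, ny // f
        cropped = dwi.signals[:, : ox * f, : oy * f, :]
        out = cropped.reshape(nb, ox, f, oy, f, nz).mean(axis=(2, 4))
    else:
        ox, oy = _out_shape(nx, factor), _out_shape(ny, factor)
        zf = (ox / nx, oy / ny, 1.0)
        out = np.stack(
            [ndi.zoom(dwi.signals[k], zf, order=1, mode="nearest", grid_mode=True)
             for k in range(nb)]
        )
    return DWISeries(out, dwi.b_values.copy(), dwi.voxel_size * factor,
                     dwi.slice_thickness)


def resample_mask(mask: np.ndarray, factor: float) -> np.ndarray:
    """Resample a binary ROI mask with the transform used by :func:`resample`.

    Masks are never interpolated: nearest-neighbour sampling keeps the
    result strictly binary.
    """
    if factor < 1:
        raise ValueError("resample factor must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    if _is_integer(factor) and round(factor) == 1:
        return mask.copy()
    nx, ny, nz = mask.shape
    if _is_integer(factor):
        f = int(round(factor))
        ox, oy = nx // f, ny // f
        return mask[f // 2: ox * f: f, f // 2: oy * f: f, :].copy()
    ox, oy = _out_shape(nx, factor), _out_shape(ny, factor)
    zf = (ox / nx, oy / ny, 1.0)
    out = ndi.zoom(mask.astype(np.uint8), zf, order=0, mode="nearest", grid_mode=True)
    return out.astype(bool)


def add_noise(dwi: DWISeries, native_sigma: float, factor: float,
              seed: int | np.random.SeedSequence) -> DWISeries:
    """Raise the total noise level of a DWI series to ``factor * native_sigma``.

    Independent zero-mean Gaussian noise with standard deviation
    ``native_sigma * sqrt(factor**2 - 1)`` is added to every voxel of every
    volume, so variances add to the target total.  ``factor == 1`` returns
    an unchanged copy.
    """
    if factor < 1:
        raise ValueError("noise factor must be >= 1")
    if native_sigma < 0:
        raise ValueError("native_sigma must be >= 0")
    if factor == 1 or native_sigma == 0:
        return DWISeries(dwi.signals.copy(), dwi.b_values.copy(),
                         dwi.voxel_size, dwi.slice_thickness)
    sigma_add = native_sigma * np.sqrt(factor**2 - 1.0)
    rng = np.random.default_rng(seed)
    noisy = dwi.signals + rng.normal(0.0, sigma_add, size=dwi.signals.shape)
    return DWISeries(noisy, dwi.b_values.copy(), dwi.voxel_size, dwi.slice_thickness)


def fit_adc(dwi: DWISeries, b_subset) -> ADCVolume:
    """Fit an ADC map by ordinary least squares of ln(S) against b.

    Per voxel, the slope of ln(S) over the chosen b-values gives
    ADC = -slope * 1e6 (reported in 1e-6 mm^2/s).  With exactly two
    b-values this reduces to ln(S(b1)/S(b2)) / (b2 - b1) * 1e6.

    Non-positive signals at voxels that still have at least two positive
    samples are clamped to 1e-3 of the series maximum before the log
    (clamp count recorded in ``meta``); voxels with fewer than two
    positive samples get ADC = 0 and are tallied in ``meta['n_zeroed']``.
    """
    b = np.asarray(b_subset, dtype=float)
    if b.size < 2:
        raise ValueError("at least two b-values are required to fit ADC")
    idx = []
    for bv in b:
        matches = np.nonzero(np.isclose(dwi.b_values, bv, atol=1e-6))[0]
        if matches.size == 0:
            raise ValueError(f"b-value {bv} not present in the series")
        idx.append(matches[0])
    S = dwi.signals[idx]  # (k, nx, ny, nz)

    positive = S > 0
    n_pos = positive.sum(axis=0)
    degenerate = n_pos < 2

    floor = 1e-3 * float(S.max()) if S.max() > 0 else 1e-12
    n_clamped = int(np.count_nonzero((~positive) & ~degenerate[None]))
    S_cl = np.clip(S, floor, None)
    y = np.log(S_cl)

    bc = b - b.mean()
    slope = np.tensordot(bc, y, axes=(0, 0)) / (bc**2).sum()
    adc = -slope * 1e6
    n_zeroed = int(np.count_nonzero(degenerate))
    if n_zeroed:
        adc[degenerate] = 0.0
        logger.warning("fit_adc: %d voxel(s) with <2 positive signals set to ADC=0",
                       n_zeroed)
    if n_clamped:
        logger.warning("fit_adc: clamped %d non-positive signal sample(s) before log",
                       n_clamped)
    return ADCVolume(adc, dwi.voxel_size,
                     meta={"n_zeroed": n_zeroed, "n_clamped": n_clamped,
                           "b_subset": tuple(float(x) for x in b)})
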