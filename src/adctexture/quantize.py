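"""Gray-level quantization of ADC values inside an ROI.

Three schemes map continuous ADC values to integer gray levels 1..N:

* ``AutoROI``  -- limits are the min/max over the whole ROI volume.
* ``AutoSlice`` -- limits are the min/max of each ROI slice, computed
  independently per slice before that slice's GLCM.
* ``Manual``   -- fixed user-supplied limits; out-of-range values are
  clipped into the boundary bins.

Bins are uniform and half-open, [lo + (k-1)*d, lo + k*d) with
d = (hi-lo)/N and the top edge closed, so v = hi maps to level N.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .preproc import ADCVolume

logger = logging.getLogger(__name__)

__all__ = ["QuantizationScheme", "QuantizedROI", "quantize_roi", "choose_manual_limits"]

_METHODS = ("AutoROI", "AutoSlice", "Manual")


@dataclass(frozen=True)
class QuantizationScheme:
    method: str
    n_levels: int = 32
    manual_min: float | None = None
    manual_max: float | None = None

    def __post_init__(self) -> None:
        if self.method not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if self.method == "Manual":
            if self.manual_min is None or self.manual_max is None:
                raise ValueError("Manual quantization requires manual_min and manual_max")
            if not self.manual_min < self.manual_max:
                raise ValueError("manual_min must be < manual_max")


@dataclass
class QuantizedROI:
    """Integer gray levels 1..N on the ROI; 0 marks voxels outside the ROI."""

    labels: np.ndarray
    mask: np.ndarray
    n_levels: int

    def slice_indices(self) -> list[int]:
        """Indices of slices with at least one ROI voxel."""
        return [z for z in range(self.mask.shape[2]) if self.mask[:, :, z].any()]


def _bin(values: np.ndarray, lo: float, hi: float, n: int, clip: bool) -> np.ndarray:
    if hi <= lo:
        logger.warning("quantize: degenerate range [%g, %g]; all labels set to 1", lo, hi)
        return np.ones(values.shape, dtype=np.int32)
    v = np.clip(values, lo, hi) if clip else values
    lab = 1 + np.floor(n * (v - lo) / (hi - lo)).astype(np.int64)
    return np.clip(lab, 1, n).astype(np.int32)


def quantize_roi(adc: ADCVolume, roi: np.ndarray,
                 scheme: QuantizationScheme) -> QuantizedROI:
    """Quantize the ADC values inside ``roi`` to gray levels 1..N."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != adc.values.shape:
        raise ValueError("ROI mask shape must match the ADC volume")
    if not roi.any():
        raise ValueError("ROI mask is empty")
    n = scheme.n_levels
    labels = np.zeros(adc.values.shape, dtype=np.int32)

    if scheme.method == "AutoROI":
        vals = adc.values[roi]
        labels[roi] = _bin(vals, float(vals.min()), float(vals.max()), n, clip=False)
    elif scheme.method == "Manual":
        labels[roi] = _bin(adc.values[roi], float(scheme.manual_min),
                           float(scheme.manual_max), n, clip=True)
    else:  # AutoSlice
        for z in range(roi.shape[2]):
            m = roi[:, :, z]
            if not m.any():
                continue
            vals = adc.values[:, :, z][m]
            sl = labels[:, :, z]
            sl[m] = _bin(vals, float(vals.min()), float(vals.max()), n, clip=False)
            labels[:, :, z] = sl
    return QuantizedROI(labels, roi, n)


def choose_manual_limits(roi_adc_batches) -> tuple[float, float]:
    """Cohort-level manual limits from per-ROI value sets.

    Returns the lower quartile of the per-ROI minima and the upper
    quartile of the per-ROI maxima (linear interpolation between order
    statistics), i.e. limits that most ROIs' ranges fall within.
    """
    batches = [np.asarray(b, dtype=float).ravel() for b in roi_adc_batches]
    if len(batches) == 0:
        raise ValueError("need at least one ROI")
    if any(b.size == 0 for b in batches):
        raise ValueError("every ROI value set must be non-empty")
    minima = np.array([b.min() for b in batches])
    maxima = np.array([b.max() for b in batches])
    return (float(np.percentile(minima, 25)), float(np.percentile(maxima, 75)))
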