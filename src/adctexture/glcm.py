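"""Symmetric, directionally independent gray-level co-occurrence matrices.

Per slice, every ordered pair of 8-adjacent voxels that both lie inside
the ROI increments counts[ref, neigh]; sweeping all eight in-plane
directions (left, right, up, down and the four diagonals) makes the
count matrix symmetric and direction invariant.  Slice matrices are
summed over the ROI and normalized once, giving one joint probability
matrix p(i, j) per ROI with sum(p) == 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .quantize import QuantizedROI

logger = logging.getLogger(__name__)

__all__ = ["GLCMCounts", "NormalizedGLCM", "glcm_slice", "glcm_roi"]

# forward half of the 8-neighbourhood; the transpose adds the reverse sweep
_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


@dataclass
class GLCMCounts:
    counts: np.ndarray  # (N, N) int64
    n_levels: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class NormalizedGLCM:
    p: np.ndarray  # (N, N) float, sums to 1, symmetric
    n_levels: int


def glcm_slice(labels: np.ndarray, mask: np.ndarray, n_levels: int) -> GLCMCounts:
    """Co-occurrence counts for one quantized slice.

    ``labels`` holds gray levels 1..N (values outside ``mask`` are
    ignored).  Pairs are only counted when both voxels are inside the
    mask.  A slice with no valid neighbour pair yields a zero matrix and
    a warning, not an error, so thin ROI tips still process.
    """
    labels = np.asarray(labels)
    mask = np.asarray(mask, dtype=bool)
    if labels.ndim != 2 or mask.shape != labels.shape:
        raise ValueError("labels and mask must be matching 2-D arrays")
    n = int(n_levels)
    counts = np.zeros((n, n), dtype=np.int64)
    for dx, dy in _OFFSETS:
        xs = slice(max(dx, 0), labels.shape[0] + min(dx, 0))
        ys = slice(max(dy, 0), labels.shape[1] + min(dy, 0))
        xs2 = slice(max(-dx, 0), labels.shape[0] + min(-dx, 0))
        ys2 = slice(max(-dy, 0), labels.shape[1] + min(-dy, 0))
        valid = mask[xs, ys] & mask[xs2, ys2]
        a = labels[xs, ys][valid] - 1
        b = labels[xs2, ys2][valid] - 1
        np.add.at(counts, (a, b), 1)
    counts = counts + counts.T  # reverse directions: symmetric by construction
    if counts.sum() == 0:
        logger.warning("glcm_slice: no valid neighbour pairs; zero matrix returned")
    return GLCMCounts(counts, n)


def glcm_roi(q: QuantizedROI) -> NormalizedGLCM:
    """ROI-level normalized GLCM: slice counts summed, then normalized once."""
    total = np.zeros((q.n_levels, q.n_levels), dtype=np.int64)
    for z in q.slice_indices():
        total += glcm_slice(q.labels[:, :, z], q.mask[:, :, z], q.n_levels).counts
    grand = total.sum()
    if grand == 0:
        raise ValueError("ROI has no co-occurring voxel pairs (no texture support)")
    return NormalizedGLCM(total / grand, q.n_levels)
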