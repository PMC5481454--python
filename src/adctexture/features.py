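"""Haralick texture features of a normalized GLCM.

Nineteen scalar descriptors are computed as functionals of the joint
gray-level probability p(i, j), i, j = 1..N, together with its marginal
quantities (row/column marginals, sum and difference distributions, and
the entropies entering the information measures of correlation).

Conventions
-----------
* Natural logarithm for every entropy; 0 * log 0 := 0.
* Correlation is (sum_ij i*j*p(i,j) - mu_x*mu_y) / (sigma_x*sigma_y).
* Sum variance is centred on the sum average mu_{x+y} (the corrected
  definition), and difference variance on mu_{x-y}.
* Cluster features default to prominence = power 3 and shade = power 4;
  ``cluster_convention="conventional"`` swaps to the more widespread
  prominence = 4 / shade = 3 assignment.
* Correlation and information measure of correlation 1 are undefined on
  zero-variance / zero-entropy GLCMs and are reported as NaN (logged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .glcm import NormalizedGLCM

logger = logging.getLogger(__name__)

__all__ = ["FEATURE_NAMES", "Marginals", "compute_marginals", "compute_features"]

FEATURE_NAMES: tuple[str, ...] = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "contrast",
    "correlation",
    "difference_entropy",
    "difference_variance",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity",
    "imc1",
    "imc2",
    "inverse_difference",
    "maximum_probability",
    "sum_average",
    "sum_entropy",
    "sum_of_squares",
    "sum_variance",
)


def _neg_xlogx(p: np.ndarray) -> float:
    """-sum p*log p with the 0*log 0 = 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


@dataclass
class Marginals:
    p_x: np.ndarray          # row marginal, index i = 1..N
    p_y: np.ndarray          # column marginal
    mu: float                # overall gray-level mean sum_i i*p_x(i)
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    p_sum: np.ndarray        # p_{x+y}(k), k = 2..2N
    p_diff: np.ndarray       # p_{x-y}(k), k = 0..N-1
    mu_sum: float            # mu_{x+y}
    mu_diff: float           # mu_{x-y}
    hx: float
    hy: float
    hxy: float
    hxy1: float
    hxy2: float


def compute_marginals(P: NormalizedGLCM | np.ndarray) -> Marginals:
    """All marginal quantities of a normalized GLCM."""
    p = P.p if isinstance(P, NormalizedGLCM) else np.asarray(P, dtype=float)
    n = p.shape[0]
    i = np.arange(1, n + 1, dtype=float)
    p_x = p.sum(axis=1)
    p_y = p.sum(axis=0)
    mu_x = float((i * p_x).sum())
    mu_y = float((i * p_y).sum())
    sigma_x = float(np.sqrt(((i - mu_x) ** 2 * p_x).sum()))
    sigma_y = float(np.sqrt(((i - mu_y) ** 2 * p_y).sum()))

    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    p_sum = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * n - 1)
    p_diff = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=n)
    k_sum = np.arange(2, 2 * n + 1, dtype=float)
    k_diff = np.arange(0, n, dtype=float)
    mu_sum = float((k_sum * p_sum).sum())
    mu_diff = float((k_diff * p_diff).sum())

    pxpy = np.outer(p_x, p_y)
    pos = p > 0
    hxy1 = float(-(p[pos] * np.log(pxpy[pos])).sum()) if pos.any() else 0.0
    return Marginals(
        p_x=p_x, p_y=p_y,
        mu=mu_x, mu_x=mu_x, mu_y=mu_y, sigma_x=sigma_x, sigma_y=sigma_y,
        p_sum=p_sum, p_diff=p_diff, mu_sum=mu_sum, mu_diff=mu_diff,
        hx=_neg_xlogx(p_x), hy=_neg_xlogx(p_y), hxy=_neg_xlogx(p),
        hxy1=hxy1, hxy2=_neg_xlogx(pxpy),
    )


def compute_features(P: NormalizedGLCM | np.ndarray, *,
                     cluster_convention: str = "printed") -> dict[str, float]:
    """Evaluate the 19 texture features on a normalized GLCM.

    Returns a dict keyed by :data:`FEATURE_NAMES`.  ``cluster_convention``
    selects the exponent assignment of the two cluster features (see the
    module docstring).
    """
    if cluster_convention not in ("printed", "conventional"):
        raise ValueError("cluster_convention must be 'printed' or 'conventional'")
    p = P.p if isinstance(P, NormalizedGLCM) else np.asarray(P, dtype=float)
    n = p.shape[0]
    m = compute_marginals(p)
    i = np.arange(1, n + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    k_sum = np.arange(2, 2 * n + 1, dtype=float)
    k_diff = np.arange(0, n, dtype=float)

    prom_pow, shade_pow = (3, 4) if cluster_convention == "printed" else (4, 3)
    cluster_base = ii + jj - 2 * m.mu

    autocorr = float((ii * jj * p).sum())
    if m.sigma_x * m.sigma_y > 0:
        correlation = (autocorr - m.mu_x * m.mu_y) / (m.sigma_x * m.sigma_y)
    else:
        correlation = math.nan
        logger.warning("correlation undefined: zero marginal variance")
    denom = max(m.hx, m.hy)
    if denom > 0:
        imc1 = (m.hxy - m.hxy1) / denom
    else:
        imc1 = math.nan
        logger.warning("imc1 undefined: zero marginal entropy")
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (m.hxy2 - m.hxy))))

    return {
        "autocorrelation": autocorr,
        "cluster_prominence": float((cluster_base ** prom_pow * p).sum()),
        "cluster_shade": float((cluster_base ** shade_pow * p).sum()),
        "contrast": float(((ii - jj) ** 2 * p).sum()),
        "correlation": float(correlation),
        "difference_entropy": _neg_xlogx(m.p_diff),
        "difference_variance": float(((k_diff - m.mu_diff) ** 2 * m.p_diff).sum()),
        "dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "energy": float((p ** 2).sum()),
        "entropy": m.hxy,
        "homogeneity": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "imc1": float(imc1),
        "imc2": float(imc2),
        "inverse_difference": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "maximum_probability": float(p.max()),
        "sum_average": m.mu_sum,
        "sum_entropy": _neg_xlogx(m.p_sum),
        "sum_of_squares": float(((ii - m.mu) ** 2 * p).sum()),
        "sum_variance": float(((k_sum - m.mu_sum) ** 2 * m.p_sum).sum()),
    }
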