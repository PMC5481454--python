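"""Naive, loop-based reference implementations used as independent oracles.

Everything here is written with plain Python loops and ``math`` so it
shares no code path with the vectorized implementations under test.
"""

from __future__ import annotations

import math


def naive_glcm_counts(labels, mask, n_levels):
    """Brute-force co-occurrence counts: every ordered 8-adjacent pair
    with both voxels inside the mask."""
    rows, cols = len(labels), len(labels[0])
    counts = [[0] * n_levels for _ in range(n_levels)]
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
               (0, 1), (1, -1), (1, 0), (1, 1)]
    for x in range(rows):
        for y in range(cols):
            if not mask[x][y]:
                continue
            for dx, dy in offsets:
                u, v = x + dx, y + dy
                if 0 <= u < rows and 0 <= v < cols and mask[u][v]:
                    counts[labels[x][y] - 1][labels[u][v] - 1] += 1
    return counts


def naive_features(p):
    """The 19 texture features evaluated with explicit double loops.

    ``p`` is a square list-of-lists (or array) of probabilities summing
    to one.  Cluster prominence uses power 3 and cluster shade power 4.
    Natural log; 0*log 0 = 0.  Correlation/imc1 are nan when undefined.
    """
    n = len(p)
    idx = list(range(1, n + 1))

    px = [sum(p[i - 1][j - 1] for j in idx) for i in idx]
    py = [sum(p[i - 1][j - 1] for i in idx) for j in idx]
    mu_x = sum(i * px[i - 1] for i in idx)
    mu_y = sum(j * py[j - 1] for j in idx)
    sigma_x = math.sqrt(sum((i - mu_x) ** 2 * px[i - 1] for i in idx))
    sigma_y = math.sqrt(sum((j - mu_y) ** 2 * py[j - 1] for j in idx))
    mu = mu_x

    p_sum = {k: 0.0 for k in range(2, 2 * n + 1)}
    p_diff = {k: 0.0 for k in range(0, n)}
    for i in idx:
        for j in idx:
            p_sum[i + j] += p[i - 1][j - 1]
            p_diff[abs(i - j)] += p[i - 1][j - 1]
    mu_sum = sum(k * v for k, v in p_sum.items())
    mu_diff = sum(k * v for k, v in p_diff.items())

    def ent(values):
        return -sum(v * math.log(v) for v in values if v > 0)

    hx, hy = ent(px), ent(py)
    hxy = ent(p[i - 1][j - 1] for i in idx for j in idx)
    hxy1 = -sum(p[i - 1][j - 1] * math.log(px[i - 1] * py[j - 1])
                for i in idx for j in idx if p[i - 1][j - 1] > 0)
    hxy2 = ent(px[i - 1] * py[j - 1] for i in idx for j in idx)

    autocorr = sum(i * j * p[i - 1][j - 1] for i in idx for j in idx)
    corr = ((autocorr - mu_x * mu_y) / (sigma_x * sigma_y)
            if sigma_x * sigma_y > 0 else math.nan)
    imc1 = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else math.nan
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))

    return {
        "autocorrelation": autocorr,
        "cluster_prominence": sum((i + j - 2 * mu) ** 3 * p[i - 1][j - 1]
                                  for i in idx for j in idx),
        "cluster_shade": sum((i + j - 2 * mu) ** 4 * p[i - 1][j - 1]
                             for i in idx for j in idx),
        "contrast": sum((i - j) ** 2 * p[i - 1][j - 1] for i in idx for j in idx),
        "correlation": corr,
        "difference_entropy": ent(p_diff.values()),
        "difference_variance": sum((k - mu_diff) ** 2 * v
                                   for k, v in p_diff.items()),
        "dissimilarity": sum(abs(i - j) * p[i - 1][j - 1]
                             for i in idx for j in idx),
        "energy": sum(p[i - 1][j - 1] ** 2 for i in idx for j in idx),
        "entropy": hxy,
        "homogeneity": sum(p[i - 1][j - 1] / (1 + (i - j) ** 2)
                           for i in idx for j in idx),
        "imc1": imc1,
        "imc2": imc2,
        "inverse_difference": sum(p[i - 1][j - 1] / (1 + abs(i - j))
                                  for i in idx for j in idx),
        "maximum_probability": max(p[i - 1][j - 1] for i in idx for j in idx),
        "sum_average": mu_sum,
        "sum_entropy": ent(p_sum.values()),
        "sum_of_squares": sum((i - mu) ** 2 * p[i - 1][j - 1]
                              for i in idx for j in idx),
        "sum_variance": sum((k - mu_sum) ** 2 * v for k, v in p_sum.items()),
    }


def naive_ks(a, b):
    """Sup ECDF gap and asymptotic Kolmogorov p-value, computed directly."""
    a, b = sorted(a), sorted(b)
    grid = sorted(set(a) | set(b))
    na, nb = len(a), len(b)

    def ecdf(sample, x):
        return sum(1 for v in sample if v <= x) / len(sample)

    d = max(abs(ecdf(a, x) - ecdf(b, x)) for x in grid)
    en = math.sqrt(na * nb / (na + nb))
    lam = en * d
    # Kolmogorov survival series Q(lam) = 2 sum_{k>=1} (-1)^{k-1} exp(-2 k^2 lam^2)
    if lam <= 0:
        p = 1.0
    else:
        p = 2.0 * sum((-1) ** (k - 1) * math.exp(-2.0 * k * k * lam * lam)
                      for k in range(1, 101))
    return d, min(max(p, 0.0), 1.0)


def random_symmetric_glcm(rng, n):
    """A random normalized symmetric matrix for oracle comparisons."""
    m = rng.random((n, n))
    m = m + m.T
    return m / m.sum()
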