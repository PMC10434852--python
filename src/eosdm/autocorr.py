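"""Spatial autocorrelation diagnostics: Moran's I and the empirical semivariogram.

Used to verify the working assumption that abundance observations from
different survey units are spatially independent.  Moran's I uses binary
distance-band weights and a permutation null; the semivariogram reports
semivariance per lag bin for visual examination.  No pass/fail verdict is
attached — the diagnostics are reported as statistics.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = ["morans_i", "empirical_semivariogram"]


def morans_i(
    values,
    coords,
    radius: float,
    n_permutations: int = 999,
    seed: int = 0,
    alternative: str = "greater",
) -> dict:
    """Moran's I with binary distance-band weights and a permutation test.

    I = (n / W) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2
    with w_ij = 1 iff 0 < d_ij <= radius.  The expectation under the null is
    E[I] = -1/(n-1); the p-value comes from ``n_permutations`` random
    relabelings of the values over the locations.  ``alternative`` is
    "greater" (positive autocorrelation, default), "less" or "two-sided".
    """
    x = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 units")
    if np.allclose(x, x[0]):
        raise ValueError("Moran's I undefined for constant values")
    d = squareform(pdist(coords))
    w = (d > 0) & (d <= radius)
    W = w.sum()
    if W == 0:
        raise ValueError("no neighbour pairs within the distance band")
    w = w.astype(float)

    def stat(v):
        z = v - v.mean()
        return n / W * float(z @ w @ z) / float(z @ z)

    I_obs = stat(x)
    expected = -1.0 / (n - 1)
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for k in range(n_permutations):
        perms[k] = stat(rng.permutation(x))
    p_greater = (1 + np.sum(perms >= I_obs)) / (n_permutations + 1)
    p_less = (1 + np.sum(perms <= I_obs)) / (n_permutations + 1)
    if alternative == "greater":
        p = p_greater
    elif alternative == "less":
        p = p_less
    elif alternative == "two-sided":
        p = min(1.0, 2 * min(p_greater, p_less))
    else:
        raise ValueError("alternative must be greater/less/two-sided")
    return {
        "I": float(I_obs),
        "expected": float(expected),
        "p": float(p),
        "alternative": alternative,
        "n": int(n),
        "n_permutations": int(n_permutations),
        "radius": float(radius),
    }


def empirical_semivariogram(values, coords, bin_width: float, max_lag: float | None = None) -> dict:
    """Empirical semivariogram gamma(h) = (1/2N_h) sum (x_i - x_j)^2 per lag bin.

    Returns bin edges, bin-centre lags, semivariance per bin and pair counts;
    bins without pairs carry NaN semivariance.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    x = np.asarray(values, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 units")
    d = pdist(coords)
    sq = pdist(x[:, None], metric="sqeuclidean")
    if max_lag is None:
        max_lag = float(d.max())
    edges = np.arange(0.0, max_lag + bin_width, bin_width)
    if edges[-1] < max_lag:
        edges = np.append(edges, max_lag)
    idx = np.digitize(d, edges[1:], right=True)
    n_bins = len(edges) - 1
    gamma = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = sel.sum()
        if counts[b]:
            gamma[b] = 0.5 * sq[sel].mean()
    return {
        "bin_edges": edges,
        "lags": 0.5 * (edges[:-1] + edges[1:]),
        "semivariance": gamma,
        "pair_counts": counts,
    }
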