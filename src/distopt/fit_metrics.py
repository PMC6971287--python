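"""Error functions driving the evolutionary fit.

Two terms make up the fitness:

* a Pearson chi-square distribution error comparing observed bin counts k_j
  with model-expected counts p_j N, where p_j is the mixture probability of
  bin j (CDF difference between the bin edges);
* a mode-overlap error: for each component, the fraction of its weighted
  density mass at the data points that is covered by the largest competing
  component, maximized over components. 0 means fully separated modes, 1
  means a component entirely underneath another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr

from .gmm_core import MixtureModel, _pdf_matrix

__all__ = [
    "BinnedSample",
    "default_bin_count",
    "bin_data",
    "expected_counts",
    "chi_square_error",
    "component_overlap_error",
    "overlap_error",
]

# Bin probabilities are floored at EXPECTED_FLOOR_SCALE / B before scaling by
# N, so empty tails cannot blow up the chi-square denominator.
EXPECTED_FLOOR_SCALE = 1e-4


@dataclass(frozen=True)
class BinnedSample:
    """Histogram substrate for the chi-square error: edges, counts, sample size."""

    edges: np.ndarray
    observed: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        observed = np.asarray(self.observed)
        if edges.ndim != 1 or edges.size < 3:
            raise ValueError("need at least 2 bins (3 edges)")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if observed.shape != (edges.size - 1,):
            raise ValueError("observed counts must have one entry per bin")
        if np.any(observed < 0):
            raise ValueError("observed counts must be non-negative")
        if int(observed.sum()) != int(self.n_total):
            raise ValueError("observed counts must sum to n_total")
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "observed", np.asarray(observed, dtype=np.int64))
        object.__setattr__(self, "n_total", int(self.n_total))

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1


def default_bin_count(data) -> int:
    """Bin count from the Scott-type bandwidth h = 3.49 sd n^(-1/3).

    B = ceil(range / h), clamped to [2, n]. Deterministic; raises on constant
    data or n < 2 where the rule is undefined.
    """
    data = np.asarray(data, dtype=float)
    n = data.size
    if n < 2:
        raise ValueError("bin-count rule needs at least two observations")
    sd = float(np.std(data, ddof=1))
    rng = float(data.max() - data.min())
    if sd == 0.0 or rng == 0.0:
        raise ValueError("bin-count rule is undefined for constant data")
    h = 3.49 * sd * n ** (-1.0 / 3.0)
    return int(min(max(math.ceil(rng / h), 2), n))


def bin_data(data, n_bins: int) -> BinnedSample:
    """Split [min, max] of the data into equal-width bins and count occupants.

    Bins are left-closed; the last bin is closed on both sides so the maximum
    lands in it.
    """
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("cannot bin an empty sample")
    if n_bins < 2:
        raise ValueError(f"need at least 2 bins, got {n_bins}")
    observed, edges = np.histogram(data, bins=n_bins, range=(data.min(), data.max()))
    return BinnedSample(edges=edges, observed=observed, n_total=data.size)


def _bin_probabilities(edges: np.ndarray, means, sds, weights) -> np.ndarray:
    z = (edges[:, None] - np.asarray(means)[None, :]) / np.asarray(sds)[None, :]
    cdf = ndtr(z) @ np.asarray(weights)
    p = np.diff(cdf)
    return np.maximum(p, EXPECTED_FLOOR_SCALE / (edges.size - 1))


def expected_counts(binned: BinnedSample, model: MixtureModel) -> np.ndarray:
    """Model-expected count per bin: N times the (floored) bin probability."""
    p = _bin_probabilities(binned.edges, model.means, model.sds, model.weights)
    return p * binned.n_total


def _chi_square(edges, observed, n_total, means, sds, weights) -> float:
    expected = _bin_probabilities(edges, means, sds, weights) * n_total
    resid = observed - expected
    return float((resid * resid / expected).sum())


def chi_square_error(binned: BinnedSample, model: MixtureModel) -> float:
    """Pearson chi-square sum_j (k_j - p_j N)^2 / (p_j N); zero iff exact fit."""
    return _chi_square(
        binned.edges, binned.observed, binned.n_total,
        model.means, model.sds, model.weights,
    )


def _overlap_components(data: np.ndarray, means, sds, weights) -> np.ndarray:
    """Per-component overlap fractions, vectorized over components.

    own_im = alpha_m N(x_i; theta_m); other_im = max over j != m of
    alpha_j N(x_i; theta_j). The component's overlap is
    sum_i min(own, other) / sum_i own, in [0, 1].
    """
    weighted = _pdf_matrix(data, np.asarray(means, float), np.asarray(sds, float))
    weighted = weighted * np.asarray(weights, float)[None, :]
    n, m = weighted.shape
    # max over the other columns: global max unless the column holds it,
    # in which case the runner-up
    order = np.argsort(weighted, axis=1)
    top = order[:, -1]
    rows = np.arange(n)
    best = weighted[rows, top]
    second = weighted[rows, order[:, -2]]
    other = np.broadcast_to(best[:, None], (n, m)).copy()
    other[rows, top] = second
    own = weighted
    num = np.minimum(own, other).sum(axis=0)
    den = np.maximum(own.sum(axis=0), 1e-300)
    return num / den


def component_overlap_error(data, model: MixtureModel, m: int) -> float:
    """Overlap fraction of component m (0-based, ascending-mean order)."""
    data = np.asarray(data, dtype=float)
    if model.n_components < 2:
        raise ValueError("overlap error requires at least two components")
    if data.size == 0:
        raise ValueError("overlap error requires a non-empty sample")
    if not (0 <= m < model.n_components):
        raise IndexError(f"component index {m} out of range")
    return float(_overlap_components(data, model.means, model.sds, model.weights)[m])


def overlap_error(data, model: MixtureModel) -> float:
    """Overall overlap error: the worst (largest) per-component overlap."""
    data = np.asarray(data, dtype=float)
    if model.n_components < 2:
        raise ValueError("overlap error requires at least two components")
    if data.size == 0:
        raise ValueError("overlap error requires a non-empty sample")
    return float(_overlap_components(data, model.means, model.sds, model.weights).max())
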