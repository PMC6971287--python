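"""Univariate Gaussian mixture models: densities, likelihood, Bayesian
decision boundaries, classification, and model-comparison statistics.

A mixture is the weighted sum of M normal components

    p(x | Theta) = sum_m alpha_m N(x; mu_m, sigma_m),

with weights alpha_m >= 0 summing to 1. Components are kept in canonical
order (ascending mean) so that fitted models are comparable across runs
regardless of label switching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import ndtr

__all__ = [
    "GaussianComponent",
    "MixtureModel",
    "DecisionBoundaries",
    "component_pdf",
    "mixture_pdf",
    "mixture_cdf",
    "mixture_quantile",
    "log_likelihood",
    "aic",
    "lr_statistic",
    "bayes_boundaries",
    "classify",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

# Floor applied to the mixture density before taking logs, so that the
# log-likelihood (and hence any fitness built on it) stays finite even when
# an outlier sits hundreds of sigmas from every component.
DENSITY_FLOOR = 1e-300

_WEIGHT_SUM_TOL = 1e-9


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian mode: mean mu, standard deviation sigma > 0, weight alpha."""

    mean: float
    sd: float
    weight: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean):
            raise ValueError(f"component mean must be finite, got {self.mean}")
        if not (self.sd > 0) or not np.isfinite(self.sd):
            raise ValueError(f"component sd must be positive, got {self.sd}")
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"component weight must lie in [0, 1], got {self.weight}")


@dataclass(frozen=True)
class MixtureModel:
    """An ordered collection of weighted Gaussian components.

    Components are sorted by ascending mean on construction (canonical
    ordering); weights must sum to 1 within 1e-9.
    """

    components: tuple[GaussianComponent, ...]

    def __init__(self, components: Iterable[GaussianComponent]):
        comps = tuple(sorted(components, key=lambda c: c.mean))
        if len(comps) < 1:
            raise ValueError("a mixture needs at least one component")
        total = sum(c.weight for c in comps)
        if abs(total - 1.0) > _WEIGHT_SUM_TOL:
            raise ValueError(f"component weights must sum to 1, got {total!r}")
        object.__setattr__(self, "components", comps)

    @classmethod
    def from_arrays(
        cls,
        means: Sequence[float],
        sds: Sequence[float],
        weights: Sequence[float],
        normalize: bool = False,
    ) -> "MixtureModel":
        means = np.asarray(means, dtype=float)
        sds = np.asarray(sds, dtype=float)
        weights = np.asarray(weights, dtype=float)
        if not (means.shape == sds.shape == weights.shape) or means.ndim != 1:
            raise ValueError("means, sds and weights must be 1-D arrays of equal length")
        if normalize:
            total = weights.sum()
            if total <= 0:
                raise ValueError("weights must have a positive sum to normalize")
            weights = weights / total
        return cls(
            GaussianComponent(m, s, w) for m, s, w in zip(means, sds, weights)
        )

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def sds(self) -> np.ndarray:
        return np.array([c.sd for c in self.components])

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    def to_dict(self) -> dict:
        return {
            "components": [
                {"mean": c.mean, "sd": c.sd, "weight": c.weight}
                for c in self.components
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        return cls(
            GaussianComponent(c["mean"], c["sd"], c["weight"])
            for c in d["components"]
        )


@dataclass(frozen=True)
class DecisionBoundaries:
    """M-1 cut points partitioning the line into per-component classification cells."""

    cuts: tuple[float, ...]

    def __post_init__(self) -> None:
        cuts = tuple(float(c) for c in self.cuts)
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise ValueError(f"boundary cuts must be strictly increasing, got {cuts}")
        object.__setattr__(self, "cuts", cuts)


def component_pdf(x, c: GaussianComponent):
    """Normal density N(x; mu, sigma) of a single component (weight ignored)."""
    x = np.asarray(x, dtype=float)
    z = (x - c.mean) / c.sd
    return np.exp(-0.5 * z * z) / (c.sd * math.sqrt(2.0 * math.pi))


def _pdf_matrix(x: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    """Component densities at each point: shape (len(x), M)."""
    z = (x[:, None] - means[None, :]) / sds[None, :]
    return np.exp(-0.5 * z * z) / (sds[None, :] * math.sqrt(2.0 * math.pi))


def mixture_pdf(x, model: MixtureModel):
    """Mixture density sum_m alpha_m N(x; mu_m, sigma_m)."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    xv = np.atleast_1d(x)
    out = _pdf_matrix(xv, model.means, model.sds) @ model.weights
    return float(out[0]) if scalar else out


def mixture_cdf(x, model: MixtureModel):
    """Mixture distribution function sum_m alpha_m Phi((x - mu_m)/sigma_m)."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    xv = np.atleast_1d(x)
    z = (xv[:, None] - model.means[None, :]) / model.sds[None, :]
    out = ndtr(z) @ model.weights
    return float(out[0]) if scalar else out


def mixture_quantile(q: float, model: MixtureModel) -> float:
    """Inverse of mixture_cdf by bracketed root finding (|cdf(x) - q| <= 1e-10)."""
    from scipy.optimize import brentq

    if not (0.0 < q < 1.0):
        raise ValueError(f"quantile level must lie in (0, 1), got {q}")
    sd_max = float(model.sds.max())
    lo = float(model.means.min()) - 10.0 * sd_max
    hi = float(model.means.max()) + 10.0 * sd_max
    # widen until the bracket straddles q (cheap: cdf tails decay as exp(-z^2/2))
    while mixture_cdf(lo, model) > q:
        lo -= 10.0 * sd_max
    while mixture_cdf(hi, model) < q:
        hi += 10.0 * sd_max
    x = brentq(lambda t: mixture_cdf(t, model) - q, lo, hi, xtol=1e-13, rtol=1e-15)
    return float(x)


def log_likelihood(data, model: MixtureModel) -> float:
    """Sum of log mixture densities over the sample; densities floored at 1e-300."""
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("log_likelihood requires a non-empty sample")
    dens = np.maximum(mixture_pdf(data, model), DENSITY_FLOOR)
    return float(np.log(dens).sum())


def n_free_parameters(model: MixtureModel) -> int:
    """Free parameters of an M-component univariate GMM: M means, M sds, M-1 weights."""
    return 3 * model.n_components - 1


def aic(data, model: MixtureModel) -> float:
    """Akaike information criterion 2k - 2 logL with k = 3M - 1."""
    return 2.0 * n_free_parameters(model) - 2.0 * log_likelihood(data, model)


def lr_statistic(data, null_model: MixtureModel, alt_model: MixtureModel) -> float:
    """Likelihood-ratio statistic max(0, 2 (logL_alt - logL_null)).

    Only the statistic is returned: the chi-square reference distribution is
    invalid for mixtures (the null lies on the parameter-space boundary), so
    no p-value is attached.
    """
    if alt_model.n_components < null_model.n_components:
        raise ValueError("alternative model must have at least as many components")
    return max(0.0, 2.0 * (log_likelihood(data, alt_model) - log_likelihood(data, null_model)))


def _pair_boundary(c1: GaussianComponent, c2: GaussianComponent) -> float:
    """Cut between two mean-adjacent components: the x in [mu1, mu2] where the
    weight-scaled densities are equal.

    Equality of alpha1 N(x; mu1, s1) and alpha2 N(x; mu2, s2) in log form is a
    quadratic a x^2 + b x + c = 0. Equal sds make it linear with the closed
    form midpoint + sigma^2 ln(alpha1/alpha2)/(mu2 - mu1). If no root lies in
    [mu1, mu2] (one component dominates the whole interval), the cut is placed
    where |log-density difference| over the interval is minimal; with two
    in-interval roots the one nearest the midpoint of the means is used.
    """
    m1, s1, w1 = c1.mean, c1.sd, max(c1.weight, DENSITY_FLOOR)
    m2, s2, w2 = c2.mean, c2.sd, max(c2.weight, DENSITY_FLOOR)
    lo, hi = min(m1, m2), max(m1, m2)
    mid = 0.5 * (m1 + m2)

    a = -0.5 / s1**2 + 0.5 / s2**2
    b = m1 / s1**2 - m2 / s2**2
    c = (
        (math.log(w1) - math.log(s1) - 0.5 * m1**2 / s1**2)
        - (math.log(w2) - math.log(s2) - 0.5 * m2**2 / s2**2)
    )

    def q(x: float) -> float:
        return (a * x + b) * x + c

    roots: list[float] = []
    if abs(a) < 1e-300 * max(1.0, abs(b)):
        if b != 0.0:
            roots = [-c / b]
    else:
        disc = b * b - 4.0 * a * c
        if disc >= 0.0:
            r = math.sqrt(disc)
            roots = [(-b - r) / (2.0 * a), (-b + r) / (2.0 * a)]

    inside = [x for x in roots if lo - 1e-12 <= x <= hi + 1e-12]
    if inside:
        cut = min(inside, key=lambda x: abs(x - mid))
        return float(min(max(cut, lo), hi))

    # dominance fallback: minimize |q| over [lo, hi]; q is quadratic so the
    # minimizer is the clipped vertex or an endpoint
    candidates = [lo, hi]
    if a != 0.0:
        candidates.append(min(max(-b / (2.0 * a), lo), hi))
    return float(min(candidates, key=lambda x: abs(q(x))))


def bayes_boundaries(model: MixtureModel) -> DecisionBoundaries:
    """Bayesian decision borders between mean-adjacent components.

    For each adjacent pair the cut is the point where the two weight-scaled
    densities cross inside the interval between the means; it is the boundary
    of the maximum-posterior classification cells.
    """
    if model.n_components < 2:
        raise ValueError("decision boundaries require at least two components")
    cuts = [
        _pair_boundary(model.components[i], model.components[i + 1])
        for i in range(model.n_components - 1)
    ]
    return DecisionBoundaries(tuple(cuts))


def classify(data, model: MixtureModel) -> np.ndarray:
    """Assign each point to the component maximizing alpha_m N(x; mu_m, sigma_m).

    Labels run 1..M in ascending-mean order; ties go to the lower label.
    """
    data = np.atleast_1d(np.asarray(data, dtype=float))
    weighted = _pdf_matrix(data, model.means, model.sds) * model.weights[None, :]
    return np.argmax(weighted, axis=1) + 1
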