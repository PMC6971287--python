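"""Minimal univariate EM mixture fitter, used as the likelihood-maximizing
baseline the evolutionary fits are contrasted against.

Deterministic by default: means are initialized at evenly spread sample
quantiles, sds at the sample sd, weights uniform, so repeated runs on the
same data give identical results (no dependence on a random seed).
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.special import logsumexp

from .gmm_core import MixtureModel

__all__ = ["DegenerateComponentError", "em_fit"]

_LOG_2PI = np.log(2.0 * np.pi)

# A component whose total responsibility mass falls below this fraction of N
# has effectively lost all its data; the fit is reported as degenerate rather
# than silently repaired.
RESPONSIBILITY_FLOOR = 1e-10


class DegenerateComponentError(RuntimeError):
    """Raised when a component's responsibility mass collapses."""


def _quantile_init(data: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    qs = (2.0 * np.arange(m) + 1.0) / (2.0 * m)
    means = np.quantile(data, qs)
    sds = np.full(m, max(data.std(), 1e-12))
    weights = np.full(m, 1.0 / m)
    return means, sds, weights


def em_fit(
    data,
    n_components: int,
    max_iter: int = 500,
    tol: float = 1e-8,
    init: Optional[MixtureModel] = None,
    return_trace: bool = False,
):
    """Fit a univariate Gaussian mixture by Expectation Maximization.

    E-step: responsibilities r_im proportional to alpha_m N(x_i; mu_m, s_m).
    M-step: weighted moment updates. Stops when the log-likelihood improves
    by less than `tol` or after `max_iter` iterations. The log-likelihood is
    non-decreasing across iterations (EM guarantee); variances are floored at
    1e-8 times the squared data range to prevent singular collapse onto a
    single point.

    Returns the fitted MixtureModel, or (model, trace) with the per-iteration
    log-likelihood when return_trace is True.
    """
    data = np.asarray(data, dtype=float)
    n = data.size
    m = int(n_components)
    if m < 1:
        raise ValueError("need at least one component")
    if np.unique(data).size < m:
        raise ValueError(f"need at least {m} distinct values to fit {m} components")

    if init is not None:
        means, sds, weights = init.means.copy(), init.sds.copy(), init.weights.copy()
    else:
        means, sds, weights = _quantile_init(data, m)

    data_range = float(data.max() - data.min())
    var_floor = 1e-8 * data_range**2 if data_range > 0 else 1e-12

    trace: list[float] = []
    prev_ll = -np.inf
    for _ in range(max_iter):
        # E-step in log space
        log_dens = (
            -0.5 * ((data[:, None] - means[None, :]) / sds[None, :]) ** 2
            - np.log(sds)[None, :]
            - 0.5 * _LOG_2PI
            + np.log(np.maximum(weights, 1e-300))[None, :]
        )
        log_norm = logsumexp(log_dens, axis=1)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_dens - log_norm[:, None])

        mass = resp.sum(axis=0)
        if np.any(mass < RESPONSIBILITY_FLOOR * n):
            raise DegenerateComponentError(
                "a component's responsibility mass collapsed; "
                "reduce the number of components or supply a better init"
            )

        # M-step
        weights = mass / n
        means = (resp * data[:, None]).sum(axis=0) / mass
        var = (resp * (data[:, None] - means[None, :]) ** 2).sum(axis=0) / mass
        sds = np.sqrt(np.maximum(var, var_floor))

        if ll - prev_ll < tol and np.isfinite(prev_ll):
            break
        prev_ll = ll

    model = MixtureModel.from_arrays(means, sds, weights, normalize=True)
    if return_trace:
        return model, trace
    return model
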