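"""Synthetic Gaussian-mixture scenarios for tests, demos and benchmarks.

Real multimodal readouts of this kind (sensory thresholds, evoked-potential
amplitudes, log expression intensities) are not bundled; instead the built-in
scenarios reproduce the distribution *shapes* that matter for exercising the
fitter:

* ``trimodal_separated`` — three well-separated equal modes; the easy case
  every fitter should solve.
* ``four_modes`` — four moderately separated modes; tests model selection at
  a higher mode count.
* ``central_dominant`` — one dominant central mode flanked by two low-weight
  overlapping margin modes; the case where likelihood-only fitting tends to
  smear components together and mode separation pays off.
* ``superimposed`` — two components with identical means but different sds;
  maximal overlap, a shape the separation-seeking fitter is deliberately
  unsuited to (and should flag via its overlap error).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gmm_core import MixtureModel

__all__ = ["Scenario", "sample_mixture", "builtin_scenarios", "get_scenario"]


@dataclass(frozen=True)
class Scenario:
    """A named ground-truth mixture with a pinned sample size and seed."""

    name: str
    truth: MixtureModel
    n: int
    seed: int

    def __post_init__(self) -> None:
        if self.n < 30:
            raise ValueError("scenario sample size must be at least 30")

    def sample(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Draw the scenario's sample; uses the pinned seed unless an rng is given."""
        if rng is None:
            rng = np.random.default_rng(self.seed)
        return sample_mixture(self.truth, self.n, rng)


def sample_mixture(truth: MixtureModel, n: int, rng: np.random.Generator) -> np.ndarray:
    """Ancestral sampling: component index by weight, then a normal draw."""
    if n < 1:
        raise ValueError("sample size must be positive")
    idx = rng.choice(truth.n_components, size=n, p=truth.weights)
    return rng.normal(truth.means[idx], truth.sds[idx])


def builtin_scenarios() -> list[Scenario]:
    """The fixed, versioned scenario definitions (constants, pinned seeds)."""
    return [
        Scenario(
            name="trimodal_separated",
            truth=MixtureModel.from_arrays(
                means=[0.0, 5.0, 10.0],
                sds=[1.0, 1.0, 1.0],
                weights=[1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0],
            ),
            n=1000,
            seed=101,
        ),
        Scenario(
            name="four_modes",
            truth=MixtureModel.from_arrays(
                means=[0.0, 3.5, 7.0, 10.5],
                sds=[1.0, 1.0, 1.0, 1.0],
                weights=[0.25, 0.25, 0.25, 0.25],
            ),
            n=1000,
            seed=202,
        ),
        Scenario(
            name="central_dominant",
            truth=MixtureModel.from_arrays(
                means=[-3.0, 0.0, 3.0],
                sds=[1.5, 1.0, 1.5],
                weights=[0.15, 0.70, 0.15],
            ),
            n=1000,
            seed=303,
        ),
        Scenario(
            name="superimposed",
            truth=MixtureModel.from_arrays(
                means=[0.0, 1e-9],
                sds=[1.0, 3.0],
                weights=[0.5, 0.5],
            ),
            n=1000,
            seed=404,
        ),
    ]


def get_scenario(name: str) -> Scenario:
    for s in builtin_scenarios():
        if s.name == name:
            return s
    names = ", ".join(s.name for s in builtin_scenarios())
    raise KeyError(f"unknown scenario {name!r}; available: {names}")
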