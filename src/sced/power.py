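"""Minimal-p diagnostics and simulation-based power for randomization tests.

Randomization-test p-values are discrete: the smallest attainable p-value is
1/R, the reciprocal of the number of admissible assignments.  A design with
1/R > alpha therefore has exactly zero power at level alpha no matter how
large the effect — fewer than 20 admissible assignments cannot reach
significance at the conventional 0.05.  For everything else, power is
estimated by Monte Carlo simulation under the randomization model: each
replicate draws a true assignment uniformly, generates data conditional on
it from the effect model, runs the test, and records rejection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .design import DesignError
from .enumeration import _as_rng, count_assignments, sample_assignment
from .inference import randomization_test
from .stats import StatisticSpec
from .synth import EffectModel, generate_series

__all__ = ["PowerEstimate", "minimal_pvalue", "has_nonzero_power", "estimate_power"]


@dataclass(frozen=True)
class PowerEstimate:
    """Estimated rejection probability with its binomial Monte Carlo error."""

    alpha: float
    n_sims: int
    rejections: int
    power: float
    mc_stderr: float
    design_summary: str
    effect_summary: str
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "n_sims": self.n_sims,
            "rejections": self.rejections,
            "power": self.power,
            "mc_stderr": self.mc_stderr,
            "design": self.design_summary,
            "effect": self.effect_summary,
            "seed": self.seed,
        }


def minimal_pvalue(R: int) -> float:
    """Lowest attainable randomization-test p-value, 1/R."""
    if R < 1:
        raise DesignError("R must be a positive count of admissible assignments")
    return 1.0 / R


def has_nonzero_power(R: int, alpha: float = 0.05) -> bool:
    """Whether significance at level alpha is attainable at all (1/R <= alpha)."""
    if not 0 < alpha < 1:
        raise DesignError("alpha must lie in (0, 1)")
    return minimal_pvalue(R) <= alpha


def estimate_power(spec, statistic: StatisticSpec, effect_model: EffectModel,
                   alpha: float = 0.05, n_sims: int = 1000,
                   seed: Union[int, np.random.Generator, None] = None,
                   method: str = "auto", n_mc: int = 1000,
                   tail: Optional[str] = None,
                   fixed_assignment=None) -> PowerEstimate:
    """Design-consistent power: the true assignment is redrawn uniformly each
    replicate (pass ``fixed_assignment`` for a fixed-truth sensitivity check).

    When 1/R > alpha the rejection probability is identically zero and the
    estimate is returned exactly, with zero variance and no simulation.
    """
    if not 0 < alpha < 1:
        raise DesignError("alpha must lie in (0, 1)")
    if n_sims < 1:
        raise DesignError("n_sims must be >= 1")
    R = count_assignments(spec)
    design_summary = f"{spec.design_family}, R={R}"
    effect_summary = (f"mu={effect_model.mu}, delta={effect_model.delta}, "
                      f"sigma={effect_model.sigma}, ar1={effect_model.ar1}")
    seed_out = seed if isinstance(seed, int) else None
    if not has_nonzero_power(R, alpha):
        return PowerEstimate(alpha, n_sims, 0, 0.0, 0.0,
                             design_summary, effect_summary, seed_out)
    rng = _as_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        truth = fixed_assignment if fixed_assignment is not None else sample_assignment(spec, rng)
        data = generate_series(spec, truth, effect_model, rng)
        result = randomization_test(data, spec, statistic, truth, tail=tail,
                                    method=method, n_mc=n_mc, seed=rng, alpha=alpha)
        if result.reject:
            rejections += 1
    power = rejections / n_sims
    stderr = float(np.sqrt(power * (1.0 - power) / n_sims))
    return PowerEstimate(alpha, n_sims, rejections, power, stderr,
                         design_summary, effect_summary, seed_out)
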