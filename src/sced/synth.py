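"""Synthetic single-case series with known level shift, noise, trend and
lag-1 autocorrelation.

Randomization tests are distribution-free, so the generator's job is
controlled structure rather than realism: a baseline level, a condition
effect, Gaussian noise (optionally AR(1), in the stationary convention where
the marginal standard deviation stays ``sigma`` regardless of the
autocorrelation), and an optional within-phase linear trend.  Changing
criterion series follow the phase criterion schedule with adherence noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .design import (
    Assignment,
    ChangingCriterionSpec,
    DesignError,
    MeasurementSeries,
    MultipleBaselineSpec,
    is_admissible,
    labels_from_changepoints,
    runs_of,
)
from .enumeration import _as_rng

__all__ = ["EffectModel", "generate_series", "generate_ccd_series"]


@dataclass(frozen=True)
class EffectModel:
    """Data-generating parameters for synthetic single-case series.

    ``delta`` shifts every B-role occasion; ``shifts`` optionally gives a
    per-condition shift for designs with more than two conditions (it
    overrides ``delta``).  ``trend`` is a per-occasion slope applied within
    each phase, restarting at zero at every phase change.  ``ar1`` is the
    lag-1 autocorrelation of the stationary noise process.
    """

    mu: float = 0.0
    delta: float = 1.0
    sigma: float = 1.0
    ar1: float = 0.0
    trend: float = 0.0
    shifts: Optional[Mapping[str, float]] = None
    ccd_adherence_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise DesignError("sigma must be non-negative")
        if not -1 < self.ar1 < 1:
            raise DesignError("ar1 must lie strictly inside (-1, 1)")
        if self.ccd_adherence_sd < 0:
            raise DesignError("ccd_adherence_sd must be non-negative")

    def shift_for(self, label: str, b_labels: Tuple[str, ...]) -> float:
        if self.shifts is not None:
            return float(self.shifts.get(label, 0.0))
        return self.delta if label in b_labels else 0.0


def _ar1_noise(rng: np.random.Generator, n: int, sigma: float, phi: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal sd ``sigma``: the first draw is
    N(0, sigma), innovations have sd sigma*sqrt(1 - phi**2)."""
    if sigma == 0:
        return np.zeros(n)
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, sigma)
    innov_sd = sigma * np.sqrt(1.0 - phi * phi)
    white = rng.normal(0.0, innov_sd, size=n - 1) if n > 1 else np.empty(0)
    for t in range(1, n):
        eps[t] = phi * eps[t - 1] + white[t - 1]
    return eps


def _series_from_labels(unit_id: str, labels: Sequence[str], model: EffectModel,
                        b_labels: Tuple[str, ...], rng: np.random.Generator) -> MeasurementSeries:
    n = len(labels)
    signal = np.array([model.mu + model.shift_for(lab, b_labels) for lab in labels])
    if model.trend != 0.0:
        for _, start, length in runs_of(tuple(labels)):
            signal[start - 1:start - 1 + length] += model.trend * np.arange(length)
    y = signal + _ar1_noise(rng, n, model.sigma, model.ar1)
    return MeasurementSeries(unit_id=unit_id, values=tuple(y))


def generate_series(spec, assignment: Assignment, model: EffectModel,
                    seed: Union[int, np.random.Generator, None] = None,
                    b_labels: Tuple[str, ...] = ("B",)):
    """Generate a series (or, for multiple baseline designs, a list of
    per-unit series) under an admissible assignment.

    y_t = mu + shift(label_t) + trend within phase + AR(1) noise; bit-identical
    for identical seeds and parameters.
    """
    if not is_admissible(spec, assignment):
        raise DesignError("assignment is not admissible under the design spec")
    rng = _as_rng(seed)
    if isinstance(spec, MultipleBaselineSpec):
        out = []
        for u, start in enumerate(assignment.start_points):
            labels = ("A",) * (start - 1) + ("B",) * (spec.n - start + 1)
            out.append(_series_from_labels(f"unit{u + 1}", labels, model, b_labels, rng))
        return out
    if isinstance(spec, ChangingCriterionSpec):
        return generate_ccd_series(spec, assignment.change_points, model, rng)
    labels = assignment.labels
    if labels is None:
        labels = labels_from_changepoints(assignment.change_points, spec.n, spec.phase_pattern)
    return _series_from_labels("unit1", labels, model, b_labels, rng)


def generate_ccd_series(spec: ChangingCriterionSpec, change_points: Sequence[int],
                        model: EffectModel,
                        seed: Union[int, np.random.Generator, None] = None) -> MeasurementSeries:
    """Series that tracks the criterion schedule with adherence noise.

    Each occasion equals its phase criterion (midpoint for range criteria)
    plus N(0, ccd_adherence_sd).  Baseline occasions centre on the fixed
    baseline criterion when the rule is ``fixed``, else on ``mu``.
    """
    cps = tuple(int(c) for c in change_points)
    if not is_admissible(spec, Assignment(design_family="changing_criterion",
                                          change_points=cps)):
        raise DesignError("change points are not admissible under the spec")
    rng = _as_rng(seed)
    if spec.baseline_criterion_rule == "fixed":
        base_level = float(spec.baseline_criterion_value)
    else:
        base_level = model.mu
    levels = [base_level] + [(lo + hi) / 2.0 for lo, hi in spec.criterion_schedule]
    bounds = (1,) + cps + (spec.n + 1,)
    y = np.empty(spec.n)
    for level, a, b in zip(levels, bounds, bounds[1:]):
        y[a - 1:b - 1] = level
    y += rng.normal(0.0, model.ccd_adherence_sd, size=spec.n) if model.ccd_adherence_sd > 0 else 0.0
    return MeasurementSeries(unit_id="unit1", values=tuple(y))
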