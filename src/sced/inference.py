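"""Reference distributions and randomization-test p-values.

The randomization test evaluates the chosen statistic at every admissible
assignment of the design (exhaustive) or at a uniform random sample of them
(Monte Carlo), and locates the observed statistic in that reference
distribution.  The observed assignment is always a member of the reference
set, so p >= 1/R (exhaustive) or 1/n_mc (Monte Carlo) and the test is valid
by construction.  Monte Carlo draws are with replacement: n_mc - 1 sampled
assignments plus the observed, with denominator n_mc.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

from .design import Assignment, ChangingCriterionSpec, DesignError, is_admissible
from .enumeration import count_assignments, enumerate_assignments, sample_assignment, _as_rng
from .stats import StatisticSpec, evaluate_statistic, resolve_ccd_criteria

__all__ = [
    "ReferenceDistribution",
    "TestResult",
    "build_reference",
    "randomization_pvalue",
    "randomization_test",
]

#: two statistic values are tied when within this relative tolerance —
#: phase means are ratios of sums, so exact binary equality is fragile
TIE_RTOL = 1e-9


def _tie_tol(a: float, b: float) -> float:
    return TIE_RTOL * max(1.0, abs(a), abs(b))


@dataclass(frozen=True)
class ReferenceDistribution:
    """Statistic values over the (enumerated or sampled) admissible set.

    ``R`` is the exact size of the admissible set even under Monte Carlo,
    where ``len(values) == n_mc`` (the observed plus ``n_mc - 1`` uniform
    draws with replacement).
    """

    statistic_name: str
    values: Tuple[float, ...]
    observed: float
    R: int
    method: str  # "exhaustive" | "monte_carlo"
    n_mc: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.method not in ("exhaustive", "monte_carlo"):
            raise DesignError(f"unknown method {self.method!r}")
        if self.method == "exhaustive" and len(self.values) != self.R:
            raise DesignError(f"exhaustive reference holds {len(self.values)} values, expected R={self.R}")
        if self.method == "monte_carlo" and self.n_mc is not None and len(self.values) != self.n_mc:
            raise DesignError(f"monte_carlo reference holds {len(self.values)} values, expected n_mc={self.n_mc}")
        arr = np.asarray(self.values, dtype=float)
        tol = _tie_tol(self.observed, self.observed)
        if not np.any(np.abs(arr - self.observed) <= np.maximum(tol, TIE_RTOL * np.abs(arr))):
            raise DesignError("observed statistic is not a member of the reference values")

    def summary(self) -> dict:
        arr = np.asarray(self.values, dtype=float)
        qs = np.quantile(arr, [0.25, 0.5, 0.75])
        return {
            "min": float(arr.min()),
            "q25": float(qs[0]),
            "median": float(qs[1]),
            "q75": float(qs[2]),
            "max": float(arr.max()),
            "R": self.R,
            "n_values": len(self.values),
            "method": self.method,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class TestResult:
    """A randomization-test outcome: observed statistic, p-value, tail and
    the verbal decision at significance level alpha."""

    statistic_name: str
    observed: float
    p_value: float
    tail: str
    R: int
    method: str
    alpha: float = 0.05
    n_mc: Optional[int] = None
    seed: Optional[int] = None

    @property
    def reject(self) -> bool:
        return self.p_value <= self.alpha

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "p_value": self.p_value,
            "tail": self.tail,
            "R": self.R,
            "method": self.method,
            "n_mc": self.n_mc,
            "seed": self.seed,
            "alpha": self.alpha,
            "decision": "reject" if self.reject else "fail to reject",
        }


def build_reference(data, spec, statistic: StatisticSpec, realized: Assignment,
                    method: str = "auto", n_mc: int = 1000,
                    seed: Union[int, np.random.Generator, None] = None,
                    max_exhaustive: int = 10 ** 7) -> ReferenceDistribution:
    """Evaluate the statistic over the admissible set (or a uniform sample).

    ``method`` "auto" enumerates exhaustively when R <= 10**4 and falls back
    to Monte Carlo otherwise.  For changing criterion designs with the
    median-of-baseline rule, the baseline criterion is resolved once from the
    realized assignment and held fixed across all reference assignments.
    """
    if not is_admissible(spec, realized):
        raise DesignError("realized assignment is not admissible under the design spec")
    R = count_assignments(spec)
    if method == "auto":
        method = "exhaustive" if R <= 10 ** 4 else "monte_carlo"

    ccd_criteria = None
    if isinstance(spec, ChangingCriterionSpec) and statistic.name == "ccd_mad":
        ccd_criteria = resolve_ccd_criteria(spec, data, realized.change_points)

    observed = evaluate_statistic(statistic, data, realized, spec=spec,
                                  ccd_criteria=ccd_criteria)

    if method == "exhaustive":
        if R > max_exhaustive:
            raise DesignError(
                f"R={R} exceeds the exhaustive cap {max_exhaustive}; use method='monte_carlo'")
        values = tuple(
            evaluate_statistic(statistic, data, a, spec=spec, ccd_criteria=ccd_criteria)
            for a in enumerate_assignments(spec))
        return ReferenceDistribution(statistic.name, values, observed, R, "exhaustive")

    if method != "monte_carlo":
        raise DesignError(f"unknown method {method!r}; expected exhaustive, monte_carlo or auto")
    if n_mc < 1:
        raise DesignError("n_mc must be >= 1")
    seed_out = seed if isinstance(seed, int) else None
    rng = _as_rng(seed)
    values = [observed]
    for _ in range(n_mc - 1):
        a = sample_assignment(spec, rng)
        values.append(evaluate_statistic(statistic, data, a, spec=spec,
                                         ccd_criteria=ccd_criteria))
    return ReferenceDistribution(statistic.name, tuple(values), observed, R,
                                 "monte_carlo", n_mc=n_mc, seed=seed_out)


def randomization_pvalue(ref: ReferenceDistribution, tail: str = "right",
                         alpha: float = 0.05) -> TestResult:
    """p-value as the proportion of reference statistics as extreme as or more
    extreme than the observed one (observed included, so p > 0).

    ``two_sided`` compares absolute values — the absolute-difference statistic
    — rather than doubling a one-sided tail.
    """
    arr = np.asarray(ref.values, dtype=float)
    obs = ref.observed
    tol = np.array([_tie_tol(v, obs) for v in arr])
    if tail == "right":
        count = int(np.sum(arr >= obs - tol))
    elif tail == "left":
        count = int(np.sum(arr <= obs + tol))
    elif tail == "two_sided":
        count = int(np.sum(np.abs(arr) >= abs(obs) - tol))
    else:
        raise DesignError(f"unknown tail {tail!r}; expected right, left or two_sided")
    p = count / len(arr)
    return TestResult(ref.statistic_name, obs, p, tail, ref.R, ref.method,
                      alpha=alpha, n_mc=ref.n_mc, seed=ref.seed)


def randomization_test(data, spec, statistic: StatisticSpec, realized: Assignment,
                       tail: Optional[str] = None, method: str = "auto",
                       n_mc: int = 1000,
                       seed: Union[int, np.random.Generator, None] = None,
                       alpha: float = 0.05,
                       return_reference: bool = False):
    """One-call randomization test: build the reference distribution and
    locate the observed statistic in it.

    Returns a :class:`TestResult`, or ``(TestResult, ReferenceDistribution)``
    when ``return_reference`` is true.  ``tail`` defaults to the statistic's
    conventional tail (left for criterion adherence, right otherwise).
    """
    if tail is None:
        tail = statistic.default_tail
    ref = build_reference(data, spec, statistic, realized, method=method,
                          n_mc=n_mc, seed=seed)
    result = randomization_pvalue(ref, tail=tail, alpha=alpha)
    if return_reference:
        return result, ref
    return result
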