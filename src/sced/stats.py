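"""Test statistics for randomization tests on single-case data.

All statistics quantify the *level* aspect of the data.  Phase designs use
sums of per-phase means (means within maximal runs), alternation designs pool
all occasions of a condition, multiple baseline designs average per-unit
mean differences, and changing criterion designs measure adherence as the
mean absolute deviation of each measurement from its phase criterion.

Statistics are computed in full floating precision; rounding to two decimals
is a display concern only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .design import (
    Assignment,
    ChangingCriterionSpec,
    DesignError,
    MeasurementSeries,
    MultipleBaselineSpec,
    PhaseDesignSpec,
    labels_from_changepoints,
    runs_of,
)

__all__ = [
    "STATISTIC_NAMES",
    "StatisticSpec",
    "phase_means",
    "phase_mean_diff",
    "alternation_mean_diff",
    "mbd_mean_diff",
    "ccd_mad",
    "resolve_ccd_criteria",
    "evaluate_statistic",
]

STATISTIC_NAMES = (
    "phase_mean_diff_BA",
    "phase_mean_diff_AB",
    "phase_mean_diff_abs",
    "alternation_mean_diff_AB",
    "mbd_mean_diff",
    "ccd_mad",
)


@dataclass(frozen=True)
class StatisticSpec:
    """A named test statistic plus the condition labels playing the baseline
    (A) and treatment (B) roles."""

    name: str
    a_labels: Tuple[str, ...] = ("A",)
    b_labels: Tuple[str, ...] = ("B",)

    def __post_init__(self) -> None:
        if self.name not in STATISTIC_NAMES:
            raise DesignError(f"unknown statistic {self.name!r}; expected one of {STATISTIC_NAMES}")
        a = tuple(str(x) for x in self.a_labels)
        b = tuple(str(x) for x in self.b_labels)
        if not a or not b:
            raise DesignError("a_labels and b_labels must be non-empty")
        if set(a) & set(b):
            raise DesignError("a_labels and b_labels must be disjoint")
        object.__setattr__(self, "a_labels", a)
        object.__setattr__(self, "b_labels", b)

    @property
    def default_tail(self) -> str:
        """Conventional tail for the statistic: smaller is better only for
        criterion adherence (left); mean differences test right by default."""
        return "left" if self.name == "ccd_mad" else "right"


def _check_lengths(series: MeasurementSeries, labels: Sequence[str]) -> None:
    if len(labels) != series.n:
        raise DesignError(f"label sequence length {len(labels)} != series length {series.n}")


def phase_means(series: MeasurementSeries, labels: Sequence[str]) -> np.ndarray:
    """Mean of the measurements within each maximal run (phase), in order."""
    _check_lengths(series, labels)
    vals = np.asarray(series.values, dtype=float)
    return np.array([vals[start - 1:start - 1 + length].mean()
                     for _, start, length in runs_of(tuple(labels))])


def phase_mean_diff(series: MeasurementSeries, labels: Sequence[str],
                    direction: str = "BA",
                    a_labels: Tuple[str, ...] = ("A",),
                    b_labels: Tuple[str, ...] = ("B",)) -> float:
    """Sum of B-phase means minus sum of A-phase means (direction BA), its
    negation (AB), or its absolute value (abs, the two-sided statistic)."""
    _check_lengths(series, labels)
    vals = np.asarray(series.values, dtype=float)
    sum_a = sum_b = 0.0
    seen_a = seen_b = False
    for lab, start, length in runs_of(tuple(labels)):
        mean = vals[start - 1:start - 1 + length].mean()
        if lab in a_labels:
            sum_a += mean
            seen_a = True
        elif lab in b_labels:
            sum_b += mean
            seen_b = True
    if not seen_a or not seen_b:
        missing = "A" if not seen_a else "B"
        raise DesignError(f"no phase carries a {missing}-role label")
    if direction == "BA":
        return sum_b - sum_a
    if direction == "AB":
        return sum_a - sum_b
    if direction == "abs":
        return abs(sum_b - sum_a)
    raise DesignError(f"unknown direction {direction!r}; expected BA, AB or abs")


def alternation_mean_diff(series: MeasurementSeries, labels: Sequence[str],
                          a_labels: Tuple[str, ...] = ("A",),
                          b_labels: Tuple[str, ...] = ("B",)) -> float:
    """Mean of all A-role measurements minus mean of all B-role measurements,
    pooled across occasions (not per run)."""
    _check_lengths(series, labels)
    vals = np.asarray(series.values, dtype=float)
    labs = np.asarray(labels, dtype=object)
    mask_a = np.isin(labs, a_labels)
    mask_b = np.isin(labs, b_labels)
    if not mask_a.any():
        raise DesignError("no occasion carries an A-role label")
    if not mask_b.any():
        raise DesignError("no occasion carries a B-role label")
    return float(vals[mask_a].mean() - vals[mask_b].mean())


def mbd_mean_diff(series_set: Sequence[MeasurementSeries],
                  start_points: Sequence[int]) -> float:
    """Average over units of (post-intervention mean − baseline mean).

    ``start_points[u]`` is the first intervention occasion of unit ``u``; the
    baseline is every earlier occasion.
    """
    if len(series_set) != len(start_points):
        raise DesignError(f"{len(series_set)} series but {len(start_points)} start points")
    diffs = []
    for series, start in zip(series_set, start_points):
        if not 2 <= start <= series.n:
            raise DesignError(
                f"start point {start} outside 2..{series.n} for unit {series.unit_id!r}")
        vals = np.asarray(series.values, dtype=float)
        diffs.append(vals[start - 1:].mean() - vals[:start - 1].mean())
    return float(np.mean(diffs))


def resolve_ccd_criteria(spec: ChangingCriterionSpec,
                         series: MeasurementSeries,
                         change_points: Sequence[int]) -> Tuple[Tuple[float, float], ...]:
    """Per-phase (lower, upper) criteria including the baseline phase.

    Under the ``median_of_baseline`` rule the baseline criterion is the median
    of the given baseline segment.  In a randomization test this is resolved
    once from the *realized* assignment and held fixed over all reference
    assignments — recomputing per candidate would change the hypothesis under
    test.
    """
    rule = spec.baseline_criterion_rule
    if rule == "none":
        raise DesignError("baseline criterion rule 'none' but baseline occasions are present")
    if rule == "fixed":
        c0 = float(spec.baseline_criterion_value)
    else:  # median_of_baseline
        cp1 = int(change_points[0])
        baseline = np.asarray(series.values[:cp1 - 1], dtype=float)
        c0 = float(np.median(baseline))
    return ((c0, c0),) + spec.criterion_schedule


def ccd_mad(series: MeasurementSeries, change_points: Sequence[int],
            spec: ChangingCriterionSpec,
            criteria: Optional[Tuple[Tuple[float, float], ...]] = None) -> float:
    """Mean absolute deviation of each measurement from its phase criterion.

    For range criteria the deviation is zero inside [lower, upper] and the
    distance to the nearer bound outside.  Zero indicates perfect adherence;
    lower values are better, so the randomization test looks at the left tail.
    ``criteria`` (one (lower, upper) per phase, baseline first) overrides the
    spec-derived criteria; pass the realized-assignment criteria when scanning
    a reference distribution.
    """
    cps = tuple(int(c) for c in change_points)
    if len(cps) != len(spec.phase_labels) - 1:
        raise DesignError(f"expected {len(spec.phase_labels) - 1} change points, got {len(cps)}")
    if criteria is None:
        criteria = resolve_ccd_criteria(spec, series, cps)
    vals = np.asarray(series.values, dtype=float)
    bounds = (1,) + cps + (series.n + 1,)
    total = 0.0
    for (lo, hi), a, b in zip(criteria, bounds, bounds[1:]):
        seg = vals[a - 1:b - 1]
        total += np.maximum.reduce([lo - seg, seg - hi, np.zeros_like(seg)]).sum()
    return float(total / series.n)


def evaluate_statistic(stat: StatisticSpec, data, assignment: Assignment,
                       spec=None,
                       ccd_criteria: Optional[Tuple[Tuple[float, float], ...]] = None) -> float:
    """Evaluate a statistic for one series (or series set) under an assignment.

    ``data`` is a single :class:`MeasurementSeries` except for
    ``mbd_mean_diff`` which takes a sequence of per-unit series.
    """
    name = stat.name
    if name in ("phase_mean_diff_BA", "phase_mean_diff_AB", "phase_mean_diff_abs"):
        labels = assignment.labels
        if labels is None:
            if not isinstance(spec, PhaseDesignSpec):
                raise DesignError("change-point assignment needs a PhaseDesignSpec to expand labels")
            labels = labels_from_changepoints(assignment.change_points, spec.n, spec.phase_pattern)
        return phase_mean_diff(data, labels, direction=name.rsplit("_", 1)[1],
                               a_labels=stat.a_labels, b_labels=stat.b_labels)
    if name == "alternation_mean_diff_AB":
        return alternation_mean_diff(data, assignment.labels,
                                     a_labels=stat.a_labels, b_labels=stat.b_labels)
    if name == "mbd_mean_diff":
        return mbd_mean_diff(data, assignment.start_points)
    if name == "ccd_mad":
        if not isinstance(spec, ChangingCriterionSpec):
            raise DesignError("ccd_mad requires a ChangingCriterionSpec")
        return ccd_mad(data, assignment.change_points, spec, criteria=ccd_criteria)
    raise DesignError(f"unknown statistic {name!r}")
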