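"""Design families for single-case experiments and their admissible assignments.

A single-case experimental design (SCED) measures one unit (participant,
behaviour, setting) repeatedly under different conditions.  Four classical
randomization schemes are modelled here:

* **phase designs** (AB, ABA, ABAB, ...): consecutive blocks of occasions per
  condition, randomized through the phase change points, with a minimum
  number of measurements per phase;
* **alternation designs**: completely randomized, alternating-treatments
  (maximum run length restriction) and randomized-block schemes over rapidly
  alternating conditions;
* **multiple baseline designs**: replicated AB designs across several units
  with staggered, randomized intervention start points;
* **changing criterion designs**: a stepwise criterion schedule whose phase
  change moments are randomized within per-boundary candidate sets.

Occasions are 1-based.  A change point is the index of the *first* occasion
of the new phase; phases are closed intervals of occasions.  Condition labels
are arbitrary strings, with ``A`` conventionally the baseline; statistics
declare which labels play the A and B roles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

__all__ = [
    "DesignError",
    "MeasurementSeries",
    "PhaseDesignSpec",
    "AlternationDesignSpec",
    "MultipleBaselineSpec",
    "ChangingCriterionSpec",
    "Assignment",
    "validate_spec",
    "labels_from_changepoints",
    "changepoints_of",
    "runs_of",
    "is_admissible",
]


class DesignError(ValueError):
    """A design specification or assignment violates one of its invariants."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise DesignError(msg)


@dataclass(frozen=True)
class MeasurementSeries:
    """Ordered real-valued measurements for one unit, occasions 1..n.

    Missing values are a hard error: a series with gaps would silently change
    the reference distribution of any randomization test run on it.
    """

    unit_id: str
    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        _require(len(vals) >= 1, "a measurement series needs at least one occasion")
        for i, v in enumerate(vals, start=1):
            _require(math.isfinite(v), f"non-finite value at occasion {i} of unit {self.unit_id!r}")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PhaseDesignSpec:
    """Phase design: ``phase_pattern`` blocks over ``n`` occasions, each phase
    at least ``min_phase_length`` occasions long."""

    phase_pattern: Tuple[str, ...]
    n: int
    min_phase_length: int = 1
    design_family: str = field(default="phase", init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase_pattern", tuple(str(p) for p in self.phase_pattern))
        k = len(self.phase_pattern)
        _require(k >= 2, f"a phase design needs at least two phases, got {k}")
        _require(len(set(self.phase_pattern)) >= 2,
                 "phase_pattern must contain at least two distinct labels")
        _require(self.min_phase_length >= 1, "min_phase_length must be a positive integer")
        _require(self.n >= k * self.min_phase_length,
                 f"n={self.n} cannot hold {k} phases of at least "
                 f"{self.min_phase_length} occasions each ({k * self.min_phase_length} needed)")

    @property
    def k(self) -> int:
        return len(self.phase_pattern)


_ALTERNATION_SCHEMES = ("completely_randomized", "alternating_treatments", "randomized_block")


@dataclass(frozen=True)
class AlternationDesignSpec:
    """Alternation design: rapid alternation of conditions over ``n`` occasions.

    ``completely_randomized`` fixes per-condition totals (reference set = label
    permutations); ``unrestricted=True`` switches to the coin-flip scheme where
    every occasion is independently any condition (|conditions|^n sequences).
    ``alternating_treatments`` additionally caps maximal run length at
    ``max_run``.  ``randomized_block`` groups occasions into ``n_blocks`` blocks
    of ``treatments_per_block`` days with each treatment once per block.
    """

    scheme: str
    n: int = 0
    condition_counts: Optional[dict] = None
    max_run: Optional[int] = None
    n_blocks: Optional[int] = None
    treatments_per_block: Optional[int] = None
    treatments: Optional[Tuple[str, ...]] = None
    unrestricted: bool = False
    design_family: str = field(default="alternation", init=False)

    def __post_init__(self) -> None:
        _require(self.scheme in _ALTERNATION_SCHEMES,
                 f"unknown alternation scheme {self.scheme!r}; expected one of {_ALTERNATION_SCHEMES}")
        if self.scheme == "randomized_block":
            _require(self.n_blocks is not None and self.n_blocks >= 1,
                     "randomized_block requires n_blocks >= 1")
            _require(self.treatments_per_block is not None and self.treatments_per_block >= 1,
                     "randomized_block requires treatments_per_block >= 1")
            treatments = self.treatments
            if treatments is None:
                # default alphabet A, B, C, ...
                treatments = tuple(chr(ord("A") + i) for i in range(self.treatments_per_block))
            treatments = tuple(str(t) for t in treatments)
            _require(len(treatments) == self.treatments_per_block,
                     "treatments must list exactly treatments_per_block labels")
            _require(len(set(treatments)) == len(treatments), "treatment labels must be distinct")
            object.__setattr__(self, "treatments", treatments)
            expected_n = self.n_blocks * self.treatments_per_block
            if self.n == 0:
                object.__setattr__(self, "n", expected_n)
            _require(self.n == expected_n,
                     f"n={self.n} but n_blocks*treatments_per_block={expected_n}")
            return
        _require(self.n >= 1, "alternation design requires n >= 1")
        if self.unrestricted:
            _require(self.scheme == "completely_randomized",
                     "unrestricted applies to the completely_randomized scheme only")
            conds = self.treatments
            if conds is None and self.condition_counts is not None:
                conds = tuple(sorted(self.condition_counts))
            _require(conds is not None and len(conds) >= 2,
                     "unrestricted scheme requires at least two condition labels")
            object.__setattr__(self, "treatments", tuple(str(c) for c in conds))
            return
        _require(self.condition_counts is not None and len(self.condition_counts) >= 2,
                 f"{self.scheme} requires condition_counts for at least two conditions")
        counts = {str(k): int(v) for k, v in self.condition_counts.items()}
        for lab, c in counts.items():
            _require(c >= 1, f"condition {lab!r} has non-positive total {c}")
        _require(sum(counts.values()) == self.n,
                 f"condition totals sum to {sum(counts.values())}, expected n={self.n}")
        object.__setattr__(self, "condition_counts", counts)
        if self.scheme == "alternating_treatments" and self.max_run is not None:
            _require(self.max_run >= 1, "max_run must be a positive integer (or None for unbounded)")


@dataclass(frozen=True)
class MultipleBaselineSpec:
    """Multiple baseline design: ``n_units`` replicated AB series of length
    ``n``, intervention start occasions randomized within ``start_window``.

    ``min_stagger`` generalizes distinctness: successive start points must
    differ by at least this many occasions (1 = distinctness only, the
    classical staggered-introduction constraint).  ``latest <= n`` is required;
    a minimum post-intervention length is not enforced by the type — encode it
    through the window itself.
    """

    n_units: int
    n: int
    start_window: Tuple[int, int]
    distinct_starts: bool = True
    min_stagger: Optional[int] = None
    design_family: str = field(default="multiple_baseline", init=False)

    def __post_init__(self) -> None:
        _require(self.n_units >= 1, "n_units must be >= 1")
        earliest, latest = (int(self.start_window[0]), int(self.start_window[1]))
        object.__setattr__(self, "start_window", (earliest, latest))
        _require(earliest >= 2, "earliest start must be >= 2 (at least one baseline occasion)")
        _require(latest <= self.n, f"latest start {latest} exceeds series length n={self.n}")
        _require(earliest <= latest, "start_window must satisfy earliest <= latest")
        stagger = self.min_stagger
        if stagger is None:
            stagger = 1 if self.distinct_starts else 0
        _require(stagger >= 0, "min_stagger must be non-negative")
        if not self.distinct_starts:
            _require(stagger == 0, "min_stagger > 0 requires distinct_starts")
        else:
            _require(stagger >= 1, "distinct_starts requires min_stagger >= 1")
            W = latest - earliest + 1
            _require(W - (self.n_units - 1) * stagger >= 1,
                     f"window width {W} cannot hold {self.n_units} starts "
                     f"with minimum stagger {stagger}")
        object.__setattr__(self, "min_stagger", stagger)

    @property
    def window_width(self) -> int:
        return self.start_window[1] - self.start_window[0] + 1


_BASELINE_RULES = ("median_of_baseline", "fixed", "none")


@dataclass(frozen=True)
class ChangingCriterionSpec:
    """Changing criterion design: baseline then treatment phases, each treatment
    phase with its own criterion, phase change moments randomized within
    per-boundary candidate lists.

    ``criterion_schedule`` holds one ``(lower, upper)`` interval per treatment
    phase (a single-point criterion has ``lower == upper``).  The baseline
    criterion comes from ``baseline_criterion_rule``: the median of the
    observed baseline segment, a fixed value, or none (baseline occasions are
    then an error when the adherence statistic is evaluated).
    """

    phase_labels: Tuple[str, ...]
    n: int
    candidate_changepoints: Tuple[Tuple[int, ...], ...]
    criterion_schedule: Tuple[Tuple[float, float], ...]
    criterion_direction: str = "decrease"
    baseline_criterion_rule: str = "median_of_baseline"
    baseline_criterion_value: Optional[float] = None
    design_family: str = field(default="changing_criterion", init=False)

    def __post_init__(self) -> None:
        labels = tuple(str(p) for p in self.phase_labels)
        object.__setattr__(self, "phase_labels", labels)
        k = len(labels)
        _require(k >= 2, "a changing criterion design needs a baseline and at least one treatment phase")
        cands = tuple(tuple(int(c) for c in lst) for lst in self.candidate_changepoints)
        object.__setattr__(self, "candidate_changepoints", cands)
        _require(len(cands) == k - 1,
                 f"{k} phases need {k - 1} candidate change-point lists, got {len(cands)}")
        for b, lst in enumerate(cands):
            _require(len(lst) >= 1, f"boundary {b + 1} has an empty candidate list")
            _require(all(x < y for x, y in zip(lst, lst[1:])),
                     f"candidate list for boundary {b + 1} must be strictly increasing")
        _require(cands[0][0] >= 2, "first change point must leave at least one baseline occasion")
        _require(cands[-1][-1] <= self.n, "last change point exceeds the number of occasions")
        for prev, nxt in zip(cands, cands[1:]):
            _require(max(prev) < min(nxt),
                     "candidate lists overlap: some combination would yield an empty phase")
        sched = tuple((float(lo), float(hi)) for lo, hi in self.criterion_schedule)
        object.__setattr__(self, "criterion_schedule", sched)
        _require(len(sched) == k - 1,
                 f"criterion_schedule needs one entry per treatment phase ({k - 1}), got {len(sched)}")
        for i, (lo, hi) in enumerate(sched):
            _require(lo <= hi, f"criterion range for treatment phase {i + 1} has lower > upper")
        _require(self.criterion_direction in ("decrease", "increase"),
                 "criterion_direction must be 'decrease' or 'increase'")
        _require(self.baseline_criterion_rule in _BASELINE_RULES,
                 f"baseline_criterion_rule must be one of {_BASELINE_RULES}")
        if self.baseline_criterion_rule == "fixed":
            _require(self.baseline_criterion_value is not None,
                     "fixed baseline criterion rule requires baseline_criterion_value")


DesignSpec = (PhaseDesignSpec, AlternationDesignSpec, MultipleBaselineSpec, ChangingCriterionSpec)


@dataclass(frozen=True)
class Assignment:
    """One realized or candidate allocation for a design.

    Exactly one of the payloads is meaningful per family: ``labels`` for
    alternation designs (and available for phase designs), ``change_points``
    for phase and changing criterion designs, ``start_points`` for multiple
    baseline designs.
    """

    design_family: str
    labels: Optional[Tuple[str, ...]] = None
    change_points: Optional[Tuple[int, ...]] = None
    start_points: Optional[Tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.labels is not None:
            object.__setattr__(self, "labels", tuple(str(c) for c in self.labels))
        if self.change_points is not None:
            object.__setattr__(self, "change_points", tuple(int(c) for c in self.change_points))
        if self.start_points is not None:
            object.__setattr__(self, "start_points", tuple(int(s) for s in self.start_points))
        _require(any(x is not None for x in (self.labels, self.change_points, self.start_points)),
                 "assignment carries no payload")

    def key(self) -> tuple:
        """Canonical sort/identity key (labels, else change/start vector)."""
        if self.labels is not None:
            return self.labels
        if self.change_points is not None:
            return self.change_points
        return self.start_points


def validate_spec(spec):
    """Re-run a spec's invariant checks and return it unchanged.

    Construction already validates; this re-validates objects that may have
    travelled through deserialization.
    """
    spec.__post_init__()
    return spec


def labels_from_changepoints(change_points: Sequence[int], n: int,
                             phase_pattern: Sequence[str]) -> Tuple[str, ...]:
    """Expand phase change points into the per-occasion condition labels.

    ``change_points[i]`` is the first occasion of phase ``i+2``; the first
    phase starts at occasion 1 and the last ends at ``n``.
    """
    cps = tuple(int(c) for c in change_points)
    pattern = tuple(str(p) for p in phase_pattern)
    _require(len(cps) == len(pattern) - 1,
             f"{len(pattern)} phases need {len(pattern) - 1} change points, got {len(cps)}")
    bounds = (1,) + cps + (n + 1,)
    for a, b in zip(bounds, bounds[1:]):
        _require(a < b, f"change points must be strictly increasing within 2..{n}: {cps}")
    _require(all(2 <= c <= n for c in cps), f"change points out of range 2..{n}: {cps}")
    out: list[str] = []
    for lab, a, b in zip(pattern, bounds, bounds[1:]):
        out.extend([lab] * (b - a))
    return tuple(out)


def runs_of(labels: Sequence[str]) -> list[tuple[str, int, int]]:
    """Maximal runs of identical labels as (label, start occasion, length)."""
    runs: list[tuple[str, int, int]] = []
    start = 1
    for i in range(2, len(labels) + 1):
        if labels[i - 1] != labels[i - 2]:
            runs.append((labels[i - 2], start, i - start))
            start = i
    runs.append((labels[-1], start, len(labels) - start + 1))
    return runs


def changepoints_of(labels: Sequence[str]) -> Tuple[int, ...]:
    """First occasions of every phase after the first (inverse of
    :func:`labels_from_changepoints` for admissible phase assignments)."""
    return tuple(r[1] for r in runs_of(labels)[1:])


def is_admissible(spec, assignment: Assignment) -> bool:
    """Check an assignment against a design spec's randomization scheme."""
    if isinstance(spec, PhaseDesignSpec):
        if assignment.labels is not None:
            labels = assignment.labels
            if len(labels) != spec.n:
                return False
        elif assignment.change_points is not None:
            try:
                labels = labels_from_changepoints(assignment.change_points, spec.n, spec.phase_pattern)
            except DesignError:
                return False
        else:
            return False
        runs = runs_of(labels)
        return (tuple(r[0] for r in runs) == spec.phase_pattern
                and all(r[2] >= spec.min_phase_length for r in runs))
    if isinstance(spec, AlternationDesignSpec):
        labels = assignment.labels
        if labels is None or len(labels) != spec.n:
            return False
        if spec.scheme == "randomized_block":
            t = spec.treatments_per_block
            blocks = [labels[i * t:(i + 1) * t] for i in range(spec.n_blocks)]
            return all(sorted(b) == sorted(spec.treatments) for b in blocks)
        if spec.unrestricted:
            return all(lab in spec.treatments for lab in labels)
        counts: dict = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        if counts != spec.condition_counts:
            return False
        if spec.scheme == "alternating_treatments" and spec.max_run is not None:
            return all(r[2] <= spec.max_run for r in runs_of(labels))
        return True
    if isinstance(spec, MultipleBaselineSpec):
        starts = assignment.start_points
        if starts is None or len(starts) != spec.n_units:
            return False
        lo, hi = spec.start_window
        if not all(lo <= s <= hi for s in starts):
            return False
        s = spec.min_stagger
        if s >= 1:
            return all(abs(a - b) >= s for i, a in enumerate(starts) for b in starts[i + 1:])
        return True
    if isinstance(spec, ChangingCriterionSpec):
        cps = assignment.change_points
        if cps is None or len(cps) != len(spec.candidate_changepoints):
            return False
        return all(c in lst for c, lst in zip(cps, spec.candidate_changepoints))
    raise DesignError(f"unknown design spec type {type(spec).__name__}")
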