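"""Counting, exhaustive enumeration, and uniform sampling of admissible assignments.

Every design family exposes three capabilities: an exact count ``R`` of the
admissible set (the reciprocal of which is the lowest attainable
randomization-test p-value), a deterministic exhaustive generator in a
canonical lexicographic order, and an exactly uniform sampler.  Sampling is
constructive where a bijection exists (compositions, permutations, cartesian
products) and by rejection from an exactly uniform superset otherwise; both
routes are uniform, not approximately so.  Monte Carlo reproducibility is
governed solely by the seed, never by enumeration order.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Iterator, Optional, Union

import numpy as np

from .design import (
    AlternationDesignSpec,
    Assignment,
    ChangingCriterionSpec,
    DesignError,
    MultipleBaselineSpec,
    PhaseDesignSpec,
    labels_from_changepoints,
)

__all__ = [
    "AssignmentSet",
    "count_phase_assignments",
    "enumerate_phase_assignments",
    "enumerate_alternation",
    "count_mbd_assignments",
    "enumerate_mbd_assignments",
    "enumerate_ccd_assignments",
    "enumerate_assignments",
    "count_assignments",
    "sample_assignment",
]


@dataclass(frozen=True)
class AssignmentSet:
    """A lazily enumerable admissible set with an exact size.

    ``size`` is computed in closed form (or by dynamic programming) and equals
    the number of assignments the generator yields; iteration is repeatable
    and in canonical lexicographic order on the label sequence or
    change/start vector.
    """

    design_family: str
    size: int
    _factory: Callable[[], Iterator[Assignment]]

    def __iter__(self) -> Iterator[Assignment]:
        return self._factory()

    def __len__(self) -> int:
        return self.size


# ---------------------------------------------------------------------------
# phase designs


def count_phase_assignments(n: int, k: int, m: int) -> int:
    """Number of compositions of ``n`` occasions into ``k`` phases of at least
    ``m`` occasions each: C(n - km + k - 1, k - 1)."""
    if n < k * m:
        raise DesignError(f"n={n} < k*m={k * m}: no admissible phase assignment exists")
    return math.comb(n - k * m + k - 1, k - 1)


def _phase_changepoint_iter(n: int, k: int, m: int) -> Iterator[tuple[int, ...]]:
    # change point i (first occasion of phase i+1) ranges so every later phase
    # keeps >= m occasions; recursion yields vectors in lexicographic order
    def rec(prefix: list[int], lo: int, remaining: int) -> Iterator[tuple[int, ...]]:
        if remaining == 0:
            yield tuple(prefix)
            return
        for cp in range(lo, n - m * remaining + 2):
            prefix.append(cp)
            yield from rec(prefix, cp + m, remaining - 1)
            prefix.pop()

    yield from rec([], m + 1, k - 1)


def enumerate_phase_assignments(spec: PhaseDesignSpec) -> AssignmentSet:
    """All label sequences with exactly the spec's phases in pattern order,
    each phase at least ``min_phase_length`` long."""
    n, k, m = spec.n, spec.k, spec.min_phase_length
    size = count_phase_assignments(n, k, m)

    def gen() -> Iterator[Assignment]:
        for cps in _phase_changepoint_iter(n, k, m):
            yield Assignment(
                design_family="phase",
                change_points=cps,
                labels=labels_from_changepoints(cps, n, spec.phase_pattern),
            )

    return AssignmentSet("phase", size, gen)


# ---------------------------------------------------------------------------
# alternation designs


@lru_cache(maxsize=None)
def _count_max_run(counts: tuple[int, ...], max_run: int) -> int:
    """Sequences over len(counts) labels with the given totals and maximal run
    length <= max_run, by DP over (remaining counts, last label, current run)."""

    @lru_cache(maxsize=None)
    def rec(remaining: tuple[int, ...], last: int, run: int) -> int:
        if all(c == 0 for c in remaining):
            return 1
        total = 0
        for lab, c in enumerate(remaining):
            if c == 0:
                continue
            if lab == last:
                if run >= max_run:
                    continue
                nxt_run = run + 1
            else:
                nxt_run = 1
            nxt = list(remaining)
            nxt[lab] -= 1
            total += rec(tuple(nxt), lab, nxt_run)
        return total

    return rec(counts, -1, 0)


def _max_run_feasible(counts: dict, max_run: int) -> bool:
    # the most frequent condition needs enough separators: c_max runs of length
    # <= r can be interleaved iff ceil(c_max / r) - 1 <= n - c_max
    c_max = max(counts.values())
    rest = sum(counts.values()) - c_max
    return math.ceil(c_max / max_run) - 1 <= rest


def enumerate_alternation(spec: AlternationDesignSpec) -> AssignmentSet:
    """Admissible label sequences for the three alternation schemes.

    Infeasible constraints (totals forcing a run longer than ``max_run``)
    yield an empty set of size 0 rather than an error.
    """
    if spec.scheme == "randomized_block":
        treatments = tuple(sorted(spec.treatments))
        size = math.factorial(spec.treatments_per_block) ** spec.n_blocks

        def gen_rbd() -> Iterator[Assignment]:
            blocks = list(itertools.permutations(treatments))
            for combo in itertools.product(blocks, repeat=spec.n_blocks):
                labels = tuple(itertools.chain.from_iterable(combo))
                yield Assignment(design_family="alternation", labels=labels)

        return AssignmentSet("alternation", size, gen_rbd)

    if spec.unrestricted:
        conds = tuple(sorted(spec.treatments))
        size = len(conds) ** spec.n

        def gen_unres() -> Iterator[Assignment]:
            for labels in itertools.product(conds, repeat=spec.n):
                yield Assignment(design_family="alternation", labels=labels)

        return AssignmentSet("alternation", size, gen_unres)

    labels_sorted = sorted(spec.condition_counts)
    counts = tuple(spec.condition_counts[lab] for lab in labels_sorted)
    max_run = spec.max_run if spec.scheme == "alternating_treatments" else None

    if max_run is None:
        size = math.factorial(spec.n)
        for c in counts:
            size //= math.factorial(c)
    elif not _max_run_feasible(spec.condition_counts, max_run):
        size = 0
    else:
        size = _count_max_run(counts, max_run)

    def gen_crd() -> Iterator[Assignment]:
        if size == 0:
            return
        from sympy.utilities.iterables import multiset_permutations

        pool = [lab for lab in labels_sorted for _ in range(spec.condition_counts[lab])]
        for perm in multiset_permutations(pool):
            labels = tuple(perm)
            if max_run is not None and _longest_run(labels) > max_run:
                continue
            yield Assignment(design_family="alternation", labels=labels)

    return AssignmentSet("alternation", size, gen_crd)


def _longest_run(labels: tuple[str, ...]) -> int:
    best = run = 1
    for a, b in zip(labels, labels[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


# ---------------------------------------------------------------------------
# multiple baseline designs


def count_mbd_assignments(W: int, u: int, distinct: bool = True,
                          min_stagger: int = 1) -> int:
    """Ordered start-point assignments of ``u`` distinguishable units into a
    window of width ``W``.

    distinct (min_stagger = 1): W!/(W-u)!; min_stagger s > 1: u! * C(W - (u-1)(s-1), u)
    via the sorted-starts gap bijection; non-distinct: W**u.
    """
    if not distinct:
        return W ** u
    if W < u:
        raise DesignError(f"window width {W} < {u} units with distinct starts")
    s = max(1, min_stagger)
    reduced = W - (u - 1) * (s - 1)
    if reduced < u:
        return 0
    return math.factorial(u) * math.comb(reduced, u)


def enumerate_mbd_assignments(spec: MultipleBaselineSpec) -> AssignmentSet:
    """Per-unit start-point vectors within the window, honoring distinctness
    and minimum stagger, in lexicographic order."""
    lo, hi = spec.start_window
    u, s = spec.n_units, spec.min_stagger
    size = count_mbd_assignments(spec.window_width, u, distinct=s >= 1, min_stagger=s)

    def gen() -> Iterator[Assignment]:
        for starts in itertools.product(range(lo, hi + 1), repeat=u):
            if s >= 1 and any(abs(a - b) < s
                              for i, a in enumerate(starts) for b in starts[i + 1:]):
                continue
            yield Assignment(design_family="multiple_baseline", start_points=starts)

    return AssignmentSet("multiple_baseline", size, gen)


# ---------------------------------------------------------------------------
# changing criterion designs


def enumerate_ccd_assignments(spec: ChangingCriterionSpec) -> AssignmentSet:
    """Cartesian product of the per-boundary candidate change points."""
    size = math.prod(len(lst) for lst in spec.candidate_changepoints)

    def gen() -> Iterator[Assignment]:
        for cps in itertools.product(*spec.candidate_changepoints):
            yield Assignment(design_family="changing_criterion", change_points=cps)

    return AssignmentSet("changing_criterion", size, gen)


# ---------------------------------------------------------------------------
# dispatch and sampling


def enumerate_assignments(spec) -> AssignmentSet:
    """Enumerate the admissible set of any design spec."""
    if isinstance(spec, PhaseDesignSpec):
        return enumerate_phase_assignments(spec)
    if isinstance(spec, AlternationDesignSpec):
        return enumerate_alternation(spec)
    if isinstance(spec, MultipleBaselineSpec):
        return enumerate_mbd_assignments(spec)
    if isinstance(spec, ChangingCriterionSpec):
        return enumerate_ccd_assignments(spec)
    raise DesignError(f"unknown design spec type {type(spec).__name__}")


def count_assignments(spec) -> int:
    """Exact size R of the admissible set, without enumerating where a closed
    form or DP count exists."""
    if isinstance(spec, PhaseDesignSpec):
        return count_phase_assignments(spec.n, spec.k, spec.min_phase_length)
    if isinstance(spec, MultipleBaselineSpec):
        return count_mbd_assignments(spec.window_width, spec.n_units,
                                     distinct=spec.min_stagger >= 1,
                                     min_stagger=spec.min_stagger)
    if isinstance(spec, ChangingCriterionSpec):
        return math.prod(len(lst) for lst in spec.candidate_changepoints)
    if isinstance(spec, AlternationDesignSpec):
        return enumerate_alternation(spec).size
    raise DesignError(f"unknown design spec type {type(spec).__name__}")


def _as_rng(seed: Union[int, np.random.Generator, None]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_assignment(spec, seed: Union[int, np.random.Generator, None] = None) -> Assignment:
    """Draw one assignment exactly uniformly from the admissible set.

    Deterministic given an integer seed; an ``np.random.Generator`` may be
    passed instead to draw several assignments from one stream.
    """
    rng = _as_rng(seed)

    if isinstance(spec, PhaseDesignSpec):
        n, k, m = spec.n, spec.k, spec.min_phase_length
        count_phase_assignments(n, k, m)  # raises if empty
        # compositions of n into k parts >= m <-> (k-1)-subsets of n-km+k-1 slots
        slots = n - k * m + k - 1
        bars = np.sort(rng.choice(slots, size=k - 1, replace=False)) if k > 1 else np.array([], dtype=int)
        bounds = np.concatenate(([-1], bars, [slots]))
        extras = np.diff(bounds) - 1
        lengths = extras + m
        cps = tuple(int(c) for c in (1 + np.cumsum(lengths))[:-1])
        return Assignment(design_family="phase", change_points=cps,
                          labels=labels_from_changepoints(cps, n, spec.phase_pattern))

    if isinstance(spec, AlternationDesignSpec):
        if spec.scheme == "randomized_block":
            treatments = np.array(sorted(spec.treatments), dtype=object)
            labels: list[str] = []
            for _ in range(spec.n_blocks):
                labels.extend(rng.permutation(treatments).tolist())
            return Assignment(design_family="alternation", labels=tuple(labels))
        if spec.unrestricted:
            conds = sorted(spec.treatments)
            labels = [conds[i] for i in rng.integers(0, len(conds), size=spec.n)]
            return Assignment(design_family="alternation", labels=tuple(labels))
        pool = np.array([lab for lab in sorted(spec.condition_counts)
                         for _ in range(spec.condition_counts[lab])], dtype=object)
        max_run = spec.max_run if spec.scheme == "alternating_treatments" else None
        if max_run is not None and not _max_run_feasible(spec.condition_counts, max_run):
            raise DesignError("admissible set is empty: totals force a run longer than max_run")
        # rejection from the uniform permutation distribution stays exactly uniform
        for _ in range(1_000_000):
            labels = tuple(rng.permutation(pool).tolist())
            if max_run is None or _longest_run(labels) <= max_run:
                return Assignment(design_family="alternation", labels=labels)
        raise DesignError("rejection sampling failed to find an admissible sequence")

    if isinstance(spec, MultipleBaselineSpec):
        lo, hi = spec.start_window
        u, s = spec.n_units, spec.min_stagger
        W = spec.window_width
        if s == 0:
            starts = rng.integers(lo, hi + 1, size=u)
            return Assignment(design_family="multiple_baseline",
                              start_points=tuple(int(x) for x in starts))
        reduced = W - (u - 1) * (s - 1)
        if reduced < u:
            raise DesignError("admissible set is empty under the stagger constraint")
        # gap bijection: sorted starts with gaps >= s <-> u-subsets of the
        # reduced window; a random unit ordering makes the draw uniform over
        # ordered vectors
        base = np.sort(rng.choice(reduced, size=u, replace=False))
        sorted_starts = base + (s - 1) * np.arange(u) + lo
        perm = rng.permutation(u)
        starts = tuple(int(sorted_starts[p]) for p in perm)
        return Assignment(design_family="multiple_baseline", start_points=starts)

    if isinstance(spec, ChangingCriterionSpec):
        cps = tuple(int(lst[rng.integers(0, len(lst))]) for lst in spec.candidate_changepoints)
        return Assignment(design_family="changing_criterion", change_points=cps)

    raise DesignError(f"unknown design spec type {type(spec).__name__}")
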