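"""Shared fixtures: the four canonical design shapes used throughout the suite."""

import pytest
from hypothesis import settings

from sced import (
    AlternationDesignSpec,
    Assignment,
    ChangingCriterionSpec,
    MeasurementSeries,
    MultipleBaselineSpec,
    PhaseDesignSpec,
    labels_from_changepoints,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def abab24():
    """ABAB withdrawal design, 24 occasions, at least three per phase (R=455)."""
    return PhaseDesignSpec(phase_pattern=("A", "B", "A", "B"), n=24, min_phase_length=3)


@pytest.fixture
def abab24_realized(abab24):
    """The realized assignment with six occasions per phase."""
    labels = labels_from_changepoints((7, 13, 19), 24, abab24.phase_pattern)
    return Assignment(design_family="phase", labels=labels, change_points=(7, 13, 19))


@pytest.fixture
def abab24_indicator(abab24_realized):
    """Series equal to 1 on B-labelled and 0 on A-labelled occasions."""
    vals = tuple(1.0 if lab == "B" else 0.0 for lab in abab24_realized.labels)
    return MeasurementSeries(unit_id="subject", values=vals)


@pytest.fixture
def atd6():
    """Alternating treatments design: 6 occasions, 3 A + 3 B, max run 2 (R=14)."""
    return AlternationDesignSpec(scheme="alternating_treatments", n=6,
                                 condition_counts={"A": 3, "B": 3}, max_run=2)


@pytest.fixture
def mbd_5x55():
    """Multiple baseline: 5 units, 55 occasions, starts on days 15..36, distinct."""
    return MultipleBaselineSpec(n_units=5, n=55, start_window=(15, 36))


@pytest.fixture
def ccd_weight():
    """Changing criterion design shaped like a stepwise weight-loss schedule:
    baseline plus nine treatment phases, two candidate change moments per
    boundary (R = 2**9 = 512), criteria stepping down 5 units per phase."""
    cands = ((12, 13), (19, 20), (26, 27), (36, 37), (44, 45),
             (54, 55), (64, 65), (77, 78), (85, 86))
    sched = tuple((306.0 - 5 * i, 306.0 - 5 * i) for i in range(9))
    return ChangingCriterionSpec(
        phase_labels=("A",) + tuple(f"B{i}" for i in range(1, 10)),
        n=95, candidate_changepoints=cands, criterion_schedule=sched,
        criterion_direction="decrease",
        baseline_criterion_rule="fixed", baseline_criterion_value=311.0)
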