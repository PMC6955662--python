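"""CSV/config I/O and run reports.

Series travel as tidy CSV with columns ``unit,occasion,value`` (occasions
1-based and contiguous per unit); realized assignments as ``unit,occasion,label``;
changing-criterion schedules as ``phase_label,lower,upper`` (single-point
criteria have lower = upper).  Design and effect configurations are flat
key:value YAML mappings.  Results serialize to JSON in full precision —
rounding to two decimals happens only in human-readable summaries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import pandas as pd
import yaml

from .design import (
    AlternationDesignSpec,
    Assignment,
    ChangingCriterionSpec,
    DesignError,
    MeasurementSeries,
    MultipleBaselineSpec,
    PhaseDesignSpec,
)
from .synth import EffectModel

__all__ = [
    "read_series_csv",
    "write_series_csv",
    "read_assignment_csv",
    "write_assignment_csv",
    "read_criteria_csv",
    "read_config",
    "spec_from_config",
    "effect_model_from_config",
    "RunReport",
]

_SERIES_COLUMNS = ("unit", "occasion", "value")


def read_series_csv(path) -> list[MeasurementSeries]:
    """Read one :class:`MeasurementSeries` per unit from a tidy CSV.

    Units are returned in order of first appearance.  Occasions must run
    contiguously from 1 within each unit; gaps, duplicates and non-numeric
    values are hard errors.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise DesignError(f"series CSV {path} lacks columns: {', '.join(missing)}")
    try:
        df["value"] = pd.to_numeric(df["value"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise DesignError(f"non-numeric value in series CSV {path}: {exc}") from exc
    out: list[MeasurementSeries] = []
    for unit in df["unit"].astype(str).drop_duplicates():
        sub = df[df["unit"].astype(str) == unit].sort_values("occasion")
        occ = sub["occasion"].to_numpy()
        if len(set(occ)) != len(occ):
            dup = int(pd.Series(occ)[pd.Series(occ).duplicated()].iloc[0])
            raise DesignError(f"duplicated occasion {dup} for unit {unit!r}")
        expected = list(range(1, len(occ) + 1))
        if list(occ) != expected:
            gap = next(e for e, o in zip(expected, list(occ) + [None]) if o != e)
            raise DesignError(f"non-contiguous occasions for unit {unit!r}: expected {gap}")
        out.append(MeasurementSeries(unit_id=unit, values=tuple(sub["value"].astype(float))))
    if not out:
        raise DesignError(f"series CSV {path} holds no data rows")
    return out


def write_series_csv(series_set: Sequence[MeasurementSeries], path) -> None:
    rows = [(s.unit_id, t, repr(v)) for s in series_set for t, v in enumerate(s.values, start=1)]
    # repr gives the shortest decimal that round-trips the binary float
    pd.DataFrame(rows, columns=list(_SERIES_COLUMNS)).to_csv(path, index=False)


def read_assignment_csv(path) -> dict[str, Tuple[str, ...]]:
    """Realized per-occasion labels, keyed by unit (``unit,occasion,label``)."""
    df = pd.read_csv(path)
    for c in ("unit", "occasion", "label"):
        if c not in df.columns:
            raise DesignError(f"assignment CSV {path} lacks column {c!r}")
    out: dict[str, Tuple[str, ...]] = {}
    for unit in df["unit"].astype(str).drop_duplicates():
        sub = df[df["unit"].astype(str) == unit].sort_values("occasion")
        out[unit] = tuple(sub["label"].astype(str))
    return out


def write_assignment_csv(assignment: Assignment, path,
                         unit_ids: Optional[Sequence[str]] = None) -> None:
    """Write a realized assignment: per-occasion labels, or for start/change
    vectors one semicolon-joined row per design."""
    if assignment.labels is not None:
        unit = (unit_ids or ["unit1"])[0]
        rows = [(unit, t, lab) for t, lab in enumerate(assignment.labels, start=1)]
        pd.DataFrame(rows, columns=["unit", "occasion", "label"]).to_csv(path, index=False)
        return
    vec = assignment.start_points if assignment.start_points is not None else assignment.change_points
    kind = "start_points" if assignment.start_points is not None else "change_points"
    pd.DataFrame([{"kind": kind, "vector": ";".join(str(v) for v in vec)}]).to_csv(path, index=False)


def read_criteria_csv(path) -> Tuple[Tuple[float, float], ...]:
    """Per-treatment-phase (lower, upper) criteria from ``phase_label,lower,upper``."""
    df = pd.read_csv(path)
    for c in ("phase_label", "lower", "upper"):
        if c not in df.columns:
            raise DesignError(f"criteria CSV {path} lacks column {c!r}")
    return tuple((float(r.lower), float(r.upper)) for r in df.itertuples())


def read_config(path) -> dict:
    """Flat key:value configuration (YAML mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise DesignError(f"config {path} must be a flat key:value mapping")
    return cfg


def _parse_counts(raw) -> dict:
    if isinstance(raw, dict):
        return {str(k): int(v) for k, v in raw.items()}
    out = {}
    for part in str(raw).split(","):
        lab, _, num = part.partition("=")
        out[lab.strip()] = int(num)
    return out


def _parse_intlist(raw) -> Tuple[int, ...]:
    if isinstance(raw, (list, tuple)):
        return tuple(int(x) for x in raw)
    return tuple(int(x) for x in str(raw).replace(";", ",").split(",") if str(x).strip())


def _parse_changepoint_lists(raw) -> Tuple[Tuple[int, ...], ...]:
    if isinstance(raw, (list, tuple)):
        return tuple(tuple(int(x) for x in lst) for lst in raw)
    return tuple(tuple(int(x) for x in grp.split(",")) for grp in str(raw).split(";") if grp.strip())


def spec_from_config(cfg: dict):
    """Build a design spec from a flat config mapping with a ``design`` key
    in {phase, crd, atd, rbd, mbd, ccd}."""
    design = str(cfg.get("design", "")).lower()
    if design == "phase":
        pattern = cfg["pattern"]
        if isinstance(pattern, str):
            pattern = tuple(pattern)
        return PhaseDesignSpec(phase_pattern=tuple(pattern), n=int(cfg["n"]),
                               min_phase_length=int(cfg.get("min_phase_length", 1)))
    if design in ("crd", "atd"):
        scheme = "completely_randomized" if design == "crd" else "alternating_treatments"
        counts = _parse_counts(cfg["counts"]) if "counts" in cfg else None
        return AlternationDesignSpec(
            scheme=scheme, n=int(cfg["n"]), condition_counts=counts,
            max_run=int(cfg["max_run"]) if cfg.get("max_run") is not None else None,
            unrestricted=bool(cfg.get("unrestricted", False)),
            treatments=tuple(str(cfg["conditions"]).split(",")) if "conditions" in cfg else None)
    if design == "rbd":
        treatments = cfg.get("treatments")
        if isinstance(treatments, str):
            treatments = tuple(t.strip() for t in treatments.split(","))
        return AlternationDesignSpec(
            scheme="randomized_block", n_blocks=int(cfg["n_blocks"]),
            treatments_per_block=int(cfg["treatments_per_block"]),
            treatments=tuple(treatments) if treatments else None)
    if design == "mbd":
        window = cfg["window"]
        if isinstance(window, str):
            lo, _, hi = window.replace("-", ":").partition(":")
            window = (int(lo), int(hi))
        return MultipleBaselineSpec(
            n_units=int(cfg["n_units"]), n=int(cfg["n"]),
            start_window=(int(window[0]), int(window[1])),
            distinct_starts=bool(cfg.get("distinct_starts", True)),
            min_stagger=int(cfg["min_stagger"]) if cfg.get("min_stagger") is not None else None)
    if design == "ccd":
        labels = cfg.get("phase_labels")
        cands = _parse_changepoint_lists(cfg["changepoints"])
        if labels is None:
            labels = tuple(["A"] + [f"B{i + 1}" for i in range(len(cands))])
        elif isinstance(labels, str):
            labels = tuple(s.strip() for s in labels.split(","))
        criteria = cfg.get("criteria")
        if isinstance(criteria, str):
            criteria = read_criteria_csv(criteria)
        else:
            criteria = tuple(
                (float(c), float(c)) if not isinstance(c, (list, tuple)) else (float(c[0]), float(c[1]))
                for c in criteria)
        return ChangingCriterionSpec(
            phase_labels=tuple(labels), n=int(cfg["n"]), candidate_changepoints=cands,
            criterion_schedule=criteria,
            criterion_direction=str(cfg.get("direction", "decrease")),
            baseline_criterion_rule=str(cfg.get("baseline_rule", "median_of_baseline")),
            baseline_criterion_value=(float(cfg["baseline_value"])
                                      if cfg.get("baseline_value") is not None else None))
    raise DesignError(f"unknown design {design!r}; expected phase, crd, atd, rbd, mbd or ccd")


def effect_model_from_config(cfg: dict) -> EffectModel:
    known = {"mu", "delta", "sigma", "ar1", "trend", "shifts", "ccd_adherence_sd"}
    kwargs = {k: v for k, v in cfg.items() if k in known}
    return EffectModel(**kwargs)


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass(frozen=True)
class RunReport:
    """Self-describing record of one randomization-test run; round-trips
    losslessly through JSON."""

    design_summary: str
    statistic_name: str
    result: dict
    reference_summary: dict
    provenance: dict

    def to_json(self) -> str:
        return json.dumps({
            "design": self.design_summary,
            "statistic": self.statistic_name,
            "result": self.result,
            "reference": self.reference_summary,
            "provenance": self.provenance,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunReport":
        obj = json.loads(text)
        return cls(design_summary=obj["design"], statistic_name=obj["statistic"],
                   result=obj["result"], reference_summary=obj["reference"],
                   provenance=obj["provenance"])
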