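"""Neurological Deficit Scale (NDS) scoring.

The NDS is a 0-70 rubric used to quantify neurological recovery of rats
after cardiac arrest: six assessment blocks (arousal, brainstem reflexes,
motor strength, sensory withdrawal, motor-behavioral, behavioral) with
enumerated subscores per component.  A healthy rat scores 70; deeper
deficits score lower.  Animals are assessed at 4, 24, 48 and 72 h
post-arrest.

The rubric ships as a human-editable TOML file (``data/nds_rubric.toml``)
and is self-checked at load: block maxima must be (19, 21, 6, 6, 6, 12)
and sum to 70, and every component's legal set must contain 0.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NdsRubric",
    "RubricComponent",
    "NdsScoreSheet",
    "ValidationReport",
    "GroupSummary",
    "load_rubric",
    "default_rubric",
    "validate_sheet",
    "total_score",
    "cohort_summary",
    "compose_subscores",
    "sheets_to_frame",
    "sheets_from_frame",
]

VALID_TIMEPOINTS_H = (4, 24, 48, 72)

_EXPECTED_ASSESSMENT_MAXIMA = {
    "arousal": 19,
    "brainstem": 21,
    "motor": 6,
    "sensory": 6,
    "motor_behavioral": 6,
    "behavioral": 12,
}


@dataclass(frozen=True)
class RubricComponent:
    name: str
    assessment: str
    levels: tuple[tuple[str, int], ...]

    @property
    def legal_values(self) -> frozenset[int]:
        return frozenset(v for _, v in self.levels)

    @property
    def max_value(self) -> int:
        return max(v for _, v in self.levels)


@dataclass(frozen=True)
class NdsRubric:
    version: str
    components: tuple[RubricComponent, ...]

    def __post_init__(self) -> None:
        self.self_check()

    def self_check(self) -> None:
        """Structural audit run at load time."""
        maxima = self.assessment_maxima()
        if maxima != _EXPECTED_ASSESSMENT_MAXIMA:
            raise ValueError(f"assessment maxima {maxima} differ from the instrument")
        if self.total_max() != 70:
            raise ValueError("rubric maximum must be 70")
        for c in self.components:
            if 0 not in c.legal_values:
                raise ValueError(f"component {c.name} has no zero level")

    def assessment_maxima(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for c in self.components:
            out[c.assessment] = out.get(c.assessment, 0) + c.max_value
        return out

    def total_max(self) -> int:
        return sum(c.max_value for c in self.components)

    def component(self, name: str) -> RubricComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def component_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    def reachable_totals(self) -> tuple[np.ndarray, list[int]]:
        """Suffix-reachability of exact totals (bitmask per component index).

        ``masks[i]`` has bit t set iff components i..end can sum to t.
        Returned together with the sorted list of reachable full totals.
        Not every integer in [0, 70] is a legal total (e.g. 69 is not).
        """
        n = len(self.components)
        masks = [0] * (n + 1)
        masks[n] = 1
        for i in range(n - 1, -1, -1):
            m = 0
            for v in self.components[i].legal_values:
                m |= masks[i + 1] << v
            masks[i] = m
        reachable = [t for t in range(self.total_max() + 1) if (masks[0] >> t) & 1]
        return np.array(masks, dtype=object), reachable


def load_rubric(path) -> NdsRubric:
    """Load a rubric from a TOML file and self-check it."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    return _rubric_from_dict(raw)


def _rubric_from_dict(raw: Mapping) -> NdsRubric:
    comps = tuple(
        RubricComponent(
            name=c["name"],
            assessment=c["assessment"],
            levels=tuple((str(lab), int(v)) for lab, v in c["levels"]),
        )
        for c in raw["component"]
    )
    return NdsRubric(version=str(raw.get("version", "?")), components=comps)


@lru_cache(maxsize=1)
def default_rubric() -> NdsRubric:
    """The packaged instrument rubric."""
    text = resources.files("ca_recovery.data").joinpath("nds_rubric.toml").read_bytes()
    return _rubric_from_dict(tomllib.loads(text.decode()))


@dataclass
class NdsScoreSheet:
    """One animal x timepoint set of component subscores."""

    animal_id: str
    group: str
    timepoint_h: int
    subscores: dict[str, int]

    def total(self) -> int:
        return int(sum(self.subscores.values()))


@dataclass
class ValidationReport:
    issues: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.issues


def validate_sheet(sheet: NdsScoreSheet, rubric: NdsRubric | None = None) -> ValidationReport:
    """List every violation of the rubric's enumerations (report, not raise)."""
    rub = rubric or default_rubric()
    report = ValidationReport()
    if sheet.timepoint_h not in VALID_TIMEPOINTS_H:
        report.issues.append(
            f"timepoint {sheet.timepoint_h} h not in {VALID_TIMEPOINTS_H}"
        )
    for comp in rub.components:
        if comp.name not in sheet.subscores:
            report.issues.append(f"missing component: {comp.name}")
            continue
        v = sheet.subscores[comp.name]
        if v not in comp.legal_values:
            report.issues.append(
                f"illegal subscore {v} for {comp.name} "
                f"(legal: {sorted(comp.legal_values)})"
            )
    for name in sheet.subscores:
        if name not in rub.component_names:
            report.issues.append(f"unknown component: {name}")
    return report


def total_score(sheet: NdsScoreSheet, rubric: NdsRubric | None = None) -> int:
    """Sum of component subscores; raises if the sheet violates the rubric."""
    report = validate_sheet(sheet, rubric)
    if not report.ok:
        raise ValueError("invalid score sheet: " + "; ".join(report.issues))
    return sheet.total()


@dataclass
class GroupSummary:
    group: str
    n: int
    representation: str  # "mean_sd" or "median_iqr"
    center: float
    spread: tuple[float, float]  # (sd, sd) or (q25, q75)
    gate_passed: bool


def cohort_summary(
    sheets: Iterable[NdsScoreSheet],
    timepoint_h: int,
    normality_gate=None,
    rubric: NdsRubric | None = None,
) -> dict[str, GroupSummary]:
    """Per-group summary at a timepoint, gated on distributional normality.

    If the gate (default: Lilliefors-corrected KS at alpha 0.05) passes in
    *both* groups the summary is mean +/- SD, otherwise median + IQR.
    Quartiles use linear interpolation (numpy default, type 7).  Requires
    >= 2 animals per group at the timepoint.
    """
    if normality_gate is None:
        from .stats import ks_normality

        def normality_gate(values):
            return bool(ks_normality(values).metadata["gate_passes"])

    totals: dict[str, list[float]] = {}
    for s in sheets:
        if s.timepoint_h == timepoint_h:
            totals.setdefault(s.group, []).append(total_score(s, rubric))
    if not totals:
        raise ValueError(f"no sheets at timepoint {timepoint_h} h")
    for g, vals in totals.items():
        if len(vals) < 2:
            raise ValueError(f"group {g} has fewer than 2 animals at {timepoint_h} h")
    parametric = all(normality_gate(np.asarray(v, dtype=float)) for v in totals.values())
    out: dict[str, GroupSummary] = {}
    for g, vals in sorted(totals.items()):
        arr = np.asarray(vals, dtype=float)
        if parametric:
            out[g] = GroupSummary(
                group=g,
                n=arr.size,
                representation="mean_sd",
                center=float(arr.mean()),
                spread=(float(arr.std(ddof=1)), float(arr.std(ddof=1))),
                gate_passed=True,
            )
        else:
            q25, q75 = np.percentile(arr, [25, 75])  # linear interpolation
            out[g] = GroupSummary(
                group=g,
                n=arr.size,
                representation="median_iqr",
                center=float(np.median(arr)),
                spread=(float(q25), float(q75)),
                gate_passed=False,
            )
    return out


def compose_subscores(
    target_total: float,
    rubric: NdsRubric | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """Realize a target total as an exact legal subscore assignment.

    The target is rounded to the nearest reachable total (ties toward the
    lower value), then decomposed with a suffix-reachability DP.  When an
    ``rng`` is given, component values are chosen uniformly among the
    feasible options so repeated calls vary; otherwise the largest feasible
    value is taken at each step.
    """
    rub = rubric or default_rubric()
    masks, reachable = _cached_reachability(rub)
    t = int(np.clip(round(target_total), 0, rub.total_max()))
    if not (masks[0] >> t) & 1:
        t = min(reachable, key=lambda r: (abs(r - t), r))
    out: dict[str, int] = {}
    rem = t
    for i, comp in enumerate(rub.components):
        feasible = [
            v
            for v in sorted(comp.legal_values, reverse=True)
            if v <= rem and (masks[i + 1] >> (rem - v)) & 1
        ]
        v = int(rng.choice(feasible)) if rng is not None else feasible[0]
        out[comp.name] = v
        rem -= v
    assert rem == 0
    return out


_REACH_CACHE: dict[int, tuple] = {}


def _cached_reachability(rub: NdsRubric):
    key = id(rub)
    if key not in _REACH_CACHE:
        _REACH_CACHE[key] = rub.reachable_totals()
    return _REACH_CACHE[key]


def sheets_to_frame(sheets: Sequence[NdsScoreSheet]) -> pd.DataFrame:
    """Long-format table: animal, group, timepoint_h, component, subscore."""
    rows = []
    for s in sheets:
        for comp, v in s.subscores.items():
            rows.append(
                {
                    "animal": s.animal_id,
                    "group": s.group,
                    "timepoint_h": s.timepoint_h,
                    "component": comp,
                    "subscore": int(v),
                }
            )
    return pd.DataFrame(rows)


def sheets_from_frame(frame: pd.DataFrame) -> list[NdsScoreSheet]:
    """Inverse of :func:`sheets_to_frame` (round-trip identity)."""
    sheets = []
    for (animal, group, tp), sub in frame.groupby(
        ["animal", "group", "timepoint_h"], sort=True
    ):
        sheets.append(
            NdsScoreSheet(
                animal_id=str(animal),
                group=str(group),
                timepoint_h=int(tp),
                subscores={
                    str(r.component): int(r.subscore) for r in sub.itertuples()
                },
            )
        )
    return sheets
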