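"""Indicator system: grade intervals, indicator specs and the evaluation hierarchy.

A multifunctional-river indicator system is a four-layer tree — target,
criterion (A-level river functions), sub-criterion (B-level secondary
functions) and indicator (C-level measurable quantities) — together with a
five-grade classification ladder per indicator:

    I (excellent) > II (good) > III (moderate) > IV (bad) > V (poor).

Each grade is a real interval in the indicator's own units.  Indicator
*direction* governs the interval layout:

* ``positive``  — larger is better; grade I occupies the high end.
* ``negative``  — smaller is better; grade I occupies the low end.
* ``bidirectional`` — best within a central band; grades II..V split into a
  branch below and a branch above the band.
* ``categorical`` — an ordinal score; each grade is a single category value.

This module owns loading/validation of the system and the crisp (interval
lookup) classification that the fuzzy machinery refines.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .errors import DomainError, SystemValidationError

GRADES: tuple[str, ...] = ("I", "II", "III", "IV", "V")
DIRECTIONS: tuple[str, ...] = ("positive", "negative", "bidirectional", "categorical")

_EPS = 1e-12


@dataclass(frozen=True)
class GradeInterval:
    """A real interval with explicit endpoint closure.

    ``lower``/``upper`` may be ``-inf``/``+inf`` (at most one side), and a
    degenerate single point is encoded as ``lower == upper`` with both ends
    closed.
    """

    lower: float
    upper: float
    lower_closed: bool = True
    upper_closed: bool = True

    def __post_init__(self) -> None:
        if math.isinf(self.lower) and math.isinf(self.upper):
            raise SystemValidationError("interval unbounded on both sides")
        if self.lower > self.upper:
            raise SystemValidationError(
                f"interval lower bound {self.lower} exceeds upper bound {self.upper}"
            )
        if self.lower == self.upper and not (self.lower_closed and self.upper_closed):
            raise SystemValidationError("singleton interval must be closed on both sides")

    # -- queries ---------------------------------------------------------
    @property
    def width(self) -> float:
        return self.upper - self.lower

    @property
    def is_singleton(self) -> bool:
        return self.lower == self.upper

    @property
    def is_bounded(self) -> bool:
        return math.isfinite(self.lower) and math.isfinite(self.upper)

    @property
    def midpoint(self) -> float:
        if not self.is_bounded:
            raise ValueError("midpoint of an unbounded interval is undefined")
        return 0.5 * (self.lower + self.upper)

    def contains(self, x: float) -> bool:
        lo_ok = x > self.lower or (self.lower_closed and x == self.lower)
        hi_ok = x < self.upper or (self.upper_closed and x == self.upper)
        return lo_ok and hi_ok

    def __str__(self) -> str:
        if self.is_singleton:
            return f"= {self.lower:g}"
        if math.isinf(self.upper):
            return f">{'=' if self.lower_closed else ''} {self.lower:g}"
        if math.isinf(self.lower):
            return f"<{'=' if self.upper_closed else ''} {self.upper:g}"
        lo = "[" if self.lower_closed else "("
        hi = "]" if self.upper_closed else ")"
        return f"{lo}{self.lower:g}, {self.upper:g}{hi}"


_INTERVAL_RE = re.compile(
    r"^\s*([\[\(])\s*([-+0-9.eE]+)\s*,\s*([-+0-9.eE]+)\s*([\]\)])\s*$"
)
_HALFLINE_RE = re.compile(r"^\s*(>=|>|<=|<)\s*([-+0-9.eE]+)\s*$")
_POINT_RE = re.compile(r"^\s*=?\s*([-+0-9.eE]+)\s*$")


def parse_interval(text: str) -> GradeInterval:
    """Parse bracket notation (``[a, b)``), half-lines (``> v``) or a bare
    value / ``= v`` singleton into a :class:`GradeInterval`."""
    m = _INTERVAL_RE.match(text)
    if m:
        lo_b, lo, hi, hi_b = m.groups()
        return GradeInterval(float(lo), float(hi), lo_b == "[", hi_b == "]")
    m = _HALFLINE_RE.match(text)
    if m:
        op, v = m.groups()
        val = float(v)
        if op in (">", ">="):
            return GradeInterval(val, math.inf, op == ">=", False)
        return GradeInterval(-math.inf, val, False, op == "<=")
    m = _POINT_RE.match(text)
    if m:
        val = float(m.group(1))
        return GradeInterval(val, val, True, True)
    raise SystemValidationError(f"cannot parse interval {text!r}")


@dataclass(frozen=True)
class IndicatorSpec:
    """One indicator: identity, direction, unit, hierarchy position and its
    five grade intervals (one or, for bidirectional indicators, two branch
    intervals per grade)."""

    id: str
    name: str
    unit: str
    direction: str
    criterion: str
    subcriterion: str
    grades: Mapping[str, tuple[GradeInterval, ...]]

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise SystemValidationError(
                f"{self.id}: unknown direction {self.direction!r}"
            )
        if set(self.grades) != set(GRADES):
            raise SystemValidationError(
                f"{self.id}: expected grade levels {GRADES}, got {tuple(self.grades)}"
            )
        for g, branches in self.grades.items():
            if not branches:
                raise SystemValidationError(f"{self.id} grade {g}: no interval")
            if len(branches) > 1 and self.direction != "bidirectional":
                raise SystemValidationError(
                    f"{self.id} grade {g}: branch intervals only allowed for "
                    "bidirectional indicators"
                )
        _validate_grade_layout(self)

    # -- queries ---------------------------------------------------------
    def branches(self) -> Iterable[tuple[str, GradeInterval]]:
        """All (grade, branch interval) pairs in grade order."""
        for g in GRADES:
            for iv in self.grades[g]:
                yield g, iv

    @property
    def domain(self) -> GradeInterval:
        """Convex hull of all grade intervals (the indicator's domain for
        non-categorical indicators)."""
        lows = [iv.lower for _, iv in self.branches()]
        highs = [iv.upper for _, iv in self.branches()]
        lo, hi = min(lows), max(highs)
        lo_closed = any(iv.lower_closed for _, iv in self.branches() if iv.lower == lo)
        hi_closed = any(iv.upper_closed for _, iv in self.branches() if iv.upper == hi)
        return GradeInterval(lo, hi, lo_closed, hi_closed)

    @property
    def ideal_center(self) -> float:
        """Center of the grade-I band for bidirectional indicators."""
        if self.direction != "bidirectional":
            raise ValueError(f"{self.id} is not bidirectional")
        return self.grades["I"][0].midpoint

    def category_values(self) -> dict[str, float]:
        """Grade -> category value for categorical indicators."""
        if self.direction != "categorical":
            raise ValueError(f"{self.id} is not categorical")
        return {g: self.grades[g][0].lower for g in GRADES}


def _validate_grade_layout(spec: IndicatorSpec) -> None:
    """Check that the grade branches tile the domain: pairwise disjoint,
    adjacent branches sharing a boundary value with complementary closure.

    Categorical indicators are exempt (isolated category points)."""
    if spec.direction == "categorical":
        vals = [spec.grades[g][0] for g in GRADES]
        if not all(iv.is_singleton for iv in vals):
            raise SystemValidationError(
                f"{spec.id}: categorical grades must be single category values"
            )
        if len({iv.lower for iv in vals}) != len(vals):
            raise SystemValidationError(f"{spec.id}: duplicated category value")
        return

    tagged = sorted(spec.branches(), key=lambda t: (t[1].lower, t[1].upper))
    for (g_a, a), (g_b, b) in zip(tagged, tagged[1:]):
        if b.lower < a.upper - _EPS:
            raise SystemValidationError(
                f"{spec.id}: grades {g_a} {a} and {g_b} {b} overlap"
            )
        if b.lower > a.upper + _EPS:
            raise SystemValidationError(
                f"{spec.id}: coverage gap between grades {g_a} {a} and {g_b} {b}"
            )
        # shared boundary: exactly one side may claim the point
        if a.upper_closed and b.lower_closed and not (a.is_singleton or b.is_singleton):
            raise SystemValidationError(
                f"{spec.id}: grades {g_a} and {g_b} both include boundary {a.upper:g}"
            )
        if not a.upper_closed and not b.lower_closed:
            raise SystemValidationError(
                f"{spec.id}: boundary {a.upper:g} between grades {g_a} and {g_b} "
                "belongs to neither"
            )


@dataclass(frozen=True)
class Hierarchy:
    """Ordered target -> criterion -> sub-criterion -> indicator tree."""

    criteria: Mapping[str, tuple[str, ...]]  # criterion id -> sub-criterion ids
    subcriteria: Mapping[str, tuple[str, ...]]  # sub-criterion id -> indicator ids

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c, subs in self.criteria.items():
            for s in subs:
                if s not in self.subcriteria:
                    raise SystemValidationError(
                        f"criterion {c} references unknown sub-criterion {s}"
                    )
                if s in seen:
                    raise SystemValidationError(f"sub-criterion {s} has two parents")
                seen.add(s)
        if seen != set(self.subcriteria):
            orphans = sorted(set(self.subcriteria) - seen)
            raise SystemValidationError(f"orphan sub-criteria: {orphans}")
        leaves = [i for subs in self.subcriteria.values() for i in subs]
        if len(leaves) != len(set(leaves)):
            raise SystemValidationError("an indicator appears under two parents")

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(self.criteria)

    @property
    def indicator_ids(self) -> tuple[str, ...]:
        return tuple(
            i for c in self.criteria for s in self.criteria[c] for i in self.subcriteria[s]
        )

    def indicators_of(self, criterion: str) -> tuple[str, ...]:
        return tuple(i for s in self.criteria[criterion] for i in self.subcriteria[s])

    def criterion_of(self, indicator: str) -> str:
        for c in self.criteria:
            if indicator in self.indicators_of(c):
                return c
        raise SystemValidationError(f"indicator {indicator} has no parent criterion")


def _parse_branches(raw) -> tuple[GradeInterval, ...]:
    if isinstance(raw, (list, tuple)):
        return tuple(parse_interval(str(r)) for r in raw)
    return (parse_interval(str(raw)),)


def load_system(source) -> tuple[Hierarchy, list[IndicatorSpec]]:
    """Load and validate an indicator system.

    ``source`` is a YAML/JSON-style mapping, a path to a YAML file, or
    ``None`` for the packaged default system.  Returns the hierarchy and
    the indicator specs in hierarchy order.
    """
    if source is None:
        source = default_system_path()
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            cfg = yaml.safe_load(fh)
    else:
        cfg = source

    try:
        raw_inds = cfg["indicators"]
    except (KeyError, TypeError):
        raise SystemValidationError("config lacks an 'indicators' section")

    specs: dict[str, IndicatorSpec] = {}
    for entry in raw_inds:
        try:
            spec = IndicatorSpec(
                id=entry["id"],
                name=entry.get("name", entry["id"]),
                unit=str(entry.get("unit", "-")),
                direction=entry["direction"],
                criterion=entry["criterion"],
                subcriterion=entry["subcriterion"],
                grades={g: _parse_branches(entry["grades"][g]) for g in GRADES},
            )
        except KeyError as exc:
            raise SystemValidationError(
                f"indicator entry {entry.get('id', '?')} missing field {exc}"
            ) from None
        if spec.id in specs:
            raise SystemValidationError(f"duplicate indicator {spec.id}")
        specs[spec.id] = spec

    if "hierarchy" in cfg:
        h = cfg["hierarchy"]
        hierarchy = Hierarchy(
            criteria={c: tuple(subs) for c, subs in h["criteria"].items()},
            subcriteria={s: tuple(inds) for s, inds in h["subcriteria"].items()},
        )
    else:  # derive the tree from the specs' parent fields
        crit: dict[str, list[str]] = {}
        sub: dict[str, list[str]] = {}
        for spec in specs.values():
            crit.setdefault(spec.criterion, [])
            if spec.subcriterion not in crit[spec.criterion]:
                crit[spec.criterion].append(spec.subcriterion)
            sub.setdefault(spec.subcriterion, []).append(spec.id)
        hierarchy = Hierarchy(
            criteria={c: tuple(v) for c, v in crit.items()},
            subcriteria={s: tuple(v) for s, v in sub.items()},
        )

    for ind in hierarchy.indicator_ids:
        if ind not in specs:
            raise SystemValidationError(f"hierarchy references missing indicator {ind}")
    for spec in specs.values():
        if spec.id not in hierarchy.indicator_ids:
            raise SystemValidationError(
                f"indicator {spec.id} not placed in the hierarchy"
            )
        if hierarchy.criterion_of(spec.id) != spec.criterion:
            raise SystemValidationError(
                f"indicator {spec.id}: criterion field {spec.criterion} disagrees "
                "with the hierarchy"
            )

    ordered = [specs[i] for i in hierarchy.indicator_ids]
    return hierarchy, ordered


def default_system_path() -> Path:
    """Path of the packaged Xiaoqing River indicator-system fixture."""
    return Path(resources.files("riverfce.data") / "xiaoqing_system.yaml")


def classify_crisp(x: float, spec: IndicatorSpec) -> str:
    """Crisp five-grade classification: the unique grade whose interval (or
    branch union) contains ``x``.

    Raises :class:`DomainError` when ``x`` falls outside every grade, which
    can only happen for systems bounded on the relevant side (e.g. a
    percentage above 100) or between categorical score values.
    """
    if not math.isfinite(x):
        raise DomainError(f"{spec.id}: value {x!r} is not finite")
    if spec.direction == "categorical":
        for g, val in spec.category_values().items():
            if abs(x - val) <= 1e-9:
                return g
        raise DomainError(
            f"{spec.id}: {x:g} is not one of the category values "
            f"{sorted(spec.category_values().values())}"
        )
    for g in GRADES:
        if any(iv.contains(x) for iv in spec.grades[g]):
            return g
    raise DomainError(f"{spec.id}: value {x:g} outside domain {spec.domain}")
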