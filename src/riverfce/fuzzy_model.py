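"""Cauchy-membership fuzzy comprehensive evaluation.

Every grade g of every indicator gets a Cauchy-shaped membership function

    r_g(x) = 1 / (1 + a2 * (x - a1)^2)

parameterized from the grade's interval [xv, xu]:

* interior grades (both interval endpoints shared with a neighboring
  grade): a1 = interval midpoint, a2 = 4 / width^2 — so r = 1 at the center
  and exactly 0.5 at both interval boundaries;
* extreme grades (one endpoint is a pole not shared with any neighbor):
  a1 = the pole (the ideal end for grade I of a well-oriented ladder, the
  worst end for grade V), a2 = 4 / width^2, and the membership saturates at
  1 beyond the pole;
* unbounded extreme grades (e.g. "> 3"): the width is borrowed from the
  adjacent grade, a1 sits that borrowed width beyond the shared boundary,
  and the membership saturates at 1 past a1;
* single-point grades (e.g. a diversity index of exactly 0): a1 = the
  point, with an effective width of ``SINGLETON_WIDTH_FRACTION`` times the
  adjacent grade's width, saturating on the far side.  A point class is the
  zero-width limit of the interval formula (a2 -> infinity), so its
  membership must collapse onto the point; a strictly positive effective
  width keeps the function finite and strictly decreasing while leaving the
  adjacent grade dominant everywhere strictly inside its own interval;
* categorical indicators: unit-width parameterization around each category
  value (a1 = the value, a2 = 4).

Bidirectional indicators evaluate both branch intervals per grade and take
the larger membership.

One evaluation unit's values yield the affiliation matrix R (indicators x
5 grades); composing with a weight vector W gives the comprehensive
evaluation vector D = W . R, and the assigned grade is the maximum of D
(maximum-affiliation principle), ties resolved toward the worse grade.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import MatrixValidationError
from .indicator_system import (
    GRADES,
    GradeInterval,
    Hierarchy,
    IndicatorSpec,
    classify_crisp,
)

_SHARED_TOL = 1e-9

#: Effective width of a single-point grade, as a fraction of the adjacent
#: grade's width.  The zero-width limit of the Cauchy parameterization is a
#: point mass; this fraction keeps a2 finite (strict monotone decay) while
#: making the point grade's membership negligible beyond the sampling
#: margin used elsewhere in the package.
SINGLETON_WIDTH_FRACTION = 1e-6

Operator = Literal["weighted_average", "max_min"]


@dataclass(frozen=True)
class MembershipParams:
    """Cauchy parameters of one grade branch: peak location a1 (indicator
    units), curvature a2 (1/units^2), and an optional saturation side on
    which the membership is clamped to 1."""

    a1: float
    a2: float
    grade: str
    saturate: str | None = None  # None | "low" | "high"

    def __post_init__(self) -> None:
        if not self.a2 > 0:
            raise MatrixValidationError(f"a2 must be positive, got {self.a2}")

    def __call__(self, x: float) -> float:
        if self.saturate == "high" and x >= self.a1:
            return 1.0
        if self.saturate == "low" and x <= self.a1:
            return 1.0
        return 1.0 / (1.0 + self.a2 * (x - self.a1) ** 2)


def _shared_endpoints(spec: IndicatorSpec, me: GradeInterval) -> tuple[bool, bool]:
    """Which finite endpoints of ``me`` coincide with an endpoint of some
    other grade's branch."""
    others = [iv for g, iv in spec.branches() if iv is not me]
    pts = [p for iv in others for p in (iv.lower, iv.upper) if math.isfinite(p)]

    def shared(p: float) -> bool:
        return math.isfinite(p) and any(abs(p - q) <= _SHARED_TOL for q in pts)

    return shared(me.lower), shared(me.upper)


def _adjacent_width(spec: IndicatorSpec, point: float, me: GradeInterval) -> float:
    """Width of the neighboring branch that shares ``point`` with ``me``."""
    for _, iv in spec.branches():
        if iv is me or not iv.is_bounded or iv.is_singleton:
            continue
        if abs(iv.lower - point) <= _SHARED_TOL or abs(iv.upper - point) <= _SHARED_TOL:
            return iv.width
    raise MatrixValidationError(
        f"{spec.id}: no finite-width neighbor at {point:g} to borrow a width from"
    )


def _branch_params(spec: IndicatorSpec, grade: str, iv: GradeInterval) -> MembershipParams:
    if spec.direction == "categorical":
        return MembershipParams(a1=iv.lower, a2=4.0, grade=grade)

    if iv.is_singleton:
        w = SINGLETON_WIDTH_FRACTION * _adjacent_width(spec, iv.lower, iv)
        lo_shared, hi_shared = _shared_endpoints(spec, iv)
        sat = "low" if hi_shared else "high"  # saturate away from the neighbor
        return MembershipParams(a1=iv.lower, a2=4.0 / w**2, grade=grade, saturate=sat)

    if not iv.is_bounded:  # unbounded extreme grade: borrow the neighbor width
        if math.isinf(iv.upper):
            w = _adjacent_width(spec, iv.lower, iv)
            return MembershipParams(
                a1=iv.lower + w, a2=4.0 / w**2, grade=grade, saturate="high"
            )
        w = _adjacent_width(spec, iv.upper, iv)
        return MembershipParams(
            a1=iv.upper - w, a2=4.0 / w**2, grade=grade, saturate="low"
        )

    lo_shared, hi_shared = _shared_endpoints(spec, iv)
    a2 = 4.0 / iv.width**2
    if lo_shared and hi_shared:  # interior grade: peak at the midpoint
        return MembershipParams(a1=iv.midpoint, a2=a2, grade=grade)
    if lo_shared:  # pole at the upper end
        return MembershipParams(a1=iv.upper, a2=a2, grade=grade, saturate="high")
    if hi_shared:  # pole at the lower end
        return MembershipParams(a1=iv.lower, a2=a2, grade=grade, saturate="low")
    raise MatrixValidationError(
        f"{spec.id} grade {grade}: isolated interval {iv} has no neighboring grade"
    )


def cauchy_params(spec: IndicatorSpec, grade: str) -> tuple[MembershipParams, ...]:
    """Cauchy membership parameters of one grade — one entry per branch
    interval (two for bidirectional indicators, otherwise one)."""
    if grade not in GRADES:
        raise ValueError(f"unknown grade {grade!r}")
    return tuple(_branch_params(spec, grade, iv) for iv in spec.grades[grade])


def grade_params(spec: IndicatorSpec) -> dict[str, tuple[MembershipParams, ...]]:
    """All five grades' membership parameters for one indicator."""
    return {g: cauchy_params(spec, g) for g in GRADES}


def membership_vector(x: float, spec: IndicatorSpec) -> np.ndarray:
    """Memberships of value ``x`` in the five grades of one indicator.

    Raises the same domain error as crisp classification for values outside
    the indicator's domain."""
    classify_crisp(x, spec)  # domain check
    params = grade_params(spec)
    return np.array([max(p(x) for p in params[g]) for g in GRADES])


def build_affiliation(
    values: Mapping[str, float] | pd.Series,
    specs: Sequence[IndicatorSpec] | Mapping[str, IndicatorSpec],
) -> pd.DataFrame:
    """Affiliation matrix R of one evaluation unit: one row per indicator,
    columns the five grade memberships."""
    if isinstance(specs, Mapping):
        specs = list(specs.values())
    missing = [s.id for s in specs if s.id not in values]
    if missing:
        raise MatrixValidationError(f"missing values for indicators: {missing}")
    rows = {s.id: membership_vector(float(values[s.id]), s) for s in specs}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(GRADES))


def argmax_grade(memberships: np.ndarray) -> str:
    """Maximum-affiliation grade; exact ties go to the worse grade
    (conservative assessment)."""
    best = 0
    for g in range(1, len(GRADES)):
        if memberships[g] >= memberships[best]:
            best = g
    return GRADES[best]


@dataclass(frozen=True)
class EvaluationVector:
    """A composed five-grade membership vector and its assigned grade."""

    memberships: np.ndarray
    grade: str
    layer: str  # indicator | criterion | target

    @property
    def normalized(self) -> np.ndarray:
        """Memberships rescaled to sum 1 for display; argmax unchanged."""
        s = self.memberships.sum()
        return self.memberships / s if s > 0 else self.memberships


def compose(
    W: np.ndarray | pd.Series,
    R: pd.DataFrame | np.ndarray,
    operator: Operator = "weighted_average",
    layer: str = "target",
) -> EvaluationVector:
    """Compose a weight vector with an affiliation matrix: D = W . R.

    ``weighted_average`` is the ordinary matrix product (all rows keep
    proportional influence; the natural choice when W sums to 1);
    ``max_min`` is the classical max-min fuzzy operator, provided for
    comparison."""
    w = np.asarray(W, dtype=float)
    r = R.to_numpy(dtype=float) if isinstance(R, pd.DataFrame) else np.asarray(R, float)
    if r.ndim != 2 or w.shape[0] != r.shape[0]:
        raise MatrixValidationError(
            f"weight vector of length {w.shape[0]} does not match {r.shape} matrix"
        )
    if operator == "weighted_average":
        d = w @ r
    elif operator == "max_min":
        d = np.max(np.minimum(w[:, None], r), axis=0)
    else:
        raise ValueError(f"unknown composition operator {operator!r}")
    return EvaluationVector(memberships=d, grade=argmax_grade(d), layer=layer)


@dataclass(frozen=True)
class LayerResults:
    """Per-layer evaluation of one unit: indicator memberships and grades,
    one composed vector per criterion, and the target-layer vector."""

    affiliation: pd.DataFrame  # indicators x grades
    indicator_grades: pd.Series
    criterion: dict[str, EvaluationVector]
    target: EvaluationVector

    def constraint_indicators(self) -> list[str]:
        """Indicators graded bad (IV) or poor (V) — the factors limiting
        this unit's function."""
        return [i for i, g in self.indicator_grades.items() if g in ("IV", "V")]

    def constraint_criteria(self) -> list[str]:
        return [c for c, v in self.criterion.items() if v.grade in ("IV", "V")]


def evaluate_layers(
    values: Mapping[str, float] | pd.Series,
    specs: Sequence[IndicatorSpec],
    fused_weights: pd.Series,
    hierarchy: Hierarchy,
    operator: Operator = "weighted_average",
) -> LayerResults:
    """Full three-layer evaluation of one unit.

    Indicator layer: per-row argmax of the affiliation matrix.  Criterion
    layer: member rows composed with the fused weights renormalized within
    the criterion.  Target layer: all rows composed with the global fused
    weights."""
    R = build_affiliation(values, specs)
    R = R.loc[list(hierarchy.indicator_ids)]
    ind_grades = pd.Series(
        {i: argmax_grade(R.loc[i].to_numpy()) for i in R.index}, name="grade"
    )
    w = fused_weights.reindex(R.index)
    if w.isna().any():
        raise MatrixValidationError("fused weights do not cover all indicators")
    crit: dict[str, EvaluationVector] = {}
    for c in hierarchy.criterion_ids:
        members = list(hierarchy.indicators_of(c))
        wc = w[members].to_numpy()
        crit[c] = compose(wc / wc.sum(), R.loc[members], operator, layer="criterion")
    target = compose(
        (w / w.sum()).to_numpy(), R, operator, layer="target"
    )
    return LayerResults(
        affiliation=R, indicator_grades=ind_grades, criterion=crit, target=target
    )
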