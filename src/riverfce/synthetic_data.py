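"""Synthetic evaluation scenarios with planted grade structure.

The study's raw per-segment indicator values were not published, so every
pipeline stage is exercised on generated data instead: a grade label is
planted for each (segment, indicator) cell, a value is placed inside that
grade's interval (deterministic midpoint or seeded uniform placement), and
near-consistent judgment matrices are drawn around a known weight vector.
Crisp re-classification of the generated values recovers the planted grades
by construction.

The default scenario emulates the study conditions: five river sections
ordered upstream to downstream with a deteriorating grade ladder (grade I
upstream through grade V downstream), the ecological-flow indicator C2 held
at grade I in every section (the published pattern that forces its entropy
weight to 0), and judgment matrices centered on the published AHP weights.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ahp import SAATY_SCALE, JudgmentMatrix
from .errors import SystemValidationError
from .fixtures import SEGMENTS, default_system, published_indicator_weights
from .fuzzy_model import grade_params
from .indicator_system import GRADES, GradeInterval, Hierarchy, IndicatorSpec

#: Relative margin by which uniform placement avoids interval boundaries.
BOUNDARY_MARGIN = 1e-6


def _sampling_interval(spec: IndicatorSpec, iv: GradeInterval, grade: str) -> tuple[float, float]:
    """Finite (lo, hi) range representing one grade branch; unbounded
    branches are capped at the membership model's virtual bound (the
    saturation point a1)."""
    if iv.is_singleton:
        return iv.lower, iv.lower
    if iv.is_bounded:
        return iv.lower, iv.upper
    # unbounded: virtual bound = the Cauchy peak of this grade
    for p in grade_params(spec)[grade]:
        if p.saturate == "high" and math.isinf(iv.upper):
            return iv.lower, p.a1
        if p.saturate == "low" and math.isinf(iv.lower):
            return p.a1, iv.upper
    raise SystemValidationError(f"{spec.id} grade {grade}: no virtual bound")


def place_value(
    spec: IndicatorSpec,
    grade: str,
    rng: np.random.Generator | None = None,
    placement: str = "midpoint",
) -> float:
    """A value strictly inside the planted grade.

    ``midpoint`` is deterministic (lowest branch for two-branch grades);
    ``uniform`` samples inside the interval, keeping a relative margin of
    ``BOUNDARY_MARGIN`` off each finite boundary, and picks a branch at
    random for bidirectional grades."""
    branches = spec.grades[grade]
    if placement == "midpoint":
        iv = branches[0]
        lo, hi = _sampling_interval(spec, iv, grade)
        return 0.5 * (lo + hi)
    if placement != "uniform":
        raise ValueError(f"unknown placement {placement!r}")
    if rng is None:
        raise ValueError("uniform placement needs a random generator")
    iv = branches[rng.integers(len(branches))] if len(branches) > 1 else branches[0]
    lo, hi = _sampling_interval(spec, iv, grade)
    if hi == lo:
        return lo
    margin = BOUNDARY_MARGIN * (hi - lo)
    return float(rng.uniform(lo + margin, hi - margin))


def generate_values(
    planted_grades: pd.DataFrame,
    specs: Sequence[IndicatorSpec] | Mapping[str, IndicatorSpec],
    seed: int | np.random.Generator = 0,
    placement: str = "midpoint",
) -> pd.DataFrame:
    """Segment x indicator value matrix realizing a planted grade table."""
    if not isinstance(specs, Mapping):
        specs = {s.id: s for s in specs}
    unknown = [c for c in planted_grades.columns if c not in specs]
    if unknown:
        raise SystemValidationError(f"planted grades for unknown indicators: {unknown}")
    bad = planted_grades.stack()[~planted_grades.stack().isin(GRADES)]
    if not bad.empty:
        raise SystemValidationError(f"invalid planted grades: {bad.to_dict()}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = pd.DataFrame(index=planted_grades.index, columns=planted_grades.columns, dtype=float)
    for col in planted_grades.columns:
        spec = specs[col]
        if planted_grades[col].nunique() == 1:
            # an indicator planted at one grade everywhere emulates a
            # quantity identical across sections (e.g. ecological-flow
            # satisfaction excellent in every section), so it gets one
            # deterministic value: its column is exactly constant and its
            # entropy weight exactly 0
            out[col] = place_value(spec, planted_grades[col].iloc[0])
            continue
        for row in planted_grades.index:
            out.loc[row, col] = place_value(spec, planted_grades.loc[row, col], rng, placement)
    return out


def snap_to_scale(value: float) -> float:
    """Nearest admissible 1-9 scale entry (or reciprocal)."""
    return min(SAATY_SCALE, key=lambda s: abs(s - value))


def generate_judgment_matrix(
    true_w: Sequence[float] | pd.Series,
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator = 0,
    labels: Sequence[str] | None = None,
    snap: bool = False,
) -> JudgmentMatrix:
    """A reciprocal judgment matrix around a known weight vector.

    Upper-triangle entries are a_ij = (w_i / w_j) * exp(eps_ij) with
    eps_ij ~ Normal(0, noise_sigma^2); reciprocals and a unit diagonal are
    filled in.  ``snap=True`` rounds entries to the 1-9 scale (and keeps
    reciprocity)."""
    w = np.asarray(true_w, dtype=float)
    if not np.all(w > 0):
        raise ValueError("true weights must be positive")
    w = w / w.sum()
    n = len(w)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if labels is None:
        labels = tuple(f"e{i + 1}" for i in range(n))
    a = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v = (w[i] / w[j]) * math.exp(rng.normal(0.0, noise_sigma))
            if snap:
                v = snap_to_scale(v)
            a[i, j] = v
            a[j, i] = 1.0 / v
    return JudgmentMatrix(a, tuple(labels))


def ladder_grades(
    indicator_ids: Sequence[str],
    segments: Sequence[str] = SEGMENTS,
    constant_excellent: Sequence[str] = ("C2",),
) -> pd.DataFrame:
    """Planted grade table with a deteriorating upstream-to-downstream
    ladder: segment k gets grade k+1 everywhere, except the indicators in
    ``constant_excellent`` which stay at grade I in every segment."""
    rows = {}
    for k, seg in enumerate(segments):
        g = GRADES[min(k, len(GRADES) - 1)]
        rows[seg] = {
            i: ("I" if i in constant_excellent else g) for i in indicator_ids
        }
    return (
        pd.DataFrame.from_dict(rows, orient="index")
        .reindex(columns=indicator_ids)
        .rename_axis("segment")
    )


@dataclass(frozen=True)
class Scenario:
    """A fully reproducible synthetic evaluation scenario."""

    seed: int
    planted_grades: pd.DataFrame
    values: pd.DataFrame
    judgment_matrices: dict[str, JudgmentMatrix]
    noise_sigma: float
    placement: str = "midpoint"

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.planted_grades.rename_axis("segment").to_csv(d / "planted_grades.csv")
        self.values.rename_axis("segment").to_csv(d / "values.csv", float_format="%.12g")
        judg = {
            name: {"labels": list(m.labels), "matrix": m.matrix.tolist()}
            for name, m in self.judgment_matrices.items()
        }
        with open(d / "judgments.yaml", "w") as fh:
            yaml.safe_dump(judg, fh, sort_keys=False)
        manifest = {
            "seed": self.seed,
            "noise_sigma": self.noise_sigma,
            "placement": self.placement,
            "segments": list(self.values.index),
            "indicators": list(self.values.columns),
        }
        with open(d / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, directory) -> "Scenario":
        d = Path(directory)
        with open(d / "manifest.json") as fh:
            manifest = json.load(fh)
        planted = pd.read_csv(d / "planted_grades.csv", index_col="segment")
        values = pd.read_csv(d / "values.csv", index_col="segment").astype(float)
        with open(d / "judgments.yaml") as fh:
            judg_raw = yaml.safe_load(fh)
        judg = {
            name: JudgmentMatrix(np.array(entry["matrix"]), tuple(entry["labels"]))
            for name, entry in judg_raw.items()
        }
        return cls(
            seed=manifest["seed"],
            planted_grades=planted,
            values=values,
            judgment_matrices=judg,
            noise_sigma=manifest["noise_sigma"],
            placement=manifest["placement"],
        )


def make_scenario(
    seed: int = 0,
    planted_grades: pd.DataFrame | None = None,
    noise_sigma: float = 0.0,
    placement: str = "midpoint",
    snap: bool = False,
    hierarchy: Hierarchy | None = None,
    specs: Sequence[IndicatorSpec] | None = None,
) -> Scenario:
    """Build the default five-section scenario (or one from a custom planted
    grade table) with judgment matrices centered on the published AHP
    weights."""
    if hierarchy is None or specs is None:
        hierarchy, specs = default_system()
    if planted_grades is None:
        planted_grades = ladder_grades(hierarchy.indicator_ids)
    rng = np.random.default_rng(seed)
    values = generate_values(planted_grades, specs, rng, placement)
    ahp_w = published_indicator_weights()["ahp"]
    crit_true = pd.Series(
        {c: ahp_w[list(hierarchy.indicators_of(c))].sum() for c in hierarchy.criterion_ids}
    )
    judg = {
        "criteria": generate_judgment_matrix(
            crit_true, noise_sigma, rng, labels=hierarchy.criterion_ids, snap=snap
        )
    }
    for c in hierarchy.criterion_ids:
        members = list(hierarchy.indicators_of(c))
        judg[c] = generate_judgment_matrix(
            ahp_w[members], noise_sigma, rng, labels=members, snap=snap
        )
    return Scenario(
        seed=seed,
        planted_grades=planted_grades,
        values=values,
        judgment_matrices=judg,
        noise_sigma=noise_sigma,
        placement=placement,
    )
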