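"""Cauchy membership functions, affiliation matrices and composition."""

import math

import numpy as np
import pandas as pd
import pytest

import riverfce as rf
from riverfce.errors import DomainError, MatrixValidationError
from riverfce.fuzzy_model import argmax_grade, grade_params
from riverfce.indicator_system import GRADES


class TestCauchyParams:
    def test_interior_grade_peaks_at_midpoint(self, spec_map):
        (p,) = rf.cauchy_params(spec_map["C11"], "IV")  # (80, 90]
        assert p.a1 == 85.0
        assert p.a2 == pytest.approx(4 / 100)
        assert p.saturate is None

    def test_worst_grade_of_negative_indicator_peaks_at_far_pole(self, spec_map):
        (p,) = rf.cauchy_params(spec_map["C11"], "V")  # (90, 100]
        assert p.a1 == 100.0
        assert p.a2 == pytest.approx(0.04)
        assert p.saturate == "high"

    def test_best_grade_of_positive_indicator_peaks_at_ideal_pole(self, spec_map):
        (p,) = rf.cauchy_params(spec_map["C2"], "I")  # [98, 100]
        assert p.a1 == 100.0
        assert p.a2 == pytest.approx(1.0)
        assert p.saturate == "high"

    def test_best_grade_of_negative_indicator_peaks_at_zero(self, spec_map):
        (p,) = rf.cauchy_params(spec_map["C1"], "I")  # [0, 0.2]
        assert p.a1 == 0.0
        assert p.saturate == "low"

    def test_unbounded_grade_borrows_neighbor_width(self, spec_map):
        (p,) = rf.cauchy_params(spec_map["C6"], "I")  # > 7.5, neighbor width 2.5
        assert p.a1 == 10.0
        assert p.a2 == pytest.approx(4 / 2.5**2)
        assert p.saturate == "high"

    def test_bidirectional_grades_have_two_branches(self, spec_map):
        branches = rf.cauchy_params(spec_map["C16"], "II")
        assert len(branches) == 2
        assert {b.a1 for b in branches} == {22.5, 35.0}
        (band,) = rf.cauchy_params(spec_map["C16"], "I")
        assert band.a1 == 27.5  # central band behaves as an interior grade
        assert band.saturate is None

    def test_categorical_unit_width(self, spec_map):
        (p,) = rf.cauchy_params(spec_map["C4"], "III")
        assert (p.a1, p.a2) == (3.0, 4.0)


class TestMembershipVector:
    def test_peak_membership_is_one(self, spec_map):
        mv = rf.membership_vector(85.0, spec_map["C11"])
        assert mv[GRADES.index("IV")] == 1.0

    def test_interior_boundary_ties_at_half(self, spec_map):
        mv = rf.membership_vector(80.0, spec_map["C11"])
        assert mv[GRADES.index("III")] == pytest.approx(0.5)
        assert mv[GRADES.index("IV")] == pytest.approx(0.5)

    def test_fragmentation_example(self, spec_map):
        # landscape fragmentation 81.2 %: bad with substantial moderate overlap
        mv = rf.membership_vector(81.2, spec_map["C11"])
        assert argmax_grade(mv) == "IV"
        assert mv[GRADES.index("IV")] == pytest.approx(1 / (1 + 0.04 * 3.8**2), abs=1e-12)
        assert mv[GRADES.index("IV")] == pytest.approx(0.6339, abs=5e-5)
        assert mv[GRADES.index("III")] == pytest.approx(0.4436, abs=5e-5)

    def test_saturation_beyond_extreme_pole(self, spec_map):
        mv = rf.membership_vector(99.0, spec_map["C2"])
        assert mv[GRADES.index("I")] == pytest.approx(0.5)
        assert rf.membership_vector(100.0, spec_map["C2"])[GRADES.index("I")] == 1.0

    def test_bidirectional_takes_best_branch(self, spec_map):
        mv_lo = rf.membership_vector(22.5, spec_map["C16"])
        mv_hi = rf.membership_vector(35.0, spec_map["C16"])
        assert mv_lo[GRADES.index("II")] == 1.0
        assert mv_hi[GRADES.index("II")] == 1.0

    def test_domain_error_propagates(self, spec_map):
        with pytest.raises(DomainError):
            rf.membership_vector(101.0, spec_map["C11"])

    def test_all_values_in_unit_interval(self, specs):
        rng = np.random.default_rng(21)
        for s in specs:
            if s.direction == "categorical":
                xs = list(s.category_values().values())
            else:
                dom = s.domain
                lo = dom.lower if math.isfinite(dom.lower) else 0.0
                hi = dom.upper if math.isfinite(dom.upper) else lo + 50.0
                xs = [x for x in rng.uniform(lo, hi, 20) if dom.contains(x)]
            for x in xs:
                mv = rf.membership_vector(x, s)
                assert ((mv > 0) & (mv <= 1)).all()


class TestMembershipIdentities:
    """Exhaustive structural identities over all 22 x 5 parameterizations."""

    def test_peak_value_is_one_everywhere(self, specs):
        for s in specs:
            for g, branches in grade_params(s).items():
                for p in branches:
                    assert p(p.a1) == 1.0, f"{s.id} {g}"

    def test_half_membership_at_interior_boundaries(self, specs):
        """Every interior (midpoint-parameterized) branch hits exactly 0.5
        at both of its interval endpoints."""
        checked = 0
        for s in specs:
            if s.direction == "categorical":
                continue
            params = grade_params(s)
            for g in GRADES:
                for iv, p in zip(s.grades[g], params[g]):
                    if p.saturate is None and not iv.is_singleton:
                        assert p(iv.lower) == pytest.approx(0.5, abs=1e-12)
                        assert p(iv.upper) == pytest.approx(0.5, abs=1e-12)
                        checked += 1
        assert checked >= 22  # interior grades exist across the system

    def test_strict_monotone_decay_away_from_peak(self, specs):
        for s in specs:
            for g, branches in grade_params(s).items():
                for p in branches:
                    w = math.sqrt(1.0 / p.a2)  # half-width scale
                    for sign in (-1.0, +1.0):
                        if (sign > 0 and p.saturate == "high") or (
                            sign < 0 and p.saturate == "low"
                        ):
                            continue  # saturated side is clamped at 1
                        vals = [p(p.a1 + sign * k * w / 2) for k in range(8)]
                        assert all(
                            a > b for a, b in zip(vals, vals[1:])
                        ), f"{s.id} {g} not strictly decaying"

    def test_crisp_fuzzy_agreement_at_interior_midpoints(self, specs):
        for s in specs:
            if s.direction == "categorical":
                continue
            for g, iv in s.branches():
                if iv.is_bounded and not iv.is_singleton:
                    x = iv.midpoint
                    assert argmax_grade(rf.membership_vector(x, s)) == rf.classify_crisp(x, s)


class TestBuildAffiliation:
    def test_grade_three_midpoints_peak_everywhere(self, specs, spec_map):
        values = {}
        for s in specs:
            iv = s.grades["III"][0]
            values[s.id] = iv.midpoint if s.direction != "categorical" else iv.lower
        R = rf.build_affiliation(values, specs)
        assert R.shape == (22, 5)
        assert (R["III"] == 1.0).all()
        assert (R.idxmax(axis=1) == "III").all()

    def test_boundary_value_yields_one_tied_row(self, specs, spec_map):
        values = {
            s.id: (
                s.grades["III"][0].midpoint
                if s.direction != "categorical"
                else s.grades["III"][0].lower
            )
            for s in specs
        }
        values["C11"] = 80.0  # moderate/bad boundary
        R = rf.build_affiliation(values, specs)
        row = R.loc["C11"]
        assert row["III"] == pytest.approx(0.5) and row["IV"] == pytest.approx(0.5)
        ties = (R.eq(R.max(axis=1), axis=0).sum(axis=1) > 1).sum()
        assert ties == 1

    def test_missing_value_rejected(self, specs):
        with pytest.raises(MatrixValidationError, match="C22"):
            rf.build_affiliation({s.id: 1.0 for s in specs[:-1]}, specs)


class TestCompose:
    def test_one_hot_weight_returns_row(self):
        R = np.array([[0.1, 0.9, 0.2, 0.1, 0.1], [0.7, 0.1, 0.1, 0.05, 0.05]])
        out = rf.compose(np.array([0.0, 1.0]), R)
        np.testing.assert_allclose(out.memberships, R[1])

    def test_tie_breaks_to_worse_grade(self):
        R = np.array([[1, 0, 0, 0, 0], [0, 1, 0, 0, 0]], dtype=float)
        out = rf.compose(np.array([0.5, 0.5]), R)
        np.testing.assert_allclose(out.memberships, [0.5, 0.5, 0, 0, 0])
        assert out.grade == "II"

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            W = rng.dirichlet(np.ones(6))
            R = rng.uniform(size=(6, 5))
            d_oracle = [sum(W[i] * R[i, g] for i in range(6)) for g in range(5)]
            np.testing.assert_allclose(
                rf.compose(W, R).memberships, d_oracle, atol=1e-12
            )

    def test_composition_linearity(self):
        rng = np.random.default_rng(78)
        W = rng.dirichlet(np.ones(4))
        R1, R2 = rng.uniform(size=(4, 5)), rng.uniform(size=(4, 5))
        alpha = 0.3
        lhs = rf.compose(W, alpha * R1 + (1 - alpha) * R2).memberships
        rhs = alpha * rf.compose(W, R1).memberships + (1 - alpha) * rf.compose(
            W, R2
        ).memberships
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)

    def test_grade_invariant_under_positive_rescaling(self):
        rng = np.random.default_rng(79)
        W = rng.dirichlet(np.ones(5))
        R = rng.uniform(size=(5, 5))
        out = rf.compose(W, R)
        assert argmax_grade(3.7 * out.memberships) == out.grade

    def test_max_min_operator(self):
        W = np.array([0.6, 0.4])
        R = np.array([[0.9, 0.1, 0, 0, 0], [0.2, 0.8, 0, 0, 0]])
        out = rf.compose(W, R, operator="max_min")
        np.testing.assert_allclose(out.memberships, [0.6, 0.4, 0, 0, 0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(MatrixValidationError):
            rf.compose(np.ones(3) / 3, np.ones((4, 5)) / 5)


@pytest.fixture(scope="module")
def fused(hierarchy, published):
    ind, _ = published
    return rf.fuse_indicator_weights(ind["ahp"], ind["entropy"]).reindex(
        hierarchy.indicator_ids
    )


class TestEvaluateLayers:
    def _values_at(self, specs, grade):
        out = {}
        for s in specs:
            iv = s.grades[grade][0]
            if s.direction == "categorical" or iv.is_singleton:
                out[s.id] = iv.lower
            elif iv.is_bounded:
                out[s.id] = iv.midpoint
            else:
                out[s.id] = rf.synthetic_data.place_value(s, grade)
        return out

    def test_uniform_grade_two_everywhere(self, specs, hierarchy, fused):
        res = rf.evaluate_layers(self._values_at(specs, "II"), specs, fused, hierarchy)
        assert (res.indicator_grades == "II").all()
        assert all(v.grade == "II" for v in res.criterion.values())
        assert res.target.grade == "II"

    def test_poor_economy_cannot_drag_down_target(self, specs, hierarchy, fused):
        """Economic function planted poor while the rest is excellent: the
        economic criterion grades V but its ~0.2 weight cannot dominate the
        target layer."""
        values = self._values_at(specs, "I")
        for i in hierarchy.indicators_of("A4"):
            spec = next(s for s in specs if s.id == i)
            iv = spec.grades["V"][0]
            values[i] = iv.lower if (iv.is_singleton or spec.direction == "categorical") else (
                iv.midpoint if iv.is_bounded else rf.synthetic_data.place_value(spec, "V")
            )
        res = rf.evaluate_layers(values, specs, fused, hierarchy)
        assert res.criterion["A4"].grade == "V"
        assert res.target.grade in ("I", "II")
        assert res.constraint_criteria() == ["A4"]
        assert set(res.constraint_indicators()) == set(hierarchy.indicators_of("A4"))

    def test_criterion_weights_renormalized(self, specs, hierarchy, fused):
        """Criterion-layer composition uses within-criterion weights that
        sum to 1, so a uniform affiliation row passes through unchanged."""
        values = self._values_at(specs, "III")
        res = rf.evaluate_layers(values, specs, fused, hierarchy)
        for c, v in res.criterion.items():
            members = list(hierarchy.indicators_of(c))
            w = fused[members] / fused[members].sum()
            expected = w.to_numpy() @ res.affiliation.loc[members].to_numpy()
            np.testing.assert_allclose(v.memberships, expected, atol=1e-12)
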