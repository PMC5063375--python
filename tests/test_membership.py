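"""Fuzzy membership grades, aggregation, and the tabulated calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmdd import (
    MembershipSpec,
    ObjectiveSets,
    build_default_memberships,
    fuzzy_equal_grade,
    fuzzy_min_grade,
    grade_design,
    solve_steady_state,
    target_count_factor,
    toy_network,
)
from fmdd.dopamine import (
    REFERENCE_ANOMALIES,
    VM50_TREATMENT_REFERENCE,
)


def fold_equal_spec(**kw):
    """Therapeutic membership on the fold scale: plateau at 1, bounds 0.1/10."""
    return MembershipSpec.equal_around(1.0, **kw)


def fold_min_spec(**kw):
    """Adverse membership on the fold scale: plateau below 1, zero at 10."""
    return MembershipSpec.minimize_above(1.0, **kw)


class TestFuzzyEqual:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (1.0, 1.0),          # plateau
            (0.486, 0.43),       # left branch, reported disease fold
            (0.806, 0.784),      # left branch, reported treated fold
            (0.05, 0.0),         # below lower bound
            (0.1, 0.0),          # at lower bound
            (12.0, 0.0),         # beyond upper bound
        ],
    )
    def test_linear_values(self, value, expected):
        assert fuzzy_equal_grade(value, fold_equal_spec()) == pytest.approx(
            expected, abs=5e-3
        )

    def test_unordered_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            MembershipSpec(kind="equal", x_lb=1.0, x_basal_lb=0.5,
                           x_basal_ub=2.0, x_ub=3.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(value=st.floats(0.0, 20.0))
    def test_range_and_unimodality(self, value):
        spec = fold_equal_spec()
        g = fuzzy_equal_grade(value, spec)
        assert 0.0 <= g <= 1.0
        # moving toward the plateau never decreases the grade
        toward = min(value + 0.01, 1.0) if value < 1.0 else max(value - 0.01, 1.0)
        assert fuzzy_equal_grade(toward, spec) >= g - 1e-12

    @pytest.mark.parametrize("shape", ["exponential", "hyperbolic", "inverse"])
    def test_nonlinear_shapes_monotone(self, shape):
        spec = fold_equal_spec(shape=shape)
        vals = np.linspace(0.1, 1.0, 50)
        grades = [fuzzy_equal_grade(v, spec) for v in vals]
        assert all(b >= a - 1e-12 for a, b in zip(grades, grades[1:]))
        assert grades[0] == pytest.approx(0.0, abs=1e-9)
        assert grades[-1] == pytest.approx(1.0, abs=1e-9)


class TestFuzzyMin:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.241, 1.0),        # below basal: fully satisfied
            (1.0, 1.0),          # at basal
            (1.512, 0.943),      # reported disease fold
            (6.953, 0.339),      # reported treated fold
            (7.962, 0.226),      # reported treated fold
            (10.0, 0.0),         # at the upper bound
            (15.0, 0.0),         # beyond
        ],
    )
    def test_linear_values(self, value, expected):
        assert fuzzy_min_grade(value, fold_min_spec()) == pytest.approx(
            expected, abs=5e-4
        )

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(value=st.floats(0.0, 20.0), bump=st.floats(0.0, 5.0))
    def test_non_increasing(self, value, bump):
        spec = fold_min_spec()
        assert fuzzy_min_grade(value + bump, spec) <= fuzzy_min_grade(value, spec) + 1e-12


class TestCountFactor:
    @pytest.mark.parametrize(
        "n, z_ub, expected",
        [(1, 10, 1.0), (1, 4, 1.0), (4, 6, 0.4), (6, 6, 0.0), (5, 9, 0.5)],
    )
    def test_values(self, n, z_ub, expected):
        assert target_count_factor(n, z_ub) == pytest.approx(expected)

    def test_exceeding_bound_rejected(self):
        with pytest.raises(ValueError):
            target_count_factor(7, 6)

    def test_more_targets_strictly_lower_overall(self):
        # same lambda, one more target -> strictly smaller overall objective
        assert target_count_factor(3, 10) < target_count_factor(2, 10)


class TestCalibration:
    def test_reference_table_grades_reproduced(self):
        """Recomputing every tabulated grade from its printed fold change with
        the default linear memberships reproduces >= 90% of cells to +-0.01
        (two anomalous cells excluded)."""
        eq = fold_equal_spec()
        mn = fold_min_spec()
        checked = matched = 0
        for species, rec in VM50_TREATMENT_REFERENCE.items():
            spec = eq if rec["status"] == "Therapeutic" else mn
            for column in ("VM50", "levodopa", "dopamine_agonist",
                           "comt_inhibitor", "maoi"):
                if (species, column) in REFERENCE_ANOMALIES:
                    continue
                fold, grade = rec[column]
                recomputed = spec.grade(fold)
                checked += 1
                if abs(recomputed - grade) <= 0.01 + 1e-12:
                    matched += 1
        assert checked >= 60
        assert matched / checked >= 0.90

    def test_anomalous_cells_really_disagree(self):
        # the two excluded cells are inconsistent with the linear rule by far
        # more than printing precision, supporting their exclusion
        eq, mn = fold_equal_spec(), fold_min_spec()
        fold, grade = VM50_TREATMENT_REFERENCE["DA-e"]["comt_inhibitor"]
        assert abs(eq.grade(fold) - grade) > 0.03
        fold, grade = VM50_TREATMENT_REFERENCE["DOPA-Q"]["comt_inhibitor"]
        assert abs(mn.grade(fold) - grade) > 0.2


class TestGradeDesign:
    def test_basal_state_is_fully_satisfied(self):
        net = toy_network()
        sets = ObjectiveSets(te=["X1"], ae=["X2"], ve_activities=["v2"], z_ub=10)
        specs = build_default_memberships(net, sets)
        state = solve_steady_state(net)
        report = grade_design(state, net, sets, specs, n_targets=1)
        assert report.lam == pytest.approx(1.0)
        assert report.overall == pytest.approx(1.0)

    def test_zero_grade_zeroes_lambda_and_overall(self):
        net = toy_network()
        sets = ObjectiveSets(te=["X1"], ae=["X2"], z_ub=10)
        specs = build_default_memberships(net, sets)
        state = solve_steady_state(net)
        state.x = state.x.copy()
        state.x[1] = 100 * net.x_basal[1]  # adverse species far above bound
        report = grade_design(state, net, sets, specs, n_targets=1)
        assert report.A == 0.0
        assert report.lam == 0.0
        assert report.overall == 0.0

    def test_overall_bounded_by_min_grade(self):
        net = toy_network()
        sets = ObjectiveSets(te=["X1"], ae=["X2"], z_ub=10)
        specs = build_default_memberships(net, sets)
        state = solve_steady_state(net)
        for n_targets in (1, 2, 3):
            report = grade_design(state, net, sets, specs, n_targets=n_targets)
            assert report.overall <= report.lam + 1e-12

    def test_missing_spec_raises(self):
        net = toy_network()
        sets = ObjectiveSets(te=["X1"], ae=["X2"], z_ub=10)
        specs = build_default_memberships(net, sets)
        del specs["X2"]
        state = solve_steady_state(net)
        with pytest.raises(KeyError):
            grade_design(state, net, sets, specs, n_targets=1)


class TestDefaultMemberships:
    def test_therapeutic_spec_breakpoints(self, dopamine_net):
        sets = ObjectiveSets(te=["DA-e"], ae=["DOPA-Q"], z_ub=10)
        specs = build_default_memberships(dopamine_net, sets)
        te = specs["DA-e"]
        assert (te.x_lb, te.x_basal_lb, te.x_basal_ub, te.x_ub) == (40, 400, 400, 4000)
        ae = specs["DOPA-Q"]
        assert ae.kind == "minimize"
        assert (ae.x_basal_ub, ae.x_ub) == (5, 50)

    def test_override_changes_only_that_spec(self, dopamine_net):
        sets = ObjectiveSets(te=["DA-e"], ae=["DOPA-Q", "DA-Q"], z_ub=10)
        custom = MembershipSpec.minimize_above(5.0, ub_fold=4.0, name="DOPA-Q")
        specs = build_default_memberships(dopamine_net, sets,
                                          overrides={"DOPA-Q": custom})
        assert specs["DOPA-Q"].x_ub == 20.0
        assert specs["DA-Q"].x_ub == 100.0

    def test_disease_overlap_rejected(self):
        with pytest.raises(ValueError):
            ObjectiveSets(te=["X1"], ve_activities=["v1"], ds=["v1"], z_ub=5)
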