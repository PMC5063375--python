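"""GMA rate evaluation, residuals, log-transform and steady-state solving."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fmdd import (
    Perturbation,
    apply_deficiency,
    evaluate_rates,
    fold_changes,
    log_transform_constraints,
    solve_steady_state,
    steady_state_residual,
)
from fmdd.fixtures import toy_steady_state
from fmdd.network import load_network, save_network
from fmdd.steady_state import _integrate


class TestEvaluateRates:
    @pytest.mark.parametrize(
        "x, alpha, G, expected",
        [
            # plain mass action: v = 2 * 3^1 * 5^0
            ((3.0, 5.0), (2.0,), [[1.0, 0.0]], [6.0]),
            # all orders zero -> constant flux regardless of x
            ((0.0, 7.0), (3.5,), [[0.0, 0.0]], [3.5]),
            # fractional order
            ((4.0,), (1.5,), [[0.5]], [3.0]),
            # inhibition: negative order
            ((4.0,), (2.0,), [[-0.5]], [1.0]),
        ],
    )
    def test_power_law_values(self, x, alpha, G, expected):
        np.testing.assert_allclose(evaluate_rates(x, alpha, G), expected)

    def test_zero_to_zero_power_is_one(self):
        # a species at zero with zero kinetic order must not zero the rate
        v = evaluate_rates([0.0, 2.0], [5.0], [[0.0, 1.0]])
        np.testing.assert_allclose(v, [10.0])

    def test_toy_rate_at_unit_concentration(self, toy):
        v = toy.rates(np.array([1.0, 0.25]))
        np.testing.assert_allclose(v, [1.0, 1.0, 1.0])

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            evaluate_rates([-1.0], [1.0], [[0.5]])


class TestResidual:
    def test_consistent_at_basal(self, toy, dopamine_net, random_nets):
        for net in [toy, dopamine_net, *random_nets]:
            res = net.residual(net.x_basal)
            scale = max(np.max(np.abs(net.rates(net.x_basal))), 1.0)
            assert np.max(np.abs(res)) <= 1e-8 * scale

    def test_toy_residual_doubled_concentration(self, toy):
        # doubling x1: influx row is a1 - a2*sqrt(2); X2 row sqrt(2) - 1
        res = steady_state_residual(
            toy, [2.0, 0.25], toy.alpha_basal, toy.u_basal
        )
        np.testing.assert_allclose(res, [1 - np.sqrt(2), np.sqrt(2) - 1])


class TestLogTransform:
    def test_zero_log_state_gives_unit_rates(self, toy):
        w, v, x, _ = log_transform_constraints(
            toy, np.zeros(2), np.zeros(3), toy.u_basal
        )
        np.testing.assert_allclose(v, 1.0)
        np.testing.assert_allclose(x, 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        y=st.lists(st.floats(-2, 2), min_size=2, max_size=2),
        a=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
    )
    def test_roundtrip_matches_linear_rates(self, y, a):
        from fmdd import toy_network

        toy = toy_network()
        y, a = np.array(y), np.array(a)
        w, v, x, res = log_transform_constraints(toy, y, a, toy.u_basal)
        v_lin = evaluate_rates(np.exp(y), np.exp(a), toy.G)
        np.testing.assert_allclose(v, v_lin, rtol=1e-12)
        res_lin = steady_state_residual(toy, np.exp(y), np.exp(a), toy.u_basal)
        np.testing.assert_allclose(res, res_lin, rtol=1e-10, atol=1e-12)

    def test_log_linear_equivalence_on_random_networks(self, random_nets):
        for net in random_nets:
            rng = np.random.default_rng(net.meta["seed"])
            for _ in range(5):
                x = rng.uniform(0.2, 4.0, net.n_species)
                y = np.log(x)
                a_hat = np.log(net.alpha_basal)
                _, v, _, res = log_transform_constraints(net, y, a_hat, net.u_basal)
                res_lin = net.residual(x)
                np.testing.assert_allclose(res, res_lin, rtol=1e-10, atol=1e-12)


class TestSolveSteadyState:
    def test_toy_closed_form(self, toy):
        st_ = solve_steady_state(toy)
        assert st_.converged
        np.testing.assert_allclose(st_.x, [1.0, 0.25], atol=1e-8)

    def test_ode_path_agrees_with_newton(self, toy):
        newton = solve_steady_state(toy)
        ode = _integrate(toy, toy.alpha_basal, toy.u_basal, toy.x_basal * 3, 1e-10)
        np.testing.assert_allclose(ode.x, newton.x, atol=1e-6)

    def test_perturbed_toy_closed_form(self, toy):
        pert = Perturbation(activity_values={"v1": 0.5})
        st_ = solve_steady_state(toy, pert)
        np.testing.assert_allclose(st_.x, toy_steady_state(0.5, 1.0, 2.0), atol=1e-8)

    def test_solver_roundtrip_after_restore(self, random_nets):
        for net in random_nets:
            pert = Perturbation(activity_folds={net.reaction_names[1]: 2.0})
            moved = solve_steady_state(net, pert)
            assert moved.converged
            back = solve_steady_state(net, x0=moved.x)
            np.testing.assert_allclose(back.x, net.x_basal, rtol=1e-6)

    def test_flux_conservation_at_steady_state(self, dopamine_net):
        # every species' influx sum equals its efflux sum (plus controls)
        st_ = solve_steady_state(dopamine_net)
        N, B = dopamine_net.N, dopamine_net.B
        influx = np.clip(N, 0, None) @ st_.v + np.clip(B, 0, None) @ dopamine_net.u_basal
        efflux = -np.clip(N, None, 0) @ st_.v - np.clip(B, None, 0) @ dopamine_net.u_basal
        np.testing.assert_allclose(influx, efflux, rtol=1e-8, atol=1e-8)


class TestDeficiency:
    def test_formula(self, toy):
        pert = apply_deficiency(toy, "v1", 50.0)
        assert pert.disease == {"v1": 0.5}
        assert apply_deficiency(toy, "v1", 100.0).disease == {"v1": 0.0}

    def test_unknown_reaction(self, toy):
        with pytest.raises(KeyError):
            apply_deficiency(toy, "nope", 10.0)

    def test_delta_out_of_range(self, toy):
        with pytest.raises(ValueError):
            apply_deficiency(toy, "v1", 120.0)

    def test_monotone_downstream_concentration(self, toy):
        # cutting the influx monotonically depletes the downstream pool
        prev = np.inf
        for delta in [0, 20, 40, 60, 80, 95]:
            st_ = solve_steady_state(toy, apply_deficiency(toy, "v1", delta))
            x2 = st_.x[1]
            assert x2 <= prev + 1e-12
            prev = x2

    def test_complete_knockout_flags_effectively_zero(self, toy):
        st_ = solve_steady_state(toy, apply_deficiency(toy, "v1", 100.0))
        assert st_.effectively_zero.all()


class TestFoldChanges:
    def test_identity(self, toy):
        st_ = solve_steady_state(toy)
        xf, vf = fold_changes(st_, st_)
        np.testing.assert_allclose(xf, 1.0)
        np.testing.assert_allclose(vf, 1.0)

    def test_halved_influx_quarter_folds(self, toy):
        ref = solve_steady_state(toy)
        st_ = solve_steady_state(toy, Perturbation(activity_values={"v1": 0.5}))
        xf, _ = fold_changes(st_, ref)
        np.testing.assert_allclose(xf, [0.25, 0.25], atol=1e-8)

    def test_zero_reference_is_nan(self, toy):
        ref = solve_steady_state(toy, apply_deficiency(toy, "v1", 100.0))
        st_ = solve_steady_state(toy)
        xf, _ = fold_changes(st_, ref)
        assert np.isnan(xf).all()


class TestModelIO:
    def test_json_roundtrip(self, tmp_path, dopamine_net):
        path = tmp_path / "model.json"
        save_network(dopamine_net, path)
        loaded = load_network(path)
        np.testing.assert_allclose(loaded.N, dopamine_net.N)
        np.testing.assert_allclose(loaded.G, dopamine_net.G)
        np.testing.assert_allclose(loaded.alpha_basal, dopamine_net.alpha_basal)
        assert loaded.species_names == dopamine_net.species_names

    def test_matrix_export(self, tmp_path, toy):
        from fmdd.network import export_matrices

        export_matrices(toy, tmp_path)
        assert (tmp_path / "N.tsv").exists()
        assert (tmp_path / "G.tsv").exists()
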