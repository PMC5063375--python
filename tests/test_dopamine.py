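"""Dopamine case study: model structure, scenarios, presets, reports."""

import numpy as np
import pytest

from fmdd import fold_changes, solve_fixed_targets, solve_steady_state
from fmdd.dopamine import (
    DRUG_PRESETS,
    SCENARIOS,
    build_synthetic_dopamine_model,
    load_dopamine_model,
    make_problem,
    run_scenario_table,
    scenario_perturbation,
)


class TestModel:
    def test_dimensions(self, dopamine_net):
        assert dopamine_net.n_species == 34
        assert dopamine_net.n_reactions == 68
        assert dopamine_net.n_controls == 3
        assert dopamine_net.control_names == ["u_t", "u_l", "u_d"]

    def test_packaged_file_matches_builder(self, dopamine_net):
        built = build_synthetic_dopamine_model()
        np.testing.assert_allclose(built.alpha_basal, dopamine_net.alpha_basal)
        np.testing.assert_allclose(built.G, dopamine_net.G)
        assert built.species_names == dopamine_net.species_names

    def test_healthy_state_concentrations(self, dopamine_net):
        state = solve_steady_state(dopamine_net, raise_on_failure=True)
        get = lambda s: state.x[dopamine_net.species_index(s)]
        assert get("DA-e") == pytest.approx(400.0, abs=1e-6)
        assert get("DOPA-Q") == pytest.approx(5.0, abs=1e-6)
        assert get("3-MT") == pytest.approx(20.0, abs=1e-6)
        assert get("DA-Q") == pytest.approx(10.0, abs=1e-6)
        assert get("HO") == pytest.approx(2.0, abs=1e-6)

    def test_tabulated_species_sit_at_their_indices(self, dopamine_net):
        # the x-subscripts of the reported species are structural anchors
        expected = {
            "DOPA-Q": 5, "DA-e": 9, "3-MT": 10, "DOPAL-e": 11, "DA-Q": 16,
            "DOPAL": 24, "DOPAC-Q": 26, "O2-": 27, "H2O2": 28, "H2O2-e": 29,
            "HO": 30, "HO-NO2": 31, "NO2": 32,
        }
        for name, one_based in expected.items():
            assert dopamine_net.species_index(name) == one_based - 1


class TestScenarios:
    def test_known_scenarios_resolve(self, dopamine_net):
        for name, entry in SCENARIOS.items():
            pert = scenario_perturbation(dopamine_net, name)
            if entry is None:
                assert not pert.disease
            else:
                reaction, delta = entry
                expected = (1 - delta / 100) * dopamine_net.alpha_basal[
                    dopamine_net.reaction_index(reaction)
                ]
                assert pert.disease[reaction] == pytest.approx(expected)

    def test_freeform_scenario(self, dopamine_net):
        pert = scenario_perturbation(dopamine_net, "alpha_15:25")
        assert "alpha_15" in pert.disease

    def test_unknown_scenario_rejected(self, dopamine_net):
        with pytest.raises(KeyError):
            scenario_perturbation(dopamine_net, "XX99")

    def test_vmat2_deficiency_monotone_in_severity(self, dopamine_net):
        i = dopamine_net.species_index("DA-e")
        folds = []
        for name in ["VM50", "VM70", "VM90", "VM95"]:
            st = solve_steady_state(
                dopamine_net, scenario_perturbation(dopamine_net, name)
            )
            assert st.converged
            folds.append(st.x[i] / 400.0)
        assert all(b < a for a, b in zip(folds, folds[1:]))
        assert folds[0] < 1.0

    def test_th_knockout_retains_dopamine_via_levodopa_route(self, dopamine_net):
        # DOPA decarboxylase still converts L-DOPA (external supply) to DA-i,
        # so extracellular dopamine survives a complete TH loss
        st = solve_steady_state(
            dopamine_net, scenario_perturbation(dopamine_net, "TH100")
        )
        assert st.converged
        da_e = st.x[dopamine_net.species_index("DA-e")]
        assert da_e > 1.0
        assert da_e < 400.0


class TestPresets:
    def test_preset_target_identities(self):
        assert DRUG_PRESETS["diet"] == ["u_t"]
        assert DRUG_PRESETS["levodopa"] == ["u_l"]
        assert DRUG_PRESETS["dopamine_agonist"] == ["u_d"]
        assert DRUG_PRESETS["comt_inhibitor"] == ["alpha_22", "alpha_26"]
        assert DRUG_PRESETS["maoi"] == ["alpha_15", "alpha_23", "alpha_24"]

    def test_dat_downregulation_restores_dopamine_under_vmat2_deficiency(
        self, dopamine_net
    ):
        # with only the therapeutic objective, regulating the dopamine
        # transporter alone fully restores DA-e in the 50% deficiency case,
        # and the optimum moves the activity below basal
        problem = make_problem(dopamine_net, "VM50", include_adverse=False,
                               include_variation=False)
        dp = solve_fixed_targets(problem, ("alpha_13",), n_starts=4, seed=0)
        assert dp.lam == pytest.approx(1.0, abs=1e-3)
        k = dopamine_net.reaction_index("alpha_13")
        assert dp.levels["alpha_13"] < dopamine_net.alpha_basal[k]

    def test_maoi_improves_vm50_therapeutic_grade(self, dopamine_net):
        problem = make_problem(dopamine_net, "VM50", include_variation=False)
        untreated = solve_fixed_targets(problem, ())
        treated = solve_fixed_targets(
            problem, tuple(DRUG_PRESETS["maoi"]), n_starts=4, seed=0
        )
        assert treated.report.T > untreated.report.T


class TestScenarioTable:
    def test_untreated_vm50_column(self, dopamine_net):
        table = run_scenario_table(dopamine_net, ["VM50"])
        sub = table[(table.scenario == "VM50") & (table.treatment == "untreated")]
        assert len(sub) == 13
        row = sub[sub.species == "DA-e"].iloc[0]
        assert row.status == "Therapeutic"
        assert 0 < row.fold < 1
        # grade consistent with the linear therapeutic membership
        assert row.grade == pytest.approx((row.fold - 0.1) / 0.9, abs=5e-3)

    def test_solver_failures_do_not_abort_table(self, dopamine_net, monkeypatch):
        import fmdd.dopamine as dop

        def boom(*a, **k):
            raise RuntimeError("forced failure")

        monkeypatch.setattr(dop, "evaluate_treatment", boom, raising=False)
        # patch the symbol used inside run_scenario_table
        monkeypatch.setattr("fmdd.inner.evaluate_treatment", boom)
        table = run_scenario_table(dopamine_net, ["VM50"])
        assert len(table) == 13
        assert table.fold.isna().all()


class TestScenarioFiles:
    def test_yaml_scenario_roundtrip(self, dopamine_net, tmp_path):
        from fmdd.dopamine import load_scenario_file

        path = tmp_path / "scenario.yaml"
        path.write_text(
            "disease:\n"
            "  - {reaction: alpha_14, delta_percent: 50}\n"
            "treatment:\n"
            "  - {target: u_l, value: 8.0}\n"
            "objectives:\n"
            "  TE: [DA-e]\n"
            "  AE: [DOPA-Q, DA-Q]\n"
            "  VE: [alpha_13, alpha_15, u_l]\n"
            "Z_UB: 6\n"
        )
        pert, sets = load_scenario_file(dopamine_net, path)
        k = dopamine_net.reaction_index("alpha_14")
        assert pert.disease["alpha_14"] == pytest.approx(
            0.5 * dopamine_net.alpha_basal[k]
        )
        assert pert.control_values["u_l"] == 8.0
        assert sets.te == ["DA-e"] and sets.z_ub == 6
        assert sets.ve_activities == ["alpha_13", "alpha_15"]
        assert sets.ve_controls_equal == ["u_l"]

    def test_scenario_perturbation_accepts_file_path(self, dopamine_net, tmp_path):
        path = tmp_path / "scenario.json"
        path.write_text(
            '{"disease": [{"reaction": "alpha_3", "delta_percent": 100}]}'
        )
        pert = scenario_perturbation(dopamine_net, str(path))
        assert pert.disease["alpha_3"] == 0.0


class TestMembershipFiles:
    def test_fold_breakpoints_resolved_against_basal(self, dopamine_net, tmp_path):
        from fmdd.membership import load_membership_specs

        path = tmp_path / "memberships.json"
        path.write_text(
            '[{"name": "DA-e", "kind": "equal", "fold": true,'
            '  "breakpoints": [0.5, 1, 1, 2]},'
            ' {"name": "DOPA-Q", "kind": "minimize", "breakpoints": [5, 25]}]'
        )
        specs = load_membership_specs(path, dopamine_net)
        assert specs["DA-e"].x_lb == pytest.approx(200.0)
        assert specs["DA-e"].x_ub == pytest.approx(800.0)
        assert specs["DOPA-Q"].x_ub == 25.0
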