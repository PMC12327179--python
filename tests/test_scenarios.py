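"""Built-in scenario fidelity, gradient scans and transition detection."""

import numpy as np
import pytest

from psfcoex import (
    ConfigurationError,
    alpha_at,
    builtin_scenario,
    classify_outcome,
    find_transitions,
    get_parameter,
    list_scenarios,
    resolve_parameters,
    run_gradient,
)

def test_registry_contents():
    names = list_scenarios()
    for expected in ["ThSi-I", "ThSi-II", "ThSi-III", "ThSi-III-gradient",
                     "ThSi-c-scaling", "SeAn", "InSi-I", "InSi-II",
                     "InSi-III"]:
        assert expected in names


def test_unknown_name_lists_alternatives():
    with pytest.raises(ConfigurationError, match="ThSi-I"):
        builtin_scenario("nope")


class TestPrintedParameterFidelity:
    def test_sterile_competition_matrix(self):
        model = builtin_scenario("ThSi-I").model
        assert get_parameter(model, "c.A.A") == -0.06
        assert get_parameter(model, "c.A.B") == -0.06
        assert get_parameter(model, "c.B.A") == -0.05
        assert get_parameter(model, "c.B.B") == -0.075

    def test_mutualist_parameters(self):
        m2 = builtin_scenario("ThSi-II").model
        assert get_parameter(m2, "sigma.A.X") == 0.002
        assert get_parameter(m2, "phi.X.A") == 10.0
        m3 = builtin_scenario("ThSi-III").model
        assert get_parameter(m3, "sigma.B.Z") == 0.0025
        assert get_parameter(m3, "phi.Z.B") == 10.0

    def test_gradient_scaling_rules(self):
        model = builtin_scenario("ThSi-III-gradient").model
        rules = {r.target: r for r in model.scaling}
        assert rules["sigma.A.X"].intercept == 0.002
        assert rules["sigma.A.X"].slope == -0.00015
        assert rules["sigma.B.Z"].intercept == 0.0025
        assert rules["sigma.B.Z"].slope == -0.0003

    def test_competition_scaling_slopes(self):
        model = builtin_scenario("ThSi-c-scaling").model
        rules = {r.target: r for r in model.scaling}
        assert rules["c.A.A"].slope == 0.0025
        assert rules["c.A.B"].slope == 0.0015
        assert rules["c.B.A"].slope == 0.001
        assert rules["c.B.B"].slope == 0.001
        for addr in rules:
            assert rules[addr].intercept == get_parameter(
                builtin_scenario("ThSi-I").model, addr)

    def test_shared_pathogen_baseline(self):
        model = builtin_scenario("SeAn").model
        assert get_parameter(model, "c.A.A") == -0.06
        assert get_parameter(model, "c.A.B") == -0.055
        assert get_parameter(model, "c.B.B") == -0.075
        assert get_parameter(model, "c.B.A") == -0.05
        assert get_parameter(model, "sigma.A.X") == -0.002
        assert get_parameter(model, "sigma.B.X") == -0.00225
        assert get_parameter(model, "phi.X.A") == 10.5
        assert get_parameter(model, "phi.X.B") == 10.0

    def test_provenance_tags_cover_all_parameters(self):
        for name in list_scenarios():
            scenario = builtin_scenario(name)
            expected_tag = ("constraint-chosen" if name.startswith("InSi")
                            else "literature")
            assert scenario.provenance, name
            assert all(tag == expected_tag
                       for tag in scenario.provenance.values()), name


class TestGradients:
    def test_constant_model_gives_identical_rows(self):
        df = run_gradient(builtin_scenario("ThSi-I"), 0, 20, 11)
        assert df["rho"].nunique() == 1
        assert (df["outcome"] == "coexistence").all()

    def test_two_mutualist_gradient_regime_sequence(self):
        df = run_gradient(builtin_scenario("ThSi-III-gradient"))
        seq = df["outcome"].drop_duplicates().tolist()
        assert seq == ["priority_effects", "exclusion_of_B", "coexistence"]

    def test_competition_scaling_gradient(self):
        df = run_gradient(builtin_scenario("ThSi-c-scaling"))
        assert df["outcome"].iloc[0] == "coexistence"
        assert df["outcome"].iloc[-1] == "exclusion_of_B"

    def test_rows_ordered_by_environment(self):
        df = run_gradient(builtin_scenario("InSi-II"))
        assert df["env_value"].is_monotonic_increasing


class TestTransitions:
    def test_two_mutualist_gradient_analytic_locations(self):
        # invasion boundaries solve 0.06 = 0.05 + 0.003 v (v = 10/3) and
        # 0.05 = 0.04 + 0.0015 v (v = 20/3) under the printed scalings
        points = find_transitions(builtin_scenario("ThSi-III-gradient"),
                                  0, 20, tol=1e-8)
        assert [p.from_label for p in points] == ["priority_effects",
                                                 "exclusion_of_B"]
        assert [p.to_label for p in points] == ["exclusion_of_B",
                                               "coexistence"]
        assert points[0].v_star == pytest.approx(10.0 / 3.0, abs=1e-6)
        assert points[1].v_star == pytest.approx(20.0 / 3.0, abs=1e-6)
        assert all(p.bracket_width <= 1e-8 for p in points)

    def test_constant_scenario_has_no_transitions(self):
        assert find_transitions(builtin_scenario("ThSi-I"), 0, 20) == []


class TestInvasionScenarios:
    def test_sterile_dominance_constraints(self):
        # invader A dominant in sterile soil: |c_AA| < |c_BA|, |c_BB| > |c_AB|
        model = builtin_scenario("InSi-I").model
        c = model.plants.c
        assert abs(c[0, 0]) < abs(c[1, 0])
        assert abs(c[1, 1]) > abs(c[0, 1])
        sterile = type(model)(model.plants, name="sterile")
        assert classify_outcome(alpha_at(sterile, 0.0)).label == \
            "exclusion_of_B"

    def test_pathogen_is_invader_specific_and_moisture_cultivated(self):
        model = builtin_scenario("InSi-I").model
        x = model.microbes[0]
        assert x.sigma[0] < 0 and x.sigma[1] == 0.0   # harms only A
        phi_low = resolve_parameters(model, 2.0).microbes[0].phi[0]
        phi_high = resolve_parameters(model, 15.0).microbes[0].phi[0]
        assert phi_high > phi_low >= 0.0
        assert resolve_parameters(model, 0.0).microbes[0].phi[1] == 0.0

    def test_pathogen_enables_coexistence_at_gradient_midpoint(self):
        model = builtin_scenario("InSi-I").model
        assert classify_outcome(alpha_at(model, 10.0)).label == "coexistence"

    def test_invader_pathogen_regime_sequence(self):
        points = find_transitions(builtin_scenario("InSi-I"), 0, 20)
        assert [(p.from_label, p.to_label) for p in points] == \
            [("exclusion_of_B", "coexistence")]

    def test_native_mutualist_declines_with_moisture(self):
        model = builtin_scenario("InSi-II").model
        y = [t for t in model.microbes if t.label == "Y"][0]
        assert y.sigma[1] > 0 and y.sigma[0] == 0.0
        get = lambda v: [t for t in resolve_parameters(model, v).microbes
                         if t.label == "Y"][0].phi[1]
        assert get(0.0) > get(5.0) >= get(15.0) == 0.0

    def test_mutualist_adds_low_moisture_priority_effects(self):
        points = find_transitions(builtin_scenario("InSi-II"), 0, 20)
        assert [(p.from_label, p.to_label) for p in points] == \
            [("priority_effects", "exclusion_of_B"),
             ("exclusion_of_B", "coexistence")]

    def test_decomposer_benefits_both_and_rises_with_moisture(self):
        model = builtin_scenario("InSi-III").model
        z = [t for t in model.microbes if t.label == "Z"][0]
        assert z.sigma[0] > 0 and z.sigma[1] > 0
        get = lambda v, j: [t for t in resolve_parameters(model, v).microbes
                            if t.label == "Z"][0].phi[j]
        for j in (0, 1):
            assert get(18.0, j) > get(10.0, j) > get(0.0, j) == 0.0

    def test_decomposer_removes_coexistence_from_gradient(self):
        df = run_gradient(builtin_scenario("InSi-III"))
        assert "coexistence" not in set(df["outcome"])
        seq = df["outcome"].drop_duplicates().tolist()
        assert seq == ["priority_effects", "exclusion_of_B"]
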