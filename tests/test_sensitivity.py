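"""One-at-a-time sweeps, local derivatives and the global screen."""

import math

import numpy as np
import pytest

from psfcoex import (
    MicrobeTaxon,
    PlantParams,
    PSFModel,
    PSFError,
    SweepSpec,
    alpha_at,
    compute_metrics,
    default_boxes,
    feedback_sweep,
    global_screen,
    local_derivatives,
    oat_sweep,
    sweep_range,
)

C_TARGETS = ["c.A.A", "c.A.B", "c.B.A", "c.B.B"]
SIGMA_TARGETS = ["sigma.A.X", "sigma.B.X"]
PHI_TARGETS = ["phi.X.A", "phi.X.B"]


def _monotone(series, direction):
    d = np.diff(series.to_numpy(dtype=float))
    return np.all(d > 0) if direction == "up" else np.all(d < 0)


class TestOatSweep:
    def test_inert_parameter_gives_constant_metrics(self):
        model = PSFModel(
            PlantParams(c=np.full((2, 2), -0.06)),
            microbes=(MicrobeTaxon("X", sigma=(0.001, 0.001),
                                   phi=(0.0, 0.0)),),
        )
        df = oat_sweep(SweepSpec("sigma.A.X", model, n_points=21))
        assert df["rho"].nunique() == 1
        assert df["fitness_ratio_BA"].nunique() == 1

    def test_shared_pathogen_baseline_metrics(self, sean_model):
        # hand evaluation through the alpha reduction:
        # a_AA=-0.081, a_AB=-0.075, a_BA=-0.073625, a_BB=-0.0975
        expected_rho = math.sqrt((0.075 * 0.073625) / (0.081 * 0.0975))
        expected_f = math.sqrt((0.081 * 0.075) / (0.0975 * 0.073625))
        df = oat_sweep(SweepSpec("c.A.A", sean_model, n_points=11))
        base = df.attrs["baseline"]
        assert base["rho"] == pytest.approx(expected_rho, rel=1e-12)
        assert base["fitness_ratio_BA"] == pytest.approx(expected_f,
                                                         rel=1e-12)
        assert base["value"] == -0.06

    def test_rows_ordered_and_positions_standardized(self, sean_model):
        df = oat_sweep(SweepSpec("phi.X.A", sean_model, n_points=21))
        assert df["value"].is_monotonic_increasing
        np.testing.assert_allclose(df["standardized_position"],
                                   (df["value"] - 0.0) / 20.0, atol=1e-15)

    def test_undefined_rows_flagged_not_dropped(self, sean_model):
        # large positive sigma pushes alpha_AA over zero: the curve is
        # truncated but rows remain
        df = oat_sweep(SweepSpec("sigma.A.X", sean_model, n_points=201))
        assert (~df["defined"]).any() and df["defined"].any()
        assert len(df) == 201
        assert df.loc[~df["defined"], "rho"].isna().all()

    def test_niche_difference_directions(self, sean_model):
        # directions verified analytically at this baseline: stabilization
        # grows with intraspecific competition strength, shrinks with
        # interspecific strength; increasing sigma (pathogen -> mutualist)
        # stabilizes; cultivation favours the competitor's stronger sigma
        # here, so niche differences shrink with phi
        directions = {
            "c.A.A": "down", "c.B.B": "down",      # weakening self-limitation
            "c.A.B": "up", "c.B.A": "up",          # weakening interspecific
            "sigma.A.X": "up", "sigma.B.X": "up",
            "phi.X.A": "down", "phi.X.B": "down",
        }
        for target, direction in directions.items():
            df = oat_sweep(SweepSpec(target, sean_model))
            nd = df.loc[df["defined"], "niche_difference"]
            assert _monotone(nd, direction), target

    def test_fitness_ratio_monotone_in_every_target(self, sean_model):
        for target in C_TARGETS + SIGMA_TARGETS + PHI_TARGETS:
            df = oat_sweep(SweepSpec(target, sean_model))
            f = df.loc[df["defined"], "fitness_ratio_BA"].to_numpy()
            d = np.diff(f)
            assert np.all(d > 0) or np.all(d < 0), target

    def test_fitness_range_ordering_sigma_over_c_over_phi(self, sean_model):
        ranges = {
            t: sweep_range(oat_sweep(SweepSpec(t, sean_model)))
            for t in C_TARGETS + SIGMA_TARGETS + PHI_TARGETS
        }
        sigma_min = min(ranges[t] for t in SIGMA_TARGETS)
        c_vals = [ranges[t] for t in C_TARGETS]
        phi_max = max(ranges[t] for t in PHI_TARGETS)
        assert sigma_min > max(c_vals) > min(c_vals) > phi_max

    def test_richness_split_leaves_baseline_invariant(self, sean_model):
        # splitting the cultivation mass of one taxon across 2 or 4 clones
        # leaves every alpha contribution, hence all metrics, unchanged
        base = compute_metrics(alpha_at(sean_model, 0.0))
        taxon = sean_model.microbes[0]
        for n in (2, 4):
            clones = tuple(
                MicrobeTaxon(f"X{k}", sigma=taxon.sigma,
                             phi=tuple(p / n for p in taxon.phi))
                for k in range(n)
            )
            split = PSFModel(sean_model.plants, microbes=clones)
            m = compute_metrics(alpha_at(split, 0.0))
            assert m.rho == pytest.approx(base.rho, rel=1e-12)
            assert m.fitness_ratio_BA == pytest.approx(base.fitness_ratio_BA,
                                                       rel=1e-12)


class TestFeedbackSweep:
    def test_default_box_covers_stated_range(self, sean_model):
        df = feedback_sweep(SweepSpec("m.A.A", sean_model, n_points=5))
        assert df["value"].iloc[0] == -0.2
        assert df["value"].iloc[-1] == 0.2

    def test_requires_feedback_address(self, sean_model):
        with pytest.raises(Exception):
            feedback_sweep(SweepSpec("c.A.A", sean_model))

    def test_weakening_feedback_directions(self, sean_model):
        # intraspecific pathogenic feedback weakening (m_ii -> 0-) erodes
        # stabilization; interspecific weakening builds it
        for target, direction in [("m.A.A", "down"), ("m.B.B", "down"),
                                  ("m.A.B", "up"), ("m.B.A", "up")]:
            df = feedback_sweep(SweepSpec(target, sean_model))
            neg = df[(df["value"] < 0) & df["defined"]]
            assert _monotone(neg["niche_difference"], direction), target

    def test_other_entries_stay_at_baseline_products(self, sean_model):
        df = feedback_sweep(SweepSpec("m.A.A", sean_model, n_points=3))
        # alpha_BB = c_BB + sigma_BX*phi_XB = -0.075 - 0.0225 at every row
        np.testing.assert_allclose(df["alpha_BB"], -0.0975, atol=1e-15)
        np.testing.assert_allclose(df["alpha_AB"], -0.075, atol=1e-15)


class TestLocalDerivatives:
    def test_closed_form_agrees_with_finite_difference(self, sean_model):
        # check=True raises on closed-form vs central-difference mismatch
        idx = local_derivatives(sean_model, check=True)
        assert len(idx) == 8

    def test_derivative_signs_match_sweep_directions(self, sean_model):
        for entry in local_derivatives(sean_model):
            df = oat_sweep(SweepSpec(entry.target, sean_model))
            sub = df[df["defined"]]
            for col, deriv in [("niche_difference", entry.d_niche_difference),
                               ("fitness_ratio_BA", entry.d_fitness_ratio)]:
                sweep_sign = np.sign(sub[col].iloc[-1] - sub[col].iloc[0])
                assert np.sign(deriv) == sweep_sign, (entry.target, col)

    def test_zero_cultivation_kills_sigma_derivative(self):
        model = PSFModel(
            PlantParams(c=np.array([[-0.06, -0.055], [-0.05, -0.075]])),
            microbes=(MicrobeTaxon("X", sigma=(-0.002, -0.00225),
                                   phi=(0.0, 0.0)),),
        )
        idx = {e.target: e for e in local_derivatives(model, check=False)}
        assert idx["sigma.A.X"].d_niche_difference == 0.0
        assert idx["sigma.A.X"].d_fitness_ratio == 0.0

    def test_undefined_baseline_advises_sweep(self, sean_model):
        from psfcoex import with_parameter

        bad = with_parameter(sean_model, "sigma.A.X", 0.01)  # alpha_AA > 0
        with pytest.raises(PSFError, match="oat_sweep"):
            local_derivatives(bad)


class TestGlobalScreen:
    def test_deterministic_given_seed(self, sean_model):
        a = global_screen(sean_model, n_samples=256, seed=5)
        b = global_screen(sean_model, n_samples=256, seed=5)
        assert a.equals(b)

    def test_point_range_has_zero_importance(self, sean_model):
        boxes = default_boxes(sean_model)
        boxes["phi.X.A"] = (10.5, 10.5)
        df = global_screen(sean_model, boxes=boxes, n_samples=256, seed=0)
        row = df[df["target"] == "phi.X.A"]
        assert row["first_order_index"].iloc[0] == 0.0

    def test_sigma_outranks_phi_for_fitness_ratio(self, sean_model):
        df = global_screen(sean_model, n_samples=8192, seed=0,
                           metric="fitness_ratio_BA")
        imp = dict(zip(df["target"], df["first_order_index"]))
        assert min(imp[t] for t in SIGMA_TARGETS) > \
            max(imp[t] for t in PHI_TARGETS)
        assert 0 < df.attrs["undefined_fraction"] < 1

    def test_too_few_samples_rejected(self, sean_model):
        with pytest.raises(Exception):
            global_screen(sean_model, n_samples=10)
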