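"""Growth potential, critical prey concentrations, sensitivity, optima."""

import math

import numpy as np
import pytest

import larvaforage as lf


class TestGrowthPotential:
    def test_dark_day_reduces_to_respiration_decay(self, builtins, calibrated):
        larva = builtins["herring"]
        G = lf.growth_potential(larva, T=10.0, photoperiod=0.0, cfg=calibrated)
        rate = calibrated.respiration_scale * larva.x_res
        assert G == pytest.approx(24 * math.log(1 - rate), abs=1e-12)

    def test_independent_of_prey_field(self, builtins, calibrated):
        larva = builtins["cod"]
        envs = [
            lf.Environment(T=5.1, photoperiod=11.8, epsilon=e, b_total=b, s=s)
            for e, b, s in [(0, 0.1, -2.0), (1e-5, 100.0, -0.5)]
        ]
        Gs = {lf.growth_potential(larva, env=env, cfg=calibrated) for env in envs}
        assert len(Gs) == 1

    def test_increases_with_digestion_scale(self, builtins, calibrated):
        larva = builtins["sprat"]
        lo = lf.growth_potential(larva, T=8.9, photoperiod=16.0, cfg=calibrated)
        hi = lf.growth_potential(
            larva, T=8.9, photoperiod=16.0,
            cfg=calibrated.replace(digestion_scale=1.2),
        )
        assert hi > lo


class TestCriticalConcentrations:
    def test_ordering_at_reference_conditions(self, builtins, calibrated):
        for name, larva in builtins.items():
            env = lf.reference_conditions(name)
            starv = lf.starvation_point(larva, env, calibrated)
            req = lf.prey_requirement(larva, env, calibrated)
            sat = lf.satiation_point(larva, env, calibrated)
            assert starv <= req <= sat, name

    def test_growth_flat_above_satiation(self, builtins, calibrated):
        larva = builtins["herring"]
        env = lf.reference_conditions("herring")
        sat = lf.satiation_point(larva, env, calibrated)
        G_max = lf.growth_potential(larva, env=env, cfg=calibrated)
        for factor in (2.0, 10.0):
            G = lf.simulate_day(larva, env.replace(b_total=factor * sat), calibrated).G
            assert G == pytest.approx(G_max, abs=1e-9)

    def test_requirement_reduces_to_starvation_at_zero_target(
        self, builtins, calibrated
    ):
        larva = builtins["sprat"]
        env = lf.reference_conditions("sprat")
        assert lf.prey_requirement(
            larva, env, calibrated, G_target=0.0
        ) == pytest.approx(lf.starvation_point(larva, env, calibrated), rel=1e-3)

    def test_requirement_increasing_in_target(self, builtins, calibrated):
        larva = builtins["anchovy"]
        env = lf.reference_conditions("anchovy")
        reqs = [
            lf.prey_requirement(larva, env, calibrated, G_target=g)
            for g in (0.0, 0.05, 0.10)
        ]
        assert reqs[0] < reqs[1] < reqs[2]

    def test_doubled_respiration_raises_starvation_point(self, builtins, calibrated):
        larva = builtins["herring"]
        env = lf.reference_conditions("herring")
        base = lf.starvation_point(larva, env, calibrated)
        doubled = lf.starvation_point(
            larva, env,
            calibrated.replace(respiration_scale=2 * calibrated.respiration_scale),
        )
        assert doubled > base

    def test_starvation_independent_of_mass_law_intercept(
        self, builtins, calibrated
    ):
        # the length-mass coefficient cancels from the spectrum and the
        # intake once handling saturation is negligible
        larva = builtins["herring"].replace(y_hand=0.01)
        env = lf.reference_conditions("herring")
        s1 = lf.starvation_point(larva, env, calibrated)
        s2 = lf.starvation_point(
            larva, env, calibrated.replace(prey_mass_coeff=25.0)
        )
        assert abs(s2 - s1) / s1 < 0.01

    def test_requirement_scales_inverse_square_of_vision(self, builtins, calibrated):
        larva = builtins["herring"]
        env = lf.reference_conditions("herring")
        base = lf.prey_requirement(larva, env, calibrated)
        wide = lf.prey_requirement(
            larva.replace(y_vis=1.2 * larva.y_vis), env, calibrated
        )
        assert base / wide == pytest.approx(1.44, rel=0.01)

    def test_unattainable_growth_reported_as_solver_error(self, builtins):
        # raw (uncalibrated) respiration makes positive growth impossible
        with pytest.raises(lf.SolverError):
            lf.starvation_point(
                builtins["cod"], lf.reference_conditions("cod"), lf.ModelConfig()
            )

    def test_bisection_stable_under_halved_tolerance(self, builtins, calibrated):
        larva = builtins["sprat"]
        env = lf.reference_conditions("sprat")
        coarse = lf.starvation_point(larva, env, calibrated)
        fine = lf.starvation_point(
            larva, env, calibrated.replace(solver_log10b_tol=5e-5)
        )
        assert fine == pytest.approx(coarse, rel=5e-4)


class TestSensitivity:
    def test_vision_range_matches_inverse_square_law(self, builtins, calibrated):
        rng = lf.sensitivity_range(
            "y_vis", "prey_requirement", builtins["herring"],
            lf.reference_conditions("herring"), calibrated,
        )
        assert rng.low_pct == pytest.approx(100 * math.sqrt(1 / 1.1), abs=0.1)
        assert rng.high_pct == pytest.approx(100 * math.sqrt(1 / 0.9), abs=0.1)

    def test_output_changes_ten_percent_at_bounds(self, builtins, calibrated):
        larva = builtins["herring"]
        env = lf.reference_conditions("herring")
        rng = lf.sensitivity_range(
            "y_swim", "prey_requirement", larva, env, calibrated
        )
        ref = rng.reference_output
        hi = lf.prey_requirement(
            larva.replace(y_swim=larva.y_swim * rng.high_pct / 100), env, calibrated
        )
        assert abs(hi - ref) / ref == pytest.approx(0.1, abs=0.005)

    def test_inert_parameter_gives_open_range(self, builtins, calibrated):
        # handling time has no effect on ad libitum growth potential
        rng = lf.sensitivity_range(
            "y_hand", "growth_potential", builtins["cod"],
            lf.reference_conditions("cod"), calibrated,
        )
        assert rng.low_pct == 0.0
        assert rng.high_pct == math.inf

    def test_unknown_parameter_rejected(self, builtins, calibrated):
        with pytest.raises(lf.ValidationError):
            lf.sensitivity_range(
                "x_unknown", "growth_potential", builtins["cod"],
                lf.reference_conditions("cod"), calibrated,
            )


class TestOptimalPrey:
    def test_cod_optimal_bin(self, builtins):
        l_opt, ratio = lf.optimal_prey_length(builtins["cod"])
        assert l_opt == pytest.approx(0.735)
        assert 0 < ratio < 1

    def test_optimum_near_continuous_limit(self, builtins):
        # closed-form argmax of l^b (1 - l/l_max) sits at l_max * b/(b+1)
        b = lf.ModelConfig().prey_mass_exp
        for larva in builtins.values():
            l_opt, _ = lf.optimal_prey_length(larva)
            l_star = larva.max_ingestible_length * b / (b + 1)
            assert abs(l_opt - l_star) <= 0.005 + 1e-12, larva.name

    def test_mean_ratio_is_two_thirds(self, builtins):
        ratios = [lf.optimal_prey_length(t)[1] for t in builtins.values()]
        assert round(100 * np.mean(ratios)) == 67


class TestOptimalSlopeAndTurbulence:
    def test_slope_optimum_is_local_minimum(self, builtins, calibrated):
        larva = builtins["cod"]
        env = lf.reference_conditions("cod")
        s_opt = lf.optimal_spectrum_slope(larva, env, calibrated)
        at = lf.starvation_point(larva, env.replace(s=s_opt), calibrated)
        for ds in (-0.1, 0.1):
            assert at <= lf.starvation_point(
                larva, env.replace(s=s_opt + ds), calibrated
            ) * (1 + 1e-6)

    def test_slope_optimum_ordering_follows_mouth_gape(self, builtins, calibrated):
        s = {
            name: lf.optimal_spectrum_slope(
                larva, lf.reference_conditions(name), calibrated
            )
            for name, larva in builtins.items()
        }
        assert s["sprat"] < s["anchovy"] < min(s["cod"], s["herring"])
        assert abs(s["cod"] - s["herring"]) < 0.25

    def test_starvation_and_satiation_monotone_in_turbulence(
        self, builtins, calibrated
    ):
        env = lf.reference_conditions("herring")
        grid = [0.0, 1e-10, 1e-8, 1e-7, 1e-6, 1e-5]
        table = lf.turbulence_response(
            builtins["herring"], env, calibrated, epsilon_grid=grid
        )
        assert table["starvation"].is_monotonic_increasing
        assert table["satiation"].is_monotonic_increasing
        # the calm-water row equals the direct solver output
        assert table.loc[0, "starvation"] == pytest.approx(
            lf.starvation_point(builtins["herring"], env.replace(epsilon=0.0),
                                calibrated)
        )

    def test_optima_report_fields(self, builtins):
        report = lf.optima_report(builtins["sprat"])
        assert report.max_ingestible_mm == pytest.approx(0.2688)
        assert report.optimal_prey_mm < report.max_ingestible_mm
        assert 0 < report.optimal_ratio < 1
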