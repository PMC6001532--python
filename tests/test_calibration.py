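import numpy as np
import pytest

from narfcs import (
    AnalysisSpec,
    MspModelSpec,
    algorithm1_grid,
    algorithm2_joint,
    algorithm3_one_at_a_time,
    check_one_at_a_time,
    generalized_curve,
    narfcs_specs,
    simulate_pm,
)

M, CYCLES, SEED = 4, 5, 77


@pytest.fixture(scope="module")
def rho_zero_data(rho_zero_params):
    return simulate_pm(rho_zero_params, 4000, seed=30)


@pytest.fixture(scope="module")
def pm_data(pm_params):
    return simulate_pm(pm_params, 6000, seed=31)


def _msp_specs():
    return [MspModelSpec(outcome="Y1"), MspModelSpec(outcome="Y2")]


class TestAlgorithm1:
    def test_uncorrelated_data_msp_tracks_csp(self, rho_zero_data):
        """With uncorrelated outcomes the conditional and marginal
        sensitivity parameters coincide: the achieved MSP at each grid
        point sits on the identity line."""
        specs = narfcs_specs(rho_zero_data, {})
        res = algorithm1_grid(
            rho_zero_data, specs, _msp_specs(),
            {"Y1": [-3.0, -1.5, 0.0], "Y2": [-3.0, 0.0]},
            m=M, cycles=CYCLES, seed=SEED,
        )
        for rec in res.grid:
            assert not rec.failed
            assert rec.msp_values["Y1"] == pytest.approx(rec.csps["Y1"], abs=0.25)

    def test_msp_at_true_csp_matches_true_msp(self, pm_params, pm_data):
        specs = narfcs_specs(pm_data, {"Y2": -4.2})
        res = algorithm1_grid(
            pm_data, specs, [MspModelSpec(outcome="Y1")],
            {"Y1": [-4.0, -2.3, 0.0]},
            m=M, cycles=CYCLES, seed=SEED,
        )
        at_true = next(r for r in res.grid if r.csps["Y1"] == -2.3)
        assert at_true.msp_values["Y1"] == pytest.approx(pm_params.mu11, abs=0.25)

    def test_effect_of_interest_recorded(self, rho_zero_data):
        specs = narfcs_specs(rho_zero_data, {})
        res = algorithm1_grid(
            rho_zero_data, specs, _msp_specs(),
            {"Y1": [-1.0, 0.0], "Y2": [0.0]},
            analysis_spec=AnalysisSpec(outcome="Y1"),
            m=M, cycles=CYCLES, seed=SEED,
        )
        for rec in res.grid:
            assert rec.effect is not None
            assert rec.effect.ci_low < rec.effect.estimate < rec.effect.ci_high

    def test_uncovered_elicited_range_flagged(self, rho_zero_data):
        specs = narfcs_specs(rho_zero_data, {})
        res = algorithm1_grid(
            rho_zero_data, specs, _msp_specs(),
            {"Y1": [-0.5, 0.0], "Y2": [0.0]},
            elicited_ranges={"Y1": (-30.0, -20.0)},
            m=M, cycles=CYCLES, seed=SEED,
        )
        assert res.range_covered == {"Y1": False}
        assert "widen" in res.recommendation

    def test_empty_test_values_rejected(self, rho_zero_data):
        specs = narfcs_specs(rho_zero_data, {})
        with pytest.raises(ValueError, match="no test values"):
            algorithm1_grid(
                rho_zero_data, specs, _msp_specs(), {"Y1": []},
                m=M, cycles=CYCLES, seed=SEED,
            )

    def test_fixed_seed_sweep_is_reproducible(self, rho_zero_data):
        specs = narfcs_specs(rho_zero_data, {})
        kw = dict(m=2, cycles=2, seed=SEED)
        r1 = algorithm1_grid(
            rho_zero_data, specs, _msp_specs(), {"Y1": [-1.0], "Y2": [0.0]}, **kw
        )
        r2 = algorithm1_grid(
            rho_zero_data, specs, _msp_specs(), {"Y1": [-1.0], "Y2": [0.0]}, **kw
        )
        assert r1.grid[0].msp_values == r2.grid[0].msp_values


class TestOneAtATimeCheck:
    def test_gaussian_grid_passes(self, pm_data):
        specs = narfcs_specs(pm_data, {})
        res = algorithm1_grid(
            pm_data, specs, _msp_specs(),
            {"Y1": [-3.0, -1.0], "Y2": [-5.0, -2.0]},
            m=M, cycles=CYCLES, seed=SEED,
        )
        check = check_one_at_a_time(res, threshold=0.3)
        assert check.passed
        assert set(check.spreads) == {"Y1", "Y2"}

    def test_single_setting_grid_rejected(self, rho_zero_data):
        specs = narfcs_specs(rho_zero_data, {})
        res = algorithm1_grid(
            rho_zero_data, specs, _msp_specs(), {"Y1": [-1.0], "Y2": [0.0]},
            m=2, cycles=2, seed=SEED,
        )
        with pytest.raises(ValueError, match="single setting"):
            check_one_at_a_time(res)

    def test_zero_threshold_fails_on_stochastic_grid(self, pm_data):
        specs = narfcs_specs(pm_data, {})
        res = algorithm1_grid(
            pm_data, specs, _msp_specs(),
            {"Y1": [-3.0, -1.0], "Y2": [-5.0, -2.0]},
            m=2, cycles=2, seed=SEED,
        )
        assert not check_one_at_a_time(res, threshold=0.0).passed


class TestAlgorithm2:
    def test_joint_search_hits_elicited_points(self, rho_zero_data):
        specs = narfcs_specs(rho_zero_data, {})
        elicited = {"Y1": -1.0, "Y2": -2.0}
        tol = {"Y1": 0.25, "Y2": 0.4}
        res = algorithm2_joint(
            rho_zero_data, specs, _msp_specs(), elicited, tol,
            initial_grids={"Y1": list(np.linspace(-4, 2, 5)),
                           "Y2": list(np.linspace(-6, 2, 5))},
            m=M, cycles=CYCLES, seed=SEED, max_rounds=6,
        )
        assert res.converged
        assert res.primary["Y1"] == pytest.approx(-1.0, abs=0.6)
        assert res.primary["Y2"] == pytest.approx(-2.0, abs=1.0)

    def test_huge_tolerance_returns_multiple_with_primary(self, rho_zero_data):
        specs = narfcs_specs(rho_zero_data, {})
        res = algorithm2_joint(
            rho_zero_data, specs, _msp_specs(),
            {"Y1": -1.0, "Y2": -1.0}, {"Y1": 50.0, "Y2": 50.0},
            initial_grids={"Y1": [-2.0, -1.0, 0.0], "Y2": [-1.0, 0.0]},
            m=2, cycles=2, seed=SEED,
        )
        assert res.converged
        assert len(res.calibrated) == 6  # every vector qualifies
        assert res.primary in res.calibrated

    def test_unconverged_flagged_with_nearest(self, rho_zero_data):
        specs = narfcs_specs(rho_zero_data, {})
        res = algorithm2_joint(
            rho_zero_data, specs, _msp_specs(),
            {"Y1": -1.0, "Y2": -1.0}, {"Y1": 1e-6, "Y2": 1e-6},
            initial_grids={"Y1": [-2.0, 0.0], "Y2": [-2.0, 0.0]},
            m=2, cycles=2, seed=SEED, max_rounds=2,
        )
        assert not res.converged
        assert res.primary is not None
        assert res.calibrated == []

    def test_nonpositive_tolerance_rejected(self, rho_zero_data):
        specs = narfcs_specs(rho_zero_data, {})
        with pytest.raises(ValueError, match="positive"):
            algorithm2_joint(
                rho_zero_data, specs, _msp_specs(),
                {"Y1": -1.0, "Y2": -1.0}, {"Y1": 0.0, "Y2": 1.0},
                initial_grids={"Y1": [-1.0], "Y2": [-1.0]},
            )


class TestAlgorithm3:
    def test_uncorrelated_data_calibrates_to_elicited_value(self, rho_zero_data):
        specs = narfcs_specs(rho_zero_data, {})
        res = algorithm3_one_at_a_time(
            rho_zero_data, specs, MspModelSpec(outcome="Y1"),
            elicited_value=-1.0, initial_range=(-4.0, 2.0),
            fixed_other_csps={"Y2": -3.0}, tolerance=0.05,
            m=M, cycles=CYCLES, seed=SEED,
        )
        assert res.converged
        assert res.primary["Y1"] == pytest.approx(-1.0, abs=0.4)

    def test_achieved_msp_monotone_in_csp(self, pm_data):
        """Across a grid sweep the achieved MSP must increase with the
        CSP for gaussian models (grid-sweep oracle)."""
        specs = narfcs_specs(pm_data, {"Y2": -4.2})
        res = algorithm1_grid(
            pm_data, specs, [MspModelSpec(outcome="Y1")],
            {"Y1": list(np.linspace(-5, 0, 6))},
            m=M, cycles=CYCLES, seed=SEED,
        )
        msps = [r.msp_values["Y1"] for r in res.grid]
        assert all(b > a - 0.1 for a, b in zip(msps, msps[1:]))
        slope = np.polyfit([r.csps["Y1"] for r in res.grid], msps, 1)[0]
        assert slope == pytest.approx(1.0, abs=0.2)

    def test_elicited_outside_achieved_range_rejected(self, rho_zero_data):
        specs = narfcs_specs(rho_zero_data, {})
        with pytest.raises(ValueError, match="widen"):
            algorithm3_one_at_a_time(
                rho_zero_data, specs, MspModelSpec(outcome="Y1"),
                elicited_value=-50.0, initial_range=(-2.0, 0.0),
                fixed_other_csps={"Y2": 0.0},
                m=2, cycles=2, seed=SEED,
            )


class TestGeneralizedCurve:
    def test_constant_summary_is_flat(self, rho_zero_data):
        specs = narfcs_specs(rho_zero_data, {})
        curve = generalized_curve(
            rho_zero_data, specs, {"Y1": [-2.0, -1.0, 0.0]},
            summary_fn=lambda df: 3.14,
            analysis_spec=AnalysisSpec(outcome="Y1"),
            m=2, cycles=2, seed=SEED,
        )
        assert (curve["summary"] == 3.14).all()

    def test_msp_summary_reproduces_grid_algorithm(self, rho_zero_data):
        """Using the per-dataset indicator-regression coefficient as the
        summary reproduces the grid algorithm's pooled MSP estimates
        exactly (same seed, same draws)."""
        specs = narfcs_specs(rho_zero_data, {})
        values = [-2.0, -1.0]

        def msp_of(df):
            x = np.column_stack(
                [np.ones(len(df)), rho_zero_data.indicators["M_Y1"]]
            )
            beta, *_ = np.linalg.lstsq(x, df["Y1"].to_numpy(), rcond=None)
            return beta[1]

        curve = generalized_curve(
            rho_zero_data, specs, {"Y1": values}, msp_of,
            analysis_spec=AnalysisSpec(outcome="Y1"),
            m=2, cycles=2, seed=SEED,
        )
        res = algorithm1_grid(
            rho_zero_data, specs, [MspModelSpec(outcome="Y1")],
            {"Y1": values}, m=2, cycles=2, seed=SEED,
        )
        expected = [r.msp_values["Y1"] for r in res.grid]
        assert np.allclose(curve["summary"].to_numpy(), expected, atol=1e-10)

    def test_marginal_mean_summary_is_affine_in_csp(self, single_var_dataset):
        """For one incomplete variable with an intercept-only model the
        completed-data mean is exactly affine in the offset under a fixed
        seed, with slope equal to the missing fraction."""
        from narfcs import NarfcsModelSpec

        ds = single_var_dataset
        specs = [NarfcsModelSpec(target="Y", predictors=())]
        deltas = [-4.0, -2.0, 0.0, 2.0]
        curve = generalized_curve(
            ds, specs, {"Y": deltas},
            summary_fn=lambda df: df["Y"].mean(),
            analysis_spec=AnalysisSpec(outcome="Y"),
            m=2, cycles=2, seed=SEED,
        )
        s = curve["summary"].to_numpy()
        diffs = np.diff(s) / np.diff(deltas)
        miss_frac = ds.values["Y"].isna().mean()
        assert np.allclose(diffs, miss_frac, atol=1e-10)
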