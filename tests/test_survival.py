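"""Surviving fractions, LQ fitting, isoeffect doses and RBE."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from protonrbe import (
    SurvivalCurveFit,
    compute_rbe,
    fit_lq,
    generate_colony_counts,
    isoeffect_dose,
    lq_survival,
    surviving_fractions,
)
from protonrbe.reference import REFERENCE_LQ


def colony_frame(rows):
    return pd.DataFrame(
        rows, columns=["mode", "position", "dose_gy", "run", "well", "seeded", "colonies"]
    )


class TestSurvivingFractions:
    def test_plating_efficiency_from_controls(self):
        rows = [("PBS", 1, 0.0, 1, w, 100, 30) for w in range(1, 7)]
        rows += [("PBS", 1, 2.0, 1, w, 200, 30) for w in range(1, 7)]
        obs = surviving_fractions(colony_frame(rows))
        ctrl = obs[obs["dose_gy"] == 0].iloc[0]
        dosed = obs[obs["dose_gy"] == 2.0].iloc[0]
        assert ctrl["mean_sf"] == pytest.approx(1.0)  # PE = 30/100 = 0.30
        assert dosed["mean_sf"] == pytest.approx(0.5)  # (30/200)/0.30

    def test_zero_colony_well_gives_zero_sf(self):
        rows = [("DS", 2, 0.0, 1, w, 100, 25) for w in range(1, 7)]
        rows += [("DS", 2, 5.0, 1, 1, 1000, 0)]
        obs = surviving_fractions(colony_frame(rows))
        assert obs[obs["dose_gy"] == 5.0]["mean_sf"].iloc[0] == 0.0

    def test_missing_controls_raise(self):
        rows = [("PBS", 1, 2.0, 1, w, 200, 30) for w in range(1, 7)]
        with pytest.raises(ValueError, match="no 0 Gy controls"):
            surviving_fractions(colony_frame(rows))

    def test_zero_control_colonies_raise(self):
        rows = [("PBS", 1, 0.0, 1, w, 100, 0) for w in range(1, 7)]
        rows += [("PBS", 1, 2.0, 1, 1, 200, 30)]
        with pytest.raises(ValueError, match="zero control colonies"):
            surviving_fractions(colony_frame(rows))

    def test_run_pooling_uses_run_means(self, small_design, truth_all):
        df = generate_colony_counts(small_design, truth_all)
        obs_w = surviving_fractions(df, pooling="wells")
        obs_r = surviving_fractions(df, pooling="runs")
        assert (obs_w["n"] == 12).all()
        assert (obs_r["n"] == 2).all()


class TestFitLQ:
    def test_noiseless_points_recovered_exactly(self):
        d = np.array([0.0, 1.0, 3.0, 5.0])
        obs = [(dd, float(lq_survival(dd, 0.26, 0.05)), 0.0, 1) for dd in d]
        fit = fit_lq(obs)
        assert fit.alpha == pytest.approx(0.26, abs=1e-10)
        assert fit.beta == pytest.approx(0.05, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_pure_linear_truth_fits_beta_at_boundary(self):
        d = np.array([0.0, 1.0, 3.0, 5.0])
        obs = [(dd, float(np.exp(-0.3 * dd)), 0.0, 1) for dd in d]
        fit = fit_lq(obs)
        assert fit.alpha == pytest.approx(0.3, abs=1e-8)
        assert fit.beta == pytest.approx(0.0, abs=1e-8)

    def test_linear_scale_option_agrees_on_noiseless_data(self):
        d = np.array([0.0, 1.0, 3.0, 5.0])
        obs = [(dd, float(lq_survival(dd, 0.2, 0.11)), 0.0, 1) for dd in d]
        fit = fit_lq(obs, scale="linear")
        assert fit.alpha == pytest.approx(0.2, abs=1e-6)
        assert fit.beta == pytest.approx(0.11, abs=1e-6)

    def test_too_few_dose_levels_raise(self):
        with pytest.raises(ValueError, match="3 distinct dose"):
            fit_lq([(0.0, 1.0, 0.0, 1), (1.0, 0.7, 0.0, 1)])

    def test_simulation_recovery_within_2se(self, truth_all):
        # study-sized data (2 runs x 6 wells, 0/1/3/5 Gy, PE 0.30) refit:
        # truth within 2 SE for a large majority of seeds, tiny bias
        from protonrbe import ExperimentDesign, Mode

        lq = truth_all["PBS1"]
        hits = 0
        alphas = []
        n_rep = 120
        for s in range(n_rep):
            design = ExperimentDesign(
                modes=(Mode.PBS,), positions=(1,), doses=(1.0, 3.0, 5.0), seed=31 * s + 1
            )
            df = generate_colony_counts(design, {"PBS1": lq})
            fit = fit_lq(surviving_fractions(df))
            alphas.append(fit.alpha)
            if (
                abs(fit.alpha - lq.alpha) <= 2 * fit.se_alpha
                and abs(fit.beta - lq.beta) <= 2 * fit.se_beta
            ):
                hits += 1
        assert hits / n_rep >= 0.90
        assert abs(np.mean(alphas) - lq.alpha) < 0.05 * lq.alpha

    def test_replicate_weighting_still_available(self, small_design, truth_all):
        df = generate_colony_counts(small_design, truth_all)
        obs = surviving_fractions(df)
        fit_p = fit_lq(obs, weighting="poisson")
        fit_r = fit_lq(obs, weighting="replicate")
        # same data, comparable point estimates from both variance models
        assert fit_r.alpha == pytest.approx(fit_p.alpha, abs=0.05)


class TestIsoeffectDose:
    @pytest.mark.parametrize(
        "alpha,beta,level,expected",
        [
            (np.log(2), 0.0, 0.5, 1.0),
            (0.0, np.log(2), 0.5, 1.0),
            (0.17, 0.03, 0.5, 2.746),  # reference gamma parameters
        ],
    )
    def test_hand_examples(self, alpha, beta, level, expected):
        fit = SurvivalCurveFit(alpha, beta)
        assert isoeffect_dose(fit, level) == pytest.approx(expected, abs=2e-3)

    def test_invalid_level_raises(self):
        with pytest.raises(ValueError):
            isoeffect_dose(SurvivalCurveFit(0.2, 0.0), 1.5)

    @given(
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=0.3),
        st.floats(min_value=0.01, max_value=0.99),
    )
    def test_inverts_survival_function(self, alpha, beta, level):
        if alpha < 1e-4 and beta < 1e-4:
            alpha = 0.1
        fit = SurvivalCurveFit(alpha, beta)
        d = isoeffect_dose(fit, level)
        assert float(lq_survival(d, alpha, beta)) == pytest.approx(level, abs=1e-10)


class TestRBE:
    def test_identity_gives_unity(self):
        fit = REFERENCE_LQ["Co60"]
        est = compute_rbe(fit, fit, 0.5)
        assert est.rbe == pytest.approx(1.0)
        assert est.se > 0

    def test_published_parameter_ratios(self):
        # dose ratios from the published rounded LQ parameters
        expected = {"PBS1": 1.415, "PBS2": 1.560, "DS1": 1.106, "DS2": 1.308}
        for label, value in expected.items():
            est = compute_rbe(REFERENCE_LQ["Co60"], REFERENCE_LQ[label], 0.5)
            assert est.rbe == pytest.approx(value, abs=2e-3)
            assert est.iso_dose_ref == pytest.approx(2.746, abs=2e-3)

    def test_antisymmetry(self):
        a, b = REFERENCE_LQ["Co60"], REFERENCE_LQ["PBS2"]
        fwd = compute_rbe(a, b, 0.5).rbe
        rev = compute_rbe(b, a, 0.5).rbe
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_monotone_in_test_alpha(self):
        ref = REFERENCE_LQ["Co60"]
        rbes = [
            compute_rbe(ref, SurvivalCurveFit(a, 0.05), 0.5).rbe
            for a in (0.1, 0.2, 0.3, 0.4)
        ]
        assert all(x < y for x, y in zip(rbes, rbes[1:]))

    def test_degenerate_fit_raises(self):
        with pytest.raises(ValueError):
            compute_rbe(REFERENCE_LQ["Co60"], SurvivalCurveFit(0.0, 0.0), 0.5)

    def test_delta_method_se_matches_parametric_bootstrap(self, rng):
        # independent oracle: resample (alpha, beta) from their fit
        # uncertainties and take the SD of the resulting RBE draws
        ref, test = REFERENCE_LQ["Co60"], REFERENCE_LQ["PBS1"]
        est = compute_rbe(ref, test, 0.5)
        n = 10_000
        ln2 = np.log(2.0)

        def iso(a, b):
            a = np.clip(a, 1e-9, None)
            b = np.clip(b, 0.0, None)
            return 2 * ln2 / (a + np.sqrt(a * a + 4 * b * ln2))

        d_ref = iso(
            rng.normal(ref.alpha, ref.se_alpha, n), rng.normal(ref.beta, ref.se_beta, n)
        )
        d_test = iso(
            rng.normal(test.alpha, test.se_alpha, n),
            rng.normal(test.beta, test.se_beta, n),
        )
        boot_sd = (d_ref / d_test).std()
        assert est.se == pytest.approx(boot_sd, rel=0.15)
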