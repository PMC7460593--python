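"""Generator contracts: mean structure, noise families, seed determinism."""

import numpy as np
import pandas as pd
import pytest

from protonrbe import (
    EndpointKind,
    ExperimentDesign,
    Mode,
    TrueLQ,
    dose_average_let,
    generate_colony_counts,
    generate_endpoint_data,
    generate_let_spectrum,
    generate_mn_cell_counts,
    generate_neutron_spectrum,
    generate_reference_colony_counts,
    solve_dose_shares,
)
from protonrbe.letd import NEUTRON_CLASS_LABELS, classify_neutrons
from protonrbe.reference import LETD_ALL_PARTICLES, LETD_TARGETS


class TestColonyCounts:
    def test_mean_structure_converges_to_lq_survival(self):
        # seeded * PE * exp(-aD - bD^2), checked at 10^4 wells, 2% tolerance
        lq = TrueLQ(0.26, 0.05)
        design = ExperimentDesign(
            modes=(Mode.PBS,),
            positions=(1,),
            doses=(1.0, 5.0),
            runs=1,
            wells_per_condition=10_000,
            seeded_cells=1000,
            seed=5,
        )
        df = generate_colony_counts(design, {"PBS1": lq})
        for dose in (0.0, 1.0, 5.0):
            expected = 1000 * 0.30 * np.exp(-0.26 * dose - 0.05 * dose**2)
            got = df.loc[df["dose_gy"] == dose, "colonies"].mean()
            assert got == pytest.approx(expected, rel=0.02)

    def test_unirradiated_mean_is_seeded_times_pe(self):
        design = ExperimentDesign(
            modes=(Mode.DS,),
            positions=(2,),
            doses=(1.0,),
            runs=1,
            wells_per_condition=5000,
            seeded_cells=100,
            seed=3,
        )
        df = generate_colony_counts(design, {"DS2": TrueLQ(0.2, 0.05)})
        ctrl = df.loc[df["dose_gy"] == 0, "colonies"]
        assert ctrl.mean() == pytest.approx(30.0, rel=0.03)

    def test_seed_reproducibility_byte_identical(self, small_design, truth_all):
        a = generate_colony_counts(small_design, truth_all)
        b = generate_colony_counts(small_design, truth_all)
        pd.testing.assert_frame_equal(a, b)
        assert a.to_csv() == b.to_csv()

    def test_different_seed_differs(self, small_design, truth_all):
        a = generate_colony_counts(small_design, truth_all)
        b = generate_colony_counts(small_design, truth_all, seed=99)
        assert not a.equals(b)

    def test_missing_truth_raises(self, small_design):
        with pytest.raises(KeyError, match="PBS1"):
            generate_colony_counts(small_design, {"DS1": TrueLQ(0.1, 0.02)})

    def test_includes_controls_and_colonies_bounded(self, small_design, truth_all):
        df = generate_colony_counts(small_design, truth_all)
        assert 0.0 in set(df["dose_gy"])
        assert (df["colonies"] >= 0).all()
        assert (df["colonies"] <= df["seeded"]).all()

    def test_reference_counts_use_label_and_position_zero(self, truth_all):
        df = generate_reference_colony_counts(truth_all["Co60"], seed=4)
        assert set(df["mode"]) == {"Co60"}
        assert set(df["position"]) == {0}
        assert set(df["dose_gy"]) == {0.0, 1.0, 2.0, 3.0, 4.0, 5.0}


class TestEndpointData:
    def test_foci_per_nucleus_mean_in_dsb_range(self, full_design):
        # ~25-35 foci per nucleus at 1 Gy
        df = generate_endpoint_data(full_design, EndpointKind.FOCI_PER_NUCLEUS)
        at_1gy = df[df["dose_gy"] == 1.0]["value"]
        assert at_1gy.between(25, 35).all()

    def test_zero_dose_zero_background_gives_zeros(self, full_design):
        df = generate_endpoint_data(
            full_design,
            EndpointKind.FOCI_PER_NUCLEUS,
            params={"background": 0.0},
            doses=(0.0,),
        )
        assert (df["value"] == 0).all()

    def test_poisson_kind_variance_matches_mean(self):
        # dispersion check on the raw per-cell counts, n = 1e5, 5% tolerance
        counts = generate_mn_cell_counts(5.0, n_bnc=100_000, seed=11)
        assert counts.var() == pytest.approx(counts.mean(), rel=0.05)

    def test_percent_kinds_bounded(self, full_design):
        for kind in (EndpointKind.APOPTOSIS_TOTAL_PCT, EndpointKind.BNC_WITH_MN_PCT):
            df = generate_endpoint_data(full_design, kind)
            assert df["value"].between(0, 100).all()

    def test_apoptosis_has_time_points(self, full_design):
        df = generate_endpoint_data(full_design, EndpointKind.APOPTOSIS_TOTAL_PCT)
        assert set(df["time_h"]) == {24.0, 48.0, 96.0}

    def test_unknown_kind_raises(self, full_design):
        with pytest.raises(ValueError):
            generate_endpoint_data(full_design, "necrosis_pct")

    def test_determinism(self, full_design):
        a = generate_endpoint_data(full_design, EndpointKind.MN_FREQUENCY)
        b = generate_endpoint_data(full_design, EndpointKind.MN_FREQUENCY)
        pd.testing.assert_frame_equal(a, b)


class TestLETSpectrumGeneration:
    @pytest.mark.parametrize("mode,position", list(LETD_TARGETS))
    def test_generated_spectra_hit_published_targets(self, mode, position):
        targets = LETD_TARGETS[(mode, position)]
        shares = solve_dose_shares(targets, LETD_ALL_PARTICLES[(mode, position)])
        spectra = generate_let_spectrum(targets, shares, seed=2)
        for species, target in targets.items():
            got = dose_average_let(spectra[species]).letd
            assert got == pytest.approx(target, rel=5e-3)

    def test_proton_peak_target_recovered(self):
        spectra = generate_let_spectrum({"protons": 3.17}, {"protons": 1.0}, seed=0)
        assert dose_average_let(spectra["protons"]).letd == pytest.approx(3.17, rel=5e-3)

    def test_dose_shares_solve_is_exact(self):
        targets = LETD_TARGETS[("PBS", 2)]
        shares = solve_dose_shares(targets, 3.11)
        mean = sum(targets[s] * w for s, w in shares.items())
        assert sum(shares.values()) == pytest.approx(1.0)
        assert mean == pytest.approx(3.11)

    def test_infeasible_target_raises(self):
        # all-particles target above every component value is unreachable
        with pytest.raises(ValueError, match="infeasible"):
            solve_dose_shares({"protons": 0.45, "electrons": 0.28}, 10.0)
        with pytest.raises(ValueError):
            generate_let_spectrum({"protons": -1.0}, {"protons": 1.0})

    def test_shares_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_let_spectrum({"protons": 1.0}, {"protons": 0.5})

    def test_determinism(self):
        a = generate_let_spectrum({"protons": 3.17}, {"protons": 1.0}, seed=7)
        b = generate_let_spectrum({"protons": 3.17}, {"protons": 1.0}, seed=7)
        np.testing.assert_array_equal(a["protons"].let, b["protons"].let)
        np.testing.assert_array_equal(a["protons"].dose_weight, b["protons"].dose_weight)


class TestNeutronSpectrumGeneration:
    def test_all_below_1mev_class(self):
        spec = generate_neutron_spectrum((1.0, 0.0, 0.0), n=2000, seed=1)
        cls = classify_neutrons(spec)
        assert cls.percentages[NEUTRON_CLASS_LABELS[0]] == 100.0

    def test_empirical_fractions_converge(self):
        fr = (0.5, 0.3, 0.2)
        spec = generate_neutron_spectrum(fr, n=100_000, seed=8)
        cls = classify_neutrons(spec)
        for f, label in zip(fr, NEUTRON_CLASS_LABELS):
            assert cls.percentages[label] / 100 == pytest.approx(f, abs=0.01)

    def test_zero_samples_raises(self):
        with pytest.raises(ValueError):
            generate_neutron_spectrum((1.0, 0.0, 0.0), n=0)

    def test_negative_fraction_raises(self):
        with pytest.raises(ValueError):
            generate_neutron_spectrum((-0.1, 0.6, 0.5), n=10)

    def test_determinism(self):
        a = generate_neutron_spectrum((0.9, 0.08, 0.02), n=500, seed=3)
        b = generate_neutron_spectrum((0.9, 0.08, 0.02), n=500, seed=3)
        np.testing.assert_array_equal(a.energy, b.energy)


class TestDesignValidation:
    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            ExperimentDesign(plating_efficiency=0.0)
        with pytest.raises(ValueError):
            ExperimentDesign(doses=(-1.0,))
        with pytest.raises(ValueError):
            ExperimentDesign(wells_per_condition=0)

    def test_true_lq_rejects_degenerate(self):
        with pytest.raises(ValueError):
            TrueLQ(0.0, 0.0)
        with pytest.raises(ValueError):
            TrueLQ(-0.1, 0.05)

    def test_dose_adaptive_seeding(self, small_design):
        assert small_design.seeded_for(0.0) == 330
        assert small_design.seeded_for(5.0) == 5000
        # doses between configured keys use the next lower key
        assert small_design.seeded_for(4.0) == 1500
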