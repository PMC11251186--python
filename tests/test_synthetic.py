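"""Generator properties: determinism, preset truth, dissociation arithmetic."""

import numpy as np
import pytest

from c4bpkit import synthetic as syn
from c4bpkit.single_particle import cdms_events_to_masses


class TestPresets:
    def test_native_weights_follow_occupancy_algebra(self):
        a1, a2, a3 = syn.occupancy_weights(0.55, 0.68)
        assert (a1, a2, a3) == pytest.approx((0.374, 0.482, 0.144))
        preset = syn.get_preset("SERUM-CDMS-NATIVE")
        assert sum(preset.component_weights.values()) == pytest.approx(1.0)

    def test_mechanistic_mass_differences_exact(self):
        # M(α7β1) − M(α6β1) = Mα and M(x+ProS) − M(x) = MProS exactly
        m7 = 7 * syn.M_ALPHA_KDA + syn.M_BETA_KDA
        m6 = 6 * syn.M_ALPHA_KDA + syn.M_BETA_KDA
        assert m7 - m6 == pytest.approx(syn.M_ALPHA_KDA, rel=1e-12)
        assert (m7 + syn.M_PROS_KDA) - m7 == pytest.approx(syn.M_PROS_KDA, rel=1e-12)
        assert m7 == pytest.approx(551.0) and m6 == pytest.approx(478.1)

    def test_invalid_presets_rejected(self):
        with pytest.raises(ValueError):
            syn.SerumPreset(name="x", mode="observed", component_weights={"a": 0.5})
        with pytest.raises(ValueError):
            syn.SerumPreset(name="x", mode="mechanistic", f7=1.2)
        with pytest.raises(ValueError):
            syn.SerumPreset(name="x", mode="mechanistic", n_events=0)


class TestCdmsGenerator:
    def test_bit_reproducible_given_seed(self):
        e1 = syn.gen_cdms_events("SERUM-CDMS-NATIVE", 100, seed=9)
        e2 = syn.gen_cdms_events("SERUM-CDMS-NATIVE", 100, seed=9)
        assert e1 == e2
        assert e1 != syn.gen_cdms_events("SERUM-CDMS-NATIVE", 100, seed=10)

    def test_heaviest_third_mean_matches_monte_carlo_oracle(self):
        # 637.6 kDa frozen from a 2e6-draw Monte-Carlo oracle sampling the
        # preset mixture directly (top third of a 0.374/0.482/0.144 blend
        # of N(633,22)/N(553,20)/N(481,20)).
        masses = cdms_events_to_masses(syn.gen_cdms_events("SERUM-CDMS-NATIVE", 5000, seed=42))
        heavy = np.sort(masses)[-len(masses) // 3 :]
        assert np.mean(heavy) == pytest.approx(637.6, abs=3.0)

    def test_mechanistic_bound_fraction(self):
        truth = syn.latent_truth("MECHANISTIC", 5000, seed=4)
        assert truth.pros_bound.mean() == pytest.approx(0.68, abs=0.02)

    def test_component_weights_converge_at_sqrt_n(self):
        """Empirical weights approach preset weights within ~4 binomial SEs."""
        preset = syn.get_preset("SERUM-CDMS-NATIVE")
        edges = (520.0, 595.0)  # boundaries between the three populations
        for n in (500, 5000):
            masses = cdms_events_to_masses(
                syn.gen_cdms_events(preset, n, seed=8, sigma_i=0.0)
            )
            w_hat = np.array(
                [
                    np.mean(masses < edges[0]),
                    np.mean((masses >= edges[0]) & (masses < edges[1])),
                    np.mean(masses >= edges[1]),
                ]
            )
            w_true = np.array([0.144, 0.482, 0.374])
            se = np.sqrt(w_true * (1 - w_true) / n)
            assert np.all(np.abs(w_hat - w_true) < 4 * se + 0.01)

    def test_rejects_bad_n(self):
        with pytest.raises(ValueError):
            syn.gen_cdms_events("SERUM-CDMS-NATIVE", 0, seed=1)


class TestAcidified:
    def test_pure_bound_population_dissociates_to_two_modes(self):
        preset = syn.SerumPreset(name="pure", mode="mechanistic", f7=1.0, q=1.0)
        masses = cdms_events_to_masses(
            syn.gen_acidified(preset, 2000, seed=2, sigma_i=0.0)
        )
        complexes = masses[masses > 200]
        pros = masses[masses <= 200]
        assert complexes.size == pros.size == 2000
        assert np.mean(complexes) == pytest.approx(551.0, abs=2.0)
        assert np.mean(pros) == pytest.approx(79.8, abs=1.0)

    def test_q_zero_identical_to_native_composition(self):
        preset = syn.SerumPreset(name="unbound", mode="mechanistic", q=0.0)
        nat = cdms_events_to_masses(syn.gen_cdms_events(preset, 500, seed=3, sigma_i=0.0))
        acid = cdms_events_to_masses(syn.gen_acidified(preset, 500, seed=3, sigma_i=0.0))
        assert np.allclose(np.sort(nat), np.sort(acid))

    def test_complex_ratio_equals_f7_split(self):
        masses = cdms_events_to_masses(syn.gen_acidified("MECHANISTIC", 5000, seed=6))
        complexes = masses[masses > 200]
        frac7 = np.mean(complexes > (551.0 + 478.1) / 2)
        assert frac7 == pytest.approx(0.55, abs=0.03)

    def test_observed_mode_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_acidified("SERUM-CDMS-NATIVE", 10, seed=0)

    def test_detection_efficiency_thins_free_pros(self):
        preset = syn.SerumPreset(
            name="m", mode="mechanistic", pros_detection_efficiency=0.5
        )
        masses = cdms_events_to_masses(syn.gen_acidified(preset, 4000, seed=1))
        n_pros = int((masses < 200).sum())
        assert n_pros == pytest.approx(0.5 * 0.68 * 4000, abs=150)


class TestMPGenerator:
    def test_noise_free_contrast_arithmetic(self):
        preset = syn.SerumPreset(
            name="one", mode="observed",
            component_masses={"x": 73.0}, component_sds={"x": 1e-9},
            component_weights={"x": 1.0},
        )
        events, _ = syn.gen_mp_events(
            preset, 1, seed=0, slope=2e-5, intercept=1e-4, noise_sd_kda=0.0
        )
        assert events[0].contrast == pytest.approx(1.56e-3, rel=1e-4)

    def test_calibrant_block_at_exact_ladder_masses(self):
        _, calib = syn.gen_mp_events("SERUM-MP-NATIVE", 10, seed=0)
        assert sorted(calib["mass_kda"].unique()) == [73.0, 149.0, 483.0, 800.0]

    def test_no_calibrants_flag(self):
        _, calib = syn.gen_mp_events("SERUM-MP-NATIVE", 10, seed=0, include_calibrants=False)
        assert calib.empty

    def test_four_population_modes_present(self):
        events, _ = syn.gen_mp_events("SERUM-MP-NATIVE", 5000, seed=7, slope=2e-5, intercept=0.0)
        masses = np.array([e.contrast for e in events]) / 2e-5
        for center in (630.0, 553.0, 487.0, 68.0):
            frac = np.mean(np.abs(masses - center) < 30)
            assert frac > 0.02, f"no population near {center} kDa"

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_mp_events("SERUM-MP-NATIVE", 10, seed=0, slope=-1.0)


class TestGlycoGenerator:
    def test_zero_psms_gives_empty_table(self):
        assert syn.gen_glyco_psms(n_psm_per_site=0).empty

    def test_eleven_distinct_sites(self, default_psms):
        assert len(default_psms.groupby(["protein", "site"])) == 11

    def test_reproducible(self):
        a = syn.gen_glyco_psms(seed=1)
        b = syn.gen_glyco_psms(seed=1)
        assert a.equals(b)


class TestPlasmaGenerator:
    def test_healthy_truth_ratio_is_six_point_five(self, healthy_cohort):
        assert np.allclose(healthy_cohort["truth"]["ratio_alpha_beta"], 6.5)

    def test_acute_truth_ratio_arithmetic(self):
        cohort = syn.gen_plasma_cohort(scenario="acute", sigma=0.0, seed=1,
                                       acute_7a_fraction=0.5)
        truth = cohort["truth"]
        acute = truth[truth["is_acute"]]
        # total α / total β = (0.5·(6·0.5+7·0.5)+0.5·7)/(0.5·1) = 13.5
        assert np.allclose(acute["ratio_alpha_beta"], 13.5)
        assert np.allclose(truth[~truth["is_acute"]]["ratio_alpha_beta"], 6.5)

    def test_crp_low_outside_acute_timepoints(self):
        cohort = syn.gen_plasma_cohort(scenario="acute", sigma=0.0, seed=1)
        truth = cohort["truth"]
        thresh = syn.CRP_ACUTE_THRESHOLD_G_L / (syn.PLASMA_MW_KDA["CRP"] * 1000.0)
        assert (truth.loc[~truth["is_acute"], "crp_m"] < thresh).all()
        assert (truth.loc[truth["is_acute"], "crp_m"] > thresh).all()

    def test_panel_has_22_reference_proteins(self, healthy_cohort):
        assert len(healthy_cohort["panel"]) == 22
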