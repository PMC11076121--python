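import numpy as np
import pandas as pd
import pytest
from scipy import stats

from colonytrack.colony_geometry import nn3_table
from colonytrack.home_range import kud_area
from colonytrack.movement_metrics import movement_activity
from colonytrack.cleaning import resample
from colonytrack.inference import sibling_correlation
from colonytrack.social_network import detect_associations, node_metrics, round_times
from colonytrack.synthetic_data import (
    SimConfig,
    make_scenario,
    simulate_chicks,
    simulate_colony,
    simulate_tracks,
)

CHI2_95_2DF = 5.991464547107979


class TestColonySim:
    def test_realised_nn3_within_band_of_targets(self):
        colony = simulate_colony(seed=5)
        nn3 = nn3_table(colony.nests)
        for cls, target in (("HD", 2.96), ("LD", 4.78)):
            got = nn3[colony.nests["density_class"] == cls].mean()
            assert abs(got - target) / target < 0.15

    def test_plot_areas_equal_850(self):
        colony = simulate_colony(seed=1)
        for poly in colony.plots.values():
            assert poly.area == pytest.approx(850.0)
        assert len(colony.plots) == 8

    def test_deterministic_given_seed(self):
        a = simulate_colony(seed=9)
        b = simulate_colony(seed=9)
        pd.testing.assert_frame_equal(a.nests, b.nests)

    def test_zero_nests_is_valid_empty_colony(self):
        cfg = SimConfig(nests_per_hd_plot=0, nests_per_ld_plot=0)
        colony = simulate_colony(cfg, seed=1)
        assert len(colony.nests) == 0

    def test_impossible_spacing_rejected(self):
        cfg = SimConfig(nests_per_hd_plot=5000, min_nest_spacing_m=1.0)
        with pytest.raises(ValueError, match="place"):
            simulate_colony(cfg, seed=1)


class TestChickSim:
    def test_counts_and_sibling_structure(self):
        colony = simulate_colony(seed=2)
        chicks = simulate_chicks(colony, seed=2)
        assert len(chicks) == 68
        assert chicks["nest_foster"].nunique() == 51
        sizes = chicks.groupby("nest_foster").size()
        assert set(sizes) == {1, 2}
        assert (sizes == 2).sum() == 17

    def test_cross_fostering_off_keeps_origin_nest(self):
        colony = simulate_colony(seed=2)
        chicks = simulate_chicks(colony, SimConfig(cross_foster=False), seed=2)
        assert (chicks["nest_origin"] == chicks["nest_foster"]).all()

    def test_full_swap_decouples_pre_and_post_density(self):
        cfg = SimConfig(cf_ld_to_hd=26, cf_hd_to_ld=50, cf_ld_to_ld=0, cf_hd_to_hd=0)
        colony = simulate_colony(seed=4)
        chicks = simulate_chicks(colony, cfg, seed=4)
        nn3 = nn3_table(colony.nests)
        r = np.corrcoef(nn3[chicks["nest_origin"]], nn3[chicks["nest_foster"]])[0, 1]
        assert r < 0.1

    def test_deterministic_given_seed(self):
        colony = simulate_colony(seed=3)
        pd.testing.assert_frame_equal(
            simulate_chicks(colony, seed=8), simulate_chicks(colony, seed=8)
        )


class TestTrackSim:
    def degenerate_config(self, **kw):
        return SimConfig(
            ou_phi=0.0, ou_sigma_base_m=0.0, offset_sigma_m=0.0,
            tag_noise_sigma_m=0.0, density_slope=0.0, activity_logsd=0.0,
            day_logsd=0.0, n_days=1, **kw,
        )

    def test_degenerate_process_stays_at_nest(self, square_colony):
        chicks = pd.DataFrame(
            {"chick_id": ["c1"], "nest_origin": ["N1"], "nest_foster": ["N1"],
             "sibling_group": ["S1"], "sex": ["M"], "age_days": [18],
             "tarsus_mm": [55.0], "mass_g": [600.0], "plot_id": ["P1"]}
        )
        truth, obs = simulate_tracks(square_colony, chicks, self.degenerate_config(), seed=1)
        nest = square_colony.nests.loc["N1"]
        assert np.allclose(truth["x"], nest["x"]) and np.allclose(truth["y"], nest["y"])
        assert np.allclose(obs["x"], nest["x"])

    def test_ar1_stationary_variance(self, square_colony):
        # per-axis stationary variance sigma^2/(1-phi^2) = 4/3 for phi=.5, sigma=1
        cfg = SimConfig(
            ou_phi=0.5, ou_sigma_base_m=1.0, offset_sigma_m=0.0,
            tag_noise_sigma_m=0.0, density_slope=0.0, activity_logsd=0.0,
            day_logsd=0.0, n_days=3,
        )
        chicks = pd.DataFrame(
            {"chick_id": ["c1"], "nest_origin": ["N2"], "nest_foster": ["N2"],
             "sibling_group": ["S1"], "sex": ["M"], "age_days": [18],
             "tarsus_mm": [55.0], "mass_g": [600.0], "plot_id": ["P1"]}
        )
        truth, _ = simulate_tracks(square_colony, chicks, cfg, seed=7)
        nest = square_colony.nests.loc["N2"]
        var = 0.5 * (np.var(truth["x"] - nest["x"]) + np.var(truth["y"] - nest["y"]))
        assert var == pytest.approx(4.0 / 3.0, rel=0.05)

    def test_mean_positional_error_matches_tag_accuracy(self):
        # Rayleigh mean = sigma * sqrt(pi/2): 0.263 m -> ~0.33 m
        bundle = make_scenario("paperlike", seed=21, n_days=1)
        truth = bundle.truth.set_index(["tag_id", "t"])
        obs = bundle.observed
        key = list(zip(obs["tag_id"], obs["t"]))[:10000]
        sub = obs.iloc[:10000]
        tr = truth.loc[key]
        err = np.hypot(sub["x"].to_numpy() - tr["x"].to_numpy(),
                       sub["y"].to_numpy() - tr["y"].to_numpy())
        assert err.mean() == pytest.approx(0.263 * np.sqrt(np.pi / 2), rel=0.05)

    def test_gap_mixture_frequencies(self):
        bundle = make_scenario("paperlike", seed=13, n_days=1)
        gaps = np.concatenate(
            [np.diff(g["t"].to_numpy()) for _, g in bundle.observed.groupby("tag_id")]
        )
        counts = np.array([(gaps == 30).sum(), (gaps == 60).sum(), (gaps == 180).sum()])
        assert counts.sum() == len(gaps)  # only the three gap classes occur
        chi2, p = stats.chisquare(counts, len(gaps) * np.array([0.8, 0.1, 0.1]))
        assert p > 0.01

    def test_same_seed_identical_bundle(self):
        a = make_scenario("paperlike", seed=3, n_days=1, nominal_interval_s=300)
        b = make_scenario("paperlike", seed=3, n_days=1, nominal_interval_s=300)
        pd.testing.assert_frame_equal(a.observed, b.observed)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_kud_of_true_track_matches_ou_analytic_area(self, square_colony):
        # isotropic OU stationary density is Gaussian: 95% area pi*chi2*var
        cfg = SimConfig(
            ou_phi=0.78, ou_sigma_base_m=0.22, offset_sigma_m=0.0,
            tag_noise_sigma_m=0.0, density_slope=0.0, activity_logsd=0.0,
            day_logsd=0.0, n_days=3,
        )
        chicks = pd.DataFrame(
            {"chick_id": ["c1"], "nest_origin": ["N2"], "nest_foster": ["N2"],
             "sibling_group": ["S1"], "sex": ["M"], "age_days": [18],
             "tarsus_mm": [55.0], "mass_g": [600.0], "plot_id": ["P1"]}
        )
        truth, _ = simulate_tracks(square_colony, chicks, cfg, seed=11)
        var = cfg.stationary_sigma_m**2
        est = kud_area(truth[["x", "y"]].to_numpy(), level=0.95)
        assert est.area_m2 == pytest.approx(np.pi * CHI2_95_2DF * var, rel=0.20)


class TestScenarios:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            make_scenario("bogus", seed=0)

    def test_null_scenario_zeroes_planted_effects(self):
        b = make_scenario("null", seed=1, n_days=1, nominal_interval_s=300)
        assert b.config.density_slope == 0.0
        assert b.config.sibling_cohesion == 0.0

    def test_cohesion_zero_gives_uncorrelated_siblings(self):
        b = make_scenario("null", seed=17, nominal_interval_s=300)
        rs = resample(b.observed, 300.0)
        act = (
            rs.groupby("tag_id", group_keys=False)[["t", "x", "y"]]
            .apply(movement_activity)
        )
        sc = sibling_correlation(act, b.chicks)
        assert abs(sc.r) < 0.45

    def test_sibling_associations_dominate_under_defaults(self):
        b = make_scenario("paperlike", seed=23, n_days=1)
        events = detect_associations(round_times(b.observed))
        nm = node_metrics(events, b.chicks)
        sib = nm["sibling_events"].sum()
        non_sib = nm["strength"].sum()
        assert sib > 5 * max(non_sib, 1)
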