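"""Tests of the synthetic landscape / community / survey generators."""

import numpy as np
import pytest
from scipy.special import expit

import ghostbirds as gb
from ghostbirds.occmodel import SiteDesign
from ghostbirds.rasters import DENSITY_METRICS, METRIC_NAMES
from ghostbirds.synthdata import SurveyDesign


def make_hyper(sd=0.0, means=(0.2, -0.1, 0.5, 1.0, 0.8, -0.3)):
    fams = ("alpha0", "alpha_route", "beta0", "beta_mid", "beta_can", "beta_burn")
    return gb.CommunityHyper(**{f: (m, sd) for f, m in zip(fams, means)})


class TestDrawCommunityParams:
    def test_degenerate_variance_gives_exact_means(self):
        params = gb.draw_community_params(make_hyper(sd=0.0), 5, seed=0)
        expected = {"alpha0": 0.2, "alpha_routeA": -0.1, "alpha_routeB": -0.1,
                    "beta0": 0.5, "beta_mid": 1.0, "beta_can": 0.8,
                    "beta_burn": -0.3}
        for slot, value in expected.items():
            assert np.allclose(params.coefs[slot], value)

    def test_large_sample_matches_hyper_law(self):
        params = gb.draw_community_params(make_hyper(sd=1.0, means=(0,) * 6),
                                          10_000, seed=1)
        x = params.coefs["beta_mid"]
        assert abs(x.mean()) < 0.05
        assert abs(x.std(ddof=1) - 1.0) < 0.05

    def test_seed_determinism(self):
        a = gb.draw_community_params(make_hyper(sd=0.7), 20, seed=9)
        b = gb.draw_community_params(make_hyper(sd=0.7), 20, seed=9)
        for slot in a.coefs:
            assert np.array_equal(a.coefs[slot], b.coefs[slot])

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            gb.CommunityHyper(alpha0=(0, -1), alpha_route=(0, 1), beta0=(0, 1),
                              beta_mid=(0, 1), beta_can=(0, 1), beta_burn=(0, 1))


class TestSimulateLandscape:
    def test_no_transition_leaves_unburned_cells_unchanged(self):
        L = gb.simulate_landscape(dims=(80, 80), ghost_fraction=0.0,
                                  burn_fraction=0.1, seed=2)
        outside = ~L.burned_mask
        for name in METRIC_NAMES:
            assert np.array_equal(L.metrics_baseline[name][outside],
                                  L.metrics_later[name][outside])

    def test_ghost_cell_count_and_placement(self):
        L = gb.simulate_landscape(dims=(100, 100), ghost_fraction=0.2,
                                  lowlying_fraction=0.5, burn_fraction=0.0,
                                  seed=3)
        n = L.ghost_mask.sum()
        assert abs(n - 2000) <= 3 * np.sqrt(2000 * 0.8)  # generous count band
        assert not np.any(L.ghost_mask & ~L.lowlying_mask)

    def test_densities_stay_in_unit_interval_after_perturbation(self):
        L = gb.simulate_landscape(dims=(100, 100), ghost_fraction=0.1,
                                  burn_fraction=0.2, seed=4)
        for name in DENSITY_METRICS:
            for book in (L.metrics_baseline, L.metrics_later):
                assert book[name].min() >= 0.0
                assert book[name].max() <= 1.0

    def test_heights_nonnegative_and_reproducible(self):
        L1 = gb.simulate_landscape(dims=(60, 60), seed=5)
        L2 = gb.simulate_landscape(dims=(60, 60), seed=5)
        for name in ("mean_height", "max_height", "sd_height"):
            assert L1.metrics_baseline[name].min() >= 0.0
            assert np.array_equal(L1.metrics_baseline[name],
                                  L2.metrics_baseline[name])
        assert np.array_equal(L1.ghost_mask, L2.ghost_mask)

    def test_infeasible_fractions_raise(self):
        with pytest.raises(ValueError, match="infeasible"):
            gb.simulate_landscape(dims=(50, 50), ghost_fraction=0.5,
                                  lowlying_fraction=0.1, seed=6)


class TestBiomassChange:
    def test_ghost_cells_labelled_ghost_and_unchanged_unaffected(self, landscape):
        labels = gb.simulate_biomass_change(landscape)
        assert labels[landscape.ghost_mask].all()
        untouched = ~landscape.ghost_mask & ~landscape.burned_mask
        assert not labels[untouched].any()

    def test_label_agreement_with_transition_mask(self, landscape):
        labels = gb.simulate_biomass_change(landscape)
        m = landscape.lowlying_mask
        agreement = (labels[m] == landscape.ghost_mask[m]).mean()
        assert agreement >= 0.95


class TestSampleSites:
    def test_minimum_spacing_enforced(self, landscape):
        sv = gb.sample_sites(landscape, n_sites=50, min_spacing=400, seed=1)
        x = sv.cols * landscape.cell_size
        yy = sv.rows * landscape.cell_size
        d2 = (x[:, None] - x) ** 2 + (yy[:, None] - yy) ** 2
        np.fill_diagonal(d2, np.inf)
        assert np.sqrt(d2.min()) >= 400.0

    def test_route_split_multinomial(self, landscape):
        sv = gb.sample_sites(landscape, n_sites=156, min_spacing=150,
                             route_split=(0.2, 0.2, 0.6), seed=2)
        counts = np.bincount(sv.route, minlength=3)  # [off, A, B]
        # ~31/31/94 expected; allow 4 sd of the binomial count
        assert abs(counts[1] - 31.2) <= 4 * np.sqrt(156 * 0.2 * 0.8)
        assert abs(counts[2] - 31.2) <= 4 * np.sqrt(156 * 0.2 * 0.8)
        assert abs(counts[0] - 93.6) <= 4 * np.sqrt(156 * 0.6 * 0.4)

    def test_seed_determinism(self, landscape):
        a = gb.sample_sites(landscape, n_sites=30, min_spacing=300, seed=7)
        b = gb.sample_sites(landscape, n_sites=30, min_spacing=300, seed=7)
        assert np.array_equal(a.rows, b.rows)
        assert np.array_equal(a.cols, b.cols)
        assert np.array_equal(a.route, b.route)

    def test_infeasible_spacing_raises(self):
        L = gb.simulate_landscape(dims=(40, 40), seed=8)
        with pytest.raises(ValueError, match="place"):
            gb.sample_sites(L, n_sites=200, min_spacing=400, seed=9)

    def test_occasion_counts_valid(self, landscape):
        sv = gb.sample_sites(landscape, n_sites=60, min_spacing=200, seed=3)
        assert np.isin(sv.n_occasions, [1, 2, 3]).all()
        assert (sv.n_occasions[sv.route > 0] == 3).all()


def saturated_design(M, J=3):
    survey = SurveyDesign(rows=np.zeros(M, dtype=int), cols=np.arange(M),
                          route=np.zeros(M, dtype=int),
                          n_occasions=np.full(M, J), min_spacing=0.0,
                          cell_size=1.0)
    design = SiteDesign(midstory=np.zeros(M), canopy=np.zeros(M),
                        burned=np.zeros(M), route=np.zeros(M, dtype=int))
    return survey, design


def intercept_params(a0, b0, K=1):
    coefs = {s: np.zeros(K) for s in ("alpha0", "alpha_routeA", "alpha_routeB",
                                      "beta0", "beta_mid", "beta_can",
                                      "beta_burn")}
    coefs["alpha0"] += a0
    coefs["beta0"] += b0
    return gb.CommunityParams(coefs=coefs)


class TestSimulateDetections:
    def test_saturated_probabilities_give_all_ones(self):
        survey, design = saturated_design(30)
        y = gb.simulate_detections(intercept_params(20.0, 20.0), survey,
                                   design, seed=0)
        assert (y.y == 1).all()

    def test_zero_occupancy_gives_all_zeros(self):
        survey, design = saturated_design(30)
        y = gb.simulate_detections(intercept_params(20.0, -20.0), survey,
                                   design, seed=0)
        assert (y.y == 0).all()

    def test_detection_at_least_once_probability(self):
        # psi=0.6, p=0.5, J=3: P(>=1 detection) = 0.6 * (1 - 0.5^3) = 0.525
        M = 2000
        survey, design = saturated_design(M)
        params = intercept_params(0.0, np.log(0.6 / 0.4))
        y = gb.simulate_detections(params, survey, design, seed=1)
        frac = (y.detection_counts()[:, 0] > 0).mean()
        se = np.sqrt(0.525 * 0.475 / M)
        assert abs(frac - 0.525) < 3 * se

    def test_per_occasion_frequency_converges_to_psi_times_p(self):
        M = 4000
        survey, design = saturated_design(M)
        params = intercept_params(np.log(0.5 / 0.5), np.log(0.4 / 0.6))
        y = gb.simulate_detections(params, survey, design, seed=2)
        for j in range(3):
            freq = (y.y[:, j, 0] == 1).mean()
            se = np.sqrt(0.2 * 0.8 / M)
            assert abs(freq - 0.4 * 0.5) < 3 * se

    def test_missing_pattern_matches_design(self, landscape):
        sv = gb.sample_sites(landscape, n_sites=60, min_spacing=200, seed=4)
        sd = gb.build_site_design(landscape, sv)
        params = gb.draw_community_params(gb.default_community_hyper(), 5, 0)
        y = gb.simulate_detections(params, sv, sd, seed=5)
        observed = y.y[:, :, 0] != -1
        assert np.array_equal(observed.sum(axis=1), sv.n_occasions)
        # missingness is a per-site prefix: occasions 0..n-1 observed
        for i in range(sv.M):
            assert observed[i, :sv.n_occasions[i]].all()


def test_build_site_design_standardizes_with_retained_constants(landscape):
    sv = gb.sample_sites(landscape, n_sites=80, min_spacing=200, seed=6)
    sd = gb.build_site_design(landscape, sv)
    assert abs(sd.midstory.mean()) < 1e-10
    assert abs(sd.midstory.std(ddof=1) - 1.0) < 1e-10
    mean, scale = sd.standardizers["canopy_density"]
    raw = landscape.metrics_later["canopy_density"][sv.rows, sv.cols]
    assert np.allclose(sd.canopy * scale + mean, raw)
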