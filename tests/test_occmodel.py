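"""Tests of the occupancy model: likelihood, sampler, diagnostics, summaries."""

import numpy as np
import pandas as pd
import pytest

import ghostbirds as gb
from ghostbirds.occmodel import (
    COEF_FAMILIES,
    DetectionArray,
    SamplerConfig,
    SiteDesign,
    full_conditional_z,
    gelman_rubin,
)

from _oracles import loglik_by_enumeration


def single_cell_data(y_hist):
    y = np.asarray(y_hist, dtype=np.int8).reshape(1, -1, 1)
    design = SiteDesign(midstory=[0.0], canopy=[0.0], burned=[0.0], route=[0])
    return DetectionArray(y=y), design


def intercept_params(psi, p, K=1):
    def logit(q):
        return np.log(q / (1 - q)) if 0 < q < 1 else (50.0 if q >= 1 else -50.0)

    coefs = {s: np.zeros(K) for s in ("alpha0", "alpha_routeA", "alpha_routeB",
                                      "beta0", "beta_mid", "beta_can",
                                      "beta_burn")}
    coefs["alpha0"] += logit(p)
    coefs["beta0"] += logit(psi)
    return gb.CommunityParams(coefs=coefs)


class TestStandardize:
    def test_three_point_closed_form(self):
        z, mean, sd = gb.standardize([1.0, 2.0, 3.0])
        assert np.allclose(z, [-1.0, 0.0, 1.0])
        assert (mean, sd) == (2.0, 1.0)

    def test_idempotence(self):
        z, _, _ = gb.standardize(np.arange(10.0))
        z2, m2, s2 = gb.standardize(z)
        assert np.allclose(z, z2, atol=1e-12)
        assert abs(m2) < 1e-12 and abs(s2 - 1) < 1e-12

    def test_round_trip(self):
        x = np.array([3.0, -1.5, 2.2, 8.0])
        z, mean, sd = gb.standardize(x)
        assert np.allclose(gb.unstandardize(z, mean, sd), x, atol=1e-12)

    def test_zero_sd_raises(self):
        with pytest.raises(ValueError, match="constant"):
            gb.standardize([2.0, 2.0, 2.0])


class TestMarginalLikelihood:
    def test_certain_occupancy_closed_form(self):
        y, design = single_cell_data([1, 0])
        ll = gb.loglik_marginal(intercept_params(1 - 1e-15, 0.5), y, design)
        assert ll == pytest.approx(np.log(0.25), abs=1e-9)

    def test_all_zero_history_closed_form(self):
        y, design = single_cell_data([0, 0])
        ll = gb.loglik_marginal(intercept_params(0.5, 0.5), y, design)
        assert ll == pytest.approx(np.log(0.5 * 0.25 + 0.5), abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        M, J, K = 3, 3, 2
        y = rng.integers(0, 2, size=(M, J, K)).astype(np.int8)
        y[1, 2, :] = -1  # a missing occasion
        ya = DetectionArray(y=y)
        design = SiteDesign(midstory=rng.standard_normal(M),
                            canopy=rng.standard_normal(M),
                            burned=rng.integers(0, 2, M).astype(float),
                            route=rng.integers(0, 3, M))
        coefs = {s: rng.normal(0, 0.8, K) for s in
                 ("alpha0", "alpha_routeA", "alpha_routeB", "beta0",
                  "beta_mid", "beta_can", "beta_burn")}
        params = gb.CommunityParams(coefs=coefs)
        assert gb.loglik_marginal(params, ya, design) == pytest.approx(
            loglik_by_enumeration(params, ya, design), abs=1e-10)

    def test_dimension_mismatch_raises(self):
        y, design = single_cell_data([1, 0])
        with pytest.raises(ValueError, match="mismatch"):
            gb.loglik_marginal(intercept_params(0.5, 0.5, K=3), y, design)


class TestFullConditionalZ:
    def test_detection_implies_presence(self):
        assert full_conditional_z(0.2, 0.5, [0, 1, 0]) == 1.0

    def test_single_occasion_closed_form(self):
        assert full_conditional_z(0.5, 0.5, [0]) == pytest.approx(1 / 3)

    def test_hand_bayes_three_zeros(self):
        # psi=0.8, p=0.3, J=3: 0.8*0.7^3 / (0.8*0.7^3 + 0.2)
        num = 0.8 * 0.7 ** 3
        assert full_conditional_z(0.8, 0.3, [0, 0, 0]) == pytest.approx(
            num / (num + 0.2), abs=1e-12)

    def test_missing_occasions_ignored(self):
        assert full_conditional_z(0.5, 0.5, [0, -1]) == pytest.approx(1 / 3)


class TestGelmanRubin:
    def test_hand_formula_two_small_chains(self):
        chains = np.array([[1.0, 2.0, 3.0], [2.0, 3.0, 4.0]])
        # W = 1, B/n = 0.5, var+ = (2/3)*1 + 0.5 -> rhat = sqrt(7/6)
        rhat = gelman_rubin(chains)
        assert rhat.iloc[0] == pytest.approx(np.sqrt(7 / 6), abs=1e-12)

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((3, 10_000))
        assert abs(gelman_rubin(chains).iloc[0] - 1.0) < 0.01

    def test_separated_chains_diverge(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((2, 500)) + np.array([[0.0], [50.0]])
        assert gelman_rubin(chains).iloc[0] > 10

    def test_zero_within_variance_undefined(self):
        chains = np.ones((2, 10))
        assert np.isnan(gelman_rubin(chains).iloc[0])


class TestSummaries:
    @staticmethod
    def from_array(arr, names):
        return gb.PosteriorSamples(draws=arr, param_names=names, z=None,
                                   config=SamplerConfig(iterations=5, thin=1,
                                                        burn_in=0),
                                   seed=0)

    def test_constant_chain(self):
        arr = np.full((2, 50, 1), 0.7)
        s = gb.summarize_posterior(self.from_array(arr, ["x"]))
        assert s.loc["x", "mean"] == pytest.approx(0.7)
        assert s.loc["x", "q2.5"] == pytest.approx(0.7)
        assert s.loc["x", "q97.5"] == pytest.approx(0.7)

    def test_linear_interpolation_quantile_rule(self):
        arr = np.arange(1.0, 101.0).reshape(1, 100, 1)
        s = gb.summarize_posterior(self.from_array(arr, ["x"]))
        assert s.loc["x", "q2.5"] == pytest.approx(3.475)
        assert s.loc["x", "q97.5"] == pytest.approx(97.525)

    def test_symmetric_draws_mean_near_median(self):
        rng = np.random.default_rng(2)
        arr = rng.standard_normal((2, 5000, 1))
        s = gb.summarize_posterior(self.from_array(arr, ["x"]))
        assert abs(s.loc["x", "mean"] - np.median(arr)) < 0.05


class TestSupportClassification:
    @staticmethod
    def summary_from_intervals(rows):
        idx, data = [], []
        for name, mean, lo, hi in rows:
            idx.append(name)
            data.append({"mean": mean, "sd": 1.0, "q2.5": lo, "q97.5": hi})
        return pd.DataFrame(data, index=idx)

    def test_interval_sign_rules(self):
        summary = self.summary_from_intervals([
            ("beta_mid[a]", 0.5, 0.2, 0.9),     # strong positive
            ("beta_can[a]", 0.1, -0.1, 0.4),    # weak
            ("beta_burn[a]", -0.3, -0.5, 0.0),  # boundary -> weak
        ])
        cls = gb.classify_support(summary).set_index("slot")
        assert cls.loc["beta_mid", "strong"]
        assert cls.loc["beta_mid", "direction"] == "positive"
        assert not cls.loc["beta_can", "strong"]
        assert not cls.loc["beta_burn", "strong"]  # endpoint at 0 overlaps

    def test_count_table_all_strong_positive(self):
        rows = []
        for k in range(4):
            rows += [(f"beta_mid[s{k}]", 1.0, 0.5, 1.5),
                     (f"beta_can[s{k}]", 1.0, 0.5, 1.5)]
        cls = gb.classify_support(self.summary_from_intervals(rows))
        table = gb.count_support_table(cls)
        for cov in ("midstory_density", "canopy_density", "either", "both"):
            assert table.loc[cov, "n_positive"] == 4
            assert table.loc[cov, "n_positive_strong"] == 4
            assert table.loc[cov, "n_negative"] == 0

    def test_counts_partition_species(self):
        rng = np.random.default_rng(3)
        rows = []
        K = 17
        for k in range(K):
            for slot in ("beta_mid", "beta_can"):
                m = rng.normal()
                w = rng.random()
                rows.append((f"{slot}[s{k}]", m, m - w, m + w))
        cls = gb.classify_support(self.summary_from_intervals(rows))
        table = gb.count_support_table(cls)
        for cov in ("midstory_density", "canopy_density"):
            assert table.loc[cov, "n_negative"] + table.loc[cov, "n_positive"] == K

    def test_recount_matches_independent_tally(self):
        rng = np.random.default_rng(4)
        rows = []
        K = 11
        for k in range(K):
            for slot in ("beta_mid", "beta_can"):
                m = rng.normal()
                w = rng.random()
                rows.append((f"{slot}[s{k}]", m, m - w, m + w))
        cls = gb.classify_support(self.summary_from_intervals(rows))
        table = gb.count_support_table(cls)
        # independent tally straight from the interval rows
        by_species = {}
        for name, m, lo, hi in rows:
            slot, label = name[:-1].split("[")
            by_species.setdefault(label, {})[slot] = (m, lo > 0 or hi < 0)
        neg_mid = sum(v["beta_mid"][0] < 0 for v in by_species.values())
        strong_neg_either = sum(
            any(m < 0 and s for m, s in v.values()) for v in by_species.values())
        assert table.loc["midstory_density", "n_negative"] == neg_mid
        assert table.loc["either", "n_negative_strong"] == strong_neg_either


class TestSampler:
    def test_seed_determinism(self):
        params, y, design = gb.simulate_community_dataset(
            gb.default_community_hyper(), 4, 30, 3, seed=1)
        cfg = SamplerConfig(chains=2, iterations=200, burn_in=100, thin=2)
        a = gb.sample_posterior(y, design, cfg, seed=5)
        b = gb.sample_posterior(y, design, cfg, seed=5)
        assert np.array_equal(a.draws, b.draws)
        assert np.array_equal(a.z, b.z)

    def test_z_fixed_at_one_where_detected(self, tiny_fit):
        _, y, _, post = tiny_fit
        detected = y.detection_counts() > 0
        assert (post.z[:, :, detected].astype(bool)).all()

    def test_retained_draw_count_and_shapes(self, tiny_fit):
        _, y, _, post = tiny_fit
        assert post.draws.shape[:2] == (3, 3000 // 5)
        assert post.z.shape == (3, 600, y.M, y.K)

    def test_rhat_below_1_1_on_default_synthetic_fit(self, tiny_fit):
        _, _, _, post = tiny_fit
        hyp = [n for n in post.param_names if n.startswith(("mu_", "sd_"))]
        assert gb.gelman_rubin(post)[hyp].max() < 1.1

    def test_burned_community_mean_sign_recovered(self, tiny_fit):
        # the generating community mean for the burned effect is negative
        _, _, _, post = tiny_fit
        assert gb.summarize_posterior(post).loc["mu_beta_burn", "mean"] < 0
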