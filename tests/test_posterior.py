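"""Conjugate updating, odds-ratio posteriors, and the convinced count."""

import numpy as np
import pytest

from vetelicit import (
    BeliefPair,
    BetaParams,
    OrSummary,
    TrialDataset,
    TrialDesign,
    convinced_below,
    odds_ratio,
    odds_ratio_posterior,
    trial_size_sweep,
    update,
)


class TestUpdate:
    def test_uniform_prior_conjugacy(self):
        pair = BeliefPair(BetaParams(1, 1), BetaParams(1, 1))
        post = update(pair, TrialDataset(n1=10, x1=7, n3=3, x3=0))
        assert (post.theta1_post.alpha, post.theta1_post.beta) == (8, 4)

    def test_paper_style_arithmetic(self):
        pair = BeliefPair(BetaParams(2, 3), BetaParams(1, 4))
        post = update(pair, TrialDataset(n1=50, x1=25, n3=25, x3=0))
        assert (post.theta1_post.alpha, post.theta1_post.beta) == (27, 28)
        assert (post.theta3_post.alpha, post.theta3_post.beta) == (1, 29)

    def test_no_data_identity(self):
        pair = BeliefPair(BetaParams(2.5, 3.5), BetaParams(1.5, 9.0))
        post = update(pair, TrialDataset(n1=0, x1=0, n3=0, x3=0))
        assert post.theta1_post == pair.theta1_prior
        assert post.theta3_post == pair.theta3_prior

    def test_invalid_dataset_rejected(self):
        with pytest.raises(ValueError):
            TrialDataset(n1=10, x1=7, n3=4, x3=0)  # n3 != n1 - x1
        with pytest.raises(ValueError):
            TrialDataset(n1=10, x1=11, n3=-1, x3=0)


class TestOddsRatioPosterior:
    def test_point_mass_theta3_gives_unit_or(self):
        post_pair = update(
            BeliefPair(BetaParams(500, 500), BetaParams(1, 10**6)),
            TrialDataset(0, 0, 0, 0),
        )
        s = odds_ratio_posterior(post_pair, n_draws=30_000, seed=0)
        assert s.median == pytest.approx(1.0, abs=1e-3)

    def test_near_point_masses_give_closed_form_or(self):
        """theta1 ~ 0.5, theta3 ~ 0.2 => theta2 = 0.6 => OR = 1.5."""
        from vetelicit import PosteriorPair

        post = PosteriorPair(
            BetaParams(5e5, 5e5),  # theta1 concentrated at 0.5
            BetaParams(2e5, 8e5),  # theta3 concentrated at 0.2
        )
        s = odds_ratio_posterior(post, n_draws=30_000, seed=1)
        assert s.median == pytest.approx(1.5, abs=0.01)

    def test_deterministic_under_seed(self):
        from vetelicit import PosteriorPair

        post = PosteriorPair(BetaParams(3, 3), BetaParams(2, 8))
        assert odds_ratio_posterior(post, seed=7) == odds_ratio_posterior(post, seed=7)

    def test_all_draws_at_least_one(self):
        """theta2 >= theta1 forces OR >= 1 for every draw."""
        from vetelicit import PosteriorPair

        post = PosteriorPair(BetaParams(2, 5), BetaParams(1.2, 30))
        _, draws = odds_ratio_posterior(post, n_draws=50_000, seed=3, return_draws=True)
        assert np.all(draws >= 1 - 1e-12)

    def test_upper95_shrinks_to_one_with_null_data(self):
        """With x3 = 0 and growing trials the OR interval collapses onto 1."""
        pair = BeliefPair(BetaParams(3, 3), BetaParams(2, 4))
        uppers = []
        for n1 in (100, 1000, 10_000):
            x1 = n1 // 2
            post = update(pair, TrialDataset(n1, x1, n1 - x1, 0))
            uppers.append(odds_ratio_posterior(post, seed=5).upper95)
        assert uppers[0] > uppers[1] > uppers[2]
        assert uppers[2] == pytest.approx(1.0, abs=0.01)

    def test_too_few_draws_rejected(self):
        from vetelicit import PosteriorPair

        with pytest.raises(ValueError):
            odds_ratio_posterior(PosteriorPair(BetaParams(2, 2), BetaParams(2, 2)), n_draws=10)


class TestConvincedBelow:
    def test_strictly_below(self):
        s = OrSummary(lower95=0.9, median=1.1, upper95=1.49, n_draws=1000, seed=0)
        assert convinced_below(s, 1.5)

    def test_boundary_not_convinced(self):
        s = OrSummary(lower95=0.9, median=1.1, upper95=1.5, n_draws=1000, seed=0)
        assert not convinced_below(s, 1.5)

    def test_odds_ratio_threshold_anchor(self):
        """A 10-point cure improvement from 0.5 is exactly the OR 1.5 bound."""
        assert odds_ratio(0.5, 0.6) == pytest.approx(1.5, abs=1e-12)


class TestTrialSizeSweep:
    def test_uniform_priors_all_convinced_at_500(self, ):
        """Flat priors plus a 500-per-arm null trial convince everyone: the
        theta3 posterior Beta(1, 1+n3) concentrates near 0."""
        pairs = [
            BeliefPair(BetaParams(1, 1), BetaParams(1, 1), expert_id=str(i))
            for i in range(6)
        ]
        res = trial_size_sweep(
            pairs, sizes=[500], design=TrialDesign(n_per_arm=500), n_draws=5000, seed=0
        )
        at500 = res.counts.set_index("size_per_arm").loc[500, "n_convinced"]
        assert at500 == len(pairs)

    def test_size_zero_row_is_prior_only(self):
        """The size-0 row must reproduce the prior-only odds-ratio analysis
        exactly (recomputable from the recorded per-row seed)."""
        from vetelicit import PosteriorPair

        pairs = [BeliefPair(BetaParams(2, 3), BetaParams(2, 6), expert_id="a")]
        res = trial_size_sweep(
            pairs, sizes=[30], design=TrialDesign(n_per_arm=30), n_draws=5000, seed=4
        )
        row = res.table[res.table.size_per_arm == 0].iloc[0]
        prior_only = odds_ratio_posterior(
            PosteriorPair(pairs[0].theta1_prior, pairs[0].theta3_prior),
            n_draws=5000,
            seed=int(row["seed"]),
        )
        assert row["upper95"] == prior_only.upper95
        assert row["median"] == prior_only.median

    def test_table_shape_and_totals(self):
        pairs = [
            BeliefPair(BetaParams(2, 2), BetaParams(2, 8), expert_id=str(i))
            for i in range(3)
        ]
        res = trial_size_sweep(
            pairs, sizes=[30, 50], design=TrialDesign(n_per_arm=50), n_draws=2000, seed=0
        )
        assert set(res.table.size_per_arm) == {0, 30, 50}
        assert len(res.table) == 9
        assert list(res.counts.size_total) == [0, 60, 100]


class TestGridPosteriorOracle:
    def test_conjugate_update_matches_grid_oracle(self):
        """Brute-force grid posterior (prior x likelihood, renormalised)
        moment-matches the closed-form beta posterior."""
        from scipy import integrate

        rng = np.random.default_rng(11)
        theta = np.linspace(1e-9, 1 - 1e-9, 40_001)
        for _ in range(10):
            a, b = rng.uniform(1.0, 8.0, size=2)
            n = int(rng.integers(5, 51))
            x = int(rng.integers(1, n))
            logpost = (a + x - 1) * np.log(theta) + (b + n - x - 1) * np.log1p(-theta)
            w = np.exp(logpost - logpost.max())
            z = integrate.simpson(w, x=theta)
            mean = integrate.simpson(w * theta, x=theta) / z
            var = integrate.simpson(w * theta**2, x=theta) / z - mean**2
            post = BetaParams(a + x, b + n - x)
            assert mean == pytest.approx(post.mean, abs=1e-6)
            assert var == pytest.approx(post.var, abs=1e-6)
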