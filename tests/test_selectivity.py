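"""Feeding selectivity: FS arithmetic, the score model, MCMC vs grid oracle."""

import math

import numpy as np
import pandas as pd
import pytest

from wheatlocust import selectivity as sel
from wheatlocust import synthetic_data as syn


class TestConsumedBiomass:
    def test_arithmetic(self):
        assert sel.consumed_dry_biomass(1.6964, 0.8482, 200.0) == pytest.approx(
            0.8482 / 200.0
        )

    def test_uneaten_equals_control(self):
        assert sel.consumed_dry_biomass(1.0, 1.0, 200.0) == 0.0

    def test_negative_difference_clamped(self):
        assert sel.consumed_dry_biomass(1.0, 1.2, 200.0) == 0.0

    def test_nonpositive_sla_rejected(self):
        with pytest.raises(ValueError):
            sel.consumed_dry_biomass(1.0, 0.5, 0.0)


class TestFeedingSelectivity:
    @pytest.mark.parametrize(
        "mw,mm,expected", [(0.5, 0.5, (0.5, 0.5)), (3.0, 1.0, (0.75, 0.25))]
    )
    def test_proportions(self, mw, mm, expected):
        assert sel.feeding_selectivity(mw, mm) == pytest.approx(expected)

    def test_degenerate_trial_flagged(self):
        fsw, fsm = sel.feeding_selectivity(0.0, 0.0)
        assert math.isnan(fsw) and math.isnan(fsm)

    def test_fs_table_proportions_sum_to_one(self, study_config):
        data = syn.simulate_dataset(study_config)
        fs = sel.compute_fs_table(data["choice_trials"])
        informative = fs[fs["informative"]]
        assert np.allclose(informative["fs_wild"] + informative["fs_modern"], 1.0)


class TestPairedT:
    def test_all_zero_differences(self):
        res = sel.paired_t_test(np.full(10, 0.5))
        assert res.t == 0.0 and res.p == 1.0

    def test_closed_form_on_four_numbers(self):
        # differences {0.2, 0.1, 0.3, 0.2}: t = mean/(sd/sqrt(n))
        diffs = np.array([0.2, 0.1, 0.3, 0.2])
        fs = (diffs + 1.0) / 2.0
        res = sel.paired_t_test(fs)
        expected_t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(4))
        assert res.t == pytest.approx(expected_t)
        assert res.df == 3
        assert res.mean_difference_pct == pytest.approx(100 * diffs.mean())

    def test_needs_two_trials(self):
        with pytest.raises(ValueError):
            sel.paired_t_test(np.array([0.7]))


class TestChoiceProbability:
    def test_symmetry(self):
        assert sel.choice_probability(0.2, 0.2) == pytest.approx(0.5)

    def test_printed_equation(self):
        assert sel.choice_probability(0.2, -0.1) == pytest.approx(0.8)

    def test_clamped_at_extremes(self):
        assert sel.choice_probability(0.5, -0.5) == pytest.approx(1 - 1e-6)

    def test_out_of_support_rejected(self):
        with pytest.raises(ValueError, match="support"):
            sel.choice_probability(0.6, 0.0)


class TestLogPosterior:
    def test_no_trials_maximized_at_zero(self):
        pairs = sel.PairStats(
            ["a", "b"],
            np.array([0], dtype=np.int64),
            np.array([1], dtype=np.int64),
            np.array([0.0]),
            np.array([0.0]),
        )
        at_zero = sel.log_posterior(np.zeros(2), pairs)
        for other in ([0.2, 0.0], [-0.3, 0.1], [0.45, -0.45]):
            assert at_zero > sel.log_posterior(np.array(other), pairs)

    def test_single_trial_direct_evaluation(self, two_accession_fs):
        one = two_accession_fs.iloc[:1]
        pairs = sel.pair_statistics(one)
        # likelihood log(0.5) + two Beta(2,2) prior terms at 0: 2*log(0.25)
        expected = math.log(0.5) + 2 * (math.log(0.5) + math.log(0.5))
        assert sel.log_posterior(np.zeros(2), pairs) == pytest.approx(expected)

    def test_boundary_is_minus_infinity(self, two_accession_fs):
        pairs = sel.pair_statistics(two_accession_fs)
        assert sel.log_posterior(np.array([0.5, 0.0]), pairs) == -math.inf

    def test_flipping_outcomes_negates_posterior_mode(self, two_accession_fs):
        pairs = sel.pair_statistics(two_accession_fs)
        flipped = two_accession_fs.assign(wild_chosen=1.0 - two_accession_fs["wild_chosen"])
        pairs_f = sel.pair_statistics(flipped)
        grid = np.linspace(-0.45, 0.45, 61)
        surface = np.array(
            [[sel.log_posterior(np.array([a, b]), pairs) for b in grid] for a in grid]
        )
        surface_f = np.array(
            [[sel.log_posterior(np.array([a, b]), pairs_f) for b in grid] for a in grid]
        )
        ia, ib = np.unravel_index(np.argmax(surface), surface.shape)
        ja, jb = np.unravel_index(np.argmax(surface_f), surface_f.shape)
        assert grid[ia] - grid[ib] == pytest.approx(-(grid[ja] - grid[jb]), abs=1e-9)


class TestMcmc:
    def test_retained_draw_count(self, two_accession_fs):
        pairs = sel.pair_statistics(two_accession_fs)
        s = sel.run_mcmc(pairs, total_steps=2000, burn_in=200, thinning=10, chains=2, seed=0)
        assert s.draws.shape == (2, 180, 2)

    def test_draws_inside_support(self, two_accession_fs):
        pairs = sel.pair_statistics(two_accession_fs)
        s = sel.run_mcmc(pairs, total_steps=3000, burn_in=500, thinning=5, chains=1, seed=0)
        assert np.all(np.abs(s.draws) < 0.5)

    def test_deterministic_given_seed(self, two_accession_fs):
        pairs = sel.pair_statistics(two_accession_fs)
        a = sel.run_mcmc(pairs, total_steps=3000, burn_in=500, thinning=5, seed=3)
        b = sel.run_mcmc(pairs, total_steps=3000, burn_in=500, thinning=5, seed=3)
        assert np.array_equal(a.draws, b.draws)

    def test_prior_only_marginals_match_shifted_beta(self):
        # Beta(2,2) shifted: mean 0, variance 1/20
        pairs = sel.PairStats(
            ["a", "b"],
            np.array([0], dtype=np.int64),
            np.array([1], dtype=np.int64),
            np.array([0.0]),
            np.array([0.0]),
        )
        s = sel.run_mcmc(pairs, seed=1)
        pooled = s.pooled
        assert np.abs(pooled.mean(axis=0)).max() < 0.01
        assert np.abs(pooled.var(axis=0) - 0.05).max() < 0.004

    def test_acceptance_rate_in_tuned_band(self, two_accession_fs):
        pairs = sel.pair_statistics(two_accession_fs)
        s = sel.run_mcmc(pairs, seed=2)
        assert np.all(s.acceptance_rate > 0.2) and np.all(s.acceptance_rate < 0.5)

    def test_invalid_proposal_sd(self, two_accession_fs):
        pairs = sel.pair_statistics(two_accession_fs)
        with pytest.raises(ValueError):
            sel.run_mcmc(pairs, proposal_sd=0.0)

    def test_label_symmetry(self, three_accession_fs):
        """Swapping the two roles in every trial negates every BS difference."""
        pairs = sel.pair_statistics(three_accession_fs)
        swapped = three_accession_fs.rename(
            columns={"wild_accession": "modern_accession",
                     "modern_accession": "wild_accession"}
        )
        pairs_s = sel.pair_statistics(swapped)
        a = sel.run_mcmc(pairs, seed=4).pooled.mean(axis=0)
        b = sel.run_mcmc(pairs_s, seed=4).pooled.mean(axis=0)
        # same accession ordering in both: means negate within MC error
        assert np.allclose(a, -b, atol=0.01)


class TestPosteriorSummary:
    def test_symmetric_sample_median_zero(self):
        chain = np.array([[-0.2], [0.2], [-0.2], [0.2]])
        draws = np.stack([chain, chain])
        s = sel.PosteriorSamples(["x"], draws, np.ones((2, 1)), 0, 8, 0, 1)
        out = sel.posterior_summary(s)
        assert out["bs_median"].iloc[0] == 0.0

    def test_identical_chains_rhat_one(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(0, 0.1, size=(1000, 1))
        draws = np.stack([chain, chain])
        s = sel.PosteriorSamples(["x"], draws, np.ones((2, 1)), 0, 1000, 0, 1)
        out = sel.posterior_summary(s)
        assert out["rhat"].iloc[0] == pytest.approx(1.0, abs=2e-3)

    def test_single_chain_rhat_omitted(self, two_accession_fs):
        pairs = sel.pair_statistics(two_accession_fs)
        s = sel.run_mcmc(pairs, total_steps=2000, burn_in=200, thinning=10, chains=1, seed=0)
        out = sel.posterior_summary(s)
        assert out["rhat"].isna().all()

    def test_recovery_rank_correlation(self):
        from scipy import stats as st

        cfg = syn.SimulationConfig(trials_per_pair=20, seed=12)
        bs_true = syn.draw_bs_true(cfg)
        trials = syn.simulate_choice_trials(cfg, bs_true)
        fs = trials.rename(columns={"fs_wild_true": "fs_wild"})
        pairs = sel.pair_statistics(fs, accessions=cfg.accession_ids)
        s = sel.run_mcmc(pairs, total_steps=20_000, burn_in=4000, thinning=8, chains=1, seed=13)
        med = np.median(s.pooled, axis=0)
        truth = np.array([bs_true[a] for a in pairs.accessions])
        assert st.spearmanr(med, truth).statistic > 0.9


class TestGridOracle:
    def test_prior_only_mean_zero(self):
        pairs = sel.PairStats(
            ["a", "b"],
            np.array([0], dtype=np.int64),
            np.array([1], dtype=np.int64),
            np.array([0.0]),
            np.array([0.0]),
        )
        out = sel.grid_oracle_posterior(pairs, 101)
        assert np.allclose(out["bs_mean"], 0.0, atol=1e-12)

    def test_single_win_orders_the_scores(self):
        pairs = sel.PairStats(
            ["M", "W"],
            np.array([1], dtype=np.int64),
            np.array([0], dtype=np.int64),
            np.array([1.0]),
            np.array([1.0]),
        )
        out = sel.grid_oracle_posterior(pairs, 101).set_index("accession_id")
        assert out.loc["W", "bs_mean"] > 0 > out.loc["M", "bs_mean"]

    def test_refinement_consistency(self, two_accession_fs):
        pairs = sel.pair_statistics(two_accession_fs)
        coarse = sel.grid_oracle_posterior(pairs, 100)["bs_mean"].to_numpy()
        fine = sel.grid_oracle_posterior(pairs, 200)["bs_mean"].to_numpy()
        assert np.abs(coarse - fine).max() < 1e-3

    def test_more_than_three_accessions_rejected(self):
        pairs = sel.PairStats(
            list("abcd"),
            np.array([0], dtype=np.int64),
            np.array([1], dtype=np.int64),
            np.array([1.0]),
            np.array([1.0]),
        )
        with pytest.raises(ValueError, match="run_mcmc"):
            sel.grid_oracle_posterior(pairs)
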