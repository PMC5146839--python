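import math

import numpy as np
import pytest
from scipy import integrate
from scipy.special import expit, logit
from scipy.stats import binom, halfcauchy, norm

from gonadrisk.data_ingest import CountTable, SexClass
from gonadrisk.hier_model import (
    GridBracketError,
    GridSpec,
    ModelConfig,
    ModelState,
    gelman_rubin,
    grid_posterior_oracle,
    log_likelihood,
    log_prior,
    sample_posterior,
)


class TestModelConfig:
    def test_default_protocol_retains_3000_draws(self):
        config = ModelConfig()
        assert config.n_kept_per_chain == 750
        assert config.n_kept == 3000

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_warmup": 20_000},  # warm-up not shorter than the chain
            {"thin": 0},
            {"n_total": 20_001},  # post-warm-up span not a thin multiple
            {"prior_scale": 0.0},
            {"n_chains": 0},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**kwargs)


class TestLogLikelihood:
    def test_symmetric_point(self):
        table = CountTable("T", {SexClass.F: 5}, {SexClass.F: 10})
        state = ModelState({SexClass.F: 0.0}, 1.0)
        expected = 10 * math.log(0.5) + math.log(math.comb(10, 5))
        assert log_likelihood(table, state) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_limit_is_zero(self):
        # p -> 0 with zero cases: the only outcome, log-probability -> 0
        table = CountTable("T", {SexClass.F: 0}, {SexClass.F: 100})
        state = ModelState({SexClass.F: -1000.0}, 1.0)
        assert log_likelihood(table, state) == pytest.approx(0.0, abs=1e-12)
        # and it is finite/overflow-safe at the other extreme
        assert np.isfinite(log_likelihood(table, ModelState({SexClass.F: 1000.0}, 1.0)))

    def test_matches_independent_binomial_pmf(self, cohort_tables):
        table = cohort_tables["HYPO"]
        effects = {c: float(logit(table.cases[c] / table.totals[c])) for c in table.classes}
        state = ModelState(effects, 2.0)
        expected = sum(
            binom.logpmf(table.cases[c], table.totals[c], expit(effects[c]))
            for c in table.classes
        )
        assert log_likelihood(table, state) == pytest.approx(expected, rel=1e-10)

    def test_missing_effect_rejected(self, toy_two_class):
        with pytest.raises(ValueError):
            log_likelihood(toy_two_class, ModelState({SexClass.F: 0.0}, 1.0))


class TestLogPrior:
    def test_half_cauchy_at_scale(self):
        # single effect: the exchangeable part is flat, only sigma contributes
        state = ModelState({SexClass.F: 0.3}, 25.0)
        assert log_prior(state, 25.0) == pytest.approx(math.log(1.0 / (25.0 * math.pi)))

    def test_nonpositive_sigma_has_zero_mass(self):
        state = ModelState({c: 0.0 for c in SexClass}, -1.0)
        assert log_prior(state, 25.0) == -math.inf

    @pytest.mark.parametrize("sigma", [0.3, 1.7, 40.0])
    def test_matches_quadrature_over_common_level(self, sigma):
        """The exchangeable prior equals the flat-level mixture
        integral(prod_i N(eta_i | mu, sigma^2) d mu) x half-Cauchy(sigma)."""
        rng = np.random.default_rng(5)
        eta = rng.normal(-2.0, 2.0, size=4)
        state = ModelState(dict(zip((SexClass.F, SexClass.NF, SexClass.M, SexClass.NM), eta)), sigma)
        center = float(eta.mean())
        peak = norm.logpdf(eta, center, sigma).sum()  # factor out the maximum
        mixture, _ = integrate.quad(
            lambda mu: np.exp(norm.logpdf(eta, mu, sigma).sum() - peak),
            center - 30 * sigma, center + 30 * sigma,
        )
        expected = peak + math.log(mixture) + halfcauchy.logpdf(sigma, scale=25.0)
        assert log_prior(state, 25.0) == pytest.approx(expected, rel=1e-9)


class TestSampler:
    def test_bit_identical_under_same_seed(self, toy_two_class, fast_config):
        a = sample_posterior(toy_two_class, fast_config)
        b = sample_posterior(toy_two_class, fast_config)
        assert np.array_equal(a.array, b.array)

    def test_seed_changes_draws(self, toy_two_class, fast_config):
        import dataclasses

        a = sample_posterior(toy_two_class, fast_config)
        b = sample_posterior(toy_two_class, dataclasses.replace(fast_config, master_seed=12))
        assert not np.array_equal(a.array, b.array)

    def test_draw_bookkeeping(self, toy_two_class, fast_config):
        draws = sample_posterior(toy_two_class, fast_config)
        assert draws.array.shape == (2, 600, 3)
        assert draws.parameters == ("sex_F", "sex_NF", "sigma")
        assert (draws.sigma > 0).all()
        frame = draws.to_frame()
        assert len(frame) == 2 * 600 * 3
        assert set(frame["parameter"]) == set(draws.parameters)

    def test_symmetric_truth_recovered(self):
        table = CountTable(
            "SYM",
            {c: 5000 for c in SexClass},
            {c: 10_000 for c in SexClass},
        )
        config = ModelConfig(n_chains=2, n_total=3000, n_warmup=1000, thin=2, master_seed=4)
        draws = sample_posterior(table, config)
        for c in table.classes:
            assert float(draws.prob(c).mean()) == pytest.approx(0.5, abs=0.02)

    def test_shrinkage_pulls_toward_pooled_level(self, cohort_fits):
        """Posterior-mean log-odds sit between the empirical class logit and
        the pooled disease logit (hierarchical shrinkage toward the common
        level), within Monte-Carlo slack."""
        for disease, fit in cohort_fits.items():
            t = fit.table
            pooled = logit(t.n_cases / t.n_total)
            for c in t.classes:
                raw = logit(t.cases[c] / t.totals[c])
                post = float(fit.draws.sex_effect(c).mean())
                lo, hi = sorted((raw, pooled))
                assert lo - 0.05 <= post <= hi + 0.05, (disease, c.value)


class TestGelmanRubin:
    def test_identical_chains_attain_minimum(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=500)
        psrf = gelman_rubin(np.stack([chain, chain]))
        # B = 0, so PSRF = sqrt((n-1)/n), the smallest attainable value
        assert psrf == pytest.approx(math.sqrt(499 / 500), abs=1e-12)

    def test_separated_chains_match_hand_formula(self):
        rng = np.random.default_rng(1)
        n = 1000
        chains = np.stack([rng.normal(0.0, 1.0, n), rng.normal(10.0, 1.0, n)])
        # hand evaluation of the between/within variance formula
        m1, m2 = chains[0].mean(), chains[1].mean()
        grand = (m1 + m2) / 2.0
        b = n * ((m1 - grand) ** 2 + (m2 - grand) ** 2) / (2 - 1)
        w = (chains[0].var(ddof=1) + chains[1].var(ddof=1)) / 2.0
        expected = math.sqrt(((n - 1) / n * w + b / n) / w)
        assert gelman_rubin(chains) == pytest.approx(expected, rel=1e-12)
        assert expected > 5  # far from convergence, as constructed

    def test_single_chain_rejected(self):
        with pytest.raises(ValueError):
            gelman_rubin(np.zeros((1, 100)))

    def test_named_parameter_lookup(self, toy_two_class, fast_config):
        draws = sample_posterior(toy_two_class, fast_config)
        assert gelman_rubin(draws, "sigma") == pytest.approx(
            gelman_rubin(draws.sigma), rel=1e-12
        )
        with pytest.raises(KeyError):
            draws.parameter("nope")
        with pytest.raises(ValueError):
            gelman_rubin(draws)


class TestGridOracle:
    def test_two_class_refinement_stable(self, toy_two_class):
        coarse = grid_posterior_oracle(toy_two_class)
        fine = grid_posterior_oracle(
            toy_two_class, grid=GridSpec(n_eta=481, n_sigma=361)
        )
        for c in toy_two_class.classes:
            assert coarse.p_mean[c] == pytest.approx(fine.p_mean[c], abs=1e-4)
        assert coarse.boundary_mass < 1e-6

    def test_exchangeability_exact(self, toy_two_class):
        res = grid_posterior_oracle(toy_two_class)
        swapped = grid_posterior_oracle(
            CountTable("T2", {SexClass.F: 5, SexClass.NF: 3},
                       {SexClass.F: 25, SexClass.NF: 20})
        )
        assert swapped.p_mean[SexClass.F] == pytest.approx(
            res.p_mean[SexClass.NF], abs=1e-12
        )
        assert swapped.p_mean[SexClass.NF] == pytest.approx(
            res.p_mean[SexClass.F], abs=1e-12
        )

    def test_symmetric_table_has_identical_marginals(self):
        table = CountTable(
            "SYM", {SexClass.F: 4, SexClass.NF: 4}, {SexClass.F: 30, SexClass.NF: 30}
        )
        res = grid_posterior_oracle(table)
        assert res.p_mean[SexClass.F] == pytest.approx(res.p_mean[SexClass.NF], abs=1e-12)
        assert res.p_quantiles[SexClass.F] == pytest.approx(
            res.p_quantiles[SexClass.NF], abs=1e-12
        )

    def test_one_class_flat_prior_mean_is_mle(self):
        # flat prior on a single log-odds is Beta(c, n-c) on p: mean c/n
        table = CountTable("ONE", {SexClass.F: 7}, {SexClass.F: 50})
        res = grid_posterior_oracle(table)
        assert res.p_mean[SexClass.F] == pytest.approx(7 / 50, abs=1e-6)

    def test_undersized_grid_detected(self, toy_two_class):
        with pytest.raises(GridBracketError):
            grid_posterior_oracle(
                toy_two_class,
                grid=GridSpec(n_eta=31, eta_halfwidth_se=0.5, n_sigma=41),
            )

    def test_more_than_two_classes_rejected(self, cohort_tables):
        with pytest.raises(ValueError):
            grid_posterior_oracle(cohort_tables["HYPO"])


class TestLargeCountConsistency:
    def test_posterior_mean_approaches_raw_proportion(self):
        """Scaling counts x10 and x100 shrinks the gap between the posterior
        mean and the raw proportion monotonically (likelihood dominance)."""
        gaps = []
        for scale in (1, 10, 100):
            table = CountTable(
                "S",
                {SexClass.F: 3 * scale, SexClass.NF: 9 * scale},
                {SexClass.F: 60 * scale, SexClass.NF: 90 * scale},
            )
            res = grid_posterior_oracle(table)
            gaps.append(
                max(abs(res.p_mean[c] - table.cases[c] / table.totals[c])
                    for c in table.classes)
            )
        assert gaps[0] > gaps[1] > gaps[2]
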