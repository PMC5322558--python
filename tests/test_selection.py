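"""PRF sampling probabilities, class likelihoods, MCMC, and diagnostics."""

import numpy as np
import pytest

from ucekit import simulate
from ucekit.selection import (
    McmcConfig,
    SfsObservation,
    ascertainment_weight,
    class_marginal_likelihood,
    gelman_psrf,
    prf_sfs_distribution,
    prf_sfs_probability,
    read_sfs_table,
    relative_fixation_rate,
    run_mcmc,
    summarize_posterior,
)


def _obs(label, counts, n=130):
    return [SfsObservation(label, int(i), n) for i in counts]


class TestPrfProbability:
    def test_neutral_n2(self):
        assert prf_sfs_probability(1, 2, 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [2, 5, 10, 25, 50])
    def test_neutral_harmonic_law(self, n):
        H = sum(1.0 / i for i in range(1, n))
        expected = np.array([1.0 / i / H for i in range(1, n)])
        got = prf_sfs_distribution(n, 0.0)
        assert np.abs(got - expected).max() < 1e-8

    @pytest.mark.parametrize("gamma", [-50.0, -20.0, -2.0, 0.0, 2.0])
    def test_normalization(self, gamma):
        for n in (10, 130, 154):
            assert abs(prf_sfs_distribution(n, gamma).sum() - 1.0) < 1e-10

    def test_negative_selection_enriches_singletons(self):
        assert prf_sfs_probability(1, 130, -20.0) > prf_sfs_probability(1, 130, 0.0)

    def test_mean_frequency_monotone_in_gamma(self):
        n = 60
        i = np.arange(1, n)
        means = [
            float(i @ prf_sfs_distribution(n, g)) / n
            for g in (-50, -20, -5, -1, 0, 1, 5)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(means, means[1:]))

    def test_out_of_range_and_guard_errors(self):
        with pytest.raises(ValueError):
            prf_sfs_probability(0, 10, 0.0)
        with pytest.raises(ValueError):
            prf_sfs_probability(10, 10, 0.0)
        with pytest.raises(OverflowError, match="gamma"):
            prf_sfs_distribution(10, -400.0)


class TestClassLikelihood:
    def test_point_mass_limit(self):
        obs = _obs("c", [1, 1, 2, 5, 30], n=60)
        mu = -5.0
        direct = sum(np.log(prf_sfs_probability(o.derived_count, 60, mu)) for o in obs)
        ll = class_marginal_likelihood(obs, mu, 1e-10)
        assert ll == pytest.approx(direct, abs=1e-6)

    def test_neutral_point_mass(self):
        obs = _obs("c", [3], n=40)
        ll = class_marginal_likelihood(obs, 0.0, 1e-8)
        assert ll == pytest.approx(np.log(prf_sfs_probability(3, 40, 0.0)), abs=1e-4)

    @pytest.mark.parametrize("mu,sigma2", [(-3.0, 1.0), (-2.0, 0.5)])
    def test_quadrature_order_stability(self, rng, mu, sigma2):
        obs = _obs("c", rng.integers(1, 129, size=200))
        a = class_marginal_likelihood(obs, mu, sigma2, gh_order=16)
        b = class_marginal_likelihood(obs, mu, sigma2, gh_order=32)
        assert abs(a - b) < 1e-6
        # mid-range wide distributions converge more slowly but stay tight
        c = class_marginal_likelihood(obs, -8.0, 4.0, gh_order=32)
        d = class_marginal_likelihood(obs, -8.0, 4.0, gh_order=64)
        assert abs(c - d) < 1e-4

    def test_truth_beats_shifted_parameters(self, rng):
        wins = 0
        for rep in range(20):
            data, _ = simulate.simulate_sfs(
                [simulate.SfsClassConfig("c", -6.0, 4.0, 500, 130)],
                np.random.default_rng(rep),
            )
            at_truth = class_marginal_likelihood(data["c"], -6.0, 4.0)
            shifted = class_marginal_likelihood(data["c"], 4.0, 4.0)
            wins += at_truth > shifted
        assert wins >= 19

    def test_ascertainment_off_is_exact_identity(self):
        obs = _obs("c", [1, 2, 3, 7], n=50)
        plain = class_marginal_likelihood(obs, -3.0, 2.0)
        asc_off = class_marginal_likelihood(obs, -3.0, 2.0, ascertained=True,
                                            div_intensity=0.0)
        assert plain == asc_off

    def test_empty_observations_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            class_marginal_likelihood([], 0.0, 1.0)


class TestAscertainment:
    def test_neutral_fixation_rate(self):
        assert relative_fixation_rate(0.0) == pytest.approx(1.0)
        assert ascertainment_weight(0.0, 2.0) == pytest.approx(np.exp(-2.0))

    def test_div_zero_disables(self):
        for g in (-10, 0, 3):
            assert ascertainment_weight(g, 0.0) == pytest.approx(1.0)

    def test_deleterious_mutations_favored(self):
        # v(-10) = 20/(e^20 - 1) ~ 4.1e-8, so the weight is near exp(0)
        assert relative_fixation_rate(-10.0) == pytest.approx(20 / (np.e**20 - 1))
        assert ascertainment_weight(-10.0, 2.0) > ascertainment_weight(0.0, 2.0)

    def test_monotone_below_zero(self):
        gs = np.array([-40.0, -20.0, -5.0, -1.0, 0.0])
        w = ascertainment_weight(gs, 2.0)
        assert all(a >= b for a, b in zip(w, w[1:]))


class TestMcmc:
    def _small_run(self, seed=9):
        data, truth = simulate.simulate_sfs(
            [simulate.SfsClassConfig("c", -5.0, 2.0, 400, 130)],
            np.random.default_rng(3),
        )
        cfg = McmcConfig(n_chains=2, n_iters=4000, thin=5, seed=seed)
        return data, truth, run_mcmc(data, cfg)

    def test_same_seed_identical_paths(self):
        data, _, res1 = self._small_run(seed=9)
        _, _, res2 = self._small_run(seed=9)
        assert np.array_equal(res1.samples, res2.samples)
        _, _, res3 = self._small_run(seed=10)
        assert not np.array_equal(res1.samples, res3.samples)

    def test_recovery_small(self):
        data, truth, res = self._small_run()
        summ = summarize_posterior(res)
        c = summ.classes[0]
        assert c.ci_low < truth["c"][0] < c.ci_high
        assert c.ci_low <= c.posterior_mean <= c.ci_high

    def test_acceptance_rates_reasonable(self):
        _, _, res = self._small_run()
        assert ((res.acceptance > 0.05) & (res.acceptance < 0.8)).all()

    def test_empty_data_error(self):
        with pytest.raises(ValueError):
            run_mcmc({}, McmcConfig(n_chains=2, n_iters=100))


class TestPsrf:
    def test_stationary_chains_converged(self, rng):
        chains = rng.multivariate_normal(
            [0, 0], [[1.0, 0.3], [0.3, 1.0]], size=(4, 5000)
        )
        assert gelman_psrf(chains) < 1.05

    def test_shifted_chains_detected(self, rng):
        a = rng.normal(0, 1, size=(1, 2000, 1))
        b = rng.normal(5, 1, size=(1, 2000, 1))
        assert gelman_psrf(np.concatenate([a, b])) > 1.2

    def test_single_chain_error(self, rng):
        with pytest.raises(ValueError, match="two chains"):
            gelman_psrf(rng.normal(size=(1, 100, 2)))

    def test_degenerate_parameter_error(self, rng):
        chains = rng.normal(size=(3, 100, 2))
        chains[:, :, 1] = 7.0
        with pytest.raises(ValueError, match="parameter index 1"):
            gelman_psrf(chains)


class TestSummaries:
    def test_constant_chain_degenerate(self):
        from ucekit.selection import McmcResult

        samples = np.full((2, 60, 2), fill_value=-3.0)
        res = McmcResult(
            class_labels=["c"], samples=samples,
            log_posts=np.zeros((2, 60)), acceptance=np.full((2, 1), 0.3),
            n_obs={"c": 10}, config=McmcConfig(),
        )
        with pytest.raises(ValueError):  # PSRF degenerates on constant chains
            summarize_posterior(res)

    def test_mean_map_close_for_unimodal(self):
        data, _, = None, None
        data, truth = simulate.simulate_sfs(
            [simulate.SfsClassConfig("c", -4.0, 1.0, 600, 130)],
            np.random.default_rng(6),
        )
        res = run_mcmc(data, McmcConfig(n_chains=2, n_iters=6000, thin=5, seed=2))
        summ = summarize_posterior(res)
        c = summ.classes[0]
        width = c.ci_high - c.ci_low
        assert abs(c.posterior_mean - c.map_estimate) < 0.5 * width


class TestIo:
    def test_round_trip_per_snp_and_aggregated(self, tmp_path):
        p1 = tmp_path / "persnp.tsv"
        p1.write_text(
            "site_class\tderived_count\tsample_size\n"
            "UCE\t1\t130\nUCE\t1\t130\nflank\t5\t130\n"
        )
        d1 = read_sfs_table(p1)
        assert len(d1["UCE"]) == 2 and len(d1["flank"]) == 1
        p2 = tmp_path / "agg.tsv"
        p2.write_text(
            "site_class\tderived_count\tsample_size\tcount\nUCE\t1\t130\t2\nflank\t5\t130\t1\n"
        )
        d2 = read_sfs_table(p2)
        assert d1 == d2

    def test_invalid_observation(self):
        with pytest.raises(ValueError):
            SfsObservation("c", 130, 130)
        with pytest.raises(ValueError):
            SfsObservation("c", 0, 130)
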