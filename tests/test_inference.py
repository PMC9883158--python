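"""Diagnostics, summaries and marginal-likelihood machinery."""

import numpy as np
import pytest
from scipy import stats

from phylocoev.inference import (
    ChainSet,
    adaptive_metropolis,
    ess,
    hpdi,
    mad,
    pp_positive,
    rhat,
    savage_dickey_logbf,
    slice_sample_1d,
    stepping_stone,
    summarize,
)


class TestRhat:
    def test_well_mixed_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((4, 10_000))
        assert rhat(chains) < 1.01

    def test_separated_chains_large(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((2, 2000))
        chains[1] += 10
        assert rhat(chains) > 1.5

    def test_trend_detected_by_split(self):
        # a single trending chain split in half has R-hat > 1.05
        x = np.linspace(0, 5, 4000) + np.random.default_rng(2).standard_normal(4000) * 0.3
        assert rhat(x.reshape(2, 2000)) > 1.05

    def test_constant_chains_nan(self):
        with pytest.warns(RuntimeWarning):
            assert np.isnan(rhat(np.ones((2, 100))))

    def test_agrees_with_arviz(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(3)
        chains = np.cumsum(rng.standard_normal((2, 500)), axis=1) * 0.05
        chains += rng.standard_normal((2, 500))
        ours = rhat(chains)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            theirs = float(az.rhat(chains[:, :, None].transpose(0, 1, 2).squeeze(-1)))
        # arviz uses rank-normalised split R-hat; agreement is approximate
        assert ours == pytest.approx(theirs, abs=0.1)

    def test_converges_with_length(self):
        rng = np.random.default_rng(4)
        vals = []
        for n in (200, 2000, 20000):
            x = np.empty((2, n))
            for c in range(2):
                # AR(1) toy sampler, geometrically ergodic
                z = 0.0
                for i in range(n):
                    z = 0.9 * z + rng.standard_normal()
                    x[c, i] = z
            vals.append(abs(rhat(x) - 1))
        assert vals[2] < vals[0] + 0.05 and vals[2] < 0.01


class TestEss:
    def test_iid_near_total(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((2, 5000))
        assert ess(chains) > 5000

    def test_autocorrelated_much_smaller(self):
        rng = np.random.default_rng(1)
        x = np.empty((2, 5000))
        for c in range(2):
            z = 0.0
            for i in range(5000):
                z = 0.95 * z + rng.standard_normal()
                x[c, i] = z
        assert ess(x) < 2000


class TestHpdi:
    def test_normal_quantiles(self):
        draws = np.random.default_rng(0).standard_normal(1_000_000)
        lo, hi = hpdi(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.02)
        assert hi == pytest.approx(1.96, abs=0.02)

    def test_uniform_width(self):
        draws = np.random.default_rng(1).random(200_000)
        lo, hi = hpdi(draws, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)

    def test_degenerate(self):
        assert hpdi(np.full(500, 3.2)) == (3.2, 3.2)

    def test_mass_validation(self):
        with pytest.raises(ValueError):
            hpdi(np.arange(100.0), mass=1.5)

    def test_narrower_than_equal_tailed(self):
        rng = np.random.default_rng(2)
        for draws in (rng.standard_normal(5000), rng.exponential(size=5000), rng.beta(2, 5, 5000)):
            lo, hi = hpdi(draws, 0.9)
            qlo, qhi = np.quantile(draws, [0.05, 0.95])
            assert hi - lo <= qhi - qlo + 1e-12


class TestMadPp:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 2, 3], 1.0), ([5, 5, 5, 5], 0.0), ([1, 1, 2, 2, 4, 6, 9], 1.0)],
    )
    def test_mad_values(self, values, expected):
        assert mad(np.array(values, dtype=float)) == expected

    def test_mad_empty(self):
        with pytest.raises(ValueError):
            mad(np.array([]))

    def test_pp_positive(self):
        rng = np.random.default_rng(0)
        assert pp_positive(rng.standard_normal(200_000)) == pytest.approx(0.5, abs=0.01)
        assert pp_positive(np.abs(rng.standard_normal(100)) + 0.1) == 1.0
        # draws centred 1.88 SDs above zero: the "97% certain" reading
        assert pp_positive(rng.standard_normal(400_000) + 1.88) == pytest.approx(
            stats.norm.cdf(1.88), abs=0.005
        )


class TestSavageDickey:
    def test_posterior_equals_prior_near_zero(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(100_000)
        bf = savage_dickey_logbf(draws, stats.norm.pdf(0))
        assert bf == pytest.approx(0.0, abs=0.2)

    def test_shifted_posterior_strong_evidence(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal(20_000) + 5
        assert savage_dickey_logbf(draws, stats.norm.pdf(0)) > 6

    def test_invariant_to_order(self):
        rng = np.random.default_rng(2)
        draws = rng.standard_normal(5000) + 0.4
        a = savage_dickey_logbf(draws, 0.4)
        b = savage_dickey_logbf(np.sort(draws), 0.4)
        assert a == pytest.approx(b, abs=1e-9)

    def test_needs_enough_draws(self):
        with pytest.raises(ValueError):
            savage_dickey_logbf(np.zeros(10), 1.0)


class TestSamplers:
    def test_adaptive_metropolis_normal_target(self):
        cs = adaptive_metropolis(
            lambda x: -0.5 * float(x @ x), np.zeros(2), n_iter=6000, burn=2000, seed=0
        )
        pooled = cs.draws.reshape(-1, 2)
        assert np.abs(pooled.mean(axis=0)).max() < 0.1
        assert np.abs(pooled.std(axis=0) - 1).max() < 0.1
        assert rhat(cs.get("p0")) < 1.05

    def test_chainset_validation(self):
        with pytest.raises(ValueError):
            ChainSet(np.zeros((2, 10, 3)), names=["a"])

    def test_slice_sampler_targets_normal(self):
        rng = np.random.default_rng(0)
        x = 0.0
        draws = []
        for _ in range(4000):
            x = slice_sample_1d(lambda v: -0.5 * (v - 2) ** 2, x, rng)
            draws.append(x)
        draws = np.array(draws[500:])
        assert draws.mean() == pytest.approx(2.0, abs=0.1)
        assert draws.std() == pytest.approx(1.0, abs=0.1)


class TestSteppingStone:
    def _toy(self, n_stones, n_iter, seed=0):
        # conjugate normal toy: y_i ~ N(mu, 1), mu ~ N(0, 1)
        rng = np.random.default_rng(42)
        y = rng.standard_normal(12) + 0.7
        n = y.size

        def loglik(mu):
            return float(-0.5 * np.sum((y - mu) ** 2) - 0.5 * n * np.log(2 * np.pi))

        def sample(beta, n_it, seed_k):
            # power posterior is conjugate: N(beta*sum(y)/(beta*n+1), 1/(beta*n+1))
            r = np.random.default_rng(seed_k)
            var = 1.0 / (beta * n + 1.0)
            return var * beta * y.sum() + np.sqrt(var) * r.standard_normal(n_it)

        est = stepping_stone(loglik, sample, n_stones=n_stones, n_iter=n_iter, seed=seed)
        # analytic marginal: y ~ N(0, I + 11'), evaluated directly
        cov = np.eye(n) + np.ones((n, n))
        exact = float(stats.multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov))
        return est, exact

    def test_matches_conjugate_marginal(self):
        est, exact = self._toy(20, 4000)
        assert est == pytest.approx(exact, abs=0.1)

    def test_unit_likelihood_gives_zero(self):
        est = stepping_stone(
            lambda x: 0.0,
            lambda beta, n_it, s: np.random.default_rng(s).standard_normal(n_it),
            n_stones=5,
            n_iter=200,
        )
        assert est == pytest.approx(0.0, abs=1e-9)

    def test_discretisation_stability(self):
        reps5 = [self._toy(5, 1500, seed=s)[0] for s in range(4)]
        reps20 = [self._toy(20, 1500, seed=s)[0] for s in range(4)]
        assert np.std(reps20) <= np.std(reps5) + 0.05


def test_summarize_fields():
    rng = np.random.default_rng(0)
    s = summarize(rng.standard_normal((2, 2000)) + 1.0)
    assert s.hpdi_low < s.median < s.hpdi_high
    assert 0.7 < s.pp_positive < 0.95
    assert s.rhat < 1.05
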