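"""Chain statistics and the binary phylogenetic mixed model."""

import numpy as np
import pandas as pd
import pytest

import moltevo as mv
from moltevo.phylo import phylo_correlation
from moltevo.pmm import (
    LOGIT_LINK_VARIANCE,
    PhylogeneticMixedLogit,
    PMMError,
    PMMSettings,
    SeparationError,
    chain_diagnostics,
    geweke_z,
    heritability,
    hpd_interval,
    lag1_autocorrelation,
    pmcmc,
)
from moltevo.simulate import SimulationSpec, simulate_liability_dataset


class TestPmcmc:
    def test_direct_count(self):
        assert pmcmc([1.0, 2.0, 3.0, -1.0]) == pytest.approx(0.5)

    def test_sign_balanced_gives_one(self):
        s = np.concatenate([np.ones(100), -np.ones(100)])
        assert pmcmc(s) == 1.0

    def test_floor_when_one_sign_unobserved(self):
        assert pmcmc(np.ones(950)) == pytest.approx(2.0 / 950)

    def test_invariances(self, rng):
        s = rng.standard_normal(500)
        assert pmcmc(3.7 * s) == pmcmc(s)  # positive rescaling
        assert pmcmc(-s) == pmcmc(s)  # sign flip swaps the two probabilities

    def test_empty_errors(self):
        with pytest.raises(PMMError):
            pmcmc([])


class TestDiagnostics:
    def test_iid_chain_ess_near_n(self, rng):
        d = chain_diagnostics(rng.standard_normal(950))
        assert 850 <= d.ess <= 1050
        assert abs(d.lag1_autocorrelation) < 0.1

    def test_ar1_chain_ess_shrinks(self, rng):
        rho = 0.9
        n = 4000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = rho * x[i - 1] + eps[i]
        d = chain_diagnostics(x)
        assert d.lag1_autocorrelation == pytest.approx(rho, abs=0.05)
        analytic = n * (1 - rho) / (1 + rho)
        assert d.ess < n / 5
        assert d.ess == pytest.approx(analytic, rel=0.6)

    def test_geweke_calibrated_on_iid_chains(self):
        rng = np.random.default_rng(42)
        zs = np.array([geweke_z(rng.standard_normal(1000)) for _ in range(200)])
        frac = np.mean(np.abs(zs) < 1.96)
        assert 0.90 <= frac <= 0.99

    def test_constant_chain_errors(self):
        with pytest.raises(PMMError):
            chain_diagnostics(np.ones(100))


class TestHeritability:
    def test_unit_variance_without_link_term(self):
        out = heritability(np.ones(100), link_variance=0.0)
        assert out["estimate"] == pytest.approx(0.5)

    def test_monotone_in_variance(self, rng):
        lo = heritability(np.full(50, 0.3))["estimate"]
        hi = heritability(np.full(50, 3.0))["estimate"]
        assert lo < hi

    def test_vanishing_variance(self):
        assert heritability(np.full(50, 1e-9))["estimate"] < 1e-8

    def test_nonpositive_rejected(self):
        with pytest.raises(PMMError):
            heritability(np.array([0.5, 0.0, 1.0]))


class TestHpd:
    def test_hpd_narrower_than_quantile_interval_on_skewed(self, rng):
        s = rng.gamma(2.0, 1.0, size=20_000)
        lo, hi = hpd_interval(s)
        qlo, qhi = np.quantile(s, [0.025, 0.975])
        assert hi - lo <= qhi - qlo
        assert np.mean((s >= lo) & (s <= hi)) >= 0.949


class TestSettings:
    def test_retained_draw_count_at_study_schedule(self):
        assert PMMSettings().n_retained == 950

    def test_non_integer_retention_rejected(self):
        with pytest.raises(PMMError):
            PMMSettings(iterations=1000, burn_in=100, thinning=7)


def _sim(n, beta1, sigma2_a, seed, tree_seed=None):
    tree = mv.simulate_yule_tree(n, seed=seed if tree_seed is None else tree_seed)
    spec = SimulationSpec(
        n_species=n, beta={"(Intercept)": 0.0, "x1": beta1}, sigma2_a=sigma2_a, seed=seed
    )
    df, truth = simulate_liability_dataset(tree, spec)
    _, C = phylo_correlation(tree, taxa=list(df.index))
    return df, C, truth


@pytest.fixture(scope="module")
def fitted():
    df, C, truth = _sim(150, 1.5, 1.0, seed=1)
    est = PhylogeneticMixedLogit(
        iterations=9000, burn_in=1000, thinning=10,
        random_state=0, separation_check=False,
    )
    return est.fit(df[["x1"]], df["response"], correlation=C), truth


class TestFit:

    def test_summary_shape_and_invariants(self, fitted):
        est, _ = fitted
        assert list(est.summary_.index) == ["(Intercept)", "x1"]
        s = est.summary_
        assert (s["lci"] <= s["estimate"]).all() and (s["estimate"] <= s["uci"]).all()
        assert ((s["pmcmc"] > 0) & (s["pmcmc"] <= 1)).all()
        assert 0.0 <= est.h2_["estimate"] <= 1.0
        assert est.n_retained_ == 800
        assert est.chain_["beta"].shape == (800, 2)
        assert np.all(est.chain_["sigma2_a"] > 0)

    def test_positive_effect_detected(self, fitted):
        est, _ = fitted
        assert est.summary_.loc["x1", "estimate"] > 0
        assert est.summary_.loc["x1", "pmcmc"] < 0.05

    def test_reproducible_given_seed(self):
        df, C, _ = _sim(30, 0.5, 0.5, seed=2)
        kw = dict(iterations=2000, burn_in=500, thinning=5, random_state=7,
                  separation_check=False)
        a = PhylogeneticMixedLogit(**kw).fit(df[["x1"]], df["response"], correlation=C)
        b = PhylogeneticMixedLogit(**kw).fit(df[["x1"]], df["response"], correlation=C)
        assert np.array_equal(a.chain_["beta"], b.chain_["beta"])

    def test_nonbinary_response_rejected(self):
        df, C, _ = _sim(30, 0.5, 0.5, seed=3)
        est = PhylogeneticMixedLogit(iterations=2000, burn_in=500, thinning=5)
        with pytest.raises(PMMError):
            est.fit(df[["x1"]], np.full(30, 2), correlation=C)

    def test_separation_raises_and_normal_prior_recovers(self):
        rng = np.random.default_rng(0)
        x = np.repeat([1, 2, 3, 4], 10)
        y = (x == 4).astype(int)  # lower levels perfectly predict absence
        X = pd.DataFrame({"migration": x + 0.0})
        est = PhylogeneticMixedLogit(iterations=2000, burn_in=500, thinning=5,
                                     random_state=0)
        with pytest.raises(SeparationError):
            est.fit(X, y)
        est.set_params(fixed_effect_prior="normal")
        est.fit(X, y)  # regularized fit completes
        assert np.isfinite(est.summary_["estimate"]).all()

    def test_matches_nonphylogenetic_oracle_when_variance_pinned(self):
        """With sigma2_a ~ 0 the fit reduces to Bayesian logistic regression
        with a unit-normal latent residual; a 2-D quadrature posterior over
        (intercept, slope) is the independent oracle."""
        from scipy.stats import logistic as logis
        from numpy.polynomial.hermite_e import hermegauss

        rng = np.random.default_rng(5)
        n = 60
        x = rng.standard_normal(n)
        eta = 0.4 + 1.0 * x + rng.standard_normal(n) + rng.logistic(size=n)
        y = (eta > 0).astype(int)
        # oracle: marginal Bernoulli probability via Gauss-Hermite over the
        # normal residual, posterior over a (b0, b1) grid with flat prior
        nodes, weights = hermegauss(40)
        weights = weights / weights.sum()
        b0g = np.linspace(-1.5, 2.5, 81)
        b1g = np.linspace(-1.0, 3.0, 81)
        B0, B1 = np.meshgrid(b0g, b1g, indexing="ij")
        logpost = np.zeros_like(B0)
        for xi, yi in zip(x, y):
            mu = B0 + B1 * xi  # (81,81)
            p1 = np.einsum(
                "k,ijk->ij", weights, logis.cdf(mu[..., None] + nodes[None, None, :])
            )
            logpost += np.log(np.where(yi == 1, p1, 1 - p1))
        post = np.exp(logpost - logpost.max())
        post /= post.sum()
        b0_mean = float((post * B0).sum())
        b1_mean = float((post * B1).sum())
        est = PhylogeneticMixedLogit(
            iterations=42_000, burn_in=2_000, thinning=40,
            fix_phylo_variance=1e-10, random_state=1, separation_check=False,
        )
        est.fit(pd.DataFrame({"x": x}), y)
        assert est.summary_.loc["(Intercept)", "estimate"] == pytest.approx(
            b0_mean, abs=0.15
        )
        assert est.summary_.loc["x", "estimate"] == pytest.approx(b1_mean, abs=0.15)
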