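"""Bayesian phylogenetic mixed model for a binary response.

The model is a latent-liability ("threshold") animal model: for species i,

    eta_i = x_i' beta + a_i + e_i,      a ~ N(0, sigma2_a * C),
    e_i ~ N(0, 1)  (residual variance fixed, not sampled),
    y_i ~ Bernoulli(logit^{-1}(eta_i))   (or y_i = 1{eta_i > 0}, probit),

where C is the phylogenetic correlation matrix.  The phylogenetic variance
carries a parameter-expanded prior: sigma2_a = alpha^2 * v with
alpha ~ N(0, alpha_v) and v inverse-Wishart(V, nu) — at the defaults
(V=1, nu=100, alpha_v=1) v concentrates near one, so the implied prior on
sigma2_a is close to a chi-square with one degree of freedom, a standard
weakly-informative choice for binary responses.  Fixed effects take an
improper flat prior, or independent N(0, 9) when separation handling is
enabled.

The sampler is Metropolis-within-Gibbs: per-site Metropolis on the
liabilities (exact truncated-normal Gibbs under the probit link), and
conjugate Gibbs for the working random effects, fixed effects, expansion
scalar and expanded variance.  Phylogenetic signal is summarized as
heritability h2 = sigma2_a / (sigma2_a + 1 + c), with c the link variance
(pi^2/3 for the logistic link by default; configurable to 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from sklearn.base import BaseEstimator

from .trait_data import detect_separation

__all__ = [
    "PMMSettings",
    "PriorSpec",
    "PMMError",
    "SeparationError",
    "PhylogeneticMixedLogit",
    "fit_binary_pmm",
    "pmcmc",
    "chain_diagnostics",
    "hpd_interval",
    "heritability",
    "ChainDiagnostics",
]

LOGIT_LINK_VARIANCE = np.pi**2 / 3.0


class PMMError(ValueError):
    pass


class SeparationError(PMMError):
    """Separation with a flat fixed-effect prior: the posterior is improper.

    Enable the zero-mean normal prior on the fixed effects
    (``fixed_effect_prior='normal'``) to regularize the fit.
    """


@dataclass(frozen=True)
class PMMSettings:
    iterations: int = 2_000_000
    burn_in: int = 100_000
    thinning: int = 2_000
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.iterations:
            raise PMMError("burn_in must be smaller than iterations")
        if (self.iterations - self.burn_in) % self.thinning:
            raise PMMError(
                "(iterations - burn_in) must be a multiple of the thinning interval"
            )

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass(frozen=True)
class PriorSpec:
    """Variance-component and fixed-effect priors.

    ``v_scale``/``nu`` parameterize the inverse-Wishart on the expanded
    variance; ``alpha_mu``/``alpha_v`` the normal on the expansion scalar.
    ``fixed_effect_prior`` is 'flat' or 'normal' (independent zero-mean,
    variance ``fixed_effect_variance`` per coefficient, intercept included).
    The residual variance is fixed at one and never sampled.
    """

    v_scale: float = 1.0
    nu: float = 100.0
    alpha_mu: float = 0.0
    alpha_v: float = 1.0
    fixed_effect_prior: str = "flat"
    fixed_effect_variance: float = 9.0

    def __post_init__(self):
        if self.fixed_effect_prior not in ("flat", "normal"):
            raise PMMError("fixed_effect_prior must be 'flat' or 'normal'")


@dataclass(frozen=True)
class ChainDiagnostics:
    ess: float
    lag1_autocorrelation: float
    geweke_z: float


# ---------------------------------------------------------------------------
# chain statistics


def pmcmc(samples) -> float:
    """Twice the smaller of the posterior sign probabilities.

    pMCMC = 2 min(P(theta > 0), P(theta < 0)); when one sign is never
    observed the value is floored at 2/n; always capped at 1.
    """
    s = np.asarray(samples, dtype=float)
    if s.size < 2:
        raise PMMError("need at least two samples")
    p_pos = float(np.mean(s > 0))
    p_neg = float(np.mean(s < 0))
    return min(1.0, max(2.0 * min(p_pos, p_neg), 2.0 / s.size))


def _autocovariances(x: np.ndarray, max_lag: int) -> np.ndarray:
    xc = x - x.mean()
    n = x.size
    return np.array([np.dot(xc[: n - k], xc[k:]) / n for k in range(max_lag + 1)])


def _spectral_variance_of_mean(x: np.ndarray) -> float:
    """Variance of the sample mean via the spectral density at zero.

    S(0) is estimated from the initial positive part of the autocovariance
    sequence, truncated at half the series length.
    """
    n = x.size
    gam = _autocovariances(x, max_lag=max(n // 2 - 1, 0))
    s0 = gam[0]
    for g in gam[1:]:
        if g <= 0:
            break
        s0 += 2.0 * g
    return max(s0, 1e-300) / n


def geweke_z(samples, first: float = 0.1, last: float = 0.5) -> float:
    """Geweke convergence z-score: first 10% vs last 50% of the chain.

    |z| < 1.96 is consistent with a stationary chain at the 0.05 level.
    """
    x = np.asarray(samples, dtype=float)
    a = x[: max(int(first * x.size), 2)]
    b = x[-max(int(last * x.size), 2):]
    va = _spectral_variance_of_mean(a)
    vb = _spectral_variance_of_mean(b)
    return float((a.mean() - b.mean()) / np.sqrt(va + vb))


def lag1_autocorrelation(samples) -> float:
    x = np.asarray(samples, dtype=float)
    gam = _autocovariances(x, 1)
    if gam[0] == 0:
        raise PMMError("constant chain: autocorrelation undefined")
    return float(gam[1] / gam[0])


def chain_diagnostics(samples) -> ChainDiagnostics:
    """ESS (autocorrelation-time estimate), lag-1 autocorrelation, Geweke z."""
    x = np.asarray(samples, dtype=float)
    if x.size < 50:
        raise PMMError("need at least 50 samples for diagnostics")
    if np.allclose(x, x[0]):
        raise PMMError("constant chain: ESS undefined")
    ess = float(az.ess(x))
    return ChainDiagnostics(ess, lag1_autocorrelation(x), geweke_z(x))


def hpd_interval(samples, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` of the samples."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    m = max(int(np.ceil(prob * n)), 2)
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def heritability(
    sigma2_a_samples, link_variance: float = LOGIT_LINK_VARIANCE
) -> dict:
    """Posterior summary of h2 = sigma2_a / (sigma2_a + 1 + c).

    The residual variance is the model's fixed 1; ``link_variance`` c is
    pi^2/3 for the logistic link (set 0 to report on the liability scale
    excluding the link)."""
    s = np.asarray(sigma2_a_samples, dtype=float)
    if np.any(s <= 0):
        raise PMMError("sigma2_a samples must be positive")
    h2 = s / (s + 1.0 + link_variance)
    lci, uci = hpd_interval(h2)
    return {"estimate": float(h2.mean()), "lci": lci, "uci": uci, "samples": h2}


# ---------------------------------------------------------------------------
# the estimator


class PhylogeneticMixedLogit(BaseEstimator):
    """Binary phylogenetic mixed model fit by MCMC (sklearn-style estimator).

    Parameters
    ----------
    iterations, burn_in, thinning : MCMC schedule.  Retained draws are
        (iterations - burn_in) / thinning (950 at the defaults).
    nu, v_scale, alpha_mu, alpha_v : parameter-expanded prior on the
        phylogenetic variance (see module docstring).
    fixed_effect_prior : 'flat' (default) or 'normal' (zero-mean, variance
        ``fixed_effect_variance`` per coefficient) — required when the
        predictors separate the response.
    link : 'logistic' (default) or 'probit'.
    link_variance_in_h2 : include the link variance in the h2 denominator.
    interval : 'hpd' (default) or 'quantile' 95% intervals.
    fix_phylo_variance : if set, sigma2_a is held at this value instead of
        sampled (useful for nesting checks against plain logistic models).
    separation_check : raise SeparationError under a flat prior when a
        predictor stratum perfectly predicts the response.
    random_state : chain seed.

    Attributes
    ----------
    summary_ : DataFrame with one row per coefficient — posterior mean,
        95% LCI/UCI, ESS, lag-1 autocorrelation, Geweke z and pMCMC.
    h2_ : dict with the posterior mean and 95% interval of heritability.
    chain_ : dict of retained draws ('beta', 'sigma2_a', 'liability').
    """

    def __init__(
        self,
        iterations: int = 2_000_000,
        burn_in: int = 100_000,
        thinning: int = 2_000,
        nu: float = 100.0,
        v_scale: float = 1.0,
        alpha_mu: float = 0.0,
        alpha_v: float = 1.0,
        fixed_effect_prior: str = "flat",
        fixed_effect_variance: float = 9.0,
        link: str = "logistic",
        link_variance_in_h2: bool = True,
        interval: str = "hpd",
        fix_phylo_variance: float | None = None,
        separation_check: bool = True,
        random_state=None,
    ):
        self.iterations = iterations
        self.burn_in = burn_in
        self.thinning = thinning
        self.nu = nu
        self.v_scale = v_scale
        self.alpha_mu = alpha_mu
        self.alpha_v = alpha_v
        self.fixed_effect_prior = fixed_effect_prior
        self.fixed_effect_variance = fixed_effect_variance
        self.link = link
        self.link_variance_in_h2 = link_variance_in_h2
        self.interval = interval
        self.fix_phylo_variance = fix_phylo_variance
        self.separation_check = separation_check
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _interval(self, samples):
        if self.interval == "hpd":
            return hpd_interval(samples)
        lo, hi = np.quantile(samples, [0.025, 0.975])
        return float(lo), float(hi)

    def fit(self, X, y, correlation=None):
        """Fit the model.

        ``X``: (n, k) predictor matrix or DataFrame (no intercept column;
        one is prepended).  ``y``: binary response.  ``correlation``: the
        phylogenetic correlation matrix aligned with the rows of X; the
        identity is used when omitted (no phylogenetic structure).
        """
        if self.link not in ("logistic", "probit"):
            raise PMMError("link must be 'logistic' or 'probit'")
        X_df = pd.DataFrame(X)
        names = ["(Intercept)"] + [str(c) for c in X_df.columns]
        Xmat = np.column_stack([np.ones(len(X_df)), X_df.to_numpy(dtype=float)])
        y = np.asarray(y, dtype=int)
        if set(np.unique(y)) != {0, 1}:
            raise PMMError("response must be binary with both states present")
        n, k = Xmat.shape
        if np.any(~np.isfinite(Xmat)):
            raise PMMError("predictors contain missing or non-finite values")
        if self.separation_check and self.fixed_effect_prior == "flat":
            flagged, offenders = detect_separation(y, X_df)
            if flagged:
                raise SeparationError(
                    f"separation detected (predictors: {offenders}); refit with "
                    "fixed_effect_prior='normal'"
                )
        C = np.eye(n) if correlation is None else np.asarray(correlation, dtype=float)
        if C.shape != (n, n):
            raise PMMError("correlation matrix does not match the data")
        evals, evecs = np.linalg.eigh(C)
        evals = np.clip(evals, 0.0, None)
        M = evecs * np.sqrt(evals)  # a = alpha * M z,  z ~ N(0, v I)

        settings = PMMSettings(
            self.iterations, self.burn_in, self.thinning,
            0 if self.random_state is None else int(self.random_state),
        )
        rng = np.random.default_rng(settings.seed)
        prior_prec_beta = (
            np.zeros(k)
            if self.fixed_effect_prior == "flat"
            else np.full(k, 1.0 / self.fixed_effect_variance)
        )

        # state
        beta = np.zeros(k)
        z = np.zeros(n)
        alpha = 1.0
        v = self.v_scale
        if self.fix_phylo_variance is not None:
            alpha = float(np.sqrt(self.fix_phylo_variance))
            v = 1.0
        liab = np.where(y == 1, 0.5, -0.5).astype(float)
        step = 2.4  # liability Metropolis step (logistic link)
        XtX = Xmat.T @ Xmat

        n_ret = settings.n_retained
        out_beta = np.empty((n_ret, k))
        out_sigma = np.empty(n_ret)
        out_liab = np.empty((n_ret, n))
        kept = 0
        acc = 0.0
        n_acc = 0

        Mz = M @ z
        for it in range(settings.iterations):
            mu = Xmat @ beta + alpha * Mz
            if self.link == "logistic":
                prop = liab + step * rng.standard_normal(n)
                def logtarget(l):
                    return y * l - np.log1p(np.exp(-np.abs(l))) - np.maximum(l, 0) \
                        - 0.5 * (l - mu) ** 2
                delta = logtarget(prop) - logtarget(liab)
                accept = np.log(rng.random(n)) < delta
                liab = np.where(accept, prop, liab)
                acc += accept.mean()
                n_acc += 1
                if it < settings.burn_in and n_acc % 200 == 0:
                    rate = acc / n_acc
                    step = min(max(step * np.exp(0.5 * (rate - 0.44)), 0.2), 10.0)
            else:  # probit: liab | y is truncated N(mu, 1)
                u = rng.random(n)
                lo = ndtr(-mu)
                liab = mu + ndtri(
                    np.where(y == 1, lo + u * (1 - lo), u * lo).clip(1e-12, 1 - 1e-12)
                )
            # z | rest (diagonal in the eigenbasis)
            r = liab - Xmat @ beta
            g = M.T @ r
            prec = alpha**2 * evals + 1.0 / max(v, 1e-12)
            z = (alpha * g) / prec + rng.standard_normal(n) / np.sqrt(prec)
            Mz = M @ z
            # beta | rest
            r2 = liab - alpha * Mz
            A = XtX + np.diag(prior_prec_beta)
            b = Xmat.T @ r2 + prior_prec_beta * 0.0
            cho = np.linalg.cholesky(A)
            mean_beta = np.linalg.solve(A, b)
            beta = mean_beta + np.linalg.solve(cho.T, rng.standard_normal(k))
            if self.fix_phylo_variance is None:
                # alpha | rest (scalar Gaussian)
                p = Mz
                pp = p @ p
                prec_a = pp + 1.0 / self.alpha_v
                mean_a = (p @ (liab - Xmat @ beta) + self.alpha_mu / self.alpha_v) / prec_a
                alpha = mean_a + rng.standard_normal() / np.sqrt(prec_a)
                # v | z (conjugate scaled inverse-chi-square)
                shape = 0.5 * (self.nu + n)
                rate = 0.5 * (self.nu * self.v_scale + z @ z)
                v = rate / rng.gamma(shape)
            if it >= settings.burn_in and (it - settings.burn_in + 1) % settings.thinning == 0:
                out_beta[kept] = beta
                out_sigma[kept] = alpha**2 * v
                out_liab[kept] = liab
                kept += 1

        self.chain_ = {
            "beta": out_beta,
            "sigma2_a": out_sigma,
            "liability": out_liab,
        }
        self.coef_names_ = names
        self.n_retained_ = n_ret
        self.acceptance_rate_ = acc / max(n_acc, 1)

        rows = []
        for j, name in enumerate(names):
            s = out_beta[:, j]
            lci, uci = self._interval(s)
            d = chain_diagnostics(s)
            rows.append(
                {
                    "term": name,
                    "estimate": float(s.mean()),
                    "lci": lci,
                    "uci": uci,
                    "ess": d.ess,
                    "autocorrelation": d.lag1_autocorrelation,
                    "geweke_z": d.geweke_z,
                    "pmcmc": pmcmc(s),
                }
            )
        self.summary_ = pd.DataFrame(rows).set_index("term")
        c = LOGIT_LINK_VARIANCE if (self.link == "logistic" and self.link_variance_in_h2) else 0.0
        sig = np.clip(out_sigma, 1e-12, None)
        self.h2_ = {k2: v2 for k2, v2 in heritability(sig, c).items() if k2 != "samples"}
        self.h2_samples_ = heritability(sig, c)["samples"]
        self.coef_ = out_beta.mean(axis=0)
        return self

    def predict_proba(self, X, correlation_cross=None):
        """Posterior-mean response probability for new rows of X.

        Marginalizes the residual and (for unobserved species) the
        phylogenetic effect by Monte Carlo over the retained draws.
        """
        X_df = pd.DataFrame(X)
        Xmat = np.column_stack([np.ones(len(X_df)), X_df.to_numpy(dtype=float)])
        rng = np.random.default_rng(0)
        etas = Xmat @ self.chain_["beta"].T  # (m, draws)
        spread = np.sqrt(self.chain_["sigma2_a"] + 1.0)
        etas = etas + spread * rng.standard_normal(etas.shape)
        if self.link == "logistic":
            p = 1.0 / (1.0 + np.exp(-etas))
        else:
            p = ndtr(etas)
        p1 = p.mean(axis=1)
        return np.column_stack([1 - p1, p1])

    def predict(self, X, **kw):
        return (self.predict_proba(X, **kw)[:, 1] > 0.5).astype(int)


def fit_binary_pmm(
    X,
    y,
    correlation=None,
    settings: PMMSettings | None = None,
    priors: PriorSpec | None = None,
    **kwargs,
) -> PhylogeneticMixedLogit:
    """Functional wrapper around :class:`PhylogeneticMixedLogit`."""
    settings = settings or PMMSettings()
    priors = priors or PriorSpec()
    est = PhylogeneticMixedLogit(
        iterations=settings.iterations,
        burn_in=settings.burn_in,
        thinning=settings.thinning,
        nu=priors.nu,
        v_scale=priors.v_scale,
        alpha_mu=priors.alpha_mu,
        alpha_v=priors.alpha_v,
        fixed_effect_prior=priors.fixed_effect_prior,
        fixed_effect_variance=priors.fixed_effect_variance,
        random_state=settings.seed,
        **kwargs,
    )
    return est.fit(X, y, correlation=correlation)
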