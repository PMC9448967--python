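"""Pagel's correlated-evolution models for two binary traits on a phylogeny.

Two binary characters define four joint states 1=(0,0), 2=(0,1), 3=(1,0),
4=(1,1) (first digit = trait x, second = trait y).  Evolution is a
continuous-time Markov chain in which only single changes are allowed, so
eight transition rates exist: q12, q21, q13, q31, q24, q42, q34, q43; the
dual transitions 1<->4 and 2<->3 have rate zero.

*Independent* model: each trait gains and loses independently of the
other's state (four free rates, mapped onto the eight).  *Dependent*
model: all eight rates free, so a trait's gain/loss rate may depend on the
other trait's state.  Restricted dependent models pin two named rates
equal; comparing unrestricted vs restricted marginal likelihoods yields
the contingent-change and temporal-order tests.

Rates carry a hyper-exponential prior: q ~ Exponential(mean m) with
m ~ Uniform(0, 10).  Marginal likelihoods come from stepping-stone
sampling along a power-posterior path; Bayes factors are
BF = 2 (log ML_1 - log ML_2), interpreted as no evidence (< 2), positive
(2-5) or strong (> 5) evidence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from ._pruning import loglik_for_rates, propagators, prune_kernel
from .phylo import FlatTree, flatten_tree
from .trait_data import BinaryTraitPair

__all__ = [
    "RATE_NAMES",
    "RATE_TRANSITIONS",
    "DependentRates",
    "IndependentRates",
    "RateModel",
    "MCMCSettings",
    "SteppingStoneSettings",
    "build_generator",
    "stationary_distribution",
    "transition_probabilities",
    "pruning_loglik",
    "sample_posterior",
    "stepping_stone_logml",
    "bayes_factor_summary",
    "interpret_bf",
    "directional_test",
    "test_battery",
    "BFSummary",
    "DirectionalTestResult",
    "PagelDiscrete",
]

#: the eight permitted single-change rates, in canonical order
RATE_NAMES = ("q12", "q21", "q13", "q31", "q24", "q42", "q34", "q43")

#: rate name -> (from_state, to_state), 0-based joint-state indices
RATE_TRANSITIONS = {
    "q12": (0, 1),
    "q21": (1, 0),
    "q13": (0, 2),
    "q31": (2, 0),
    "q24": (1, 3),
    "q42": (3, 1),
    "q34": (2, 3),
    "q43": (3, 2),
}

_FORBIDDEN = {"q14", "q41", "q23", "q32"}


class CoevoError(ValueError):
    pass


@dataclass(frozen=True)
class DependentRates:
    q12: float
    q21: float
    q13: float
    q31: float
    q24: float
    q42: float
    q34: float
    q43: float

    def __post_init__(self):
        for name in RATE_NAMES:
            if getattr(self, name) < 0:
                raise CoevoError(f"negative rate {name}")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in RATE_NAMES], dtype=float)


@dataclass(frozen=True)
class IndependentRates:
    """Gain/loss rates of each trait, independent of the other's state."""

    alpha1: float  # gain of trait x
    beta1: float  # loss of trait x
    alpha2: float  # gain of trait y
    beta2: float  # loss of trait y

    def __post_init__(self):
        for name in ("alpha1", "beta1", "alpha2", "beta2"):
            if getattr(self, name) < 0:
                raise CoevoError(f"negative rate {name}")

    def to_dependent(self) -> DependentRates:
        return DependentRates(
            q13=self.alpha1,
            q24=self.alpha1,
            q31=self.beta1,
            q42=self.beta1,
            q12=self.alpha2,
            q34=self.alpha2,
            q21=self.beta2,
            q43=self.beta2,
        )

    def as_array(self) -> np.ndarray:
        return self.to_dependent().as_array()


def build_generator(rates) -> np.ndarray:
    """4x4 generator matrix Q over the joint states.

    Off-diagonal entries carry the eight permitted rates; the dual-change
    cells (1,4), (4,1), (2,3), (3,2) are structurally zero; each diagonal
    is minus its row's off-diagonal sum.
    """
    if isinstance(rates, IndependentRates):
        rates = rates.to_dependent()
    if isinstance(rates, DependentRates):
        arr = rates.as_array()
    else:
        arr = np.asarray(rates, dtype=float)
        if arr.shape != (8,):
            raise CoevoError("expected eight rates in canonical order")
        if np.any(arr < 0):
            raise CoevoError("negative rate")
    Q = np.zeros((4, 4))
    for name, val in zip(RATE_NAMES, arr):
        i, j = RATE_TRANSITIONS[name]
        Q[i, j] = val
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution pi with pi Q = 0, sum(pi) = 1."""
    A = np.vstack([Q.T, np.ones(Q.shape[0])])
    b = np.zeros(Q.shape[0] + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def transition_probabilities(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t): a stochastic matrix (rows sum to 1)."""
    if t < 0:
        raise CoevoError("branch length must be nonnegative")
    return propagators(Q, np.array([t]))[0]


# ---------------------------------------------------------------------------
# likelihood


def _root_prior(root_rule, Q: np.ndarray) -> np.ndarray:
    if isinstance(root_rule, str):
        if root_rule == "uniform":
            return np.full(4, 0.25)
        if root_rule == "stationary":
            return stationary_distribution(Q)
        raise CoevoError(f"unknown root rule {root_rule!r}")
    pi = np.asarray(root_rule, dtype=float)
    if pi.shape != (4,) or np.any(pi < 0):
        raise CoevoError("root prior must be four nonnegative weights")
    return pi / pi.sum()


def _tip_partials(flat: FlatTree, pair: BinaryTraitPair) -> np.ndarray:
    lookup = dict(zip(pair.taxa, pair.joint_states()))
    missing = [lab for lab in flat.tip_labels if lab not in lookup]
    if missing:
        raise CoevoError(f"tip states missing for: {missing[:5]}")
    partials = np.zeros((flat.n_tips, 4))
    for i, lab in enumerate(flat.tip_labels):
        partials[i, lookup[lab]] = 1.0
    return partials


def _as_flat(tree) -> FlatTree:
    return tree if isinstance(tree, FlatTree) else flatten_tree(tree)


def pruning_loglik(tree, pair: BinaryTraitPair, Q: np.ndarray, root_rule="uniform"):
    """Felsenstein-pruning log-likelihood of a trait pair under generator Q.

    Polytomies are handled natively; the root state is integrated under
    ``root_rule`` ('uniform' by default, 'stationary', or explicit weights).
    """
    flat = _as_flat(tree)
    partials = _tip_partials(flat, pair)
    pi = _root_prior(root_rule, Q)
    P = propagators(Q, flat.branch_lengths)
    return float(
        prune_kernel(
            flat.postorder, flat.child_ptr, flat.child_idx, P, partials, flat.root, pi
        )
    )


# ---------------------------------------------------------------------------
# model parameterizations


@dataclass(frozen=True)
class RateModel:
    """Maps the eight rate slots onto free parameters and fixed values.

    ``param_index[i] >= 0`` points slot i at a free parameter;
    ``param_index[i] == -1`` pins slot i at ``fixed_values[i]``.
    """

    kind: str
    param_index: tuple
    fixed_values: tuple
    n_free: int

    @classmethod
    def dependent(cls) -> "RateModel":
        return cls("dependent", tuple(range(8)), (0.0,) * 8, 8)

    @classmethod
    def independent(cls) -> "RateModel":
        # free params: alpha1, beta1, alpha2, beta2
        mapping = {"q13": 0, "q24": 0, "q31": 1, "q42": 1,
                   "q12": 2, "q34": 2, "q21": 3, "q43": 3}
        return cls(
            "independent",
            tuple(mapping[n] for n in RATE_NAMES),
            (0.0,) * 8,
            4,
        )

    @classmethod
    def restricted(cls, rate_a: str, rate_b: str) -> "RateModel":
        """Dependent model with two named rates constrained equal."""
        for r in (rate_a, rate_b):
            if r in _FORBIDDEN:
                raise CoevoError(f"{r} is a structurally-zero (dual) transition")
            if r not in RATE_NAMES:
                raise CoevoError(f"unknown rate {r!r}")
        if rate_a == rate_b:
            raise CoevoError("restriction must name two distinct rates")
        index = {}
        nxt = 0
        out = []
        for n in RATE_NAMES:
            key = rate_a if n in (rate_a, rate_b) else n
            if key not in index:
                index[key] = nxt
                nxt += 1
            out.append(index[key])
        return cls("restricted", tuple(out), (0.0,) * 8, nxt)

    @classmethod
    def fixed(cls, rates) -> "RateModel":
        arr = build_generator(rates)  # validates
        vals = tuple(float(arr[RATE_TRANSITIONS[n]]) for n in RATE_NAMES)
        return cls("fixed", (-1,) * 8, vals, 0)

    @classmethod
    def single_free(cls, free_rate: str, fixed_rates) -> "RateModel":
        """One named rate free, the other seven fixed (used for oracles)."""
        if free_rate not in RATE_NAMES:
            raise CoevoError(f"unknown rate {free_rate!r}")
        arr = build_generator(fixed_rates)
        vals = tuple(float(arr[RATE_TRANSITIONS[n]]) for n in RATE_NAMES)
        idx = tuple(0 if n == free_rate else -1 for n in RATE_NAMES)
        return cls("single_free", idx, vals, 1)

    def rates_from_params(self, params: np.ndarray) -> np.ndarray:
        out = np.array(self.fixed_values, dtype=float)
        for i, pi in enumerate(self.param_index):
            if pi >= 0:
                out[i] = params[pi]
        return out

    def free_rate_names(self) -> list[str]:
        """One representative rate name per free parameter."""
        names = [""] * self.n_free
        for n, pi in zip(RATE_NAMES, self.param_index):
            if pi >= 0 and not names[pi]:
                names[pi] = n
        return names


@dataclass(frozen=True)
class MCMCSettings:
    iterations: int = 2_000_000
    burn_in: int = 100_000
    thinning: int = 2_000
    seed: int = 0

    def __post_init__(self):
        if (self.iterations - self.burn_in) % self.thinning:
            raise CoevoError(
                "retained draws (iterations - burn_in)/thinning must be an integer"
            )

    @property
    def n_retained(self) -> int:
        return (self.iterations - self.burn_in) // self.thinning


@dataclass(frozen=True)
class SteppingStoneSettings:
    stones: int = 100
    iterations_per_stone: int = 10_000
    alpha: float = 0.4  # Beta(alpha, 1) quantile schedule for the powers
    seed: int = 0

    def __post_init__(self):
        if self.stones < 2:
            raise CoevoError("need at least two stones")

    def powers(self) -> np.ndarray:
        k = np.arange(self.stones + 1)
        return (k / self.stones) ** (1.0 / self.alpha)


# ---------------------------------------------------------------------------
# MCMC machinery


class _Target:
    """Power posterior L(theta)^beta * prior for a RateModel."""

    def __init__(self, tree, pair, model: RateModel, root_rule="uniform",
                 prior_upper: float = 10.0, use_likelihood: bool = True):
        self.flat = _as_flat(tree)
        self.partials = _tip_partials(pair=pair, flat=self.flat)
        self.model = model
        self.root_rule = root_rule
        self.prior_upper = prior_upper
        self.use_likelihood = use_likelihood

    def loglik(self, rates8: np.ndarray) -> float:
        if not self.use_likelihood:
            return 0.0
        if self.root_rule == "stationary":
            Q = build_generator(rates8)
            pi = _root_prior(self.root_rule, Q)
            P = propagators(Q, self.flat.branch_lengths)
            return float(
                prune_kernel(
                    self.flat.postorder, self.flat.child_ptr, self.flat.child_idx,
                    P, self.partials, self.flat.root, pi,
                )
            )
        pi = _root_prior(self.root_rule, np.zeros((4, 4)))
        return loglik_for_rates(
            np.asarray(rates8, dtype=float), self.flat.branch_lengths,
            self.flat.postorder, self.flat.child_ptr, self.flat.child_idx,
            self.partials, self.flat.root, pi,
        )

    @staticmethod
    def log_rate_prior(values: np.ndarray, m: float) -> float:
        # q ~ Exponential(mean m), independently per free value
        if m <= 0:
            return -np.inf
        return float(-values.size * np.log(m) - values.sum() / m)


def _run_power_chain(
    target: _Target,
    beta: float,
    n_iter: int,
    rng: np.random.Generator,
    state=None,
    record_every: int = 1,
    adapt: bool = False,
):
    """Metropolis-within-Gibbs chain on (free rates, hyper-mean m).

    Returns the final state and the recorded (params, loglik) samples.
    The target is L^beta x prior; beta=0 samples the prior alone.
    """
    model = target.model
    nf = model.n_free
    if state is None:
        m = rng.uniform(0.0, target.prior_upper)
        params = rng.exponential(m, size=nf) if nf else np.empty(0)
        scales = np.full(nf, 0.6)
        state = [params, m, None, scales]
    params, m, ll, scales = state
    if ll is None:
        ll = target.loglik(model.rates_from_params(params))
    kept_params = []
    kept_ll = []
    log_prior = target.log_rate_prior(params, m)
    for it in range(n_iter):
        # rate updates: multiplicative lognormal proposals
        for j in range(nf):
            prop = params.copy()
            prop[j] = params[j] * np.exp(scales[j] * rng.standard_normal())
            ll_prop = target.loglik(model.rates_from_params(prop))
            lp_prop = target.log_rate_prior(prop, m)
            delta = (
                beta * (ll_prop - ll)
                + (lp_prop - log_prior)
                + np.log(prop[j] / params[j])  # Jacobian of the log walk
            )
            if np.log(rng.random()) < delta:
                params, ll, log_prior = prop, ll_prop, lp_prop
                if adapt:
                    scales[j] = min(scales[j] * 1.05, 5.0)
            elif adapt:
                scales[j] = max(scales[j] * 0.97, 0.02)
        # hyper-mean update: reflected random walk on (0, upper)
        if nf:
            m_prop = m + 0.8 * rng.standard_normal()
            upper = target.prior_upper
            while m_prop < 0 or m_prop > upper:
                m_prop = -m_prop if m_prop < 0 else 2 * upper - m_prop
            lp_prop = target.log_rate_prior(params, m_prop)
            if np.log(rng.random()) < lp_prop - log_prior:
                m, log_prior = m_prop, lp_prop
        if (it + 1) % record_every == 0:
            kept_params.append(params.copy())
            kept_ll.append(ll)
    state = [params, m, ll, scales]
    return state, np.array(kept_params), np.array(kept_ll)


def _rj_chain(target: _Target, settings: MCMCSettings, rng: np.random.Generator):
    """Reversible-jump partition sampler over the dependent model's rates.

    State: a label per rate — 0 for the zero class, g >= 1 for shared-value
    bins — plus one value per bin and the hyper-mean m.  The partition
    prior is uniform; new bin values are proposed from the Exp(m) prior, so
    reassignment moves accept with the likelihood ratio times the ratio of
    candidate-destination counts (proposal symmetry correction).
    """
    model = target.model
    if model.kind != "dependent":
        raise CoevoError("reversible jump is defined on the dependent model")
    n = 8
    labels = np.ones(n, dtype=int)  # start all rates in one shared bin
    values = {1: rng.exponential(2.0)}
    m = rng.uniform(0, target.prior_upper)
    scales = 0.6

    def rates_of(labels, values):
        return np.array([0.0 if l == 0 else values[l] for l in labels])

    ll = target.loglik(rates_of(labels, values))

    def n_candidates(labels):
        # destinations for any rate: zero class + existing bins + a new bin
        return len(set(labels) - {0}) + 2

    kept = []
    z_counts = np.zeros(n)
    n_kept = 0
    total = settings.iterations
    for it in range(total):
        # --- value updates (multiplicative MH) + hyper-mean
        vals = np.array(list(values.values())) if values else np.empty(0)
        for g in list(values):
            prop = values[g] * np.exp(scales * rng.standard_normal())
            lab_rates = rates_of(labels, {**values, g: prop})
            ll_prop = target.loglik(lab_rates)
            delta = (
                ll_prop - ll
                + (-(prop - values[g]) / m)  # Exp(m) prior ratio
                + np.log(prop / values[g])
            )
            if np.log(rng.random()) < delta:
                values[g] = prop
                ll = ll_prop
        if values:
            vals = np.array(list(values.values()))
            m_prop = m + 0.8 * rng.standard_normal()
            while m_prop < 0 or m_prop > target.prior_upper:
                m_prop = -m_prop if m_prop < 0 else 2 * target.prior_upper - m_prop
            delta = target.log_rate_prior(vals, m_prop) - target.log_rate_prior(vals, m)
            if np.log(rng.random()) < delta:
                m = m_prop
        # --- reassignment move
        i = rng.integers(n)
        cur = labels[i]
        bins = sorted(set(labels) - {0})
        destinations = [0] + bins + ["new"]
        destinations = [d for d in destinations if d != cur]
        dest = destinations[rng.integers(len(destinations))]
        new_labels = labels.copy()
        new_values = dict(values)
        if dest == "new":
            g_new = max(bins, default=0) + 1
            new_labels[i] = g_new
            new_values[g_new] = rng.exponential(m)
        else:
            new_labels[i] = dest
        # drop emptied bins
        for g in list(new_values):
            if not np.any(new_labels == g):
                del new_values[g]
        ll_prop = target.loglik(rates_of(new_labels, new_values))
        # uniform partition prior; prior-draw proposals for new values cancel
        delta = ll_prop - ll + np.log(
            n_candidates(labels) / n_candidates(new_labels)
        )
        if np.log(rng.random()) < delta:
            labels, values, ll = new_labels, new_values, ll_prop
        if it >= settings.burn_in and (it - settings.burn_in + 1) % settings.thinning == 0:
            kept.append(rates_of(labels, values))
            z_counts += labels == 0
            n_kept += 1
    kept = np.array(kept)
    z_values = 100.0 * z_counts / max(n_kept, 1)
    return kept, z_values


def sample_posterior(
    tree,
    pair: BinaryTraitPair,
    model: RateModel | str = "dependent",
    settings: MCMCSettings | None = None,
    rj: bool = False,
    root_rule="uniform",
    prior_upper: float = 10.0,
    use_likelihood: bool = True,
):
    """Posterior sample of transition rates under the hyper-exponential prior.

    Returns ``(chain, summary)``: ``chain`` holds the retained 8-column rate
    samples and the log-likelihood trace; ``summary`` is a per-rate frame of
    posterior means (zeros from the reversible-jump zero class included) and
    Z-values (percent of retained samples assigned to zero; identically 0
    with ``rj`` off).
    """
    if isinstance(model, str):
        model = {"dependent": RateModel.dependent(),
                 "independent": RateModel.independent()}[model]
    settings = settings or MCMCSettings()
    rng = np.random.default_rng(settings.seed)
    target = _Target(tree, pair, model, root_rule, prior_upper, use_likelihood)
    if rj:
        rates, z_values = _rj_chain(target, settings, rng)
        ll_trace = np.array([target.loglik(r) for r in rates])
    else:
        state, _, _ = _run_power_chain(
            target, 1.0, settings.burn_in, rng, adapt=True
        )
        state, kept_params, ll_trace = _run_power_chain(
            target,
            1.0,
            settings.iterations - settings.burn_in,
            rng,
            state=state,
            record_every=settings.thinning,
        )
        if model.n_free:
            rates = np.array([model.rates_from_params(p) for p in kept_params])
        else:
            rates = np.tile(np.array(model.fixed_values), (settings.n_retained, 1))
        z_values = np.zeros(8)
    mean_incl = rates.mean(axis=0)
    with np.errstate(invalid="ignore"):
        nz = rates.copy()
        nz[nz == 0] = np.nan
        mean_excl = np.nanmean(nz, axis=0)
    summary = pd.DataFrame(
        {
            "rate": RATE_NAMES,
            "mean": mean_incl,
            "mean_nonzero": mean_excl,
            "z_value": z_values,
        }
    ).set_index("rate")
    chain = {"rates": rates, "loglik": ll_trace}
    return chain, summary


def stepping_stone_logml(
    tree,
    pair: BinaryTraitPair,
    model: RateModel | str,
    ss: SteppingStoneSettings | None = None,
    root_rule="uniform",
    prior_upper: float = 10.0,
) -> float:
    """Stepping-stone estimate of the log marginal likelihood.

    The power-posterior path L^beta runs from the posterior (beta=1) toward
    the prior (beta=0) along Beta(0.4, 1)-quantile powers; each stone's
    contribution is the log mean importance ratio
    ``logmeanexp((beta_k - beta_{k-1}) * loglik)`` over samples drawn at the
    lower power.  Deterministic given the settings seed.  A model with no
    free parameters has log ML equal to its log-likelihood exactly.
    """
    if isinstance(model, str):
        model = {"dependent": RateModel.dependent(),
                 "independent": RateModel.independent()}[model]
    ss = ss or SteppingStoneSettings()
    target = _Target(tree, pair, model, root_rule, prior_upper)
    if model.n_free == 0:
        return target.loglik(np.array(model.fixed_values))
    rng = np.random.default_rng(ss.seed)
    betas = ss.powers()
    n_iter = ss.iterations_per_stone
    warm = max(n_iter // 5, 20)
    # burn in at the posterior, then walk the powers downward
    state, _, _ = _run_power_chain(target, 1.0, warm * 3, rng, adapt=True)
    logml = 0.0
    for k in range(ss.stones, 0, -1):
        b_low, b_high = betas[k - 1], betas[k]
        state, _, _ = _run_power_chain(target, b_low, warm, rng, state=state)
        state, _, lls = _run_power_chain(
            target, b_low, n_iter, rng, state=state, record_every=1
        )
        logml += logsumexp((b_high - b_low) * lls) - np.log(lls.size)
    return float(logml)


# ---------------------------------------------------------------------------
# Bayes factors


@dataclass(frozen=True)
class BFSummary:
    """Mean, 95% CI and evidence category of a set of Bayes-factor estimates."""

    bf_values: np.ndarray
    mean: float
    lci: float
    uci: float
    category: str

    def __str__(self):
        return f"BF = {self.mean:.2f} ({self.lci:.2f}/{self.uci:.2f}) [{self.category}]"


def interpret_bf(mean_bf: float) -> str:
    """Evidence category: < 2 none, 2-5 positive, > 5 strong."""
    if not np.isfinite(mean_bf):
        raise CoevoError("BF must be finite")
    if mean_bf < 2.0:
        return "none"
    if mean_bf <= 5.0:
        return "positive"
    return "strong"


def bayes_factor_summary(logml_a: Sequence[float], logml_b: Sequence[float]) -> BFSummary:
    """All-pairs Bayes factors BF = 2 (logML_a - logML_b), summarized.

    With 10 runs of each model, the 10 x 10 pairings give 100 BF estimates;
    the mean, the 95% CI of the estimates, and the evidence category of the
    mean are reported.
    """
    a = np.asarray(logml_a, dtype=float)
    b = np.asarray(logml_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise CoevoError("empty log marginal likelihood inputs")
    bf = 2.0 * (a[:, None] - b[None, :]).ravel()
    mean = float(bf.mean())
    if bf.size > 1 and bf.std() > 0:
        lci, uci = np.quantile(bf, [0.025, 0.975])
    else:
        lci = uci = mean
    return BFSummary(bf, mean, float(lci), float(uci), interpret_bf(mean))


# ---------------------------------------------------------------------------
# directional tests


@dataclass(frozen=True)
class DirectionalTestResult:
    restriction: tuple
    bf: BFSummary
    direction: str  # e.g. "q12 < q34", or "q12 ~ q34" when BF < 2
    meaning: str


_CONTINGENT_PAIRS = [("q12", "q34"), ("q21", "q43"), ("q13", "q24"), ("q31", "q42")]
_TEMPORAL_STANDARD = [("q12", "q13"), ("q42", "q43")]
_TEMPORAL_INVERTED = [("q31", "q34"), ("q21", "q24")]

_MEANINGS = {
    ("q12", "q34"): "gain of trait x contingent on the state of trait y",
    ("q21", "q43"): "loss of trait x contingent on the state of trait y",
    ("q13", "q24"): "gain of trait y contingent on the state of trait x",
    ("q31", "q42"): "loss of trait y contingent on the state of trait x",
    ("q12", "q13"): "temporal order of trait gains from joint absence",
    ("q42", "q43"): "temporal order of trait losses from joint presence",
    ("q31", "q34"): "temporal order under inverted trait orientation (gains)",
    ("q21", "q24"): "temporal order under inverted trait orientation (losses)",
}


def directional_test(
    tree,
    pair: BinaryTraitPair,
    restriction: tuple,
    ss: SteppingStoneSettings | None = None,
    n_runs: int = 10,
    posterior_settings: MCMCSettings | None = None,
    root_rule="uniform",
    prior_upper: float = 10.0,
    seed: int = 0,
) -> DirectionalTestResult:
    """Rate-restriction test: unrestricted vs (rate_a = rate_b) dependent model.

    Both models' log marginal likelihoods are estimated ``n_runs`` times by
    stepping-stone sampling; all pairings give the BF sample whose mean is
    categorized.  The inferred direction (which rate is smaller) comes from
    the unrestricted model's posterior means.
    """
    rate_a, rate_b = restriction
    restricted = RateModel.restricted(rate_a, rate_b)
    ss = ss or SteppingStoneSettings()
    rng = np.random.default_rng(seed)
    free_mls, restr_mls = [], []
    for _ in range(n_runs):
        s1, s2 = rng.integers(2**31, size=2)
        free_mls.append(
            stepping_stone_logml(
                tree, pair, RateModel.dependent(),
                SteppingStoneSettings(ss.stones, ss.iterations_per_stone, ss.alpha, int(s1)),
                root_rule, prior_upper,
            )
        )
        restr_mls.append(
            stepping_stone_logml(
                tree, pair, restricted,
                SteppingStoneSettings(ss.stones, ss.iterations_per_stone, ss.alpha, int(s2)),
                root_rule, prior_upper,
            )
        )
    bf = bayes_factor_summary(free_mls, restr_mls)
    post = posterior_settings or MCMCSettings(
        iterations=6_000, burn_in=1_000, thinning=10, seed=int(rng.integers(2**31))
    )
    _, summary = sample_posterior(
        tree, pair, RateModel.dependent(), post,
        root_rule=root_rule, prior_upper=prior_upper,
    )
    ma, mb = summary.loc[rate_a, "mean"], summary.loc[rate_b, "mean"]
    if bf.mean < 2.0:
        direction = f"{rate_a} ~ {rate_b}"
    elif ma < mb:
        direction = f"{rate_a} < {rate_b}"
    else:
        direction = f"{rate_a} > {rate_b}"
    meaning = _MEANINGS.get((rate_a, rate_b), f"rate restriction {rate_a} = {rate_b}")
    return DirectionalTestResult((rate_a, rate_b), bf, direction, meaning)


def battery_comparisons(inverted_orientation: bool = False) -> list[tuple]:
    """The six standard rate comparisons (four contingent, two temporal).

    When state 0 of one trait is associated with state 1 of the other
    (inverted orientation), the temporal-order comparisons swap to
    q31 vs q34 and q21 vs q24.
    """
    temporal = _TEMPORAL_INVERTED if inverted_orientation else _TEMPORAL_STANDARD
    return _CONTINGENT_PAIRS + temporal


def test_battery(
    tree,
    pair: BinaryTraitPair,
    ss: SteppingStoneSettings | None = None,
    n_runs: int = 10,
    seed: int = 0,
    **kwargs,
) -> list[DirectionalTestResult]:
    """Run the full contingent-change / temporal-order battery (6 tests)."""
    rng = np.random.default_rng(seed)
    results = []
    for restriction in battery_comparisons(pair.inverted_orientation):
        results.append(
            directional_test(
                tree, pair, restriction, ss=ss, n_runs=n_runs,
                seed=int(rng.integers(2**31)), **kwargs,
            )
        )
    return results


# ---------------------------------------------------------------------------
# estimator facade


class PagelDiscrete(BaseEstimator):
    """Correlated-evolution model for two binary traits (estimator facade).

    Parameters
    ----------
    model : 'dependent' | 'independent', or a RateModel.
    reversible_jump : sample rate-to-{zero, shared-bin} assignments and
        report Z-values (percent of posterior visits at zero).
    iterations, burn_in, thinning : MCMC schedule; retained draws are
        (iterations - burn_in) / thinning.
    root_rule : 'uniform' (default), 'stationary', or explicit weights.
    prior_upper : upper bound of the Uniform hyper-prior on the
        exponential prior mean for all rates.
    random_state : seed for the chain.

    Attributes (after fit)
    ----------------------
    rate_summary_ : per-rate posterior means and Z-values.
    rates_ : posterior mean of the eight rates (array).
    chain_ : dict with retained rate samples and the log-likelihood trace.
    n_retained_ : number of retained draws.
    """

    def __init__(
        self,
        model="dependent",
        reversible_jump=False,
        iterations=2_000_000,
        burn_in=100_000,
        thinning=2_000,
        root_rule="uniform",
        prior_upper=10.0,
        random_state=None,
    ):
        self.model = model
        self.reversible_jump = reversible_jump
        self.iterations = iterations
        self.burn_in = burn_in
        self.thinning = thinning
        self.root_rule = root_rule
        self.prior_upper = prior_upper
        self.random_state = random_state

    def fit(self, X, y=None, *, tree):
        """Fit to a BinaryTraitPair (or (taxa, x, y) triple) on ``tree``."""
        pair = X if isinstance(X, BinaryTraitPair) else BinaryTraitPair(*X)
        settings = MCMCSettings(
            self.iterations, self.burn_in, self.thinning,
            0 if self.random_state is None else int(self.random_state),
        )
        chain, summary = sample_posterior(
            tree, pair, self.model, settings, rj=self.reversible_jump,
            root_rule=self.root_rule, prior_upper=self.prior_upper,
        )
        self.chain_ = chain
        self.rate_summary_ = summary
        self.rates_ = summary["mean"].to_numpy()
        self.n_retained_ = settings.n_retained
        self._tree = tree
        self._pair = pair
        return self

    def score(self, X=None, y=None) -> float:
        """Log-likelihood at the posterior-mean rates."""
        return pruning_loglik(
            self._tree, self._pair, build_generator(self.rates_), self.root_rule
        )

    def log_marginal_likelihood(self, ss: SteppingStoneSettings | None = None) -> float:
        model = self.model
        if isinstance(model, str):
            model = {"dependent": RateModel.dependent(),
                     "independent": RateModel.independent()}[model]
        return stepping_stone_logml(
            self._tree, self._pair, model, ss,
            root_rule=self.root_rule, prior_upper=self.prior_upper,
        )
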