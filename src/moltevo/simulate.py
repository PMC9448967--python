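"""Synthetic trees and trait tables with the structure the analyses assume.

Every generator is deterministic given its seed.  Trees are pure-birth
(Yule) and rescaled to unit height — the simplest ultrametric generator,
matching the dated-supertree setting without mimicking avian
diversification heterogeneity.  Binary trait pairs evolve by exact
event-driven simulation of the 4-state joint CTMC; binary responses come
from the same liability model the mixed model fits (fixed effects +
phylogenetic random effect + unit residual, thresholded through the
logistic or probit link), with the simulation truth stored for recovery
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .coevo import stationary_distribution
from .phylo import check_ultrametric, phylo_correlation, tip_labels
from .trait_data import (
    BinaryTraitPair,
    Month,
    MoltObservation,
    SpeciesRecord,
    SpeciesTable,
)

__all__ = [
    "SimulationSpec",
    "simulate_yule_tree",
    "simulate_ctmc_pair",
    "simulate_liability_dataset",
    "simulate_study_table",
]


def simulate_yule_tree(n: int, seed: int = 0, birth_rate: float = 1.0) -> dendropy.Tree:
    """Pure-birth tree with ``n`` tips, rescaled to unit root-to-tip depth.

    Tips are labeled t1..tn.  Deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError("need at least two tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.age_ = 0.0
    tips = [tree.seed_node]
    t = 0.0
    while len(tips) < n:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        node = tips.pop(rng.integers(len(tips)))
        node.split_time_ = t
        for _ in range(2):
            child = node.new_child()
            tips.append(child)
    t_end = t + rng.exponential(1.0 / (birth_rate * len(tips)))
    # assign branch lengths from split times
    for node in tree.preorder_node_iter():
        start = getattr(node.parent_node, "split_time_", 0.0) if node.parent_node else 0.0
        end = getattr(node, "split_time_", t_end)
        node.edge.length = None if node.parent_node is None else end - start
    order = rng.permutation(n)
    for leaf, i in zip(tree.leaf_node_iter(), order):
        leaf.taxon = taxa[int(i)]
    depth = check_ultrametric(tree, rel_tol=1e-6)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= depth
    return tree


def simulate_ctmc_pair(
    tree: dendropy.Tree,
    Q: np.ndarray,
    root=None,
    seed: int = 0,
    inverted_orientation: bool = False,
) -> BinaryTraitPair:
    """Evolve a joint binary trait pair along the tree under generator Q.

    Exact event-driven simulation: waiting times are exponential with the
    current state's total exit rate and jumps follow the embedded chain.
    ``root`` is a fixed state index (0..3), a distribution of length 4, or
    None for the stationary distribution of Q.
    """
    Q = np.asarray(Q, dtype=float)
    rng = np.random.default_rng(seed)
    if root is None:
        pi = stationary_distribution(Q)
        root_state = int(rng.choice(4, p=pi))
    elif np.ndim(root) == 0:
        root_state = int(root)
    else:
        pi = np.asarray(root, dtype=float)
        root_state = int(rng.choice(4, p=pi / pi.sum()))

    states = {tree.seed_node: root_state}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        s = states[node.parent_node]
        remaining = node.edge.length or 0.0
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if wait >= remaining:
                break
            remaining -= wait
            probs = Q[s].copy()
            probs[s] = 0.0
            probs = np.clip(probs, 0, None)
            s = int(rng.choice(4, p=probs / probs.sum()))
        states[node] = s
    taxa, xs, ys = [], [], []
    for leaf in tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        s = states[leaf]
        xs.append(s // 2)
        ys.append(s % 2)
    return BinaryTraitPair(tuple(taxa), np.array(xs), np.array(ys),
                           inverted_orientation=inverted_orientation)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the liability-model data generator.

    ``beta`` maps predictor names to true fixed effects (an '(Intercept)'
    key is honored); ``ordinal_probs`` gives each ordinal predictor's
    category probabilities keyed by name; predictors absent from it are
    drawn standard normal (continuous).  ``sigma2_a`` is the phylogenetic
    variance; the residual is the unit-variance latent of the chosen link.
    """

    n_species: int = 100
    beta: dict = field(default_factory=dict)
    sigma2_a: float = 1.0
    ordinal_probs: dict = field(default_factory=dict)
    link: str = "logistic"
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 4:
            raise ValueError("need at least four species")
        if self.sigma2_a < 0:
            raise ValueError("sigma2_a must be nonnegative")
        if self.link not in ("logistic", "probit"):
            raise ValueError("link must be 'logistic' or 'probit'")


def simulate_liability_dataset(tree: dendropy.Tree, spec: SimulationSpec):
    """Draw predictors and a binary response from the liability model.

    Returns ``(data, truth)``: ``data`` is a DataFrame indexed by taxon
    with the predictors and the binary ``response``; ``truth`` records the
    generating parameters and the latent components.

    The latent is eta = X beta + a + e with a ~ N(0, sigma2_a C) (C the
    tree's phylogenetic correlation) and e the link's unit latent
    (standard logistic, scaled to variance 1, or standard normal); the
    response is 1{eta > 0}.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    labels = tip_labels(tree)
    n = len(labels)
    if n != spec.n_species:
        raise ValueError("tree tip count does not match spec.n_species")
    names = [k for k in spec.beta if k != "(Intercept)"]
    X = {}
    for name in names:
        if name in spec.ordinal_probs:
            p = np.asarray(spec.ordinal_probs[name], dtype=float)
            X[name] = rng.choice(np.arange(1, p.size + 1), size=n, p=p / p.sum())
        else:
            X[name] = rng.standard_normal(n)
    df = pd.DataFrame(X, index=labels, dtype=float)
    eta = np.full(n, float(spec.beta.get("(Intercept)", 0.0)))
    for name in names:
        eta = eta + spec.beta[name] * df[name].to_numpy()
    _, C = phylo_correlation(tree, taxa=labels)
    a = np.zeros(n)
    if spec.sigma2_a > 0:
        L = np.linalg.cholesky(C + 1e-10 * np.eye(n))
        a = np.sqrt(spec.sigma2_a) * (L @ rng.standard_normal(n))
    if spec.link == "logistic":
        # standard logistic latent: the mixed model's unit residual plus
        # the logistic link variance pi^2/3
        e = rng.standard_normal(n) + rng.logistic(0.0, 1.0, size=n)
    else:
        e = rng.standard_normal(n)
    eta = eta + a + e
    df["response"] = (eta > 0).astype(int)
    truth = {
        "beta": dict(spec.beta),
        "sigma2_a": spec.sigma2_a,
        "phylo_effect": a,
        "liability": eta,
        "link": spec.link,
    }
    return df, truth


_TRACT_POOL = [
    "head",
    "body",
    "wing-coverts",
    "tertials",
    "rectrices",
    "secondaries",
    "primaries",
]

_SPRING = [Month.JANUARY, Month.FEBRUARY, Month.MARCH, Month.APRIL]


def simulate_study_table(seed: int = 0, n_species: int = 188) -> SpeciesTable:
    """A full synthetic species table shaped like the study schema.

    188 rows by default, with molt presence, months, extent and tracts
    generated with plausible dependencies (migratory species molt more
    often and more completely; some molts are confined to November and
    December so the two timing rules differ), suitable as an end-to-end
    fixture.  Synthetic — statistical stand-in, not the archived table.
    """
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_species):
        migration = int(rng.choice([1, 2, 3, 4, 5], p=[0.3, 0.15, 0.15, 0.15, 0.25]))
        habitat = int(rng.integers(1, 7))
        foraging = int(rng.choice([0, 1, 2], p=[0.7, 0.2, 0.1]))
        greg = int(rng.choice([1, 2, 3, 4], p=[0.15, 0.3, 0.3, 0.25]))
        mass = float(np.exp(rng.normal(3.0, 0.8)))
        dichro = float(rng.gamma(2.0, 20.0))
        sexsel = float(rng.standard_normal())
        p_molt = 1.0 / (1.0 + np.exp(-(-1.2 + 0.55 * migration - 0.25 * greg)))
        has_molt = bool(rng.random() < p_molt)
        if has_molt:
            if rng.random() < 0.25:  # early-winter-only molt
                months = frozenset(
                    rng.choice([Month.NOVEMBER, Month.DECEMBER],
                               size=rng.integers(1, 3), replace=False)
                )
            else:
                k = int(rng.integers(1, 4))
                months = frozenset(rng.choice(_SPRING, size=k, replace=False))
                if rng.random() < 0.3:
                    months = months | {Month.NOVEMBER}
            complete = migration == 5 and rng.random() < 0.5
            if complete:
                tracts = frozenset(_TRACT_POOL)
                extent = "complete"
            else:
                k = int(rng.integers(1, 4))
                tracts = frozenset(
                    rng.choice(_TRACT_POOL[:4], size=k, replace=False)
                )
                extent = "partial"
            molt = MoltObservation(True, months, extent, tracts)
        else:
            molt = MoltObservation(False)
        records.append(
            SpeciesRecord(
                species=f"Species_{i + 1:03d}",
                body_mass=mass,
                dichromatism=dichro,
                sexual_selection=sexsel,
                migration=migration,
                habitat=habitat,
                aerial_foraging=foraging,
                gregariousness=greg,
                molt=molt,
            )
        )
    return SpeciesTable(records)
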