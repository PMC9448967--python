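"""Generator matrices, CTMC propagators and the pruning likelihood.

The pruning recursion is checked against two independent oracles: full
enumeration over all internal-state assignments on small trees, and the
factorization of the independent model into two single-trait two-state
likelihoods.
"""

import itertools

import numpy as np
import pytest

import moltevo as mv
from moltevo._pruning import propagators, prune_kernel
from moltevo.coevo import (
    CoevoError,
    RATE_NAMES,
    RATE_TRANSITIONS,
    RateModel,
    build_generator,
    pruning_loglik,
    stationary_distribution,
    transition_probabilities,
)
from moltevo.phylo import flatten_tree
from moltevo.trait_data import BinaryTraitPair


class TestGenerator:
    def test_structural_zeros_and_row_sums(self, dep_rates):
        Q = build_generator(mv.DependentRates(*([1.0] * 8)))
        assert np.allclose(Q.sum(axis=1), 0.0)
        for i, j in [(0, 3), (3, 0), (1, 2), (2, 1)]:
            assert Q[i, j] == 0.0

    def test_independent_mapping(self):
        Q = build_generator(mv.IndependentRates(0.2, 0.3, 0.5, 0.7))
        # gains of trait x (q13, q24) share alpha1; gains of y (q12, q34) alpha2
        assert Q[0, 2] == Q[1, 3] == 0.2
        assert Q[2, 0] == Q[3, 1] == 0.3
        assert Q[0, 1] == Q[2, 3] == 0.5
        assert Q[1, 0] == Q[3, 2] == 0.7

    def test_dual_transition_not_a_parameter(self):
        assert "q14" not in RATE_NAMES
        with pytest.raises(CoevoError):
            RateModel.restricted("q14", "q23")

    def test_negative_rate_rejected(self):
        with pytest.raises(CoevoError):
            mv.DependentRates(*([-0.1] + [1.0] * 7))


class TestPropagators:
    def test_zero_time_and_zero_generator_give_identity(self, dep_rates):
        Q = build_generator(dep_rates)
        assert np.allclose(transition_probabilities(Q, 0.0), np.eye(4))
        assert np.allclose(transition_probabilities(np.zeros((4, 4)), 2.0), np.eye(4))

    def test_matches_power_series(self, dep_rates):
        Q = build_generator(dep_rates)
        t = 0.7
        series = np.eye(4)
        term = np.eye(4)
        for k in range(1, 40):
            term = term @ (Q * t) / k
            series = series + term
        assert np.allclose(transition_probabilities(Q, t), series, atol=1e-9)

    def test_semigroup_property(self, dep_rates):
        Q = build_generator(dep_rates)
        P = transition_probabilities
        assert np.allclose(P(Q, 0.3) @ P(Q, 0.4), P(Q, 0.7), atol=1e-9)

    def test_rows_stochastic(self, dep_rates):
        Q = build_generator(dep_rates)
        P = propagators(Q, np.linspace(0.0, 3.0, 7))
        assert np.all(P >= 0)
        assert np.allclose(P.sum(axis=2), 1.0, atol=1e-12)

    def test_negative_time_rejected(self, dep_rates):
        with pytest.raises(CoevoError):
            transition_probabilities(build_generator(dep_rates), -0.1)


def brute_force_loglik(tree, pair, Q, root_prior=None):
    """Enumeration oracle: sum over all internal-state assignments."""
    nodes = list(tree.postorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    state = dict(zip(pair.taxa, pair.joint_states()))
    P = {
        n: propagators(Q, np.array([n.edge.length or 0.0]))[0]
        for n in nodes
        if n.parent_node
    }
    pi = np.full(4, 0.25) if root_prior is None else root_prior
    root = tree.seed_node
    total = 0.0
    for assign in itertools.product(range(4), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        p = pi[amap[root]]
        for n in nodes:
            if n.parent_node is None:
                continue
            s = state[n.taxon.label] if n.is_leaf() else amap[n]
            p *= P[n][amap[n.parent_node], s]
        total += p
    return np.log(total)


def two_state_loglik(tree, taxa, states, gain, loss):
    """Single-trait two-state pruning via the generic kernel."""
    flat = flatten_tree(tree)
    Q = np.array([[-gain, gain], [loss, -loss]])
    P = propagators(Q, flat.branch_lengths)
    lookup = dict(zip(taxa, states))
    partials = np.zeros((flat.n_tips, 2))
    for i, lab in enumerate(flat.tip_labels):
        partials[i, lookup[lab]] = 1.0
    return prune_kernel(
        flat.postorder, flat.child_ptr, flat.child_idx, P, partials, flat.root,
        np.array([0.5, 0.5]),
    )


class TestPruningLikelihood:
    def test_matches_enumeration_on_small_trees(self, dep_rates):
        Q = build_generator(dep_rates)
        for n, seed in [(4, 1), (5, 2), (6, 3)]:
            tree = mv.simulate_yule_tree(n, seed=seed)
            pair = mv.simulate_ctmc_pair(tree, Q, root=0, seed=seed)
            assert pruning_loglik(tree, pair, Q) == pytest.approx(
                brute_force_loglik(tree, pair, Q), abs=1e-10
            )

    def test_two_tip_closed_form(self, dep_rates):
        Q = build_generator(dep_rates)
        tree = mv.parse_newick("(A:0.4,B:0.9);")
        pair = BinaryTraitPair(("A", "B"), [1, 0], [0, 1])
        sA, sB = pair.joint_states()
        PA = transition_probabilities(Q, 0.4)
        PB = transition_probabilities(Q, 0.9)
        expected = np.log(sum(0.25 * PA[r, sA] * PB[r, sB] for r in range(4)))
        assert pruning_loglik(tree, pair, Q) == pytest.approx(expected, abs=1e-12)

    def test_independent_model_factorizes(self, mid_tree):
        """Joint 4-state likelihood = product of per-trait 2-state likelihoods."""
        rates = mv.IndependentRates(0.3, 0.6, 0.8, 0.4)
        Q = build_generator(rates)
        pair = mv.simulate_ctmc_pair(mid_tree, Q, root=0, seed=5)
        joint = pruning_loglik(mid_tree, pair, Q)
        lx = two_state_loglik(mid_tree, pair.taxa, pair.trait_x, rates.alpha1, rates.beta1)
        ly = two_state_loglik(mid_tree, pair.taxa, pair.trait_y, rates.alpha2, rates.beta2)
        assert joint == pytest.approx(lx + ly, abs=1e-10)

    def test_invariant_to_child_order_and_tip_permutation(self, small_tree, dep_rates):
        Q = build_generator(dep_rates)
        pair = mv.simulate_ctmc_pair(small_tree, Q, root=0, seed=9)
        ref = pruning_loglik(small_tree, pair, Q)
        rotated = small_tree.clone(depth=1)
        for node in rotated.preorder_node_iter():
            node.set_child_nodes(list(reversed(node.child_nodes())))
        assert pruning_loglik(rotated, pair, Q) == pytest.approx(ref, abs=1e-12)
        perm = np.random.default_rng(1).permutation(len(pair.taxa))
        shuffled = BinaryTraitPair(
            tuple(np.array(pair.taxa)[perm]), pair.trait_x[perm], pair.trait_y[perm]
        )
        assert pruning_loglik(small_tree, shuffled, Q) == pytest.approx(ref, abs=1e-12)

    def test_dependent_mle_dominates_independent(self, mid_pair, mid_tree):
        """The independent model is nested in the dependent model."""
        ind = mv.IndependentRates(0.6, 0.6, 0.9, 0.9)
        li = pruning_loglik(mid_tree, mid_pair, build_generator(ind))
        # the dependent model can reproduce the independent likelihood exactly
        ld = pruning_loglik(mid_tree, mid_pair, build_generator(ind.to_dependent()))
        assert ld == pytest.approx(li, abs=1e-12)

    def test_missing_tip_state_errors(self, small_tree, dep_rates):
        pair = BinaryTraitPair(("nope", "x"), [0, 1], [0, 1])
        with pytest.raises(CoevoError, match="missing"):
            pruning_loglik(small_tree, pair, build_generator(dep_rates))


class TestStationaryDistribution:
    def test_stationary_is_left_null_vector(self, dep_rates):
        Q = build_generator(dep_rates)
        pi = stationary_distribution(Q)
        assert np.allclose(pi @ Q, 0.0, atol=1e-12)
        assert pi.sum() == pytest.approx(1.0)
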