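"""Low-level CTMC likelihood kernels.

Propagator matrices P(t) = expm(Qt) are computed for all branches at once
by eigendecomposition (with a scipy ``expm`` fallback when Q is close to
defective), and the postorder pruning recursion runs over a flattened tree
representation.  The recursion is JIT-compiled with numba when available;
a pure-numpy twin is kept both as fallback and as a cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm as _scipy_expm

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


def propagators(Q: np.ndarray, ts: np.ndarray) -> np.ndarray:
    """Stack of transition-probability matrices expm(Q t) for each t.

    Rows sum to one; small negative round-off entries are clipped to zero.
    """
    Q = np.asarray(Q, dtype=float)
    ts = np.asarray(ts, dtype=float)
    if np.any(ts < 0):
        raise ValueError("negative branch length")
    k = Q.shape[0]
    P = None
    try:
        w, V = np.linalg.eig(Q)
        Vinv = np.linalg.inv(V)
        if np.linalg.cond(V) < 1e10:
            E = np.exp(np.multiply.outer(ts, w))
            P = np.einsum("ij,bj,jk->bik", V, E, Vinv).real
    except np.linalg.LinAlgError:
        P = None
    if P is None or not np.all(np.abs(P.sum(axis=2) - 1.0) < 1e-9):
        # near-defective Q: scaling-and-squaring per unique branch length
        P = np.empty((ts.size, k, k))
        uniq, inv = np.unique(ts, return_inverse=True)
        mats = np.array([_scipy_expm(Q * t) for t in uniq])
        P = mats[inv]
    np.clip(P, 0.0, None, out=P)
    return P


@njit(cache=False)
def _prune_numba(postorder, child_ptr, child_idx, P, tip_partials, root, root_prior):
    n_nodes = P.shape[0]
    k = P.shape[1]
    partial = np.zeros((n_nodes, k))
    n_tips = tip_partials.shape[0]
    for i in range(n_tips):
        for s in range(k):
            partial[i, s] = tip_partials[i, s]
    log_scale = 0.0
    for ni in range(postorder.shape[0]):
        node = postorder[ni]
        prod = np.ones(k)
        for ci in range(child_ptr[ni], child_ptr[ni + 1]):
            child = child_idx[ci]
            for s in range(k):
                acc = 0.0
                for t in range(k):
                    acc += P[child, s, t] * partial[child, t]
                prod[s] *= acc
        total = 0.0
        for s in range(k):
            total += prod[s]
        if total <= 0.0:
            return -np.inf
        for s in range(k):
            partial[node, s] = prod[s] / total
        log_scale += np.log(total)
    like = 0.0
    for s in range(k):
        like += root_prior[s] * partial[root, s]
    if like <= 0.0:
        return -np.inf
    return np.log(like) + log_scale


def _prune_numpy(postorder, child_ptr, child_idx, P, tip_partials, root, root_prior):
    n_nodes, k = P.shape[0], P.shape[1]
    partial = np.zeros((n_nodes, k))
    partial[: tip_partials.shape[0]] = tip_partials
    log_scale = 0.0
    for ni, node in enumerate(postorder):
        prod = np.ones(k)
        for ci in range(child_ptr[ni], child_ptr[ni + 1]):
            child = child_idx[ci]
            prod *= P[child] @ partial[child]
        total = prod.sum()
        if total <= 0.0:
            return -np.inf
        partial[node] = prod / total
        log_scale += np.log(total)
    like = float(root_prior @ partial[root])
    if like <= 0.0:
        return -np.inf
    return np.log(like) + log_scale


prune_kernel = _prune_numba if _HAVE_NUMBA else _prune_numpy

# canonical rate order q12,q21,q13,q31,q24,q42,q34,q43 -> (from, to)
_RATE_FROM = np.array([0, 1, 0, 2, 1, 3, 2, 3], dtype=np.int64)
_RATE_TO = np.array([1, 0, 2, 0, 3, 1, 3, 2], dtype=np.int64)


@njit(cache=False)
def _loglik_rates_jit(
    rates, blens, postorder, child_ptr, child_idx, tip_partials, root, root_prior
):
    """Fused kernel: generator -> eigendecomposition -> propagators -> pruning.

    Returns nan when the eigen route is numerically unreliable; the caller
    falls back to the scipy expm path.
    """
    Q = np.zeros((4, 4), dtype=np.complex128)
    for r in range(8):
        Q[_RATE_FROM[r], _RATE_TO[r]] = rates[r]
    for i in range(4):
        s = 0.0
        for j in range(4):
            if j != i:
                s += Q[i, j].real
        Q[i, i] = -s
    w, V = np.linalg.eig(Q)
    Vinv = np.linalg.inv(V)
    n = blens.shape[0]
    P = np.empty((n, 4, 4))
    for b in range(n):
        e = np.exp(w * blens[b])
        for i in range(4):
            rowsum = 0.0
            for j in range(4):
                acc = 0.0 + 0.0j
                for l in range(4):
                    acc += V[i, l] * e[l] * Vinv[l, j]
                val = acc.real
                if val < 0.0:
                    val = 0.0
                P[b, i, j] = val
                rowsum += val
            if abs(rowsum - 1.0) > 1e-8:
                return np.nan
    return _prune_numba(
        postorder, child_ptr, child_idx, P, tip_partials, root, root_prior
    )


def loglik_for_rates(
    rates, blens, postorder, child_ptr, child_idx, tip_partials, root, root_prior
):
    """Pruning log-likelihood for eight canonical-order rates.

    Uses the fused JIT kernel when available and falls back to the robust
    eig/expm propagator route on numerical trouble.
    """
    if _HAVE_NUMBA:
        ll = _loglik_rates_jit(
            np.asarray(rates, dtype=float), blens, postorder, child_ptr, child_idx,
            tip_partials, root, root_prior,
        )
        if not np.isnan(ll):
            return float(ll)
    Q = np.zeros((4, 4))
    rates = np.asarray(rates, dtype=float)
    for r in range(8):
        Q[_RATE_FROM[r], _RATE_TO[r]] = rates[r]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    P = propagators(Q, blens)
    return float(
        prune_kernel(postorder, child_ptr, child_idx, P, tip_partials, root, root_prior)
    )
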