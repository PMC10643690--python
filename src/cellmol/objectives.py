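"""Contrastive objectives and continuous modern Hopfield retrieval.

Two objectives are provided.  InfoNCE scores a batch of matched
image/structure embedding pairs (x_i, z_i) with a symmetric softmax
cross-entropy over scaled cosine similarities,

    L = -1/N sum_i ln[ exp(t s_ii) / sum_j exp(t s_ij) ]
        -1/N sum_i ln[ exp(t s_ii) / sum_j exp(t s_ji) ],

with s_ij = x_i^T z_j and inverse temperature t.  InfoLOOB is the
leave-one-out variant whose denominators exclude the matched pair, applied
to embeddings first retrieved from continuous modern Hopfield memories:
the retrieval U softmax(beta U^T q) interpolates between the memory mean
(beta = 0) and the nearest stored pattern (beta -> infinity), reinforcing
the covariance structure shared by the batch.

Every function here is a pure numpy function; differentiable counterparts
for training (same math on autograd tensors) live alongside with a
``_t`` suffix.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp as _np_lse
from scipy.special import softmax as _np_softmax

from .nn import Tensor, l2_normalize, logsumexp as lse_t, softmax as softmax_t

__all__ = [
    "similarity_matrix", "infonce_loss", "hopfield_retrieve", "infoloob_loss",
    "bilinear_score", "bilinear_infonce",
    "infonce_loss_t", "hopfield_retrieve_t", "infoloob_loss_t",
]

_NORM_ATOL = 1e-5


def _check_normalized(A: np.ndarray, name: str) -> np.ndarray:
    A = np.asarray(A, dtype=np.float64)
    if A.ndim != 2:
        raise ValueError(f"{name} must be a 2-D matrix")
    norms = np.linalg.norm(A, axis=1)
    if not np.allclose(norms, 1.0, atol=_NORM_ATOL):
        raise ValueError(f"{name} rows must be unit-norm")
    return A


def similarity_matrix(X, Z) -> np.ndarray:
    """Cosine similarities s_ij = x_i^T z_j for unit-norm rows."""
    X = _check_normalized(X, "X")
    Z = _check_normalized(Z, "Z")
    if X.shape[1] != Z.shape[1]:
        raise ValueError("embedding dimensions differ")
    return X @ Z.T


def infonce_loss(X, Z, tau_inv: float) -> float:
    """Symmetric InfoNCE over a batch of matched pairs (row i of X matches
    row i of Z).  N=1 gives exactly 0 (the softmax is over the matched pair
    alone)."""
    if tau_inv <= 0:
        raise ValueError("tau_inv must be positive")
    S = similarity_matrix(X, Z)
    if S.shape[0] != S.shape[1]:
        raise ValueError("matched batches must have equal size")
    return _infonce_from_scores(tau_inv * S)


def _infonce_from_scores(S: np.ndarray) -> float:
    diag = np.diag(S)
    term_rows = float(np.mean(_np_lse(S, axis=1) - diag))
    term_cols = float(np.mean(_np_lse(S, axis=0) - diag))
    return term_rows + term_cols


def hopfield_retrieve(memory, queries, beta: float) -> np.ndarray:
    """Retrieve from a continuous modern Hopfield memory.

    retrieved_i = normalize( M^T softmax(beta M q_i) ) for memory rows M.
    beta = 0 returns the normalized memory mean for every query; large beta
    returns the stored row most similar to the query.
    """
    memory = np.asarray(memory, dtype=np.float64)
    if memory.ndim != 2 or memory.shape[0] == 0:
        raise ValueError("memory must be a nonempty (M, d) matrix")
    _check_normalized(memory, "memory")
    queries = np.atleast_2d(np.asarray(queries, dtype=np.float64))
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if queries.shape[1] != memory.shape[1]:
        raise ValueError("query and memory dimensions differ")
    weights = _np_softmax(beta * queries @ memory.T, axis=1)  # (K, M)
    retrieved = weights @ memory
    norms = np.linalg.norm(retrieved, axis=1, keepdims=True)
    return retrieved / norms


def infoloob_loss(X, Z, beta: float, tau_inv: float,
                  memory_x=None, memory_z=None) -> float:
    """InfoLOOB objective on Hopfield-retrieved embeddings.

    Image embeddings X and structure embeddings Z are both retrieved from
    the image memory U (giving U_x, U_z) and from the structure memory V
    (giving V_x, V_z); by default the memories are the current batch
    (U = X, V = Z).  The leave-one-out denominators exclude the matched
    pair, so N = 1 is rejected, and the loss can be negative.
    """
    X = _check_normalized(X, "X")
    Z = _check_normalized(Z, "Z")
    N = X.shape[0]
    if Z.shape[0] != N:
        raise ValueError("matched batches must have equal size")
    if N < 2:
        raise ValueError("InfoLOOB needs N >= 2 (leave-one-out denominator)")
    U = X if memory_x is None else _check_normalized(memory_x, "memory_x")
    V = Z if memory_z is None else _check_normalized(memory_z, "memory_z")
    U_x = hopfield_retrieve(U, X, beta)
    U_z = hopfield_retrieve(U, Z, beta)
    V_x = hopfield_retrieve(V, X, beta)
    V_z = hopfield_retrieve(V, Z, beta)
    return (_loob_term(U_x, U_z, tau_inv, rows_are_queries=True)
            + _loob_term(V_x, V_z, tau_inv, rows_are_queries=False))


def _loob_term(A: np.ndarray, B: np.ndarray, tau_inv: float,
               rows_are_queries: bool) -> float:
    S = tau_inv * (A @ B.T)
    diag = np.diag(S).copy()
    masked = S.copy()
    np.fill_diagonal(masked, -np.inf)
    axis = 1 if rows_are_queries else 0
    return float(np.mean(_np_lse(masked, axis=axis) - diag))


def bilinear_score(x, z, W) -> float:
    """Baseline bilinear compatibility x^T W z."""
    x = np.asarray(x, dtype=np.float64)
    z = np.asarray(z, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if W.shape != (x.shape[-1], z.shape[-1]):
        raise ValueError("W shape must be (dim_x, dim_z)")
    return float(x @ W @ z)


def bilinear_infonce(X_feat, Z_feat, W, tau_inv: float) -> float:
    """Symmetric InfoNCE with bilinear scores x_i^T W z_j replacing cosine
    similarities (features need not be normalized)."""
    X_feat = np.asarray(X_feat, dtype=np.float64)
    Z_feat = np.asarray(Z_feat, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if W.shape != (X_feat.shape[1], Z_feat.shape[1]):
        raise ValueError("W shape must be (dim_x, dim_z)")
    if X_feat.shape[0] != Z_feat.shape[0]:
        raise ValueError("matched batches must have equal size")
    if tau_inv <= 0:
        raise ValueError("tau_inv must be positive")
    S = tau_inv * (X_feat @ W @ Z_feat.T)
    return _infonce_from_scores(S)


# ---------------------------------------------------------------------------
# differentiable counterparts (identical math on autograd tensors)
# ---------------------------------------------------------------------------

def infonce_loss_t(X: Tensor, Z: Tensor, tau_inv: float) -> Tensor:
    S = (X @ Z.T) * tau_inv
    N = S.shape[0]
    diag_mask = np.eye(N)
    diag = (S * diag_mask).sum(axis=1)
    rows = (lse_t(S, axis=1).reshape(N) - diag).mean()
    cols = (lse_t(S, axis=0).reshape(N) - diag).mean()
    return rows + cols


def hopfield_retrieve_t(memory: Tensor, queries: Tensor, beta: float) -> Tensor:
    weights = softmax_t((queries @ memory.T) * beta, axis=1)
    return l2_normalize(weights @ memory)


def infoloob_loss_t(X: Tensor, Z: Tensor, beta: float, tau_inv: float) -> Tensor:
    N = X.shape[0]
    if N < 2:
        raise ValueError("InfoLOOB needs N >= 2")
    U_x = hopfield_retrieve_t(X, X, beta)
    U_z = hopfield_retrieve_t(X, Z, beta)
    V_x = hopfield_retrieve_t(Z, X, beta)
    V_z = hopfield_retrieve_t(Z, Z, beta)
    neg_inf_diag = np.where(np.eye(N) > 0, -1e30, 0.0)
    diag_mask = np.eye(N)

    def term(A, B, axis):
        S = (A @ B.T) * tau_inv
        diag = (S * diag_mask).sum(axis=1)
        masked = S + neg_inf_diag
        return (lse_t(masked, axis=axis).reshape(N) - diag).mean()

    return term(U_x, U_z, 1) + term(V_x, V_z, 0)
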