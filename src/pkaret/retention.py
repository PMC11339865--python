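"""The retention mechanism, in recurrent, parallel and graph-adapted forms.

Retention replaces softmax attention with a position-dependent exponential
decay.  In sequence form it is defined by the recurrence

    S_n = gamma * S_{n-1} + K_n^T V_n,        output_n = Q_n S_n,

with S_0 = 0, which is exactly equivalent to the parallel form

    output = ((Q K^T) . D) V,   D[n, m] = gamma^(n-m) for n >= m else 0,

where ``.`` is the elementwise product.  Molecules have no canonical atom
order, so the graph adaptation used inside the network replaces the causal
decay with the symmetric D[i, j] = gamma^d(i, j), d being the topological
(bond-hop) distance: the fewer bonds between two atoms, the stronger their
interaction.  This keeps the operator permutation-equivariant.

Multi-head graph retention additionally injects the scaled adjacency,
topological-distance and Coulomb matrices as additive biases on the per-head
score matrix Q K^T (heads assigned round-robin across the three matrices),
and the concatenated heads are group-normalized before the output mix —
GroupNorm's invariance to positive rescaling stabilizes the un-normalized
decay weighting.

All functions are polymorphic over ``numpy.ndarray`` and
:class:`~pkaret.autodiff.Tensor`, so the same code serves inference, oracle
tests and training.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

from .autodiff import Tensor, concatenate, exp
from .chem_graph import InterAtomicMatrices

BIAS_MATRICES = ("adjacency", "distance", "coulomb")


def gamma_schedule(n_heads: int) -> np.ndarray:
    """Per-head decay values gamma_h = 1 - 2**(-5 - h), spanning strong to weak."""
    return 1.0 - 2.0 ** (-5.0 - np.arange(n_heads))


@dataclass
class RetentionParams:
    """Weights and configuration of one multi-head retention block.

    ``Wq``/``Wk``/``Wv`` map the model dimension to ``n_heads * head_dim``
    columns (head h owns the contiguous slice ``h*head_dim:(h+1)*head_dim``);
    ``Wo`` mixes the concatenated heads back to the output dimension.
    Weights may be plain arrays (inference) or autodiff tensors (training).
    """

    n_heads: int
    head_dim: int
    gammas: np.ndarray
    Wq: Any
    Wk: Any
    Wv: Any
    Wo: Any
    bias_assignment: tuple[str, ...]
    n_groups: int

    def __post_init__(self) -> None:
        g = np.asarray(self.gammas, dtype=float)
        if g.shape != (self.n_heads,) or np.any(g <= 0) or np.any(g >= 1):
            raise ValueError("need one gamma per head with 0 < gamma < 1")
        if len(self.bias_assignment) != self.n_heads:
            raise ValueError("bias_assignment must name one matrix per head")
        bad = set(self.bias_assignment) - set(BIAS_MATRICES) - {"none"}
        if bad:
            raise ValueError(f"unknown bias matrices: {sorted(bad)}")
        if any(b != "none" for b in self.bias_assignment) and self.n_heads % 3:
            raise ValueError("bias injection requires n_heads divisible by 3")

    @classmethod
    def create(cls, d_model: int, n_heads: int, rng: np.random.Generator,
               use_bias: bool = True, n_groups: int | None = None,
               trainable: bool = False) -> "RetentionParams":
        if d_model % n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        hd = d_model // n_heads
        scale = 1.0 / np.sqrt(d_model)

        def w(rows, cols):
            m = rng.normal(0.0, scale, size=(rows, cols))
            return Tensor(m, requires_grad=True) if trainable else m

        assignment = tuple(BIAS_MATRICES[h % 3] if use_bias else "none"
                           for h in range(n_heads))
        return cls(n_heads=n_heads, head_dim=hd, gammas=gamma_schedule(n_heads),
                   Wq=w(d_model, n_heads * hd), Wk=w(d_model, n_heads * hd),
                   Wv=w(d_model, n_heads * hd), Wo=w(n_heads * hd, d_model),
                   bias_assignment=assignment,
                   n_groups=n_groups if n_groups is not None else n_heads)

    def weights(self) -> list[Any]:
        return [self.Wq, self.Wk, self.Wv, self.Wo]


def recurrent_retention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                        gamma: float) -> tuple[np.ndarray, np.ndarray]:
    """Step-by-step evaluation of the retention recurrence (sequence mode).

    Rows of Q, K, V are the per-step vectors.  Returns the per-step outputs
    (L x d_v) and the final state S_L = sum_m gamma^(L-m) K_m^T V_m.
    """
    Q, K, V = (np.atleast_2d(np.asarray(m, dtype=float)) for m in (Q, K, V))
    if not (len(Q) == len(K) == len(V)):
        raise ValueError("Q, K, V must have equal sequence lengths")
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must lie in [0, 1)")
    S = np.zeros((K.shape[1], V.shape[1]))
    outputs = np.zeros((len(Q), V.shape[1]))
    for n in range(len(Q)):
        S = gamma * S + np.outer(K[n], V[n])
        outputs[n] = Q[n] @ S
    return outputs, S


def sequence_decay_matrix(length: int, gamma: float) -> np.ndarray:
    """Causal decay D[n, m] = gamma^(n-m) for n >= m, zero above the diagonal."""
    n = np.arange(length)
    diff = n[:, None] - n[None, :]
    return np.where(diff >= 0, float(gamma) ** np.maximum(diff, 0), 0.0)


def graph_decay_matrix(Dtop: np.ndarray, gamma: float) -> np.ndarray:
    """Symmetric decay D[i, j] = gamma^Dtop[i, j]; diagonal 1, entries in (0, 1]."""
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    Dtop = np.asarray(Dtop, dtype=float)
    if Dtop.ndim != 2 or Dtop.shape[0] != Dtop.shape[1]:
        raise ValueError("Dtop must be square")
    if np.any(Dtop < 0) or not np.allclose(Dtop, Dtop.T):
        raise ValueError("Dtop must be symmetric and non-negative")
    return float(gamma) ** Dtop


def parallel_retention(Q, K, V, D):
    """Parallel form ((Q K^T) . D) V; the dual of the recurrence.

    In sequence mode (causal D) this matches :func:`recurrent_retention` to
    numerical precision; with a graph decay matrix it is the
    permutation-equivariant operator used in the network.
    """
    qn = Q.shape[0]
    if K.shape[0] != qn or V.shape[0] != K.shape[0]:
        raise ValueError("Q, K, V row counts must agree")
    if D.shape != (qn, K.shape[0]):
        raise ValueError(f"decay matrix shape {D.shape} != ({qn}, {K.shape[0]})")
    return ((Q @ K.T) * D) @ V


def group_normalize(X, n_groups: int, eps: float = 1e-5):
    """Per-row GroupNorm: zero mean, unit variance within each channel group.

    Invariant to positive rescaling of the input (up to eps), which is what
    makes the un-normalized retention scores numerically safe.
    """
    n, d = X.shape
    if d % n_groups:
        raise ValueError(f"feature dim {d} not divisible by {n_groups} groups")
    xr = X.reshape(n, n_groups, d // n_groups)
    mu = xr.mean(axis=2, keepdims=True)
    cen = xr - mu
    var = (cen ** 2).mean(axis=2, keepdims=True)
    return (cen * (var + eps) ** -0.5).reshape(n, d)


def _softmax_rows(S):
    if isinstance(S, Tensor):
        shift = S.data.max(axis=-1, keepdims=True)
    else:
        shift = S.max(axis=-1, keepdims=True)
    e = exp(S - shift)
    return e / e.sum(axis=-1, keepdims=True)


def _head_scores(X, mats, params: RetentionParams, h: int, use_bias_mats: bool):
    sl = (slice(None), slice(h * params.head_dim, (h + 1) * params.head_dim))
    Q = X @ params.Wq[sl]
    K = X @ params.Wk[sl]
    V = X @ params.Wv[sl]
    scores = Q @ K.T
    name = params.bias_assignment[h]
    if use_bias_mats and name != "none":
        if mats is None:
            raise ValueError(f"head {h} requires the scaled {name} matrix "
                             "but no InterAtomicMatrices were provided")
        scores = scores + mats.scaled(name)
    return scores, V


def biased_multihead_retention(X, mats: InterAtomicMatrices | None,
                               params: RetentionParams, Dtop: np.ndarray,
                               use_bias_mats: bool = True):
    """Multi-head graph retention over atom (or bond) tokens.

    Per head h: scores = Q_h K_h^T + B_h with B_h the head's scaled
    inter-atomic matrix ("none" -> no bias); output_h = (scores . D_h) V_h
    with D_h = gamma_h^Dtop.  Heads are concatenated, group-normalized and
    linearly mixed; output shape equals input shape.
    """
    outs = []
    for h in range(params.n_heads):
        scores, V = _head_scores(X, mats, params, h, use_bias_mats)
        D = graph_decay_matrix(Dtop, params.gammas[h])
        outs.append((scores * D) @ V)
    mixed = group_normalize(concatenate(outs, axis=1), params.n_groups)
    return mixed @ params.Wo


def biased_multihead_attention(X, mats: InterAtomicMatrices | None,
                               params: RetentionParams, Dtop: np.ndarray,
                               use_bias_mats: bool = True):
    """Ablation stand-in: scaled dot-product softmax attention with the same
    bias-matrix injection, so swapping it against retention isolates the
    decay mechanism.  ``Dtop`` is accepted and ignored."""
    outs = []
    inv_sqrt = 1.0 / np.sqrt(params.head_dim)
    for h in range(params.n_heads):
        scores, V = _head_scores(X, mats, params, h, use_bias_mats)
        outs.append(_softmax_rows(scores * inv_sqrt) @ V)
    mixed = group_normalize(concatenate(outs, axis=1), params.n_groups)
    return mixed @ params.Wo
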