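"""The node-and-edge pooling layer primitives (pure numpy reference ops).

One pooling step on a graph with node representations Z and adjacency A:

1. *Attention features*  H = f(D̃⁻¹ Ã Z Θ) with Ã = A + I — one round of
   row-normalised neighbourhood aggregation, so a node's attention feature
   mixes its own features with its neighbours'.
2. *Attention scores*    Att_i = cos(p, H_i) ∈ [−1, 1] — cosine of the angle
   between the attention feature and a trainable projection vector p.
3. *Top-k selection*     keep the k best-scoring gene nodes (drug nodes are
   always retained — they feed the readout).
4. *Edge re-weighting*   A' = A(idx, idx) ∘ W(gids, gids), a Hadamard product
   with a trainable, globally indexed symmetric weight matrix, so the same
   gene–gene interaction has the same learned strength in every sample.
5. *Edge filtering*      keep the top fraction of edges by |weight|.

These functions are the layer's reference semantics, written for clarity and
used directly by the tests; the trainable model composes the same arithmetic
from autodiff tensors.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import numpy as np

__all__ = [
    "PoolLayerParams",
    "PoolState",
    "EdgeMLPParams",
    "attention_features",
    "attention_scores",
    "topk_select",
    "pool_graph",
    "edge_filter",
    "edge_filter_mask",
    "edge_attention_mlp",
]

_NORM_EPS = 1e-12


@dataclasses.dataclass
class PoolLayerParams:
    """Trainable quantities of one pooling layer.

    ``edge_weights`` is indexed by the *global* node vocabulary (all genes in
    sorted order plus two drug slots); it is stored dense and symmetrised as
    (W + Wᵀ)/2 wherever it is applied.
    """

    theta: np.ndarray            # hₜ × hₜ₊₁ attention-feature projection
    proj: np.ndarray             # hₜ₊₁ attention direction
    edge_weights: np.ndarray     # N × N over the global vocabulary
    k: int | float               # node budget (count, or fraction of genes)
    edge_keep_fraction: float = 0.9

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.proj = np.asarray(self.proj, dtype=float).ravel()
        self.edge_weights = np.asarray(self.edge_weights, dtype=float)
        if isinstance(self.k, float) and not (0.0 < self.k <= 1.0):
            raise ValueError("fractional k must lie in (0, 1]")
        if isinstance(self.k, int) and self.k <= 0:
            raise ValueError("k must be positive")
        if not (0.0 < self.edge_keep_fraction <= 1.0):
            raise ValueError("edge_keep_fraction must lie in (0, 1]")

    @property
    def edge_weights_sym(self) -> np.ndarray:
        return 0.5 * (self.edge_weights + self.edge_weights.T)


@dataclasses.dataclass
class PoolState:
    """Per-layer trace kept for interpretability."""

    attention: np.ndarray          # score of every node entering the layer
    kept_idx: np.ndarray           # retained positions (ascending)
    pooled_adjacency: np.ndarray   # weighted adjacency after filtering
    kept_global_ids: np.ndarray    # global vocabulary ids of retained nodes


@dataclasses.dataclass
class EdgeMLPParams:
    """Two-layer MLP scoring a concatenated node-feature pair (optional mode)."""

    w1: np.ndarray   # 2h × m
    b1: np.ndarray   # m
    w2: np.ndarray   # m
    b2: float = 0.0


def attention_features(Z, A, theta, activation=np.tanh) -> np.ndarray:
    """Row-normalised propagation H = f(D̃⁻¹ Ã Z Θ), Ã = A + I.

    The self-loop guarantees every row degree is ≥ 1, so the normalisation is
    always defined.  ``A`` may carry non-negative edge weights.
    """
    Z = np.asarray(Z, dtype=float)
    A = np.asarray(A, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n = A.shape[0]
    if A.shape != (n, n):
        raise ValueError("adjacency must be square")
    if Z.shape[0] != n:
        raise ValueError(f"Z has {Z.shape[0]} rows but A has {n} nodes")
    if theta.shape[0] != Z.shape[1]:
        raise ValueError("theta rows must match the feature dimension of Z")
    A_tilde = A + np.eye(n)
    deg = A_tilde.sum(axis=1)
    return activation((A_tilde @ Z @ theta) / deg[:, None])


def attention_scores(H, proj) -> np.ndarray:
    """Cosine between each attention-feature row and the projection vector.

    Rows with vanishing norm score 0 (the neutral cosine).  All outputs lie
    in [−1, 1] by construction.
    """
    H = np.asarray(H, dtype=float)
    proj = np.asarray(proj, dtype=float).ravel()
    # one summation kernel for all three products keeps the arithmetic
    # consistent, so exactly collinear rows satisfy dots² == nn_h·nn_p in
    # floating point and can be mapped to exactly ±1
    nn_p = float(np.sum(proj * proj))
    if nn_p == 0.0:
        raise ValueError("projection vector must be non-zero")
    nn_h = np.sum(H * H, axis=1)
    dots = np.sum(H * proj, axis=1)
    prod = nn_h * nn_p
    ok = nn_h > _NORM_EPS ** 2
    scores = np.zeros(H.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        scores[ok] = dots[ok] / np.sqrt(prod[ok])
    collinear = ok & (dots * dots == prod)
    scores[collinear] = np.sign(dots[collinear])
    return np.clip(scores, -1.0, 1.0)


def _resolve_k(k, n_genes: int) -> int:
    if isinstance(k, bool) or not isinstance(k, (int, float, np.integer, np.floating)):
        raise TypeError("k must be an int count or a fraction in (0, 1]")
    if isinstance(k, (float, np.floating)):
        # floats are fractions of the gene count (1.0 keeps every gene)
        if not (0.0 < k <= 1.0):
            raise ValueError("fractional k must lie in (0, 1]")
        return math.ceil(k * n_genes)
    k = int(k)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n_genes:
        warnings.warn(
            f"k={k} exceeds the {n_genes} gene nodes; keeping all genes",
            stacklevel=2,
        )
        return n_genes
    return k


def topk_select(att, k, protected=(), global_ids=None) -> np.ndarray:
    """Positions of the k best-scoring unprotected nodes plus all protected.

    ``k`` counts gene (unprotected) nodes only; a fractional ``k`` keeps
    ⌈k·n_genes⌉ of them.  Score ties break toward the smaller global id.
    The result is sorted ascending by position.
    """
    att = np.asarray(att, dtype=float).ravel()
    n = att.shape[0]
    protected = np.asarray(sorted(protected), dtype=np.intp)
    if protected.size and (protected.min() < 0 or protected.max() >= n):
        raise IndexError("protected positions out of range")
    gids = np.arange(n) if global_ids is None else np.asarray(global_ids)
    mask = np.ones(n, dtype=bool)
    mask[protected] = False
    gene_pos = np.flatnonzero(mask)
    kk = _resolve_k(k, gene_pos.size)
    order = np.lexsort((gids[gene_pos], -att[gene_pos]))
    kept = gene_pos[order[:kk]]
    return np.sort(np.concatenate([kept, protected]))


def pool_graph(A, Z, idx, W_global, global_ids):
    """Induced-subgraph pooling with globally indexed edge re-weighting.

    Returns ``(A_next, Z_kept)`` where ``A_next = A(idx,idx) ∘ W(gids,gids)``
    (W symmetrised first) and ``Z_kept = Z(idx,:)``.  Zero entries of the
    induced adjacency stay zero — the Hadamard product never creates edges.
    """
    A = np.asarray(A, dtype=float)
    Z = np.asarray(Z, dtype=float)
    idx = np.asarray(idx, dtype=np.intp)
    W = np.asarray(W_global, dtype=float)
    gids = np.asarray(global_ids)[idx]
    W_sym = 0.5 * (W + W.T)
    A_next = A[np.ix_(idx, idx)] * W_sym[np.ix_(gids, gids)]
    return A_next, Z[idx]


def _undirected_edges(A):
    iu, ju = np.triu_indices(A.shape[0], k=1)
    nz = A[iu, ju] != 0
    return iu[nz], ju[nz]


def edge_filter_mask(A_weighted, keep_fraction, node_ids=None,
                     total_edges=None) -> np.ndarray:
    """Boolean mask of the surviving entries of :func:`edge_filter`."""
    A = np.asarray(A_weighted, dtype=float)
    if not (0.0 < keep_fraction <= 1.0):
        raise ValueError("keep_fraction must lie in (0, 1]")
    if not np.allclose(A, A.T):
        raise ValueError("weighted adjacency must be symmetric")
    n = A.shape[0]
    ids = np.arange(n) if node_ids is None else np.asarray(node_ids)
    iu, ju = _undirected_edges(A)
    n_edges = iu.size
    budget = n_edges if total_edges is None else int(total_edges)
    keep_count = min(n_edges, math.ceil(keep_fraction * budget))
    mask = np.zeros((n, n), dtype=bool)
    if n_edges == 0:
        return mask
    w = np.abs(A[iu, ju])
    gi = np.minimum(ids[iu], ids[ju])
    gj = np.maximum(ids[iu], ids[ju])
    # primary: largest |weight|; ties: lexicographically smaller global-id pair
    order = np.lexsort((gj, gi, -w))
    keep = order[:keep_count]
    mask[iu[keep], ju[keep]] = True
    mask[ju[keep], iu[keep]] = True
    return mask


def edge_filter(A_weighted, keep_fraction, node_ids=None,
                total_edges=None) -> np.ndarray:
    """Keep the ⌈keep_fraction · E⌉ undirected edges of largest |weight|.

    ``E`` is the layer's edge budget: by default the number of nonzero
    undirected edges of the input, or ``total_edges`` when the caller pins
    the budget (re-applying the filter with a pinned budget is a no-op).
    Removed edges are zeroed symmetrically.
    """
    mask = edge_filter_mask(A_weighted, keep_fraction, node_ids, total_edges)
    return np.where(mask, np.asarray(A_weighted, dtype=float), 0.0)


def edge_attention_mlp(H, mlp_params: EdgeMLPParams, node_cap: int = 512) -> np.ndarray:
    """Pairwise edge attention e_ij = relu(MLP(H_i ∥ H_j)) (optional mode).

    Materialises all n² concatenated pairs, so it refuses graphs above
    ``node_cap`` nodes: the quadratic memory cost is the reason the default
    mode uses the globally indexed weight matrix instead.
    The result is symmetrised as (e + eᵀ)/2.
    """
    H = np.asarray(H, dtype=float)
    n, h = H.shape
    if n > node_cap:
        raise ValueError(
            f"pairwise edge attention on {n} nodes exceeds the cap of "
            f"{node_cap}: the n²·h memory cost of materialising all pairs "
            "is prohibitive; use the global edge-weight mode instead"
        )
    w1 = np.asarray(mlp_params.w1, dtype=float)
    if w1.shape[0] != 2 * h:
        raise ValueError("w1 must have 2h rows")
    left, right = w1[:h], w1[h:]
    pre = (H @ left)[:, None, :] + (H @ right)[None, :, :] + np.asarray(mlp_params.b1)
    hid = np.maximum(pre, 0.0)
    raw = hid @ np.asarray(mlp_params.w2, dtype=float).ravel() + float(mlp_params.b2)
    e = np.maximum(raw, 0.0)
    return 0.5 * (e + e.T)
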