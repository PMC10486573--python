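"""Hierarchical pooling model: alternating pool/GNN blocks and readout.

Architecture (defaults follow the published configuration: two graph
convolution layers, two pooling layers, 200 genes kept in the last layer,
90% of edges kept per pooling layer):

    Z⁰ = X  →  [pool → GCN] × n_pool_layers  →  (extra GCNs, if any)
           →  score = u₁ᵀ Dᵀ D u₂   (pair factorisation readout)
                or  MLP(u)          (single-drug head)

where u₁, u₂ are the final representations of the drug nodes.  The first
pooling layer scores nodes directly on the raw 3-dimensional features
(expression and the two drug-target indicators), so node selection is
load-bearing: the only route from gene information to the drug-centred
readout is through the genes that survive pooling.  Every propagation uses
the row-normalised rule f(D̃⁻¹ Ã Z Θ); the attention branch uses tanh
(bounded features stabilise the cosine), representation layers use a leaky
rectifier (the small negative slope prevents the dead-unit collapse a hard
rectifier is prone to in narrow graph networks).  After top-k selection the
kept *gene* rows are gated by their attention score so the attention
parameters receive gradient through the prediction loss; drug rows pass
through ungated.

Two architectural details make the score exactly invariant under the
documented drug-swap contract: the first-layer weights of the two drug
indicator feature columns are tied (in both the attention and the
representation branch), and the global edge-weight matrices are symmetrised
at every use.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .autodiff import Tensor
from .network_io import MolecularNetwork
from .pooling import PoolState, edge_filter_mask, topk_select

__all__ = [
    "ModelConfig",
    "ModelParams",
    "init_params",
    "forward",
    "predict",
    "readout_pair",
    "readout_single",
    "save_checkpoint",
    "load_checkpoint",
    "swap_drug_slots",
]


@dataclasses.dataclass
class ModelConfig:
    """Hyperparameters of the hierarchical pooling model."""

    n_gnn_layers: int = 2
    n_pool_layers: int = 2
    hidden_dims: tuple = (64, 64)          # one entry per embedding GCN layer
    k_schedule: tuple = (400, 200)         # genes kept per pooling layer
    edge_keep_fraction: float = 0.9
    readout: str = "pair_factorization"    # or "single_mlp"
    edge_mode: str = "global_w"            # or "mlp" (pairwise attention)
    mlp_hidden: int = 16
    mlp_node_cap: int = 512
    seed: int = 0

    def __post_init__(self):
        self.hidden_dims = tuple(self.hidden_dims)
        self.k_schedule = tuple(self.k_schedule)
        if len(self.hidden_dims) != self.n_gnn_layers:
            raise ValueError("hidden_dims must have one entry per GNN layer")
        if self.n_gnn_layers < self.n_pool_layers:
            raise ValueError("need at least one GNN layer per pooling layer")
        if len(self.k_schedule) != self.n_pool_layers:
            raise ValueError("k_schedule must have one entry per pool layer")
        ks = [k for k in self.k_schedule]
        if any(b > a for a, b in zip(ks, ks[1:])):
            raise ValueError("k_schedule must be non-increasing")
        if not (0.0 < self.edge_keep_fraction <= 1.0):
            raise ValueError("edge_keep_fraction must lie in (0, 1]")
        if self.readout not in ("pair_factorization", "single_mlp"):
            raise ValueError(f"unknown readout: {self.readout!r}")
        if self.edge_mode not in ("global_w", "mlp"):
            raise ValueError(f"unknown edge_mode: {self.edge_mode!r}")

    @property
    def dim(self) -> int:
        """Representation width carried through pooling and readout."""
        return self.hidden_dims[-1]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclasses.dataclass
class ModelParams:
    """All trainable tensors, keyed by role."""

    tensors: dict[str, Tensor]
    n_vocab: int

    def all(self) -> list[Tensor]:
        return list(self.tensors.values())

    def __getitem__(self, key: str) -> Tensor:
        return self.tensors[key]

    def groups(self) -> dict[str, list[str]]:
        """Parameter names by role (attention / edge weights / GNN / decoder)."""
        out: dict[str, list[str]] = {"theta_att": [], "proj": [], "edge_w": [],
                                     "gnn": [], "decoder": []}
        for name in self.tensors:
            if "theta_att" in name:
                out["theta_att"].append(name)
            elif "proj" in name:
                out["proj"].append(name)
            elif name.endswith("_W") or "_mlp_" in name:
                out["edge_w"].append(name)
            elif "gnn" in name:
                out["gnn"].append(name)
            else:
                out["decoder"].append(name)
        return out


def _glorot(rng, fan_in, fan_out, shape=None):
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=shape or (fan_in, fan_out))


def init_params(cfg: ModelConfig, n_vocab: int,
                rng: np.random.Generator | None = None) -> ModelParams:
    """Initialise parameters for a vocabulary of ``n_vocab`` genes.

    Global edge-weight matrices start at all-ones so the untrained layer
    reduces to plain induced-subgraph pooling.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    N = n_vocab + 2  # two reserved drug slots
    t: dict[str, Tensor] = {}

    prev = 3  # raw features: expression + two drug-target indicators
    for p in range(cfg.n_pool_layers):
        h = cfg.hidden_dims[p]
        # attention weights and projections start non-negative: before any
        # training a node's score then increases with its expression and
        # drug-target indicators, encoding the prior that targeted,
        # transcriptionally active genes drive synergy (and breaking the
        # sign symmetry of the cosine, under which "select" and "discard"
        # basins are otherwise interchangeable)
        if p == 0:
            # layer-0 maps act on raw features; the two indicator rows are
            # tied (stored as 2×h: [expression row; shared indicator row])
            t["pool0_theta_att_tied"] = Tensor(np.abs(_glorot(rng, 3, h, (2, h))),
                                               requires_grad=True)
            t["pool0_gnn_tied"] = Tensor(_glorot(rng, 3, h, (2, h)),
                                         requires_grad=True)
        else:
            t[f"pool{p}_theta_att"] = Tensor(np.abs(_glorot(rng, prev, h)),
                                             requires_grad=True)
            t[f"pool{p}_gnn"] = Tensor(_glorot(rng, prev, h),
                                       requires_grad=True)
        t[f"pool{p}_proj"] = Tensor(np.abs(rng.standard_normal((h, 1))),
                                    requires_grad=True)
        if cfg.edge_mode == "global_w":
            t[f"pool{p}_W"] = Tensor(np.ones((N, N)), requires_grad=True)
        else:
            m = cfg.mlp_hidden
            t[f"pool{p}_mlp_wl"] = Tensor(_glorot(rng, h, m), requires_grad=True)
            t[f"pool{p}_mlp_wr"] = Tensor(_glorot(rng, h, m), requires_grad=True)
            t[f"pool{p}_mlp_b1"] = Tensor(np.zeros((1, m)), requires_grad=True)
            t[f"pool{p}_mlp_w2"] = Tensor(rng.standard_normal((m, 1)) / np.sqrt(m),
                                          requires_grad=True)
            t[f"pool{p}_mlp_b2"] = Tensor(np.zeros((1, 1)), requires_grad=True)
        prev = h

    # any GNN layers beyond the pool blocks run after the last pooling step
    for layer in range(cfg.n_pool_layers, cfg.n_gnn_layers):
        h = cfg.hidden_dims[layer]
        t[f"final_gnn{layer}"] = Tensor(_glorot(rng, prev, h),
                                        requires_grad=True)
        prev = h

    if cfg.readout == "pair_factorization":
        t["decoder_D"] = Tensor(_glorot(rng, prev, prev), requires_grad=True)
    else:
        m = max(cfg.mlp_hidden, 4)
        t["head_w1"] = Tensor(_glorot(rng, prev, m), requires_grad=True)
        t["head_b1"] = Tensor(np.zeros((1, m)), requires_grad=True)
        t["head_w2"] = Tensor(rng.standard_normal((m, 1)) / np.sqrt(m),
                              requires_grad=True)
        t["head_b2"] = Tensor(np.zeros((1, 1)), requires_grad=True)
    return ModelParams(tensors=t, n_vocab=n_vocab)


# ---------------------------------------------------------------------------
# differentiable building blocks
# ---------------------------------------------------------------------------

def _propagate(A: Tensor, Z: Tensor, theta: Tensor) -> Tensor:
    """Row-normalised propagation (D̃⁻¹ Ã Z Θ) on a possibly weighted A.

    Degrees use |Ã| row sums so trained (possibly negative) edge weights can
    never drive the normaliser through zero; for non-negative adjacencies
    this coincides with the plain row-sum rule.
    """
    n = A.shape[0]
    eye = Tensor(np.eye(n))
    A_tilde = A + eye
    deg = A_tilde.abs().sum(axis=1, keepdims=True).clip_min(1e-8)
    return (A_tilde @ Z @ theta) / deg


def _cosine_scores(H: Tensor, proj: Tensor) -> Tensor:
    """Differentiable cosine attention; returns an n×1 column."""
    eps = 1e-12
    dots = H @ proj                                        # n×1
    nn_h = (H * H).sum(axis=1, keepdims=True)              # n×1
    nn_p = (proj * proj).sum()                             # 0-d
    denom = (nn_h * nn_p).clip_min(eps ** 2).sqrt()
    guard = Tensor((nn_h.data > eps ** 2).astype(float))
    return dots / denom * guard


def forward(net: MolecularNetwork, params: ModelParams, cfg: ModelConfig):
    """Predict a synergy score; returns ``(score: Tensor, trace: [PoolState])``.

    The trace records, per pooling layer, the attention scores over the
    incoming nodes, the retained positions and global ids, and the pooled
    weighted adjacency — the raw material for the importance analysis.
    """
    if cfg.readout == "pair_factorization" and len(net.drug_positions) != 2:
        raise ValueError("pair_factorization readout requires two drug nodes")
    if cfg.readout == "single_mlp" and len(net.drug_positions) != 1:
        raise ValueError("single_mlp readout requires exactly one drug node")

    A = Tensor(net.adjacency)
    Z = Tensor(net.node_features)
    gids = net.global_node_ids.copy()
    drug_pos = np.asarray(net.drug_positions, dtype=np.intp)

    def _theta(name_tied, name_plain, p):
        # layer-0 maps expand the tied 2-row store to rows [expr, ind, ind]
        if p == 0:
            return params[name_tied].take_rows([0, 1, 1])
        return params[name_plain]

    trace: list[PoolState] = []
    for p in range(cfg.n_pool_layers):
        theta_att = _theta("pool0_theta_att_tied", f"pool{p}_theta_att", p)
        H = _propagate(A, Z, theta_att).tanh()
        att = _cosine_scores(H, params[f"pool{p}_proj"])
        att_np = att.data.ravel()
        idx = topk_select(att_np, cfg.k_schedule[p],
                          protected=drug_pos, global_ids=gids)
        kept_gids = gids[idx]

        # induced subgraph, re-weighted edge strengths
        A_sub = A.take_submatrix(idx)
        if cfg.edge_mode == "global_w":
            W_sym = params[f"pool{p}_W"].symmetrize()
            A_w = A_sub * W_sym.take_submatrix(kept_gids)
        else:
            if H.shape[0] > cfg.mlp_node_cap:
                raise ValueError(
                    f"pairwise edge attention on {H.shape[0]} nodes exceeds "
                    f"the cap of {cfg.mlp_node_cap}: the quadratic memory "
                    "cost of scoring all pairs is prohibitive"
                )
            E = H.pairwise_mlp(params[f"pool{p}_mlp_wl"],
                               params[f"pool{p}_mlp_wr"],
                               params[f"pool{p}_mlp_b1"],
                               params[f"pool{p}_mlp_w2"],
                               params[f"pool{p}_mlp_b2"]).symmetrize()
            A_w = A_sub * E.take_submatrix(idx)

        mask = edge_filter_mask(A_w.data, cfg.edge_keep_fraction,
                                node_ids=kept_gids)
        A_next = A_w * Tensor(mask.astype(float))

        # keep + gate: gene rows scaled by (1+att)/2 ∈ [0,1], drug rows pass
        # through.  The gate is a positive monotone map of the score, so a
        # gene can only be informative downstream by scoring high — with a
        # signed gate the model can park informative genes at att ≈ −1 (a
        # harmless sign flip) and the selection loses its meaning.
        Z_kept = Z.take_rows(idx)
        is_drug = np.isin(idx, drug_pos)
        gene_col = Tensor((~is_drug).astype(float)[:, None])
        gate = (att.take_rows(idx) + 1.0) * 0.5 * gene_col \
            + Tensor(is_drug.astype(float)[:, None])
        Z_gated = Z_kept * gate

        theta_gnn = _theta("pool0_gnn_tied", f"pool{p}_gnn", p)
        Z = _propagate(A_next, Z_gated, theta_gnn).leaky_relu(0.1)
        _check_finite(Z, f"pool layer {p}")

        trace.append(PoolState(
            attention=att_np.copy(),
            kept_idx=idx.copy(),
            pooled_adjacency=A_next.data.copy(),
            kept_global_ids=kept_gids.copy(),
        ))
        # re-index for the next layer
        pos_of = {old: new for new, old in enumerate(idx)}
        drug_pos = np.asarray([pos_of[d] for d in drug_pos], dtype=np.intp)
        gids = kept_gids
        A = A_next

    for layer in range(cfg.n_pool_layers, cfg.n_gnn_layers):
        Z = _propagate(A, Z, params[f"final_gnn{layer}"]).leaky_relu(0.1)
        _check_finite(Z, f"final GNN layer {layer}")

    if cfg.readout == "pair_factorization":
        D = params["decoder_D"]
        u1 = Z.take_rows([drug_pos[0]]).transpose()   # h×1
        u2 = Z.take_rows([drug_pos[1]]).transpose()
        score = ((D @ u1).transpose() @ (D @ u2)).sum()
    else:
        u = Z.take_rows([drug_pos[0]])                # 1×h
        hid = (u @ params["head_w1"] + params["head_b1"]).relu()
        score = (hid @ params["head_w2"] + params["head_b2"]).sum()
    _check_finite(score, "readout")
    return score, trace


def _check_finite(t: Tensor, where: str) -> None:
    if not np.all(np.isfinite(t.data)):
        raise FloatingPointError(f"non-finite values produced in {where}")


def predict(net: MolecularNetwork, params: ModelParams, cfg: ModelConfig):
    """Forward pass returning a plain float and the pooling trace."""
    score, trace = forward(net, params, cfg)
    return float(score.data), trace


# ---------------------------------------------------------------------------
# readout reference functions (pure numpy contracts)
# ---------------------------------------------------------------------------

def readout_pair(u1, u2, D) -> float:
    """Factorisation decoder score = u₁ᵀ Dᵀ D u₂ (symmetric in u₁, u₂)."""
    u1 = np.asarray(u1, dtype=float).ravel()
    u2 = np.asarray(u2, dtype=float).ravel()
    D = np.asarray(D, dtype=float)
    if D.shape[1] != u1.size or u1.size != u2.size:
        raise ValueError("dimension mismatch in pair readout")
    return float((D @ u1) @ (D @ u2))


def readout_single(u, head_params) -> float:
    """Two-layer MLP head for single-drug networks.

    ``head_params`` is ``(w1, b1, w2, b2)`` with one relu between the two
    affine maps.
    """
    w1, b1, w2, b2 = head_params
    u = np.asarray(u, dtype=float).ravel()
    hid = np.maximum(u @ np.asarray(w1) + np.asarray(b1).ravel(), 0.0)
    return float(hid @ np.asarray(w2).ravel() + float(np.asarray(b2).ravel()[0]))


# ---------------------------------------------------------------------------
# parameter plumbing
# ---------------------------------------------------------------------------

def swap_drug_slots(params: ModelParams) -> ModelParams:
    """Exchange the two drug slots of every global edge-weight matrix.

    Completes the drug-order swap contract: relabelling drug A↔B in a network
    moves each drug onto the other reserved slot, so an order-invariance
    check swaps the corresponding rows/columns of every Wᵗ as well.
    """
    V = params.n_vocab
    perm = np.arange(V + 2)
    perm[[V, V + 1]] = [V + 1, V]
    tensors = {}
    for name, t in params.tensors.items():
        if name.startswith("pool") and name.endswith("_W"):
            tensors[name] = Tensor(t.data[np.ix_(perm, perm)].copy(),
                                   requires_grad=t.requires_grad)
        else:
            tensors[name] = Tensor(t.data.copy(), requires_grad=t.requires_grad)
    return ModelParams(tensors=tensors, n_vocab=V)


def save_checkpoint(path, params: ModelParams, cfg: ModelConfig) -> None:
    """Serialise parameters + config; round-trips exactly."""
    path = Path(path)
    arrays = {name: t.data for name, t in params.tensors.items()}
    meta = json.dumps({"config": cfg.to_dict(), "n_vocab": params.n_vocab})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[ModelParams, ModelConfig]:
    with np.load(Path(path)) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        tensors = {
            name: Tensor(data[name].copy(), requires_grad=True)
            for name in data.files if name != "__meta__"
        }
    cfg = ModelConfig.from_dict(meta["config"])
    return ModelParams(tensors=tensors, n_vocab=int(meta["n_vocab"])), cfg
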