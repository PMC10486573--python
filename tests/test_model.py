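"""End-to-end model contracts: shapes, invariances, gradient flow."""

import dataclasses

import numpy as np
import pytest

from sanepool.autodiff import Tensor
from sanepool.model import (ModelConfig, forward, init_params,
                            load_checkpoint, readout_pair, readout_single,
                            save_checkpoint, swap_drug_slots)
from sanepool.network_io import swap_drug_order


@pytest.fixture
def setup(tiny_networks, tiny_model_config):
    vocab, nets = tiny_networks
    params = init_params(tiny_model_config, len(vocab),
                         np.random.default_rng(5))
    return vocab, nets, params, tiny_model_config


class TestForward:
    def test_gene_counts_follow_k_schedule(self, setup):
        vocab, nets, params, cfg = setup
        _, trace = forward(nets[0], params, cfg)
        n_drugs = len(nets[0].drug_positions)
        for state, k in zip(trace, cfg.k_schedule):
            assert len(state.kept_idx) == k + n_drugs
            assert np.sum(state.kept_global_ids < len(vocab)) == k

    def test_drug_nodes_survive_every_layer(self, setup):
        vocab, nets, params, cfg = setup
        _, trace = forward(nets[0], params, cfg)
        for state in trace:
            drug_ids = set(nets[0].drug_slots)
            assert drug_ids <= set(state.kept_global_ids.tolist())

    def test_noop_pooling_preserves_adjacency(self, tiny_networks):
        vocab, nets = tiny_networks
        net = nets[0]
        cfg = ModelConfig(hidden_dims=(8, 8),
                          k_schedule=(net.n_genes, net.n_genes),
                          edge_keep_fraction=1.0)
        params = init_params(cfg, len(vocab), np.random.default_rng(5))
        _, trace = forward(net, params, cfg)
        for state in trace:
            np.testing.assert_allclose(state.pooled_adjacency, net.adjacency)

    def test_monotone_graph_shrinkage(self, setup):
        vocab, nets, params, cfg = setup
        for net in nets[:5]:
            _, trace = forward(net, params, cfg)
            nodes = [net.n_nodes] + [len(s.kept_idx) for s in trace]
            edges = [np.count_nonzero(np.triu(net.adjacency, 1))] + \
                [np.count_nonzero(np.triu(s.pooled_adjacency, 1)) for s in trace]
            assert nodes == sorted(nodes, reverse=True)
            assert edges == sorted(edges, reverse=True)

    def test_node_permutation_invariance(self, setup):
        vocab, nets, params, cfg = setup
        net = nets[3]
        perm = np.random.default_rng(0).permutation(net.n_nodes)
        s0, t0 = forward(net, params, cfg)
        s1, t1 = _forward_permuted(net, perm, params, cfg)
        assert s0.data == pytest.approx(s1.data, rel=1e-9, abs=1e-12)
        assert set(t0[-1].kept_global_ids.tolist()) == \
            set(t1[-1].kept_global_ids.tolist())

    def test_wrong_readout_for_drug_count(self, setup):
        vocab, nets, params, cfg = setup
        single_cfg = dataclasses.replace(cfg, readout="single_mlp")
        with pytest.raises(ValueError):
            forward(nets[0], params, single_cfg)


def _forward_permuted(net, perm, params, cfg):
    """Forward on a node-permuted view of ``net`` (global ids carried along).

    After permutation genes are no longer a contiguous prefix, so a light
    stand-in object exposes exactly the attributes the forward pass reads.
    """

    class Shim:
        pass

    shim = Shim()
    shim.node_features = net.node_features[perm]
    shim.adjacency = net.adjacency[np.ix_(perm, perm)]
    shim.global_node_ids = net.global_node_ids[perm]
    shim.drug_positions = tuple(int(np.flatnonzero(perm == d)[0])
                                for d in net.drug_positions)
    shim.drug_slots = net.drug_slots
    shim.cell_line = net.cell_line
    shim.synergy = net.synergy
    return forward(shim, params, cfg)


class TestDrugOrderInvariance:
    def test_score_invariant_under_swap_contract(self, setup):
        vocab, nets, params, cfg = setup
        # generic (distinct) edge weights so filter tie-breaks are immaterial
        rng = np.random.default_rng(11)
        for name, t in params.tensors.items():
            if name.endswith("_W"):
                t.data = t.data + 0.1 * rng.standard_normal(t.data.shape)
        net = nets[1]
        s0, _ = forward(net, params, cfg)
        s1, _ = forward(swap_drug_order(net), swap_drug_slots(params), cfg)
        assert s0.data == pytest.approx(s1.data, rel=1e-9, abs=1e-12)


class TestGradientFlow:
    def test_every_parameter_group_gets_gradient(self, setup):
        vocab, nets, params, cfg = setup
        for t in params.all():
            t.zero_grad()
        for net in nets[:12]:
            score, _ = forward(net, params, cfg)
            err = score - Tensor(np.array(net.synergy))
            (err * err).backward()
        groups = params.groups()
        for group, names in groups.items():
            if not names:
                continue
            total = sum(float(np.abs(params[n].grad).sum())
                        for n in names if params[n].grad is not None)
            assert total > 0, f"no gradient reached group {group}"


class TestReadouts:
    def test_identity_basis(self):
        e1 = np.array([1.0, 0.0, 0.0])
        assert readout_pair(e1, e1, np.eye(3)) == 1.0

    def test_symmetric_in_drug_order(self, rng):
        D = rng.standard_normal((4, 4))
        u1, u2 = rng.standard_normal(4), rng.standard_normal(4)
        assert readout_pair(u1, u2, D) == pytest.approx(readout_pair(u2, u1, D))

    def test_matches_matrix_vector_oracle(self, rng):
        D = rng.standard_normal((4, 4))
        u1, u2 = rng.standard_normal(4), rng.standard_normal(4)
        assert readout_pair(u1, u2, D) == pytest.approx((D @ u1) @ (D @ u2),
                                                        abs=1e-12)

    def test_dim_mismatch(self, rng):
        with pytest.raises(ValueError):
            readout_pair(np.ones(3), np.ones(4), np.eye(4))

    def test_single_zero_weights_returns_bias(self):
        head = (np.zeros((3, 4)), np.zeros(4), np.zeros(4), np.array([2.5]))
        assert readout_single(np.ones(3), head) == 2.5

    def test_single_hand_computation(self):
        w1 = np.array([[1.0, 0.0], [0.0, 1.0]])
        head = (w1, np.array([0.0, -1.0]), np.array([1.0, 2.0]), np.array([0.5]))
        # u=[2,3] -> hid=relu([2,2])=[2,2] -> 2*1+2*2+0.5 = 6.5
        assert readout_single(np.array([2.0, 3.0]), head) == 6.5

    def test_single_continuous_in_u(self, rng):
        w1 = rng.standard_normal((3, 5))
        head = (w1, rng.standard_normal(5), rng.standard_normal(5),
                rng.standard_normal(1))
        u = rng.standard_normal(3)
        base = readout_single(u, head)
        for eps in (1e-3, 1e-5):
            assert abs(readout_single(u + eps, head) - base) < 1.0


class TestCheckpoint:
    def test_round_trip_exact(self, setup, tmp_path):
        vocab, nets, params, cfg = setup
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, params, cfg)
        params2, cfg2 = load_checkpoint(path)
        assert cfg2 == cfg
        assert set(params2.tensors) == set(params.tensors)
        for name in params.tensors:
            np.testing.assert_array_equal(params2[name].data,
                                          params[name].data)
        s0, _ = forward(nets[0], params, cfg)
        s1, _ = forward(nets[0], params2, cfg2)
        assert s0.data == s1.data


class TestModelConfig:
    def test_increasing_k_schedule_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(k_schedule=(100, 200))

    def test_round_trips_via_dict(self):
        cfg = ModelConfig(hidden_dims=(16, 16), k_schedule=(30, 10))
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg
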