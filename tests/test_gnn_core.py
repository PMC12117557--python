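"""Graph encoders: hand-traced propagation, dense oracle, invariances."""

import copy

import numpy as np
import pytest
from rdkit import Chem

from hybridscreen._autograd import Parameter
from hybridscreen.chem_io import Molecule
from hybridscreen.featurize import FeaturizedGraph, FeatureScheme, featurize_graph
from hybridscreen.gnn_core import (ENCODER_REGISTRY, EncoderConfig, GCNEncoder,
                                   GraphBatch, SchNetEncoder, gcn_encode,
                                   make_encoder, register_encoder)


def graph_from(node_features, edges, coords=None):
    node_features = np.asarray(node_features, dtype=float)
    edge_index = (np.asarray(edges, dtype=np.intp).reshape(-1, 2)
                  if len(edges) else np.zeros((0, 2), np.intp))
    return FeaturizedGraph(
        node_features=node_features,
        edge_index=edge_index,
        edge_features=np.zeros((len(edge_index), 0)),
        label=0, coordinates=coords,
        elements=np.zeros(len(node_features), np.intp))


def identity_params(d, n_layers=1):
    return {f"W{k}": Parameter(np.eye(d)) for k in range(n_layers)} | {
        f"b{k}": Parameter(np.zeros(d)) for k in range(n_layers)}


class TestGCN:
    def test_isolated_node_identity_weights(self):
        # self-loop weight 1/sqrt(1*1) = 1; relu is identity on positives
        x = np.array([[0.5, 1.5, 2.0]])
        g = graph_from(x, [])
        cfg = EncoderConfig(name="gcn", hidden_width=3, n_layers=1)
        emb = gcn_encode(g, identity_params(3), cfg)
        assert np.allclose(emb, x[0])

    def test_two_connected_nodes_average(self):
        # all normalization coefficients 1/sqrt(2*2) = 0.5 -> each node
        # becomes (x0 + x1)/2; mean readout keeps that value
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        g = graph_from(x, [(0, 1), (1, 0)])
        cfg = EncoderConfig(name="gcn", hidden_width=2, n_layers=1)
        emb = gcn_encode(g, identity_params(2), cfg)
        assert np.allclose(emb, (x[0] + x[1]) / 2)

    @pytest.mark.parametrize("seed", range(20))
    def test_dense_matrix_oracle(self, seed):
        """Per layer the encoder must equal relu(D^-1/2 A D^-1/2 X W + b)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        d, w = 4, 6
        x = rng.standard_normal((n, d))
        mask = np.triu(rng.random((n, n)) < 0.4, 1)
        edges = [(i, j) for i in range(n) for j in range(n) if mask[i, j]]
        edges = edges + [(j, i) for i, j in edges]
        g = graph_from(x, edges)

        cfg = EncoderConfig(name="gcn", hidden_width=w, n_layers=2, readout="mean")
        enc = GCNEncoder(cfg, d)
        params = enc.init_params(rng)
        batch = GraphBatch.from_graphs([g])
        emb = enc.forward(batch, params).data[0]

        A = np.eye(n)
        for i, j in edges:
            A[i, j] = 1.0
        Dinv = np.diag(1.0 / np.sqrt(A.sum(1)))
        P = Dinv @ A @ Dinv
        h = x
        for k in range(2):
            h = np.maximum(P @ h @ params[f"W{k}"].data + params[f"b{k}"].data, 0)
        assert np.allclose(emb, h.mean(axis=0), atol=1e-6)

    def test_permutation_invariance(self, rng):
        m = Molecule.from_smiles("CC(=O)Oc1ccccc1C(=O)O", "asp", 0)
        g1 = featurize_graph(m)
        perm = rng.permutation(m.mol.GetNumAtoms()).tolist()
        m2 = Molecule(id="p", mol=Chem.RenumberAtoms(m.mol, perm), activity=0)
        g2 = featurize_graph(m2)
        cfg = EncoderConfig(name="gcn", hidden_width=16, n_layers=3)
        enc = GCNEncoder(cfg, g1.node_features.shape[1])
        params = enc.init_params(np.random.default_rng(0))
        e1 = enc.forward(GraphBatch.from_graphs([g1]), params).data
        e2 = enc.forward(GraphBatch.from_graphs([g2]), params).data
        assert np.allclose(e1, e2, atol=1e-6)


class TestSchNet:
    CFG = EncoderConfig(name="schnet", hidden_width=12, n_layers=2,
                        readout="sum", cutoff=10.0, n_rbf=20)

    def make(self, d_node=4, n_elements=5):
        return SchNetEncoder(self.CFG, d_node, n_elements)

    def test_rigid_motion_invariance(self, synth_3d, rng):
        from scipy.spatial.transform import Rotation
        m = list(synth_3d.molecule_set)[0]
        g1 = featurize_graph(m)
        enc = SchNetEncoder(self.CFG, g1.node_features.shape[1], 10)
        params = enc.init_params(np.random.default_rng(3))
        e1 = enc.forward(GraphBatch.from_graphs([g1], need_coordinates=True),
                         params).data
        g2 = copy.deepcopy(g1)
        R = Rotation.random(rng=rng).as_matrix()
        g2.coordinates = g1.coordinates @ R.T + np.array([5.0, -2.0, 1.0])
        e2 = enc.forward(GraphBatch.from_graphs([g2], need_coordinates=True),
                         params).data
        assert np.abs(e1 - e2).max() <= 1e-5 * np.abs(e1).max()

    def test_isolated_atom_hand_trace(self):
        """No neighbors: the embedding is the atom-wise transform of the
        element embedding, with every convolution contribution empty."""
        enc = self.make()
        params = enc.init_params(np.random.default_rng(1))
        g = graph_from(np.zeros((1, 4)), [], coords=np.zeros((1, 3)))
        g.elements = np.array([2], np.intp)
        emb = enc.forward(GraphBatch.from_graphs([g], need_coordinates=True),
                          params).data[0]

        def ssp(x):
            return np.logaddexp(0, x) - np.log(2)

        x = params["embed"].data[2]
        for k in range(self.CFG.n_layers):
            agg = np.zeros_like(x)  # empty convolution sum
            v = ssp(agg @ params[f"post1_W{k}"].data + params[f"post1_b{k}"].data)
            x = x + v @ params[f"post2_W{k}"].data + params[f"post2_b{k}"].data
        expected = (ssp(x @ params["out_W1"].data + params["out_b1"].data)
                    @ params["out_W2"].data + params["out_b2"].data)
        assert np.allclose(emb, expected, atol=1e-10)

    def test_distance_changes_embedding(self):
        enc = self.make()
        params = enc.init_params(np.random.default_rng(5))
        embs = []
        for d in (1.2, 2.7):
            g = graph_from(np.zeros((2, 4)), [],
                           coords=np.array([[0.0, 0, 0], [d, 0, 0]]))
            g.elements = np.array([1, 1], np.intp)
            embs.append(enc.forward(
                GraphBatch.from_graphs([g], need_coordinates=True), params).data)
        assert not np.allclose(embs[0], embs[1])

    def test_missing_coordinates_fatal(self):
        g = graph_from(np.zeros((2, 4)), [(0, 1), (1, 0)])
        with pytest.raises(ValueError, match="coordinates"):
            GraphBatch.from_graphs([g], need_coordinates=True)

    def test_permutation_invariance(self, synth_3d, rng):
        m = list(synth_3d.molecule_set)[1]
        g1 = featurize_graph(m)
        perm = rng.permutation(g1.num_nodes)
        g2 = copy.deepcopy(g1)
        g2.node_features = g1.node_features[perm]
        g2.elements = g1.elements[perm]
        g2.coordinates = g1.coordinates[perm]
        g2.edge_index = np.zeros((0, 2), np.intp)
        enc = SchNetEncoder(self.CFG, g1.node_features.shape[1], 10)
        params = enc.init_params(np.random.default_rng(2))
        e1 = enc.forward(GraphBatch.from_graphs([g1], need_coordinates=True), params).data
        e2 = enc.forward(GraphBatch.from_graphs([g2], need_coordinates=True), params).data
        assert np.allclose(e1, e2, atol=1e-8)


class TestRegistry:
    def test_unknown_encoder_fatal(self):
        with pytest.raises(ValueError, match="registered"):
            make_encoder(EncoderConfig(name="spherenet"), 4, 10)

    def test_registration_extends(self):
        class Dummy(GCNEncoder):
            pass

        register_encoder("dummy", Dummy)
        try:
            enc = make_encoder(EncoderConfig(name="dummy"), 4, 10)
            assert isinstance(enc, Dummy)
        finally:
            del ENCODER_REGISTRY["dummy"]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EncoderConfig(dropout=1.0)
        with pytest.raises(ValueError):
            EncoderConfig(n_layers=0)
        with pytest.raises(ValueError):
            EncoderConfig(readout="max")
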