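"""Descriptor-integrated GNN classifier for activity prediction.

The core method: a graph encoder produces a learned representation h of
the molecular graph, which is concatenated with an expert-crafted
descriptor vector h_dp; an MLP head maps [h || h_dp] through ReLU hidden
layers (with dropout) and a sigmoid to a predicted activity p-hat,
trained by minimizing binary cross-entropy with Adam.  Ablations fall out
of the same class: encoder-only (no descriptors) and descriptor-only
(no encoder) baselines.

Training keeps the final-epoch parameters — no early stopping and no
validation-based selection — and is bit-reproducible given the seed.

The estimator follows scikit-learn conventions (``fit`` / ``predict_proba``
/ ``get_params``); X is a list of :class:`~hybridscreen.chem_io.Molecule`
or pre-featurized graphs rather than a feature matrix.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from ._autograd import Parameter, Tensor
from .chem_io import Molecule
from .descriptors import DescriptorScaler, builtin_descriptor_matrix
from .featurize import FeaturizedGraph, FeatureScheme, featurize_graph
from .gnn_core import EncoderConfig, GraphBatch, make_encoder
from .metrics import RankedResult

EPS = 1e-7  # score clip in the loss, for numerical stability


def bce_loss(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mean binary cross-entropy with scores clipped to [EPS, 1 - EPS]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    p = np.clip(scores, EPS, 1.0 - EPS)
    return float(-(labels * np.log(p) + (1 - labels) * np.log(1 - p)).mean())


def predict_one(h, h_dp, params: dict, hidden: tuple = ()) -> float:
    """Score a single molecule from its embedding and/or descriptor vector.

    Concatenation order is [h then h_dp]; either part may be absent, but
    not both.
    """
    parts = [np.asarray(v, dtype=float) for v in (h, h_dp) if v is not None]
    if not parts:
        raise ValueError("need at least one of h, h_dp")
    x = np.concatenate(parts)[None, :]
    if x.shape[1] != params["mlp_W0"].data.shape[0]:
        raise ValueError(
            f"input width {x.shape[1]} does not match MLP input width "
            f"{params['mlp_W0'].data.shape[0]}"
        )
    t = Tensor(x)
    n_hidden = len(hidden) if hidden else _count_hidden(params)
    for k in range(n_hidden):
        t = (t @ params[f"mlp_W{k}"] + params[f"mlp_b{k}"]).relu()
    k = n_hidden
    t = (t @ params[f"mlp_W{k}"] + params[f"mlp_b{k}"]).sigmoid()
    return float(t.data[0, 0])


def _count_hidden(params: dict) -> int:
    k = 0
    while f"mlp_W{k + 1}" in params:
        k += 1
    return k


class _Adam:
    """Adaptive-moment gradient descent over a named parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * p.grad
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


class HybridScreeningClassifier(BaseEstimator, ClassifierMixin):
    """GNN + descriptor hybrid activity classifier.

    Parameters
    ----------
    encoder : str or None
        Registered encoder name ('gcn', 'schnet') or None for the
        descriptor-only baseline.
    use_descriptors : bool
        Concatenate the descriptor vector h_dp to the learned embedding.
        At least one of ``encoder`` / ``use_descriptors`` must be active.
    mlp_hidden : tuple of int
        Hidden-layer widths of the classifier head.
    dropout : float
        Dropout rate in the MLP hidden layers (training only).
    epochs, batch_size, learning_rate : training protocol knobs.
    pos_weight : float or None
        Optional positive-class weight in the loss.
    encoder_width, encoder_layers, encoder_readout, cutoff, n_rbf,
    encoder_dropout : encoder hyperparameters (see EncoderConfig).
    feature_scheme : FeatureScheme or None
        Graph featurization scheme; default scheme if None.
    random_state : int
        Seed for parameter initialization, batch shuffling and dropout.
    """

    def __init__(self, encoder="gcn", use_descriptors=True,
                 mlp_hidden=(128, 64), dropout=0.2, epochs=30,
                 batch_size=128, learning_rate=1e-3, pos_weight=None,
                 encoder_width=128, encoder_layers=3, encoder_readout="mean",
                 cutoff=10.0, n_rbf=50, encoder_dropout=0.0,
                 feature_scheme=None, random_state=0):
        self.encoder = encoder
        self.use_descriptors = use_descriptors
        self.mlp_hidden = mlp_hidden
        self.dropout = dropout
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.pos_weight = pos_weight
        self.encoder_width = encoder_width
        self.encoder_layers = encoder_layers
        self.encoder_readout = encoder_readout
        self.cutoff = cutoff
        self.n_rbf = n_rbf
        self.encoder_dropout = encoder_dropout
        self.feature_scheme = feature_scheme
        self.random_state = random_state

    # -- plumbing -------------------------------------------------------------

    def _encoder_config(self) -> EncoderConfig:
        return EncoderConfig(
            name=self.encoder, hidden_width=self.encoder_width,
            n_layers=self.encoder_layers, readout=self.encoder_readout,
            cutoff=self.cutoff, n_rbf=self.n_rbf,
            dropout=self.encoder_dropout,
        )

    def _prepare(self, X, descriptors):
        """X -> (graphs, ids, labels, raw descriptor matrix or None)."""
        scheme = self.feature_scheme or FeatureScheme()
        if len(X) == 0:
            raise ValueError("empty molecule list")
        if isinstance(X[0], Molecule):
            graphs = [featurize_graph(m, scheme) for m in X]
            mols = X
        else:
            graphs = list(X)
            mols = None
        ids = np.asarray([g.mol_id for g in graphs])
        labels = np.asarray([g.label for g in graphs], dtype=int)
        desc = None
        if self.use_descriptors:
            if descriptors is not None:
                desc = np.asarray(descriptors, dtype=float)
                if desc.shape[0] != len(graphs):
                    raise ValueError("descriptor row count != molecule count")
            else:
                if mols is None:
                    raise ValueError(
                        "pre-featurized input needs an explicit descriptor matrix"
                    )
                desc = builtin_descriptor_matrix(mols)
        return graphs, ids, labels, desc

    def _forward_batch(self, batch: GraphBatch, desc: np.ndarray | None,
                       training: bool, rng) -> Tensor:
        if self._encoder is not None:
            h = self._encoder.forward(batch, self.params_, training=training, rng=rng)
            if desc is not None:
                h = h.concat(Tensor(desc), axis=1)
        else:
            h = Tensor(desc)
        n_hidden = len(self.mlp_hidden)
        for k in range(n_hidden):
            h = (h @ self.params_[f"mlp_W{k}"] + self.params_[f"mlp_b{k}"]).relu()
            if training and self.dropout > 0:
                mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                h = h * Tensor(mask)
        h = (h @ self.params_[f"mlp_W{n_hidden}"] + self.params_[f"mlp_b{n_hidden}"])
        return h.sigmoid()

    # -- sklearn API ----------------------------------------------------------

    def fit(self, X, y=None, descriptors=None):
        """Train on a list of molecules (or featurized graphs).

        ``y`` defaults to the activity labels carried by the molecules.
        ``descriptors`` optionally supplies an external [n, d_dp] matrix;
        otherwise the built-in descriptor set is computed.
        """
        if self.encoder is None and not self.use_descriptors:
            raise ValueError("need an encoder, descriptors, or both")
        graphs, ids, labels, desc = self._prepare(X, descriptors)
        if y is not None:
            labels = np.asarray(y, dtype=int)
        if len(np.unique(labels)) < 2:
            raise ValueError("training set must contain both classes")
        for g, lab in zip(graphs, labels):
            g.label = int(lab)

        rng = np.random.default_rng(self.random_state)
        self.classes_ = np.array([0, 1])
        self.scaler_ = None
        if desc is not None:
            self.scaler_ = DescriptorScaler().fit(desc)
            desc = self.scaler_.transform(desc)
            self.d_dp_ = desc.shape[1]
        else:
            self.d_dp_ = 0
        self.d_node_ = graphs[0].node_features.shape[1]
        scheme = self.feature_scheme or FeatureScheme()

        self._encoder = None
        self.params_ = {}
        mlp_in = self.d_dp_
        if self.encoder is not None:
            cfg = self._encoder_config()
            self._encoder = make_encoder(cfg, self.d_node_, len(scheme.elements))
            self.params_.update(self._encoder.init_params(rng))
            mlp_in += self._encoder.out_width

        dims = [mlp_in] + list(self.mlp_hidden) + [1]
        for k in range(len(dims) - 1):
            bound = 1.0 / np.sqrt(dims[k])
            self.params_[f"mlp_W{k}"] = Parameter(
                rng.uniform(-bound, bound, (dims[k], dims[k + 1])))
            self.params_[f"mlp_b{k}"] = Parameter(np.zeros(dims[k + 1]))

        opt = _Adam(self.params_, lr=self.learning_rate)
        n = len(graphs)
        need_xyz = self._encoder is not None and self._encoder.requires_coordinates
        self.loss_history_ = []
        for _epoch in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                batch = GraphBatch.from_graphs(
                    [graphs[i] for i in idx], cutoff=self.cutoff,
                    need_coordinates=need_xyz)
                bdesc = desc[idx] if desc is not None else None
                p = self._forward_batch(batch, bdesc, training=True, rng=rng)
                p = p.reshape(-1).clip(EPS, 1.0 - EPS)
                yb = labels[idx].astype(float)
                w = np.ones_like(yb)
                if self.pos_weight is not None:
                    w = np.where(yb == 1, self.pos_weight, 1.0)
                terms = (Tensor(yb * w) * p.log()
                         + Tensor((1 - yb) * w) * (1.0 - p).log())
                loss = -(terms.sum() * (1.0 / len(yb)))
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
            self.loss_history_.append(epoch_loss / n)
        return self

    def decision_function(self, X, descriptors=None) -> np.ndarray:
        """Predicted activity scores p-hat in (0, 1); dropout disabled."""
        if not hasattr(self, "params_"):
            raise ValueError("model is not fitted")
        graphs, ids, labels, desc = self._prepare(X, descriptors)
        if desc is not None:
            desc = self.scaler_.transform(desc)
        need_xyz = self._encoder is not None and self._encoder.requires_coordinates
        scores = np.empty(len(graphs))
        for start in range(0, len(graphs), 1024):
            chunk = graphs[start:start + 1024]
            batch = GraphBatch.from_graphs(chunk, cutoff=self.cutoff,
                                           need_coordinates=need_xyz)
            d = desc[start:start + 1024] if desc is not None else None
            p = self._forward_batch(batch, d, training=False, rng=None)
            scores[start:start + len(chunk)] = p.data[:, 0]
        return scores

    def predict_proba(self, X, descriptors=None) -> np.ndarray:
        p = self.decision_function(X, descriptors)
        return np.column_stack([1 - p, p])

    def predict(self, X, descriptors=None) -> np.ndarray:
        return (self.decision_function(X, descriptors) >= 0.5).astype(int)

    def score_test_set(self, X, descriptors=None) -> RankedResult:
        """Score a test set into a RankedResult for metric evaluation."""
        if isinstance(X[0], Molecule):
            ids = np.asarray([m.id for m in X])
            labels = np.asarray([m.activity for m in X], dtype=int)
        else:
            ids = np.asarray([g.mol_id for g in X])
            labels = np.asarray([g.label for g in X], dtype=int)
        scores = self.decision_function(X, descriptors)
        return RankedResult(ids=ids, scores=scores, labels=labels)

    # -- persistence ----------------------------------------------------------

    def save(self, path):
        """Self-describing checkpoint: parameters + config + scaler."""
        blobs = {k: p.data for k, p in self.params_.items()}
        if self.scaler_ is not None:
            blobs["__scaler_mean"] = self.scaler_.mean_
            blobs["__scaler_scale"] = self.scaler_.scale_
            blobs["__scaler_const"] = self.scaler_.constant_mask_
        cfg = {k: (list(v) if isinstance(v, tuple) else v)
               for k, v in self.get_params().items() if k != "feature_scheme"}
        blobs["__config"] = np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8)
        np.savez(path, **blobs)

    @classmethod
    def load(cls, path) -> "HybridScreeningClassifier":
        data = np.load(path)
        cfg = json.loads(bytes(data["__config"]).decode())
        cfg["mlp_hidden"] = tuple(cfg["mlp_hidden"])
        model = cls(**cfg)
        model.classes_ = np.array([0, 1])
        model.params_ = {k: Parameter(v) for k, v in data.items()
                         if not k.startswith("__")}
        model.scaler_ = None
        if "__scaler_mean" in data:
            model.scaler_ = DescriptorScaler(
                mean_=data["__scaler_mean"], scale_=data["__scaler_scale"],
                constant_mask_=data["__scaler_const"])
            model.d_dp_ = len(model.scaler_.mean_)
        model._encoder = None
        if model.encoder is not None:
            scheme = FeatureScheme()
            model.d_node_ = scheme.d_node
            model._encoder = make_encoder(model._encoder_config(),
                                          scheme.d_node, len(scheme.elements))
        return model


def train(X, cfg_kwargs: dict | None = None, descriptors=None
          ) -> HybridScreeningClassifier:
    """Functional wrapper: fit a classifier on labelled molecules."""
    model = HybridScreeningClassifier(**(cfg_kwargs or {}))
    return model.fit(X, descriptors=descriptors)


def score_test_set(model: HybridScreeningClassifier, X,
                   descriptors=None) -> RankedResult:
    return model.score_test_set(X, descriptors=descriptors)
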