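"""Graph encoders producing the learned molecular representation h.

Two encoders are provided behind a registry:

``gcn``
    Spectral-motivated graph convolution: each layer aggregates neighbor
    features (self-loops included) with symmetric degree normalization
    1/sqrt(deg_i * deg_j), applies a linear map and a ReLU; a mean or sum
    readout over final node states gives the graph embedding.

``schnet``
    Continuous-filter convolutions over interatomic distances: a learned
    per-element embedding is refined by interaction blocks in which each
    pairwise distance, expanded in a Gaussian radial basis, is mapped by a
    filter-generating network to per-channel weights; shifted-softplus
    nonlinearities and residual updates; sum readout.  Requires 3D
    coordinates; bond features are ignored by design.

New architectures (e.g. spherical message passing) can be added through
``register_encoder`` without touching this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ._autograd import Parameter, Tensor
from .featurize import FeaturizedGraph, build_radius_edges

__all__ = [
    "EncoderConfig", "GraphBatch", "GCNEncoder", "SchNetEncoder",
    "ENCODER_REGISTRY", "register_encoder", "make_encoder",
    "gcn_encode", "schnet_encode",
]


@dataclass
class EncoderConfig:
    """Architecture hyperparameters for a graph encoder."""

    name: str = "gcn"
    hidden_width: int = 128
    n_layers: int = 3              # GCN layers / SchNet interaction blocks
    readout: str = "mean"          # 'mean' or 'sum'
    cutoff: float = 10.0           # Å, radius-graph cutoff (schnet)
    n_rbf: int = 50                # Gaussian radial basis functions (schnet)
    dropout: float = 0.0

    def __post_init__(self):
        if self.hidden_width < 1 or self.n_layers < 1 or self.n_rbf < 1:
            raise ValueError("hidden_width, n_layers and n_rbf must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.readout not in ("mean", "sum"):
            raise ValueError(f"unknown readout {self.readout!r}")


@dataclass
class GraphBatch:
    """A block-diagonal merge of several featurized graphs."""

    node_features: np.ndarray        # [N, d_node]
    elements: np.ndarray             # [N] element vocabulary indices
    segment_ids: np.ndarray          # [N] graph index per node
    n_graphs: int
    # message-passing structure over bonds, self-loops included:
    mp_src: np.ndarray
    mp_dst: np.ndarray
    mp_coef: np.ndarray              # 1/sqrt(deg_i deg_j) per edge
    # radius-graph structure (empty unless coordinates were given):
    radius_src: np.ndarray = field(default_factory=lambda: np.zeros(0, np.intp))
    radius_dst: np.ndarray = field(default_factory=lambda: np.zeros(0, np.intp))
    radius_dist: np.ndarray = field(default_factory=lambda: np.zeros(0))
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @classmethod
    def from_graphs(cls, graphs: list, cutoff: float = 10.0,
                    need_coordinates: bool = False) -> "GraphBatch":
        xs, elems, segs, labels = [], [], [], []
        mp_edges = []
        r_src, r_dst, r_dist = [], [], []
        offset = 0
        for gi, g in enumerate(graphs):
            n = g.num_nodes
            xs.append(g.node_features)
            elems.append(g.elements if g.elements is not None
                         else np.zeros(n, np.intp))
            segs.append(np.full(n, gi, np.intp))
            labels.append(g.label)
            if g.num_edges:
                mp_edges.append(g.edge_index + offset)
            if need_coordinates:
                if g.coordinates is None:
                    raise ValueError(
                        f"encoder requires 3D coordinates but molecule "
                        f"{g.mol_id!r} has none"
                    )
                ei, di = build_radius_edges(g.coordinates, cutoff)
                if len(ei):
                    r_src.append(ei[:, 0] + offset)
                    r_dst.append(ei[:, 1] + offset)
                    r_dist.append(di)
            offset += n

        N = offset
        x = np.vstack(xs)
        bond_edges = (np.vstack(mp_edges) if mp_edges
                      else np.zeros((0, 2), np.intp))
        # self-loops + symmetric normalization, degrees counted with loops
        loops = np.arange(N, dtype=np.intp)
        src = np.concatenate([bond_edges[:, 0], loops])
        dst = np.concatenate([bond_edges[:, 1], loops])
        deg = np.bincount(dst, minlength=N).astype(float)
        coef = 1.0 / np.sqrt(deg[src] * deg[dst])
        return cls(
            node_features=x,
            elements=np.concatenate(elems),
            segment_ids=np.concatenate(segs),
            n_graphs=len(graphs),
            mp_src=src, mp_dst=dst, mp_coef=coef,
            radius_src=(np.concatenate(r_src) if r_src else np.zeros(0, np.intp)),
            radius_dst=(np.concatenate(r_dst) if r_dst else np.zeros(0, np.intp)),
            radius_dist=(np.concatenate(r_dist) if r_dist else np.zeros(0)),
            labels=np.asarray(labels, dtype=float),
        )


def _uniform_init(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def _dropout(x: Tensor, rate: float, rng: np.random.Generator) -> Tensor:
    mask = (rng.random(x.shape) >= rate).astype(float) / (1.0 - rate)
    return x * Tensor(mask)


class GCNEncoder:
    """Symmetric-normalized graph convolution with configurable readout."""

    requires_coordinates = False

    def __init__(self, cfg: EncoderConfig, d_node: int, n_elements: int = 0):
        self.cfg = cfg
        self.d_node = d_node

    @property
    def out_width(self) -> int:
        return self.cfg.hidden_width

    def init_params(self, rng: np.random.Generator) -> dict:
        w = self.cfg.hidden_width
        dims = [self.d_node] + [w] * self.cfg.n_layers
        params = {}
        for k in range(self.cfg.n_layers):
            params[f"W{k}"] = Parameter(_uniform_init(rng, dims[k], (dims[k], dims[k + 1])))
            params[f"b{k}"] = Parameter(np.zeros(dims[k + 1]))
        return params

    def forward(self, batch: GraphBatch, params: dict, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        x = Tensor(batch.node_features)
        coef = Tensor(batch.mp_coef[:, None])
        n = batch.num_nodes
        for k in range(self.cfg.n_layers):
            msgs = x.gather_rows(batch.mp_src) * coef
            agg = msgs.scatter_add_rows(batch.mp_dst, n)
            x = (agg @ params[f"W{k}"] + params[f"b{k}"]).relu()
            if training and self.cfg.dropout > 0:
                x = _dropout(x, self.cfg.dropout, rng)
        if self.cfg.readout == "mean":
            return x.segment_mean(batch.segment_ids, batch.n_graphs)
        return x.segment_sum(batch.segment_ids, batch.n_graphs)


class SchNetEncoder:
    """Continuous-filter convolutions over a radius graph; needs coordinates."""

    requires_coordinates = True

    def __init__(self, cfg: EncoderConfig, d_node: int, n_elements: int):
        self.cfg = replace(cfg, readout="sum") if cfg.readout != "sum" else cfg
        self.n_elements = n_elements
        centers = np.linspace(0.0, cfg.cutoff, cfg.n_rbf)
        self._centers = centers
        self._gamma = 1.0 / (2.0 * (centers[1] - centers[0]) ** 2)

    @property
    def out_width(self) -> int:
        return self.cfg.hidden_width

    def expand_rbf(self, dist: np.ndarray) -> np.ndarray:
        """Gaussian radial basis over [0, cutoff]; width = center spacing."""
        return np.exp(-self._gamma * (dist[:, None] - self._centers[None, :]) ** 2)

    def init_params(self, rng: np.random.Generator) -> dict:
        w, r = self.cfg.hidden_width, self.cfg.n_rbf
        params = {"embed": Parameter(_uniform_init(rng, w, (self.n_elements, w)))}
        for k in range(self.cfg.n_layers):
            for nm, (fi, fo) in {
                "atom": (w, w),          # pre-convolution atom-wise map
                "filt1": (r, w),         # filter-generating network
                "filt2": (w, w),
                "post1": (w, w),         # post-convolution atom-wise maps
                "post2": (w, w),
            }.items():
                params[f"{nm}_W{k}"] = Parameter(_uniform_init(rng, fi, (fi, fo)))
                params[f"{nm}_b{k}"] = Parameter(np.zeros(fo))
        params["out_W1"] = Parameter(_uniform_init(rng, w, (w, w)))
        params["out_b1"] = Parameter(np.zeros(w))
        params["out_W2"] = Parameter(_uniform_init(rng, w, (w, w)))
        params["out_b2"] = Parameter(np.zeros(w))
        return params

    def forward(self, batch: GraphBatch, params: dict, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        n = batch.num_nodes
        x = params["embed"].gather_rows(batch.elements)
        rbf = Tensor(self.expand_rbf(batch.radius_dist))
        has_edges = len(batch.radius_src) > 0
        for k in range(self.cfg.n_layers):
            h = x @ params[f"atom_W{k}"] + params[f"atom_b{k}"]
            if has_edges:
                filt = (rbf @ params[f"filt1_W{k}"] + params[f"filt1_b{k}"]
                        ).shifted_softplus() @ params[f"filt2_W{k}"] + params[f"filt2_b{k}"]
                msgs = h.gather_rows(batch.radius_src) * filt
                agg = msgs.scatter_add_rows(batch.radius_dst, n)
            else:
                agg = h * Tensor(np.zeros((n, 1)))
            v = ((agg @ params[f"post1_W{k}"] + params[f"post1_b{k}"]
                  ).shifted_softplus() @ params[f"post2_W{k}"] + params[f"post2_b{k}"])
            x = x + v
        out = ((x @ params["out_W1"] + params["out_b1"]).shifted_softplus()
               @ params["out_W2"] + params["out_b2"])
        return out.segment_sum(batch.segment_ids, batch.n_graphs)


ENCODER_REGISTRY: dict[str, type] = {}


def register_encoder(name: str, cls: type) -> None:
    """Register an encoder class under a name usable in EncoderConfig."""
    ENCODER_REGISTRY[name] = cls


register_encoder("gcn", GCNEncoder)
register_encoder("schnet", SchNetEncoder)


def make_encoder(cfg: EncoderConfig, d_node: int, n_elements: int):
    if cfg.name not in ENCODER_REGISTRY:
        raise ValueError(
            f"unknown encoder {cfg.name!r}; registered: {sorted(ENCODER_REGISTRY)}"
        )
    return ENCODER_REGISTRY[cfg.name](cfg, d_node, n_elements)


def _encode_one(encoder, g: FeaturizedGraph, params: dict) -> np.ndarray:
    batch = GraphBatch.from_graphs(
        [g], cutoff=encoder.cfg.cutoff,
        need_coordinates=encoder.requires_coordinates,
    )
    return encoder.forward(batch, params).data[0]


def gcn_encode(g: FeaturizedGraph, params: dict, cfg: EncoderConfig) -> np.ndarray:
    """Embed one graph with the GCN encoder (inference mode)."""
    return _encode_one(GCNEncoder(cfg, g.node_features.shape[1]), g, params)


def schnet_encode(g: FeaturizedGraph, params: dict, cfg: EncoderConfig,
                  n_elements: int = 10) -> np.ndarray:
    """Embed one graph with the SchNet encoder (inference mode)."""
    if g.coordinates is None:
        raise ValueError("schnet encoder requires 3D coordinates on the graph")
    return _encode_one(SchNetEncoder(cfg, g.node_features.shape[1], n_elements), g, params)
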