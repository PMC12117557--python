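"""Numeric graph inputs for the GNN encoders.

The default scheme encodes, per heavy atom: element one-hot over the
allowed set, degree one-hot (0-5), formal charge one-hot (clipped to
[-2, 2]), aromaticity flag, ring-membership flag and total attached
hydrogen one-hot (0-4); per bond: bond-order one-hot
{single, double, triple, aromatic} and a ring flag.  Every undirected
bond yields both directed edges.  The scheme is declared in config so a
different feature list can be dropped in without touching the encoders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from rdkit import Chem

from .chem_io import DEFAULT_ALLOWED_ELEMENTS, Molecule

ELEMENT_ORDER = sorted(DEFAULT_ALLOWED_ELEMENTS)  # fixed, alphabetical

_BOND_ORDER = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}

KNOWN_NODE_FEATURES = ("element", "degree", "formal_charge", "aromatic",
                       "in_ring", "num_hs")
KNOWN_EDGE_FEATURES = ("bond_order", "in_ring")


@dataclass
class FeatureScheme:
    """Declared node/edge feature lists with their vocabularies."""

    node_features: tuple = KNOWN_NODE_FEATURES
    edge_features: tuple = KNOWN_EDGE_FEATURES
    elements: tuple = tuple(ELEMENT_ORDER)
    max_degree: int = 5
    charge_range: tuple = (-2, 2)
    max_num_hs: int = 4
    explicit_hydrogens: bool = False

    def __post_init__(self):
        for f in self.node_features:
            if f not in KNOWN_NODE_FEATURES:
                raise ValueError(f"unknown node feature {f!r}")
        for f in self.edge_features:
            if f not in KNOWN_EDGE_FEATURES:
                raise ValueError(f"unknown edge feature {f!r}")

    @property
    def d_node(self) -> int:
        widths = {
            "element": len(self.elements),
            "degree": self.max_degree + 1,
            "formal_charge": self.charge_range[1] - self.charge_range[0] + 1,
            "aromatic": 1,
            "in_ring": 1,
            "num_hs": self.max_num_hs + 1,
        }
        return sum(widths[f] for f in self.node_features)

    @property
    def d_edge(self) -> int:
        widths = {"bond_order": 4, "in_ring": 1}
        return sum(widths[f] for f in self.edge_features)


@dataclass
class FeaturizedGraph:
    """Numeric realization of a molecular graph.

    ``edge_index`` holds directed pairs, shape [num_edges, 2]; every
    undirected bond contributes both directions.
    """

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_features: np.ndarray
    label: int
    coordinates: Optional[np.ndarray] = None
    elements: Optional[np.ndarray] = None  # per-atom index into scheme.elements
    mol_id: str = ""

    @property
    def num_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def num_edges(self) -> int:
        return self.edge_index.shape[0]


def _one_hot(index: int, width: int) -> np.ndarray:
    v = np.zeros(width)
    v[min(max(index, 0), width - 1)] = 1.0
    return v


def featurize_graph(mol: Molecule, scheme: FeatureScheme | None = None) -> FeaturizedGraph:
    """Convert a molecule to node/edge feature arrays under a declared scheme.

    Heavy-atom graph by default (hydrogens enter via the H-count feature);
    set ``scheme.explicit_hydrogens`` to include them as nodes.
    """
    scheme = scheme or FeatureScheme()
    rmol = Chem.AddHs(mol.mol) if scheme.explicit_hydrogens else mol.mol
    elem_index = {e: i for i, e in enumerate(scheme.elements)}

    n = rmol.GetNumAtoms()
    node_rows, elem_ids = [], []
    for atom in rmol.GetAtoms():
        parts = []
        for f in scheme.node_features:
            if f == "element":
                sym = atom.GetSymbol()
                if sym not in elem_index:
                    raise ValueError(f"element {sym!r} outside the declared scheme")
                parts.append(_one_hot(elem_index[sym], len(scheme.elements)))
            elif f == "degree":
                parts.append(_one_hot(atom.GetDegree(), scheme.max_degree + 1))
            elif f == "formal_charge":
                lo, hi = scheme.charge_range
                parts.append(_one_hot(atom.GetFormalCharge() - lo, hi - lo + 1))
            elif f == "aromatic":
                parts.append(np.array([float(atom.GetIsAromatic())]))
            elif f == "in_ring":
                parts.append(np.array([float(atom.IsInRing())]))
            elif f == "num_hs":
                parts.append(_one_hot(atom.GetTotalNumHs(), scheme.max_num_hs + 1))
        node_rows.append(np.concatenate(parts))
        elem_ids.append(elem_index[atom.GetSymbol()])

    edges, edge_rows = [], []
    for bond in rmol.GetBonds():
        parts = []
        for f in scheme.edge_features:
            if f == "bond_order":
                parts.append(_one_hot(_BOND_ORDER.get(bond.GetBondType(), 0), 4))
            elif f == "in_ring":
                parts.append(np.array([float(bond.IsInRing())]))
        feat = np.concatenate(parts) if parts else np.zeros(0)
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.extend([(i, j), (j, i)])
        edge_rows.extend([feat, feat])

    coords = None
    if rmol.GetNumConformers():
        coords = np.asarray(rmol.GetConformer().GetPositions(), dtype=float)

    return FeaturizedGraph(
        node_features=np.asarray(node_rows, dtype=float).reshape(n, scheme.d_node),
        edge_index=(np.asarray(edges, dtype=np.intp).reshape(-1, 2)
                    if edges else np.zeros((0, 2), dtype=np.intp)),
        edge_features=(np.asarray(edge_rows, dtype=float).reshape(-1, scheme.d_edge)
                       if edge_rows else np.zeros((0, scheme.d_edge))),
        label=mol.activity,
        coordinates=coords,
        elements=np.asarray(elem_ids, dtype=np.intp),
        mol_id=mol.id,
    )


def build_radius_edges(coordinates: np.ndarray, cutoff: float
                       ) -> tuple[np.ndarray, np.ndarray]:
    """All directed pairs (i, j), i != j, with ||x_i - x_j|| <= cutoff.

    Returns (edge_index [m, 2], distances [m]).  Symmetric by construction:
    (j, i) is included whenever (i, j) is.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    if not np.all(np.isfinite(coordinates)):
        raise ValueError("non-finite coordinates")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    diff = coordinates[:, None, :] - coordinates[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    n = len(coordinates)
    mask = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    src, dst = np.nonzero(mask)
    edge_index = np.stack([src, dst], axis=1).astype(np.intp)
    return edge_index, dist[src, dst]
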