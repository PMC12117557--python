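"""Expert-crafted molecular descriptors (h_dp) and their preprocessing.

Two sources are supported: a built-in set of molecule-level descriptors
computed with RDKit (scalar and 2D quantities: size, rings, polarity,
lipophilicity, element counts), and an importer for externally computed
descriptor tables (CSV keyed by molecule id, e.g. a 391-column QSAR
feature table).  A train-fitted z-score scaler standardizes either source
before it enters the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .chem_io import DEFAULT_ALLOWED_ELEMENTS, Molecule, MoleculeSet

_ELEMENTS = sorted(DEFAULT_ALLOWED_ELEMENTS)

BUILTIN_DESCRIPTOR_NAMES = (
    "heavy_atom_count",
    "mol_weight",
    "ring_count",
    "aromatic_ring_count",
    "aromatic_atom_count",
    "hbd_count",
    "hba_count",
    "rotatable_bond_count",
    "tpsa",
    "logp",
    "formal_charge_sum",
    "fraction_csp3",
    "heteroatom_count",
) + tuple(f"count_{e}" for e in _ELEMENTS)


def compute_builtin_descriptors(mol: Molecule) -> np.ndarray:
    """Molecule-level descriptor vector; deterministic and 2D-only.

    Invariant to atom ordering and to any 3D coordinates on the molecule.
    """
    m = mol.mol
    counts = {e: 0 for e in _ELEMENTS}
    for a in m.GetAtoms():
        sym = a.GetSymbol()
        if sym in counts:
            counts[sym] += 1
    counts["H"] = counts.get("H", 0) + sum(a.GetTotalNumHs() for a in m.GetAtoms())
    values = [
        m.GetNumHeavyAtoms(),
        Descriptors.MolWt(m),
        rdMolDescriptors.CalcNumRings(m),
        rdMolDescriptors.CalcNumAromaticRings(m),
        sum(a.GetIsAromatic() for a in m.GetAtoms()),
        Lipinski.NumHDonors(m),
        Lipinski.NumHAcceptors(m),
        rdMolDescriptors.CalcNumRotatableBonds(m),
        rdMolDescriptors.CalcTPSA(m),
        Crippen.MolLogP(m),
        sum(a.GetFormalCharge() for a in m.GetAtoms()),
        rdMolDescriptors.CalcFractionCSP3(m),
        rdMolDescriptors.CalcNumHeteroatoms(m),
    ] + [counts[e] for e in _ELEMENTS]
    return np.asarray(values, dtype=float)


def builtin_descriptor_matrix(ms: MoleculeSet) -> np.ndarray:
    return np.vstack([compute_builtin_descriptors(m) for m in ms])


def load_descriptor_table(path, ms: MoleculeSet) -> tuple[np.ndarray, list, dict]:
    """Load an external per-molecule descriptor CSV aligned to a molecule set.

    The first column must be ``id``; remaining columns are numeric features.
    Every molecule must be matched exactly once.  Missing cells are imputed
    with the feature mean over the table (never label-aware); the count is
    flagged in the report.

    Returns (matrix [n_molecules, d_dp] in molecule-set order, feature
    names, report dict).
    """
    df = pd.read_csv(path)
    if df.columns[0] != "id":
        raise ValueError(f"{path}: first column must be 'id', got {df.columns[0]!r}")
    df["id"] = df["id"].astype(str)
    dup = df["id"][df["id"].duplicated()].tolist()
    if dup:
        raise ValueError(f"{path}: duplicate descriptor rows for ids {dup[:5]}")
    wanted = ms.ids()
    missing = [i for i in wanted if i not in set(df["id"])]
    if missing:
        raise ValueError(f"{path}: no descriptor row for ids {missing[:10]}")
    df = df.set_index("id").loc[wanted]
    try:
        mat = df.to_numpy(dtype=float)
    except ValueError as e:
        raise ValueError(f"{path}: non-numeric feature column: {e}") from e
    n_imputed = int(np.isnan(mat).sum())
    if n_imputed:
        col_means = np.nanmean(mat, axis=0)
        nan_r, nan_c = np.nonzero(np.isnan(mat))
        mat[nan_r, nan_c] = col_means[nan_c]
    if not np.all(np.isfinite(mat)):
        raise ValueError(f"{path}: non-finite descriptor values after imputation")
    report = {"d_dp": mat.shape[1], "n_imputed": n_imputed}
    return mat, list(df.columns), report


@dataclass
class DescriptorScaler:
    """Train-fitted z-score standardization (population sd, ddof=0).

    Features with zero training variance are flagged and mapped to 0 so
    they carry no signal; the transform is affine and invertible on the
    retained (non-constant) features.
    """

    mean_: np.ndarray = field(default=None, repr=False)
    scale_: np.ndarray = field(default=None, repr=False)
    constant_mask_: np.ndarray = field(default=None, repr=False)

    def fit(self, X: np.ndarray) -> "DescriptorScaler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("scaler requires at least 2 training rows")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        self.constant_mask_ = sd == 0
        self.scale_ = np.where(self.constant_mask_, 1.0, sd)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("scaler is not fitted")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.mean_.shape[0]:
            raise ValueError(
                f"descriptor width {X.shape[1]} does not match fitted width "
                f"{self.mean_.shape[0]}"
            )
        Z = (X - self.mean_) / self.scale_
        Z[:, self.constant_mask_] = 0.0
        return Z

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        X = np.asarray(Z, dtype=float) * self.scale_ + self.mean_
        X[:, self.constant_mask_] = self.mean_[self.constant_mask_]
        return X


def fit_apply_scaler(train: np.ndarray, full: np.ndarray
                     ) -> tuple[np.ndarray, DescriptorScaler]:
    """Fit a z-score scaler on training rows only; apply it to all rows."""
    scaler = DescriptorScaler().fit(train)
    return scaler.transform(full), scaler
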