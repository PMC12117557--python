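"""Reading, validating, deduplicating and writing labelled molecule sets.

Screening data arrives as SMILES lists or SDF (V2000) files with a binary
activity label per record.  Parsing, canonicalization and writing delegate
to RDKit; this module adds the screening-specific contracts: label handling,
element-validity filtering, duplicate collapsing with an explicit
label-conflict policy, and a machine-readable rejection report.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

#: Elements accepted by default: typical organic screening chemotypes.
DEFAULT_ALLOWED_ELEMENTS = frozenset(
    {"H", "C", "N", "O", "S", "P", "F", "Cl", "Br", "I"}
)

DUPLICATE_POLICIES = ("keep-active", "keep-first", "drop-conflict")


class MoleculeError(ValueError):
    """Fatal problem with a molecule file or set."""


@dataclass
class Molecule:
    """One screening compound: an RDKit mol plus id and binary activity label."""

    id: str
    mol: Chem.Mol
    activity: int
    _canonical: Optional[str] = field(default=None, repr=False, compare=False)

    @classmethod
    def from_smiles(cls, smiles: str, id: str, activity: int) -> "Molecule":
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise MoleculeError(f"unparsable SMILES for id {id!r}: {smiles!r}")
        return cls(id=id, mol=mol, activity=int(activity))

    @property
    def canonical_structure_key(self) -> str:
        """Canonical SMILES; the dedup key."""
        if self._canonical is None:
            self._canonical = Chem.MolToSmiles(self.mol)
        return self._canonical

    @property
    def atoms(self) -> list:
        """(element, formal charge, optional xyz in Å) per atom."""
        conf = self.mol.GetConformer() if self.mol.GetNumConformers() else None
        out = []
        for a in self.mol.GetAtoms():
            xyz = None
            if conf is not None:
                p = conf.GetAtomPosition(a.GetIdx())
                xyz = (p.x, p.y, p.z)
            out.append((a.GetSymbol(), a.GetFormalCharge(), xyz))
        return out

    @property
    def bonds(self) -> list:
        """(i, j, order) per bond; order in {1, 2, 3, 'aromatic'}."""
        order_map = {
            Chem.BondType.SINGLE: 1,
            Chem.BondType.DOUBLE: 2,
            Chem.BondType.TRIPLE: 3,
            Chem.BondType.AROMATIC: "aromatic",
        }
        return [
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order_map.get(b.GetBondType(), 1))
            for b in self.mol.GetBonds()
        ]

    @property
    def smiles(self) -> str:
        return self.canonical_structure_key


@dataclass
class MoleculeSet:
    molecules: list
    name: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [m.id for m in self.molecules]
        if len(set(ids)) != len(ids):
            dupes = [i for i, c in collections.Counter(ids).items() if c > 1]
            raise MoleculeError(f"duplicate molecule ids: {dupes[:5]}")
        for m in self.molecules:
            if m.activity not in (0, 1):
                raise MoleculeError(f"molecule {m.id!r} has non-binary label {m.activity!r}")

    def __len__(self):
        return len(self.molecules)

    def __iter__(self):
        return iter(self.molecules)

    def labels(self) -> list:
        return [m.activity for m in self.molecules]

    def ids(self) -> list:
        return [m.id for m in self.molecules]

    def subset(self, ids: Iterable[str], name: str = "") -> "MoleculeSet":
        wanted = set(ids)
        return MoleculeSet(
            [m for m in self.molecules if m.id in wanted],
            name=name or self.name,
            provenance=dict(self.provenance),
        )


@dataclass
class RejectionReport:
    """Per-record rejection log: (id, reason) rows plus per-reason counts."""

    rows: list = field(default_factory=list)  # (id, reason)
    canonicalization: str = "rdkit canonical SMILES"

    def add(self, mol_id: str, reason: str):
        self.rows.append((mol_id, reason))

    @property
    def counts(self) -> dict:
        return dict(collections.Counter(r for _, r in self.rows))

    def __len__(self):
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["id", "reason"])

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def _parse_label(raw, where: str) -> int:
    try:
        val = int(float(raw))
    except (TypeError, ValueError):
        raise MoleculeError(f"non-numeric activity label {raw!r} at {where}")
    if val not in (0, 1):
        raise MoleculeError(f"activity label must be 0/1, got {raw!r} at {where}")
    return val


def _load_smiles(path: Path, label_field: str) -> tuple[list, list]:
    """SMILES list: one record per line, whitespace-separated smiles/id/label."""
    molecules, rejections = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise MoleculeError(
                    f"{path}:{lineno}: expected 'smiles id label' columns "
                    f"(label column {label_field!r} missing)"
                )
            smiles, mol_id, raw_label = parts[0], parts[1], parts[2]
            label = _parse_label(raw_label, f"{path}:{lineno}")
            mol = Chem.MolFromSmiles(smiles)
            if mol is None:
                rejections.append((mol_id, "unparsable structure"))
                continue
            molecules.append(Molecule(id=mol_id, mol=mol, activity=label))
    return molecules, rejections


def _load_sdf(path: Path, label_field: str) -> tuple[list, list]:
    molecules, rejections = [], []
    supplier = Chem.SDMolSupplier(str(path), removeHs=True, sanitize=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            rejections.append((f"record_{i}", "unparsable structure"))
            continue
        if not mol.HasProp(label_field):
            raise MoleculeError(
                f"{path}: SDF record {i} lacks the label tag {label_field!r}"
            )
        label = _parse_label(mol.GetProp(label_field), f"{path} record {i}")
        mol_id = mol.GetProp("_Name") if mol.GetProp("_Name") else f"record_{i}"
        molecules.append(Molecule(id=mol_id, mol=mol, activity=label))
    return molecules, rejections


def load_molecules(path, format: str, label_field: str = "activity",
                   name: str = "") -> MoleculeSet:
    """Load a labelled molecule set from a SMILES list or SDF file.

    Unparsable records are counted in ``provenance['rejections']`` rather
    than aborting; a missing label column/tag or zero parsable records is
    fatal.
    """
    path = Path(path)
    if not path.exists():
        raise MoleculeError(f"no such file: {path}")
    if format == "smiles":
        molecules, rejections = _load_smiles(path, label_field)
    elif format == "sdf":
        molecules, rejections = _load_sdf(path, label_field)
    else:
        raise MoleculeError(f"unknown format {format!r} (use 'smiles' or 'sdf')")
    if not molecules:
        raise MoleculeError(f"{path}: zero parsable records")
    return MoleculeSet(
        molecules,
        name=name or path.stem,
        provenance={
            "source": str(path),
            "format": format,
            "n_parsed": len(molecules),
            "n_rejected": len(rejections),
            "rejections": rejections,
        },
    )


def write_molecules(ms: MoleculeSet, path, format: str,
                    label_field: str = "activity") -> None:
    """Write a molecule set as a SMILES list or SDF with the label as a tag."""
    path = Path(path)
    if format == "smiles":
        with open(path, "w") as fh:
            for m in ms:
                fh.write(f"{m.smiles} {m.id} {m.activity}\n")
    elif format == "sdf":
        writer = Chem.SDWriter(str(path))
        writer.SetKekulize(True)
        for m in ms:
            mol = Chem.Mol(m.mol)
            mol.SetProp("_Name", m.id)
            mol.SetProp(label_field, str(m.activity))
            writer.write(mol)
        writer.close()
    else:
        raise MoleculeError(f"unknown format {format!r}")


def filter_and_deduplicate(
    ms: MoleculeSet,
    allowed_elements: frozenset = DEFAULT_ALLOWED_ELEMENTS,
    duplicate_policy: str = "keep-active",
) -> tuple[MoleculeSet, RejectionReport]:
    """Drop molecules with disallowed elements; collapse structural duplicates.

    Duplicates share a canonical structure key.  Label conflicts among
    duplicates are resolved by ``duplicate_policy``:

    - ``keep-active``: the surviving record is active if any duplicate is
      (a confirmed active outweighs an inactive read);
    - ``keep-first``: first occurrence wins;
    - ``drop-conflict``: conflicting groups are removed entirely.
    """
    if len(ms) == 0:
        raise MoleculeError("empty molecule set")
    if duplicate_policy not in DUPLICATE_POLICIES:
        raise MoleculeError(f"unknown duplicate policy {duplicate_policy!r}")

    report = RejectionReport()
    valid = []
    for m in ms:
        symbols = {a.GetSymbol() for a in m.mol.GetAtoms()}
        bad = symbols - allowed_elements
        if bad:
            report.add(m.id, "atom type")
        else:
            valid.append(m)

    groups: dict[str, list] = collections.OrderedDict()
    for m in valid:
        groups.setdefault(m.canonical_structure_key, []).append(m)

    survivors = []
    for key, members in groups.items():
        if len(members) == 1:
            survivors.append(members[0])
            continue
        labels = {m.activity for m in members}
        if len(labels) == 1 or duplicate_policy == "keep-first":
            keep = members[0]
        elif duplicate_policy == "keep-active":
            keep = next(m for m in members if m.activity == 1)
        else:  # drop-conflict
            for m in members:
                report.add(m.id, "label conflict")
            continue
        survivors.append(keep)
        for m in members:
            if m is not keep:
                report.add(m.id, "duplicate")

    if not survivors:
        raise MoleculeError("all molecules rejected by filtering/deduplication")

    out = MoleculeSet(
        survivors,
        name=ms.name,
        provenance={
            **ms.provenance,
            "filtered": True,
            "duplicate_policy": duplicate_policy,
            "canonicalization": report.canonicalization,
            "rejection_counts": report.counts,
        },
    )
    return out, report
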