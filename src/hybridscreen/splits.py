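"""Random and scaffold-based train/test partitioning.

The random split is a seeded uniform permutation with a floor rule for
the train size.  The scaffold split groups molecules by their Bemis-Murcko
framework (ring systems plus linkers, atom types retained) and assigns
whole groups to one side, so no scaffold family ever straddles the
train/test boundary — a proxy for generalization to novel chemotypes.
Groups are assigned greedily, largest first, which places big scaffold
families in training and leaves rare chemotypes for the test side;
equal-size groups are shuffled under the seed so repeated scaffold splits
differ.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem_io import Molecule, MoleculeSet

#: Reserved scaffold key for acyclic molecules (empty framework).
ACYCLIC_KEY = ""


@dataclass
class SplitIndices:
    train_ids: list
    test_ids: list
    kind: str            # 'random' or 'scaffold'
    seed: int
    train_fraction: float
    test_has_both_classes: bool = True

    def __post_init__(self):
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValueError(f"train/test overlap: {sorted(overlap)[:5]}")
        if not self.train_ids or not self.test_ids:
            raise ValueError("both split sides must be nonempty")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(i, "train") for i in self.train_ids]
            + [(i, "test") for i in self.test_ids],
            columns=["id", "side"],
        )

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind="random", seed=0, train_fraction=0.8):
        df = pd.read_csv(path, dtype={"id": str})
        return cls(
            train_ids=df.loc[df["side"] == "train", "id"].tolist(),
            test_ids=df.loc[df["side"] == "test", "id"].tolist(),
            kind=kind, seed=seed, train_fraction=train_fraction,
        )


def _flag_test_classes(split: SplitIndices, ms: MoleculeSet) -> SplitIndices:
    label_of = {m.id: m.activity for m in ms}
    test_labels = {label_of[i] for i in split.test_ids}
    split.test_has_both_classes = test_labels == {0, 1}
    return split


def random_split(ms: MoleculeSet, frac: float = 0.8, seed: int = 0) -> SplitIndices:
    """Uniformly random partition; first floor(frac*N) of the permutation train."""
    if not 0.0 < frac < 1.0:
        raise ValueError("train fraction must be in (0, 1)")
    n = len(ms)
    if n < 2:
        raise ValueError("need at least 2 molecules to split")
    n_train = int(np.floor(frac * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split would leave one side empty")
    ids = np.asarray(ms.ids())
    perm = np.random.default_rng(seed).permutation(n)
    split = SplitIndices(
        train_ids=ids[perm[:n_train]].tolist(),
        test_ids=ids[perm[n_train:]].tolist(),
        kind="random", seed=seed, train_fraction=frac,
    )
    return _flag_test_classes(split, ms)


def murcko_scaffold_key(mol: Molecule) -> str:
    """Canonical SMILES of the Bemis-Murcko framework; '' for acyclic."""
    scaffold = MurckoScaffold.GetScaffoldForMol(mol.mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ACYCLIC_KEY
    return Chem.MolToSmiles(scaffold)


def scaffold_split(ms: MoleculeSet, frac: float = 0.8, seed: int = 0,
                   acyclic_individually: bool = False) -> SplitIndices:
    """Greedy largest-first scaffold-group partition.

    Groups (by scaffold key) go whole to the training side until it holds
    at least floor(frac*N) molecules; the remainder is the test side.
    Equal-size runs in the group ordering are shuffled under the seed.
    With ``acyclic_individually`` each acyclic molecule forms its own group
    instead of sharing the reserved empty-scaffold group.
    """
    if not 0.0 < frac < 1.0:
        raise ValueError("train fraction must be in (0, 1)")
    groups: dict[str, list] = collections.defaultdict(list)
    for m in ms:
        key = murcko_scaffold_key(m)
        if key == ACYCLIC_KEY and acyclic_individually:
            key = f"{ACYCLIC_KEY}//{m.id}"
        groups[key].append(m.id)
    if len(groups) < 2:
        raise ValueError(
            "scaffold split impossible: all molecules share one scaffold group"
        )
    # order: size descending, key ascending; then shuffle equal-size runs
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    rng = np.random.default_rng(seed)
    final: list = []
    i = 0
    while i < len(ordered):
        j = i
        while j < len(ordered) and len(ordered[j][1]) == len(ordered[i][1]):
            j += 1
        run = ordered[i:j]
        final.extend(run[k] for k in rng.permutation(len(run)))
        i = j
    n = len(ms)
    n_target = int(np.floor(frac * n))
    train_ids, test_ids = [], []
    for _key, members in final:
        if len(train_ids) < n_target:
            train_ids.extend(members)
        else:
            test_ids.extend(members)
    if not test_ids:
        raise ValueError("scaffold split left the test side empty")
    split = SplitIndices(
        train_ids=train_ids, test_ids=test_ids,
        kind="scaffold", seed=seed, train_fraction=frac,
    )
    return _flag_test_classes(split, ms)
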