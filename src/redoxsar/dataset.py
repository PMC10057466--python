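"""Compound dataset, molecular graphs and seeded conformers.

The bundled dataset covers 30 organic micropollutants (pharmaceuticals,
pesticides, plasticizers and single-ring aromatics) whose photocatalytic
degradation was profiled with radical scavengers to obtain a K coefficient
(oxidative HO* share over reductive O2*- share) per compound, together
with the transformed response used for regression modeling. Structures are
curated parent (salt-stripped, neutral) SMILES for each CAS number.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import AllChem

from .kinetics import transform_response

#: test-set members fixed by the curated train/test split
TEST_SET = frozenset({"AMX", "CIP", "1,4-DMB", "p-MP", "SZM"})

#: |transform_response(K) - printed t| bound when both columns are printed
#: at 3 decimals: 0.5e-3 * max|dt/dK| + 0.5e-3 = 7.5e-4 (double rounding).
_T_CONSISTENCY_TOL = 7.5e-4

_CAS_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")


def _embedding_seed(seed: int) -> int:
    """Map a user seed to a strictly positive RDKit embedding seed.

    RDKit derives per-conformer seeds multiplicatively from the base
    seed, so 0 collapses a requested ensemble onto one repeated
    geometry and negative values disable seeding altogether.
    """
    return int(seed) % (2**31 - 1) + 1


class DatasetError(ValueError):
    """Raised when a compound table fails validation."""


@dataclass(frozen=True)
class Compound:
    """One dataset row: identity, structure, split label and responses."""

    index: int
    name: str
    abbr: str
    cas: str
    smiles: str
    split: str
    K: float
    t_response: float


def _validate_cas(cas: str) -> None:
    if not _CAS_RE.match(cas):
        raise DatasetError(f"malformed CAS registry number: {cas!r}")
    digits = cas.replace("-", "")
    check = sum(int(d) * i for i, d in enumerate(reversed(digits[:-1]), start=1)) % 10
    if check != int(digits[-1]):
        raise DatasetError(f"CAS checksum failure: {cas!r}")


def load_dataset(path_or_default: str | None = None, *, expect_split: bool = True) -> list[Compound]:
    """Load and validate a compound table.

    Parameters
    ----------
    path_or_default : str or None
        CSV path with columns ``index,name,abbr,cas,smiles,split,K,tK``;
        ``None`` loads the bundled 30-compound table.
    expect_split : bool
        Enforce the curated 25 train / 5 test split and the 30-row count
        (disable for user-supplied tables of other sizes).

    Returns
    -------
    list of Compound

    Raises
    ------
    DatasetError
        On missing columns, duplicate abbreviations, malformed CAS,
        unparsable SMILES, inconsistent K/transformed-K pairs, or a split
        that is not 25/5 when ``expect_split`` is set.
    """
    if path_or_default is None:
        with resources.as_file(resources.files("redoxsar.data") / "table1.csv") as p:
            frame = pd.read_csv(p)
    else:
        frame = pd.read_csv(path_or_default)

    required = ["index", "name", "abbr", "cas", "smiles", "split", "K", "tK"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DatasetError(f"missing dataset columns: {missing}")

    if frame["abbr"].duplicated().any():
        dupes = sorted(frame.loc[frame["abbr"].duplicated(), "abbr"])
        raise DatasetError(f"duplicate abbreviations: {dupes}")

    compounds: list[Compound] = []
    for row in frame.itertuples(index=False):
        _validate_cas(str(row.cas))
        if Chem.MolFromSmiles(str(row.smiles)) is None:
            raise DatasetError(f"unparsable SMILES for {row.abbr}: {row.smiles!r}")
        if row.split not in ("train", "test"):
            raise DatasetError(f"split label must be train/test, got {row.split!r}")
        K = float(row.K)
        t = float(row.tK)
        if K < 0:
            raise DatasetError(f"negative K for {row.abbr}")
        if abs(transform_response(K) - t) > _T_CONSISTENCY_TOL:
            raise DatasetError(
                f"inconsistent K/transformed pair for {row.abbr}: "
                f"t(K)={transform_response(K):.6f} vs printed {t}"
            )
        compounds.append(
            Compound(
                index=int(row.index),
                name=str(row.name),
                abbr=str(row.abbr),
                cas=str(row.cas),
                smiles=str(row.smiles),
                split=str(row.split),
                K=K,
                t_response=t,
            )
        )

    if expect_split:
        n_train = sum(c.split == "train" for c in compounds)
        n_test = sum(c.split == "test" for c in compounds)
        if len(compounds) != 30 or (n_train, n_test) != (25, 5):
            raise DatasetError(
                f"expected 30 compounds split 25 train / 5 test, "
                f"got {len(compounds)} ({n_train}/{n_test})"
            )
        test_members = {c.abbr for c in compounds if c.split == "test"}
        if test_members != set(TEST_SET):
            raise DatasetError(f"unexpected test-set members: {sorted(test_members)}")

    return compounds


def dataset_frame(compounds: Sequence[Compound]) -> pd.DataFrame:
    """Compounds as a DataFrame indexed by abbreviation."""
    return pd.DataFrame(
        {
            "name": [c.name for c in compounds],
            "cas": [c.cas for c in compounds],
            "smiles": [c.smiles for c in compounds],
            "split": [c.split for c in compounds],
            "K": [c.K for c in compounds],
            "t_response": [c.t_response for c in compounds],
        },
        index=pd.Index([c.abbr for c in compounds], name="abbr"),
    )


# ---------------------------------------------------------------------------
# molecular graph
# ---------------------------------------------------------------------------

@dataclass
class MolecularGraph:
    """Hydrogen-depleted heavy-atom graph with topological distances.

    ``dist`` holds all-pairs shortest-path lengths in bond counts.
    Attached-hydrogen counts and formal charges stay on the heavy atoms so
    pharmacophore typing does not need explicit hydrogens. The parsed RDKit
    molecule is retained for substructure queries.
    """

    elements: list[str]
    formal_charges: list[int]
    num_hs: list[int]
    bonds: list[tuple[int, int]]
    dist: np.ndarray
    mol: Chem.Mol = field(repr=False)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def atoms_of(self, element: str) -> list[int]:
        return [i for i, el in enumerate(self.elements) if el == element]

    def pair_distances(self, elem_a: str, elem_b: str) -> set[int]:
        """Set of topological distances realized between two element types."""
        out: set[int] = set()
        for i in self.atoms_of(elem_a):
            for j in self.atoms_of(elem_b):
                if i != j:
                    out.add(int(self.dist[i, j]))
        return out


def build_graph(smiles: str) -> MolecularGraph:
    """Build the H-depleted graph of a single-fragment structure.

    Topological distances are bond counts on the heavy-atom skeleton;
    multi-fragment inputs (salts, mixtures) are rejected because shortest
    paths between fragments are undefined.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    if len(Chem.GetMolFrags(mol)) != 1:
        raise ValueError(
            f"multi-fragment structure {smiles!r}: strip salts/counterions first"
        )
    dist = Chem.GetDistanceMatrix(mol).astype(int)
    return MolecularGraph(
        elements=[a.GetSymbol() for a in mol.GetAtoms()],
        formal_charges=[a.GetFormalCharge() for a in mol.GetAtoms()],
        num_hs=[a.GetTotalNumHs() for a in mol.GetAtoms()],
        bonds=[(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()],
        dist=dist,
        mol=mol,
    )


# ---------------------------------------------------------------------------
# conformers
# ---------------------------------------------------------------------------

@dataclass
class Conformer:
    """Seeded 3D geometry of the hydrogen-complete structure (Angstrom)."""

    elements: list[str]
    coordinates: np.ndarray
    seed: int

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def distance_matrix(self) -> np.ndarray:
        d = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((d**2).sum(axis=2))


def embed_conformer(smiles: str, seed: int, *, max_attempts: int = 5) -> Conformer:
    """Deterministic distance-geometry embedding with force-field refinement.

    Hydrogens are added, coordinates come from ETKDGv3 seeded with
    ``seed`` and are relaxed with MMFF94 (UFF fallback). The same seed
    reproduces identical coordinates bit for bit.
    """
    base = Chem.MolFromSmiles(smiles)
    if base is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    mol = Chem.AddHs(base)
    params = AllChem.ETKDGv3()
    params.useRandomCoords = False
    last_seed = _embedding_seed(seed)
    for attempt in range(max_attempts):
        last_seed = _embedding_seed(int(seed) + 7919 * attempt)
        params.randomSeed = last_seed
        if AllChem.EmbedMolecule(mol, params) == 0:
            break
    else:
        raise RuntimeError(f"conformer embedding failed after {max_attempts} attempts: {smiles!r}")
    try:
        if AllChem.MMFFHasAllMoleculeParams(mol):
            AllChem.MMFFOptimizeMolecule(mol, maxIters=2000)
        else:
            AllChem.UFFOptimizeMolecule(mol, maxIters=2000)
    except Exception:  # pragma: no cover - rdkit optimizer edge cases
        pass
    coords = mol.GetConformer().GetPositions().copy()
    if not np.all(np.isfinite(coords)):
        raise RuntimeError(f"non-finite conformer coordinates for {smiles!r}")
    return Conformer(
        elements=[a.GetSymbol() for a in mol.GetAtoms()],
        coordinates=coords,
        seed=last_seed,
    )


def embed_conformer_ensemble(smiles: str, seed: int, n_confs: int = 25) -> list[Conformer]:
    """Seeded multi-conformer ensemble, force-field refined.

    Used for conformation-dependent descriptors, which are averaged over
    the ensemble to damp the conformational noise of any single
    embedding. Deterministic for a given (seed, n_confs).
    """
    if n_confs < 1:
        raise ValueError("n_confs must be >= 1")
    if n_confs == 1:
        return [embed_conformer(smiles, seed)]
    base = Chem.MolFromSmiles(smiles)
    if base is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    mol = Chem.AddHs(base)
    params = AllChem.ETKDGv3()
    params.randomSeed = _embedding_seed(seed)
    ids = AllChem.EmbedMultipleConfs(mol, numConfs=n_confs, params=params)
    if len(ids) == 0:
        return [embed_conformer(smiles, seed)]
    if AllChem.MMFFHasAllMoleculeParams(mol):
        AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=2000)
    else:
        AllChem.UFFOptimizeMoleculeConfs(mol, maxIters=2000)
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    out = []
    for cid in ids:
        coords = mol.GetConformer(cid).GetPositions().copy()
        if np.all(np.isfinite(coords)):
            out.append(Conformer(elements=elements, coordinates=coords, seed=int(seed)))
    if not out:
        raise RuntimeError(f"no finite conformers for {smiles!r}")
    return out
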