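"""Molecular descriptor families of the degradation-mechanism model.

Four families are implemented from first principles:

* **MATS** — Moran autocorrelation of an atomic property over the
  H-depleted graph at a topological lag,
* **Mor (3D-MoRSE)** — scattering-function sums over the 3D geometry of
  the hydrogen-complete molecule,
* **CATS2D** — counts of pharmacophore-type pairs (donor, acceptor,
  positive, negative, lipophilic) at topological lags 0-9,
* **B0k (2D atom pairs)** — presence/absence of an element pair at an
  exact topological distance.

2D descriptors are computed on the H-depleted heavy-atom graph; 3D-MoRSE
uses seeded conformers with explicit hydrogens. ``surrogate`` columns are
pass-through numeric descriptors for quantities computed elsewhere (e.g.
quantum-chemical values supplied by the user).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.preprocessing import MinMaxScaler

from .dataset import (
    Compound,
    Conformer,
    MolecularGraph,
    build_graph,
    embed_conformer,
    embed_conformer_ensemble,
)
from .elements import DEFAULT_PROPERTIES

PPP_TYPES = ("D", "A", "P", "N", "L")

# --------------------------------------------------------------------------
# descriptor specs
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DescriptorSpec:
    """One named descriptor: family plus its parameters.

    family in {"MATS", "MoRSE", "CATS2D", "B0k", "surrogate"}; parameters:
    ``lag`` (MATS lag, MoRSE signal or CATS2D/B0k topological distance),
    ``weight`` in {u, m, v, e, p}, ``pair`` (element pair for B0k or
    pharmacophore-type pair for CATS2D) and ``label`` for surrogates.
    """

    family: str
    lag: int | None = None
    weight: str | None = None
    pair: tuple[str, str] | None = None
    label: str | None = None

    @property
    def name(self) -> str:
        if self.family == "MATS":
            return f"MATS{self.lag}{self.weight}"
        if self.family == "MoRSE":
            return f"Mor{self.lag:02d}{self.weight}"
        if self.family == "CATS2D":
            a, b = self.pair
            return f"CATS2D_{self.lag:02d}_{a}{b}"
        if self.family == "B0k":
            a, b = self.pair
            return f"B{self.lag:02d}[{a}-{b}]"
        if self.family == "surrogate":
            return self.label
        raise ValueError(f"unknown descriptor family {self.family!r}")

    @classmethod
    def from_name(cls, name: str) -> "DescriptorSpec":
        """Parse a rendered descriptor name back into a spec."""
        import re

        m = re.fullmatch(r"MATS(\d)([umvep])", name)
        if m:
            return cls("MATS", lag=int(m.group(1)), weight=m.group(2))
        m = re.fullmatch(r"Mor(\d{2})([umvep])", name)
        if m:
            return cls("MoRSE", lag=int(m.group(1)), weight=m.group(2))
        m = re.fullmatch(r"CATS2D_(\d{2})_([DAPNL])([DAPNL])", name)
        if m:
            return cls("CATS2D", lag=int(m.group(1)), pair=(m.group(2), m.group(3)))
        m = re.fullmatch(r"B(\d{2})\[(\w+)-(\w+)\]", name)
        if m:
            return cls("B0k", lag=int(m.group(1)), pair=(m.group(2), m.group(3)))
        return cls("surrogate", label=name)


def final_model_specs() -> list[DescriptorSpec]:
    """The five descriptors of the selected five-variable model."""
    return [
        DescriptorSpec("MATS", lag=4, weight="v"),
        DescriptorSpec("MoRSE", lag=10, weight="u"),
        DescriptorSpec("CATS2D", lag=1, pair=("D", "N")),
        DescriptorSpec("B0k", lag=4, pair=("C", "Cl")),
        DescriptorSpec("B0k", lag=8, pair=("C", "O")),
    ]


def default_grid() -> list[DescriptorSpec]:
    """A configurable screening grid of the four families.

    MATS lags 1-8 x weights {m,v,e,p}; MoRSE signals 1-32 x {u,v};
    CATS2D all 15 type pairs x lags 0-9; B0k over {C,N,O,S,Cl,F} element
    pairs x distances 1-10.
    """
    specs: list[DescriptorSpec] = []
    for lag in range(1, 9):
        for w in "mvep":
            specs.append(DescriptorSpec("MATS", lag=lag, weight=w))
    for sig in range(1, 33):
        for w in ("u", "v"):
            specs.append(DescriptorSpec("MoRSE", lag=sig, weight=w))
    for a, b in itertools.combinations_with_replacement(PPP_TYPES, 2):
        for lag in range(0, 10):
            specs.append(DescriptorSpec("CATS2D", lag=lag, pair=(a, b)))
    elems = ("C", "N", "O", "S", "Cl", "F")
    for a, b in itertools.combinations_with_replacement(elems, 2):
        for k in range(1, 11):
            specs.append(DescriptorSpec("B0k", lag=k, pair=(a, b)))
    return specs


# --------------------------------------------------------------------------
# pharmacophore typing
# --------------------------------------------------------------------------

_NITRO = Chem.MolFromSmarts("[N+](=O)[O-]")
_CARBOXYL_C = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
_SULFONIC_S = Chem.MolFromSmarts("[SX4](=O)(=O)[OX2H1]")
_PHOSPHONIC_P = Chem.MolFromSmarts("[PX4](=O)[OX2H1]")
_BASIC_AMINE = Chem.MolFromSmarts("[NX3;!$([N]a);!$([N]C=[O,N,S]);!$([N][S,P]=O);!$([N]=*)]")
_LIPO_NEIGHBORS = frozenset({"C", "S", "F", "Cl", "Br", "I"})


def assign_ppp_types(graph: MolecularGraph) -> list[frozenset[str]]:
    """Assign pharmacophore point types to every heavy atom.

    D: O or N bearing at least one hydrogen. A: any oxygen, plus nitrogen
    with no hydrogen outside nitro groups. P: positively charged atoms or
    basic (aliphatic, non-amide, non-anilinic) amine N. N: negatively
    charged atoms or the central atom of an acidic group (carboxylic C,
    sulfonic S, phosphonic P) — typing the central atom puts the -COOH
    donor-negative pair at topological distance 1. L: carbon or sulfur
    whose neighbors are all C/S/halogen (hydrogens allowed). Nitro groups
    are treated as neutral: their charge-separated depiction contributes
    no P/N types. Typing is total; atoms may carry several types or none.
    """
    mol = graph.mol
    nitro_atoms: set[int] = set()
    for match in mol.GetSubstructMatches(_NITRO):
        nitro_atoms.update(match)
    negative_centers: set[int] = set()
    for patt in (_CARBOXYL_C, _SULFONIC_S, _PHOSPHONIC_P):
        for match in mol.GetSubstructMatches(patt):
            negative_centers.add(match[0])
    basic_n = {match[0] for match in mol.GetSubstructMatches(_BASIC_AMINE)}

    types: list[frozenset[str]] = []
    for atom in mol.GetAtoms():
        i = atom.GetIdx()
        el = atom.GetSymbol()
        n_h = atom.GetTotalNumHs()
        charge = atom.GetFormalCharge()
        t: set[str] = set()
        if el in ("O", "N") and n_h >= 1:
            t.add("D")
        if el == "O":
            t.add("A")
        elif el == "N" and n_h == 0 and i not in nitro_atoms:
            t.add("A")
        if (charge > 0 and i not in nitro_atoms) or i in basic_n:
            t.add("P")
        if (charge < 0 and i not in nitro_atoms) or i in negative_centers:
            t.add("N")
        if el in ("C", "S"):
            if all(nb.GetSymbol() in _LIPO_NEIGHBORS for nb in atom.GetNeighbors()):
                t.add("L")
        types.append(frozenset(t))
    return types


def cats2d(
    graph: MolecularGraph,
    lag: int,
    pair: tuple[str, str],
    types: list[frozenset[str]] | None = None,
) -> int:
    """Raw count of pharmacophore-type pairs at a topological lag.

    At lag 0 the count is over single atoms carrying both members of the
    pair (self-pairs); at lag >= 1 each unordered atom pair at that
    distance is counted once if one atom carries the first type and the
    other the second, in either orientation.
    """
    if not 0 <= lag <= 9:
        raise ValueError("CATS2D lag must be in 0..9")
    a, b = pair
    for t in (a, b):
        if t not in PPP_TYPES:
            raise ValueError(f"unknown pharmacophore type {t!r}")
    if types is None:
        types = assign_ppp_types(graph)
    if lag == 0:
        return sum(1 for t in types if a in t and b in t)
    count = 0
    for i in range(graph.n_atoms):
        for j in range(i + 1, graph.n_atoms):
            if graph.dist[i, j] != lag:
                continue
            ti, tj = types[i], types[j]
            if (a in ti and b in tj) or (b in ti and a in tj):
                count += 1
    return count


def atom_pair_presence(graph: MolecularGraph, elem_a: str, elem_b: str, k: int) -> int:
    """1 iff some atom of ``elem_a`` sits exactly ``k`` bonds from one of ``elem_b``."""
    if not 1 <= k <= 10:
        raise ValueError("topological distance k must be in 1..10")
    return int(k in graph.pair_distances(elem_a, elem_b))


def moran_autocorrelation(
    graph: MolecularGraph, k: int, weights, include_hydrogens: bool = True
) -> float:
    """Moran autocorrelation MATS_k of an atomic property at lag k.

    MATS_k = [ (1/D_k) * sum_{d(i,j)=k} (w_i - wbar)(w_j - wbar) ]
             / [ (1/A) * sum_i (w_i - wbar)^2 ]

    with D_k the number of ordered atom pairs at distance k and A the
    atom count. By default the autocorrelation runs over the
    hydrogen-complete graph — the convention of the reference descriptor
    calculators, whose carbon-scaled property weights assign hydrogens
    their own (small) contributions; ``include_hydrogens=False`` restricts
    it to the heavy-atom skeleton. ``weights`` is a scheme letter
    (u/m/v/e/p, carbon-scaled properties) or an explicit per-atom array
    matching the chosen graph. Returns 0 when no pair sits at the lag or
    the property has zero variance; both conventions keep descriptor
    matrices dense. The statistic is invariant to any affine rescaling of
    the weights, so the carbon scaling does not change MATS values.
    """
    if include_hydrogens:
        mol = Chem.AddHs(graph.mol)
        elements = [a.GetSymbol() for a in mol.GetAtoms()]
        dist = Chem.GetDistanceMatrix(mol).astype(int)
    else:
        elements = graph.elements
        dist = graph.dist
    n = len(elements)
    if n < 2:
        return 0.0
    if isinstance(weights, str):
        w = np.asarray(DEFAULT_PROPERTIES.weights(weights, elements))
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,):
            raise ValueError(
                f"weights array must have one value per atom of the "
                f"{'H-complete' if include_hydrogens else 'H-depleted'} graph ({n})"
            )
    centered = w - w.mean()
    denom = float(centered @ centered) / n
    if denom <= 0.0:
        return 0.0
    mask = dist == k
    np.fill_diagonal(mask, False)
    n_pairs = int(mask.sum())  # ordered pairs
    if n_pairs == 0:
        return 0.0
    num = float(centered @ (mask @ centered)) / n_pairs
    return num / denom


def morse_descriptor(conformer: Conformer, signal: int, weights: str = "u") -> float:
    """3D-MoRSE value Mor(signal) over the H-complete geometry.

    Mor_t = sum_{i<j} w_i w_j sin(s r_ij)/(s r_ij) with scattering
    parameter s = t - 1 (1/Angstrom); the s = 0 term is the limit
    w_i w_j. Depends on interatomic distances only, hence invariant under
    rigid motions of the coordinates.
    """
    if not 1 <= signal <= 32:
        raise ValueError("MoRSE signal must be in 1..32")
    n = conformer.n_atoms
    if n < 2:
        return 0.0
    w = np.asarray(DEFAULT_PROPERTIES.weights(weights, conformer.elements))
    r = conformer.distance_matrix()
    iu = np.triu_indices(n, k=1)
    rij = r[iu]
    if np.any(rij <= 0.0):
        raise ValueError("coincident atoms in conformer (zero interatomic distance)")
    s = float(signal - 1)
    ww = (w[:, None] * w[None, :])[iu]
    if s == 0.0:
        return float(ww.sum())
    x = s * rij
    return float((ww * np.sin(x) / x).sum())


def morse_ensemble(conformers: Sequence[Conformer], signal: int, weights: str = "u") -> float:
    """Ensemble-average 3D-MoRSE value over a conformer set.

    The average damps the conformational sensitivity of single-embedding
    MoRSE values and is the package's stand-in for descriptors computed
    on a single optimized geometry.
    """
    if len(conformers) == 0:
        raise ValueError("empty conformer ensemble")
    return float(np.mean([morse_descriptor(c, signal, weights) for c in conformers]))


# --------------------------------------------------------------------------
# matrix computation
# --------------------------------------------------------------------------


def _compound_inputs(compounds) -> tuple[list[str], list[str]]:
    """(ids, smiles) from Compound objects, (id, smiles) pairs or SMILES."""
    ids, smiles = [], []
    for i, c in enumerate(compounds):
        if isinstance(c, Compound):
            ids.append(c.abbr)
            smiles.append(c.smiles)
        elif isinstance(c, (tuple, list)) and len(c) == 2:
            ids.append(str(c[0]))
            smiles.append(str(c[1]))
        else:
            ids.append(f"mol{i + 1}")
            smiles.append(str(c))
    return ids, smiles


def compute_matrix(
    compounds: Sequence,
    specs: Sequence[DescriptorSpec],
    seed: int = 7,
    surrogates: pd.DataFrame | None = None,
    n_confs: int = 50,
) -> pd.DataFrame:
    """Dense descriptor matrix (compounds x named descriptors).

    Conformer ensembles for MoRSE columns (``n_confs`` members) are
    embedded deterministically from ``seed``, so repeated calls reproduce
    the matrix exactly. Surrogate specs are filled from the
    ``surrogates`` frame (indexed by compound id). Per-compound failures
    propagate with the compound id attached.
    """
    if len(specs) == 0:
        raise ValueError("no descriptor specs given")
    ids, smiles = _compound_inputs(compounds)
    need_3d = any(s.family == "MoRSE" for s in specs)
    rows = []
    for cid, smi in zip(ids, smiles):
        try:
            graph = build_graph(smi)
            types = assign_ppp_types(graph)
            confs = embed_conformer_ensemble(smi, seed, n_confs) if need_3d else None
            row = {}
            for spec in specs:
                if spec.family == "MATS":
                    val = moran_autocorrelation(graph, spec.lag, spec.weight)
                elif spec.family == "MoRSE":
                    val = morse_ensemble(confs, spec.lag, spec.weight)
                elif spec.family == "CATS2D":
                    val = cats2d(graph, spec.lag, spec.pair, types)
                elif spec.family == "B0k":
                    val = atom_pair_presence(graph, *spec.pair, spec.lag)
                elif spec.family == "surrogate":
                    if surrogates is None or spec.name not in surrogates.columns:
                        raise ValueError(f"no surrogate values supplied for {spec.name}")
                    val = float(surrogates.loc[cid, spec.name])
                else:
                    raise ValueError(f"unknown descriptor family {spec.family!r}")
                row[spec.name] = float(val)
            rows.append(row)
        except Exception as exc:
            raise RuntimeError(f"descriptor computation failed for {cid}: {exc}") from exc
    frame = pd.DataFrame(rows, index=pd.Index(ids, name="abbr"))
    return frame[[s.name for s in specs]]


def prefilter_correlated(
    matrix: pd.DataFrame, r_threshold: float = 0.99
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Drop near-duplicate descriptor columns by a greedy correlation scan.

    Constant columns are dropped first (partner ``None``); then columns
    are scanned in order and, for every pair with |Pearson r| >=
    ``r_threshold``, the later column is dropped. The removal log lists
    (dropped, kept_partner, r).
    """
    removals: list[tuple[str, str | None, float]] = []
    values = matrix.to_numpy(float)
    std = values.std(axis=0)
    keep_mask = std > 0
    for name in matrix.columns[~keep_mask]:
        removals.append((name, None, 0.0))
    kept_cols = list(matrix.columns[keep_mask])
    sub = matrix[kept_cols]
    if len(kept_cols) > 1:
        corr = np.corrcoef(sub.to_numpy(float), rowvar=False)
        dropped: set[int] = set()
        for i in range(len(kept_cols)):
            if i in dropped:
                continue
            for j in range(i + 1, len(kept_cols)):
                if j in dropped:
                    continue
                if abs(corr[i, j]) >= r_threshold:
                    dropped.add(j)
                    removals.append((kept_cols[j], kept_cols[i], float(corr[i, j])))
        kept_cols = [c for k, c in enumerate(kept_cols) if k not in dropped]
    return matrix[kept_cols], removals


# --------------------------------------------------------------------------
# scikit-learn estimators
# --------------------------------------------------------------------------


class DescriptorCalculator(BaseEstimator, TransformerMixin):
    """Stateless transformer: structures in, descriptor matrix out.

    Parameters
    ----------
    specs : "final-model", "default" or a list of DescriptorSpec/names
    seed : int
        Conformer-embedding seed for 3D-MoRSE columns.
    n_confs : int
        Ensemble size over which MoRSE values are averaged.
    """

    def __init__(self, specs="final-model", seed: int = 7, n_confs: int = 50):
        self.specs = specs
        self.seed = seed
        self.n_confs = n_confs

    def _resolved_specs(self) -> list[DescriptorSpec]:
        if self.specs == "final-model":
            return final_model_specs()
        if self.specs == "default":
            return default_grid()
        return [
            s if isinstance(s, DescriptorSpec) else DescriptorSpec.from_name(str(s))
            for s in self.specs
        ]

    def fit(self, X=None, y=None):
        self.specs_ = self._resolved_specs()
        self.feature_names_out_ = [s.name for s in self.specs_]
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "specs_"):
            self.fit()
        return compute_matrix(X, self.specs_, seed=self.seed, n_confs=self.n_confs)

    def get_feature_names_out(self, input_features=None):
        if not hasattr(self, "specs_"):
            self.fit()
        return np.asarray(self.feature_names_out_, dtype=object)


class CorrelationFilter(BaseEstimator, TransformerMixin):
    """Greedy |r| >= threshold column pre-filter (fit learns kept columns)."""

    def __init__(self, threshold: float = 0.99):
        self.threshold = threshold

    def fit(self, X: pd.DataFrame, y=None):
        reduced, removals = prefilter_correlated(X, self.threshold)
        self.kept_columns_ = list(reduced.columns)
        self.removals_ = removals
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.kept_columns_]


class MinMaxNormalizer(BaseEstimator, TransformerMixin):
    """Per-column min-max scaling fitted on training rows only.

    Fitted columns span [0, 1] on the training rows; rows outside the
    training range map outside [0, 1] (no clipping), and constant
    training columns map to 0. Thin wrapper over sklearn's MinMaxScaler
    that preserves DataFrame structure and round-trips exactly.
    """

    def fit(self, X: pd.DataFrame, y=None):
        self.columns_ = list(X.columns)
        self._scaler = MinMaxScaler(clip=False)
        self._scaler.fit(X.to_numpy(float))
        self.data_min_ = pd.Series(self._scaler.data_min_, index=self.columns_)
        self.data_max_ = pd.Series(self._scaler.data_max_, index=self.columns_)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        arr = self._scaler.transform(X[self.columns_].to_numpy(float))
        return pd.DataFrame(arr, index=X.index, columns=self.columns_)

    def inverse_transform(self, X: pd.DataFrame) -> pd.DataFrame:
        arr = self._scaler.inverse_transform(X[self.columns_].to_numpy(float))
        return pd.DataFrame(arr, index=X.index, columns=self.columns_)

    def to_dict(self) -> dict:
        return {
            "columns": self.columns_,
            "min": self.data_min_.tolist(),
            "max": self.data_max_.tolist(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "MinMaxNormalizer":
        frame = pd.DataFrame(
            [payload["min"], payload["max"]], columns=payload["columns"]
        )
        return cls().fit(frame)


def normalize(
    matrix: pd.DataFrame, training_ids: Sequence[str]
) -> tuple[pd.DataFrame, MinMaxNormalizer]:
    """Min-max normalize all rows with ranges fitted on training rows."""
    missing = [i for i in training_ids if i not in matrix.index]
    if missing:
        raise KeyError(f"training ids not in matrix: {missing}")
    scaler = MinMaxNormalizer().fit(matrix.loc[list(training_ids)])
    return scaler.transform(matrix), scaler
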