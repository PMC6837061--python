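"""Attributed molecular graphs from SMILES.

Molecules are represented as heavy-atom graphs: nodes carry fixed-length
atom feature vectors (element one-hot with an "other" slot, degree,
attached-hydrogen count, implicit valence, aromaticity), edges carry bond
feature vectors (bond-order one-hot, conjugation, ring membership).
Hydrogens are implicit and enter only through the attached-H count.

Parsing is delegated to RDKit; atom order is RDKit's order for the input
string, which is deterministic for a given SMILES.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem

logger = logging.getLogger(__name__)

#: Default element vocabulary; anything else maps to the trailing "other" slot.
DEFAULT_ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")

#: Per-degree transition matrices exist for degrees 0..MAX_DEGREE only.
MAX_DEGREE = 5

_H_COUNTS = 5       # one-hot 0..4 attached hydrogens
_VALENCES = 6       # one-hot 0..5 implicit valence
_BOND_ORDERS = 4    # single / double / triple / aromatic

BOND_FEATURE_DIM = _BOND_ORDERS + 2  # + conjugated flag + in-ring flag


def atom_feature_dim(elements: tuple[str, ...] = DEFAULT_ELEMENTS) -> int:
    """Length F_a of an atom feature vector for a given element vocabulary."""
    return (len(elements) + 1) + (MAX_DEGREE + 1) + _H_COUNTS + _VALENCES + 1


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecular graph."""


@dataclass
class MolecularGraph:
    """Heavy-atom molecular graph with fixed-width atom and bond features.

    Attributes
    ----------
    atom_features : (n_atoms, F_a) float array.
    edge_src, edge_dst : directed edge endpoint indices; every bond (v, w)
        appears twice, as v->w and w->v, so the neighbour relation is
        symmetric by construction.
    edge_features : (n_edges, F_b) float array; identical for v->w and w->v.
    degrees : per-atom bond counts.
    smiles : the string the graph was parsed from (if any).
    """

    atom_features: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_features: np.ndarray
    degrees: np.ndarray
    smiles: str | None = None
    _degree_groups: dict[int, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.edge_src.shape[0] // 2

    def neighbors(self, v: int) -> np.ndarray:
        return self.edge_dst[self.edge_src == v]

    def degree_groups(self) -> dict[int, np.ndarray]:
        """Atom indices grouped by degree (cached; used by message passing)."""
        if self._degree_groups is None:
            groups: dict[int, np.ndarray] = {}
            for d in np.unique(self.degrees):
                groups[int(d)] = np.flatnonzero(self.degrees == d)
            self._degree_groups = groups
        return self._degree_groups

    def environment_multiset(self) -> list[tuple]:
        """Multiset of (atom feature, sorted neighbour features) pairs.

        Invariant under graph isomorphism: two SMILES spellings of the same
        molecule produce equal multisets (after sorting).
        """
        items = []
        for v in range(self.n_atoms):
            nbr = sorted(
                tuple(self.atom_features[w]) for w in self.neighbors(v)
            )
            items.append((tuple(self.atom_features[v]), tuple(nbr)))
        return sorted(items)

    def to_json_dict(self) -> dict:
        """JSON-serializable dump of the featurized graph (debugging aid)."""
        return {
            "smiles": self.smiles,
            "atom_features": self.atom_features.tolist(),
            "edge_src": self.edge_src.tolist(),
            "edge_dst": self.edge_dst.tolist(),
            "edge_features": self.edge_features.tolist(),
            "degrees": self.degrees.tolist(),
        }


def _one_hot(index: int, size: int) -> np.ndarray:
    v = np.zeros(size)
    v[index] = 1.0
    return v


def featurize_atom(
    atom: Chem.Atom, elements: tuple[str, ...] = DEFAULT_ELEMENTS
) -> np.ndarray:
    """Fixed-length feature vector for an RDKit atom.

    Layout: element one-hot (+ "other"), degree one-hot 0..5, attached-H
    count one-hot 0..4, implicit valence one-hot 0..5, aromaticity flag.
    Out-of-vocabulary elements map to the "other" slot rather than failing.
    """
    sym = atom.GetSymbol()
    elem_idx = elements.index(sym) if sym in elements else len(elements)
    degree = atom.GetDegree()
    if degree > MAX_DEGREE:
        raise SmilesParseError(
            f"atom {atom.GetIdx()} ({sym}) has degree {degree} > {MAX_DEGREE}; "
            "per-degree transition matrices are only defined up to degree "
            f"{MAX_DEGREE}"
        )
    h_count = min(atom.GetTotalNumHs(), _H_COUNTS - 1)
    valence = min(atom.GetImplicitValence(), _VALENCES - 1)
    return np.concatenate(
        [
            _one_hot(elem_idx, len(elements) + 1),
            _one_hot(degree, MAX_DEGREE + 1),
            _one_hot(h_count, _H_COUNTS),
            _one_hot(valence, _VALENCES),
            [1.0 if atom.GetIsAromatic() else 0.0],
        ]
    )


def featurize_bond(bond: Chem.Bond) -> np.ndarray:
    """Bond feature vector: order one-hot, conjugation flag, ring flag.

    Symmetric by construction (no direction-dependent entries).
    """
    bt = bond.GetBondType()
    order = np.zeros(_BOND_ORDERS)
    if bt == Chem.BondType.SINGLE:
        order[0] = 1.0
    elif bt == Chem.BondType.DOUBLE:
        order[1] = 1.0
    elif bt == Chem.BondType.TRIPLE:
        order[2] = 1.0
    elif bt == Chem.BondType.AROMATIC:
        order[3] = 1.0
    return np.concatenate(
        [
            order,
            [1.0 if bond.GetIsConjugated() else 0.0],
            [1.0 if bond.IsInRing() else 0.0],
        ]
    )


def parse_smiles(
    smiles: str, elements: tuple[str, ...] = DEFAULT_ELEMENTS
) -> MolecularGraph:
    """Parse one SMILES string into a :class:`MolecularGraph`.

    Raises :class:`SmilesParseError` for empty or syntactically invalid
    input, or when any atom exceeds the supported maximum degree. For
    multi-fragment inputs (salts, mixtures) only the largest fragment by
    heavy-atom count is kept.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumAtoms())

    atoms = np.array(
        [featurize_atom(a, elements) for a in mol.GetAtoms()], dtype=np.float64
    )
    src, dst, efeat = [], [], []
    for bond in mol.GetBonds():
        v, w = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        e = featurize_bond(bond)
        src += [v, w]
        dst += [w, v]
        efeat += [e, e]
    n = mol.GetNumAtoms()
    edge_src = np.asarray(src, dtype=np.intp)
    edge_dst = np.asarray(dst, dtype=np.intp)
    edge_features = (
        np.asarray(efeat, dtype=np.float64)
        if efeat
        else np.zeros((0, BOND_FEATURE_DIM))
    )
    degrees = np.bincount(edge_src, minlength=n).astype(np.intp)
    return MolecularGraph(
        atom_features=atoms,
        edge_src=edge_src,
        edge_dst=edge_dst,
        edge_features=edge_features,
        degrees=degrees,
        smiles=smiles,
    )


def read_dataset(
    path,
    smiles_col: str = "smiles",
    target_col: str | None = "y",
    elements: tuple[str, ...] = DEFAULT_ELEMENTS,
) -> tuple[list[MolecularGraph], np.ndarray, int]:
    """Read a CSV of SMILES (and optionally targets) into graphs.

    Rows whose SMILES cannot be parsed are dropped with a logged warning;
    the number dropped is returned. Rows with a missing/empty target are
    kept as unlabelled (target NaN) for the semi-supervised stage; the same
    applies when ``target_col`` is None or absent from the file.

    Returns
    -------
    graphs, targets (NaN where unlabelled), n_dropped.
    """
    df = pd.read_csv(path)
    if smiles_col not in df.columns:
        raise KeyError(
            f"column {smiles_col!r} not found in {path} "
            f"(columns: {list(df.columns)})"
        )
    has_target = target_col is not None and target_col in df.columns
    graphs: list[MolecularGraph] = []
    targets: list[float] = []
    n_dropped = 0
    for _, row in df.iterrows():
        try:
            g = parse_smiles(str(row[smiles_col]), elements)
        except SmilesParseError as exc:
            logger.warning("dropping row: %s", exc)
            n_dropped += 1
            continue
        graphs.append(g)
        if has_target and pd.notna(row[target_col]):
            targets.append(float(row[target_col]))
        else:
            targets.append(np.nan)
    return graphs, np.asarray(targets, dtype=np.float64), n_dropped
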