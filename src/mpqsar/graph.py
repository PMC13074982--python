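"""Hydrogen-explicit molecular graphs with per-atom property weights.

SMILES parsing and aromaticity perception are delegated to RDKit; the graph is
then frozen into a light-weight container carrying exactly what the descriptor
engine needs: element symbols, per-atom property weights (mass, van der Waals
volume, polarizability), Kekule bond orders with aromatic flags, and the
all-pairs topological distance matrix in bond counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from rdkit import Chem, RDLogger
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

RDLogger.DisableLog("rdApp.*")

#: weighting schemes: atomic mass / van der Waals volume / polarizability
SCHEMES = ("m", "v", "p")

_SCHEME_FIELDS = {"m": "mass", "v": "vdw_volume", "p": "polarizability"}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


class UnsupportedElementError(ValueError):
    """Raised when a molecule contains an element outside the property table."""


class DisconnectedGraphError(ValueError):
    """Raised for multi-fragment molecules (descriptors are undefined there)."""


class PropertyTableError(KeyError):
    """Raised when the property table lacks a required element or column."""


@dataclass(frozen=True)
class Atom:
    element: str
    mass: float
    vdw_volume: float
    polarizability: float
    is_terminal: bool
    exact_mass: float  # most-abundant isotope; Burden-matrix diagonal only


@dataclass(frozen=True)
class Bond:
    i: int
    j: int
    order: float  # Kekule order: 1.0, 2.0 or 3.0
    aromatic: bool = False


class AtomPropertyTable:
    """Per-element constants behind the m/v/p weighting schemes.

    Loaded from a plain-text CSV so the calibrated constants can be diffed
    against their sources (Bondi/Rowland-Taylor radii, CRC polarizabilities,
    IUPAC atomic weights). ``provenance`` carries the table's header comment.
    """

    def __init__(self, rows: dict[str, dict[str, float]], provenance: str = ""):
        self._rows = rows
        self.provenance = provenance
        for el, props in rows.items():
            for f in ("mass", "vdw_volume", "polarizability", "exact_mass"):
                if f not in props:
                    raise PropertyTableError(f"element {el!r} lacks {f!r}")
                if props[f] <= 0:
                    raise ValueError(f"{f} of {el!r} must be positive")

    @classmethod
    def default(cls) -> "AtomPropertyTable":
        text = (
            resources.files("mpqsar.data") / "atomic_properties.csv"
        ).read_text()
        comments = [l for l in text.splitlines() if l.startswith("#")]
        lines = [l for l in text.splitlines() if l and not l.startswith("#")]
        rows = {}
        for rec in csv.DictReader(lines):
            rows[rec["element"]] = {
                k: float(v) for k, v in rec.items() if k != "element"
            }
        return cls(rows, provenance="\n".join(comments))

    @property
    def elements(self) -> frozenset[str]:
        return frozenset(self._rows)

    def __contains__(self, element: str) -> bool:
        return element in self._rows

    def get(self, element: str, prop: str) -> float:
        try:
            return self._rows[element][prop]
        except KeyError as exc:
            raise PropertyTableError(
                f"no property {prop!r} for element {element!r}"
            ) from exc


_DEFAULT_TABLE: AtomPropertyTable | None = None


def default_property_table() -> AtomPropertyTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = AtomPropertyTable.default()
    return _DEFAULT_TABLE


@dataclass
class MoleculeGraph:
    """Hydrogen-explicit molecular graph with topological distances."""

    atoms: list[Atom]
    bonds: list[Bond]
    dist: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        seen = set()
        for b in self.bonds:
            if b.i == b.j:
                raise ValueError("self-bond")
            key = (min(b.i, b.j), max(b.i, b.j))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)
        if self.dist is None:
            self.dist = topological_distances(self)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def formula_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for a in self.atoms:
            out[a.element] = out.get(a.element, 0) + 1
        return out


def topological_distances(g: MoleculeGraph) -> np.ndarray:
    """All-pairs shortest path lengths in bond counts (BFS on the bond list).

    Raises :class:`DisconnectedGraphError` for multi-fragment inputs: the
    autocorrelation lags have no defined semantics across fragments.
    """
    n = g.n_atoms
    if n == 0:
        return np.zeros((0, 0), dtype=int)
    rows = [b.i for b in g.bonds] + [b.j for b in g.bonds]
    cols = [b.j for b in g.bonds] + [b.i for b in g.bonds]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, _ = connected_components(adj, directed=False)
    if n_comp != 1:
        raise DisconnectedGraphError(
            f"graph has {n_comp} fragments; descriptors require one"
        )
    d = shortest_path(adj, method="D", unweighted=True, directed=False)
    return d.astype(int)


def parse_molecule(
    smiles: str, table: AtomPropertyTable | None = None
) -> MoleculeGraph:
    """Parse a SMILES string into a hydrogen-explicit :class:`MoleculeGraph`.

    Implicit hydrogens are made explicit before anything else: the calibrated
    autocorrelation conventions include H atoms in the weight vectors and the
    distance matrix. Formal charges (e.g. the nitro group written as
    ``[N+](=O)[O-]``) do not alter property lookup.
    """
    table = table or default_property_table()
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    bad = sorted(
        {a.GetSymbol() for a in mol.GetAtoms() if a.GetSymbol() not in table}
    )
    if bad:
        raise UnsupportedElementError(
            f"unsupported element(s) {bad} in {smiles!r}; "
            f"supported: {sorted(table.elements)}"
        )
    mol = Chem.AddHs(mol)
    kek = Chem.Mol(mol)
    Chem.Kekulize(kek, clearAromaticFlags=True)

    atoms = []
    for a in mol.GetAtoms():
        el = a.GetSymbol()
        atoms.append(
            Atom(
                element=el,
                mass=table.get(el, "mass"),
                vdw_volume=table.get(el, "vdw_volume"),
                polarizability=table.get(el, "polarizability"),
                is_terminal=a.GetDegree() == 1,
                exact_mass=table.get(el, "exact_mass"),
            )
        )
    bonds = []
    for b in mol.GetBonds():
        kb = kek.GetBondBetweenAtoms(b.GetBeginAtomIdx(), b.GetEndAtomIdx())
        bonds.append(
            Bond(
                i=b.GetBeginAtomIdx(),
                j=b.GetEndAtomIdx(),
                order=float(kb.GetBondTypeAsDouble()),
                aromatic=b.GetIsAromatic(),
            )
        )
    dist = np.asarray(Chem.GetDistanceMatrix(mol), dtype=int)
    return MoleculeGraph(atoms=atoms, bonds=bonds, dist=dist)


def atom_weights(g: MoleculeGraph, scheme: str) -> np.ndarray:
    """Per-atom weight vector for scheme ``m`` (mass), ``v`` (volume) or ``p``."""
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    f = _SCHEME_FIELDS[scheme]
    return np.array([getattr(a, f) for a in g.atoms], dtype=float)
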