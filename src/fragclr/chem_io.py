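"""Parsing of molecules into hydrogen-depleted annotated graphs.

A molecule is represented as an annotated graph ``G = {V, E, X_atom, X_bond}``
over heavy atoms only: hydrogens are folded into the atom environment and never
appear as nodes.  The atom feature scheme deliberately records the number of
heavy-atom bonds of every atom (``heavy_degree``): this redundancy between the
topology ``E`` and the annotation ``X_atom`` is what makes fragment-pair views
recognisably *invalid* molecular graphs, which is the core of the
semantic-invariance argument implemented in :mod:`fragclr.views`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

# Silence RDKit's own stderr chatter; malformed records are reported through
# the module logger instead.
RDLogger.DisableLog("rdApp.*")

#: Fixed element vocabulary (organic subset); anything else maps to "other".
ELEMENTS: tuple[str, ...] = ("C", "N", "O", "S", "P", "F", "Cl", "Br", "I", "B")
OTHER_ELEMENT = "other"
ELEMENT_VOCAB: tuple[str, ...] = ELEMENTS + (OTHER_ELEMENT,)

HYBRIDIZATIONS: tuple[str, ...] = ("SP", "SP2", "SP3", "other")
BOND_ORDERS: tuple[str, ...] = ("single", "double", "triple", "aromatic")

_BOND_TYPE_MAP = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}


@dataclass(frozen=True)
class AtomFeatures:
    """Annotation of a single heavy atom.

    ``heavy_degree`` is the number of bonds to other heavy atoms and must equal
    the atom's degree in the parent graph; it is the information carrier that
    lets a fragment-pair view be distinguished from every real molecule.
    """

    element: str
    heavy_degree: int
    formal_charge: int
    aromatic: bool
    hybridization: str
    in_ring: bool

    def __post_init__(self) -> None:
        if self.element not in ELEMENT_VOCAB:
            raise ValueError(f"element {self.element!r} not in vocabulary")
        if self.heavy_degree < 0:
            raise ValueError("heavy_degree must be >= 0")

    def element_onehot(self) -> np.ndarray:
        v = np.zeros(len(ELEMENT_VOCAB))
        v[ELEMENT_VOCAB.index(self.element)] = 1.0
        return v


@dataclass(frozen=True)
class BondFeatures:
    """Annotation of a single bond (order, conjugation, ring membership)."""

    order: str
    conjugated: bool
    in_ring: bool

    def __post_init__(self) -> None:
        if self.order not in BOND_ORDERS:
            raise ValueError(f"unknown bond order {self.order!r}")


Edge = tuple[int, int]


def _as_edge(i: int, j: int) -> Edge:
    if i == j:
        raise ValueError("self-loop edge")
    return (i, j) if i < j else (j, i)


@dataclass
class MolecularGraph:
    """Hydrogen-depleted annotated molecular graph.

    ``edges`` stores each unordered heavy-atom pair once as ``(min, max)``;
    atom indexing is 0-based and follows the RDKit atom order of the parsed
    input.  ``mol`` keeps the RDKit molecule for canonicalisation, scaffold
    extraction and brute-force view reconstruction; it is excluded from
    equality.
    """

    atoms: list[AtomFeatures]
    edges: frozenset[Edge]
    edge_features: dict[Edge, BondFeatures]
    smiles: str
    mol: Chem.Mol = field(compare=False, repr=False, default=None)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def degree(self, i: int) -> int:
        return sum(1 for e in self.edges if i in e)

    def neighbors(self, i: int) -> list[int]:
        return sorted(j for e in self.edges for j in e if i in e and j != i)

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        n = self.n_atoms
        for (i, j) in self.edges:
            if not (0 <= i < j < n):
                raise ValueError(f"bad edge ({i}, {j}) for {n} atoms")
            if (i, j) not in self.edge_features:
                raise ValueError(f"edge ({i}, {j}) lacks features")
        deg = {i: 0 for i in range(n)}
        for (i, j) in self.edges:
            deg[i] += 1
            deg[j] += 1
        for i, a in enumerate(self.atoms):
            if deg[i] != a.heavy_degree:
                raise ValueError(
                    f"atom {i}: degree {deg[i]} != heavy_degree {a.heavy_degree}"
                )

    # ---- numeric featurisation used by the encoders -------------------------

    def atom_matrix(self) -> np.ndarray:
        """Atom feature matrix X_atom, one row per heavy atom."""
        rows = []
        for a in self.atoms:
            hyb = np.zeros(len(HYBRIDIZATIONS))
            hyb[HYBRIDIZATIONS.index(a.hybridization)] = 1.0
            rows.append(
                np.concatenate(
                    [
                        a.element_onehot(),
                        [float(a.heavy_degree)],
                        [float(a.formal_charge)],
                        [1.0 if a.aromatic else 0.0],
                        hyb,
                        [1.0 if a.in_ring else 0.0],
                    ]
                )
            )
        return np.asarray(rows)

    def bond_vector(self, e: Edge) -> np.ndarray:
        bf = self.edge_features[e]
        order = np.zeros(len(BOND_ORDERS))
        order[BOND_ORDERS.index(bf.order)] = 1.0
        return np.concatenate(
            [order, [1.0 if bf.conjugated else 0.0], [1.0 if bf.in_ring else 0.0]]
        )


ATOM_FEATURE_DIM = len(ELEMENT_VOCAB) + 3 + len(HYBRIDIZATIONS) + 1
BOND_FEATURE_DIM = len(BOND_ORDERS) + 2

#: Version tag of the declared feature scheme, stored in checkpoints.
FEATURE_SCHEME_VERSION = "fragclr-atom11-bond6-v1"


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a valid molecule."""


def _atom_features(atom: Chem.Atom) -> AtomFeatures:
    sym = atom.GetSymbol()
    if sym not in ELEMENTS:
        logger.warning("element %s outside vocabulary, mapped to 'other'", sym)
        sym = OTHER_ELEMENT
    hyb = str(atom.GetHybridization())
    if hyb not in HYBRIDIZATIONS:
        hyb = "other"
    return AtomFeatures(
        element=sym,
        heavy_degree=atom.GetDegree(),
        formal_charge=atom.GetFormalCharge(),
        aromatic=atom.GetIsAromatic(),
        hybridization=hyb,
        in_ring=atom.IsInRing(),
    )


def graph_from_mol(mol: Chem.Mol, smiles: str | None = None) -> MolecularGraph:
    """Build a :class:`MolecularGraph` from a sanitised RDKit molecule."""
    if mol.GetNumAtoms() == 0:
        raise SmilesParseError("molecule has no heavy atoms")
    atoms = [_atom_features(a) for a in mol.GetAtoms()]
    edges = set()
    edge_features: dict[Edge, BondFeatures] = {}
    for bond in mol.GetBonds():
        bt = bond.GetBondType()
        if bt not in _BOND_TYPE_MAP:
            raise SmilesParseError(f"unsupported bond type {bt}")
        e = _as_edge(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
        edges.add(e)
        edge_features[e] = BondFeatures(
            order=_BOND_TYPE_MAP[bt],
            conjugated=bond.GetIsConjugated(),
            in_ring=bond.IsInRing(),
        )
    g = MolecularGraph(
        atoms=atoms,
        edges=frozenset(edges),
        edge_features=edge_features,
        smiles=smiles if smiles is not None else Chem.MolToSmiles(mol),
        mol=mol,
    )
    g.validate()
    return g


def parse_smiles(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a hydrogen-depleted annotated graph.

    Valence-violating or syntactically invalid strings raise
    :class:`SmilesParseError`.  Multi-fragment inputs (salts) keep only the
    largest fragment.  Stereochemistry is dropped: the graph is 2-D topology
    plus the declared atom/bond annotations.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumAtoms())
        logger.warning("multi-fragment input %r: kept largest fragment", smiles)
    Chem.RemoveStereochemistry(mol)
    return graph_from_mol(mol, smiles=Chem.MolToSmiles(mol))


def canonical_smiles(g: MolecularGraph) -> str:
    return Chem.MolToSmiles(g.mol)


class ParsedFile(NamedTuple):
    """Result of reading a molecule file: graphs, optional labels, skip count."""

    graphs: list[MolecularGraph]
    labels: "object"  # pandas DataFrame when the source was a CSV, else None
    n_skipped: int


class EmptyCorpusError(ValueError):
    """Raised when a molecule file yields zero valid records."""


def _parse_many(records: Iterable[tuple[str, object]]) -> tuple[list, list, int]:
    graphs, kept_meta, skipped = [], [], 0
    for smiles, meta in records:
        try:
            graphs.append(parse_smiles(smiles))
            kept_meta.append(meta)
        except SmilesParseError as exc:
            logger.warning("skipping record: %s", exc)
            skipped += 1
    return graphs, kept_meta, skipped


def read_molecule_file(
    path: str | Path, format: str = "smiles_lines", smiles_column: str = "smiles"
) -> ParsedFile:
    """Read molecules from a file, skipping (and counting) invalid records.

    Supported formats: ``smiles_lines`` (one SMILES per line, ``#`` comments),
    ``csv`` (must contain a ``smiles`` column; remaining columns are returned
    as an aligned label frame), and ``sdf`` (V2000).  Order of valid records
    is preserved; zero valid records raise :class:`EmptyCorpusError`.
    """
    import pandas as pd

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    labels = None
    if format == "smiles_lines":
        records = []
        for line in path.read_text().splitlines():
            line = line.split("#", 1)[0].strip()
            if line:
                records.append((line, None))
        graphs, _, skipped = _parse_many(records)
    elif format == "csv":
        df = pd.read_csv(path)
        if smiles_column not in df.columns:
            raise ValueError(f"CSV lacks a {smiles_column!r} column")
        records = [(row[smiles_column], idx) for idx, row in df.iterrows()]
        graphs, kept_idx, skipped = _parse_many(records)
        labels = df.loc[kept_idx].drop(columns=[smiles_column]).reset_index(drop=True)
    elif format == "sdf":
        records = []
        with open(path, "rb") as fh:
            supplier = Chem.ForwardSDMolSupplier(fh)
            raw = list(supplier)
        graphs, skipped = [], 0
        for mol in raw:
            if mol is None:
                logger.warning("skipping unparseable SDF record")
                skipped += 1
                continue
            Chem.RemoveStereochemistry(mol)
            graphs.append(graph_from_mol(mol))
    else:
        raise ValueError(f"unknown format {format!r}")

    if not graphs:
        raise EmptyCorpusError(f"no valid molecules in {path}")
    logger.info("read %d molecules from %s (%d skipped)", len(graphs), path, skipped)
    return ParsedFile(graphs=graphs, labels=labels, n_skipped=skipped)
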