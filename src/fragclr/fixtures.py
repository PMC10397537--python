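"""Deterministic toy molecules and a seeded generator of valence-valid graphs.

Everything downstream — view generation, certification, pre-training and
transfer — is exercised on these synthetic corpora, so no external chemical
database is needed.  The random generator grows a bonded tree atom by atom
under a fixed per-element valence budget, optionally closing rings, and
therefore can only emit chemically valid (if unglamorous) molecules.  It
samples a convenient corner of chemical space, not a realistic one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chem_io import MolecularGraph, parse_smiles
from .views import enumerate_breakable_bonds

__all__ = ["FixtureSpec", "toy_corpus", "random_molecules", "synthetic_labels"]

#: Maximum heavy-atom bonds the generator will give each element.  Sulfur is
#: capped at 2: the generator's job is never to emit an invalid molecule, not
#: to mimic real valence-state distributions.
VALENCE: dict[str, int] = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1,
                           "Br": 1}

#: Per-atom additive contributions for the LogP-like synthetic label
#: (hydrophobic elements positive, polar negative; purely a deterministic toy).
_LOGP_LIKE: dict[str, float] = {"C": 0.3, "N": -0.4, "O": -0.5, "S": 0.2,
                                "F": 0.25, "Cl": 0.55, "Br": 0.7}
_AROMATIC_BONUS = 0.1


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the random-molecule generator."""

    n_molecules: int = 100
    seed: int = 0
    max_heavy_atoms: int = 9
    ring_probability: float = 0.2
    element_weights: dict[str, float] = field(
        default_factory=lambda: {"C": 0.6, "N": 0.12, "O": 0.14, "S": 0.04,
                                 "F": 0.05, "Cl": 0.05}
    )

    def __post_init__(self) -> None:
        if self.max_heavy_atoms < 2:
            raise ValueError("max_heavy_atoms must be >= 2")
        for el in self.element_weights:
            if el not in VALENCE:
                raise ValueError(f"no valence budget for element {el!r}")


def toy_corpus() -> list[str]:
    """A fixed, version-pinned list of hand-picked molecules.

    Includes acetophenone and benzene (the classic subgraph-masking
    counterexample: deleting acetophenone's acetyl group leaves benzene, a
    different molecule entirely), plus small acyclic/ring/amide/ester cases.
    """
    return [
        "CC(=O)c1ccccc1",   # acetophenone
        "c1ccccc1",         # benzene (no breakable bond)
        "CC",               # ethane
        "CCO",              # ethanol
        "CC(C)C",           # isobutane
        "CC(=O)NC",         # N-methylacetamide (amide)
        "CC(=O)OC",         # methyl acetate (ester)
        "CCN(CC)CC",        # triethylamine
        "C1CCCCC1",         # cyclohexane (no breakable bond)
        "Cc1ccccc1O",       # 2-methylphenol
        "CCCl",             # chloroethane
        "C#N",              # hydrogen cyanide (no single bond)
    ]


def _grow_molecule(rng: np.random.Generator, spec: FixtureSpec) -> str:
    elements = sorted(spec.element_weights)
    weights = np.array([spec.element_weights[e] for e in elements])
    weights = weights / weights.sum()
    n_atoms = int(rng.integers(2, spec.max_heavy_atoms + 1))

    rw = Chem.RWMol()
    free: list[int] = []  # remaining valence per atom
    first = str(rng.choice(elements, p=weights))
    rw.AddAtom(Chem.Atom(first))
    free.append(VALENCE[first])
    while rw.GetNumAtoms() < n_atoms:
        anchors = [i for i, f in enumerate(free) if f > 0]
        if not anchors:
            break
        anchor = int(anchors[rng.integers(len(anchors))])
        el = str(rng.choice(elements, p=weights))
        idx = rw.AddAtom(Chem.Atom(el))
        rw.AddBond(anchor, idx, Chem.BondType.SINGLE)
        free[anchor] -= 1
        free.append(VALENCE[el] - 1)
    # optional ring closure between two non-adjacent atoms with free valence
    if rng.random() < spec.ring_probability and rw.GetNumAtoms() >= 3:
        open_atoms = [i for i, f in enumerate(free) if f > 0]
        candidates = [
            (a, b)
            for ai, a in enumerate(open_atoms)
            for b in open_atoms[ai + 1:]
            if rw.GetBondBetweenAtoms(a, b) is None
        ]
        if candidates:
            a, b = candidates[int(rng.integers(len(candidates)))]
            rw.AddBond(a, b, Chem.BondType.SINGLE)
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return Chem.MolToSmiles(mol)


def random_molecules(spec: FixtureSpec) -> list[str]:
    """Seeded list of valence-valid SMILES grown as random bonded trees.

    With ``ring_probability = 0`` every molecule is acyclic, so any molecule
    with at least two atoms has at least one breakable bond; with ring
    closures enabled some small molecules are pure rings with no breakable
    bond, exercising the corpus filter.
    """
    rng = np.random.default_rng(spec.seed)
    return [_grow_molecule(rng, spec) for _ in range(spec.n_molecules)]


def synthetic_labels(mols: list[MolecularGraph | str], task: str) -> np.ndarray:
    """Deterministic labels computable from the graph alone.

    ``has_oxygen`` — binary indicator of an oxygen atom;
    ``nb_count`` — the number of breakable acyclic single bonds (Nb);
    ``fragment_logp_like`` — an additive per-atom contribution score standing
    in for LogP-style properties.
    """
    graphs = [parse_smiles(m) if isinstance(m, str) else m for m in mols]
    if task == "has_oxygen":
        return np.array(
            [float(any(a.element == "O" for a in g.atoms)) for g in graphs]
        )
    if task == "nb_count":
        return np.array(
            [float(len(enumerate_breakable_bonds(g))) for g in graphs]
        )
    if task == "fragment_logp_like":
        out = []
        for g in graphs:
            score = sum(
                _LOGP_LIKE.get(a.element, 0.0)
                + (_AROMATIC_BONUS if a.aromatic else 0.0)
                for a in g.atoms
            )
            out.append(score)
        return np.array(out)
    raise ValueError(f"unknown label task {task!r}")
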