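"""Fragment-pair view generation and machine-checkable semantic invariance.

A *fragment-pair view* of a molecule removes exactly one acyclic single bond
``e_ij`` from the edge set, leaving the atom and bond annotations untouched:
``G' = {V, E - {e_ij}, X_atom, X_bond}``.  The result is a two-component graph
whose topology disagrees with the recorded per-atom bond counts at exactly the
two severed endpoints.  Two brute-force oracles certify the construction:

* *conflict freedom* — ``G'`` is not a valid molecular graph of any molecule,
  because the degrees of the two endpoints are one lower than their recorded
  heavy-atom bond counts;
* *ambiguity freedom* — re-adding a single bond at the unique pair of
  degree-deficient atoms reconstructs exactly one molecule, the parent, so no
  other molecule can produce the same view.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem

from .chem_io import Edge, MolecularGraph, graph_from_mol

__all__ = [
    "FragmentPairView",
    "InvarianceCertificate",
    "enumerate_breakable_bonds",
    "make_view",
    "all_views",
    "is_valid_molecular_graph",
    "reconstruct",
    "certify",
]


@dataclass
class FragmentPairView:
    """A parent graph with one acyclic single bond removed.

    ``component_assignment`` maps every atom index to component 0 or 1;
    component 0 is the one containing the lower-indexed endpoint of the
    removed edge.
    """

    parent: MolecularGraph
    removed_edge: Edge
    edges_prime: frozenset[Edge]
    component_assignment: dict[int, int]

    @property
    def component_sizes(self) -> tuple[int, int]:
        sizes = [0, 0]
        for c in self.component_assignment.values():
            sizes[c] += 1
        return tuple(sizes)

    def degree(self, i: int) -> int:
        return sum(1 for e in self.edges_prime if i in e)


@dataclass
class InvarianceCertificate:
    """Brute-force evidence that one view is semantically invariant."""

    view: FragmentPairView
    is_valid_molecular_graph: bool
    reconstruction_count: int
    reconstruction_is_parent: bool

    @property
    def passed(self) -> bool:
        return (
            not self.is_valid_molecular_graph
            and self.reconstruction_count == 1
            and self.reconstruction_is_parent
        )


def enumerate_breakable_bonds(g: MolecularGraph) -> list[Edge]:
    """All acyclic single bonds of ``g``, sorted by atom-index pair.

    A bond is breakable iff its order is single (aromatic bonds are excluded
    even where a kekulised form would write them as single) and it lies on no
    cycle, so that removing it disconnects the graph into exactly two pieces.
    The length of the returned list is the number of fragment-pair views, Nb.
    """
    out = []
    for e in sorted(g.edges):
        bf = g.edge_features[e]
        if bf.order == "single" and not bf.in_ring:
            out.append(e)
    return out


def _components(n_atoms: int, edges: frozenset[Edge]) -> list[set[int]]:
    adj = {i: set() for i in range(n_atoms)}
    for (i, j) in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen: set[int] = set()
    comps = []
    for start in range(n_atoms):
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            stack.extend(adj[v] - comp)
        seen |= comp
        comps.append(comp)
    return comps


def make_view(g: MolecularGraph, e: Edge) -> FragmentPairView:
    """Remove one breakable bond, returning the resulting fragment-pair view."""
    if e not in g.edges:
        raise ValueError(f"edge {e} not in graph")
    if e not in enumerate_breakable_bonds(g):
        raise ValueError(f"edge {e} is not an acyclic single bond")
    edges_prime = frozenset(g.edges - {e})
    comps = _components(g.n_atoms, edges_prime)
    assert len(comps) == 2, "removing an acyclic bond must split the graph in two"
    lo = min(e)
    if lo not in comps[0]:
        comps = [comps[1], comps[0]]
    assignment = {i: c for c, comp in enumerate(comps) for i in comp}
    return FragmentPairView(
        parent=g, removed_edge=e, edges_prime=edges_prime,
        component_assignment=assignment,
    )


def all_views(g: MolecularGraph) -> list[FragmentPairView]:
    """One fragment-pair view per breakable bond, in enumeration order."""
    return [make_view(g, e) for e in enumerate_breakable_bonds(g)]


def is_valid_molecular_graph(v: FragmentPairView) -> bool:
    """Whether the view's topology is consistent with its atom annotations.

    True iff every atom's degree in the pruned edge set equals its recorded
    heavy-atom bond count.  Any view produced by :func:`make_view` returns
    False — the two severed endpoints each have a deficit of one — which is
    precisely what rules out the view being a real molecule's graph.
    """
    return all(
        v.degree(i) == a.heavy_degree for i, a in enumerate(v.parent.atoms)
    )


def _deficits(v: FragmentPairView) -> dict[int, int]:
    return {
        i: a.heavy_degree - v.degree(i) for i, a in enumerate(v.parent.atoms)
    }


def reconstruct(v: FragmentPairView) -> list[MolecularGraph]:
    """Brute-force enumeration of all molecules that could have produced ``v``.

    Tries every unordered atom pair with a degree deficit of exactly one at
    both ends, re-adds a single bond there, and keeps each candidate whose
    topology is again consistent with the annotations.  For any view built by
    :func:`make_view` exactly one candidate survives and it is isomorphic to
    the parent: the removed bond's endpoints are the only deficient atoms.
    """
    deficits = _deficits(v)
    candidates = [i for i, d in deficits.items() if d == 1]
    results = []
    for ai in range(len(candidates)):
        for bi in range(ai + 1, len(candidates)):
            a, b = candidates[ai], candidates[bi]
            e = (a, b) if a < b else (b, a)
            if e in v.edges_prime:
                continue
            # degree consistency after re-adding (a, b) holds only if no other
            # atom is deficient
            if any(d != 0 for i, d in deficits.items() if i not in (a, b)):
                continue
            rw = Chem.RWMol(v.parent.mol)
            rw.RemoveBond(*v.removed_edge)
            rw.AddBond(a, b, Chem.BondType.SINGLE)
            mol = rw.GetMol()
            try:
                Chem.SanitizeMol(mol)
            except Exception:  # candidate is not a chemically valid molecule
                continue
            results.append(graph_from_mol(mol))
    return results


def certify(g: MolecularGraph) -> list[InvarianceCertificate]:
    """Run both brute-force oracles over every fragment-pair view of ``g``."""
    parent_canonical = Chem.MolToSmiles(g.mol)
    certs = []
    for v in all_views(g):
        recons = reconstruct(v)
        is_parent = (
            len(recons) == 1
            and Chem.MolToSmiles(recons[0].mol) == parent_canonical
        )
        certs.append(
            InvarianceCertificate(
                view=v,
                is_valid_molecular_graph=is_valid_molecular_graph(v),
                reconstruction_count=len(recons),
                reconstruction_is_parent=is_parent,
            )
        )
    return certs
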