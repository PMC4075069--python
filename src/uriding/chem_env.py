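"""Covalent connectivity and chemical-environment names for hydrogens.

Hydrogen atoms are grouped by an invariom-style name that encodes the
parent element and the parent's remaining neighbours, e.g. a methyl
hydrogen on a C bonded to one further C and two H is ``H1c[1c1h1h]``
and a water hydrogen is ``H1o[1h]``.  Hydrogens sharing a name sit in
the same covalent bonding environment, so their U ratios can be
averaged meaningfully.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .crystal_io import CrystalStructure

__all__ = ["BondGraph", "build_connectivity", "h_environment_name", "group_hydrogens"]


@dataclass
class BondGraph:
    """Undirected covalent bond graph over atom labels."""

    adjacency: dict[str, set[str]] = field(default_factory=dict)
    bond_lengths: dict[frozenset, float] = field(default_factory=dict)

    def add_bond(self, a: str, b: str, length: float) -> None:
        if a == b:
            raise ValueError(f"self-bond on {a}")
        self.adjacency.setdefault(a, set()).add(b)
        self.adjacency.setdefault(b, set()).add(a)
        self.bond_lengths[frozenset((a, b))] = length

    def neighbours(self, label: str) -> set[str]:
        return self.adjacency.get(label, set())


def build_connectivity(structure: CrystalStructure, tolerance: float = 0.40) -> BondGraph:
    """Perceive bonds from distances: bonded iff d ≤ r_cov(i)+r_cov(j)+tol.

    H–H bonds are never formed.  Radii come from gemmi's covalent-radius
    table (Cordero et al.).  Hydrogens that end up with zero or more
    than one heavy neighbour are flagged with a warning; downstream
    grouping excludes them.
    """
    pos = structure.cart_positions()
    graph = BondGraph()
    atoms = structure.atoms
    for a in atoms:
        graph.adjacency.setdefault(a.label, set())
    for i in range(len(atoms)):
        ai = atoms[i]
        for j in range(i + 1, len(atoms)):
            aj = atoms[j]
            if ai.is_hydrogen and aj.is_hydrogen:
                continue
            d = float(np.linalg.norm(pos[ai.label] - pos[aj.label]))
            if d <= ai.covalent_radius + aj.covalent_radius + tolerance:
                graph.add_bond(ai.label, aj.label, d)
    for a in atoms:
        if a.is_hydrogen:
            heavy = [n for n in graph.neighbours(a.label)]
            if len(heavy) != 1:
                warnings.warn(
                    f"hydrogen {a.label} has {len(heavy)} covalent neighbours; "
                    "excluded from ratio analysis", stacklevel=2)
    return graph


def _bracket_sort_key(symbol: str) -> tuple[int, str]:
    # H sorts last; other elements in reverse-alphabetical order
    # (matches e.g. [1o1c1c], [1n1c1h], [1c1h1h]).
    low = symbol.lower()
    if low == "h":
        return (1, "")
    return (0, "".join(chr(255 - ord(ch)) for ch in low))


def h_environment_name(graph: BondGraph, structure: CrystalStructure, h_label: str) -> str:
    """Environment name for one hydrogen, e.g. ``H1c[1o1c1c]``.

    All bond orders are emitted as 1; single bonds are the only case
    that occurs for hydrogen parents' bracket contents in practice, and
    fractional-order perception is out of scope.
    """
    atom = structure[h_label]
    if not atom.is_hydrogen:
        raise ValueError(f"{h_label} is not a hydrogen atom")
    neighbours = sorted(graph.neighbours(h_label))
    if len(neighbours) != 1:
        raise ValueError(
            f"hydrogen {h_label} has {len(neighbours)} covalent neighbours, expected 1")
    parent = neighbours[0]
    parent_el = structure[parent].element
    others = [structure[n].element for n in graph.neighbours(parent) if n != h_label]
    others.sort(key=_bracket_sort_key)
    bracket = "".join("1" + el.lower() for el in others)
    return f"H1{parent_el.lower()}[{bracket}]"


def group_hydrogens(structure: CrystalStructure,
                    graph: BondGraph | None = None,
                    tolerance: float = 0.40) -> dict[str, list[tuple[str, str]]]:
    """Partition valid hydrogens into environment groups.

    Returns a mapping ``name -> [(h_label, parent_label), ...]``.
    Hydrogens without exactly one covalent neighbour are silently
    excluded (a warning was already issued during bond perception).
    """
    if graph is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            graph = build_connectivity(structure, tolerance=tolerance)
    groups: dict[str, list[tuple[str, str]]] = {}
    for a in structure.atoms:
        if not a.is_hydrogen:
            continue
        nbrs = graph.neighbours(a.label)
        if len(nbrs) != 1:
            continue
        name = h_environment_name(graph, structure, a.label)
        groups.setdefault(name, []).append((a.label, next(iter(nbrs))))
    return groups
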