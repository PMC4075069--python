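"""Idealized reference geometries for classification checks.

Small sp³ model compounds — methanol, 2-aminopropane, propane,
2-propanol, ethylamine, ethane and water — whose hydrogens realise the
chemical environments the classifier must name.  Geometries use ideal
tetrahedral angles and standard bond lengths (C–C 1.52, C–O 1.43,
C–N 1.47, C–H 1.09, N–H 1.01, O–H 0.96 Å); they are synthetic
constructions for validating bond perception and environment naming,
not refined structures.
"""

from __future__ import annotations

import numpy as np

from .crystal_io import Atom, CrystalStructure, UnitCell

__all__ = ["structure_from_cartesian", "water_molecule", "model_compound_cases"]

_T3 = 1.0 / np.sqrt(3.0)
TETRA = [np.array([1, 1, 1]) * _T3, np.array([1, -1, -1]) * _T3,
         np.array([-1, 1, -1]) * _T3, np.array([-1, -1, 1]) * _T3]


def structure_from_cartesian(atoms_cart, cell_edge: float = 20.0,
                             u_iso: float = 0.01,
                             temperature: float | None = None) -> CrystalStructure:
    """P1 structure from (label, element, cartesian Å) triples, centred
    in a cubic box, every atom given an isotropic ADP."""
    cell = UnitCell(cell_edge, cell_edge, cell_edge, 90, 90, 90)
    shift = cell_edge / 2.0
    atoms = [Atom(label=lab, element=el,
                  frac_xyz=(np.asarray(xyz, dtype=float) + shift) / cell_edge,
                  u_iso=u_iso)
             for lab, el, xyz in atoms_cart]
    return CrystalStructure(cell=cell, atoms=atoms, temperature=temperature)


def _attached_dirs(back_dir: np.ndarray, n: int) -> list[np.ndarray]:
    """n unit vectors at the tetrahedral angle to the bond running along
    ``back_dir``, spread 120° apart about it."""
    d = back_dir / np.linalg.norm(back_dir)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p1 = np.cross(d, ref)
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(d, p1)
    out = []
    for k in range(n):
        th = 2.0 * np.pi * k / 3.0
        out.append(d / 3.0 + np.sqrt(8.0) / 3.0 * (np.cos(th) * p1 + np.sin(th) * p2))
    return out


def _methyl(parent_pos, c_label, direction, h_prefix, start=1):
    c_pos = parent_pos + 1.52 * direction
    atoms = [(c_label, "C", c_pos)]
    for i, d in enumerate(_attached_dirs(direction, 3)):
        atoms.append((f"{h_prefix}{start + i}", "H", c_pos + 1.09 * d))
    return atoms


def water_molecule():
    return [("O1", "O", np.zeros(3)),
            ("H1", "H", np.array([0.96, 0.0, 0.0])),
            ("H2", "H", 0.96 * np.array([-0.2504, 0.9681, 0.0]))]


def model_compound_cases() -> list[tuple[str, list, str, str]]:
    """(compound, atoms, probe H label, expected environment name)."""
    t1, t2, t3, t4 = TETRA
    cases = []

    # methanol CH3-OH: hydroxyl H -> H1o[1c]
    o = np.zeros(3)
    atoms = [("O1", "O", o), ("HO", "H", o + 0.96 * t2)]
    atoms += _methyl(o, "C1", t1, "H", 1)
    cases.append(("methanol", atoms, "HO", "H1o[1c]"))

    # 2-aminopropane (CH3)2CH-NH2: methine H -> H1c[1n1c1c]
    c = np.zeros(3)
    atoms = [("C2", "C", c), ("H3", "H", c + 1.09 * t4)]
    n_pos = c + 1.47 * t3
    atoms.append(("N1", "N", n_pos))
    atoms += [(f"HN{i}", "H", n_pos + 1.01 * d)
              for i, d in enumerate(_attached_dirs(t3, 2), 1)]
    atoms += _methyl(c, "C1", t1, "HA", 1)
    atoms += _methyl(c, "C3", t2, "HB", 1)
    cases.append(("2-aminopropane", atoms, "H3", "H1c[1n1c1c]"))

    # propane CH3-CH2-CH3: methylene H -> H1c[1c1c1h]
    c = np.zeros(3)
    atoms = [("C2", "C", c), ("H4", "H", c + 1.09 * t3), ("H5", "H", c + 1.09 * t4)]
    atoms += _methyl(c, "C1", t1, "HA", 1)
    atoms += _methyl(c, "C3", t2, "HB", 1)
    cases.append(("propane", atoms, "H4", "H1c[1c1c1h]"))

    # 2-propanol (CH3)2CH-OH: methine H -> H1c[1o1c1c]
    c = np.zeros(3)
    o = c + 1.43 * t3
    atoms = [("C2", "C", c), ("H6", "H", c + 1.09 * t4), ("O1", "O", o),
             ("HO", "H", o + 0.96 * _attached_dirs(t3, 1)[0])]
    atoms += _methyl(c, "C1", t1, "HA", 1)
    atoms += _methyl(c, "C3", t2, "HB", 1)
    cases.append(("2-propanol", atoms, "H6", "H1c[1o1c1c]"))

    # ethylamine CH3-CH2-NH2: methylene H -> H1c[1n1c1h]
    c = np.zeros(3)
    n_pos = c + 1.47 * t2
    atoms = [("C1", "C", c), ("H7", "H", c + 1.09 * t3), ("H8", "H", c + 1.09 * t4),
             ("N1", "N", n_pos)]
    atoms += [(f"HN{i}", "H", n_pos + 1.01 * d)
              for i, d in enumerate(_attached_dirs(t2, 2), 1)]
    atoms += _methyl(c, "C2", t1, "HA", 1)
    cases.append(("ethylamine", atoms, "H7", "H1c[1n1c1h]"))

    # ethane CH3-CH3: methyl H -> H1c[1c1h1h]
    c1 = np.zeros(3)
    c2 = c1 + 1.52 * t1
    atoms = [("C1", "C", c1)]
    atoms += [(f"H{9 + i}", "H", c1 + 1.09 * d)
              for i, d in enumerate(_attached_dirs(-t1, 3))]
    atoms.append(("C2", "C", c2))
    atoms += [(f"HB{i}", "H", c2 + 1.09 * d)
              for i, d in enumerate(_attached_dirs(t1, 3), 1)]
    cases.append(("ethane", atoms, "H9", "H1c[1c1h1h]"))

    # water: H1o[1h]
    cases.append(("water", water_molecule(), "H1", "H1o[1h]"))
    return cases
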