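"""Crystal structures, displacement tensors and CIF input/output.

Anisotropic displacement parameters (ADPs) live in two bases:

* the **CIF basis** — the dimensionless ``U^cif`` convention used by the
  ``_atom_site_aniso_U_*`` loop, referred to the reciprocal-axis
  normalised crystallographic frame;
* the **Cartesian basis** — a plain mean-square-displacement matrix in
  Å², in an orthonormal frame with *a* along *x* and *b* in the *xy*
  plane.

The conversion is ``U_cart = M N U_cif Nᵀ Mᵀ`` with
``N = diag(a*, b*, c*)`` and ``M`` the fractional→Cartesian
orthogonalisation matrix; it is exactly invertible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "UnitCell",
    "DisplacementTensor",
    "Atom",
    "CrystalStructure",
    "read_cif",
    "write_structure_cif",
    "orthogonalization_matrix",
    "u_cif_to_cart",
    "u_cart_to_cif",
    "u_eq",
]

_EIGHT_PI_SQ = 8.0 * math.pi * math.pi


class CifError(ValueError):
    """Raised for unreadable or internally inconsistent CIF content."""


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell constants: lengths in Å, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0:
            raise ValueError("degenerate cell: non-positive volume")

    def _gemmi(self) -> gemmi.UnitCell:
        return gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)

    @property
    def volume(self) -> float:
        """Cell volume in Å³ (closed-form triple product)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return -1.0
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def reciprocal(self) -> "UnitCell":
        r = self._gemmi().reciprocal()
        return UnitCell(r.a, r.b, r.c, r.alpha, r.beta, r.gamma)


def orthogonalization_matrix(cell: UnitCell) -> np.ndarray:
    """Fractional→Cartesian matrix M (a ∥ x, b in the xy plane).

    ``M @ frac`` gives Cartesian Å coordinates; ``det(M)`` equals the
    cell volume.
    """
    m = np.array(cell._gemmi().orth.mat.tolist(), dtype=float)
    # gemmi may carry a signed zero; normalise for cleanliness
    m[np.abs(m) < 1e-14] = 0.0
    return m


@dataclass(frozen=True)
class DisplacementTensor:
    """Symmetric 3×3 mean-square displacement tensor with a basis tag.

    ``basis`` is ``"cif"`` (dimensionless U^cif convention) or
    ``"cartesian"`` (Å²).  Non-positive-semidefinite tensors are legal
    (experimental ADPs occasionally are); use :attr:`is_psd` to check.
    """

    matrix: np.ndarray
    basis: str = "cartesian"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("displacement tensor must be 3x3")
        if not np.allclose(m, m.T, atol=1e-10):
            raise ValueError("displacement tensor must be symmetric")
        object.__setattr__(self, "matrix", 0.5 * (m + m.T))
        if self.basis not in ("cif", "cartesian"):
            raise ValueError(f"unknown basis tag {self.basis!r}")

    @classmethod
    def from_components(
        cls,
        u11: float, u22: float, u33: float,
        u12: float, u13: float, u23: float,
        basis: str = "cartesian",
    ) -> "DisplacementTensor":
        return cls(
            np.array([[u11, u12, u13], [u12, u22, u23], [u13, u23, u33]]),
            basis=basis,
        )

    @property
    def components(self) -> tuple[float, float, float, float, float, float]:
        """(U11, U22, U33, U12, U13, U23)."""
        m = self.matrix
        return (m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2])

    @property
    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvalsh(self.matrix)

    @property
    def is_psd(self) -> bool:
        return bool(self.eigenvalues.min() >= -1e-12)


@dataclass
class Atom:
    label: str
    element: str
    frac_xyz: np.ndarray
    occupancy: float = 1.0
    u_cif: DisplacementTensor | None = None
    u_iso: float | None = None

    def __post_init__(self) -> None:
        self.frac_xyz = np.asarray(self.frac_xyz, dtype=float)
        if self.frac_xyz.shape != (3,) or not np.all(np.isfinite(self.frac_xyz)):
            raise ValueError(f"atom {self.label}: bad fractional coordinates")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.label}: occupancy outside [0, 1]")
        el = gemmi.Element(self.element)
        if el.atomic_number == 0:
            raise ValueError(f"atom {self.label}: unrecognised element {self.element!r}")
        self.element = el.name

    @property
    def mass(self) -> float:
        """Standard atomic weight (amu)."""
        return gemmi.Element(self.element).weight

    @property
    def covalent_radius(self) -> float:
        """Covalent radius in Å (gemmi's table, after Cordero et al.)."""
        return gemmi.Element(self.element).covalent_r

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def has_adp(self) -> bool:
        return self.u_cif is not None or self.u_iso is not None


@dataclass
class CrystalStructure:
    """P1 contents of an asymmetric unit with displacement parameters."""

    cell: UnitCell
    atoms: list[Atom]
    temperature: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        labels = [a.label for a in self.atoms]
        if len(set(labels)) != len(labels):
            raise ValueError("atom labels are not unique")

    def __getitem__(self, label: str) -> Atom:
        for a in self.atoms:
            if a.label == label:
                return a
        raise KeyError(label)

    def cart_positions(self) -> dict[str, np.ndarray]:
        """Cartesian Å coordinates keyed by atom label."""
        m = orthogonalization_matrix(self.cell)
        return {a.label: m @ a.frac_xyz for a in self.atoms}

    def u_cart(self, label: str) -> DisplacementTensor:
        """Cartesian ADP of an atom; isotropic atoms are expanded to u·I."""
        atom = self[label]
        if atom.u_cif is not None:
            return u_cif_to_cart(atom.u_cif, self.cell)
        if atom.u_iso is not None:
            return DisplacementTensor(np.eye(3) * atom.u_iso, basis="cartesian")
        raise ValueError(f"atom {label} carries no displacement parameters")


def u_cif_to_cart(u: DisplacementTensor, cell: UnitCell) -> DisplacementTensor:
    """Convert a CIF-convention tensor to the Cartesian MSD matrix (Å²)."""
    if u.basis != "cif":
        raise ValueError(f"expected a cif-basis tensor, got {u.basis!r}")
    m = orthogonalization_matrix(cell)
    rec = cell.reciprocal
    n = np.diag([rec.a, rec.b, rec.c])
    mn = m @ n
    return DisplacementTensor(mn @ u.matrix @ mn.T, basis="cartesian")


def u_cart_to_cif(u: DisplacementTensor, cell: UnitCell) -> DisplacementTensor:
    """Inverse of :func:`u_cif_to_cart`; round-trips to better than 1e-12."""
    if u.basis != "cartesian":
        raise ValueError(f"expected a cartesian-basis tensor, got {u.basis!r}")
    m = orthogonalization_matrix(cell)
    rec = cell.reciprocal
    n = np.diag([rec.a, rec.b, rec.c])
    inv = np.linalg.inv(m @ n)
    return DisplacementTensor(inv @ u.matrix @ inv.T, basis="cif")


def u_eq(u: DisplacementTensor, method: str = "arithmetic", label: str = "") -> float:
    """Equivalent isotropic displacement of a Cartesian tensor (Å²).

    ``arithmetic`` is the mean of the diagonal (trace/3, rotation
    invariant); ``geometric`` is the cube root of the product of the
    eigenvalues and requires a positive-definite tensor.
    """
    if u.basis != "cartesian":
        raise ValueError("u_eq operates on Cartesian tensors")
    if method == "arithmetic":
        return float(np.trace(u.matrix) / 3.0)
    if method == "geometric":
        ev = u.eigenvalues
        if ev.min() <= 0:
            who = f" for atom {label}" if label else ""
            raise ValueError(f"geometric U_eq undefined{who}: non-positive eigenvalue {ev.min():.3e}")
        return float(np.prod(ev) ** (1.0 / 3.0))
    raise ValueError(f"unknown averaging method {method!r}")


# ---------------------------------------------------------------------------
# CIF reading / writing (gemmi.cif does the syntax; we do the science)

_ANISO_U_TAGS = ["_atom_site_aniso_U_11", "_atom_site_aniso_U_22", "_atom_site_aniso_U_33",
                 "_atom_site_aniso_U_12", "_atom_site_aniso_U_13", "_atom_site_aniso_U_23"]
_ANISO_B_TAGS = [t.replace("_U_", "_B_") for t in _ANISO_U_TAGS]


def _num(block: gemmi.cif.Block, tag: str) -> float | None:
    val = block.find_value(tag)
    if val is None or val in ("?", "."):
        return None
    x = gemmi.cif.as_number(val)  # strips standard uncertainties "9.854(3)"
    if math.isnan(x):
        raise CifError(f"unparseable number {val!r} for {tag}")
    return x


def read_cif(path) -> CrystalStructure:
    """Read a small-molecule CIF into a :class:`CrystalStructure`.

    Atoms listed in an ``_atom_site_aniso`` loop (U or B convention,
    ``B = 8π² U``) carry ``u_cif``; others keep their ``U_iso`` (or
    ``B_iso`` converted).  Aniso labels are matched case-sensitively
    against site labels; an orphan aniso label is fatal.
    """
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()

    cell_vals = {}
    for name in ("a", "b", "c"):
        v = _num(block, f"_cell_length_{name}")
        if v is None:
            raise CifError(f"{path}: missing _cell_length_{name}")
        cell_vals[name] = v
    for name in ("alpha", "beta", "gamma"):
        v = _num(block, f"_cell_angle_{name}")
        cell_vals[name] = 90.0 if v is None else v
    cell = UnitCell(**cell_vals)

    site = block.find("_atom_site_", ["label", "fract_x", "fract_y", "fract_z"])
    if len(site) == 0:
        raise CifError(f"{path}: no _atom_site_ loop")
    type_col = block.find_loop("_atom_site_type_symbol")
    occ_col = block.find_loop("_atom_site_occupancy")
    uiso_col = block.find_loop("_atom_site_U_iso_or_equiv")
    biso_col = block.find_loop("_atom_site_B_iso_or_equiv")

    def col(loopcol, i):
        if len(loopcol) == 0:
            return None
        v = loopcol[i]
        return None if v in ("?", ".") else v

    atoms: list[Atom] = []
    for i, row in enumerate(site):
        label = gemmi.cif.as_string(row[0])
        sym = col(type_col, i)
        if sym is None:
            # derive element from the leading alphabetic part of the label
            sym = "".join(ch for ch in label if ch.isalpha())[:2]
            if gemmi.Element(sym).atomic_number == 0:
                sym = sym[:1]
        occ_s = col(occ_col, i)
        u_iso = None
        us = col(uiso_col, i)
        bs = col(biso_col, i)
        if us is not None:
            u_iso = gemmi.cif.as_number(us)
        elif bs is not None:
            u_iso = gemmi.cif.as_number(bs) / _EIGHT_PI_SQ
        atoms.append(Atom(
            label=label,
            element=sym,
            frac_xyz=[gemmi.cif.as_number(row[j]) for j in (1, 2, 3)],
            occupancy=1.0 if occ_s is None else gemmi.cif.as_number(occ_s),
            u_iso=u_iso,
        ))
    by_label = {a.label: a for a in atoms}

    aniso_labels = block.find_loop("_atom_site_aniso_label")
    if len(aniso_labels) > 0:
        scale = 1.0
        cols = [block.find_loop(t) for t in _ANISO_U_TAGS]
        if any(len(c) == 0 for c in cols):
            cols = [block.find_loop(t) for t in _ANISO_B_TAGS]
            scale = 1.0 / _EIGHT_PI_SQ
        if any(len(c) == 0 for c in cols):
            raise CifError(f"{path}: aniso loop lacks a complete U_ij or B_ij set")
        for i in range(len(aniso_labels)):
            lab = gemmi.cif.as_string(aniso_labels[i])
            if lab not in by_label:
                raise CifError(f"{path}: aniso label {lab!r} has no matching _atom_site entry")
            comps = [gemmi.cif.as_number(c[i]) * scale for c in cols]
            by_label[lab].u_cif = DisplacementTensor.from_components(*comps, basis="cif")
            by_label[lab].u_iso = None

    for a in atoms:
        if not a.has_adp:
            warnings.warn(f"atom {a.label} has no displacement parameters", stacklevel=2)
        if a.occupancy < 1.0:
            warnings.warn(f"atom {a.label} has occupancy {a.occupancy} (disorder?)", stacklevel=2)

    temp = _num(block, "_diffrn_ambient_temperature")
    return CrystalStructure(cell=cell, atoms=atoms, temperature=temp,
                            provenance=f"read from {path}")


def write_structure_cif(structure: CrystalStructure, path) -> None:
    """Write a structure as a v1.1 CIF re-readable by :func:`read_cif`.

    Numbers are written with 14 decimal places so that a write→read
    round trip is lossless well below 1e-9 (and a TLS refit of a
    round-tripped rigid-body fixture keeps R below 1e-10).
    """
    doc = gemmi.cif.Document()
    block = doc.add_new_block("uriding")
    f = "{:.14f}".format
    cell = structure.cell
    for tag, val in [("_cell_length_a", cell.a), ("_cell_length_b", cell.b),
                     ("_cell_length_c", cell.c), ("_cell_angle_alpha", cell.alpha),
                     ("_cell_angle_beta", cell.beta), ("_cell_angle_gamma", cell.gamma),
                     ("_cell_volume", cell.volume)]:
        block.set_pair(tag, f(val))
    if structure.temperature is not None:
        block.set_pair("_diffrn_ambient_temperature", f(structure.temperature))

    loop = block.init_loop("_atom_site_", ["label", "type_symbol", "fract_x",
                                           "fract_y", "fract_z", "occupancy",
                                           "U_iso_or_equiv", "adp_type"])
    for a in structure.atoms:
        if a.u_cif is not None:
            adp_type = "Uani"
            uiso = u_eq(u_cif_to_cart(a.u_cif, cell))
        elif a.u_iso is not None:
            adp_type = "Uiso"
            uiso = a.u_iso
        else:
            adp_type = "."
            uiso = None
        loop.add_row([a.label, a.element, f(a.frac_xyz[0]), f(a.frac_xyz[1]),
                      f(a.frac_xyz[2]), f(a.occupancy),
                      "?" if uiso is None else f(uiso), adp_type])

    aniso = [a for a in structure.atoms if a.u_cif is not None]
    if aniso:
        loop = block.init_loop("_atom_site_aniso_",
                               ["label", "U_11", "U_22", "U_33", "U_12", "U_13", "U_23"])
        for a in aniso:
            u11, u22, u33, u12, u13, u23 = a.u_cif.components
            loop.add_row([a.label] + [f(x) for x in (u11, u22, u33, u12, u13, u23)])
    doc.write_file(str(path))
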