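"""Synthetic fixtures: a toy hydrate with known rigid-body + internal motion.

The generator builds a small organic fragment plus one water molecule
in an orthorhombic P1 cell and forward-computes every atom's ADP at a
grid of temperatures as

    U_obs(i, T) = U_tls(i, T) + U_int(i, T) [+ noise],

where U_tls comes from a known ground-truth TLS model whose tensors
grow with a simple lattice law (constant zero-point floor below 50 K,
linear growth above) and U_int from a hand-built set of internal normal
modes: X–H stretches and bends above 1000 cm⁻¹, skeletal heavy-atom
modes in the 250–900 cm⁻¹ range, and one sub-cutoff lattice-like mode
that is listed in the mode file but excluded (by the frequency cutoff)
from the generated ADPs, mirroring how low-frequency molecular modes
are distrusted and replaced by the TLS fit.

Because all ground truth is retained, every stage of the analysis
pipeline — CIF round trips, bond perception, internal ADPs, the TLS
fit, the TLS+ONIOM recombination and the ratio curves — can be tested
end to end without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .crystal_io import (Atom, CrystalStructure, DisplacementTensor, UnitCell,
                         orthogonalization_matrix, u_cart_to_cif, u_eq,
                         write_structure_cif)
from .modes import NormalMode, NormalModeSet, internal_adps, write_modes, DEFAULT_CUTOFF
from .tls import TLSModel, predict_adps

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "write_fixture",
            "DEFAULT_TEMPS", "scaled_tls"]

#: Default temperature grid (K) for multi-temperature fixtures.
DEFAULT_TEMPS = (9.0, 30.0, 50.0, 75.0, 100.0, 150.0, 200.0, 250.0)

_T3 = 1.0 / np.sqrt(3.0)
# tetrahedral unit directions
_TD = {
    "t1": np.array([1, 1, 1]) * _T3,
    "t2": np.array([1, -1, -1]) * _T3,
    "t3": np.array([-1, 1, -1]) * _T3,
    "t4": np.array([-1, -1, 1]) * _T3,
}


@dataclass
class FixtureSpec:
    """Parameters of the synthetic multi-temperature fixture.

    The defaults define the reference study conditions: an 8-point
    9–250 K temperature grid, a 200 cm⁻¹ internal-mode cutoff, a
    noiseless forward model, and rigid-body magnitudes typical of a
    small-molecule crystal at cryogenic temperature (zero-point T of
    ~0.003 Å², L of ~1 deg²).
    """

    seed: int = 0
    temps: tuple[float, ...] = DEFAULT_TEMPS
    noise_sd: float = 0.0              # Å², Gaussian on each U component
    cutoff: float = DEFAULT_CUTOFF     # cm⁻¹, applied in generation too
    lattice_floor_K: float = 50.0      # below this the TLS term is its zero-point value
    lattice_slope_per_K: float = 0.045  # relative growth of the TLS term above the floor
    include_sub_cutoff_mode: bool = True
    #: override for the ground-truth rigid-body motion; its origin is
    #: re-anchored at the heavy-atom centroid (the fit's origin choice)
    tls_truth: "TLSModel | None" = None

    def ground_tls(self, origin: np.ndarray) -> TLSModel:
        if self.tls_truth is not None:
            t = self.tls_truth
            return TLSModel(T=t.T, L=t.L, S=t.S, origin=origin)
        """Zero-point (low-temperature) ground-truth TLS model.

        Magnitudes are chosen so that at the lowest temperatures the
        hydrogen zero-point internal motion dominates the lattice term
        (heavy-atom lattice U_eq ≈ 0.0017 Å², L ≈ 0.5 deg²), as in
        well-ordered molecular crystals near 10 K.
        """
        T = np.array([[0.0016, 0.0002, 0.0001],
                      [0.0002, 0.0018, 0.00015],
                      [0.0001, 0.00015, 0.0015]])
        L = np.array([[1.6e-4, 2.5e-5, 1.0e-5],
                      [2.5e-5, 1.3e-4, 2.0e-5],
                      [1.0e-5, 2.0e-5, 1.8e-4]])
        S = np.array([[5.0e-5, 3.0e-5, -2.0e-5],
                      [2.5e-5, -3.5e-5, 1.5e-5],
                      [-1.0e-5, 2.0e-5, -1.5e-5]])
        S = S - np.eye(3) * (np.trace(S) / 3.0)
        return TLSModel(T=T, L=L, S=S, origin=origin)


def scaled_tls(base: TLSModel, temperature: float, floor_K: float = 50.0,
               slope_per_K: float = 0.045) -> TLSModel:
    """Lattice temperature law: constant zero-point floor, then linear.

    g(T) = 1 for T ≤ floor, 1 + slope·(T − floor) above; T, L and S all
    scale with g.  The default slope makes the lattice term at 250 K
    about ten times its zero-point value, as observed for well-ordered
    molecular crystals.  This law is a deliberately simple surrogate —
    the analysis never predicts lattice motion, it always fits it.
    """
    g = 1.0 if temperature <= floor_K else 1.0 + slope_per_K * (temperature - floor_K)
    return TLSModel(T=base.T * g, L=base.L * g, S=base.S * g, origin=base.origin)


@dataclass
class Fixture:
    """Generated structures plus complete ground truth."""

    spec: FixtureSpec
    structures: dict[float, CrystalStructure]
    modes: NormalModeSet
    truth_tls: dict[float, TLSModel]
    truth_h_u: dict[float, dict[str, DisplacementTensor]]   # total H tensors
    truth_ratios: dict[float, dict[str, float]]             # per H label, arithmetic

    @property
    def temps(self) -> tuple[float, ...]:
        return self.spec.temps


def _toy_geometry() -> tuple[list[tuple[str, str, np.ndarray]], list[tuple[str, str]]]:
    """Cartesian toy molecule + water; returns (atoms, h_parent pairs).

    7 heavy atoms; hydrogens cover four environments: methyl
    H1c[1c1h1h], methine H1c[1o1c1c], methylene H1c[1c1c1h], hydroxyl
    H1o[1c] and water H1o[1h].
    """
    t1, t2, t3, t4 = _TD["t1"], _TD["t2"], _TD["t3"], _TD["t4"]
    c2 = np.zeros(3)
    c1 = 1.52 * t1                       # methyl carbon
    c3 = 1.52 * t2                       # methylene carbon
    o1 = 1.43 * t3                       # hydroxyl oxygen
    h4 = 1.09 * t4                       # methine H on C2
    # methyl hydrogens around C1 (bond back along -t1)
    m_dirs = [np.array([1, 1, -1]) * _T3, np.array([1, -1, 1]) * _T3,
              np.array([-1, 1, 1]) * _T3]
    h123 = [c1 + 1.09 * d for d in m_dirs]
    # methylene: C3 bonded to C2, C4 and 2 H
    c4 = c3 + 1.52 * np.array([-1, -1, -1]) * _T3
    g_dirs = [np.array([1, 1, -1]) * _T3, np.array([1, -1, 1]) * _T3]
    h45 = [c3 + 1.09 * d for d in g_dirs]
    o2 = c4 + 1.22 * np.array([-1, 1, -1]) * _T3     # carbonyl-like O on C4
    h_oh = o1 + 0.96 * np.array([1, 1, -1]) * _T3    # hydroxyl H
    # water well separated from the molecule
    ow = np.array([3.4, -3.4, 3.2])
    hw1 = ow + 0.96 * np.array([1.0, 0.0, 0.0])
    hw2 = ow + 0.96 * np.array([-0.2504, 0.9681, 0.0])   # ~104.5 deg

    atoms = [
        ("C1", "C", c1), ("C2", "C", c2), ("C3", "C", c3), ("C4", "C", c4),
        ("O1", "O", o1), ("O2", "O", o2), ("OW", "O", ow),
        ("H1", "H", h123[0]), ("H2", "H", h123[1]), ("H3", "H", h123[2]),
        ("H4", "H", h4),
        ("H5", "H", h45[0]), ("H6", "H", h45[1]),
        ("H7", "H", h_oh),
        ("HW1", "H", hw1), ("HW2", "H", hw2),
    ]
    h_parents = [("H1", "C1"), ("H2", "C1"), ("H3", "C1"), ("H4", "C2"),
                 ("H5", "C3"), ("H6", "C3"), ("H7", "O1"),
                 ("HW1", "OW"), ("HW2", "OW")]
    return atoms, h_parents


def _stretch_mode(labels: list[str], masses: np.ndarray, freq: float,
                  moving: str, recoil: str, direction: np.ndarray) -> NormalMode:
    """Two-atom stretch-like mode, momentum conserving, mass weighted.

    For x_H m_H = −x_X m_X the mass-weighted components satisfy
    q_X / q_H = −sqrt(m_H / m_X).
    """
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    vec = np.zeros((len(labels), 3))
    i_h, i_x = labels.index(moving), labels.index(recoil)
    vec[i_h] = d
    vec[i_x] = -np.sqrt(masses[i_h] / masses[i_x]) * d
    vec /= np.sqrt(np.sum(vec**2))
    return NormalMode(frequency=freq, eigenvector=vec)


def _pair_mode(labels: list[str], masses: np.ndarray, freq: float,
               a: str, b: str, direction: np.ndarray) -> NormalMode:
    """Heavy-atom pair stretch (equal and opposite mass-weighted motion)."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    vec = np.zeros((len(labels), 3))
    vec[labels.index(a)] = d
    vec[labels.index(b)] = -d
    vec /= np.sqrt(np.sum(vec**2))
    return NormalMode(frequency=freq, eigenvector=vec)


def _perp_pair(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = direction / np.linalg.norm(direction)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p1 = np.cross(d, ref)
    p1 /= np.linalg.norm(p1)
    return p1, np.cross(d, p1)


def _build_modes(atoms, h_parents, spec: FixtureSpec) -> NormalModeSet:
    labels = [a[0] for a in atoms]
    import gemmi
    masses = np.array([gemmi.Element(a[1]).weight for a in atoms])
    pos = {a[0]: a[2] for a in atoms}

    mode_list: list[NormalMode] = []
    for h, parent in h_parents:
        bond = pos[h] - pos[parent]
        is_oh = parent.startswith("O")
        stretch = 3600.0 if is_oh else 2950.0
        bends = (1500.0, 1250.0) if is_oh else (1350.0, 1150.0)
        mode_list.append(_stretch_mode(labels, masses, stretch, h, parent, bond))
        p1, p2 = _perp_pair(bond)
        mode_list.append(_stretch_mode(labels, masses, bends[0], h, parent, p1))
        mode_list.append(_stretch_mode(labels, masses, bends[1], h, parent, p2))
    # skeletal heavy-atom modes: grow appreciably with T, keeping the
    # parent U_eq rising even below the lattice floor
    skeletal = [("C1", "C2", 900.0), ("C2", "C3", 800.0), ("C3", "C4", 700.0),
                ("C2", "O1", 1050.0), ("C4", "O2", 1650.0),
                ("C1", "C3", 400.0), ("C2", "C4", 300.0), ("O1", "O2", 250.0)]
    for a, b, freq in skeletal:
        mode_list.append(_pair_mode(labels, masses, freq,
                                    a, b, pos[b] - pos[a]))
    if spec.include_sub_cutoff_mode:
        # lattice-like molecular rattle: present in the mode file, below
        # the cutoff, hence absent from every generated ADP
        vec = np.zeros((len(labels), 3))
        for i, lab in enumerate(labels):
            vec[i] = np.sqrt(masses[i]) * np.array([0.5, 0.3, 0.8])
        vec /= np.sqrt(np.sum(vec**2))
        mode_list.append(NormalMode(frequency=80.0, eigenvector=vec))
    return NormalModeSet(atom_labels=labels, masses=masses, modes=mode_list)


def generate_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Forward-generate the multi-temperature fixture with ground truth.

    Heavy-atom and hydrogen ADPs at each temperature are the sum of the
    scaled ground-truth TLS prediction and the internal-mode ADPs at
    the generation cutoff, plus optional Gaussian noise on each unique
    tensor component.  The same seed always produces bit-identical
    results.
    """
    spec = spec or FixtureSpec()
    rng = np.random.default_rng(spec.seed)

    # cell: orthorhombic box comfortably holding the fragment (P1)
    cell = UnitCell(9.854, 9.249, 10.144, 90.0, 90.0, 90.0)
    atoms_cart, h_parents = _toy_geometry()
    shift = np.array([4.0, 4.5, 4.0])    # keep everything inside the cell
    m_inv = np.linalg.inv(orthogonalization_matrix(cell))

    modes = _build_modes(atoms_cart, h_parents, spec)
    labels = [a[0] for a in atoms_cart]
    pos = {a[0]: a[2] + shift for a in atoms_cart}
    heavy = [lab for lab, el, _ in atoms_cart if el != "H"]
    hydrogens = [lab for lab, el, _ in atoms_cart if el == "H"]

    centroid = np.mean([pos[lab] for lab in heavy], axis=0)
    base_tls = spec.ground_tls(origin=centroid)

    structures: dict[float, CrystalStructure] = {}
    truth_tls: dict[float, TLSModel] = {}
    truth_h_u: dict[float, dict[str, DisplacementTensor]] = {}
    truth_ratios: dict[float, dict[str, float]] = {}
    parent_of = dict(h_parents)

    for temp in spec.temps:
        model_t = scaled_tls(base_tls, temp, floor_K=spec.lattice_floor_K,
                             slope_per_K=spec.lattice_slope_per_K)
        truth_tls[temp] = model_t
        u_tls = predict_adps(model_t, pos)
        u_int = internal_adps(modes, temp, cutoff=spec.cutoff)

        atom_objs = []
        h_u_t: dict[str, DisplacementTensor] = {}
        ratios_t: dict[str, float] = {}
        for lab, el, _ in atoms_cart:
            total = u_tls[lab].matrix + u_int[lab].matrix
            if spec.noise_sd > 0:
                noise = rng.normal(0.0, spec.noise_sd, size=6)
                n11, n22, n33, n12, n13, n23 = noise
                total = total + np.array([[n11, n12, n13],
                                          [n12, n22, n23],
                                          [n13, n23, n33]])
            u_cart = DisplacementTensor(total, basis="cartesian")
            if el == "H":
                h_u_t[lab] = u_cart
            atom_objs.append(Atom(
                label=lab, element=el, frac_xyz=m_inv @ pos[lab],
                u_cif=u_cart_to_cif(u_cart, cell)))
        # ground-truth ratio bookkeeping (noise-free forward values)
        for h in hydrogens:
            parent = parent_of[h]
            num = u_eq(DisplacementTensor(
                u_tls[h].matrix + u_int[h].matrix, basis="cartesian"))
            den = u_eq(DisplacementTensor(
                u_tls[parent].matrix + u_int[parent].matrix, basis="cartesian"))
            ratios_t[h] = num / den
        structures[temp] = CrystalStructure(
            cell=cell, atoms=atom_objs, temperature=temp,
            provenance=f"synthetic fixture seed={spec.seed} T={temp}K")
        truth_h_u[temp] = h_u_t
        truth_ratios[temp] = ratios_t

    return Fixture(spec=spec, structures=structures, modes=modes,
                   truth_tls=truth_tls, truth_h_u=truth_h_u,
                   truth_ratios=truth_ratios)


def write_fixture(fixture: Fixture, directory) -> dict[str, list[str]]:
    """Serialise the fixture: one CIF per temperature, a mode file and a
    JSON ground-truth sidecar.  Returns the written paths by kind."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cifs = []
    for temp in fixture.temps:
        path = directory / f"fixture_{temp:07.2f}K.cif"
        write_structure_cif(fixture.structures[temp], path)
        cifs.append(str(path))
    mode_path = directory / "fixture_modes.txt"
    write_modes(fixture.modes, mode_path)

    spec_d = asdict(fixture.spec)
    if spec_d.get("tls_truth") is not None:
        spec_d["tls_truth"] = {k: np.asarray(v).tolist()
                               for k, v in spec_d["tls_truth"].items()}
    truth = {
        "spec": spec_d,
        "tls": {
            str(t): {"T": m.T.tolist(), "L": m.L.tolist(), "S": m.S.tolist(),
                     "origin": m.origin.tolist()}
            for t, m in fixture.truth_tls.items()
        },
        "hydrogen_u": {
            str(t): {lab: u.matrix.tolist() for lab, u in d.items()}
            for t, d in fixture.truth_h_u.items()
        },
        "ratios": {
            str(t): dict(d) for t, d in fixture.truth_ratios.items()
        },
    }
    truth_path = directory / "fixture_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    return {"cif": cifs, "modes": [str(mode_path)], "truth": [str(truth_path)]}
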