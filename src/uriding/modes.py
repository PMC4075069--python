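"""Harmonic normal modes and temperature-dependent internal ADPs.

Each internal (intramolecular) normal mode of frequency ν contributes a
rank-1 term to every atom's mean-square displacement tensor,

    U_int(i) = Σ_k  h / (8π² m_i c ν_k) · coth(h c ν_k / (2 k_B T)) · e_ik e_ikᵀ,

where e_ik is atom i's segment of the mass-weighted, unit-normalised
eigenvector of mode k and m_i the atomic mass.  The coth factor is the
Boltzmann population of a quantum harmonic oscillator; it tends to 1 at
T → 0 (zero-point motion) and to 2k_BT/(hcν) in the classical limit.

Low-frequency modes describe motion of the molecule within the crystal
framework; the molecular (Einstein) picture estimates their frequencies
poorly, so modes below a cutoff (default 200 cm⁻¹) are dropped and the
lattice term is instead taken from a TLS fit (see :mod:`uriding.tls`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import constants

from .crystal_io import DisplacementTensor

__all__ = [
    "NormalMode",
    "NormalModeSet",
    "read_modes",
    "write_modes",
    "mode_msd_factor",
    "internal_adps",
    "DEFAULT_CUTOFF",
]

#: Frequency threshold (cm⁻¹) below which modes are treated as lattice
#: motion and excluded from internal ADPs.
DEFAULT_CUTOFF = 200.0

# h/(8π² c) in amu·Å²·cm⁻¹: prefactor of the per-mode MSD.
_MSD_PREFACTOR = constants.h / (8.0 * math.pi**2 * constants.c * 100.0 * constants.u) * 1e20
# hc/k_B in cm·K (second radiation constant): argument scale of coth.
_HC_OVER_KB = constants.h * constants.c * 100.0 / constants.k


@dataclass
class NormalMode:
    """One harmonic mode: wavenumber (cm⁻¹) + mass-weighted eigenvector.

    A negative frequency denotes an imaginary mode.  The eigenvector is
    stored as an (N, 3) array normalised so the sum of squares over all
    atoms is 1.
    """

    frequency: float
    eigenvector: np.ndarray

    def __post_init__(self) -> None:
        self.eigenvector = np.asarray(self.eigenvector, dtype=float)
        if self.eigenvector.ndim != 2 or self.eigenvector.shape[1] != 3:
            raise ValueError("eigenvector must be an (N, 3) array")
        if not np.all(np.isfinite(self.eigenvector)):
            raise ValueError("eigenvector has non-finite components")
        norm = float(np.sum(self.eigenvector**2))
        if abs(norm - 1.0) > 1e-6:
            if abs(norm - 1.0) < 1e-3:
                warnings.warn(
                    f"mode at {self.frequency:.1f} cm-1 renormalised "
                    f"(|e|^2 was {norm:.8f})", stacklevel=2)
                self.eigenvector = self.eigenvector / math.sqrt(norm)
            else:
                raise ValueError(
                    f"mode at {self.frequency:.1f} cm-1 badly normalised: |e|^2 = {norm:.6f}")


@dataclass
class NormalModeSet:
    """Normal modes aligned with the atoms of a crystal structure."""

    atom_labels: list[str]
    masses: np.ndarray
    modes: list[NormalMode] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        if len(self.atom_labels) != len(self.masses):
            raise ValueError("label and mass lists differ in length")
        if np.any(self.masses <= 0):
            raise ValueError("atomic masses must be positive")
        for m in self.modes:
            if m.eigenvector.shape[0] != len(self.atom_labels):
                raise ValueError("mode eigenvector length does not match atom count")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_labels)

    def index_of(self, label: str) -> int:
        return self.atom_labels.index(label)


def mode_msd_factor(frequency: float, temperature: float) -> float:
    """Thermal population factor coth(hcν / 2k_BT) of one oscillator.

    Equals 1 at T = 0 (pure zero-point motion) and grows monotonically
    with temperature, approaching 2k_BT/(hcν) classically.
    ``frequency`` in cm⁻¹ must be positive; imaginary modes must be
    filtered before calling.
    """
    if frequency <= 0:
        raise ValueError(f"non-positive frequency {frequency} cm-1 (imaginary mode?)")
    if temperature < 0:
        raise ValueError("negative temperature")
    if temperature == 0.0:
        return 1.0
    x = _HC_OVER_KB * frequency / (2.0 * temperature)
    return 1.0 / math.tanh(x)


def mode_axial_msd(frequency: float, mass: float, temperature: float) -> float:
    """MSD (Å²) along the mode axis for a single atom carrying the whole
    eigenvector: h/(8π² m c ν) · coth(hcν/2k_BT)."""
    return _MSD_PREFACTOR / (mass * frequency) * mode_msd_factor(frequency, temperature)


def internal_adps(modes: NormalModeSet, temperature: float,
                  cutoff: float = DEFAULT_CUTOFF) -> dict[str, DisplacementTensor]:
    """Internal-motion ADPs (Å², Cartesian) per atom at one temperature.

    Modes with frequency below ``cutoff`` are omitted; imaginary
    (negative-frequency) modes are skipped with a warning.  The result
    is a sum of rank-1 PSD terms, hence PSD.
    """
    if temperature < 0:
        raise ValueError("negative temperature")
    n = modes.n_atoms
    u = np.zeros((n, 3, 3))
    imaginary = [m.frequency for m in modes.modes if m.frequency <= 0]
    if imaginary:
        warnings.warn(
            f"skipping {len(imaginary)} imaginary mode(s): "
            + ", ".join(f"{f:.1f}" for f in imaginary), stacklevel=2)
    used = 0
    for mode in modes.modes:
        if mode.frequency <= 0 or mode.frequency < cutoff:
            continue
        used += 1
        amp = _MSD_PREFACTOR / mode.frequency * mode_msd_factor(mode.frequency, temperature)
        # e_i e_iᵀ / m_i for every atom at once
        outer = np.einsum("ia,ib->iab", mode.eigenvector, mode.eigenvector)
        u += amp * outer / modes.masses[:, None, None]
    if used == 0:
        warnings.warn(f"no modes at or above the {cutoff} cm-1 cutoff; "
                      "internal ADPs are zero", stacklevel=2)
    return {lab: DisplacementTensor(u[i], basis="cartesian")
            for i, lab in enumerate(modes.atom_labels)}


# ---------------------------------------------------------------------------
# Plain-text mode file format
#
#   URIDING-MODES 1
#   atoms <N>
#   <label> <mass-amu>            (N lines)
#   mode <frequency-cm-1>
#   <ex> <ey> <ez>                (N lines, mass-weighted eigenvector)
#   mode ...
#
# Blank lines and lines starting with '#' are ignored.

_MAGIC = "URIDING-MODES 1"


def write_modes(modes: NormalModeSet, path) -> None:
    """Write a mode set in the documented plain-text format (lossless:
    floats are printed with 17 significant digits)."""
    with open(path, "w") as fh:
        fh.write(_MAGIC + "\n")
        fh.write(f"atoms {modes.n_atoms}\n")
        for lab, mass in zip(modes.atom_labels, modes.masses):
            fh.write(f"{lab} {mass:.17g}\n")
        for mode in modes.modes:
            fh.write(f"mode {mode.frequency:.17g}\n")
            for row in mode.eigenvector:
                fh.write(f"{row[0]:.17g} {row[1]:.17g} {row[2]:.17g}\n")


def read_modes(path) -> NormalModeSet:
    """Read a mode file written by :func:`write_modes` (or by a
    converter from quantum-chemistry output)."""
    with open(path) as fh:
        raw = fh.readlines()
    lines: list[tuple[int, str]] = [
        (i + 1, ln.strip()) for i, ln in enumerate(raw)
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines or lines[0][1] != _MAGIC:
        raise ValueError(f"{path}: not a '{_MAGIC}' file")

    def parse_float(token: str, lineno: int) -> float:
        try:
            return float(token)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: unparseable number {token!r}") from None

    pos = 1
    lineno, header = lines[pos]
    if not header.startswith("atoms "):
        raise ValueError(f"{path}:{lineno}: expected 'atoms <N>'")
    n = int(header.split()[1])
    pos += 1
    labels, masses = [], []
    for _ in range(n):
        if pos >= len(lines):
            raise ValueError(f"{path}: truncated atom table (expected {n} atoms)")
        lineno, ln = lines[pos]
        parts = ln.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected '<label> <mass>'")
        labels.append(parts[0])
        masses.append(parse_float(parts[1], lineno))
        pos += 1

    mode_list: list[NormalMode] = []
    while pos < len(lines):
        lineno, ln = lines[pos]
        if not ln.startswith("mode "):
            raise ValueError(f"{path}:{lineno}: expected 'mode <frequency>'")
        freq = parse_float(ln.split()[1], lineno)
        pos += 1
        vec = np.empty((n, 3))
        for i in range(n):
            if pos >= len(lines):
                raise ValueError(
                    f"{path}: truncated eigenvector for mode at {freq} cm-1 "
                    f"(atom count mismatch: expected {n} rows)")
            lineno, ln = lines[pos]
            parts = ln.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 components")
            vec[i] = [parse_float(p, lineno) for p in parts]
            pos += 1
        mode_list.append(NormalMode(frequency=freq, eigenvector=vec))
    return NormalModeSet(atom_labels=labels, masses=np.array(masses), modes=mode_list)
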