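"""Schomaker–Trueblood rigid-body (TLS) analysis of ADPs.

A rigid body undergoing small random translations t and librations ω
about an origin displaces an atom at r by  u = t + ω × (r − origin).
With T = ⟨t tᵀ⟩ (Å²), L = ⟨ω ωᵀ⟩ (rad²) and S = ⟨ω tᵀ⟩ (Å·rad) the
atomic mean-square displacement tensor is

    U(r) = T + A L Aᵀ + A S + Sᵀ Aᵀ,      A ω = ω × (r − origin).

U is linear in the 20 free parameters (6 T, 6 L, 8 S — the trace of S
is indeterminate and fixed to zero by convention), so fitting T, L, S
to observed ADPs is a linear least-squares problem.

The TLS+ONIOM pipeline combines this lattice term, fitted to the
experimental non-hydrogen ADPs after subtracting quantum-chemically
computed internal motion, with the internal ADPs themselves to predict
hydrogen displacement parameters at each temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .crystal_io import CrystalStructure, DisplacementTensor
from .modes import NormalModeSet, internal_adps, DEFAULT_CUTOFF

__all__ = [
    "TLSModel",
    "TLSFitReport",
    "predict_adps",
    "fit_tls",
    "subtract_internal",
    "tls_plus_oniom",
]


def _spin(d: np.ndarray) -> np.ndarray:
    """Matrix A with A ω = ω × d."""
    return np.array([[0.0, d[2], -d[1]],
                     [-d[2], 0.0, d[0]],
                     [d[1], -d[0], 0.0]])


@dataclass
class TLSModel:
    """T (Å²), L (rad²), S (Å·rad, traceless) tensors plus their origin."""

    T: np.ndarray
    L: np.ndarray
    S: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        for name, m in (("T", self.T), ("L", self.L), ("S", self.S)):
            if m.shape != (3, 3):
                raise ValueError(f"{name} must be 3x3")
        for name, m in (("T", self.T), ("L", self.L)):
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
        if abs(np.trace(self.S)) > 1e-10:
            raise ValueError("S must be traceless (trace(S) = 0 convention)")
        # remove any residual numerical trace so the invariant holds exactly
        self.S = self.S - np.eye(3) * (np.trace(self.S) / 3.0)
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")

    @property
    def L_deg2(self) -> np.ndarray:
        """Libration tensor in deg² for human-readable reports."""
        return self.L * (180.0 / np.pi) ** 2


@dataclass
class TLSFitReport:
    """Outcome of a TLS least-squares fit."""

    model: TLSModel
    residual: float                       # R = [Σw ΔU² / Σw U_obs²]^1/2
    delta_u: dict[str, DisplacementTensor] = field(default_factory=dict)
    n_observations: int = 0
    n_parameters: int = 20


def predict_adps(model: TLSModel, positions: dict[str, np.ndarray]) -> dict[str, DisplacementTensor]:
    """Rigid-body ADP U(r) = T + A L Aᵀ + A S + Sᵀ Aᵀ at each position."""
    out = {}
    for label, r in positions.items():
        a = _spin(np.asarray(r, dtype=float) - model.origin)
        u = model.T + a @ model.L @ a.T + a @ model.S + model.S.T @ a.T
        out[label] = DisplacementTensor(0.5 * (u + u.T), basis="cartesian")
    return out


# Parameter vector layout for the linear fit:
#   p[0:6]   T11 T22 T33 T12 T13 T23
#   p[6:12]  L11 L22 L33 L12 L13 L23
#   p[12:20] S11 S22 S12 S13 S21 S23 S31 S32   (S33 = -S11-S22)
_SYM_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def _unpack(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    T = np.zeros((3, 3))
    L = np.zeros((3, 3))
    for k, (i, j) in enumerate(_SYM_IDX):
        T[i, j] = T[j, i] = p[k]
        L[i, j] = L[j, i] = p[6 + k]
    s11, s22, s12, s13, s21, s23, s31, s32 = p[12:20]
    S = np.array([[s11, s12, s13],
                  [s21, s22, s23],
                  [s31, s32, -s11 - s22]])
    return T, L, S


def _pack(model: TLSModel) -> np.ndarray:
    p = np.empty(20)
    for k, (i, j) in enumerate(_SYM_IDX):
        p[k] = model.T[i, j]
        p[6 + k] = model.L[i, j]
    S = model.S
    p[12:20] = [S[0, 0], S[1, 1], S[0, 1], S[0, 2], S[1, 0], S[1, 2], S[2, 0], S[2, 1]]
    return p


def fit_tls(adps: dict[str, DisplacementTensor],
            positions: dict[str, np.ndarray],
            weights: dict[str, float] | None = None) -> TLSFitReport:
    """Fit T, L, S to observed Cartesian ADPs by linear least squares.

    The origin is fixed at the centroid of the fitted atoms and reported
    with the model (T and S are origin dependent).  Each atom supplies
    its 6 unique tensor components as observations, unit-weighted per
    atom unless weights are given; off-diagonal components carry a √2
    factor so the minimised quantity — and the reported residual
    R = [Σ w ‖U_obs − U_calc‖²_F / Σ w ‖U_obs‖²_F]^½ — is built on the
    rotation-invariant Frobenius norm.  Requires at least 4 atoms not
    all collinear; a rank-deficient design (e.g. all atoms collinear)
    is an error.
    """
    labels = list(adps)
    if set(labels) - set(positions):
        missing = sorted(set(labels) - set(positions))
        raise ValueError(f"no positions for atoms: {', '.join(missing)}")
    n = len(labels)
    if n < 4:
        raise ValueError(f"TLS fit needs at least 4 atoms, got {n}")
    for lab in labels:
        if adps[lab].basis != "cartesian":
            raise ValueError(f"ADP of {lab} is not in the Cartesian basis")

    origin = np.mean([positions[lab] for lab in labels], axis=0)
    w = np.array([1.0 if weights is None else weights[lab] for lab in labels])

    # Design matrix: response of the 6 unique U components to each parameter.
    design = np.zeros((6 * n, 20))
    for col in range(20):
        p = np.zeros(20)
        p[col] = 1.0
        T, L, S = _unpack(p)
        probe = TLSModel(T=T, L=L, S=S, origin=origin)
        pred = predict_adps(probe, {lab: positions[lab] for lab in labels})
        for row, lab in enumerate(labels):
            design[6 * row:6 * row + 6, col] = pred[lab].components

    obs = np.concatenate([adps[lab].components for lab in labels])
    # off-diagonal components enter the tensor twice: the sqrt(2) factor
    # makes the implied norm the (rotation-invariant) Frobenius norm
    comp_w = np.tile(np.array([1.0, 1.0, 1.0, np.sqrt(2), np.sqrt(2), np.sqrt(2)]), n)
    sw = np.repeat(np.sqrt(w), 6) * comp_w
    dw = design * sw[:, None]
    ow = obs * sw

    rank = np.linalg.matrix_rank(dw, tol=1e-9 * max(1.0, np.abs(dw).max()))
    if rank < 20:
        raise ValueError(
            f"rank-deficient TLS design matrix (rank {rank} < 20): "
            "atom arrangement is degenerate (collinear or planar cloud)")

    p, *_ = np.linalg.lstsq(dw, ow, rcond=None)
    T, L, S = _unpack(p)
    model = TLSModel(T=T, L=L, S=S, origin=origin)

    calc = predict_adps(model, {lab: positions[lab] for lab in labels})
    delta = {lab: DisplacementTensor(adps[lab].matrix - calc[lab].matrix,
                                     basis="cartesian") for lab in labels}
    num = sum(wi * np.sum(delta[lab].matrix ** 2) for wi, lab in zip(w, labels))
    den = sum(wi * np.sum(adps[lab].matrix ** 2) for wi, lab in zip(w, labels))
    residual = float(np.sqrt(num / den)) if den > 0 else 0.0
    return TLSFitReport(model=model, residual=residual, delta_u=delta,
                        n_observations=6 * n, n_parameters=20)


def subtract_internal(adps_obs: dict[str, DisplacementTensor],
                      adps_internal: dict[str, DisplacementTensor],
                      ) -> dict[str, DisplacementTensor]:
    """Componentwise U_obs − U_int; the external (lattice) part.

    Atoms whose difference acquires a negative eigenvalue are flagged
    with a warning but kept — downweighting or exclusion is the
    caller's decision.
    """
    if set(adps_obs) != set(adps_internal):
        only_obs = sorted(set(adps_obs) - set(adps_internal))
        only_int = sorted(set(adps_internal) - set(adps_obs))
        raise ValueError(
            f"label mismatch: only in observed {only_obs}, only in internal {only_int}")
    out = {}
    for lab, u in adps_obs.items():
        diff = DisplacementTensor(u.matrix - adps_internal[lab].matrix, basis="cartesian")
        if not diff.is_psd:
            warnings.warn(
                f"external ADP of {lab} is not PSD after internal-mode subtraction "
                f"(min eigenvalue {diff.eigenvalues.min():.2e})", stacklevel=2)
        out[lab] = diff
    return out


@dataclass
class TLSOniomResult:
    """Predicted hydrogen ADPs plus diagnostics from one temperature."""

    hydrogen_u: dict[str, DisplacementTensor]
    hydrogen_internal: dict[str, DisplacementTensor]
    hydrogen_tls: dict[str, DisplacementTensor]
    non_h_total: dict[str, DisplacementTensor]
    fit: TLSFitReport
    temperature: float


def tls_plus_oniom(structure: CrystalStructure,
                   modes: NormalModeSet,
                   temperature: float,
                   cutoff: float = DEFAULT_CUTOFF) -> TLSOniomResult:
    """Predict hydrogen ADPs by the TLS+ONIOM recombination at one T.

    Pipeline: internal ADPs from the modes at T → subtract from the
    observed non-hydrogen ADPs → TLS fit on the non-hydrogen residue
    (hydrogen observations, if any, are never fitted) → evaluate the
    rigid-body prediction at the hydrogen positions → add back the
    hydrogen internal ADPs.
    """
    u_int = internal_adps(modes, temperature, cutoff=cutoff)
    positions = structure.cart_positions()

    non_h = [a for a in structure.atoms if not a.is_hydrogen and a.u_cif is not None]
    if len(non_h) < 4:
        raise ValueError("need at least 4 anisotropic non-H atoms for the TLS fit")
    obs = {a.label: structure.u_cart(a.label) for a in non_h}
    missing = [a.label for a in non_h if a.label not in u_int]
    if missing:
        raise ValueError(f"modes do not cover atoms: {', '.join(missing)}")

    external = subtract_internal(obs, {a.label: u_int[a.label] for a in non_h})
    fit = fit_tls(external, {a.label: positions[a.label] for a in non_h})

    h_atoms = [a for a in structure.atoms if a.is_hydrogen]
    h_tls = predict_adps(fit.model, {a.label: positions[a.label] for a in h_atoms})
    h_u = {}
    h_int = {}
    for a in h_atoms:
        if a.label not in u_int:
            raise ValueError(f"modes do not cover hydrogen {a.label}")
        h_int[a.label] = u_int[a.label]
        h_u[a.label] = DisplacementTensor(
            h_tls[a.label].matrix + u_int[a.label].matrix, basis="cartesian")

    non_h_total = {
        a.label: DisplacementTensor(
            predict_adps(fit.model, {a.label: positions[a.label]})[a.label].matrix
            + u_int[a.label].matrix,
            basis="cartesian")
        for a in non_h
    }
    return TLSOniomResult(hydrogen_u=h_u, hydrogen_internal=h_int, hydrogen_tls=h_tls,
                          non_h_total=non_h_total, fit=fit, temperature=temperature)
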