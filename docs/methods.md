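# Methods

## Model

The package treats an atom's mean-square displacement tensor as the sum of two
statistically independent contributions:

* **Internal (intramolecular) motion.** Molecular normal modes within the
  molecular Einstein approximation: each mode is an independent quantum
  harmonic oscillator, lattice phonon dispersion is ignored. Mode k with
  wavenumber ν_k contributes to atom i

  U_int(i) = h/(8π² m_i c ν_k) · coth(h c ν_k / 2k_B T) · e_ik e_ikᵀ,

  where e_ik is the atom's segment of the mass-weighted, unit-normalised
  eigenvector and m_i its atomic mass (per-atom de-mass-weighting; CODATA
  constants via scipy). The coth factor is exactly 1 at T = 0 (zero point) and
  approaches 2k_BT/(hcν) classically; it is monotone in T, so every internal
  tensor grows with temperature. The tensor is a sum of rank-1 PSD terms and
  hence PSD.

* **External (lattice) motion.** A Schomaker–Trueblood rigid body: small random
  translations t and librations ω about an origin give
  U(r) = T + A L Aᵀ + A S + Sᵀ Aᵀ with A ω = ω × (r − origin),
  T = ⟨ttᵀ⟩ (Å²), L = ⟨ωωᵀ⟩ (rad²), S = ⟨ωtᵀ⟩ (Å·rad).

The TLS+ONIOM recombination predicts hydrogen ADPs at a given temperature by
(i) evaluating U_int for every atom, (ii) subtracting it from the observed
non-hydrogen ADPs, (iii) fitting T, L, S to the residue (hydrogen
observations are never fitted — X-ray hydrogen ADPs are the quantity under
test, not input), and (iv) adding the hydrogen internal tensors back to the
rigid-body prediction at the hydrogen positions. Ratios
U_eq(H)/U_eq(parent) are then averaged over hydrogens sharing an environment
name.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| cutoff | 200 cm⁻¹ | modes below it are treated as lattice motion and dropped from U_int; the rigid-body fit supplies that motion instead |
| temperature grid | 9, 30, 50, 75, 100, 150, 200, 250 K | evaluation points for multiplier tables |
| averaging | arithmetic | U_eq = trace/3; geometric (∛ of eigenvalue product) available — the two give the same ratios to well within the group spread |
| bond tolerance | 0.40 Å | bonded iff d ≤ r_cov(i)+r_cov(j)+tol; radii from gemmi's table (Cordero et al.) |
| TLS weights | unit | optional per-atom 1/σ² weights accepted |

The 200 cm⁻¹ cutoff is the point below which molecular-cluster frequency
calculations stop being trustworthy for crystal-frame motion; doubling the
cutoff can only shrink internal tensors (tested as an invariant).

## Numerical choices

* **TLS fit.** Linear least squares over 20 free parameters (6 T, 6 L, 8 S).
  The S diagonal is indeterminate by one gauge degree of freedom; trace(S)=0 is
  imposed exactly through the parametrisation (a convention, not physics). The
  origin is fixed at the centroid of the fitted atoms and always serialized
  with the model, since T and S are origin dependent. Off-diagonal tensor
  components carry a √2 weight so the minimised quantity and the residual
  R = [Σ‖U_obs−U_calc‖²_F / Σ‖U_obs‖²_F]^½ use the Frobenius norm — the only
  choice invariant under a global rotation of positions and tensors (equal
  weighting of the six unique components is not). A rank-deficient design
  (collinear/planar atom cloud, or fewer than 4 atoms) is a hard error.
* **Basis conventions.** CIF tensors are the dimensionless U^cif convention;
  Cartesian tensors are MSD matrices in Å² with a ∥ x, b in the xy plane
  (the orthogonalisation convention is documented because deposited files
  never state one). U_cart = M N U_cif Nᵀ Mᵀ, N = diag(a*,b*,c*); the
  conversion is exactly invertible and U_eq uses the full metric
  transformation, valid for any crystal system. B values are converted as
  U = B/8π².
* **Degenerate inputs.** Non-PSD experimental tensors are retained with a
  warning (only geometric U_eq refuses them, naming the atom). Internal-mode
  subtraction that leaves a negative eigenvalue is flagged but kept.
  Imaginary (negative) frequencies are skipped with a warning listing them.
  Hydrogens with zero or ≥2 covalent neighbours are warned about and excluded
  from ratio analysis. Sub-unit occupancies are flagged (rotational-disorder
  modelling is out of scope).
* **Environment names.** All bond orders are emitted as 1 (fractional-order
  perception is out of scope; order 1 is the only case arising for hydrogen
  environments here). Inside the bracket, neighbour elements sort
  reverse-alphabetically with H last — the ordering fixed by the reference
  name set in `uriding.reference` (e.g. `[1n1c1c]`, `[1c1h1h]`).
* **Averaging.** Group means use an unweighted mean and sample standard
  deviation; records are sorted canonically before aggregation so tables are
  bit-identical under input reordering. Group uncertainty is the spread
  across symmetry-equivalent hydrogens, not propagated refinement σ's
  (standard uncertainties are parsed but not propagated in v1).

## The synthetic fixture

The generator (`uriding.synthetic`) emulates a multi-temperature diffraction
study of a small hydrate: a 7-heavy-atom organic fragment (methyl, methylene,
methine, hydroxyl groups) plus one water in an orthorhombic P1 cell, with
ADPs forward-generated as U_tls(T) + U_int(T) (+ optional Gaussian noise) at
the default 8-point 9–250 K grid.

* **Internal modes**: per X–H bond one stretch (2950 cm⁻¹ C–H, 3600 cm⁻¹ O–H)
  and two bends (1150–1500 cm⁻¹), momentum-conserving and mass-weighted; eight
  skeletal heavy-atom modes at 250–1650 cm⁻¹; and one 80 cm⁻¹ lattice-like
  mode that is present in the mode file but — lying below the cutoff —
  contributes to no generated ADP, mirroring the analysis's distrust of
  low-frequency molecular modes.
* **Lattice law**: the ground-truth T, L, S scale with
  g(T) = 1 below 50 K and 1 + 0.045(T−50) above — a constant zero-point floor
  with linear classical growth. The magnitudes (zero-point heavy-atom lattice
  U_eq ≈ 0.0017 Å², L ≈ 0.5 deg², ×10 growth by 250 K) are chosen so the
  fixture reproduces the benchmark compound's observed behaviour: heavy-atom
  U_eq ≈ 0.003 Å² at 9 K and ≈ 0.02 Å² at 250 K, hydrogen/parent ratios close
  to four at 9 K falling to 1.3–1.6 at 250 K, i.e. the cryogenic ratio is more
  than twice the 250 K value in every environment. The law is a surrogate:
  the analysis never predicts lattice motion, it always fits it, so only the
  fixture's internal consistency matters.
* **Ground truth** (TLS models, hydrogen tensors, forward ratio curves) is
  retained and serialized, so the full pipeline can be checked for exact
  recovery. Same seed ⇒ bit-identical output files.

What passing on the fixture does **not** show: real data carry refinement
noise and model bias, methyl rotational disorder above ~150 K (which the
benchmark compound exhibits and which no harmonic treatment captures),
correlated σ(U) structure, and anharmonicity. The fixture validates the
machinery and the qualitative physics, not experimental error budgets.

## Problem sizes

The test suite and the acceptance script run on the 16-atom fixture (8
temperatures), a 12-atom random cloud for fit round trips, and Monte-Carlo
oracles of 4·10⁵–10⁶ samples for covariance checks — sizes at which every
linear-algebra identity is testable to near machine precision while the whole
suite completes in seconds.

## Known limitations

* One rigid body per asymmetric unit; no per-fragment TLS, no screw-axis
  decomposition, no libration bond-length corrections.
* P1 contents only; no symmetry expansion, structure factors or refinement.
* Quantum-chemical frequency calculations are external: the package consumes
  their modes through its own documented text format (a converter from vendor
  outputs is a plug-in point, not included).
* Isotropic-equivalent output only; anisotropic hydrogen ADP estimation in the
  SHADE style is out of scope.
* Fractional bond orders in environment names are not perceived.
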