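# uriding

Temperature-dependent multipliers for the riding-hydrogen model.

## The problem

Small-molecule X-ray refinements usually constrain each hydrogen's isotropic
displacement parameter to its bonded parent atom, `U_iso(H) = k · U_eq(X)` with
the fixed multipliers k = 1.2 (1.5 for hydroxyl and methyl H). Those constants
were calibrated on room-temperature data. At cryogenic temperatures the picture
changes: a hydrogen's motion is dominated by high-frequency internal
vibrations (X–H stretches and bends) whose amplitude is almost all zero-point
motion and barely grows with temperature, while the parent atom's motion is
dominated by lattice (external, rigid-body) displacements that shrink strongly
on cooling. The ratio U(H)/U_eq(X) is therefore temperature dependent — near
9 K it can reach four for a methine C–H — and the fixed 1.2/1.5 convention
underestimates hydrogen displacements below ~100 K.

`uriding` computes these ratios per chemical environment and temperature with
the **TLS+ONIOM recombination**:

1. **Internal motion.** Each molecular normal mode of wavenumber ν (from an
   external quantum-chemical frequency calculation) contributes to atom i

   U_int(i) = Σ_k  h/(8π² m_i c ν_k) · coth(h c ν_k / 2k_B T) · e_ik e_ikᵀ,

   the quantum harmonic-oscillator mean-square displacement with Boltzmann
   temperature scaling (e_ik = mass-weighted eigenvector segment, m_i = atomic
   mass). Modes below a 200 cm⁻¹ cutoff are excluded: the molecular (Einstein)
   picture estimates lattice-like frequencies too poorly to use.

2. **External motion.** The internal ADPs are subtracted from the observed
   non-hydrogen ADPs and the residue is fitted by a Schomaker–Trueblood
   rigid-body model, U(r) = T + A L Aᵀ + A S + Sᵀ Aᵀ (20 free parameters,
   trace(S) = 0), by linear least squares.

3. **Recombination.** The fitted rigid-body field is evaluated at the hydrogen
   positions and the hydrogen internal ADPs are added back:
   U(H) = U_TLS(H) + U_int(H). Ratios U_eq(H)/U_eq(parent) are then averaged
   over hydrogens sharing an invariom-style environment name (e.g.
   `H1c[1c1h1h]` for a methyl H) and tabulated against temperature.

Hydrogens are classified by bond connectivity perceived from covalent radii;
the environment name encodes the parent element and the parent's remaining
neighbours, so chemically distinct hydrogens (hydroxyl vs water vs methyl) get
separate multiplier curves.

## Worked example

Generate the synthetic benchmark fixture (a toy hydrate with known rigid-body
and internal motion), then compute TLS+ONIOM multiplier curves:

```sh
uriding simulate --seed 1 --out fx
uriding ratios fx/fixture_*.cif --modes fx/fixture_modes.txt --out rat
```

which prints (first environment shown):

```
environment     T     mean       sd  n   dev_1.2   dev_1.5
H1c[1c1c1h]   9.0 3.910593 0.025643  2  2.710593  2.410593
H1c[1c1c1h]  30.0 3.910593 0.025643  2  2.710593  2.410593
H1c[1c1c1h]  50.0 3.910578 0.025643  2  2.710578  2.410578
H1c[1c1c1h]  75.0 2.832413 0.033533  2  1.632413  1.332413
H1c[1c1c1h] 100.0 2.352315 0.037025  2  1.152315  0.852315
H1c[1c1c1h] 150.0 1.903879 0.040202  2  0.703879  0.403879
H1c[1c1c1h] 200.0 1.689198 0.041628  2  0.489198  0.189198
H1c[1c1c1h] 250.0 1.563074 0.042403  2  0.363074  0.063074
```

Each row is one (environment, temperature) cell: the mean ratio
U_eq(H)/U_eq(parent) over the n hydrogens of that environment, its sample
standard deviation, and the deviation from the conventional 1.2 and 1.5
multipliers. The methylene ratio falls monotonically from 3.91 at 9 K —
where hydrogen zero-point motion dwarfs the frozen lattice — to 1.56 at
250 K, close to the classical convention; a fixed multiplier is wrong by more
than a factor of two at 9 K. Other useful commands:

```sh
uriding classify fx/fixture_0009.00K.cif          # H environment names
uriding tlsfit fx/fixture_0009.00K.cif \
        --modes fx/fixture_modes.txt --out fit    # TLS report + predicted H ADPs
uriding internal-adps fx/fixture_modes.txt        # internal U tensors per T
```

`tlsfit` prints `TLS R = 1.168e-12` on the noiseless fixture: the rigid-body
fit reproduces the external ADPs to numerical precision.

## Library use

```python
from uriding import read_cif, read_modes, tls_plus_oniom, multiplier_curve

structure = read_cif("structure_at_9K.cif")      # non-H atoms anisotropic
modes = read_modes("modes.txt")                  # documented plain-text format
result = tls_plus_oniom(structure, modes, temperature=9.0, cutoff=200.0)
result.hydrogen_u                                # predicted H tensors (Å²)
result.fit.residual                              # TLS R factor
```

The mode file format is plain text: a `URIDING-MODES 1` header, an atom table
(label, mass in amu), then per mode a `mode <cm-1>` line followed by one
mass-weighted eigenvector row per atom (see `uriding.modes`).

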