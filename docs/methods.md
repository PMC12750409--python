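# Methods

This note documents the models, conventions and numerical choices behind
`voasim`, in the order the pipeline runs.

## Geometry construction

Chains are grown residue by residue with the natural-extension reference
frame (NeRF) rule from a fixed internal-coordinate template (N–CA 1.458 Å,
CA–C 1.525 Å, C–N 1.329 Å; N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°;
trans peptide bond ω = 180°, configurable).  Backbone torsions are the only
degrees of freedom exposed per conformer; the canonical (φ, ψ) table is
PPII (−75, 150), α (−60, −45), 3₁₀ (−49, −26), parallel β (−140, 130),
antiparallel β (−120, 115) degrees.  Any self-consistent template satisfies
the build→measure round trip; the shipped one reproduces requested interior
torsions to ~1e−13 degrees.  Side-chain χ₁/χ₂ default to 180° (extended);
no canonical side-chain rotamers are imposed because the fibril side-chain
packing is genuinely unknown.  Termini are neutral NH₂/COOH.  Glutamate
side chains carry COOH when `protonation="protonated"` and COO⁻ otherwise,
giving 16 or 15 atoms per residue plus 3 terminal atoms.

The torsion-restraint writer emits, for every defined φ/ψ, the four atom
indices (1-based), the target angle, a ±5° flat-bottom half-width and a
128 kcal/mol wall force constant — metadata for external restrained
dynamics, not used internally.

### Fibril packing

`build_fibril` is a *topological* starting-model builder.  The β-strand
built from (−120, 115) torsions twists by ≈ 2.7°/residue; packing twisted
strands at cross-β distances is impossible without clashes, so the builder
flattens the strand (counter-rotating each residue about the strand axis —
the standard idealization for cross-β models) before stacking.  Strands
repeat along y at 4.8 Å, sheets along z at 10 Å; antiparallel neighbours are
180°-rotated about z with a small registry offset (x ≈ 0.9 Å for even, −2.4 Å
for odd strand lengths; z −0.6 Å) and all strands are rolled −30° about
their axis.  These conventions were chosen once so that all assemblies from
1×1 to 3×4 are clash-free (minimum inter-chain distance ≥ 2 Å); they claim
nothing about the true β₂ registry or hydrogen-bond geometry, which is
why only topology (chain count, antiparallel CA-trace directions, CA–CA
spacing, absence of <1.5 Å contacts) is ever asserted.

`mirror` reflects through x = 0 (any plane is equivalent up to rigid
motion).  `deuterate` relabels N–H/O–H hydrogens (amide H, terminal NH₂,
carboxyl HE2, terminal HXT) to mass 2.014 amu without moving atoms.

## Fragmentation

Fragments are residue windows (whole residues only — side chains are never
severed, because the carboxyl tensors carry the diagnostic signal) cut with
span s and stride 1 by default, giving ceil((n−s)/stride)+1 windows per
chain and maximal overlap.  Severed backbone valences are completed with
hydrogen caps along the broken bond direction (C–H 1.09, N–H 1.01 Å) or,
optionally, with chemically realistic caps that rebuild the lost neighbour:
acetyl on the N side (3 heavy atoms: C, O, CH₃) and N-methylamide on the C
side (2 heavy atoms: N, CH₃).  Mapped fragment atoms keep their parent
coordinates verbatim.  Fibril fragmentation adds cross-chain fragments: a
2-residue window from each of two chains whose heavy atoms approach within
the contact cutoff (default 5 Å).

## Cartesian-coordinate transfer

For every parent atom covered by a fragment, a proper rotation is fitted
(Kabsch, det +1 enforced) between the fragment and parent positions of the
atom's neighbourhood (bonded atoms plus everything within 2.5 Å, minimum 4
points, residue-backbone fallback).  Per-atom rank-2 tensors transform as
R T Rᵀ, Hessian blocks as R_a F_ab R_bᵀ, and each index of the rank-3/4
derivative tensors rotates with the owning atom's rotation.

Overlapping contributions are combined with triangular weights — linear
decay of an atom's weight with its residue's distance from the fragment
centre, floored at 0.05 and normalized per atom.  The weight rule is
deliberately test-isolated: identity and equivariance hold for any
normalized rule.  Hessian cross blocks take the geometric mean of the two
atom weights, renormalized over the fragments containing both atoms, and
the assembled Hessian is symmetrized.  Atom pairs never co-resident in any
fragment get a zero block; their count is reported
(`meta["zeroed_cross_blocks"]`) and decreases monotonically with span —
zeroing rather than extrapolating keeps the transfer linear.

Origin-dependent tensors (AAT, ∂G′/∂x, ∂A/∂x) are re-referenced to the
parent origin before mixing, using the standard shift relations (for a
shift d: ΔM = −¼ ε d P; ΔG′ = −(ν̃_exc/2) ε d α; ΔA = −(3/2)(d∘α)_sym +
δ d·α).  Under a rigid fragment motion the effective shift is computed
per atom from the fitted rotation, which makes transfer exactly
equivariant under rigid motions of either side.

## Harmonic analysis

Units are Å, amu, mdyn/Å; ν̃ = 1302.79 √λ cm⁻¹.  Rigid-body projection uses
mass-weighted translation/rotation vectors (QR-orthonormalized; linear
systems detected by a 1e−8 relative degeneracy of the smallest inertia
moment keep 3N−5 modes).  Projected eigenvalues below −1e−10·‖H‖ are
flagged as imaginary modes.  Mode vectors are stored mass-weighted
orthonormal.

Partial optimization minimizes a pluggable energy engine in normal-mode
coordinates with modes below `freeze_below` (default 100 cm⁻¹) excluded
from the step.  Steps are trust-radius-limited Newton when the engine
supplies a Hessian (projected gradient descent otherwise), with rejection
and trust-radius halving on energy increase, grad_tol 1e−6, max 200 steps.
The mode basis is recomputed every step by default; the fixed-basis variant
keeps frozen-mode displacements identically zero and is the one checked
against the closed-form constrained-quadratic solution.

## Intensities

Conventions: apt[a]_{αβ} = ∂μ_α/∂x_{aβ}; aat analogous for m; derivative
tensors carry the (atom, coordinate) indices first.  Far-from-resonance
invariants from mode-contracted derivatives α′, G′′, A′:

    a = tr α′/3,  β(α)² = ½(3 α′:α′ − (tr α′)²),
    β(G′)² = ½(3 α′:G′′ − tr α′ tr G′′),  β(A)² = (ν̃_exc/2) α′_{αβ} ε_{αγδ} A′_{γ,δβ}

Raman(180°, SCP) ∝ 45a² + 7β(α)²; ROA ∝ 48β(G′)² + 16β(A)².  Both carry the
Stokes prefactor (ν̃_exc − ν̃)⁴/ν̃ and the Boltzmann factor at the configured
temperature (default 300 K).  Absolute cross sections are not calibrated:
each spectroscopy has one documented global constant (K_IR = K_VCD = 100,
K_Raman = K_ROA = 1e−14) and all scientific checks are sign-, ratio- or
invariance-based, because the experimental normalization of VOA intensities
is instrument-relative and unrecoverable here.

Modes below `min_wavenumber` (default 20 cm⁻¹) are excluded from band
lists: they are quasi-rigid or floppy-torsional remnants whose harmonic
Stokes amplitude diverges as 1/ν̃ and whose eigenvectors are numerically
unstable inside degenerate clusters.  Sum-rule checks pass
`min_wavenumber=None` to keep the complete set.

## Spectra and comparison

Broadening superposes unit-area Lorentzians (Γ = FWHM/2; peak height
2I/(πΓ)).  Frequency scaling is piecewise multiplicative on band positions
only; the shipped default is the identity map, with interval factors
supplied as configuration data when comparison to experiment demands them.
Snapshot averaging is a pointwise (weighted) mean on a shared grid; grids
are never silently resampled — `resample` exists but must be called
explicitly (the pipeline logs when it resamples a reference).  Background
subtraction is sample − c·background with c either given or least-squares
fitted over a signal-sparse window (default 1750–1900 cm⁻¹).

The similarity factor integrates by the trapezoidal rule on the spectrum
grid (default 1 cm⁻¹ step) over 230–1800 cm⁻¹ (Raman/ROA) or 1250–1800 cm⁻¹
(IR/VCD); closed-form Lorentzian-overlap oracles bound the quadrature error
below 1e−3 at these settings.

## The surrogate engine

The engine treats its construction geometry as the exact minimum of a
distance-harmonic surface: every bonded 1-2 pair, every 1-3 pair and every
1-4 pair contributes k/2 (r − r₀)² with r₀ taken from that geometry.  This
gives an analytic, exactly positive-semidefinite Hessian (Σ k ûûᵀ blocks)
satisfying the translational sum rule identically, with gradients and
Hessians available at displaced geometries for the optimizer.  Bond
constants are per element pair with a short-bond (double-bond) tier —
C=O 10.2, C–O 5.1, amide C–N 6.6, C–N 5.3, C–C 4.5/8.5, C–H 4.8, N–H 6.2,
O–H 7.2 mdyn/Å; 1-3 pairs 0.55 (0.38 with H), 1-4 pairs 0.07 — chosen once
so C=O stretches land in 1600–1800 cm⁻¹ and X–H stretches in
2800–3600 cm⁻¹, giving the spectral regions their usual qualitative
meaning.  The parameter table covers H (and D via mass), C, N, O, Na.

Intensity models: APT = atomic charge ·I plus a ±0.25 ûûᵀ bond
charge-flux term; ∂α/∂x from bond polarizabilities α_bond = (1.10·r)·I +
(0.85·r)(ûûᵀ − I/3) (linear length dependence makes the derivatives
non-trivial and analytic); AAT, ∂G′/∂x and ∂A/∂x from distributed-origin
constructions over per-atom α/APT contributions (each bond's contribution
split evenly between its atoms).  Consequences, exact by construction:
mirror geometries yield parity-transformed tensors (axial quantities pick
up det M = −1), every origin-shift relation holds identically, the
rotational-strength sum rule Σᵢ Rᵢ = 0 holds over the complete mode set,
and — because the surrogate α is symmetric — each ROA invariant is
individually origin-independent.

What the surrogate does *not* emulate: real normal-mode compositions
(amide I/II/III mixing), solvent shifts, anharmonicity, hydrogen-bond
specific force-constant changes, or any DFT-level band position.  Passing
tests therefore certify the *machinery* — transfer fidelity, parity,
origin- and rotation-invariance, convergence with fragment size, isotope
monotonicity — not agreement with measured polyglutamate spectra.  Real
tensors can be injected through the property-exchange format to obtain
quantitative predictions.

`jitter_snapshots` rebuilds a single chain with Gaussian-perturbed backbone
torsions (zero-mean, given σ), emulating restrained-dynamics snapshot
diversity; it is exact in the sense that the sample torsion spread equals
the generating σ.  `make_reference_spectrum` adds seeded Gaussian noise and
a polynomial baseline to broadened bands to stand in for experimental
references, recording all generation parameters.

## Numerical choices and edge cases

- Degenerate normal modes (identical residues decouple almost exactly)
  make per-mode intensities ill-defined; all cross-geometry comparisons in
  tests run on broadened spectra (degenerate-subspace sums are invariant)
  or on a deliberately asymmetric 5-atom chiral toy.
- Zero-frequency modes: ν̃ = c√λ is infinitely sensitive at λ = 0, so
  frequency-equality assertions use a 20 cm⁻¹ floor with a loose absolute
  bound below it.
- Collinear dihedral configurations return NaN rather than a value.
- Kabsch fitting rejects sets with fewer than 3 points or rank < 2.
- Problem sizes: tests and the acceptance script run on 3–10-residue
  strands (≤ 153 atoms) and a 12-chain/30-residue fibril for topology only;
  the fragment-convergence study uses a 10-residue PPII strand with spans
  2–6.  These sizes keep every check closed-form-verifiable while
  exercising the same code paths as production-size systems.

## Known limitations

- The builder's fibril is a packing convention, not a structural model of
  protonated-polyglutamate fibrils; inter-strand hydrogen bonding is not
  optimized.
- The surrogate force field has two residual near-zero internal modes per
  terminus class (floppy NH₂/OH torsions under-constrained by 1-4 springs);
  they are excluded by the 20 cm⁻¹ floor.
- `jitter_snapshots` supports single chains only; fibril snapshot
  ensembles would require per-chain rebuild plus re-superposition, which is
  out of scope.
- VCD/IR molar-absorptivity conversion and Raman absolute cross sections
  are fixed documented constants, not calibrated quantities.
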