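# Methods

This note records the models behind `synthonic`, the defaults that matter,
and the choices made where the design was genuinely open.  Energies are
kcal/mol, distances Å, charges electron units throughout.

## Interaction model

Non-bonded atom pairs interact through a Momany-type atom–atom potential:

    E_ij = −A/r⁶ + B/r¹²                       (van der Waals)
    E_ij = −A_hb/r¹⁰ + B_hb/r¹²                (tagged H-bond pairs)
    E_ij += k q_i q_j / (D r)                  (Coulomb)

with k = 332.0637 kcal Å/(mol e²) and dielectric D = 1 by default.  A pair
uses the 10-12 form iff (donor-attached hydrogen type, acceptor type)
appears in the parameter file's `hbond` table — Momany-style force fields
tag these pairs explicitly, and the tag table is part of the swappable
parameter file.  Unlisted hetero pairs combine by the geometric mean of the
homo-pair coefficients.  Pairs closer than 0.5 Å raise an error: rigid
unrelaxed bodies that close are a broken structure, not a physical state.

The shipped parameter set is synthetic and self-consistent: 6-12
coefficients from round-number van der Waals well depths and minimum
positions (A = 2εr_min⁶, B = εr_min¹²), 10-12 coefficients from an H-bond
well of 1.5–2 kcal/mol at 1.85–1.95 Å.  It exists so the fixtures have
well-defined energies; any production use should swap in a validated set
via the documented file grammar (`type`, `pair`, `hbond`, `dielectric`
records).

Charges are an input artifact (label → q file).  A built-in PEOE
(Gasteiger) implementation is provided for when no charge file exists:
χ(q) = a + bq + cq², transfers damped by (1/2)ⁿ per iteration and
normalised by the donor's cation electronegativity (20.02 for H), seeded
with formal charges so the net charge is conserved exactly.  Twelve
iterations are the default; fewer than six are rejected as unconverged.
The implementation reproduces the reference PEOE values (methane C −0.078,
H +0.019) and is cross-checked against rdkit's independent implementation
in the test suite.

## Lattice energy

The lattice energy is the half-sum over all neighbour molecules whose
mass-weighted centre of gravity lies within the limiting radius r_max of
the central molecule (the first asymmetric-unit molecule; all Z
symmetry-equivalent choices are verified equal in the tests):

    E_latt = ½ Σ_k E(central, k),   |COG_k − COG_c| ≤ r_max

The cutoff acts on whole molecules, never on atoms, so neutral charge
groups stay intact and the direct Coulomb sum converges without Ewald
machinery.  The supercell is sized automatically from the smallest
perpendicular cell height plus one safety shell; an explicitly undersized
supercell raises an error naming the required shells.

One numerical caveat: a neighbour whose COG distance equals r_max to the
last bit sits on a knife edge; choose r_max away from exact lattice
translation lengths (the convergence profile makes such plateaus visible).

Convergence is profiled on a radius grid (default 5–25 Å, 1 Å steps,
mirroring the sphere-expansion protocol); the final grid point equals the
lattice sum exactly and the per-step increments are percentages of it.
Fragment partitioning assigns each atom-pair term half to the fragment of
each partner atom (neighbour atoms map back to asymmetric-unit fragments),
then applies the lattice ½ — fragment energies sum to E_latt exactly, and
each fragment reports its dispersive/coulombic composition.

The sublimation cross-check uses ΔH_s = −E_latt − 2RT − ΔE_pt with ΔE_pt
the proton-transfer energy of the zwitterion (gas-phase neutral tautomer
vs solid-state zwitterion).  ΔE_pt is a required user input — it cannot be
derived from the crystal structure — and the functional form is
overridable.

## Synthons

Neighbour interactions are clustered into classes by energy (0.01
kcal/mol), COG distance (0.01 Å) and the conjugacy invariants of the
generating rotation.  Symmetry-equivalent pairs are numerically identical,
so these tolerances are deliberately tight; loosening them would merge
genuinely distinct synthons.  Classes are ranked by |energy| (ties: closer
distance, then lexicographic operator id) and labelled A, B, C, …

The percent contribution uses the half-sum convention

    percent = multiplicity × E_pair / E_latt × 100

with multiplicity counted over the central molecule's neighbours; summed
over all classes this gives 200 % (each bond counted from both ends).

Chemistry classification: `h_bond` if any donor–H⋯acceptor contact has
D⋯A ≤ 3.2 Å and D–H⋯A ≥ 120° (N, O donors; N, O, F acceptors — all four
thresholds configurable); else `coulombic` if |E_coul| > |E_vdw + E_hb|;
else `vdw`.  The reported fragment pair is the one carrying the largest
absolute atom-pair energy.

## Faces, slices and interfacial factors

The BFDH list enumerates coprime (hkl) up to a maximum index, collapses
them into Laue-orbit forms, and applies the general systematic-absence
rule (extinct iff some operator fixes hkl with a non-integral phase);
an extinct reflection is replaced by its smallest allowed multiple, e.g.
(0 0 1) → (0 0 2) under a 2₁ screw axis.  Forms are ranked by d-spacing.

For a form, a neighbour belongs to the slice when its COG lies inside the
slab of thickness d_hkl centred on the central molecule's COG and normal
to (hkl); everything else is attachment.  Because the two sets partition
the same neighbour list, E_slice + E_att = E_latt holds to machine
precision by construction — an atom-based membership rule was rejected
precisely because it breaks this conservation.  Among the Z
symmetry-equivalent central choices the most stabilising (most negative)
E_slice is reported — "maximum slice energy" in the absolute-value sense,
i.e. the most saturated termination.  For a full form all Z choices agree.

Anisotropy factor ε = E_slice/E_latt ∈ [0, 1]; Jackson factor
α = ε (ΔH_f/(RT) − ln X_seq) with the enthalpy of fusion ΔH_f and solute
mole fraction X_seq as required user inputs (they are solution
properties, not derivable from the crystal).

## Surface slabs and the systematic search

A slab is cut from the unrelaxed bulk: molecules whose COG depth falls in
a window of thickness × d_hkl centred on the reference molecule's COG,
repeated over an integer lattice basis of the surface plane (two shortest
independent in-plane vectors).  Rugosity R_g is the RMS deviation of all
atomic centres along the surface normal in a single-d-spacing slab; it is
invariant under lateral repetition.

The systematic search moves the rigid probe's COG over a lateral grid in
exact multiples of t_step (default 0.2 Å; refining the step therefore
nests the grids and can only lower the minimum) covering one surface
cell, at heights 1.5–6.0 Å above the topmost atomic plane, and rotates it
through intrinsic Z–X–Z Euler angles in rot_step increments (default 30°,
i.e. 12×6×12 orientations with the polar angle covering [0, 180)).  The
height protocol and the Euler convention are package choices — both are
recorded in the run log and configurable.  Pose energies are
molecule-by-molecule sums with the same whole-molecule cutoff as the
lattice sum; poses with any atom–atom contact below 1.0 Å are recorded
but rejected (rigid unrelaxed bodies make sub-bonding overlaps
unphysical).  The slab must extend at least a cutoff beyond the probe's
grid for the periodicity invariant to hold; the default 3×3 repeats suit
the fixture cells, larger cells or cutoffs need more.

Top-N interaction distributions first cluster away poses within 0.5 Å and
30° of a better pose, since raw grid poses oversample each binding basin,
then report the N best energies with per-pose H-bond/vdW/Coulomb
percentages (percentages of absolute component magnitudes, summing to
100).

## Modified attachment energies and Wulff shapes

    model 1: U = E_att (U_solute − U_solvent)/U_solute
    model 2: model 1 with U_solvent → U_solvent · R_g/R_g,min
    model 3: model 2 with U_solute → U_solute/α

Each is a named expression with a config override, because the canonical
literature forms admit variants.  Under all three, strengthening solvent
binding moves U monotonically toward zero and past it: U ≥ 0 means the
face's growth is blocked and it is excluded from the shape (the Wulff
rates are |E_att| or |U| of growing faces only — the standard
attachment-energy growth-rate proxy).

The Wulff shape is the intersection of half-spaces at distances
proportional to the rates, computed with Qhull; it equals the polar-dual
convex hull construction to machine precision (verified on random rate
sets) and is scale-invariant in the rates.  Forms are expanded to the
Laue orbit of the structure's operators (or, without operators, a
metric-derived holohedry: mmm for right-angled cells, the full cubic
orbit for metrically cubic cells).  A corner case fixed by construction:
{111} at √3 × the {100} rate touches the cube corners exactly and gets
zero area.

## Synthetic fixtures

The zwitterion fixture is a 19-atom NH₃⁺–CH(COO⁻)–CH₂–CH₂–COOH molecule
with standard bond lengths, hand-assigned point charges (net exactly
zero, ±0.57 e on carboxylate oxygens, +0.33 e on ammonium hydrogens) in a
10 × 12 × 11 Å P2₁2₁2₁2₁ cell, Z = 4, chosen so the closest
intermolecular contact is 2.9 Å.  It emulates the fragment chemistry,
space group and energy scale of an amino-acid crystal (E_latt ≈ −25
kcal/mol, coulomb-dominated); it does not emulate real hydrogen-bond
geometry or a validated force field, so tests passing on it demonstrate
the correctness of the machinery (conservation laws, oracle equality,
symmetry invariance), not chemical accuracy for any real compound.  The
dipole fixture (pure point charges, zero vdW) has a closed-form lattice
sum; the primitive-cubic fixture pins synthon multiplicities.  Generation
is deterministic: identical spec and seed give byte-identical files, and
packings with contacts under 1.7 Å are rejected with the offending pair.

## Problem sizes and defaults used in the shipped runs

The test suite and the acceptance script run the fixture workflow with
r_max 16.5–18 Å, 4–6 faces, search grids of 1.0–1.5 Å / 90–120°, and
3×3 slabs — coarse enough to complete in seconds per stage while
exercising every code path at full precision (the conservation residuals
they verify are ≤ 1e-8 regardless of grid coarseness).  Production
settings (0.2 Å / 30°, r_max 25 Å, 8 faces) are the package defaults in
`RunConfig`.

## Known limitations

- Direct summation only; no Ewald, polarisability or intramolecular
  terms.  Charged (non-neutral) unit cells are out of scope.
- Surfaces are unrelaxed bulk terminations; no surface reconstruction,
  solvation shells, or kinetic (BCF/spiral) growth models.
- Probe molecules are rigid; internal flexibility is not sampled.
- Molecular volume/surface area are accepted as inputs, not computed; the
  void-space percentage has no universal probe definition and is not
  reported.
- The synthon equivalence test keys on energy/distance/rotation-conjugacy;
  accidentally degenerate but symmetry-distinct pairs (energies within
  0.01 kcal/mol **and** distances within 0.01 Å **and** conjugate
  rotations) would merge.
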