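# synthonic

Solvent-aware crystal morphology prediction for molecular crystals.

Crystals grown from solution rarely show the shape that gas-phase
attachment-energy theory predicts, because solvent molecules bind to some
habit faces more strongly than to others and slow their growth.
`synthonic` implements a digital workflow that starts from a
crystallographic structure (CIF) and ends at a solvent-modified particle
shape:

1. **Lattice energy** by atom–atom summation over expanding spheres
   around a central molecule, with a Momany-type potential
   (6-12 van der Waals, 10-12 hydrogen bond, Coulomb):
   `E_latt = ½ Σ_k E(central, k)` for neighbours with centre-of-gravity
   distance ≤ r_max; convergence is profiled on a 1 Å radius grid and the
   energy is partitioned onto molecular fragments (ammonium, carboxylate,
   …).
2. **Synthons**: the neighbour interactions are clustered into
   symmetry-equivalence classes, ranked A, B, C, … by |energy| and
   classified (h-bond / coulombic / vdW) with their fragment pairs,
   multiplicities and centre-of-gravity distances.
3. **Faces**: a BFDH list ranked by interplanar d-spacing (with
   systematic-absence replacement, e.g. (0 0 1) → (0 0 2) under a 2₁
   screw axis), and for each face the partition
   `E_latt = E_slice + E_att` by slab membership of each neighbour, the
   anisotropy factor `ε = E_slice/E_latt` and the Jackson factor
   `α = ε (ΔH_f/RT − ln x)`.
4. **Surface binding**: rigid solvent/solute probes scanned over each
   face's surface cell on a translation grid with full Z–X–Z Euler
   rotations; outputs are binding-site maps, strongest binding energies
   `U_solvent`, `U_solute`, the top-N interaction distribution with
   H-bond/vdW/Coulomb percentages, and the plane rugosity `R_g` (RMS
   normal displacement of atomic centres in a one-d-spacing layer).
5. **Morphology**: three modified attachment energies

   - model 1: `U = E_att (U_solute − U_solvent)/U_solute`
   - model 2: solvent term scaled by rugosity, `U_solvent · R_g/R_g,min`
   - model 3: solute term scaled by surface entropy, `U_solute/α`

   used as relative growth rates in a Wulff construction (half-space
   intersection), giving face areas and aspect ratios.

Everything is testable offline: `synthonic.fixtures` generates small
synthetic orthorhombic crystals (a 19-atom amino-acid-like zwitterion in
P2₁2₁2₁2₁, a point-dipole crystal, a primitive-cubic toy) whose energies
have brute-force or closed-form oracles.

## Worked example

```sh
synthonic fixture --kind zwitterion --out fx
cat > run.yaml <<EOF
structure: fx/zwitterion.cif
potential: fx/potential.params
charges: fx/charges.dat
r_max: 18.0
n_faces: 4
t_step: 1.5
rot_step: 120.0
delta_H_f: 5.0
X_seq: 0.01
EOF
synthonic run-all --config run.yaml --out out
```

prints

```
E_latt = -24.9735 kcal/mol
reports written to out
```

and `out/` then contains `structure_report.json`, the convergence table,
the synthon table, `faces.tsv`, per-face pose dumps, and OFF polyhedra
with face-area summaries for the plain attachment-energy shape and each
solvent-modified model.  The synthon table for this fixture starts

```
label  energy_kcal_mol  cog_distance_A  multiplicity  percent_of_lattice  chemistry   fragments
A      -12.4627         6.120           2             99.81               coulombic   carboxylate-carboxylic acid
```

i.e. the strongest synthon is a coulombic carboxylate–carboxylic-acid
contact occurring twice around the central molecule; the percent column
follows the half-sum convention (multiplicity × energy / E_latt), so the
percents of all classes sum to 200 %.

The same stages are available as library calls (`parse_cif`,
`lattice_sum`, `enumerate_synthons`, `bfdh_form_list`,
`systematic_search`, `wulff_construct`, …); see the docstrings and
`docs/methods.md`.

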