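"""Synthon enumeration: symmetry-equivalence classes of molecule-molecule
interactions around the central molecule, ranked and chemically classified.

A synthon class groups neighbors with identical interaction energy and
COG distance (within tight tolerances - symmetry-equivalent pairs are
numerically identical) and the same generating-rotation conjugacy.  Its
percent contribution to the lattice energy follows the half-sum
convention: percent = multiplicity x pair energy / E_latt x 100, so the
percents of all classes sum to 200%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import LatticeEnergyResult, NeighborInteraction
from .potential import ChargeSet, PotentialParams

__all__ = ["SynthonRecord", "enumerate_synthons", "rank_and_label",
           "classify_chemistry", "synthon_table"]

HB_DONOR_ELEMENTS = {"N", "O"}
HB_ACCEPTOR_ELEMENTS = {"N", "O", "F"}
HB_MAX_DA = 3.2       # Angstrom donor...acceptor
HB_MIN_ANGLE = 120.0  # degrees D-H...A


@dataclass
class SynthonRecord:
    label: str
    energy: float                 # pair energy, kcal/mol
    multiplicity: int
    cog_distance: float           # Angstrom
    percent_of_lattice: float
    members: list = field(default_factory=list)   # NeighborInteraction list
    chemistry: str = ""
    fragment_pair: tuple = ()
    hbond_distance: float | None = None

    @property
    def representative(self) -> NeighborInteraction:
        return self.members[0]


def _rotation_class(nb: NeighborInteraction, ops) -> tuple:
    """Conjugacy invariants (trace, det) of the generating rotation."""
    R = ops[nb.neighbor.op_index].rot_array
    return (int(np.trace(R)), int(round(np.linalg.det(R))))


def enumerate_synthons(result: LatticeEnergyResult,
                       tolerance: float = 0.01,
                       dist_tol: float = 0.01) -> list:
    """Cluster the neighbor list into synthon classes.

    Neighbors join a class when their pair energy agrees within
    ``tolerance`` (kcal/mol), COG distance within ``dist_tol`` (A) and the
    generating symmetry rotations are conjugate.  The decomposition is a
    partition: every neighbor lands in exactly one class.
    """
    ops = result.structure.ops
    classes: list[list[NeighborInteraction]] = []
    order = sorted(result.per_neighbor,
                   key=lambda nb: (nb.energy.total, nb.distance,
                                   nb.neighbor.key()))
    for nb in order:
        placed = False
        for cls in classes:
            ref = cls[0]
            if (abs(nb.energy.total - ref.energy.total) <= tolerance
                    and abs(nb.distance - ref.distance) <= dist_tol
                    and _rotation_class(nb, ops) == _rotation_class(ref, ops)):
                cls.append(nb)
                placed = True
                break
        if not placed:
            classes.append([nb])
    E = result.E_latt
    records = []
    for cls in classes:
        cls.sort(key=lambda nb: nb.neighbor.key())
        e = float(np.mean([nb.energy.total for nb in cls]))
        d = float(np.mean([nb.distance for nb in cls]))
        records.append(SynthonRecord(
            label="", energy=e, multiplicity=len(cls), cog_distance=d,
            percent_of_lattice=100.0 * len(cls) * e / E if E != 0 else 0.0,
            members=cls))
    return records


def rank_and_label(records: list, polymorph_tag: str = "") -> list:
    """Sort by descending |energy| and assign labels A, B, C, ...

    Ties break on smaller COG distance, then on the lexicographic id of
    the representative's generating operator, making the labeling
    deterministic under input permutation.
    """
    if not records:
        raise ValueError("need at least one synthon record")
    records = sorted(records, key=lambda r: (
        -abs(r.energy), r.cog_distance, r.representative.neighbor.key()))
    for i, rec in enumerate(records):
        base = chr(ord("A") + i) if i < 26 else f"S{i + 1}"
        rec.label = base + polymorph_tag
    return records


def classify_chemistry(record: SynthonRecord, structure,
                       params: PotentialParams | None = None,
                       charges: ChargeSet | None = None,
                       central=None,
                       hb_max_da: float = HB_MAX_DA,
                       hb_min_angle: float = HB_MIN_ANGLE) -> SynthonRecord:
    """Tag a synthon as h_bond / coulombic / vdw and name its fragment pair.

    h_bond: any donor-H...acceptor contact with D...A <= ``hb_max_da`` and
    D-H...A angle >= ``hb_min_angle`` between the two partners; otherwise
    coulombic when |coulomb| > |vdw + hbond|, else vdw.  The fragment pair
    reported is the one carrying the largest absolute interaction energy.
    """
    nb = record.representative
    if central is None:
        raise ValueError("pass the central MoleculeInstance as central=")
    hb_d = _hbond_distance(central, nb.neighbor, hb_max_da, hb_min_angle)
    e = nb.energy
    if hb_d is not None:
        record.chemistry = "h_bond"
        record.hbond_distance = hb_d
    elif abs(e.coulomb) > abs(e.vdw + e.hbond):
        record.chemistry = "coulombic"
    else:
        record.chemistry = "vdw"
    if params is not None and charges is not None:
        from .potential import molecule_pair_matrices
        vdw, hbe, coul = molecule_pair_matrices(central, nb.neighbor,
                                                params, charges)
        tot = np.abs(vdw + hbe + coul)
        i, j = np.unravel_index(tot.argmax(), tot.shape)
        record.fragment_pair = tuple(sorted((
            central.fragment_map[i], nb.neighbor.fragment_map[j])))
    return record


def _hbond_distance(mol_a, mol_b, max_da: float, min_angle: float):
    """Shortest qualifying donor...acceptor distance across two molecules."""
    best = None
    for donor_mol, acceptor_mol in ((mol_a, mol_b), (mol_b, mol_a)):
        bonds = donor_mol.template.bonds
        el_d = donor_mol.elements
        el_a = acceptor_mol.elements
        acc_idx = [j for j, e in enumerate(el_a) if e in HB_ACCEPTOR_ELEMENTS]
        if not acc_idx:
            continue
        acc_xyz = acceptor_mol.coords[acc_idx]
        for i, j in bonds:
            for d_i, h_i in ((i, j), (j, i)):
                if el_d[d_i] not in HB_DONOR_ELEMENTS or el_d[h_i] != "H":
                    continue
                D = donor_mol.coords[d_i]
                H = donor_mol.coords[h_i]
                da = np.linalg.norm(acc_xyz - D, axis=1)
                for k, dist_da in enumerate(da):
                    if dist_da > max_da:
                        continue
                    A = acc_xyz[k]
                    v1 = D - H
                    v2 = A - H
                    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if ang >= min_angle:
                        if best is None or dist_da < best:
                            best = float(dist_da)
    return best


def synthon_table(records: list) -> str:
    """Delimited text table: label, energy, distance, multiplicity,
    % of lattice energy, chemistry, fragment pair, H-bond distance."""
    lines = ["label\tenergy_kcal_mol\tcog_distance_A\tmultiplicity\t"
             "percent_of_lattice\tchemistry\tfragments\thbond_distance_A"]
    for r in records:
        hb = f"{r.hbond_distance:.3f}" if r.hbond_distance is not None else "-"
        frg = "-".join(r.fragment_pair) if r.fragment_pair else "-"
        lines.append(f"{r.label}\t{r.energy:.4f}\t{r.cog_distance:.3f}\t"
                     f"{r.multiplicity}\t{r.percent_of_lattice:.2f}\t"
                     f"{r.chemistry}\t{frg}\t{hb}")
    return "\n".join(lines) + "\n"
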