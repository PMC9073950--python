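"""Lattice energy by expanding-sphere summation around a central molecule.

E_latt = 1/2 * sum over neighbor molecules (COG distance <= r_max) of the
molecule-molecule interaction energy; the half avoids double counting each
pairwise bond.  The module also profiles convergence against the limiting
radius, partitions the lattice energy onto molecular fragments, and
cross-checks against an experimental sublimation enthalpy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cell import CrystalStructure, MoleculeInstance, expand_symmetry
from .constants import R_KCAL
from .potential import (ChargeSet, EnergyBreakdown, PotentialParams,
                        molecule_pair_energy, molecule_pair_matrices)

__all__ = [
    "NeighborInteraction", "LatticeEnergyResult", "ConvergenceProfile",
    "FragmentPartition", "ThermoParams", "SupercellTooSmallError",
    "lattice_sum", "convergence_profile", "partition_fragments",
    "sublimation_consistency", "required_shells",
]


class SupercellTooSmallError(ValueError):
    pass


@dataclass
class NeighborInteraction:
    neighbor: MoleculeInstance
    energy: EnergyBreakdown
    distance: float           # COG-COG, Angstrom
    delta_cog: np.ndarray     # Cartesian vector central -> neighbor


@dataclass
class LatticeEnergyResult:
    structure: CrystalStructure
    central: MoleculeInstance
    r_max: float
    per_neighbor: list

    @property
    def breakdown(self) -> EnergyBreakdown:
        total = EnergyBreakdown()
        for nb in self.per_neighbor:
            total = total + nb.energy
        return total.scaled(0.5)

    @property
    def E_latt(self) -> float:
        return 0.5 * sum(nb.energy.total for nb in self.per_neighbor)


@dataclass
class ConvergenceProfile:
    radii: np.ndarray
    cumulative_E: np.ndarray
    increment_percent: np.ndarray
    coulomb_fraction: np.ndarray

    def table(self) -> str:
        """Delimited text: radius, cumulative E, % added, Coulomb %."""
        lines = ["radius_A\tcumulative_E_kcal_mol\tpercent_added\tcoulomb_percent"]
        for r, e, p, c in zip(self.radii, self.cumulative_E,
                              self.increment_percent, self.coulomb_fraction):
            lines.append(f"{r:.2f}\t{e:.6f}\t{p:.3f}\t{c:.3f}")
        return "\n".join(lines) + "\n"


@dataclass
class FragmentPartition:
    fragments: dict  # label -> dict(energy, percent, dispersive_percent, coulombic_percent)

    def total(self) -> float:
        return sum(v["energy"] for v in self.fragments.values())


@dataclass
class ThermoParams:
    T: float
    delta_E_pt: float = 0.0
    delta_H_s_exp: float | None = None
    R: float = R_KCAL

    def __post_init__(self):
        if self.T <= 0:
            raise ValueError("temperature must be > 0")


# --------------------------------------------------------------------------


def _min_cell_height(structure: CrystalStructure) -> float:
    """Smallest perpendicular distance between opposite cell faces."""
    M = structure.cell.matrix
    V = structure.cell.volume
    heights = []
    for i in range(3):
        j, k = (i + 1) % 3, (i + 2) % 3
        area = np.linalg.norm(np.cross(M[:, j], M[:, k]))
        heights.append(V / area)
    return min(heights)


def required_shells(structure: CrystalStructure, r_max: float) -> int:
    """Supercell radius (in cells) that encloses the r_max sphere with a
    one-cell safety margin for whole-molecule overhang."""
    return int(math.ceil(r_max / _min_cell_height(structure))) + 1


def lattice_sum(structure: CrystalStructure, params: PotentialParams,
                charges: ChargeSet, r_max: float,
                shells: int | None = None,
                central_choice: int = 0) -> LatticeEnergyResult:
    """Expanding-sphere lattice energy.

    ``central_choice`` selects which symmetry image of the (first)
    asymmetric-unit molecule acts as the central molecule; all choices are
    equivalent by symmetry.  ``shells`` overrides the automatically sized
    supercell; an explicit value too small for ``r_max`` raises
    :class:`SupercellTooSmallError`.
    """
    needed = required_shells(structure, r_max)
    if shells is None:
        shells = needed
    elif shells < needed:
        raise SupercellTooSmallError(
            f"supercell with shells={shells} cannot enclose a {r_max} A "
            f"sphere; need shells >= {needed}")
    instances = expand_symmetry(structure, shells)
    mol0 = structure.molecules()[0]
    central = next(
        inst for inst in instances
        if inst.template is mol0
        and inst.op_index == central_choice % len(structure.ops)
        and inst.lattice_translation == (0, 0, 0))
    per_neighbor = []
    for inst in instances:
        if inst is central:
            continue
        delta = inst.cog - central.cog
        d = float(np.linalg.norm(delta))
        if d > r_max or d < 1e-9:
            continue
        e = molecule_pair_energy(central, inst, params, charges)
        per_neighbor.append(NeighborInteraction(inst, e, d, delta))
    per_neighbor.sort(key=lambda nb: (nb.distance, nb.neighbor.key()))
    return LatticeEnergyResult(structure, central, r_max, per_neighbor)


def convergence_profile(structure: CrystalStructure, params: PotentialParams,
                        charges: ChargeSet, r_min: float, r_max: float,
                        step: float = 1.0,
                        result: LatticeEnergyResult | None = None) -> ConvergenceProfile:
    """Cumulative lattice energy at radii r_min..r_max (inclusive).

    The final point equals ``lattice_sum(r_max)`` exactly; increments are
    percentages of that final energy, so they sum to 100% (re-binning the
    radius grid never changes the cumulative values).
    """
    if not (r_min < r_max and step > 0):
        raise ValueError("need r_min < r_max and step > 0")
    if result is None:
        result = lattice_sum(structure, params, charges, r_max)
    radii = np.arange(r_min, r_max - 1e-9, step)
    radii = np.append(radii, r_max)
    dists = np.array([nb.distance for nb in result.per_neighbor])
    totals = np.array([nb.energy.total for nb in result.per_neighbor])
    coulombs = np.array([nb.energy.coulomb for nb in result.per_neighbor])
    cum = np.empty(len(radii))
    cfrac = np.empty(len(radii))
    for i, r in enumerate(radii):
        mask = dists <= r + 1e-12
        cum[i] = 0.5 * totals[mask].sum()
        cfrac[i] = (100.0 * 0.5 * coulombs[mask].sum() / cum[i]
                    if cum[i] != 0 else 0.0)
    E = result.E_latt
    inc = np.diff(np.concatenate(([0.0], cum)))
    inc_pct = 100.0 * inc / E if E != 0 else np.zeros_like(inc)
    return ConvergenceProfile(radii, cum, inc_pct, cfrac)


def partition_fragments(result: LatticeEnergyResult, params: PotentialParams,
                        charges: ChargeSet,
                        fragment_map: dict | None = None) -> FragmentPartition:
    """Partition E_latt onto molecular fragments.

    Every atom-pair energy term is assigned half to the fragment of each
    partner atom (neighbor atoms map back to their asymmetric-unit
    fragment), then scaled by the lattice 1/2; fragment energies therefore
    sum to E_latt exactly.
    """
    central = result.central
    fmap = fragment_map if fragment_map is not None else central.fragment_map
    n = len(central.labels)
    missing = [i for i in range(n) if i not in fmap]
    if missing:
        raise ValueError(f"unlabeled atoms at indices {missing}")
    labels = sorted(set(fmap.values()))
    acc = {lab: np.zeros(3) for lab in labels}  # vdw+hb (disp), coulomb, total
    for nb in result.per_neighbor:
        vdw, hbe, coul = molecule_pair_matrices(central, nb.neighbor,
                                                params, charges)
        tot = vdw + hbe + coul
        disp = vdw + hbe
        # neighbor images share the asymmetric-unit atom order, so an
        # explicit fragment map applies to them as well
        nb_map = fmap if fragment_map is not None else nb.neighbor.fragment_map
        row_t = tot.sum(axis=1)
        col_t = tot.sum(axis=0)
        row_d = disp.sum(axis=1)
        col_d = disp.sum(axis=0)
        row_c = coul.sum(axis=1)
        col_c = coul.sum(axis=0)
        for i in range(n):
            a = acc[fmap[i]]
            a += 0.5 * np.array([row_d[i], row_c[i], row_t[i]])
        for j in range(tot.shape[1]):
            a = acc[nb_map[j]]
            a += 0.5 * np.array([col_d[j], col_c[j], col_t[j]])
    E = result.E_latt
    out = {}
    for lab in labels:
        disp, coul, tot = acc[lab] * 0.5  # lattice half-sum
        denom = abs(disp) + abs(coul)
        out[lab] = {
            "energy": tot,
            "percent": 100.0 * tot / E if E != 0 else 0.0,
            "dispersive_percent": 100.0 * abs(disp) / denom if denom else 0.0,
            "coulombic_percent": 100.0 * abs(coul) / denom if denom else 0.0,
        }
    return FragmentPartition(out)


def sublimation_consistency(E_latt: float, thermo: ThermoParams,
                            form=None) -> dict:
    """Predicted sublimation enthalpy from the lattice energy.

    Default functional form: dH_s = -E_latt - 2RT - dE_pt, where dE_pt is
    the proton-transfer energy of the zwitterion (gas-phase neutral vs
    solid-state zwitterionic tautomer).  ``form`` may override with any
    callable (E_latt, thermo) -> dH_s.
    """
    if form is None:
        pred = -E_latt - 2.0 * thermo.R * thermo.T - thermo.delta_E_pt
    else:
        pred = form(E_latt, thermo)
    out = {"delta_H_s_pred": pred, "two_RT": 2.0 * thermo.R * thermo.T}
    if thermo.delta_H_s_exp is not None:
        out["residual"] = pred - thermo.delta_H_s_exp
    return out
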