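"""Momany-type atom-atom interaction energies.

A non-bonded pair contributes E = -A/r^6 + B/r^12 (van der Waals) or, when
the pair is tagged as a hydrogen-bonding donor-H/acceptor pair,
E = -A_hb/r^10 + B_hb/r^12 (the classic 10-12 form), plus an unscreened
Coulomb term k q_i q_j / (D r).  Energies are kcal/mol, distances Angstrom,
charges electron units.

The cutoff is applied at the whole-molecule level: either all atom pairs of
a molecule pair are summed or none, keeping neutral charge groups intact so
that direct Coulomb sums converge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .constants import COULOMB_KCAL

__all__ = [
    "EnergyBreakdown", "PotentialParams", "ChargeSet", "PotentialFileError",
    "load_potential", "dump_potential", "load_charges", "dump_charges",
    "pair_energy", "molecule_pair_energy", "molecule_pair_matrices",
    "OverlapError",
]

MIN_PAIR_DISTANCE = 0.5  # Angstrom; closer means a broken structure


class PotentialFileError(ValueError):
    """Malformed parameter or charge file."""


class OverlapError(ValueError):
    """Atom pair below the physical minimum distance."""


@dataclass(frozen=True)
class EnergyBreakdown:
    vdw: float = 0.0
    hbond: float = 0.0
    coulomb: float = 0.0

    @property
    def total(self) -> float:
        return self.vdw + self.hbond + self.coulomb

    def __add__(self, other: "EnergyBreakdown") -> "EnergyBreakdown":
        return EnergyBreakdown(self.vdw + other.vdw,
                               self.hbond + other.hbond,
                               self.coulomb + other.coulomb)

    def scaled(self, f: float) -> "EnergyBreakdown":
        return EnergyBreakdown(self.vdw * f, self.hbond * f, self.coulomb * f)


ZERO_ENERGY = EnergyBreakdown()


@dataclass
class PotentialParams:
    """6-12/10-12/Coulomb parameter set.

    ``types`` maps an atom type to its homo-pair (A, B); unlisted hetero
    pairs combine by the geometric mean of the homo-pair coefficients.
    ``pairs`` holds explicit (A, B) overrides keyed by a sorted type tuple.
    ``hbond`` maps (donor-attached-H type, acceptor type) to (A_hb, B_hb);
    these pairs use the 10-12 term instead of the 6-12 one.
    """

    types: dict = field(default_factory=dict)
    pairs: dict = field(default_factory=dict)
    hbond: dict = field(default_factory=dict)
    dielectric: float = 1.0
    coulomb_constant: float = COULOMB_KCAL

    def __post_init__(self):
        if self.dielectric <= 0:
            raise ValueError("dielectric must be > 0")
        for d in (self.types, self.pairs, self.hbond):
            for key, (A, B) in d.items():
                if A < 0 or B < 0:
                    raise ValueError(f"negative coefficient for {key}")

    def lookup(self, t1: str, t2: str) -> tuple:
        """(A, B) for a type pair, geometric-mean combined if unlisted."""
        key = tuple(sorted((t1, t2)))
        if key in self.pairs:
            return self.pairs[key]
        try:
            A1, B1 = self.types[t1]
            A2, B2 = self.types[t2]
        except KeyError as exc:
            raise KeyError(f"atom type {exc} not in parameter set") from exc
        return (math.sqrt(A1 * A2), math.sqrt(B1 * B2))

    def hbond_lookup(self, t1: str, t2: str):
        """(A_hb, B_hb) if (t1,t2) or (t2,t1) is a tagged H-bond pair."""
        return self.hbond.get((t1, t2)) or self.hbond.get((t2, t1))

    def matrices(self, types_a: Sequence[str], types_b: Sequence[str]):
        """Coefficient matrices (A, B, hb_mask, A_hb, B_hb) for two type lists."""
        na, nb = len(types_a), len(types_b)
        A = np.empty((na, nb))
        B = np.empty((na, nb))
        hb = np.zeros((na, nb), bool)
        Ah = np.zeros((na, nb))
        Bh = np.zeros((na, nb))
        for i, ti in enumerate(types_a):
            for j, tj in enumerate(types_b):
                A[i, j], B[i, j] = self.lookup(ti, tj)
                h = self.hbond_lookup(ti, tj)
                if h is not None:
                    hb[i, j] = True
                    Ah[i, j], Bh[i, j] = h
        return A, B, hb, Ah, Bh


@dataclass
class ChargeSet:
    """Per-atom partial charges (e) keyed by atom label."""

    charges: dict
    provenance: str = "file"

    def __getitem__(self, label: str) -> float:
        return self.charges[label]

    def array(self, labels: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.charges[l] for l in labels])
        except KeyError as exc:
            raise KeyError(f"no charge for atom label {exc}") from exc

    def net_charge(self, labels: Sequence[str] | None = None) -> float:
        if labels is None:
            return float(sum(self.charges.values()))
        return float(self.array(labels).sum())

    def validate_net(self, formal_charge: float,
                     labels: Sequence[str] | None = None,
                     tol: float = 1e-6) -> None:
        net = self.net_charge(labels)
        if abs(net - formal_charge) > tol:
            raise ValueError(f"net charge {net:.6f} does not match declared "
                             f"formal charge {formal_charge}")


# --------------------------------------------------------------------------
# parameter/charge file grammar
#
#   # comment
#   dielectric <D>
#   type  <name> <A> <B>
#   pair  <t1> <t2> <A> <B>
#   hbond <donor_H_type> <acceptor_type> <A_hb> <B_hb>
#
# charge files:  <atom_label> <q>


def load_potential(text: str) -> PotentialParams:
    params = PotentialParams()
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        try:
            if tok[0] == "dielectric":
                params.dielectric = float(tok[1])
            elif tok[0] == "coulomb_constant":
                params.coulomb_constant = float(tok[1])
            elif tok[0] == "type":
                params.types[tok[1]] = (float(tok[2]), float(tok[3]))
            elif tok[0] == "pair":
                params.pairs[tuple(sorted(tok[1:3]))] = (float(tok[3]), float(tok[4]))
            elif tok[0] == "hbond":
                params.hbond[(tok[1], tok[2])] = (float(tok[3]), float(tok[4]))
            else:
                raise ValueError(f"unknown record {tok[0]!r}")
        except (IndexError, ValueError) as exc:
            raise PotentialFileError(f"line {ln}: {exc} in {raw!r}") from exc
    if params.dielectric <= 0:
        raise PotentialFileError("dielectric must be > 0")
    return params


def dump_potential(params: PotentialParams) -> str:
    lines = [f"dielectric {params.dielectric!r}",
             f"coulomb_constant {params.coulomb_constant!r}"]
    for t, (A, B) in sorted(params.types.items()):
        lines.append(f"type {t} {A!r} {B!r}")
    for (t1, t2), (A, B) in sorted(params.pairs.items()):
        lines.append(f"pair {t1} {t2} {A!r} {B!r}")
    for (t1, t2), (A, B) in sorted(params.hbond.items()):
        lines.append(f"hbond {t1} {t2} {A!r} {B!r}")
    return "\n".join(lines) + "\n"


def load_charges(text: str, provenance: str = "file") -> ChargeSet:
    charges = {}
    for ln, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tok = line.split()
        if len(tok) != 2:
            raise PotentialFileError(f"line {ln}: expected '<label> <q>' in {raw!r}")
        try:
            charges[tok[0]] = float(tok[1])
        except ValueError as exc:
            raise PotentialFileError(f"line {ln}: {exc}") from exc
    return ChargeSet(charges, provenance)


def dump_charges(cs: ChargeSet) -> str:
    return "\n".join(f"{l} {q!r}" for l, q in cs.charges.items()) + "\n"


# --------------------------------------------------------------------------
# energies


def pair_energy(type_i: str, type_j: str, q_i: float, q_j: float, r: float,
                params: PotentialParams,
                cutoff: float | None = None) -> EnergyBreakdown:
    """Single atom-pair energy breakdown at separation ``r``."""
    if r <= 0:
        raise ValueError("r must be > 0")
    if r < MIN_PAIR_DISTANCE:
        raise OverlapError(
            f"atoms {type_i}/{type_j} at {r:.3f} A overlap (< "
            f"{MIN_PAIR_DISTANCE} A); the structure is broken")
    if cutoff is not None and r > cutoff:
        return ZERO_ENERGY
    hb = params.hbond_lookup(type_i, type_j)
    if hb is not None:
        Ah, Bh = hb
        e_hb = -Ah / r**10 + Bh / r**12
        e_vdw = 0.0
    else:
        A, B = params.lookup(type_i, type_j)
        e_vdw = -A / r**6 + B / r**12
        e_hb = 0.0
    e_c = params.coulomb_constant * q_i * q_j / (params.dielectric * r)
    return EnergyBreakdown(e_vdw, e_hb, e_c)


def molecule_pair_matrices(mol_a, mol_b, params: PotentialParams,
                           charges: ChargeSet):
    """Per-atom-pair (vdw, hbond, coulomb) energy matrices for two molecules.

    Rows index atoms of ``mol_a``, columns atoms of ``mol_b``.
    """
    r = cdist(mol_a.coords, mol_b.coords)
    if (r < MIN_PAIR_DISTANCE).any():
        i, j = np.unravel_index(r.argmin(), r.shape)
        raise OverlapError(
            f"atoms {mol_a.labels[i]}@{mol_a.key()} and "
            f"{mol_b.labels[j]}@{mol_b.key()} at {r[i, j]:.3f} A overlap")
    A, B, hb, Ah, Bh = params.matrices(mol_a.atom_types, mol_b.atom_types)
    inv2 = 1.0 / (r * r)
    inv6 = inv2 ** 3
    inv12 = inv6 ** 2
    vdw = np.where(hb, 0.0, -A * inv6 + B * inv12)
    hbe = np.where(hb, -Ah * inv6 * inv2 * inv2 + Bh * inv12, 0.0)
    qa = charges.array(mol_a.labels)
    qb = charges.array(mol_b.labels)
    coul = params.coulomb_constant * np.outer(qa, qb) / (params.dielectric * r)
    return vdw, hbe, coul


def molecule_pair_energy(mol_a, mol_b, params: PotentialParams,
                         charges: ChargeSet,
                         cutoff: float | None = None) -> EnergyBreakdown:
    """Molecule-molecule interaction energy (sum over the atom-pair cross
    product).  ``cutoff`` is a COG-COG limiting radius: molecule pairs
    beyond it contribute exactly zero (whole-molecule cutoff convention).
    """
    if cutoff is not None:
        if np.linalg.norm(np.asarray(mol_a.cog) - np.asarray(mol_b.cog)) > cutoff:
            return ZERO_ENERGY
    vdw, hbe, coul = molecule_pair_matrices(mol_a, mol_b, params, charges)
    return EnergyBreakdown(float(vdw.sum()), float(hbe.sum()), float(coul.sum()))
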