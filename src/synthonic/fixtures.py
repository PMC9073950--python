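"""Synthetic molecular-crystal fixtures with analytically known energies.

Every stage of the workflow is testable without external structure files:
the generators emit small orthorhombic crystals (P1 or P2_1 2_1 2_1) as
CIF text plus matching potential-parameter and charge files.  The
zwitterion fixture mimics an amino-acid-like molecule (ammonium,
carboxylate, carboxylic acid and aliphatic fragments); the dipole and
cubic fixtures are simple enough for closed-form or brute-force oracles.

Generation is deterministic: the same spec and seed give byte-identical
files.
"""

from __future__ import annotations

import math

import numpy as np

from .cell import (AtomSite, CrystalStructure, Molecule, UnitCell, parse_cif,
                   write_cif)
from .potential import ChargeSet, PotentialParams, dump_charges, dump_potential

__all__ = [
    "PackingClashError", "water_molecule", "water_charges",
    "zwitterion_sites", "zwitterion_charges", "zwitterion_crystal",
    "dipole_crystal", "dipole_charges", "dipole_potential", "cubic_crystal",
    "default_potential", "generate_fixture",
]

P212121 = "P 21 21 21"


class PackingClashError(ValueError):
    """Generated packing places two molecules unphysically close."""


# --------------------------------------------------------------------------
# shipped generic 6-12 / 10-12 parameter set
#
# The Lennard-Jones-style coefficients are derived from round-number van
# der Waals well depths and minimum-energy distances (A = 2 eps rmin^6,
# B = eps rmin^12); the 10-12 hydrogen-bond coefficients from a well of
# depth eps_hb at r* (A_hb = 6 eps_hb r*^10, B_hb = 5 eps_hb r*^12).
# They are a synthetic, self-consistent set for the fixtures, not a
# published force field, and are fully swappable via the parameter file.

_VDW = {
    # type: (eps kcal/mol, rmin A)
    "H": (0.02, 2.75),
    "HN": (0.01, 1.80),
    "HO": (0.01, 1.80),
    "C": (0.10, 3.85),
    "N": (0.16, 3.65),
    "O": (0.20, 3.35),
    "X": (0.15, 3.40),   # generic site for toy fixtures
}

_HB = {
    # (donor-attached H type, acceptor type): (eps_hb, r*)
    ("HN", "O"): (2.0, 1.85),
    ("HO", "O"): (2.0, 1.85),
    ("HN", "N"): (1.5, 1.95),
    ("HO", "N"): (1.5, 1.95),
}


def default_potential() -> PotentialParams:
    types = {}
    for t, (eps, rmin) in _VDW.items():
        types[t] = (2.0 * eps * rmin**6, eps * rmin**12)
    hbond = {}
    for pair, (eps, rstar) in _HB.items():
        hbond[pair] = (6.0 * eps * rstar**10, 5.0 * eps * rstar**12)
    return PotentialParams(types=types, hbond=hbond, dielectric=1.0)


# --------------------------------------------------------------------------
# geometry helpers

_BOND = {"CC": 1.53, "CN": 1.49, "CO": 1.25, "C=O": 1.21, "COH": 1.31,
         "OH": 0.97, "NH": 1.03, "CH": 1.09}


def _unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


def _tripod(center, axis, length, n=3, tilt_deg=70.0):
    """n points around ``axis`` from ``center`` at tetrahedral-ish tilt."""
    axis = _unit(axis)
    seed = np.array([0.0, 0.0, 1.0])
    if abs(axis @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e2 = _unit(np.cross(axis, seed))
    e3 = np.cross(axis, e2)
    tilt = math.radians(tilt_deg)
    out = []
    for k in range(n):
        ang = 2.0 * math.pi * k / n
        d = math.cos(tilt) * axis + math.sin(tilt) * (
            math.cos(ang) * e2 + math.sin(ang) * e3)
        out.append(center + length * _unit(d))
    return out


def water_molecule() -> Molecule:
    """Rigid standard water geometry (O-H 0.9572 A, H-O-H 104.52 deg)."""
    ang = math.radians(104.52)
    coords = np.array([
        [0.0, 0.0, 0.0],
        [0.9572, 0.0, 0.0],
        [0.9572 * math.cos(ang), 0.9572 * math.sin(ang), 0.0],
    ])
    return Molecule(atom_indices=[0, 1, 2],
                    labels=["OW", "HW1", "HW2"],
                    elements=["O", "H", "H"],
                    atom_types=["O", "HO", "HO"],
                    frac=coords, bonds=[(0, 1), (0, 2)],
                    fragment_map={0: "water", 1: "water", 2: "water"})


def water_charges() -> dict:
    return {"OW": -0.82, "HW1": 0.41, "HW2": 0.41}


def zwitterion_geometry():
    """19-atom amino-acid-like zwitterion: NH3+ -CH(COO-)-CH2-CH2-COOH.

    Returns (labels, elements, atom_types, coords).  Bond lengths follow
    standard values; the overall conformation is an extended chain.
    """
    B = _BOND
    ca = np.array([0.0, 0.0, 0.0])
    cb = ca + np.array([1.25, 0.0, 0.883])
    cg = cb + np.array([1.25, 0.0, -0.883])
    cd = cg + np.array([1.25, 0.0, 0.883])
    n1 = ca + 1.49 * _unit([-0.82, 0.0, 0.58])
    c1 = ca + 1.53 * _unit([-0.33, 0.94, -0.33])
    o1 = c1 + 1.25 * _unit([0.35, 0.90, 0.28])
    o2 = c1 + 1.25 * _unit([-1.05, 0.35, -0.75])
    ha = ca + 1.09 * _unit([0.0, -0.95, -0.42])
    hns = _tripod(n1, n1 - ca, B["NH"], n=3, tilt_deg=68.0)
    hb1, hb2 = _tripod(cb, np.array([0.0, 0.0, 1.0]), B["CH"], n=2,
                       tilt_deg=55.0)
    hg1, hg2 = _tripod(cg, np.array([0.0, 0.0, -1.0]), B["CH"], n=2,
                       tilt_deg=55.0)
    od1 = cd + 1.21 * _unit([0.42, 0.88, 0.30])
    od2 = cd + 1.31 * _unit([0.75, -0.80, 0.55])
    ho1 = od2 + 0.97 * _unit([0.1, -0.9, 0.5])
    labels = ["N1", "HN1", "HN2", "HN3", "CA", "HA", "C1", "O1", "O2",
              "CB", "HB1", "HB2", "CG", "HG1", "HG2", "CD", "OD1", "OD2",
              "HO1"]
    elements = ["N", "H", "H", "H", "C", "H", "C", "O", "O",
                "C", "H", "H", "C", "H", "H", "C", "O", "O", "H"]
    types = ["N", "HN", "HN", "HN", "C", "H", "C", "O", "O",
             "C", "H", "H", "C", "H", "H", "C", "O", "O", "HO"]
    coords = np.array([n1, *hns, ca, ha, c1, o1, o2,
                       cb, hb1, hb2, cg, hg1, hg2, cd, od1, od2, ho1])
    return labels, elements, types, coords


def zwitterion_charges() -> dict:
    """Hand-assigned point charges for the zwitterion fixture (net 0)."""
    q = {
        "N1": -0.30, "HN1": 0.33, "HN2": 0.33, "HN3": 0.33,
        "CA": 0.10, "HA": 0.06,
        "C1": 0.36, "O1": -0.57, "O2": -0.57,
        "CB": -0.06, "HB1": 0.03, "HB2": 0.03,
        "CG": -0.06, "HG1": 0.03, "HG2": 0.03,
        "CD": 0.45, "OD1": -0.43, "OD2": -0.40,
    }
    q["HO1"] = -round(sum(q.values()), 10)
    return q


def zwitterion_sites(cell: UnitCell, origin_frac=(0.37, 0.05, 0.27),
                     rotation: np.ndarray | None = None):
    labels, elements, types, coords = zwitterion_geometry()
    if rotation is not None:
        coords = coords @ np.asarray(rotation, float).T
    frac = cell.cart_to_frac(coords) + np.asarray(origin_frac, float)
    return [AtomSite(l, e, f, atom_type=t)
            for l, e, t, f in zip(labels, elements, types, frac)]


def _check_packing(structure: CrystalStructure, min_dist: float = 1.7):
    from .cell import expand_symmetry
    insts = expand_symmetry(structure, 1)
    central = [i for i in insts if i.lattice_translation == (0, 0, 0)]
    for a in central:
        for b in insts:
            if a.key() == b.key() and a.template is b.template:
                continue
            if np.linalg.norm(a.cog - b.cog) > 25.0:
                continue
            from scipy.spatial.distance import cdist
            d = cdist(a.coords, b.coords)
            if d.min() < min_dist:
                i, j = np.unravel_index(d.argmin(), d.shape)
                raise PackingClashError(
                    f"molecules {a.key()} and {b.key()} clash: atoms "
                    f"{a.labels[i]}/{b.labels[j]} at {d.min():.2f} A")


def zwitterion_crystal(cell=(10.0, 12.0, 11.0),
                       origin_frac=(0.37, 0.05, 0.27),
                       check: bool = True) -> CrystalStructure:
    """Amino-acid-like zwitterion in a P2_1 2_1 2_1 cell (Z = 4)."""
    uc = UnitCell(*cell)
    sites = zwitterion_sites(uc, origin_frac)
    from .cell import SymmetryOp
    ops = [SymmetryOp.from_triplet(t) for t in
           ("x,y,z", "-x+1/2,-y,z+1/2", "x+1/2,-y+1/2,-z", "-x,y+1/2,-z+1/2")]
    s = CrystalStructure(uc, ops, sites, spacegroup=P212121)
    if check:
        _check_packing(s)
    return s


def dipole_crystal(a: float = 6.0, separation: float = 0.8,
                   q: float = 0.30) -> CrystalStructure:
    """P1 cubic crystal of one rigid two-site dipole per cell.

    Both sites carry zero-vdW atom types, so the lattice energy is a pure
    point-charge sum with a closed-form small-supercell oracle.
    """
    uc = UnitCell(a, a, a)
    half = 0.5 * separation / a
    sites = [AtomSite("D1", "N", (0.5 - half, 0.5, 0.5), atom_type="D0"),
             AtomSite("D2", "O", (0.5 + half, 0.5, 0.5), atom_type="D0")]
    from .cell import SymmetryOp
    ops = [SymmetryOp.from_triplet("x,y,z")]
    return CrystalStructure(uc, ops, sites, spacegroup="P 1")


def dipole_charges(q: float = 0.30) -> dict:
    return {"D1": q, "D2": -q}


def dipole_potential() -> PotentialParams:
    return PotentialParams(types={"D0": (0.0, 0.0)})


def cubic_crystal(a: float = 5.0) -> CrystalStructure:
    """Primitive cubic P1 crystal of single-site molecules (6 nearest
    neighbors -> first synthon class multiplicity 6)."""
    uc = UnitCell(a, a, a)
    sites = [AtomSite("X1", "C", (0.25, 0.25, 0.25), atom_type="X")]
    from .cell import SymmetryOp
    return CrystalStructure(uc, [SymmetryOp.from_triplet("x,y,z")], sites,
                            spacegroup="P 1")


# --------------------------------------------------------------------------
# file-emitting generator


def generate_fixture(spec: dict, seed: int = 0) -> dict:
    """Emit CIF + parameter + charge file texts for a named fixture.

    ``spec`` keys: ``kind`` in {"zwitterion", "dipole", "cubic"}; optional
    ``cell`` (lengths), ``jitter`` (A, uniform coordinate noise drawn from
    ``seed``).  Deterministic: identical (spec, seed) give byte-identical
    text.  Raises :class:`PackingClashError` when the packing is unsound.
    """
    kind = spec.get("kind", "zwitterion")
    jitter = float(spec.get("jitter", 0.0))
    rng = np.random.default_rng(seed)
    if kind == "zwitterion":
        cell = tuple(spec.get("cell", (10.0, 12.0, 11.0)))
        structure = zwitterion_crystal(cell, check=False)
        charges = zwitterion_charges()
        params = default_potential()
    elif kind == "dipole":
        cell = tuple(spec.get("cell", (6.0, 6.0, 6.0)))
        structure = dipole_crystal(cell[0], spec.get("separation", 0.8),
                                   spec.get("q", 0.30))
        charges = dipole_charges(spec.get("q", 0.30))
        params = dipole_potential()
    elif kind == "cubic":
        structure = cubic_crystal(spec.get("cell", (5.0,))[0])
        charges = {"X1": 0.0}
        params = default_potential()
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    if jitter > 0:
        frac_noise = rng.uniform(-jitter, jitter,
                                 (len(structure.asymmetric_unit), 3))
        frac_noise = structure.cell.cart_to_frac(frac_noise)
        for site, dn in zip(structure.asymmetric_unit, frac_noise):
            site.frac = site.frac + dn
        structure._molecules = None
    _check_packing(structure)
    cif = write_cif(structure, data_name=f"{kind}_fixture")
    parse_cif(cif)  # round-trip sanity
    return {
        "cif": cif,
        "potential": dump_potential(params),
        "charges": dump_charges(ChargeSet(charges)),
    }
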