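"""Crystal structures: CIF parsing, symmetry expansion and cell metrics.

A :class:`CrystalStructure` holds a unit cell, a closed set of symmetry
operators and the asymmetric-unit atom sites.  Whole molecules are
reassembled across periodic boundaries by minimum-image hopping along the
bond graph, so that every downstream energy is a genuine molecule-molecule
quantity and never a fragment-image artifact.

Conventions: fractional coordinates of the asymmetric unit live in [0, 1);
the Cartesian frame has *a* along x and *b* in the x-y plane.  Distances
are Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .constants import ATOMIC_MASSES, AVOGADRO, COVALENT_RADII, known_element

__all__ = [
    "UnitCell", "SymmetryOp", "AtomSite", "Molecule", "MoleculeInstance",
    "CrystalStructure", "CifParseError", "UnknownElementError",
    "MoleculeExtractionError", "parse_cif", "write_cif", "extract_molecules",
    "expand_symmetry", "cell_metrics", "structure_report",
]

BOND_TOLERANCE_DEFAULT = 0.4  # Angstrom over covalent-radius sum


class CifParseError(ValueError):
    """Raised when a CIF document lacks a required block or item."""


class UnknownElementError(ValueError):
    """Raised for element symbols with no covalent-radius entry."""


class MoleculeExtractionError(ValueError):
    """Raised when the bonding rule cannot produce sane whole molecules."""


# --------------------------------------------------------------------------
# unit cell


@dataclass(frozen=True)
class UnitCell:
    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must be in (0, 180)")
        if self._sin_volume_factor() <= 0:
            raise ValueError("cell metric tensor is not positive definite")

    def _sin_volume_factor(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        return 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg

    @property
    def matrix(self) -> np.ndarray:
        """Fractional-to-Cartesian matrix; columns are the cell vectors."""
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(self._sin_volume_factor())
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    @property
    def volume(self) -> float:
        return self.a * self.b * self.c * math.sqrt(self._sin_volume_factor())

    def frac_to_cart(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, float) @ self.matrix.T

    def cart_to_frac(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, float) @ np.linalg.inv(self.matrix).T

    def reciprocal_vector(self, hkl: Sequence[int]) -> np.ndarray:
        """Cartesian reciprocal-lattice vector h a* + k b* + l c* (no 2pi)."""
        return np.asarray(hkl, float) @ np.linalg.inv(self.matrix)

    def d_spacing(self, hkl: Sequence[int]) -> float:
        return 1.0 / float(np.linalg.norm(self.reciprocal_vector(hkl)))


# --------------------------------------------------------------------------
# symmetry


@dataclass(frozen=True)
class SymmetryOp:
    """Fractional-space symmetry operator x' = R x + t."""

    rotation: tuple  # 3x3 nested tuple of ints
    translation: tuple  # fractional 3-vector, values in [0, 1)

    def __post_init__(self):
        R = np.asarray(self.rotation)
        if R.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        det = round(float(np.linalg.det(R)))
        if det not in (1, -1):
            raise ValueError("rotation determinant must be +/-1")

    @classmethod
    def from_triplet(cls, triplet: str) -> "SymmetryOp":
        import gemmi
        op = gemmi.Op(triplet)
        den = gemmi.Op.DEN
        rot = np.array(op.rot, float) / den
        if not np.allclose(rot, np.round(rot)):
            raise CifParseError(f"non-integer rotation in operator {triplet!r}")
        tran = (np.array(op.tran, float) / den) % 1.0
        return cls(tuple(map(tuple, np.round(rot).astype(int))),
                   tuple(tran))

    def triplet(self) -> str:
        names = "xyz"
        parts = []
        for row, t in zip(self.rotation, self.translation):
            s = ""
            for coef, n in zip(row, names):
                if coef == 1:
                    s += f"+{n}"
                elif coef == -1:
                    s += f"-{n}"
                elif coef != 0:
                    s += f"{coef:+d}*{n}"
            frac = _frac_str(t)
            if frac:
                s += frac
            parts.append(s.lstrip("+"))
        return ",".join(parts)

    @property
    def rot_array(self) -> np.ndarray:
        return np.asarray(self.rotation, int)

    @property
    def tran_array(self) -> np.ndarray:
        return np.asarray(self.translation, float)

    def apply(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, float) @ self.rot_array.T + self.tran_array

    def compose(self, other: "SymmetryOp") -> "SymmetryOp":
        R = self.rot_array @ other.rot_array
        t = (self.rot_array @ other.tran_array + self.tran_array) % 1.0
        return SymmetryOp(tuple(map(tuple, R)), tuple(np.round(t, 12)))

    def same_as(self, other: "SymmetryOp", tol: float = 1e-9) -> bool:
        dt = (self.tran_array - other.tran_array) % 1.0
        dt = np.minimum(dt, 1.0 - dt)
        return (self.rot_array == other.rot_array).all() and (dt < tol).all()


IDENTITY_OP = SymmetryOp(((1, 0, 0), (0, 1, 0), (0, 0, 1)), (0.0, 0.0, 0.0))


def _frac_str(t: float) -> str:
    if abs(t) < 1e-9:
        return ""
    from fractions import Fraction
    f = Fraction(t).limit_denominator(24)
    return f"+{f.numerator}/{f.denominator}" if f > 0 else f"{f.numerator}/{f.denominator}"


def _check_group_closure(ops: Sequence[SymmetryOp]) -> None:
    for g in ops:
        for h in ops:
            gh = g.compose(h)
            if not any(gh.same_as(o) for o in ops):
                raise CifParseError(
                    f"symmetry operators do not form a closed group: "
                    f"{g.triplet()} * {h.triplet()} missing")


# --------------------------------------------------------------------------
# atoms, molecules, structures


@dataclass
class AtomSite:
    label: str
    element: str
    frac: np.ndarray
    atom_type: str = ""
    charge: float | None = None

    def __post_init__(self):
        if not known_element(self.element):
            raise UnknownElementError(f"unknown element symbol {self.element!r}")
        self.frac = np.asarray(self.frac, float)
        if not np.all(np.isfinite(self.frac)):
            raise ValueError(f"non-finite fractional coordinates for {self.label}")
        if not self.atom_type:
            self.atom_type = self.element


@dataclass
class Molecule:
    """A whole molecule of the asymmetric unit, unwrapped across boundaries.

    ``frac`` rows follow the order of ``atom_indices`` into the
    asymmetric-unit site list.
    """

    atom_indices: list
    labels: list
    elements: list
    atom_types: list
    frac: np.ndarray                       # unwrapped fractional coords
    bonds: list                            # (i, j) local index pairs
    fragment_map: dict = field(default_factory=dict)  # local idx -> label

    def cart(self, cell: UnitCell) -> np.ndarray:
        return cell.frac_to_cart(self.frac)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[e] for e in self.elements])


@dataclass
class MoleculeInstance:
    """A symmetry/lattice image of an asymmetric-unit molecule."""

    template: Molecule
    op_index: int
    lattice_translation: tuple           # integer 3-vector
    coords: np.ndarray                   # Cartesian, Angstrom
    cog: np.ndarray                      # Cartesian center of gravity

    @property
    def labels(self):
        return self.template.labels

    @property
    def elements(self):
        return self.template.elements

    @property
    def atom_types(self):
        return self.template.atom_types

    @property
    def fragment_map(self):
        return self.template.fragment_map

    def key(self) -> tuple:
        return (self.op_index, self.lattice_translation)


@dataclass
class CrystalStructure:
    cell: UnitCell
    ops: list
    asymmetric_unit: list
    spacegroup: str = ""
    bond_tolerance: float = BOND_TOLERANCE_DEFAULT
    _molecules: list | None = field(default=None, repr=False)

    @property
    def Z_prime(self) -> int:
        return len(self.molecules())

    @property
    def Z(self) -> int:
        return self.Z_prime * len(self.ops)

    def molecules(self) -> list:
        if self._molecules is None:
            self._molecules = extract_molecules(self, self.bond_tolerance)
        return self._molecules

    def frac_array(self) -> np.ndarray:
        return np.array([a.frac for a in self.asymmetric_unit])


# --------------------------------------------------------------------------
# CIF I/O (documents parsed with gemmi.cif)

_BUILTIN_GROUPS = {"P1": ["x,y,z"],
                   "P212121": ["x,y,z",
                               "-x+1/2,-y,z+1/2",
                               "x+1/2,-y+1/2,-z",
                               "-x,y+1/2,-z+1/2"]}


def parse_cif(text: str, bond_tolerance: float = BOND_TOLERANCE_DEFAULT) -> CrystalStructure:
    """Parse a CIF 1.1 document into a :class:`CrystalStructure`.

    Requires cell parameters, symmetry (an explicit operator loop or a
    space-group symbol) and fractional atom sites.  The optional
    ``_atom_site_ff_type`` item carries force-field atom types through a
    round trip; absent that, the element symbol is used as the type.
    """
    import gemmi

    try:
        doc = gemmi.cif.read_string(text)
        block = doc.sole_block()
    except Exception as exc:  # gemmi raises RuntimeError/ValueError
        raise CifParseError(f"unreadable CIF document: {exc}") from exc

    def number(tag):
        val = block.find_value(tag)
        if val is None:
            raise CifParseError(f"missing cell item {tag}")
        return gemmi.cif.as_number(val)

    cell = UnitCell(number("_cell_length_a"), number("_cell_length_b"),
                    number("_cell_length_c"), number("_cell_angle_alpha"),
                    number("_cell_angle_beta"), number("_cell_angle_gamma"))

    triplets = [gemmi.cif.as_string(t) for t in
                block.find_loop("_symmetry_equiv_pos_as_xyz")]
    if not triplets:
        triplets = [gemmi.cif.as_string(t) for t in
                    block.find_loop("_space_group_symop_operation_xyz")]
    sg_name = (block.find_value("_symmetry_space_group_name_H-M")
               or block.find_value("_space_group_name_H-M_alt") or "")
    sg_name = gemmi.cif.as_string(sg_name) if sg_name else ""
    if not triplets:
        if not sg_name:
            raise CifParseError("missing symmetry block: no operator loop "
                                "(_symmetry_equiv_pos_as_xyz) and no space-group symbol")
        key = sg_name.replace(" ", "").replace("_", "")
        if key in _BUILTIN_GROUPS:
            triplets = _BUILTIN_GROUPS[key]
        else:
            sg = gemmi.find_spacegroup_by_name(sg_name)
            if sg is None:
                raise CifParseError(f"unknown space group {sg_name!r}; "
                                    "supply explicit symmetry operators")
            triplets = [op.triplet() for op in sg.operations()]
    ops = [SymmetryOp.from_triplet(t) for t in triplets]
    _check_group_closure(ops)

    labels = [gemmi.cif.as_string(v) for v in
              block.find_loop("_atom_site_label")]
    if not labels:
        raise CifParseError("missing atom block: no _atom_site_label loop")
    symbols = [gemmi.cif.as_string(v) for v in
               block.find_loop("_atom_site_type_symbol")] or None
    fx = [gemmi.cif.as_number(v) for v in block.find_loop("_atom_site_fract_x")]
    fy = [gemmi.cif.as_number(v) for v in block.find_loop("_atom_site_fract_y")]
    fz = [gemmi.cif.as_number(v) for v in block.find_loop("_atom_site_fract_z")]
    if not (len(labels) == len(fx) == len(fy) == len(fz)):
        raise CifParseError("atom_site loop has inconsistent column lengths")
    fftypes = [gemmi.cif.as_string(v) for v in
               block.find_loop("_atom_site_ff_type")] or [""] * len(labels)

    sites = []
    for i, lab in enumerate(labels):
        elem = symbols[i] if symbols else _element_from_label(lab)
        frac = np.array([fx[i], fy[i], fz[i]]) % 1.0
        sites.append(AtomSite(lab, elem, frac, atom_type=fftypes[i]))
    return CrystalStructure(cell, ops, sites, spacegroup=sg_name,
                            bond_tolerance=bond_tolerance)


def _element_from_label(label: str) -> str:
    sym = "".join(ch for ch in label if ch.isalpha())
    for cand in (sym[:2].capitalize(), sym[:1].upper()):
        if known_element(cand):
            return cand
    raise UnknownElementError(f"cannot infer element from label {label!r}")


def write_cif(structure: CrystalStructure, data_name: str = "synthonic") -> str:
    """Serialize a structure to CIF text (round-trips through parse_cif)."""
    c = structure.cell
    lines = [f"data_{data_name}"]
    if structure.spacegroup:
        lines.append(f"_symmetry_space_group_name_H-M   '{structure.spacegroup}'")
    lines += [
        f"_cell_length_a   {c.a:.6f}",
        f"_cell_length_b   {c.b:.6f}",
        f"_cell_length_c   {c.c:.6f}",
        f"_cell_angle_alpha   {c.alpha:.6f}",
        f"_cell_angle_beta   {c.beta:.6f}",
        f"_cell_angle_gamma   {c.gamma:.6f}",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
    ]
    lines += [f"  '{op.triplet()}'" for op in structure.ops]
    lines += [
        "loop_",
        "_atom_site_label",
        "_atom_site_type_symbol",
        "_atom_site_ff_type",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
    ]
    for a in structure.asymmetric_unit:
        f = a.frac % 1.0
        lines.append(f"  {a.label} {a.element} {a.atom_type} "
                     f"{f[0]:.8f} {f[1]:.8f} {f[2]:.8f}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# molecule extraction and symmetry expansion

_SHIFTS = np.array(list(product((-1, 0, 1), repeat=3)), float)


def _bond_graph(cell: UnitCell, sites: Sequence[AtomSite], tol: float):
    """Minimum-image bond list: (i, j, shift) with shift applied to atom j."""
    n = len(sites)
    frac = np.array([a.frac % 1.0 for a in sites])
    radii = np.array([COVALENT_RADII[a.element] for a in sites])
    M = cell.matrix
    bonds = []
    for i in range(n):
        d = frac[None, :, :] + _SHIFTS[:, None, :] - frac[i]  # (27, n, 3)
        cart = d @ M.T
        dist = np.linalg.norm(cart, axis=-1)
        best = dist.argmin(axis=0)
        dmin = dist[best, np.arange(n)]
        for j in range(i + 1, n):
            if dmin[j] < radii[i] + radii[j] + tol:
                bonds.append((i, j, tuple(_SHIFTS[best[j]].astype(int))))
    return bonds


def extract_molecules(structure: CrystalStructure,
                      bond_tolerance: float = BOND_TOLERANCE_DEFAULT,
                      fragment_rules: Callable | None = None,
                      fragment_labels: dict | None = None) -> list:
    """Partition the asymmetric unit into whole (unwrapped) molecules.

    Two atoms bond when their minimum-image distance is below the sum of
    covalent radii plus ``bond_tolerance``.  Each connected component is
    unwrapped by hopping bonds across periodic boundaries so its geometry
    is contiguous.  Fragment labels come from ``fragment_labels``
    (atom label -> fragment) when given, else from ``fragment_rules``
    (callable on the molecule), else from built-in zwitterion heuristics
    (:func:`label_fragments`).
    """
    sites = structure.asymmetric_unit
    if not sites:
        raise MoleculeExtractionError("no atom sites present")
    bonds = _bond_graph(structure.cell, sites, bond_tolerance)
    n = len(sites)
    if bonds:
        ii, jj, _ = zip(*bonds)
        adj = coo_matrix((np.ones(len(bonds)), (ii, jj)), shape=(n, n))
        ncomp, comp = connected_components(adj, directed=False)
    else:
        ncomp, comp = n, np.arange(n)

    shift_of = {}
    for i, j, s in bonds:
        shift_of[(i, j)] = np.array(s, float)
        shift_of[(j, i)] = -np.array(s, float)
    neighbors = {i: [] for i in range(n)}
    for i, j, _ in bonds:
        neighbors[i].append(j)
        neighbors[j].append(i)

    molecules = []
    for ci in range(ncomp):
        members = sorted(np.flatnonzero(comp == ci))
        pos = {members[0]: sites[members[0]].frac % 1.0}
        stack = [members[0]]
        while stack:
            i = stack.pop()
            for j in neighbors[i]:
                if j in pos:
                    continue
                base_j = sites[j].frac % 1.0
                base_i = sites[i].frac % 1.0
                pos[j] = pos[i] + (base_j + shift_of[(i, j)] - base_i)
                stack.append(j)
        idx = list(members)
        frac = np.array([pos[i] for i in idx])
        local_bonds = [(idx.index(i), idx.index(j)) for i, j, _ in bonds
                       if i in pos and j in pos and comp[i] == ci]
        mol = Molecule(
            atom_indices=idx,
            labels=[sites[i].label for i in idx],
            elements=[sites[i].element for i in idx],
            atom_types=[sites[i].atom_type for i in idx],
            frac=frac,
            bonds=local_bonds,
        )
        if fragment_labels is not None:
            mol.fragment_map = {k: fragment_labels[lab]
                                for k, lab in enumerate(mol.labels)}
        elif fragment_rules is not None:
            mol.fragment_map = fragment_rules(mol)
        else:
            mol.fragment_map = label_fragments(mol)
        molecules.append(mol)

    if len(molecules) > 1:
        for mol in molecules:
            if len(mol.labels) == 1:
                import warnings
                warnings.warn(
                    f"lone-atom component {mol.labels} while other "
                    f"components are larger; check bond tolerance",
                    stacklevel=2)
    return molecules


def label_fragments(mol: Molecule) -> dict:
    """Heuristic fragment labels for amino-acid-like molecules.

    Recognises carboxylate (-COO-), carboxylic acid (-COOH), ammonium
    (-NH3+) and assigns everything else to the aliphatic chain.
    """
    nbrs = {i: [] for i in range(len(mol.labels))}
    for i, j in mol.bonds:
        nbrs[i].append(j)
        nbrs[j].append(i)
    frag = {}
    el = mol.elements
    for i in range(len(el)):
        if el[i] != "C":
            continue
        oxy = [j for j in nbrs[i] if el[j] == "O"]
        if len(oxy) == 2:
            o_h = [h for o in oxy for h in nbrs[o] if el[h] == "H"]
            name = "carboxylic acid" if o_h else "carboxylate"
            frag[i] = name
            for o in oxy:
                frag[o] = name
            for h in o_h:
                frag[h] = name
    for i in range(len(el)):
        if el[i] == "N":
            hyd = [j for j in nbrs[i] if el[j] == "H"]
            if len(hyd) >= 3:
                frag[i] = "ammonium"
                for h in hyd:
                    frag[h] = "ammonium"
    for i in range(len(el)):
        frag.setdefault(i, "aliphatic")
    return frag


def expand_symmetry(structure: CrystalStructure, shells: int) -> list:
    """All whole molecules in the (2*shells+1)^3 supercell.

    Every instance is a rigid image of its asymmetric-unit template; its
    mass-weighted center of gravity determines the home cell (interaction
    distances are COG-COG throughout).
    """
    if shells < 0:
        raise ValueError("shells must be >= 0")
    mols = structure.molecules()
    cell = structure.cell
    M = cell.matrix
    out = []
    rng = range(-shells, shells + 1)
    for mol in mols:
        w = mol.masses / mol.masses.sum()
        for oi, op in enumerate(structure.ops):
            frac = op.apply(mol.frac)
            cog_f = w @ frac
            base_shift = np.floor(cog_f)  # wrap COG into [0,1)
            frac0 = frac - base_shift
            for tx, ty, tz in product(rng, rng, rng):
                t = np.array([tx, ty, tz], float)
                fr = frac0 + t
                cart = fr @ M.T
                out.append(MoleculeInstance(
                    template=mol, op_index=oi,
                    lattice_translation=(tx, ty, tz),
                    coords=cart, cog=w @ cart))
    return out


# --------------------------------------------------------------------------
# cell-derived metrics


def cell_metrics(structure: CrystalStructure, molecular_volume: float,
                 molar_mass: float, Z: int | None = None) -> dict:
    """Volume (A^3), density (g/cm^3) and packing coefficient.

    density = Z M / (N_A V); packing = Z V_mol / V_cell.
    """
    if molecular_volume <= 0:
        raise ValueError("molecular_volume must be > 0")
    if molar_mass <= 0:
        raise ValueError("molar_mass must be > 0")
    Z = structure.Z if Z is None else Z
    V = structure.cell.volume
    density = Z * molar_mass / (AVOGADRO * V * 1e-24)
    packing = Z * molecular_volume / V
    return {"volume": V, "density": density, "packing_coefficient": packing}


def structure_report(structure: CrystalStructure) -> dict:
    """Normalized JSON-able structure summary."""
    mols = structure.molecules()
    return {
        "cell": {k: getattr(structure.cell, k)
                 for k in ("a", "b", "c", "alpha", "beta", "gamma")},
        "volume": structure.cell.volume,
        "spacegroup": structure.spacegroup,
        "n_ops": len(structure.ops),
        "ops": [op.triplet() for op in structure.ops],
        "Z": structure.Z,
        "Z_prime": structure.Z_prime,
        "molecules": [
            {"labels": m.labels,
             "formula": _formula(m.elements),
             "fragments": sorted(set(m.fragment_map.values()))}
            for m in mols],
    }


def _formula(elements: Iterable[str]) -> str:
    from collections import Counter
    cnt = Counter(elements)
    order = sorted(cnt, key=lambda e: (e != "C", e != "H", e))
    return "".join(f"{e}{cnt[e] if cnt[e] > 1 else ''}" for e in order)
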