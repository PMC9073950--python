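"""Crystal morphology: BFDH face lists, slice/attachment energy partition,
interfacial (Jackson alpha) factors, solvent-modified attachment energies
and Wulff construction.

The attachment-energy postulate identifies |E_att| of a face with its
relative growth rate; the Wulff shape is the inner envelope of planes at
distances proportional to those rates.  Three solvent-modified models
rescale E_att by the balance of solute/solvent surface binding, optionally
weighted by surface rugosity and the Jackson alpha factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Callable, Sequence

import numpy as np
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

from .cell import CrystalStructure, UnitCell
from .constants import R_KCAL
from .lattice import LatticeEnergyResult, lattice_sum
from .potential import ChargeSet, PotentialParams

__all__ = [
    "FaceForm", "FaceRecord", "WulffShape", "WulffError",
    "bfdh_form_list", "is_absent", "slice_attachment_from_result",
    "slice_attachment_partition", "anisotropy_factor", "jackson_alpha",
    "modified_attachment_energy", "wulff_construct", "face_table",
]


class WulffError(ValueError):
    pass


@dataclass(frozen=True)
class FaceForm:
    hkl: tuple
    d_spacing: float
    multiplicity: int

    def __post_init__(self):
        if self.d_spacing <= 0:
            raise ValueError("d-spacing must be > 0")

    def name(self) -> str:
        return "{%d %d %d}" % self.hkl


@dataclass
class FaceRecord:
    form: FaceForm
    E_slice: float = 0.0
    E_att: float = 0.0
    epsilon: float = 0.0
    R_g: float = 0.0
    U_solute: float = 0.0
    U_solvent: float = 0.0
    alpha: float = 0.0
    U_eps: dict = field(default_factory=dict)  # model number -> kcal/mol


# --------------------------------------------------------------------------
# BFDH face list with systematic absences


def is_absent(hkl: Sequence[int], ops) -> bool:
    """General systematic-absence rule: (hkl) is extinct iff some operator
    (R, t) fixes hkl (hkl.R == hkl) while hkl.t is non-integral."""
    h = np.asarray(hkl, int)
    for op in ops:
        if np.array_equal(h @ op.rot_array, h):
            phase = float(h @ op.tran_array)
            if abs(phase - round(phase)) > 1e-9:
                return True
    return False


def _point_rotations(ops) -> list:
    """Unique rotation parts of the operator set plus the inversion
    (Friedel's law), i.e. the Laue group acting on Miller indices."""
    mats = []
    for op in ops:
        for R in (op.rot_array, -op.rot_array):
            if not any(np.array_equal(R, M) for M in mats):
                mats.append(R)
    return mats


def _form_orbit(hkl: tuple, rotations) -> list:
    h = np.asarray(hkl, int)
    orbit = []
    for R in rotations:
        v = tuple((h @ R).tolist())
        if v not in orbit:
            orbit.append(v)
    return orbit


def bfdh_form_list(structure: CrystalStructure, n: int,
                   max_index: int = 3) -> list:
    """Top-``n`` crystal forms ranked by interplanar d-spacing.

    Symmetry-equivalent (hkl) collapse into one form (Laue-group orbit);
    systematically absent reflections are replaced by their smallest
    allowed multiple, e.g. (0 0 1) -> (0 0 2) under a 2_1 screw axis, and
    the d-spacing of that multiple does the ranking (BFDH rule).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rotations = _point_rotations(structure.ops)
    cell = structure.cell
    seen = set()
    forms = []
    rng = range(-max_index, max_index + 1)
    for hkl in product(rng, rng, rng):
        if hkl == (0, 0, 0):
            continue
        if math.gcd(math.gcd(abs(hkl[0]), abs(hkl[1])), abs(hkl[2])) != 1:
            continue
        orbit = _form_orbit(hkl, rotations)
        rep = max(orbit)
        if rep in seen:
            continue
        seen.add(rep)
        for m in range(1, 5):
            mh = tuple(m * x for x in rep)
            if not is_absent(mh, structure.ops):
                forms.append(FaceForm(mh, cell.d_spacing(mh), len(orbit)))
                break
    forms.sort(key=lambda f: (-f.d_spacing, tuple(-x for x in f.hkl)))
    return forms[:n]


# --------------------------------------------------------------------------
# slice / attachment partition (E_latt = E_slice + E_att)


def slice_attachment_from_result(result: LatticeEnergyResult,
                                 form: FaceForm) -> tuple:
    """Partition one lattice sum into (E_slice, E_att) for a form.

    A neighbor belongs to the slice when its COG lies inside the slab of
    thickness d_hkl centered on the central molecule's COG and oriented
    normal to (hkl); otherwise it is an attachment neighbor.  The two
    energies share the pair set of the lattice sum, so their total equals
    E_latt exactly.
    """
    cell = result.structure.cell
    g = cell.reciprocal_vector(form.hkl)
    n_hat = g / np.linalg.norm(g)
    half = 0.5 * form.d_spacing
    e_slice = 0.0
    e_att = 0.0
    for nb in result.per_neighbor:
        if abs(float(nb.delta_cog @ n_hat)) <= half + 1e-9:
            e_slice += nb.energy.total
        else:
            e_att += nb.energy.total
    return 0.5 * e_slice, 0.5 * e_att


def slice_attachment_partition(structure: CrystalStructure,
                               params: PotentialParams, charges: ChargeSet,
                               form: FaceForm, r_max: float,
                               results: Sequence[LatticeEnergyResult] | None = None
                               ) -> tuple:
    """(E_slice, E_att) for a form, maximizing slice stability over the Z
    symmetry-equivalent choices of central molecule.

    ``results`` may supply precomputed lattice sums (one per central
    choice) to avoid recomputation; by symmetry all choices agree for a
    full form, and the most stabilizing (most negative) E_slice is
    reported.
    """
    if results is None:
        results = [lattice_sum(structure, params, charges, r_max,
                               central_choice=i)
                   for i in range(len(structure.ops))]
    best = None
    for res in results:
        es, ea = slice_attachment_from_result(res, form)
        if best is None or es < best[0]:
            best = (es, ea)
    return best


def anisotropy_factor(E_slice: float, E_latt: float) -> float:
    """epsilon_hkl = E_slice / E_latt, the fraction of lattice bonding
    saturated within the growth slice."""
    if E_latt == 0:
        raise ValueError("lattice energy is zero; anisotropy undefined")
    return E_slice / E_latt


def jackson_alpha(epsilon: float, delta_H_f: float, T: float,
                  X_seq: float, R: float = R_KCAL) -> float:
    """Jackson surface-entropy factor.

    alpha = epsilon * (dH_f / (R T) - ln X_seq), with dH_f the enthalpy of
    fusion (kcal/mol) and X_seq the solute mole fraction at the growth
    condition.  High alpha indicates smooth, low alpha rough interfacial
    growth.
    """
    if T <= 0:
        raise ValueError("temperature must be > 0")
    if not 0 < X_seq <= 1:
        raise ValueError("X_seq must be in (0, 1]")
    return epsilon * (delta_H_f / (R * T) - math.log(X_seq))


# --------------------------------------------------------------------------
# solvent-modified attachment energies


def modified_attachment_energy(face: FaceRecord, model: int,
                               R_g_min: float | None = None,
                               expression: Callable | None = None) -> float:
    """Solvent/solute-corrected attachment energy U_eps for one face.

    model 1: U = E_att * (U_solute - U_solvent) / U_solute
    model 2: as 1 with U_solvent -> U_solvent * (R_g / R_g_min)
    model 3: as 2 with U_solute -> U_solute / alpha

    ``expression`` overrides the built-in form; it receives the face
    record and R_g_min and returns U_eps.
    """
    if expression is not None:
        return expression(face, R_g_min)
    if model not in (1, 2, 3):
        raise ValueError("model must be 1, 2 or 3")
    u_solute = face.U_solute
    if u_solute >= 0:
        raise ValueError(f"face {face.form.name()}: U_solute must be "
                         "attractive (negative)")
    u_solvent = face.U_solvent
    if model >= 2:
        if R_g_min is None or R_g_min <= 0:
            raise ValueError(f"face {face.form.name()}: model {model} "
                             "needs R_g_min > 0")
        u_solvent = u_solvent * (face.R_g / R_g_min)
    if model == 3:
        if face.alpha <= 0:
            raise ValueError(f"face {face.form.name()}: model 3 needs "
                             "alpha > 0")
        u_solute = u_solute / face.alpha
    return face.E_att * (u_solute - u_solvent) / u_solute


# --------------------------------------------------------------------------
# Wulff construction


@dataclass
class WulffShape:
    vertices: np.ndarray          # (n, 3) Cartesian, arbitrary scale
    faces: list                   # (hkl, ordered vertex-index loop)
    face_areas: dict              # representative hkl -> absolute area
    relative_areas: dict          # representative hkl -> % of total area
    aspect_ratio: tuple           # sorted bounding-box extents, min = 1

    @property
    def volume(self) -> float:
        return float(ConvexHull(self.vertices).volume)

    def to_off(self) -> str:
        lines = ["OFF", f"{len(self.vertices)} {len(self.faces)} 0"]
        for v in self.vertices:
            lines.append(f"{v[0]:.8f} {v[1]:.8f} {v[2]:.8f}")
        for _, loop in self.faces:
            lines.append(str(len(loop)) + " " + " ".join(map(str, loop)))
        return "\n".join(lines) + "\n"

    def area_summary(self) -> str:
        lines = ["hkl\trelative_area_percent"]
        for hkl, pct in sorted(self.relative_areas.items(),
                               key=lambda kv: -kv[1]):
            lines.append("(%d %d %d)\t%.3f" % (*hkl, pct))
        return "\n".join(lines) + "\n"


def _metric_laue_rotations(cell: UnitCell) -> list:
    """Holohedral rotations consistent with the cell metric: sign flips
    (mmm) for any right-angled cell, plus axis permutations when the cell
    is metrically cubic."""
    flips = [np.diag((s1, s2, s3)) for s1 in (1, -1) for s2 in (1, -1)
             for s3 in (1, -1)]
    right_angles = all(abs(getattr(cell, a) - 90.0) < 1e-9
                       for a in ("alpha", "beta", "gamma"))
    cubic = right_angles and abs(cell.a - cell.b) < 1e-9 and \
        abs(cell.b - cell.c) < 1e-9
    if not cubic:
        return flips if right_angles else \
            [np.eye(3, dtype=int), -np.eye(3, dtype=int)]
    from itertools import permutations
    perms = [np.eye(3, dtype=int)[list(p)] for p in permutations(range(3))]
    return [f @ p for f in flips for p in perms]


def _polygon_area_3d(pts: np.ndarray) -> float:
    if len(pts) < 3:
        return 0.0
    c = pts.mean(axis=0)
    s = np.zeros(3)
    for i in range(len(pts)):
        s += np.cross(pts[i] - c, pts[(i + 1) % len(pts)] - c)
    return 0.5 * float(np.linalg.norm(s))


def wulff_construct(forms_rates: Sequence[tuple], cell: UnitCell,
                    rotations=None, ops=None) -> WulffShape:
    """Wulff shape from (FaceForm-or-hkl, growth rate) pairs.

    Each form is expanded to its Laue-group orbit (derived from ``ops``
    when given, else ``rotations``, else the orthorhombic mmm orbit of
    independent sign flips); every plane sits at a distance from the
    origin proportional to its rate.  The
    shape is the intersection of the half-spaces, computed with Qhull;
    relative face areas are reported per form and the aspect ratio as the
    sorted bounding-box extents normalized to the smallest.
    """
    if rotations is None:
        if ops is not None:
            rotations = _point_rotations(ops)
        else:
            rotations = _metric_laue_rotations(cell)
    planes = []   # (rep_hkl, unit normal, distance)
    rates = [float(r) for _, r in forms_rates]
    if not rates or min(rates) <= 0:
        raise WulffError("all growth rates must be > 0")
    scale = max(rates)
    for (form, rate) in forms_rates:
        hkl = form.hkl if isinstance(form, FaceForm) else tuple(form)
        for v in _form_orbit(hkl, rotations):
            g = cell.reciprocal_vector(v)
            n_hat = g / np.linalg.norm(g)
            planes.append((hkl, n_hat, float(rate) / scale))
    normals = np.array([p[1] for p in planes])
    if np.linalg.matrix_rank(normals) < 3:
        raise WulffError("plane normals do not span 3-space; shape unbounded")
    halfspaces = np.hstack([normals, -np.array([[p[2]] for p in planes])])
    try:
        hs = HalfspaceIntersection(halfspaces, np.zeros(3))
    except QhullError as exc:
        raise WulffError(f"half-space intersection failed: {exc}") from exc
    verts = hs.intersections
    # deduplicate near-coincident Qhull vertices
    key = np.round(verts / 1e-8).astype(np.int64)
    _, idx = np.unique(key, axis=0, return_index=True)
    vertices = verts[np.sort(idx)]
    faces = []
    face_areas: dict = {}
    for rep, n_hat, dist in planes:
        on_plane = np.flatnonzero(np.abs(vertices @ n_hat - dist) < 1e-7)
        if len(on_plane) < 3:
            continue
        pts = vertices[on_plane]
        c = pts.mean(axis=0)
        ref = pts[0] - c
        ref -= n_hat * (ref @ n_hat)
        if np.linalg.norm(ref) < 1e-12:
            continue
        ref /= np.linalg.norm(ref)
        other = np.cross(n_hat, ref)
        ang = np.arctan2((pts - c) @ other, (pts - c) @ ref)
        order = on_plane[np.argsort(ang)]
        area = _polygon_area_3d(vertices[order])
        if area < 1e-10:
            continue
        faces.append((rep, order.tolist()))
        face_areas[rep] = face_areas.get(rep, 0.0) + area
    total = sum(face_areas.values())
    for form, _ in forms_rates:
        hkl = form.hkl if isinstance(form, FaceForm) else tuple(form)
        face_areas.setdefault(hkl, 0.0)
    relative = {hkl: 100.0 * a / total for hkl, a in face_areas.items()}
    extents = np.sort(vertices.max(axis=0) - vertices.min(axis=0))
    aspect = tuple(extents / extents[0])
    return WulffShape(vertices, faces, face_areas, relative, aspect)


# --------------------------------------------------------------------------


def face_table(records: Sequence[FaceRecord]) -> str:
    """Delimited text table of per-face quantities (one row per form)."""
    lines = ["hkl\td_spacing_A\tU_solvent\tU_solute\tR_g_A\tE_slice\tE_att\t"
             "epsilon_percent\talpha\tU_eps_m1\tU_eps_m2\tU_eps_m3"]
    for r in records:
        cells = ["(%d %d %d)" % r.form.hkl, f"{r.form.d_spacing:.4f}",
                 f"{r.U_solvent:.4f}", f"{r.U_solute:.4f}", f"{r.R_g:.4f}",
                 f"{r.E_slice:.4f}", f"{r.E_att:.4f}",
                 f"{100.0 * r.epsilon:.2f}", f"{r.alpha:.3f}"]
        for m in (1, 2, 3):
            cells.append(f"{r.U_eps[m]:.4f}" if m in r.U_eps else "-")
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
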