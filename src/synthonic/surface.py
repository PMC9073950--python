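"""Surface slabs, plane rugosity and the grid-based systematic search.

A slab is a single- or multi-d-spacing layer of whole molecules cut from
the unrelaxed bulk crystal and repeated laterally.  A rigid probe molecule
(solvent or solute) is translated on a grid covering one surface unit cell
and rotated through three Euler angles; every pose's interaction energy
with the slab is evaluated with the same atom-atom potential used for the
lattice energy, giving binding-site maps, strongest-binding energies and
top-N interaction distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .cell import CrystalStructure, Molecule, MoleculeInstance, expand_symmetry
from .morphology import FaceForm
from .potential import ChargeSet, EnergyBreakdown, PotentialParams

__all__ = [
    "Slab", "ProbePose", "GridSearchResult", "SurfaceError",
    "build_slab", "plane_rugosity", "systematic_search",
    "interaction_distribution", "probe_instance", "pose_table",
    "binding_map",
]

CLASH_THRESHOLD_DEFAULT = 1.0  # Angstrom atom-atom


class SurfaceError(ValueError):
    pass


@dataclass
class Slab:
    form: FaceForm
    molecules: list               # MoleculeInstance list
    normal: np.ndarray            # unit vector
    thickness: int                # multiples of d_hkl
    lateral_vectors: np.ndarray   # (2, 3) Cartesian in-plane lattice vectors

    @property
    def top_z(self) -> float:
        """Topmost atomic plane along the normal (z = 0 surface reference)."""
        return max(float((m.coords @ self.normal).max()) for m in self.molecules)

    def atom_coords(self) -> np.ndarray:
        return np.vstack([m.coords for m in self.molecules])


@dataclass
class ProbePose:
    position: np.ndarray     # probe COG, Cartesian
    grid_xy: tuple           # fractional steps along the two lateral vectors
    height: float            # above the topmost atomic plane
    euler: tuple             # (phi, theta, psi) degrees, Z-X-Z intrinsic
    energy: EnergyBreakdown
    accepted: bool

    def component_percentages(self) -> tuple:
        mags = (abs(self.energy.hbond), abs(self.energy.vdw),
                abs(self.energy.coulomb))
        s = sum(mags)
        if s == 0:
            return (0.0, 0.0, 0.0)
        return tuple(100.0 * m / s for m in mags)  # (hbond, vdw, coulomb) %


@dataclass
class GridSearchResult:
    slab: Slab
    poses: list

    @property
    def accepted(self) -> list:
        return [p for p in self.poses if p.accepted]

    @property
    def minimum(self) -> ProbePose:
        acc = self.accepted
        if not acc:
            raise SurfaceError("no accepted poses; expand the height range")
        return min(acc, key=lambda p: p.energy.total)

    def top_n(self, n: int) -> list:
        return sorted(self.accepted, key=lambda p: p.energy.total)[:n]


# --------------------------------------------------------------------------
# slab construction


def _integer_solutions(hkl, limit=4):
    h = np.asarray(hkl, int)
    sols = []
    rng = range(-limit, limit + 1)
    for v in product(rng, rng, rng):
        if v != (0, 0, 0):
            sols.append((np.array(v), int(h @ np.array(v))))
    return sols


def in_plane_lattice_vectors(cell, hkl) -> np.ndarray:
    """Two shortest independent integer lattice vectors with h.u = 0."""
    M = cell.matrix
    candidates = [(np.linalg.norm(M @ v), v) for v, dot in
                  _integer_solutions(hkl) if dot == 0]
    candidates.sort(key=lambda t: (t[0], tuple(t[1])))
    u1 = candidates[0][1]
    for _, v in candidates[1:]:
        if np.linalg.norm(np.cross(u1, v)) > 1e-9:
            return np.array([u1, v])
    raise SurfaceError(f"degenerate lateral vectors for {tuple(hkl)}")


def depth_step_vector(hkl):
    """Integer lattice vector advancing the slab depth by the smallest
    positive amount (gcd(h,k,l) d-spacings)."""
    best = None
    for v, dot in _integer_solutions(hkl):
        if dot > 0 and (best is None or dot < best[1]):
            best = (v, dot)
    return best


def build_slab(structure: CrystalStructure, form: FaceForm,
               thickness: int = 1, lateral_repeats: tuple = (1, 1),
               central_choice: int = 0) -> Slab:
    """Cut an (hkl) slab of ``thickness`` d-spacings from the bulk.

    The slab window of depth thickness x d_hkl is centered on the COG of
    the reference molecule (``central_choice`` selects the termination
    among the Z symmetry-equivalent cuts, consistent with the
    slice-energy convention).  Molecules are whole, unrelaxed, and
    repeated over ``lateral_repeats`` surface cells centered on the
    origin cell.
    """
    if thickness < 1:
        raise SurfaceError("thickness must be >= 1")
    cell = structure.cell
    g = cell.reciprocal_vector(form.hkl)
    n_hat = g / np.linalg.norm(g)
    d = form.d_spacing
    u = in_plane_lattice_vectors(cell, form.hkl)
    u_cart = (u @ cell.matrix.T).astype(float)
    v3, gstep = depth_step_vector(form.hkl)
    depth_period = gstep * d

    home = expand_symmetry(structure, 0)
    ref = home[central_choice % len(home)]
    s_ref = float(ref.cog @ n_hat)
    lo = s_ref - 0.5 * thickness * d - 1e-9
    hi = s_ref + 0.5 * thickness * d - 1e-9

    r1, r2 = lateral_repeats
    i_range = range(-(r1 // 2), r1 - r1 // 2)
    j_range = range(-(r2 // 2), r2 - r2 // 2)
    M = cell.matrix
    out = []
    for m in home:
        s_m = float(m.cog @ n_hat)
        # integer k with lo < s_m + k*depth_period <= hi
        k_lo = math.ceil((lo - s_m) / depth_period)
        k_hi = math.floor((hi - s_m) / depth_period)
        for k in range(k_lo, k_hi + 1):
            for i in i_range:
                for j in j_range:
                    t = i * u[0] + j * u[1] + k * v3
                    shift = M @ t.astype(float)
                    lat = tuple(np.array(m.lattice_translation) + t)
                    out.append(MoleculeInstance(
                        template=m.template, op_index=m.op_index,
                        lattice_translation=tuple(int(x) for x in lat),
                        coords=m.coords + shift, cog=m.cog + shift))
    if not out:
        raise SurfaceError(f"empty slab for {form.name()}")
    return Slab(form, out, n_hat, thickness, u_cart)


def plane_rugosity(slab: Slab) -> float:
    """Surface roughness R_g: RMS deviation along the normal of the atomic
    centers of the molecules in a single-d-spacing surface layer."""
    if slab.thickness != 1:
        raise SurfaceError("rugosity is defined for a single-d-spacing slab")
    if not slab.molecules:
        raise SurfaceError("empty slab")
    s = slab.atom_coords() @ slab.normal
    return float(np.sqrt(np.mean((s - s.mean()) ** 2)))


# --------------------------------------------------------------------------
# probes and the systematic search


def probe_instance(mol: Molecule, cell=None, coords: np.ndarray | None = None) -> MoleculeInstance:
    """Wrap a template molecule as a free-standing rigid probe."""
    if coords is None:
        if cell is None:
            raise ValueError("pass cell= or coords=")
        coords = mol.cart(cell)
    w = mol.masses / mol.masses.sum()
    return MoleculeInstance(template=mol, op_index=-1,
                            lattice_translation=(0, 0, 0),
                            coords=np.asarray(coords, float),
                            cog=w @ np.asarray(coords, float))


def _euler_grid(rot_step: float):
    phis = np.arange(0.0, 360.0, rot_step)
    thetas = np.arange(0.0, 180.0, rot_step)
    psis = np.arange(0.0, 360.0, rot_step)
    return [(p, t, s) for p in phis for t in thetas for s in psis]


def systematic_search(slab: Slab, probe: MoleculeInstance,
                      params: PotentialParams, charges: ChargeSet,
                      t_step: float = 0.2, rot_step: float = 30.0,
                      heights: tuple = (1.5, 6.0), cutoff: float = 15.0,
                      clash: float = CLASH_THRESHOLD_DEFAULT,
                      grid_origin: np.ndarray | None = None) -> GridSearchResult:
    """Exhaustive rigid-body probe search over one surface unit cell.

    The probe COG visits a lateral grid of ``t_step`` spacing covering one
    surface cell, at heights ``heights[0]..heights[1]`` (same step) above
    the topmost atomic plane, and at each point is rotated through a
    Z-X-Z Euler grid of ``rot_step`` degrees.  Energies are sums of
    molecule-molecule interactions with slab molecules within ``cutoff``
    of the probe COG.  Poses with any atom-atom contact below ``clash``
    are recorded but rejected.
    """
    n_hat = slab.normal
    u1, u2 = slab.lateral_vectors
    if grid_origin is None:
        grid_origin = np.zeros(3)
    base = np.asarray(grid_origin, float)
    # lateral fractions covering one surface cell; steps are exact
    # multiples of t_step so a refined grid contains the coarse one
    len1, len2 = np.linalg.norm(u1), np.linalg.norm(u2)
    f1s = np.arange(0.0, len1 - 1e-9, t_step) / len1
    f2s = np.arange(0.0, len2 - 1e-9, t_step) / len2
    zs = np.arange(heights[0], heights[1] + 1e-9, t_step)
    top = slab.top_z

    w = probe.template.masses / probe.template.masses.sum()
    p0 = probe.coords - probe.cog
    slab_data = []
    for m in slab.molecules:
        qb = charges.array(m.labels)
        mats = params.matrices(probe.atom_types, m.atom_types)
        slab_data.append((m, qb, mats))
    qa = charges.array(probe.labels)
    kq = params.coulomb_constant / params.dielectric

    poses = []
    for phi, theta, psi in _euler_grid(rot_step):
        R = Rotation.from_euler("ZXZ", (phi, theta, psi), degrees=True)
        pr = p0 @ R.as_matrix().T
        for f1 in f1s:
            for f2 in f2s:
                lateral = base + f1 * u1 + f2 * u2
                lateral = lateral - n_hat * float(lateral @ n_hat)
                for z in zs:
                    pos = lateral + (top + z) * n_hat
                    pp = pr + pos
                    vdw = hbe = coul = 0.0
                    ok = True
                    for m, qb, (A, B, hb, Ah, Bh) in slab_data:
                        if np.linalg.norm(m.cog - pos) > cutoff:
                            continue
                        r = cdist(pp, m.coords)
                        if r.min() < clash:
                            ok = False
                        r = np.maximum(r, 1e-6)
                        inv2 = 1.0 / (r * r)
                        inv6 = inv2 ** 3
                        inv12 = inv6 ** 2
                        vdw += float(np.where(hb, 0.0, -A * inv6 + B * inv12).sum())
                        hbe += float(np.where(hb, -Ah * inv6 * inv2 * inv2
                                              + Bh * inv12, 0.0).sum())
                        coul += float((kq * np.outer(qa, qb) / r).sum())
                    poses.append(ProbePose(
                        position=pos, grid_xy=(float(f1), float(f2)),
                        height=float(z), euler=(float(phi), float(theta), float(psi)),
                        energy=EnergyBreakdown(vdw, hbe, coul),
                        accepted=ok))
    result = GridSearchResult(slab, poses)
    if not result.accepted:
        raise SurfaceError("no accepted poses (all clashing); "
                           "expand the height range")
    return result


def interaction_distribution(result: GridSearchResult, n: int = 500,
                             pos_tol: float = 0.5,
                             ang_tol: float = 30.0) -> dict:
    """Top-``n`` distinct binding interactions, most negative first.

    Raw grid poses oversample each binding basin, so poses within
    ``pos_tol`` (A) and ``ang_tol`` (deg, circular) of a better pose are
    clustered away before ranking.  Returns sorted energies, per-pose
    component percentages (H-bond, vdW, Coulomb) and their means; when
    fewer than ``n`` distinct minima exist, all are returned with
    ``complete=False``.
    """
    acc = sorted(result.accepted, key=lambda p: p.energy.total)
    kept = []
    for p in acc:
        dominated = False
        for q in kept:
            if np.linalg.norm(p.position - q.position) < pos_tol and all(
                    _circ_diff(a, b) < ang_tol
                    for a, b in zip(p.euler, q.euler)):
                dominated = True
                break
        if not dominated:
            kept.append(p)
        if len(kept) >= n:
            break
    pct = np.array([p.component_percentages() for p in kept])
    return {
        "poses": kept,
        "energies": np.array([p.energy.total for p in kept]),
        "component_percentages": pct,
        "mean_percentages": pct.mean(axis=0) if len(pct) else np.zeros(3),
        "complete": len(kept) >= n,
    }


def _circ_diff(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


# --------------------------------------------------------------------------
# text exports


def pose_table(result: GridSearchResult) -> str:
    lines = ["x\ty\tz\tphi\ttheta\tpsi\tE_total\tE_vdw\tE_hb\tE_coul\taccepted"]
    for p in result.poses:
        e = p.energy
        lines.append(
            f"{p.position[0]:.3f}\t{p.position[1]:.3f}\t{p.position[2]:.3f}\t"
            f"{p.euler[0]:.1f}\t{p.euler[1]:.1f}\t{p.euler[2]:.1f}\t"
            f"{e.total:.4f}\t{e.vdw:.4f}\t{e.hbond:.4f}\t{e.coulomb:.4f}\t"
            f"{int(p.accepted)}")
    return "\n".join(lines) + "\n"


def binding_map(result: GridSearchResult) -> str:
    """Raster of the best accepted energy per lateral grid point (TSV)."""
    best: dict = {}
    for p in result.accepted:
        key = p.grid_xy
        if key not in best or p.energy.total < best[key]:
            best[key] = p.energy.total
    f1s = sorted({k[0] for k in best})
    f2s = sorted({k[1] for k in best})
    lines = ["f1\\f2\t" + "\t".join(f"{f:.3f}" for f in f2s)]
    for f1 in f1s:
        row = [f"{f1:.3f}"]
        for f2 in f2s:
            v = best.get((f1, f2))
            row.append(f"{v:.4f}" if v is not None else "nan")
        lines.append("\t".join(row))
    return "\n".join(lines) + "\n"
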