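"""Slab construction, rugosity and the systematic probe search."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from synthonic.cell import Molecule
from synthonic.morphology import FaceForm, bfdh_form_list
from synthonic.potential import ChargeSet, molecule_pair_energy
from synthonic.surface import (Slab, SurfaceError, build_slab,
                               binding_map, interaction_distribution,
                               plane_rugosity, pose_table, probe_instance,
                               systematic_search)

COARSE = dict(t_step=2.5, rot_step=180.0, heights=(2.0, 4.0), cutoff=12.0)


@pytest.fixture(scope="module")
def zwit_form(zwit_structure):
    return bfdh_form_list(zwit_structure, 1)[0]


@pytest.fixture(scope="module")
def zwit_slab(zwit_structure, zwit_form):
    return build_slab(zwit_structure, zwit_form, thickness=1,
                      lateral_repeats=(3, 3))


class TestBuildSlab:
    def test_single_thickness_count(self, zwit_structure, zwit_form):
        slab = build_slab(zwit_structure, zwit_form, thickness=1)
        assert len(slab.molecules) == zwit_structure.Z

    def test_lateral_repeats_scale_count(self, zwit_structure, zwit_form,
                                         zwit_slab):
        assert len(zwit_slab.molecules) == zwit_structure.Z * 9

    def test_doubling_thickness_doubles_count(self, zwit_structure,
                                              zwit_form):
        n1 = len(build_slab(zwit_structure, zwit_form, 1).molecules)
        n2 = len(build_slab(zwit_structure, zwit_form, 2).molecules)
        assert n2 == 2 * n1

    def test_slab_molecules_unrelaxed(self, zwit_structure, zwit_slab):
        """Slab molecules keep the bulk (rigid) internal geometry."""
        ref = pdist(zwit_structure.molecules()[0].cart(zwit_structure.cell))
        for mol in zwit_slab.molecules[::7]:
            np.testing.assert_allclose(pdist(mol.coords), ref, atol=1e-8)

    def test_invalid_thickness(self, zwit_structure, zwit_form):
        with pytest.raises(SurfaceError):
            build_slab(zwit_structure, zwit_form, thickness=0)


def _point_slab(offsets, normal=(0.0, 0.0, 1.0)):
    """Slab of single-atom molecules at given normal offsets."""
    mols = []
    for k, h in enumerate(offsets):
        m = Molecule(atom_indices=[0], labels=[f"P{k}"], elements=["C"],
                     atom_types=["X"], frac=np.zeros((1, 3)), bonds=[])
        mols.append(probe_instance(m, coords=np.array([[0.0, 0.0, h]])))
    return Slab(FaceForm((0, 0, 1), 5.0, 2), mols,
                np.asarray(normal, float), 1,
                np.array([[5.0, 0, 0], [0, 5.0, 0]]))


class TestRugosity:
    def test_coplanar_atoms_zero(self):
        assert plane_rugosity(_point_slab([2.0, 2.0, 2.0])) == 0.0

    def test_two_atoms_at_plus_minus_h(self):
        h = 0.73
        assert plane_rugosity(_point_slab([-h, h])) == pytest.approx(h)

    def test_invariant_under_lateral_repeats(self, zwit_structure,
                                             zwit_form, zwit_slab):
        r1 = plane_rugosity(build_slab(zwit_structure, zwit_form, 1, (1, 1)))
        assert plane_rugosity(zwit_slab) == pytest.approx(r1, rel=1e-12)

    def test_requires_single_d_spacing(self, zwit_structure, zwit_form):
        slab2 = build_slab(zwit_structure, zwit_form, 2)
        with pytest.raises(SurfaceError):
            plane_rugosity(slab2)


class TestSystematicSearch:
    def test_far_probe_zero_energy(self, zwit_slab, water_probe,
                                   zwit_params, merged_charges):
        res = systematic_search(zwit_slab, water_probe, zwit_params,
                                merged_charges, t_step=4.0, rot_step=360.0,
                                heights=(30.0, 31.0), cutoff=12.0)
        assert all(p.energy.total == 0.0 for p in res.poses)
        assert res.minimum.energy.total == 0.0

    def test_coarse_grid_matches_brute_force(self, zwit_slab, water_probe,
                                             zwit_params, merged_charges):
        """Grid search equals exhaustive pose-by-pose enumeration built
        from molecule_pair_energy."""
        res = systematic_search(zwit_slab, water_probe, zwit_params,
                                merged_charges, **COARSE)
        u1, u2 = zwit_slab.lateral_vectors
        n_hat = zwit_slab.normal
        checked = 0
        for p in res.poses[::11]:
            R = Rotation.from_euler("ZXZ", p.euler, degrees=True).as_matrix()
            coords = (water_probe.coords - water_probe.cog) @ R.T + p.position
            probe = probe_instance(water_probe.template, coords=coords)
            total = 0.0
            for m in zwit_slab.molecules:
                if np.linalg.norm(m.cog - p.position) > COARSE["cutoff"]:
                    continue
                total += molecule_pair_energy(probe, m, zwit_params,
                                              merged_charges).total
            assert p.energy.total == pytest.approx(total, abs=1e-9)
            checked += 1
        assert checked >= 10

    def test_minimum_bounds_all_poses(self, zwit_slab, water_probe,
                                      zwit_params, merged_charges):
        res = systematic_search(zwit_slab, water_probe, zwit_params,
                                merged_charges, **COARSE)
        emin = res.minimum.energy.total
        assert all(emin <= p.energy.total for p in res.accepted)

    def test_lattice_translation_invariance(self, zwit_structure, zwit_form,
                                            water_probe, zwit_params,
                                            merged_charges):
        """Shifting the grid origin by a lateral lattice vector leaves the
        minimum unchanged (periodicity).  The slab is wide enough that
        both grids stay more than a cutoff away from its edges."""
        slab = build_slab(zwit_structure, zwit_form, 1, (7, 5))
        kw = dict(t_step=2.5, rot_step=180.0, heights=(2.0, 4.0),
                  cutoff=6.0)
        res0 = systematic_search(slab, water_probe, zwit_params,
                                 merged_charges, **kw)
        res1 = systematic_search(slab, water_probe, zwit_params,
                                 merged_charges,
                                 grid_origin=slab.lateral_vectors[0], **kw)
        assert res1.minimum.energy.total == pytest.approx(
            res0.minimum.energy.total, abs=1e-6)

    def test_grid_refinement_never_raises_minimum(self, zwit_slab,
                                                  water_probe, zwit_params,
                                                  merged_charges):
        kw = dict(rot_step=180.0, heights=(2.0, 4.0), cutoff=12.0)
        coarse = systematic_search(zwit_slab, water_probe, zwit_params,
                                   merged_charges, t_step=3.0, **kw)
        fine = systematic_search(zwit_slab, water_probe, zwit_params,
                                 merged_charges, t_step=1.5, **kw)
        assert fine.minimum.energy.total <= \
            coarse.minimum.energy.total + 1e-9

    def test_clash_poses_rejected_not_minima(self, zwit_slab, water_probe,
                                             zwit_params, merged_charges):
        res = systematic_search(zwit_slab, water_probe, zwit_params,
                                merged_charges, t_step=2.5, rot_step=180.0,
                                heights=(0.0, 3.0), cutoff=12.0)
        rejected = [p for p in res.poses if not p.accepted]
        assert rejected  # probe at the surface plane must clash somewhere
        assert res.minimum.accepted


@pytest.fixture(scope="module")
def search(zwit_slab, water_probe, zwit_params, merged_charges):
    return systematic_search(zwit_slab, water_probe, zwit_params,
                             merged_charges, t_step=1.5, rot_step=120.0,
                             heights=(2.0, 4.0), cutoff=12.0)


class TestDistribution:
    def test_percentages_sum_to_100(self, search):
        dist = interaction_distribution(search, n=50)
        sums = dist["component_percentages"].sum(axis=1)
        np.testing.assert_allclose(sums, 100.0, atol=0.1)

    def test_sorted_sublist_of_accepted(self, search):
        dist = interaction_distribution(search, n=50)
        e = dist["energies"]
        assert (np.diff(e) >= 0).all()
        totals = {round(p.energy.total, 12) for p in search.accepted}
        assert all(round(x, 12) in totals for x in e)

    def test_incomplete_flag_when_few_minima(self, search):
        dist = interaction_distribution(search, n=10**6)
        assert not dist["complete"]

    def test_zero_charge_probe_has_no_coulomb(self, zwit_slab, zwit_params,
                                              zwit_charges):
        neutral = Molecule(atom_indices=[0], labels=["Q0"], elements=["C"],
                           atom_types=["C"], frac=np.zeros((1, 3)), bonds=[])
        probe = probe_instance(neutral, coords=np.zeros((1, 3)))
        merged = dict(zwit_charges.charges)
        merged["Q0"] = 0.0
        res = systematic_search(zwit_slab, probe, zwit_params,
                                ChargeSet(merged), t_step=3.0,
                                rot_step=360.0, heights=(2.0, 4.0),
                                cutoff=12.0)
        dist = interaction_distribution(res, n=20)
        assert np.allclose(dist["component_percentages"][:, 2], 0.0)


def test_text_exports(zwit_slab, water_probe, zwit_params, merged_charges):
    res = systematic_search(zwit_slab, water_probe, zwit_params,
                            merged_charges, t_step=4.0, rot_step=360.0,
                            heights=(2.0, 3.0), cutoff=12.0)
    table = pose_table(res).splitlines()
    assert table[0].startswith("x\ty\tz")
    assert len(table) == len(res.poses) + 1
    raster = binding_map(res).splitlines()
    assert raster[0].startswith("f1")
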