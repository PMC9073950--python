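"""BFDH forms, slice/attachment partition, alpha factors, modified
attachment energies and Wulff construction."""

import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull

from synthonic.cell import UnitCell
from synthonic.constants import R_KCAL
from synthonic.fixtures import cubic_crystal
from synthonic.lattice import lattice_sum
from synthonic.morphology import (FaceForm, FaceRecord, WulffError,
                                  _form_orbit, _metric_laue_rotations,
                                  anisotropy_factor, bfdh_form_list,
                                  face_table, is_absent, jackson_alpha,
                                  modified_attachment_energy,
                                  slice_attachment_from_result,
                                  wulff_construct)
from synthonic.potential import ChargeSet, PotentialParams

from test_lattice import two_atom_structure


class TestBfdh:
    def test_p1_cubic_top_form(self):
        s = cubic_crystal(10.0)
        forms = bfdh_form_list(s, 3)
        assert forms[0].d_spacing == pytest.approx(10.0)
        assert sorted(abs(x) for x in forms[0].hkl) == [0, 0, 1]

    def test_screw_axis_extinctions(self, zwit_structure):
        """2_1 screw axes: (0 0 1) absent, (0 0 2) takes its place."""
        assert is_absent((0, 0, 1), zwit_structure.ops)
        assert is_absent((1, 0, 0), zwit_structure.ops)
        assert is_absent((0, 1, 0), zwit_structure.ops)
        assert not is_absent((0, 0, 2), zwit_structure.ops)
        assert not is_absent((0, 1, 1), zwit_structure.ops)
        hkls = [f.hkl for f in bfdh_form_list(zwit_structure, 20)]
        assert (0, 0, 2) in hkls
        assert (0, 0, 1) not in hkls

    def test_sorted_by_descending_d(self, zwit_structure):
        forms = bfdh_form_list(zwit_structure, 8)
        ds = [f.d_spacing for f in forms]
        assert ds == sorted(ds, reverse=True)

    def test_orbit_multiplicities(self, zwit_structure):
        by_hkl = {f.hkl: f.multiplicity
                  for f in bfdh_form_list(zwit_structure, 20)}
        assert by_hkl[(0, 0, 2)] == 2
        assert by_hkl[(1, 1, 1)] == 8
        assert by_hkl[(0, 1, 1)] == 4


class TestSliceAttachment:
    def test_conservation_on_every_form(self, zwit_structure, zwit_result):
        """E_slice + E_att = E_latt on each BFDH form."""
        E = zwit_result.E_latt
        for form in bfdh_form_list(zwit_structure, 8):
            es, ea = slice_attachment_from_result(zwit_result, form)
            assert es + ea == pytest.approx(E, abs=1e-6)

    def test_infinite_slab_has_zero_attachment(self, zwit_result):
        form = FaceForm((0, 0, 1), d_spacing=1e6, multiplicity=2)
        es, ea = slice_attachment_from_result(zwit_result, form)
        assert ea == 0.0
        assert es == pytest.approx(zwit_result.E_latt)

    def test_one_dimensional_chain_zero_slice(self):
        """Interactions only along the chain axis all cross a plane
        normal to it, so E_slice = 0."""
        s = two_atom_structure((30.0, 30.0, 4.0), (0.4, 0.4, 0.3),
                               (0.01, 0.0, 0.1))
        p = PotentialParams(types={"t": (20.0, 500.0)})
        cs = ChargeSet({"D1": 0.0, "D2": 0.0})
        res = lattice_sum(s, p, cs, r_max=18.0)
        form = FaceForm((0, 0, 1), s.cell.d_spacing((0, 0, 1)), 2)
        es, ea = slice_attachment_from_result(res, form)
        assert es == 0.0
        assert ea == pytest.approx(res.E_latt)

    def test_epsilon_decreases_as_slab_thins(self, zwit_result):
        """Thinning the slab moves bonds from slice to attachment, so the
        anisotropy factor can only decrease."""
        E = zwit_result.E_latt
        eps = []
        for d in (12.0, 8.0, 5.0, 3.0, 1.5):
            es, _ = slice_attachment_from_result(
                zwit_result, FaceForm((0, 1, 1), d, 4))
            eps.append(anisotropy_factor(es, E))
        assert all(a >= b - 1e-12 for a, b in zip(eps, eps[1:]))
        assert eps[0] > eps[-1]


class TestFactors:
    def test_epsilon_limits(self):
        assert anisotropy_factor(-40.0, -40.0) == 1.0
        assert anisotropy_factor(0.0, -40.0) == 0.0
        with pytest.raises(ValueError):
            anisotropy_factor(1.0, 0.0)

    def test_alpha_vanishes_for_pure_melt(self):
        assert jackson_alpha(0.7, 0.0, 298.15, 1.0) == 0.0

    def test_alpha_hand_evaluation(self):
        got = jackson_alpha(0.5, 5.0, 298.15, 0.01)
        expect = 0.5 * (5.0 / (R_KCAL * 298.15) - math.log(0.01))
        assert got == pytest.approx(expect, rel=1e-12)
        assert got == pytest.approx(0.5 * (5.0 / 0.5925 + 4.6052), abs=2e-3)

    def test_alpha_linear_in_epsilon(self):
        a1 = jackson_alpha(0.25, 3.0, 300.0, 0.05)
        a2 = jackson_alpha(0.50, 3.0, 300.0, 0.05)
        assert a2 == pytest.approx(2 * a1)

    def test_alpha_invalid_inputs(self):
        with pytest.raises(ValueError):
            jackson_alpha(0.5, 5.0, 298.15, 0.0)
        with pytest.raises(ValueError):
            jackson_alpha(0.5, 5.0, -1.0, 0.5)


def _face(E_att=-10.0, U_solute=-8.0, U_solvent=-4.0, R_g=1.0, alpha=2.0):
    form = FaceForm((0, 1, 1), 5.0, 4)
    return FaceRecord(form, E_slice=-30.0, E_att=E_att, epsilon=0.75,
                      R_g=R_g, U_solute=U_solute, U_solvent=U_solvent,
                      alpha=alpha)


class TestModifiedAttachment:
    def test_no_solvent_reduces_to_attachment(self):
        f = _face(U_solvent=0.0)
        assert modified_attachment_energy(f, 1) == pytest.approx(f.E_att)

    def test_model2_reduces_to_model1_at_min_rugosity(self):
        f = _face(R_g=1.3)
        m1 = modified_attachment_energy(f, 1)
        m2 = modified_attachment_energy(f, 2, R_g_min=1.3)
        assert m2 == pytest.approx(m1)

    def test_stronger_solvent_binding_never_strengthens_growth(self):
        """As U_solvent becomes more negative the modified attachment
        energy moves monotonically toward zero and beyond (growth
        blocked): the effective growth rate max(0, -U_eps) never
        increases."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            f = _face(E_att=-rng.uniform(2, 15),
                      U_solute=-rng.uniform(6, 12), R_g=rng.uniform(1, 3),
                      alpha=rng.uniform(1, 8))
            for model, kw in ((1, {}), (2, {"R_g_min": 1.0}),
                              (3, {"R_g_min": 1.0})):
                prev = None
                for us in np.linspace(0.0, -5.0, 8):
                    f.U_solvent = us
                    u = modified_attachment_energy(f, model, **kw)
                    if prev is not None:
                        assert u >= prev - 1e-12
                        assert max(0.0, -u) <= max(0.0, -prev) + 1e-12
                    prev = u

    def test_model3_divides_solute_by_alpha(self):
        f = _face()
        u2 = modified_attachment_energy(f, 2, R_g_min=1.0)
        f_alpha1 = _face(alpha=1.0)
        u3 = modified_attachment_energy(f_alpha1, 3, R_g_min=1.0)
        assert u3 == pytest.approx(u2)

    def test_errors(self):
        with pytest.raises(ValueError, match="U_solute"):
            modified_attachment_energy(_face(U_solute=1.0), 1)
        with pytest.raises(ValueError, match="R_g_min"):
            modified_attachment_energy(_face(), 2)
        with pytest.raises(ValueError, match="alpha"):
            modified_attachment_energy(_face(alpha=0.0), 3, R_g_min=1.0)
        with pytest.raises(ValueError, match="model"):
            modified_attachment_energy(_face(), 4)

    def test_custom_expression_override(self):
        f = _face()
        got = modified_attachment_energy(
            f, 1, expression=lambda face, rgmin: 42.0)
        assert got == 42.0


class TestWulff:
    CUBE = UnitCell(10, 10, 10)

    def test_cube_from_100_family(self):
        shape = wulff_construct([((1, 0, 0), 1.0)], self.CUBE)
        assert len(shape.faces) == 6
        assert shape.aspect_ratio == pytest.approx((1.0, 1.0, 1.0))
        areas = list(shape.relative_areas.values())
        assert areas[0] == pytest.approx(100.0)

    def test_octahedron_truncation_threshold(self):
        """{111} at rate sqrt(3) x {100} exactly touches the cube
        corners: zero area at the threshold, positive just below."""
        at = wulff_construct([((1, 0, 0), 1.0), ((1, 1, 1), math.sqrt(3))],
                             self.CUBE)
        assert at.relative_areas[(1, 1, 1)] == pytest.approx(0.0, abs=1e-8)
        below = wulff_construct(
            [((1, 0, 0), 1.0), ((1, 1, 1), 0.98 * math.sqrt(3))], self.CUBE)
        assert below.relative_areas[(1, 1, 1)] > 0.0

    @pytest.mark.parametrize("trial", range(5))
    def test_dual_hull_oracle(self, trial):
        """Half-space intersection equals the polar-dual hull."""
        rng = np.random.default_rng(trial)
        rates = [((1, 0, 0), rng.uniform(0.8, 1.5)),
                 ((1, 1, 1), rng.uniform(0.8, 1.5)),
                 ((0, 1, 1), rng.uniform(0.8, 1.5))]
        shape = wulff_construct(rates, self.CUBE)
        rots = _metric_laue_rotations(self.CUBE)
        mx = max(r for _, r in rates)
        pts = []
        for hkl, r in rates:
            for v in _form_orbit(hkl, rots):
                g = self.CUBE.reciprocal_vector(v)
                pts.append(g / np.linalg.norm(g) / (r / mx))
        hull = ConvexHull(np.array(pts))
        dual_vertices = np.array([eq[:3] / -eq[3] for eq in hull.equations])
        assert ConvexHull(dual_vertices).volume == pytest.approx(
            shape.volume, rel=1e-9)

    def test_scale_invariance(self):
        rates = [((1, 0, 0), 1.0), ((1, 1, 1), 1.3), ((0, 1, 1), 0.9)]
        s1 = wulff_construct(rates, self.CUBE)
        s2 = wulff_construct([(h, 7.3 * r) for h, r in rates], self.CUBE)
        for hkl in s1.relative_areas:
            assert s1.relative_areas[hkl] == pytest.approx(
                s2.relative_areas[hkl], abs=1e-9)
        assert s1.aspect_ratio == pytest.approx(s2.aspect_ratio)

    def test_unbounded_shape_rejected(self):
        with pytest.raises(WulffError):
            wulff_construct([((1, 0, 0), 1.0)], UnitCell(10, 11, 12))

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(WulffError):
            wulff_construct([((1, 0, 0), 0.0)], self.CUBE)

    def test_off_export(self):
        shape = wulff_construct([((1, 0, 0), 1.0)], self.CUBE)
        off = shape.to_off().splitlines()
        assert off[0] == "OFF"
        nv, nf, _ = map(int, off[1].split())
        assert nv == 8 and nf == 6


def test_face_table_layout():
    rec = _face()
    rec.U_eps = {1: -5.0, 2: -4.0}
    text = face_table([rec])
    lines = text.strip().splitlines()
    assert lines[0].startswith("hkl")
    assert "(0 1 1)" in lines[1]
    assert lines[1].endswith("-")  # model 3 not computed
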