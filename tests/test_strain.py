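"""Deformation gradients, Green-Lagrange tensors, AHA mapping and projection."""

import numpy as np
import pytest

from alignedstrain import aha
from alignedstrain.phantom import (
    PhantomSpec,
    analytic_displacement,
    render_phantom,
    truth_keyframes,
    truth_segmental_strain,
)
from alignedstrain.registration import DisplacementFieldSet, compose_fields
from alignedstrain.strain import (
    build_aha_map,
    deformation_gradient,
    green_lagrange,
    project_strain,
    segmental_strain,
    strain_for_field,
)

from conftest import small_spec


class TestDeformationGradient:
    SPACING = (8.0, 1.5, 1.5)

    def test_zero_field_gives_identity(self):
        F = deformation_gradient(np.zeros((2, 8, 8, 2)), self.SPACING)
        assert np.allclose(F, np.eye(2))

    def test_affine_field_exact_at_interior(self):
        # u(x) = (s - 1)(x - c): the derivative of a linear field is exact
        s = 0.9
        n = 16
        c = (n - 1) / 2
        yy, xx = np.meshgrid(np.arange(n, dtype=float), np.arange(n, dtype=float), indexing="ij")
        f = np.zeros((1, n, n, 2))
        f[0, ..., 0] = (s - 1) * (yy - c)
        f[0, ..., 1] = (s - 1) * (xx - c)
        F = deformation_gradient(f, self.SPACING)
        assert np.allclose(F, s * np.eye(2), atol=1e-12)

    def test_second_order_convergence_on_smooth_field(self):
        # halving the grid spacing shrinks the derivative error ~4x
        def u_fn(y, x):
            return np.stack([np.sin(0.25 * x) * np.cos(0.2 * y), np.cos(0.3 * y + 0.1 * x)], -1)

        def jac_fn(y, x):
            J = np.zeros(y.shape + (2, 2))
            J[..., 0, 0] = -0.2 * np.sin(0.25 * x) * np.sin(0.2 * y)
            J[..., 0, 1] = 0.25 * np.cos(0.25 * x) * np.cos(0.2 * y)
            J[..., 1, 0] = -0.3 * np.sin(0.3 * y + 0.1 * x)
            J[..., 1, 1] = -0.1 * np.sin(0.3 * y + 0.1 * x)
            return J

        errs = []
        for h in (1.0, 0.5):
            n = int(16 / h) + 1
            y = np.arange(n) * h
            yy, xx = np.meshgrid(y, y, indexing="ij")
            field_mm = u_fn(yy, xx)
            field_vox = field_mm / h
            F = deformation_gradient(field_vox[None], (8.0, h, h))[0]
            true = jac_fn(yy, xx) + 0.0
            interior = (slice(2, -2), slice(2, -2))
            errs.append(np.abs((F - np.eye(2)) - true)[interior].max())
        assert errs[1] < errs[0] / 3

    def test_single_voxel_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            deformation_gradient(np.zeros((2, 1, 8, 2)), self.SPACING)


class TestGreenLagrange:
    def test_identity_gives_zero(self):
        F = np.broadcast_to(np.eye(2), (4, 4, 2, 2)).copy()
        assert np.allclose(green_lagrange(F), 0)

    def test_rotation_gives_zero(self):
        for theta in (0.3, 1.2, -2.0):
            R = np.array(
                [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
            )
            E = green_lagrange(R[None, None])
            assert np.allclose(E, 0, atol=1e-12)

    def test_isotropic_scaling_closed_form(self):
        E = green_lagrange(0.9 * np.eye(2)[None])
        assert np.allclose(E, (0.81 - 1) / 2 * np.eye(2))

    def test_symmetry_for_random_gradients(self):
        rng = np.random.default_rng(0)
        F = np.eye(2) + 0.1 * rng.normal(size=(5, 5, 2, 2))
        E = green_lagrange(F)
        assert np.allclose(E, np.swapaxes(E, -1, -2))


class TestAhaPartition:
    def test_ten_slices_split_4_3_3(self):
        rings = aha.partition_slices(10)
        assert rings.count("basal") == 4
        assert rings.count("mid") == 3
        assert rings.count("apical") == 3
        assert rings == sorted(rings, key=("basal", "mid", "apical").index)

    @pytest.mark.parametrize("n", range(3, 15))
    def test_counts_sum_and_order(self, n):
        rings = aha.partition_slices(n)
        assert len(rings) == n
        assert rings.count("basal") >= rings.count("apical")

    def test_sector_bounds_round_trip(self):
        alpha0 = 0.4
        for seg in aha.ALL_SEGMENTS:
            lo, hi = aha.sector_bounds(seg, alpha0)
            mid = (lo + hi) / 2
            ring = aha.ring_of_segment(seg)
            assert aha.segment_for_angle(np.array(mid), ring, alpha0) == seg


class TestBuildAhaMap:
    def test_probe_voxel_matches_analytic_sector(self, quiet_spec, quiet_phantom):
        amap = build_aha_map(quiet_phantom.masks.labels, quiet_phantom.keyframes.ed)
        labels = quiet_phantom.masks.labels[quiet_phantom.keyframes.ed]
        alpha0 = quiet_spec.alpha0
        z = 0  # basal slice
        cy, cx = amap.centres["basal"]
        ys, xs = np.nonzero(labels[z] == 2)
        alpha = np.arctan2(ys - cy, xs - cx)
        expected = aha.segment_for_angle(alpha, "basal", alpha0)
        got = amap.segment_ids[z, ys, xs]
        assert np.mean(expected == got) > 0.97  # borders may differ by discretization

    def test_all_16_segments_present(self, quiet_phantom):
        amap = build_aha_map(quiet_phantom.masks.labels, 0)
        assert set(np.unique(amap.segment_ids)) == {0, *aha.ALL_SEGMENTS}

    def test_missing_rv_rejected(self, quiet_phantom):
        labels = quiet_phantom.masks.labels[0].copy()
        labels[labels == 1] = 0
        with pytest.raises(ValueError, match="orient"):
            build_aha_map(labels)

    def test_rotating_anatomy_rotates_origin(self):
        a = render_phantom(small_spec(rv_offset_angle=180.0))
        b = render_phantom(small_spec(rv_offset_angle=240.0))
        ma = build_aha_map(a.masks.labels, 0)
        mb = build_aha_map(b.masks.labels, 0)
        diff = np.angle(np.exp(1j * (mb.alpha0 - ma.alpha0)))
        assert diff == pytest.approx(np.deg2rad(60.0), abs=0.05)


class TestProjection:
    def test_isotropic_tensor_projects_equally(self, quiet_phantom):
        amap = build_aha_map(quiet_phantom.masks.labels, 0)
        alpha = 0.07
        E = np.broadcast_to(alpha * np.eye(2), amap.segment_ids.shape + (2, 2))
        err, ecc = project_strain(E, amap)
        myo = amap.segment_ids > 0
        assert np.allclose(err[myo], alpha)
        assert np.allclose(ecc[myo], alpha)

    def test_zero_tensor_projects_to_zero(self, quiet_phantom):
        amap = build_aha_map(quiet_phantom.masks.labels, 0)
        E = np.zeros(amap.segment_ids.shape + (2, 2))
        err, ecc = project_strain(E, amap)
        myo = amap.segment_ids > 0
        assert np.allclose(err[myo], 0)
        assert np.allclose(ecc[myo], 0)


class TestSegmentalStrain:
    def test_zero_fields_give_zero_strain(self, quiet_phantom):
        shape = quiet_phantom.masks.labels.shape[1:]
        zero = np.zeros(shape + (2,))
        fields = DisplacementFieldSet(
            composed={k: zero.copy() for k in ("MS", "ES", "PF", "MD", "ED")},
            sequential={
                p: zero.copy()
                for p in (("ED", "MS"), ("MS", "ES"), ("ES", "PF"), ("PF", "MD"), ("MD", "ED"))
            },
        )
        table = segmental_strain(
            fields, quiet_phantom.masks, quiet_phantom.keyframes, (8.0, 2.0, 2.0)
        )
        assert np.allclose(table[["Err", "Ecc"]], 0.0)

    def test_closed_form_recovery_on_analytic_fields(self, quiet_spec, quiet_phantom):
        fields = DisplacementFieldSet.from_analytic(quiet_spec, quiet_phantom.keyframes)
        table = segmental_strain(
            fields, quiet_phantom.masks, quiet_phantom.keyframes, quiet_spec.spacing
        )
        merged = table.merge(
            quiet_phantom.truth_strain,
            on=["scheme", "phase", "aha_segment"],
            suffixes=("", "_true"),
        )
        assert np.abs(merged.Ecc - merged.Ecc_true).mean() < 0.01
        assert np.abs(merged.Err - merged.Err_true).mean() < 0.01

    def test_homogeneous_phantom_has_equal_segments(self, quiet_spec, quiet_phantom):
        fields = DisplacementFieldSet.from_analytic(quiet_spec, quiet_phantom.keyframes)
        table = segmental_strain(
            fields, quiet_phantom.masks, quiet_phantom.keyframes, quiet_spec.spacing
        )
        per_phase = table.groupby(["scheme", "phase"])["Ecc"].agg(np.ptp)
        assert per_phase.max() < 0.01

    def test_hypokinetic_segment_has_attenuated_ecc(self):
        spec = small_spec(hypokinetic_segments={5: 0.5})
        ph = render_phantom(spec)
        fields = DisplacementFieldSet.from_analytic(spec, ph.keyframes)
        table = segmental_strain(fields, ph.masks, ph.keyframes, spec.spacing)
        es = table[(table.scheme == "ED2K") & (table.phase == "ED-ES")].set_index("aha_segment")
        assert abs(es.loc[5, "Ecc"]) < abs(es.loc[2, "Ecc"])

    def test_rotation_only_motion_gives_zero_strain(self):
        torsion = np.zeros(20)
        torsion[10] = 12.0
        spec = small_spec(contraction_profile=np.ones(20), torsion_profile=torsion)
        f = analytic_displacement(spec, 0, 10)
        ph = render_phantom(small_spec())
        amap = build_aha_map(ph.masks.labels, 0)
        per_seg = strain_for_field(f, amap, spec.spacing)
        vals = np.array(list(per_seg.values()))
        assert np.abs(vals).max() < 1e-6

    def test_torsion_does_not_change_measured_strain(self, quiet_spec):
        twisted = small_spec(torsion_profile=np.linspace(0, 10, 20))
        ph_a = render_phantom(quiet_spec)
        ph_b = render_phantom(twisted)
        fields_a = DisplacementFieldSet.from_analytic(quiet_spec, ph_a.keyframes)
        fields_b = DisplacementFieldSet.from_analytic(twisted, ph_b.keyframes)
        ta = segmental_strain(fields_a, ph_a.masks, ph_a.keyframes, quiet_spec.spacing)
        tb = segmental_strain(fields_b, ph_b.masks, ph_b.keyframes, twisted.spacing)
        assert np.abs(ta.Ecc.to_numpy() - tb.Ecc.to_numpy()).max() < 1e-3

    def test_composed_equals_sequential_composition(self, quiet_spec, quiet_phantom):
        kf = quiet_phantom.keyframes
        ed_ms = analytic_displacement(quiet_spec, kf.ed, kf.ms)
        ms_es = analytic_displacement(quiet_spec, kf.ms, kf.es)
        ed_es = analytic_displacement(quiet_spec, kf.ed, kf.es)
        amap = build_aha_map(quiet_phantom.masks.labels, kf.ed)
        direct = strain_for_field(ed_es, amap, quiet_spec.spacing)
        chained = strain_for_field(
            compose_fields(ed_ms, ms_es), amap, quiet_spec.spacing
        )
        for seg in aha.ALL_SEGMENTS:
            assert direct[seg][1] == pytest.approx(chained[seg][1], abs=0.01)

    def test_thickening_phantom_sign_pattern(self):
        spec = small_spec(motion_mode="thickening")
        ph = render_phantom(spec)
        fields = DisplacementFieldSet.from_analytic(spec, ph.keyframes)
        table = segmental_strain(fields, ph.masks, ph.keyframes, spec.spacing)
        es = table[(table.scheme == "ED2K") & (table.phase == "ED-ES")]
        assert np.all(es.Ecc < 0)
        assert np.all(es.Err > 0)
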