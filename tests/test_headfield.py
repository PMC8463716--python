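"""Tests for the 3D Biot-Savart loop engine, mesh dosimetry, and the
hypomagnetic-zone search."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

import phonesmf as p
from phonesmf.fieldmap import HotSpot
from phonesmf.headfield import WireSingularityError


@pytest.fixture(scope="module")
def upper_loop(model1_upper_fit):
    """Model-1 upper source as a free-standing 3D loop below the z=0 plane."""
    f = model1_upper_fit
    return p.Loop3D(
        center_mm=(0.0, 0.0, -f.T_mm / 2.0),
        axis=(0.0, 0.0, 1.0),
        radius_mm=f.r_mm,
        current_mA=f.I_mA,
    )


class TestLoopField:
    @pytest.mark.parametrize("n_segments, rtol", [(360, 1e-3), (3600, 1e-5)])
    def test_on_axis_matches_closed_form(self, upper_loop, model1_upper_fit, n_segments, rtol):
        for z in (0.0, 15.0, 55.0):
            numeric = p.loop_field_at_point(upper_loop, (0.0, 0.0, z), n_segments=n_segments)
            assert numeric[2] == pytest.approx(p.slc_field(z, model1_upper_fit), rel=rtol)
            assert np.allclose(numeric[:2], 0.0, atol=1e-9)

    def test_mirror_symmetry_across_loop_plane(self, upper_loop):
        up = p.loop_field_at_point(upper_loop, (9.0, 4.0, -4.2 + 7.0))
        down = p.loop_field_at_point(upper_loop, (9.0, 4.0, -4.2 - 7.0))
        assert up[2] == pytest.approx(down[2], rel=1e-9)
        assert up[0] == pytest.approx(-down[0], rel=1e-9)
        assert up[1] == pytest.approx(-down[1], rel=1e-9)

    def test_field_linear_in_current(self, upper_loop):
        doubled = p.Loop3D(
            center_mm=upper_loop.center_mm,
            axis=upper_loop.axis,
            radius_mm=upper_loop.radius_mm,
            current_mA=2.0 * upper_loop.current_mA,
        )
        pt = (12.0, -5.0, 20.0)
        assert np.allclose(
            p.loop_field_at_point(doubled, pt), 2.0 * p.loop_field_at_point(upper_loop, pt)
        )

    def test_far_field_matches_point_dipole(self, upper_loop):
        # |B| on axis at 100 radii: dipole with moment mu_r * I * pi * r^2
        d = 100.0 * upper_loop.radius_mm
        pt = upper_loop.center_mm + d * upper_loop.axis
        numeric = p.loop_field_at_point(upper_loop, pt, n_segments=720)
        m_eff = upper_loop.mu_r * upper_loop.current_mA * np.pi * upper_loop.radius_mm**2
        dipole_uT = 0.2 * m_eff / d**3  # 2 * (mu0/4pi) m / d^3 in these units
        assert np.linalg.norm(numeric) == pytest.approx(dipole_uT, rel=1e-3)

    def test_point_on_wire_rejected(self, upper_loop):
        on_wire = upper_loop.center_mm + np.array([upper_loop.radius_mm, 0.0, 0.0])
        with pytest.raises(WireSingularityError):
            p.loop_field_at_point(upper_loop, on_wire)

    def test_too_few_segments_rejected(self, upper_loop):
        with pytest.raises(ValueError):
            p.loop_field_at_point(upper_loop, (0, 0, 10.0), n_segments=4)


class TestPlaceLoops:
    def spots_and_fits(self, model1):
        spots = [HotSpot(h.label, h.x_mm, h.y_mm) for h in model1.hotspots]
        fits = [h.slc for h in model1.hotspots]
        return spots, fits

    def test_identity_pose_buries_loops_at_half_thickness(self, model1):
        spots, fits = self.spots_and_fits(model1)
        loops = p.place_loops_from_fits(np.eye(4), model1.geometry, spots, fits)
        assert np.allclose(loops[0].center_mm, (0.0, 70.0, -4.2))
        assert np.allclose(loops[1].center_mm, (0.0, -60.0, -4.2))
        assert all(np.allclose(lp.axis, (0, 0, 1)) for lp in loops)

    def test_translation_moves_centers_only(self, model1):
        spots, fits = self.spots_and_fits(model1)
        pose = np.eye(4)
        pose[:3, 3] = (5.0, -2.0, 30.0)
        loops = p.place_loops_from_fits(pose, model1.geometry, spots, fits)
        assert np.allclose(loops[0].center_mm, (5.0, 68.0, 25.8))
        assert np.allclose(loops[0].axis, (0.0, 0.0, 1.0))

    def test_rotation_carries_axes(self, model1):
        spots, fits = self.spots_and_fits(model1)
        pose = np.eye(4)
        pose[:3, :3] = Rotation.from_euler("y", 90, degrees=True).as_matrix()
        loops = p.place_loops_from_fits(pose, model1.geometry, spots, fits)
        assert np.allclose(loops[0].axis, (1.0, 0.0, 0.0), atol=1e-12)
        assert loops[0].radius_mm == fits[0].r_mm
        assert loops[0].current_mA == fits[0].I_mA

    def test_non_rigid_pose_rejected(self, model1):
        spots, fits = self.spots_and_fits(model1)
        pose = np.diag([2.0, 1.0, 1.0, 1.0])  # a stretch, not a rotation
        with pytest.raises(ValueError, match="rigid"):
            p.place_loops_from_fits(pose, model1.geometry, spots, fits)

    def test_fit_count_must_match(self, model1):
        spots, fits = self.spots_and_fits(model1)
        with pytest.raises(ValueError):
            p.place_loops_from_fits(np.eye(4), model1.geometry, spots, fits[:1])


class TestFieldOnMesh:
    def test_background_only(self):
        mesh = p.make_head_mesh(50.0, 60.0, 55.0, n_subdivisions=1)
        result = p.field_on_mesh([], mesh, background=p.UniformField((0.0, 0.0, 50.0)))
        assert np.allclose(result.vectors_uT, (0.0, 0.0, 50.0))
        assert np.allclose(result.magnitudes_uT, 50.0)

    def test_superposition_of_two_loops(self, upper_loop):
        other = p.Loop3D(
            center_mm=(0.0, -130.0, -4.2), axis=(0.0, 0.0, 1.0), radius_mm=10.0, current_mA=22.6
        )
        mesh = p.make_head_mesh(40.0, 40.0, 40.0, n_subdivisions=1)
        mesh.apply_translation([0.0, 0.0, 80.0])  # keep vertices off both wires
        both = p.field_on_mesh([upper_loop, other], mesh)
        a = p.field_on_mesh([upper_loop], mesh)
        b = p.field_on_mesh([other], mesh)
        assert np.allclose(both.vectors_uT, a.vectors_uT + b.vectors_uT)

    def test_frame_invariance_of_magnitudes(self, upper_loop):
        mesh = p.make_head_mesh(40.0, 45.0, 50.0, n_subdivisions=1)
        mesh.apply_translation([0.0, 0.0, 80.0])
        R = Rotation.from_euler("zyx", [31.0, -47.0, 12.0], degrees=True).as_matrix()
        rotated_mesh = mesh.copy()
        rotated_mesh.apply_transform(
            np.block([[R, np.zeros((3, 1))], [np.zeros((1, 3)), np.ones((1, 1))]])
        )
        rotated_loop = p.Loop3D(
            center_mm=R @ upper_loop.center_mm,
            axis=R @ upper_loop.axis,
            radius_mm=upper_loop.radius_mm,
            current_mA=upper_loop.current_mA,
        )
        bg = np.array([20.0, 0.0, -45.0])
        base = p.field_on_mesh([upper_loop], mesh, background=p.UniformField(bg))
        rot = p.field_on_mesh([rotated_loop], rotated_mesh, background=p.UniformField(R @ bg))
        assert np.allclose(base.magnitudes_uT, rot.magnitudes_uT, rtol=1e-9)

    def test_vertex_on_wire_names_vertex(self, upper_loop):
        mesh = p.make_head_mesh(40.0, 40.0, 40.0, n_subdivisions=0)
        mesh.vertices[0] = upper_loop.center_mm + [upper_loop.radius_mm, 0.0, 0.0]
        with pytest.raises(WireSingularityError) as err:
            p.field_on_mesh([upper_loop], mesh)
        assert 0 in err.value.indices


class TestUniformField:
    def test_atypical_magnitude_warns(self):
        with pytest.warns(UserWarning, match="geomagnetic"):
            p.UniformField((0.0, 0.0, 10.0))

    def test_magnitude_above_100_rejected(self):
        with pytest.raises(ValueError):
            p.UniformField((0.0, 0.0, 150.0))

    def test_typical_field_accepted_silently(self, recwarn):
        p.UniformField((20.0, 0.0, -45.0))
        assert len(recwarn) == 0


class TestHypomagneticZones:
    def test_antiparallel_background_cancels_on_axis(self, upper_loop, model1_upper_fit):
        # oracle: invert the closed form for B(z) = 50 µT -> z = 36.06 mm
        z_expected = brentq(lambda z: p.slc_field(z, model1_upper_fit) - 50.0, 10.0, 100.0)
        points = p.find_hypomagnetic_zones(
            [upper_loop],
            p.UniformField((0.0, 0.0, -50.0)),
            region_mm=((-6.0, -6.0, 25.0), (6.0, 6.0, 45.0)),
        )
        assert len(points) >= 1
        on_axis = min(points, key=lambda q: np.hypot(q[0], q[1]))
        assert np.hypot(on_axis[0], on_axis[1]) < 0.5
        assert on_axis[2] == pytest.approx(z_expected, abs=0.1)

    def test_parallel_background_has_no_axial_zero(self, upper_loop):
        points = p.find_hypomagnetic_zones(
            [upper_loop],
            p.UniformField((0.0, 0.0, 50.0)),
            region_mm=((-6.0, -6.0, 25.0), (6.0, 6.0, 45.0)),
        )
        # the axial component cannot cancel; any zero must lie off-axis
        assert all(np.hypot(q[0], q[1]) > 1.0 for q in points)

    def test_overwhelming_background_yields_nothing(self, upper_loop):
        points = p.find_hypomagnetic_zones(
            [upper_loop],
            p.UniformField((0.0, 0.0, -60.0)),
            region_mm=((-5.0, -5.0, 150.0), (5.0, 5.0, 170.0)),
        )
        assert points.shape == (0, 3)

    def test_invalid_inputs_rejected(self, upper_loop):
        with pytest.raises(ValueError):
            p.find_hypomagnetic_zones(
                [upper_loop], p.UniformField((0, 0, -50.0)),
                region_mm=((0, 0, 30), (0, 0, 20)),
            )
        with pytest.raises(ValueError):
            p.find_hypomagnetic_zones(
                [upper_loop], p.UniformField((0, 0, -50.0)),
                region_mm=((-5, -5, 25), (5, 5, 45)), epsilon_uT=0.0,
            )
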