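"""Sliding decomposition, cross-shear ratio, and the wear law."""

import numpy as np
import pytest

import kneewear as kw
from kneewear.errors import ConfigurationError
from kneewear.frames import rotation, translation
from kneewear.geometry import SurfaceMesh, sphere_surface
from kneewear.kinematics import (
    GaitProfile,
    PoseTrajectory,
    get_condition,
    generate_profiles,
)
from kneewear.wear import (
    FRICTION_COEFFICIENT,
    SlidingHistory,
    WearCoefficientMap,
    compute_sliding,
    cross_shear_field,
    cross_shear_ratio,
    default_wear_map,
    principal_orientation,
    wear_volume,
)


# ---------------------------------------------------------------------------
# fabrication helpers
# ---------------------------------------------------------------------------


def single_node_mesh() -> SurfaceMesh:
    v = np.array([[0.0, 0.0, 0.0]])
    return SurfaceMesh(
        vertices=v,
        faces=np.zeros((0, 3), dtype=np.int64),
        normals=np.array([[0.0, 1.0, 0.0]]),
        areas=np.array([2.5]),
        mask=np.array([True]),
    )


def make_history(increments, pressures=None, area=2.5) -> SlidingHistory:
    """Planar sliding history at one node (normal +y)."""
    inc = np.asarray(increments, dtype=float)[:, None, :]
    if pressures is None:
        pressures = np.ones(len(inc))
    return SlidingHistory(
        increments=inc,
        pressures=np.asarray(pressures, dtype=float)[:, None],
        normals=np.array([[0.0, 1.0, 0.0]]),
        areas=np.array([area]),
    )


def trajectory_from_transforms(transforms, profile) -> PoseTrajectory:
    from kneewear.geometry import CoRSpec

    return PoseTrajectory(
        profile=profile,
        cor=CoRSpec("distal", np.zeros(3)),
        ie_axis_z_mm=0.0,
        transforms=np.stack(transforms),
    )


def dummy_profile(n) -> GaitProfile:
    cond = get_condition("distal/intermediate")
    z = np.zeros(n)
    return GaitProfile(cond, np.arange(n) / n, z + 100.0, z, z, z)


def contact_states(mesh, pressures):
    out = []
    for p in pressures:
        p = np.asarray(p, dtype=float)
        out.append(
            kw.ContactState(
                pressure_MPa=p,
                penetration_mm=p / 100.0,
                contact_area_mm2=float(mesh.areas[p > 0].sum()),
                centroid_mm=np.array([0.0, 0.0]),
                total_force_N=float(p @ mesh.areas),
                in_articulating_region=True,
            )
        )
    return out


# ---------------------------------------------------------------------------
# sliding increments
# ---------------------------------------------------------------------------


class TestSliding:
    def test_static_pose_gives_zero_increments(self):
        mesh = single_node_mesh()
        n = 8
        poses = trajectory_from_transforms([np.eye(4)] * n, dummy_profile(n))
        contacts = contact_states(mesh, [np.array([1.0])] * n)
        h = compute_sliding(poses, contacts, mesh, sphere_surface(10.0))
        assert h.total_sliding()[0] == 0.0

    def test_ap_out_and_back_accumulates_path_length(self):
        """10 mm out and back at a continuously loaded node slides 20 mm."""
        mesh = single_node_mesh()
        x = np.array([0.0, 2.5, 5.0, 7.5, 10.0, 7.5, 5.0, 2.5])
        poses = trajectory_from_transforms(
            [translation([xi, 0, 0]) for xi in x], dummy_profile(len(x))
        )
        contacts = contact_states(mesh, [np.array([1.0])] * len(x))
        h = compute_sliding(poses, contacts, mesh, sphere_surface(10.0))
        assert h.total_sliding()[0] == pytest.approx(20.0, rel=1e-12)

    def test_flexion_only_cycle_matches_arc_length_oracle(self):
        """Rotation about the ML axis slides each node by r * dtheta."""
        n = 256
        theta = 40.0 * np.sin(np.pi * np.arange(n) / n) ** 2  # 0 -> 40 -> 0
        cor_point = np.array([0.0, 30.0, 0.0])
        poses = trajectory_from_transforms(
            [rotation([0, 0, 1], th, point=cor_point) for th in theta],
            dummy_profile(n),
        )
        mesh = single_node_mesh()  # node at origin, r = 30 below the axis
        contacts = contact_states(mesh, [np.array([1.0])] * n)
        h = compute_sliding(poses, contacts, mesh, sphere_surface(10.0))
        r = np.linalg.norm(cor_point)
        arc = r * np.deg2rad(np.abs(np.diff(np.append(theta, theta[0])))).sum()
        # chords understate arcs by O(dtheta^2); 256 samples ~ 0.1%
        assert h.total_sliding()[0] == pytest.approx(arc, rel=2e-3)
        # increments are tangent to the surface
        dots = np.einsum("snj,nj->sn", h.increments, h.normals)
        np.testing.assert_allclose(dots, 0.0, atol=1e-9)

    def test_unloaded_samples_contribute_no_sliding(self):
        mesh = single_node_mesh()
        x = [0.0, 5.0, 10.0, 5.0]
        poses = trajectory_from_transforms(
            [translation([xi, 0, 0]) for xi in x], dummy_profile(4)
        )
        pressures = [np.array([1.0]), np.array([0.0]), np.array([1.0]), np.array([1.0])]
        contacts = contact_states(mesh, pressures)
        h = compute_sliding(poses, contacts, mesh, sphere_surface(10.0))
        # loaded increments: 0->1 (5), 2->3 (5), 3->0 (5); unloaded 1->2 skipped
        assert h.total_sliding()[0] == pytest.approx(15.0)


# ---------------------------------------------------------------------------
# principal orientation and CSR
# ---------------------------------------------------------------------------


def grid_search_orientation(h: SlidingHistory, node=0, step_deg=0.1):
    """Brute-force maximiser of the parallel frictional work (oracle)."""
    ds = h.increments[:, node, :]
    mag = np.linalg.norm(ds, axis=1)
    w = FRICTION_COEFFICIENT * h.pressures[:, node] * mag
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    best, best_work = None, -1.0
    for a in angles:
        e = np.array([np.cos(a), 0.0, np.sin(a)])
        with np.errstate(invalid="ignore"):
            cos = np.where(mag > 0, ds @ e / np.maximum(mag, 1e-300), 0.0)
        work = float((w * cos**2).sum())
        if work > best_work:
            best, best_work = e, work
    return best, best_work


class TestOrientation:
    def test_collinear_increments_recover_the_direction(self):
        d = np.array([0.6, 0.0, 0.8])
        h = make_history([d * s for s in (1.0, -2.0, 0.5)])
        axis, degenerate = principal_orientation(h, 0)
        assert not degenerate
        assert abs(axis @ d) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_equal_work_ties_break_toward_ap(self):
        h = make_history([[1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        axis, degenerate = principal_orientation(h, 0)
        assert degenerate
        assert abs(axis[0]) == pytest.approx(1.0, abs=1e-9)

    def test_random_histories_match_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            inc = rng.normal(size=(100, 3)) * [1.0, 0.0, 0.4]
            p = rng.uniform(0.1, 10.0, size=100)
            h = make_history(inc, p)
            axis, _ = principal_orientation(h, 0)
            oracle_axis, oracle_work = grid_search_orientation(h)
            ds = h.increments[:, 0, :]
            mag = np.linalg.norm(ds, axis=1)
            w = FRICTION_COEFFICIENT * p * mag
            work = float((w * (ds @ axis / mag) ** 2).sum())
            # eigen solution must do at least as well as the 0.1 deg grid
            assert work >= oracle_work * (1 - 1e-6)
            assert abs(axis @ oracle_axis) > np.cos(np.deg2rad(0.2))

    def test_zero_sliding_node_is_skipped(self):
        h = make_history([[0.0, 0.0, 0.0]])
        with pytest.raises(ValueError, match="orientation undefined"):
            principal_orientation(h, 0)


class TestCrossShear:
    def test_unidirectional_path_has_zero_csr(self):
        h = make_history([[1, 0, 0], [-2, 0, 0], [0.5, 0, 0]])
        axis, _ = principal_orientation(h, 0)
        assert cross_shear_ratio(h, axis, 0) == pytest.approx(0.0, abs=1e-12)

    def test_equal_work_orthogonal_path_reaches_the_half_bound(self):
        h = make_history([[1, 0, 0], [0, 0, 1]])
        axis, _ = principal_orientation(h, 0)
        assert cross_shear_ratio(h, axis, 0) == pytest.approx(0.5, abs=1e-12)

    def test_figure_eight_matches_direct_summation(self):
        """Lissajous path: CSR equals an explicit trigonometric summation."""
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        path = np.column_stack([np.sin(t), 0 * t, 0.5 * np.sin(2 * t)])
        inc = np.diff(np.vstack([path, path[:1]]), axis=0)
        p = 2.0 + np.cos(t)
        h = make_history(inc, p)
        axis, _ = principal_orientation(h, 0)
        csr = cross_shear_ratio(h, axis, 0)

        mag = np.linalg.norm(inc, axis=1)
        w = FRICTION_COEFFICIENT * p * mag
        cos = inc @ axis / mag
        expected = float((w * (1 - cos**2)).sum() / w.sum())
        assert csr == pytest.approx(expected, rel=1e-12)
        assert 0.0 < csr < 0.5

    def test_csr_bounded_on_random_paths(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = rng.integers(4, 60)
            inc = rng.normal(size=(n, 3)) * [1.0, 0.0, rng.uniform(0, 1)]
            h = make_history(inc, rng.uniform(0.01, 30.0, size=n))
            axis, _ = principal_orientation(h, 0)
            csr = cross_shear_ratio(h, axis, 0)
            assert 0.0 <= csr <= 0.5 + 1e-12

    def test_vectorised_field_agrees_with_per_node_summation(self):
        rng = np.random.default_rng(3)
        inc = rng.normal(size=(40, 3)) * [1.0, 0.0, 0.3]
        h = make_history(inc, rng.uniform(0.1, 5.0, size=40))
        field = cross_shear_field(h)
        axis, _ = principal_orientation(h, 0)
        assert field.csr[0] == pytest.approx(cross_shear_ratio(h, axis, 0), abs=1e-10)


# ---------------------------------------------------------------------------
# wear coefficient map and wear law
# ---------------------------------------------------------------------------


class TestWearMap:
    def test_validation_rejects_decreasing_or_negative_tables(self):
        with pytest.raises(ConfigurationError):
            WearCoefficientMap(np.array([0.0, 0.1]), np.array([2e-9, 1e-9]))
        with pytest.raises(ConfigurationError):
            WearCoefficientMap(np.array([0.0, 0.1]), np.array([-1e-9, 1e-9]))

    def test_log_linear_interpolation(self):
        cmap = WearCoefficientMap(np.array([0.0, 0.1]), np.array([1e-10, 1e-8]))
        assert float(cmap(0.05)) == pytest.approx(1e-9, rel=1e-9)

    def test_out_of_range_is_clamped_with_warning(self):
        cmap = WearCoefficientMap(np.array([0.01, 0.1]), np.array([1e-10, 1e-8]))
        with pytest.warns(UserWarning, match="clamped"):
            assert float(cmap(0.5)) == pytest.approx(1e-8)

    def test_default_maps_are_monotone_and_crosslinked_wears_less(self):
        gvf, xlk = default_wear_map("GVF"), default_wear_map("XLK")
        grid = np.linspace(0, 0.5, 101)
        assert (np.diff(gvf(grid)) >= -1e-30).all()
        assert (xlk(grid) < gvf(grid)).all()
        assert float(gvf(0.0)) > 0.0


class TestWearLaw:
    def test_zero_coefficient_means_zero_wear(self):
        h = make_history([[1, 0, 0], [0, 0, 1]])
        mesh = single_node_mesh()
        cmap = WearCoefficientMap(np.array([0.0, 0.5]), np.array([0.0, 0.0]))
        field = cross_shear_field(h)
        res = wear_volume(contact_states(mesh, [h.pressures[0]]), h, field, cmap, mesh)
        assert res.volumetric_wear_rate_mm3_per_MC == 0.0

    def test_uniform_coefficient_single_node_is_c_a_s_exactly(self):
        """W = C * A * S for one node with constant coefficient."""
        c0, area, s_total = 3e-9, 2.5, 14.0
        inc = [[7.0, 0, 0], [-7.0, 0, 0]]
        h = make_history(inc, area=area)
        mesh = single_node_mesh()
        cmap = WearCoefficientMap(np.array([0.0, 0.5]), np.array([c0, c0]))
        field = cross_shear_field(h)
        res = wear_volume(contact_states(mesh, [h.pressures[0]]), h, field, cmap, mesh)
        assert res.volumetric_wear_rate_mm3_per_MC == pytest.approx(
            c0 * area * s_total * 1e6, rel=1e-12
        )

    def test_wear_scales_linearly_with_sliding(self):
        rng = np.random.default_rng(5)
        inc = rng.normal(size=(30, 3)) * [1.0, 0.0, 0.3]
        mesh = single_node_mesh()
        cmap = default_wear_map("GVF")
        h1 = make_history(inc)
        h2 = make_history(2 * inc)
        f1, f2 = cross_shear_field(h1), cross_shear_field(h2)
        assert f2.csr[0] == pytest.approx(f1.csr[0], abs=1e-12)  # directions unchanged
        r1 = wear_volume(contact_states(mesh, [h1.pressures[0]]), h1, f1, cmap, mesh)
        r2 = wear_volume(contact_states(mesh, [h2.pressures[0]]), h2, f2, cmap, mesh)
        assert r2.volumetric_wear_rate_mm3_per_MC == pytest.approx(
            2 * r1.volumetric_wear_rate_mm3_per_MC, rel=1e-12
        )


# ---------------------------------------------------------------------------
# whole-condition behaviour
# ---------------------------------------------------------------------------


class TestRunCondition:
    def test_wear_depth_nonnegative_and_volume_consistent(self, gvf_results, default_mesh):
        res = gvf_results["distal/intermediate"]
        assert (res.wear_depth_mm >= 0).all()
        vol = float(res.wear_depth_mm @ default_mesh.areas)
        assert vol == pytest.approx(res.volumetric_wear_rate_mm3_per_MC, rel=1e-9)
        assert 0.0 <= res.average_csr <= 0.5

    def test_mirrored_knee_gives_identical_wear(
        self, default_geometry, coarse_mesh, gvf_material, gvf_map
    ):
        """A left knee with mirrored rotation input wears identically."""
        from kneewear.kinematics import WaveformTemplates

        cond = get_condition("distal/intermediate")
        right = kw.run_condition(
            cond, default_geometry, gvf_material, gvf_map,
            n_samples=48, mesh=coarse_mesh, side="right",
        )
        t = WaveformTemplates.default()
        mirrored = t.with_channel(
            "ie_shape", (lambda f: (lambda x: -np.asarray(f(x))))(t.ie_shape)
        )
        left = kw.run_condition(
            cond, default_geometry, gvf_material, gvf_map,
            n_samples=48, mesh=coarse_mesh, side="left", templates=mirrored,
        )
        assert left.volumetric_wear_rate_mm3_per_MC == pytest.approx(
            right.volumetric_wear_rate_mm3_per_MC, rel=1e-9
        )

    def test_geometry_update_mode_stays_near_linear_extrapolation(
        self, default_geometry, coarse_mesh, gvf_material, gvf_map
    ):
        """Worn-surface feedback changes little over short horizons."""
        cond = get_condition("distal/intermediate")
        base = kw.run_condition(
            cond, default_geometry, gvf_material, gvf_map,
            n_samples=48, mesh=coarse_mesh,
        )
        updated = kw.run_condition(
            cond, default_geometry, gvf_material, gvf_map,
            n_samples=48, mesh=coarse_mesh,
            n_cycles_update=5e5, total_MC=1.0,
        )
        assert updated.volumetric_wear_rate_mm3_per_MC == pytest.approx(
            base.volumetric_wear_rate_mm3_per_MC, rel=0.05
        )
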