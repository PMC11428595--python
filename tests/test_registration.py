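import numpy as np
import pytest

from dentalid.cloud import PointCloud
from dentalid.features import compute_fpfh
from dentalid.preprocess import PreprocessParams, voxel_downsample
from dentalid.registration import (
    DegenerateGeometryError,
    RegistrationParams,
    RigidTransform,
    estimate_rigid_transform,
    fitness,
    icp,
    match_fpfh,
    register_coarse_to_fine,
    rmse,
    sac_ia,
)
from dentalid.synthetic import PerturbationParams, generate_contour, perturb
from conftest import fast_reg_params, random_rotation, small_arch_params


def rotation_angle_deg(R):
    return np.degrees(np.arccos(np.clip((np.trace(R) - 1) / 2, -1, 1)))


def rot_z(deg):
    c, s = np.cos(np.radians(deg)), np.sin(np.radians(deg))
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


class TestEstimateRigidTransform:
    def test_identical_pairs_give_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        tf = estimate_rigid_transform(pts, pts)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(tf.translation, 0.0, atol=1e-12)

    def test_recovers_known_transform_exactly(self, rng):
        src = rng.normal(size=(4, 3))
        R, t = random_rotation(rng), rng.normal(size=3)
        tf = estimate_rigid_transform(src, src @ R.T + t)
        np.testing.assert_allclose(tf.rotation, R, atol=1e-9)
        np.testing.assert_allclose(tf.translation, t, atol=1e-9)
        resid = np.mean(np.sum((src @ tf.rotation.T + tf.translation - (src @ R.T + t)) ** 2, axis=1))
        assert resid < 1e-18

    def test_beats_rotation_grid_search_oracle(self, rng):
        # planar-rotation instance: grid over the rotation angle at 0.5 deg
        # with optimal (centroid-matching) translation per angle
        src = rng.normal(size=(10, 3))
        truth = rot_z(33.3)
        tgt = src @ truth.T + np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.01, (10, 3))
        tf = estimate_rigid_transform(src, tgt)
        closed = np.mean(np.sum((tf.apply(src) - tgt) ** 2, axis=1))
        best_grid = np.inf
        for deg in np.arange(0.0, 360.0, 0.5):
            R = rot_z(deg)
            t = tgt.mean(0) - R @ src.mean(0)
            best_grid = min(best_grid, np.mean(np.sum((src @ R.T + t - tgt) ** 2, axis=1)))
        assert closed <= best_grid + 1e-15

    def test_output_is_proper_rotation(self, rng):
        for _ in range(20):
            src = rng.normal(size=(5, 3))
            tgt = rng.normal(size=(5, 3))
            tf = estimate_rigid_transform(src, tgt)  # invariants checked in __post_init__
            assert np.isclose(np.linalg.det(tf.rotation), 1.0, atol=1e-9)

    def test_collinear_degenerate(self):
        src = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(DegenerateGeometryError):
            estimate_rigid_transform(src, src + 1.0)


class TestMatchFPFH:
    def test_self_match_with_tie_break(self, rng):
        desc = rng.uniform(size=(12, 33))
        desc[5] = desc[2]  # duplicate: tie must go to the lower index
        idx = match_fpfh(desc, desc)
        assert idx[2] == 2 and idx[5] == 2
        others = [i for i in range(12) if i != 5]
        np.testing.assert_array_equal(idx[others], others)

    def test_single_target(self, rng):
        idx = match_fpfh(rng.uniform(size=(7, 33)), rng.uniform(size=(1, 33)))
        np.testing.assert_array_equal(idx, 0)

    def test_matches_exhaustive_argmin_oracle(self, rng):
        s = rng.uniform(size=(30, 33))
        t = rng.uniform(size=(25, 33))
        idx = match_fpfh(s, t)
        for i in range(30):
            dists = [np.sum((s[i] - t[j]) ** 2) for j in range(25)]
            assert idx[i] == int(np.argmin(dists))


class TestMetrics:
    def test_identical_clouds(self, rng):
        pts = rng.normal(size=(50, 3))
        a, b = PointCloud(pts), PointCloud(pts.copy())
        assert fitness(a, b, 1.0) == 1.0
        assert rmse(a, b, 1.0) == 0.0

    def test_disjoint_clouds(self, rng):
        a = PointCloud(rng.normal(size=(20, 3)))
        b = PointCloud(rng.normal(size=(20, 3)) + 1000.0)
        assert fitness(a, b, 2.0) == 0.0
        assert rmse(a, b, 2.0) == np.inf

    def test_constructed_fraction(self):
        tgt = PointCloud(np.column_stack([np.arange(10.0) * 100, np.zeros(10), np.zeros(10)]))
        moved = tgt.points.copy()
        moved[:7] += [0.5, 0, 0]   # 7 points within 1 mm of a target point
        moved[7:] += [50.0, 0, 0]  # 3 points far from every target point
        assert fitness(PointCloud(moved), tgt, 1.0) == pytest.approx(0.7)

    def test_rmse_hand_computed(self):
        tgt = PointCloud([[0.0, 0, 0], [100.0, 0, 0]])
        moved = PointCloud([[0.3, 0, 0], [100.4, 0, 0]])
        assert rmse(moved, tgt, 1.0) == pytest.approx(np.sqrt((0.09 + 0.16) / 2))
        single = PointCloud([[0.3, 0, 0]])
        assert rmse(single, tgt, 1.0) == pytest.approx(0.3)


@pytest.fixture(scope="module")
def contour_pair():
    cloud = generate_contour(small_arch_params(seed=4))
    ds = voxel_downsample(cloud, 1.0)
    desc = compute_fpfh(ds, 5.0)
    return cloud, ds, desc


class TestSacIa:
    def test_self_registration_any_seed(self, contour_pair):
        cloud, ds, desc = contour_pair
        for seed in (0, 99):
            res = sac_ia(ds, ds, desc, desc, fast_reg_params(seed=seed), cloud, cloud)
            assert res.fitness == 1.0
            assert res.rmse < 1e-6

    def test_recovers_pose_offset(self, contour_pair, rng):
        cloud, ds, desc = contour_pair
        R = random_rotation(rng)
        # scale to a 25 degree rotation about the same axis
        from scipy.spatial.transform import Rotation

        rv = Rotation.from_matrix(R).as_rotvec()
        R25 = Rotation.from_rotvec(rv / np.linalg.norm(rv) * np.radians(25)).as_matrix()
        t = np.array([3.0, -2.0, 2.5])
        moved = cloud.transformed(R25, t)
        ds_m = voxel_downsample(moved, 1.0)
        desc_m = compute_fpfh(ds_m, 5.0)
        res = sac_ia(ds_m, ds, desc_m, desc, fast_reg_params(seed=5), moved, cloud)
        err_R = rotation_angle_deg(res.transform.rotation @ R25)
        err_t = np.linalg.norm(res.transform.apply(moved.points) - cloud.points, axis=1).mean()
        assert err_R < 5.0
        assert err_t < 2.0

    def test_incongruent_target_gives_zero_fitness(self, contour_pair):
        # a wide arch can never be fitted onto a sub-0.1 mm blob: every
        # candidate leaves all points outside a tight inlier radius
        from dentalid.cloud import normalize_rows
        from dentalid.features import FPFHDescriptorSet

        cloud, ds, desc = contour_pair
        g = np.random.default_rng(0)
        blob = PointCloud(
            g.normal(scale=0.03, size=(20, 3)) + 1e4,
            normalize_rows(g.normal(size=(20, 3))),
        )
        blob_desc = FPFHDescriptorSet(g.uniform(0, 100, (20, 33)), 5.0)
        res = sac_ia(
            ds, blob, desc, blob_desc,
            fast_reg_params(corr_dist=0.01), cloud, blob,
        )
        assert res.fitness == 0.0
        assert res.rmse == np.inf
        assert not res.converged

    def test_bitwise_reproducible(self, contour_pair):
        cloud, ds, desc = contour_pair
        a = sac_ia(ds, ds, desc, desc, fast_reg_params(seed=3), cloud, cloud)
        b = sac_ia(ds, ds, desc, desc, fast_reg_params(seed=3), cloud, cloud)
        np.testing.assert_array_equal(a.transform.rotation, b.transform.rotation)
        np.testing.assert_array_equal(a.transform.translation, b.transform.translation)
        assert (a.fitness, a.rmse) == (b.fitness, b.rmse)

    def test_source_smaller_than_t_rejected(self, contour_pair):
        cloud, ds, desc = contour_pair
        tiny = PointCloud(ds.points[:2], ds.normals[:2])
        with pytest.raises(ValueError, match="t="):
            sac_ia(tiny, ds, desc.descriptors[:2], desc, fast_reg_params(), tiny, cloud)


class TestICP:
    def test_self_registration_converges_immediately(self, contour_pair):
        cloud, _, _ = contour_pair
        res = icp(cloud, cloud, params=RegistrationParams())
        assert res.converged
        assert res.rmse < 1e-9
        assert res.fitness == 1.0

    def test_recovers_small_transform_to_machine_precision(self, contour_pair):
        cloud, _, _ = contour_pair
        R, t = rot_z(3.0), np.array([0.5, 0.2, -0.3])
        moved = cloud.transformed(R, t)
        res = icp(moved, cloud, params=RegistrationParams())
        assert res.rmse < 1e-6
        assert rotation_angle_deg(res.transform.rotation @ R) < 0.01

    def test_error_trace_non_increasing(self, contour_pair, rng):
        cloud, _, _ = contour_pair
        for k in range(5):
            R, t = rot_z(rng.uniform(0.5, 4.0)), rng.normal(0, 0.4, 3)
            res = icp(cloud.transformed(R, t), cloud, params=RegistrationParams())
            trace = np.array(res.error_trace)
            assert np.all(np.diff(trace) <= 1e-9)

    def test_no_overlap_returns_zero_fitness(self, contour_pair):
        cloud, _, _ = contour_pair
        far = PointCloud(cloud.points + 1e4, cloud.normals)
        res = icp(cloud, far, params=RegistrationParams())
        assert not res.converged
        assert res.fitness == 0.0


class TestCoarseToFine:
    def test_self_registration(self, contour_pair):
        cloud, _, _ = contour_pair
        res = register_coarse_to_fine(cloud, cloud, PreprocessParams(), fast_reg_params())
        assert res.fitness == 1.0
        assert res.rmse < 1e-6

    def test_beats_icp_alone_on_large_offset(self, contour_pair):
        cloud, _, _ = contour_pair
        moved = cloud.transformed(rot_z(30.0), np.array([10.0, 3.0, 0.0]))
        params = fast_reg_params(seed=2)
        c2f = register_coarse_to_fine(moved, cloud, PreprocessParams(), params)
        alone = icp(moved, cloud, params=params)
        assert c2f.rmse <= alone.rmse

    def test_noise_floor(self, contour_pair):
        cloud, _, _ = contour_pair
        sigma = 0.05
        q, _ = perturb(
            cloud,
            PerturbationParams(
                max_rotation=10, max_translation=3, noise_sigma=sigma,
                dropout_fraction=0.0, scan_seed=8,
            ),
        )
        res = register_coarse_to_fine(q, cloud, PreprocessParams(), fast_reg_params(seed=3))
        assert sigma / 2 <= res.rmse <= 3 * sigma


class TestRigidTransform:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))  # reflection

    def test_compose_and_inverse(self, rng):
        a = RigidTransform(random_rotation(rng), rng.normal(size=3))
        b = RigidTransform(random_rotation(rng), rng.normal(size=3))
        pts = rng.normal(size=(10, 3))
        np.testing.assert_allclose(a.compose(b).apply(pts), a.apply(b.apply(pts)), atol=1e-12)
        np.testing.assert_allclose(a.inverse().apply(a.apply(pts)), pts, atol=1e-12)

    def test_serialization_contains_matrix(self):
        from dentalid.registration import RegistrationResult

        res = RegistrationResult(RigidTransform.identity(), 1.0, 0.0, 10, 3, True)
        text = res.to_text(seed=7)
        assert "transform_4x4_row_major" in text
        assert "seed = 7" in text
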