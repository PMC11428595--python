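import numpy as np
import pytest

from dentalid.cloud import PointCloud, normalize_rows


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sphere_cloud(r=2.0, n=2000, seed=0, inward=False):
    """Quasi-uniform sample of a sphere surface with radial unit normals."""
    g = np.random.default_rng(seed)
    v = g.normal(size=(n, 3))
    dirs = normalize_rows(v)
    normals = -dirs if inward else dirs
    return PointCloud(r * dirs, normals)


def cylinder_cloud(r=1.0, length=8.0, spacing=0.15, inward=False):
    n_ang = int(2 * np.pi * r / spacing)
    n_len = int(length / spacing)
    th = np.linspace(0, 2 * np.pi, n_ang, endpoint=False)
    z = np.linspace(0, length, n_len)
    TH, Z = np.meshgrid(th, z)
    pts = np.column_stack([r * np.cos(TH).ravel(), r * np.sin(TH).ravel(), Z.ravel()])
    nrm = np.column_stack([np.cos(TH).ravel(), np.sin(TH).ravel(), np.zeros(Z.size)])
    if inward:
        nrm = -nrm
    return PointCloud(pts, nrm)


def plane_cloud(n_side=40, extent=8.0, seed=0):
    g = np.random.default_rng(seed)
    xy = g.uniform(-extent / 2, extent / 2, size=(n_side * n_side, 2))
    pts = np.column_stack([xy, np.zeros(len(xy))])
    nrm = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
    return PointCloud(pts, nrm)


def bowl_cloud(r=2.0, n=1500, seed=0):
    """Concave hemisphere (opening up) with normals toward a viewpoint above,
    i.e. pointing at the sphere centre: the surface bends toward its normals."""
    g = np.random.default_rng(seed)
    v = g.normal(size=(n, 3))
    dirs = normalize_rows(v)
    dirs[:, 2] = -np.abs(dirs[:, 2])  # lower hemisphere of the sphere
    centre = np.array([0.0, 0.0, r])
    pts = centre + r * dirs
    return PointCloud(pts, -dirs)


def random_rotation(g):
    from scipy.spatial.transform import Rotation

    return Rotation.random(random_state=np.random.RandomState(g.integers(2**31))).as_matrix()


def small_arch_params(seed=0, **kw):
    """Compact, fast subject used across registration/identification tests."""
    from dentalid.synthetic import ArchParams

    defaults = dict(
        n_teeth=6,
        arch_width=36.0,
        arch_depth=28.0,
        points_per_tooth=80,
        subject_seed=seed,
    )
    defaults.update(kw)
    return ArchParams(**defaults)


def fast_reg_params(seed=0, **kw):
    from dentalid.registration import RegistrationParams

    defaults = dict(sacia_iterations=300, seed=seed)
    defaults.update(kw)
    return RegistrationParams(**defaults)
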