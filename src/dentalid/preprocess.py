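"""Stage 1 — surface feature extraction from intraoral-scan point clouds.

The discriminative geometry of a dentition lives in the crown contour: the
rolled margin where each tooth crown meets the gingiva.  On a mean-curvature
map of the scan (outward-oriented normals) that margin shows up as a band of
strongly negative curvature, and thresholding the field at −0.6 mm⁻¹
extracts it.  This module provides the full stage: PCA normal estimation,
mean curvature by pseudo-inverse quadric fitting, contour thresholding,
connected-component denoising, angular-sector subregion segmentation, and
centroid voxel downsampling.

Sign convention: curvature is measured in the local frame whose w-axis is
the point's normal, so a surface bending away from its normal (a sphere with
outward normals, or the convex gingival roll seen from outside the mouth)
has negative mean curvature, H = −1/r for the sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .cloud import PointCloud, normalize_rows

__all__ = [
    "PreprocessParams",
    "CurvatureField",
    "estimate_normals",
    "mean_curvature",
    "extract_contour",
    "remove_small_components",
    "segment_subregions",
    "voxel_downsample",
]


@dataclass
class PreprocessParams:
    """Tunable knobs of the preprocessing stage (distances in mm).

    ``curvature_threshold`` defaults to −0.6 mm⁻¹, the crown-contour
    extraction level; ``voxel_size`` defaults to 1.0 mm.
    """

    normal_k: int = 20
    curvature_k: int = 20
    curvature_threshold: float = -0.6
    link_radius: float = 1.0
    min_component_size: int = 20
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.curvature_k < 6:
            raise ValueError("curvature_k must be >= 6 (a quadric has 6 coefficients)")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.link_radius <= 0:
            raise ValueError("link_radius must be > 0")


@dataclass
class CurvatureField:
    """Per-point mean curvature H (mm⁻¹) aligned with a parent cloud."""

    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask must have the same length")
        if not np.all(np.isfinite(self.values[self.valid_mask])):
            raise ValueError("valid curvature values must be finite")


def estimate_normals(
    cloud: PointCloud, normal_k: int = 20, viewpoint: np.ndarray | None = None
) -> PointCloud:
    """PCA normals from the ``normal_k`` nearest neighbours of each point.

    The normal is the eigenvector of the local covariance with the smallest
    eigenvalue, sign-flipped to point toward ``viewpoint`` (default: 100 mm
    above the cloud centroid along +z, the occlusal direction for a scan in
    canonical pose).
    """
    pts = cloud.points
    if len(pts) < normal_k + 1:
        raise ValueError(
            f"need at least normal_k+1={normal_k + 1} points, got {len(pts)}"
        )
    if viewpoint is None:
        viewpoint = pts.mean(axis=0) + np.array([0.0, 0.0, 100.0])
    viewpoint = np.asarray(viewpoint, dtype=np.float64)
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=normal_k + 1)
    nbrs = pts[idx]  # (n, k+1, 3) includes the point itself
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)  # ascending eigenvalues
    normals = vecs[:, :, 0]
    flip = np.einsum("ni,ni->n", normals, viewpoint - pts) < 0
    normals[flip] *= -1.0
    return PointCloud(pts.copy(), normalize_rows(normals), cloud.label)


def mean_curvature(cloud: PointCloud, curvature_k: int = 20) -> CurvatureField:
    """Mean curvature by pseudo-inverse quadric fitting.

    Each point's ``curvature_k`` neighbours are expressed in a local frame
    with the w-axis along the point's normal; the graph quadric
    ``w = a·u² + b·uv + c·v² + d·u + e·v + f`` is fitted by least squares
    (Moore–Penrose pseudo-inverse) and H is the mean curvature of that graph
    surface at the point's (u, v) = (0, 0) projection:

        H = ((1+e²)·2a − 2deb + (1+d²)·2c) / (2·(1 + d² + e²)^{3/2})

    Rank-deficient neighbourhoods are flagged invalid instead of raising.
    """
    if not cloud.has_normals:
        raise ValueError("mean_curvature requires normals; run estimate_normals first")
    if curvature_k < 6:
        raise ValueError("curvature_k must be >= 6")
    pts = cloud.points
    n = len(pts)
    if n < curvature_k + 1:
        raise ValueError("cloud smaller than curvature_k + 1")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=curvature_k + 1)
    values = np.zeros(n)
    valid = np.ones(n, dtype=bool)

    # local frames: w = normal, (u, v) any orthonormal complement
    w_ax = cloud.normals
    ref = np.where(np.abs(w_ax[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]])
    u_ax = normalize_rows(np.cross(ref, w_ax))
    v_ax = np.cross(w_ax, u_ax)

    rel = pts[idx] - pts[:, None, :]  # (n, k+1, 3)
    u = np.einsum("nkj,nj->nk", rel, u_ax)
    v = np.einsum("nkj,nj->nk", rel, v_ax)
    w = np.einsum("nkj,nj->nk", rel, w_ax)
    design = np.stack([u * u, u * v, v * v, u, v, np.ones_like(u)], axis=-1)
    for i in range(n):
        coef, _, rank, _ = np.linalg.lstsq(design[i], w[i], rcond=None)
        if rank < 6:
            valid[i] = False
            continue
        a, b, c, d, e, _ = coef
        denom = (1.0 + d * d + e * e) ** 1.5
        values[i] = ((1 + e * e) * 2 * a - 2 * d * e * b + (1 + d * d) * 2 * c) / (
            2 * denom
        )
    values[~valid] = np.nan
    return CurvatureField(values, valid)


def extract_contour(
    cloud: PointCloud, curv: CurvatureField, threshold: float = -0.6
) -> PointCloud:
    """Points with valid curvature strictly below ``threshold`` (mm⁻¹).

    Order and normals are preserved; the label is carried over.  The default
    −0.6 selects the crown-contour band.
    """
    if len(curv.values) != len(cloud):
        raise ValueError("curvature field is not aligned with the cloud")
    keep = curv.valid_mask & np.less(
        curv.values, threshold, where=curv.valid_mask, out=np.zeros(len(cloud), bool)
    )
    return cloud.select(keep)


def remove_small_components(
    cloud: PointCloud, link_radius: float = 1.0, min_component_size: int = 20
) -> PointCloud:
    """Drop connected components smaller than ``min_component_size``.

    Two points are linked when closer than ``link_radius``; a reproducible
    stand-in for manual noise cleanup below the tooth outline.
    """
    if link_radius <= 0:
        raise ValueError("link_radius must be > 0")
    n = len(cloud)
    if n == 0 or min_component_size <= 1:
        return cloud.copy()
    tree = cKDTree(cloud.points)
    pairs = tree.query_pairs(link_radius, output_type="ndarray")
    graph = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = connected_components(graph, directed=False)
    counts = np.bincount(labels)
    return cloud.select(counts[labels] >= min_component_size)


def segment_subregions(
    contour: PointCloud,
    gingival_band: float = 0.5,
    anterior_half_angle_deg: float = 30.0,
) -> dict[str, PointCloud]:
    """Split a crown contour into the gingival line and its three sectors.

    Expects canonical pose: occlusal axis +z, arch opening toward −y.  The
    gingival margin line is the height band within ``gingival_band`` of the
    cloud's z-range above its minimum; the three areas partition it by
    angular sector about the arch centroid — anterior within
    ``anterior_half_angle_deg`` of the (±y) symmetry axis, the rest split
    left/right by the sign of x.

    Returns a dict with keys ``gingival_line``, ``left_posterior``,
    ``anterior``, ``right_posterior``.
    """
    if len(contour) < 50:
        raise ValueError("contour too sparse to sector (< 50 points)")
    pts = contour.points
    z = pts[:, 2]
    zmin, zmax = z.min(), z.max()
    band = z <= zmin + gingival_band * (zmax - zmin) + 1e-12
    idx_band = np.flatnonzero(band)
    centroid = pts.mean(axis=0)
    rel = pts[idx_band] - centroid
    # angle from the arch symmetry axis (±y), sign-agnostic so a 180° pose
    # flip about z swaps left and right but leaves the anterior sector fixed
    ang = np.degrees(np.arctan2(np.abs(rel[:, 0]), np.abs(rel[:, 1])))
    anterior = ang <= anterior_half_angle_deg
    left = ~anterior & (rel[:, 0] < 0)
    right = ~anterior & (rel[:, 0] >= 0)
    return {
        "gingival_line": contour.select(idx_band),
        "left_posterior": contour.select(idx_band[left]),
        "anterior": contour.select(idx_band[anterior]),
        "right_posterior": contour.select(idx_band[right]),
    }


def voxel_downsample(cloud: PointCloud, voxel_size: float = 1.0) -> PointCloud:
    """Centroid voxel-grid downsampling.

    Space is partitioned into axis-aligned cubes of edge ``voxel_size``
    anchored at the cloud's minimum corner; each non-empty voxel contributes
    one output point, the centre of gravity G_d = (1/N_d)·Σ (x_j, y_j, z_j)
    of its N_d members.  Points landing exactly on a voxel boundary go to
    the lower-index voxel, and the output is ordered by lexicographic voxel
    index, making the binning bit-reproducible.  Normals, if present, are
    averaged and renormalized (a zero average falls back to the first
    member's normal).
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    pts = cloud.points
    t = (pts - pts.min(axis=0)) / voxel_size
    idx = np.ceil(t).astype(np.int64) - 1  # boundary ties -> lower voxel
    np.clip(idx, 0, None, out=idx)
    voxel_dt = np.dtype([(c, idx.dtype) for c in "abc"])
    keys, inverse, counts = np.unique(
        np.ascontiguousarray(idx).view(voxel_dt).ravel(),
        return_inverse=True,
        return_counts=True,
    )
    m = len(keys)
    sums = np.zeros((m, 3))
    np.add.at(sums, inverse, pts)
    centroids = sums / counts[:, None]
    normals = None
    if cloud.normals is not None:
        nsum = np.zeros((m, 3))
        np.add.at(nsum, inverse, cloud.normals)
        nn = np.linalg.norm(nsum, axis=1)
        degenerate = nn < 1e-12
        if np.any(degenerate):
            first = np.full(m, -1, dtype=np.int64)
            # first member (lowest original index) of each voxel
            for j in range(len(pts) - 1, -1, -1):
                first[inverse[j]] = j
            nsum[degenerate] = cloud.normals[first[degenerate]]
        normals = normalize_rows(nsum)
    return PointCloud(centroids, normals, cloud.label)
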