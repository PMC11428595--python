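"""Stage 2 — FPFH local geometric descriptors.

For a query point Ps with normal ns and a neighbour Pt with normal nt, the
Darboux frame

    U = ns,   V = U × (Pt − Ps) / ‖U × (Pt − Ps)‖,   W = U × V

defines three pose-invariant pair features

    α = V · nt,   φ = U · (Pt − Ps)/‖Pt − Ps‖,   θ = atan2(W · nt, U · nt).

Binning each feature over its range into 11 sub-intervals (33 bins total)
for all in-radius neighbours of Ps gives its simple point feature histogram
(SPFH); the fast variant re-weights neighbours' SPFHs by inverse distance:

    FPFH(Ps) = SPFH(Ps) + (1/n) Σᵢ (1/ωᵢ) · SPFH(Pkᵢ).

Each 11-bin block of an SPFH is normalized to sum to 100, which makes the
descriptor independent of sampling density.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .cloud import PointCloud

__all__ = [
    "DarbouxFrame",
    "PairFeatures",
    "FPFHDescriptorSet",
    "DegeneratePairError",
    "darboux_frame",
    "pair_features",
    "compute_spfh",
    "compute_fpfh",
    "export_descriptors",
]

N_BINS_PER_FEATURE = 11
N_BINS = 3 * N_BINS_PER_FEATURE
_DEGENERATE_CROSS = 1e-12


class DegeneratePairError(ValueError):
    """The pair direction is parallel to the source normal; no frame exists."""


@dataclass(frozen=True)
class DarbouxFrame:
    """Right-handed orthonormal frame (U, V, W) attached to a point pair."""

    U: np.ndarray
    V: np.ndarray
    W: np.ndarray


@dataclass(frozen=True)
class PairFeatures:
    """The (α, φ, θ) angular features of one ordered point pair."""

    alpha: float
    phi: float
    theta: float


@dataclass
class FPFHDescriptorSet:
    """Per-point 33-bin FPFH descriptors aligned with a point cloud.

    Bin layout: indices 0–10 ← α, 11–21 ← φ, 22–32 ← θ.
    """

    descriptors: np.ndarray
    radius: float

    def __post_init__(self) -> None:
        self.descriptors = np.asarray(self.descriptors, dtype=np.float64)
        if self.descriptors.ndim != 2 or self.descriptors.shape[1] != N_BINS:
            raise ValueError(f"descriptors must be (n, {N_BINS})")
        if np.any(self.descriptors < 0) or not np.all(np.isfinite(self.descriptors)):
            raise ValueError("descriptor entries must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.descriptors)


def darboux_frame(ps: np.ndarray, ns: np.ndarray, pt: np.ndarray) -> DarbouxFrame:
    ps, ns, pt = (np.asarray(a, dtype=np.float64) for a in (ps, ns, pt))
    d = pt - ps
    cross = np.cross(ns, d)
    norm = np.linalg.norm(cross)
    if norm < _DEGENERATE_CROSS:
        raise DegeneratePairError("pair direction parallel to source normal")
    v = cross / norm
    return DarbouxFrame(U=ns.copy(), V=v, W=np.cross(ns, v))


def pair_features(
    ps: np.ndarray, ns: np.ndarray, pt: np.ndarray, nt: np.ndarray
) -> PairFeatures:
    frame = darboux_frame(ps, ns, pt)
    d = np.asarray(pt, dtype=np.float64) - np.asarray(ps, dtype=np.float64)
    nt = np.asarray(nt, dtype=np.float64)
    return PairFeatures(
        alpha=float(frame.V @ nt),
        phi=float(frame.U @ (d / np.linalg.norm(d))),
        theta=float(np.arctan2(frame.W @ nt, frame.U @ nt)),
    )


def _bin_indices(alpha, phi, theta):
    """Map (α, φ, θ) arrays to bin indices in their three 11-bin blocks."""
    b = N_BINS_PER_FEATURE
    ia = np.clip(np.floor((alpha + 1.0) / 2.0 * b), 0, b - 1).astype(np.intp)
    ip = np.clip(np.floor((phi + 1.0) / 2.0 * b), 0, b - 1).astype(np.intp)
    it = np.clip(np.floor((theta + np.pi) / (2 * np.pi) * b), 0, b - 1).astype(np.intp)
    return ia, b + ip, 2 * b + it


def _neighbor_pairs(cloud: PointCloud, radius: float):
    """Flat (source, neighbour) index arrays for all in-radius pairs, self and
    exactly-coincident duplicates excluded."""
    tree = cKDTree(cloud.points)
    neigh = tree.query_ball_point(cloud.points, radius)
    src = np.concatenate(
        [np.full(len(lst), i, dtype=np.intp) for i, lst in enumerate(neigh)]
    ) if len(neigh) else np.empty(0, np.intp)
    dst = (
        np.concatenate([np.asarray(lst, dtype=np.intp) for lst in neigh])
        if len(neigh)
        else np.empty(0, np.intp)
    )
    keep = src != dst
    src, dst = src[keep], dst[keep]
    dist = np.linalg.norm(cloud.points[dst] - cloud.points[src], axis=1)
    keep = dist > _DEGENERATE_CROSS
    return src[keep], dst[keep], dist[keep]


def _spfh_from_pairs(n_points, src, dst, dist, points, normals):
    """Raw SPFH accumulation + per-block percentage normalization."""
    hist = np.zeros((n_points, N_BINS))
    if len(src):
        d = points[dst] - points[src]
        ns = normals[src]
        nt = normals[dst]
        cross = np.cross(ns, d)
        cnorm = np.linalg.norm(cross, axis=1)
        ok = cnorm > _DEGENERATE_CROSS  # degenerate pairs are skipped, not binned
        s, d, ns, nt, cross, cnorm, w = (
            src[ok], d[ok], ns[ok], nt[ok], cross[ok], cnorm[ok], dist[ok],
        )
        v = cross / cnorm[:, None]
        wax = np.cross(ns, v)
        alpha = np.einsum("ij,ij->i", v, nt)
        phi = np.einsum("ij,ij->i", ns, d) / w
        theta = np.arctan2(
            np.einsum("ij,ij->i", wax, nt), np.einsum("ij,ij->i", ns, nt)
        )
        for bins in _bin_indices(alpha, phi, theta):
            np.add.at(hist, (s, bins), 1.0)
    # normalize each 11-bin block to percentage
    for k in range(3):
        block = hist[:, k * N_BINS_PER_FEATURE : (k + 1) * N_BINS_PER_FEATURE]
        sums = block.sum(axis=1, keepdims=True)
        nz = sums[:, 0] > 0
        block[nz] *= 100.0 / sums[nz]
    return hist


def compute_spfh(cloud: PointCloud, radius_k: float) -> np.ndarray:
    """Simple point feature histograms, one 33-bin row per point.

    Each of the three 11-bin blocks sums to 100 for points with at least one
    non-degenerate in-radius neighbour, and is all-zero otherwise.
    """
    if not cloud.has_normals:
        raise ValueError("compute_spfh requires normals")
    if radius_k <= 0:
        raise ValueError("radius_k must be > 0")
    src, dst, dist = _neighbor_pairs(cloud, radius_k)
    return _spfh_from_pairs(len(cloud), src, dst, dist, cloud.points, cloud.normals)


def compute_fpfh(cloud: PointCloud, radius_k: float) -> FPFHDescriptorSet:
    """Fast point feature histograms over an exact in-radius neighbourhood."""
    if not cloud.has_normals:
        raise ValueError("compute_fpfh requires normals")
    if radius_k <= 0:
        raise ValueError("radius_k must be > 0")
    src, dst, dist = _neighbor_pairs(cloud, radius_k)
    spfh = _spfh_from_pairs(len(cloud), src, dst, dist, cloud.points, cloud.normals)
    fpfh = spfh.copy()
    if len(src):
        weighted = np.zeros_like(spfh)
        np.add.at(weighted, src, spfh[dst] / dist[:, None])
        counts = np.bincount(src, minlength=len(cloud)).astype(np.float64)
        nz = counts > 0
        fpfh[nz] += weighted[nz] / counts[nz, None]
    return FPFHDescriptorSet(fpfh, radius=radius_k)


def export_descriptors(
    cloud: PointCloud, desc: FPFHDescriptorSet, path: str | Path
) -> None:
    """Write one row per point (x, y, z, 33 bins) as tab-separated text,
    with the radius and bin layout recorded in a comment header."""
    if len(desc) != len(cloud):
        raise ValueError("descriptor set is not aligned with the cloud")
    header = (
        f"radius_k_mm = {desc.radius}\n"
        "bins: 0-10 alpha in [-1,1], 11-21 phi in [-1,1], 22-32 theta in (-pi,pi]\n"
        "columns: x y z b0 ... b32"
    )
    np.savetxt(
        path,
        np.hstack([cloud.points, desc.descriptors]),
        fmt="%.9g",
        delimiter="\t",
        header=header,
    )
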