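"""Stage 3 core — coarse-to-fine rigid registration of dental point clouds.

Coarse alignment is sample-consensus initial alignment (SAC-IA): repeatedly
draw ``t`` well-spread source points, pair each with the target point of
most similar FPFH descriptor, fit the rigid transform of the ``t`` pairs in
closed form, and score the transform on the full (pre-downsampling) clouds;
the candidate with highest fitness, then lowest RMSE, wins.  Fine alignment
is point-to-point ICP seeded with the SAC-IA transform, iterating
nearest-neighbour pairing (gated by an inlier distance and an optional
normal-compatibility angle) and the closed-form least-squares update that
minimizes the mean squared pair residual

    E(R, T) = (1/N) Σₕ ‖qₕ − (R·pₕ + T)‖².

Fitness is the fraction of transformed-source points with a target
neighbour within the inlier distance; RMSE is the root mean square of those
inlier distances (+inf when there are none).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree, distance

from .cloud import PointCloud

__all__ = [
    "RigidTransform",
    "RegistrationResult",
    "RegistrationParams",
    "DegenerateGeometryError",
    "estimate_rigid_transform",
    "match_fpfh",
    "fitness",
    "rmse",
    "sac_ia",
    "icp",
    "register_coarse_to_fine",
]

log = logging.getLogger(__name__)

_SCORE_CHUNK = 64  # candidates scored per batch; fixed so results never vary


class DegenerateGeometryError(ValueError):
    """Point pairs are collinear/degenerate; the rigid fit is underdetermined."""


@dataclass(frozen=True)
class RigidTransform:
    """Rotation ``R`` (3×3, proper orthogonal) + translation ``T`` (mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "rotation", np.asarray(self.rotation, dtype=np.float64))
        object.__setattr__(
            self, "translation", np.asarray(self.translation, dtype=np.float64)
        )
        R = self.rotation
        if R.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation length 3")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise ValueError("rotation determinant is not +1 (improper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def matrix(self) -> np.ndarray:
        """4×4 homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m


@dataclass
class RegistrationResult:
    """Outcome of one registration: transform plus alignment metrics."""

    transform: RigidTransform
    fitness: float
    rmse: float
    n_correspondences: int
    iterations: int
    converged: bool
    coarse: "RegistrationResult | None" = None
    error_trace: list[float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.fitness <= 1.0):
            raise ValueError("fitness must lie in [0, 1]")
        if self.n_correspondences > 0 and not self.rmse >= 0:
            raise ValueError("rmse must be >= 0 when correspondences exist")

    def to_text(self, seed: int | None = None) -> str:
        """Audit record: homogeneous matrix row-major + metrics."""
        rows = [
            "transform_4x4_row_major = "
            + " ".join(f"{v:.12g}" for v in self.transform.matrix().ravel()),
            f"fitness = {self.fitness:.9g}",
            f"rmse_mm = {self.rmse:.9g}",
            f"n_correspondences = {self.n_correspondences}",
            f"iterations = {self.iterations}",
            f"converged = {self.converged}",
        ]
        if seed is not None:
            rows.append(f"seed = {seed}")
        return "\n".join(rows) + "\n"


@dataclass
class RegistrationParams:
    """Knobs of the SAC-IA → ICP scheme (distances mm, angles degrees)."""

    sacia_samples: int = 3
    sacia_iterations: int = 1000
    min_sample_spacing: float = 5.0
    corr_dist: float = 2.0
    fpfh_radius: float = 5.0
    icp_max_iter: int = 50
    icp_tol: float = 1e-6
    normal_angle_max: float = 45.0
    use_normal_rejection: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sacia_samples < 3:
            raise ValueError("sacia_samples must be >= 3")
        for name in ("min_sample_spacing", "corr_dist", "fpfh_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def _kabsch(src: np.ndarray, tgt: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Closed-form least-squares rigid fit (centroid + SVD, reflection guard).

    Returns (R, t, second_singular_value) — the caller uses the singular
    value to detect collinear geometry.
    """
    cs = src.mean(axis=0)
    ct = tgt.mean(axis=0)
    H = (src - cs).T @ (tgt - ct)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d if d != 0 else 1.0])
    R = Vt.T @ D @ U.T
    return R, ct - R @ cs, S[1]


def estimate_rigid_transform(
    source_pts: np.ndarray, target_pts: np.ndarray
) -> RigidTransform:
    """Rotation + translation minimizing the mean squared pair residual.

    Computed in closed form via centroid subtraction and SVD of the
    cross-covariance, with a reflection guard on the determinant.
    """
    src = np.asarray(source_pts, dtype=np.float64)
    tgt = np.asarray(target_pts, dtype=np.float64)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source and target must be equal-length (n, 3) arrays")
    if len(src) < 3:
        raise ValueError("need at least 3 point pairs")
    spread = np.linalg.svd(src - src.mean(axis=0), compute_uv=False)
    if spread[1] <= 1e-9 * max(spread[0], 1e-12):
        raise DegenerateGeometryError("source points are collinear")
    R, t, _ = _kabsch(src, tgt)
    return RigidTransform(R, t)


def match_fpfh(source_desc, target_desc, indices: np.ndarray | None = None) -> np.ndarray:
    """Exact nearest neighbour in 33-D descriptor space (ties → lowest index).

    Returns the matched target index for each queried source index.
    """
    s = np.asarray(source_desc.descriptors if hasattr(source_desc, "descriptors") else source_desc)
    t = np.asarray(target_desc.descriptors if hasattr(target_desc, "descriptors") else target_desc)
    if len(s) == 0 or len(t) == 0:
        raise ValueError("descriptor sets must be non-empty")
    if indices is not None:
        s = s[np.asarray(indices)]
    # exhaustive distance matrix: exact, and argmin breaks ties by lowest index
    return np.argmin(distance.cdist(s, t, "sqeuclidean"), axis=1)


def _inlier_distances(tree: cKDTree, pts: np.ndarray, corr_dist: float) -> np.ndarray:
    d, _ = tree.query(pts, k=1, distance_upper_bound=corr_dist)
    return d


def fitness(transformed: PointCloud, target: PointCloud, corr_dist: float) -> float:
    """Fraction of transformed points with a target neighbour within
    ``corr_dist``; the alignment-degree metric, in [0, 1]."""
    if len(transformed) == 0:
        raise ValueError("transformed cloud is empty")
    d = _inlier_distances(cKDTree(target.points), transformed.points, corr_dist)
    return float(np.count_nonzero(np.isfinite(d)) / len(d))


def rmse(transformed: PointCloud, target: PointCloud, corr_dist: float) -> float:
    """Root mean square of inlier nearest-neighbour distances (mm); +inf
    when no transformed point has a target neighbour within ``corr_dist``."""
    if len(transformed) == 0:
        raise ValueError("transformed cloud is empty")
    d = _inlier_distances(cKDTree(target.points), transformed.points, corr_dist)
    d = d[np.isfinite(d)]
    if len(d) == 0:
        return float("inf")
    return float(np.sqrt(np.mean(d * d)))


def _draw_samples(
    rng: np.random.Generator,
    points: np.ndarray,
    n_iter: int,
    t: int,
    min_spacing: float,
) -> np.ndarray:
    """(n_iter, t) index array of random samples with pairwise spacing
    >= min_spacing; the spacing constraint is dropped (with a warning) for
    rows that still fail after many redraw rounds."""
    n = len(points)
    samples = rng.integers(0, n, size=(n_iter, t))
    for round_ in range(200):
        ok = np.ones(n_iter, dtype=bool)
        for i in range(t):
            for j in range(i + 1, t):
                dij = np.linalg.norm(
                    points[samples[:, i]] - points[samples[:, j]], axis=1
                )
                ok &= dij >= min_spacing
        bad = ~ok
        if not bad.any():
            return samples
        samples[bad] = rng.integers(0, n, size=(int(bad.sum()), t))
    log.warning(
        "min_sample_spacing=%.3g unreachable for %d candidates; spacing relaxed",
        min_spacing,
        int(bad.sum()),
    )
    return samples


def sac_ia(
    source: PointCloud,
    target: PointCloud,
    source_desc,
    target_desc,
    params: RegistrationParams,
    full_source: PointCloud | None = None,
    full_target: PointCloud | None = None,
) -> RegistrationResult:
    """Sample-consensus initial alignment on FPFH correspondences.

    Draws ``sacia_samples`` spread-out source points per iteration, pairs
    them with their FPFH nearest neighbours in the target, fits the rigid
    transform of the pairs, and scores every candidate by fitness and RMSE
    on the full (pre-downsampling) clouds.  The candidate with
    lexicographically best (fitness desc, RMSE asc) wins; deterministic for
    a fixed ``params.seed``.
    """
    full_source = full_source if full_source is not None else source
    full_target = full_target if full_target is not None else target
    t = params.sacia_samples
    if len(source) < t:
        raise ValueError(f"source has {len(source)} points, need at least t={t}")
    rng = np.random.default_rng(params.seed)
    matched = match_fpfh(source_desc, target_desc)  # target index per source point
    samples = _draw_samples(
        rng, source.points, params.sacia_iterations, t, params.min_sample_spacing
    )

    src_trip = source.points[samples]  # (B, t, 3)
    tgt_trip = target.points[matched[samples]]
    cs = src_trip.mean(axis=1, keepdims=True)
    ct = tgt_trip.mean(axis=1, keepdims=True)
    H = np.einsum("bti,btj->bij", src_trip - cs, tgt_trip - ct)
    U, S, Vt = np.linalg.svd(H)
    dets = np.linalg.det(np.einsum("bij,bkj->bik", Vt.transpose(0, 2, 1), U))
    D = np.repeat(np.eye(3)[None], len(H), axis=0)
    D[:, 2, 2] = np.where(dets < 0, -1.0, 1.0)
    R = np.einsum("bji,bjk,blk->bil", Vt, D, U)
    T = ct[:, 0, :] - np.einsum("bij,bj->bi", R, cs[:, 0, :])
    # a candidate whose matched pairs are (near-)collinear is underdetermined
    src_spread = np.linalg.svd(src_trip - cs, compute_uv=False)
    degenerate = src_spread[:, 1] <= 1e-9 * np.maximum(src_spread[:, 0], 1e-12)

    tree = cKDTree(full_target.points)
    lo = full_target.points.min(axis=0) - params.corr_dist
    hi = full_target.points.max(axis=0) + params.corr_dist
    P = full_source.points
    n_full = len(P)
    best = (-1.0, np.inf)
    best_idx = -1
    best_n_corr = 0
    for start in range(0, len(R), _SCORE_CHUNK):
        sl = slice(start, start + _SCORE_CHUNK)
        Rc, Tc, degc = R[sl], T[sl], degenerate[sl]
        moved = np.einsum("cij,nj->cni", Rc, P) + Tc[:, None, :]
        inside = np.all((moved >= lo) & (moved <= hi), axis=2)
        inside_frac = inside.mean(axis=1)
        for k in range(len(Rc)):
            if degc[k]:
                continue
            # a point outside the corr_dist-expanded target box cannot match,
            # so inside_frac bounds fitness from above: candidates that cannot
            # strictly beat the current best fitness are skipped exactly
            if inside_frac[k] < best[0]:
                continue
            d = _inlier_distances(tree, moved[k][inside[k]], params.corr_dist)
            d = d[np.isfinite(d)]
            n_corr = len(d)
            fit = n_corr / n_full
            rms = float(np.sqrt(np.mean(d * d))) if n_corr else np.inf
            if fit > best[0] or (fit == best[0] and rms < best[1]):
                best = (fit, rms)
                best_idx = start + k
                best_n_corr = n_corr
    if best_idx < 0 or best[0] < 0:
        raise DegenerateGeometryError("all SAC-IA candidates were degenerate")
    return RegistrationResult(
        transform=RigidTransform(R[best_idx], T[best_idx]),
        fitness=float(best[0]),
        rmse=float(best[1]),
        n_correspondences=best_n_corr,
        iterations=params.sacia_iterations,
        converged=best[0] > 0,
    )


def icp(
    source: PointCloud,
    target: PointCloud,
    init: RigidTransform | None = None,
    params: RegistrationParams | None = None,
) -> RegistrationResult:
    """Point-to-point ICP with inlier-distance and normal-angle gating.

    Starting from ``init`` (identity by default), alternates exact
    nearest-neighbour pairing within ``corr_dist`` — rejecting pairs whose
    normals differ by more than ``normal_angle_max`` degrees when both
    clouds carry normals — with the closed-form rigid update.  Terminates
    when the change in inlier RMS error drops below ``icp_tol`` or after
    ``icp_max_iter`` iterations.
    """
    if len(source) == 0 or len(target) == 0:
        raise ValueError("both clouds must be non-empty")
    params = params or RegistrationParams()
    current = init or RigidTransform.identity()
    tree = cKDTree(target.points)
    pts = current.apply(source.points)
    normals = (
        source.normals @ current.rotation.T if source.has_normals else None
    )
    cos_max = np.cos(np.radians(params.normal_angle_max))
    use_normals = (
        params.use_normal_rejection and normals is not None and target.has_normals
    )
    prev_err = np.inf
    converged = False
    n_iter = 0
    n_corr = 0
    trace: list[float] = []
    for n_iter in range(1, params.icp_max_iter + 1):
        d, j = tree.query(pts, k=1, distance_upper_bound=params.corr_dist)
        mask = np.isfinite(d)
        if use_normals and mask.any():
            jm = j[mask]
            cos = np.einsum("ij,ij->i", normals[mask], target.normals[jm])
            keep = cos >= cos_max
            mask[np.flatnonzero(mask)[~keep]] = False
        n_corr = int(mask.sum())
        if n_corr == 0:
            break
        err = float(np.sqrt(np.mean(d[mask] ** 2)))
        trace.append(err)
        if abs(prev_err - err) < params.icp_tol:
            converged = True
            break
        prev_err = err
        if n_corr < 3:
            break
        try:
            step = estimate_rigid_transform(pts[mask], target.points[j[mask]])
        except DegenerateGeometryError:
            break
        pts = step.apply(pts)
        if normals is not None:
            normals = normals @ step.rotation.T
        current = step.compose(current)
    moved = PointCloud(pts, label=source.label)
    fit = fitness(moved, target, params.corr_dist)
    err = rmse(moved, target, params.corr_dist)
    return RegistrationResult(
        transform=current,
        fitness=fit,
        rmse=err,
        n_correspondences=n_corr,
        iterations=n_iter,
        converged=converged,
        error_trace=trace,
    )


def register_coarse_to_fine(
    source: PointCloud,
    target: PointCloud,
    pre=None,
    reg: RegistrationParams | None = None,
) -> RegistrationResult:
    """Full stage-3 scheme: voxel downsample → FPFH → SAC-IA → ICP.

    Metrics of the returned result are computed on the full input clouds;
    the SAC-IA stage result is attached as ``result.coarse``.
    """
    from .features import compute_fpfh
    from .preprocess import PreprocessParams, estimate_normals, voxel_downsample

    if len(source) == 0 or len(target) == 0:
        raise ValueError("both clouds must be non-empty")
    pre = pre or PreprocessParams()
    reg = reg or RegistrationParams()
    ds = []
    for cloud in (source, target):
        d = voxel_downsample(cloud, pre.voxel_size)
        if not d.has_normals:
            k = min(pre.normal_k, len(d) - 1)
            d = estimate_normals(d, max(k, 3))
        ds.append(d)
    ds_s, ds_t = ds
    desc_s = compute_fpfh(ds_s, reg.fpfh_radius)
    desc_t = compute_fpfh(ds_t, reg.fpfh_radius)
    coarse = sac_ia(ds_s, ds_t, desc_s, desc_t, reg, full_source=source, full_target=target)
    log.info(
        "SAC-IA: fitness=%.4f rmse=%.4f mm (%d candidates)",
        coarse.fitness,
        coarse.rmse,
        reg.sacia_iterations,
    )
    fine = icp(source, target, coarse.transform, params=reg)
    log.info("ICP: fitness=%.4f rmse=%.4f mm (%d iterations)", fine.fitness, fine.rmse, fine.iterations)
    fine.coarse = coarse
    return fine
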