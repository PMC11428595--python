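"""Seeded synthetic dental-arch generators.

Clinical intraoral scans are private, so every stage of the pipeline is
exercised on synthetic geometry instead: a U-shaped (parabolic) dental arch
of ``n_teeth`` crowns whose sizes, positions and margin shapes jitter per
subject, giving each synthetic subject an individual crown-contour
signature of the same flavour — and the same 0–1.5 mm RMSE scale — as real
dentitions, without claiming anatomical realism.

Two cloud flavours are produced:

* :func:`generate_arch` — a full surface scan stand-in (gingiva sheet,
  spherical crown caps, and a convex torus "margin roll" around each crown
  base).  The roll's tube radius is small enough that its fitted mean
  curvature falls below the −0.6 mm⁻¹ contour threshold while caps
  (≈ −1/r_tooth) and gingiva (≈ 0) stay above it, so stage-1 extraction
  recovers one closed ring per tooth.
* :func:`generate_contour` — the idealized stage-1 output directly: one
  scalloped closed margin curve per tooth with analytic normals, used to
  test stages 2–3 in isolation.

A perturbation model emulates a repeat scan: optional regional tooth-loss
deletion, uniform dropout, Gaussian sensor noise, and a random rigid pose
change with known ground truth.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np

from .cloud import PointCloud, normalize_rows
from .registration import RigidTransform

__all__ = [
    "ArchParams",
    "PerturbationParams",
    "generate_arch",
    "generate_contour",
    "perturb",
    "build_benchmark",
    "derive_seed",
]

REGIONS = ("left_posterior", "anterior", "right_posterior")

# fixed surface-sampling spacing (mm) for generate_arch; dense enough that a
# 20-neighbour quadric fit sees a well-conditioned patch on the margin roll
_SURFACE_SPACING = 0.25
_TUBE_RADIUS = 0.55  # margin-roll tube radius (mm): |H| ≈ 1/0.55 ≈ 1.8 on the roll


@dataclass
class ArchParams:
    """Shape parameters of one synthetic subject (all lengths in mm)."""

    n_teeth: int = 14
    arch_width: float = 50.0
    arch_depth: float = 40.0
    tooth_radius_mean: float = 3.0
    tooth_radius_sd: float = 0.25
    bump_height_mean: float = 1.2
    bump_height_sd: float = 0.3
    points_per_tooth: int = 150
    subject_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_teeth < 4:
            raise ValueError("n_teeth must be >= 4")
        for name in ("arch_width", "arch_depth", "tooth_radius_mean", "bump_height_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class PerturbationParams:
    """Repeat-scan emulation: pose change, noise, dropout, regional loss."""

    max_rotation: float = 30.0
    max_translation: float = 10.0
    noise_sigma: float = 0.05
    dropout_fraction: float = 0.2
    removed_region: str | None = None
    scan_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout_fraction < 1.0):
            raise ValueError("dropout_fraction must be in [0, 1)")
        if self.removed_region is not None and self.removed_region not in REGIONS:
            raise ValueError(f"removed_region must be one of {REGIONS} or None")


def _arch_curve(params: ArchParams, n_dense: int = 2000):
    """Dense parabolic arch curve in canonical pose (opening toward −y)."""
    t = np.linspace(-1.0, 1.0, n_dense)
    x = 0.5 * params.arch_width * t
    y = 0.5 * params.arch_depth - params.arch_depth * t * t
    return np.column_stack([x, y])


def _tooth_frames(params: ArchParams):
    """Arc-length-uniform tooth centres + unit tangent per tooth."""
    curve = _arch_curve(params)
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    # centre each tooth in its arc-length slot
    targets = (np.arange(params.n_teeth) + 0.5) / params.n_teeth * total
    centers = np.column_stack(
        [np.interp(targets, s, curve[:, 0]), np.interp(targets, s, curve[:, 1])]
    )
    ahead = np.column_stack(
        [
            np.interp(targets + 0.5, s, curve[:, 0]),
            np.interp(targets + 0.5, s, curve[:, 1]),
        ]
    )
    tangents = normalize_rows(ahead - centers)
    return centers, tangents


def _subject_teeth(params: ArchParams, rng: np.random.Generator):
    """Per-tooth randomized shape: radius, undulation, jitter, harmonics."""
    n = params.n_teeth
    radii = np.maximum(0.8, rng.normal(params.tooth_radius_mean, params.tooth_radius_sd, n))
    undulation = np.maximum(0.1, rng.normal(params.bump_height_mean, params.bump_height_sd, n))
    jitter = rng.normal(0.0, params.tooth_radius_sd, size=(n, 3))
    ecc = rng.normal(0.0, 0.06, n)  # ellipse eccentricity of the margin ring
    harm_amp = rng.normal(0.0, 0.05, size=(n, 2))
    harm_phase = rng.uniform(0.0, 2 * np.pi, size=(n, 3))
    return radii, undulation, jitter, ecc, harm_amp, harm_phase


def generate_contour(params: ArchParams) -> PointCloud:
    """Idealized crown-contour cloud: one closed margin ring per tooth.

    Each ring is an ellipse-like curve around its tooth centre with
    per-subject radial harmonics and a scalloped vertical undulation, and
    carries outward-tilted unit normals.  Deterministic in
    ``params.subject_seed``; labelled ``subject_<seed>``.
    """
    rng = np.random.default_rng(params.subject_seed)
    centers, tangents = _tooth_frames(params)
    radii, undulation, jitter, ecc, harm_amp, harm_phase = _subject_teeth(params, rng)
    normals_xy90 = np.column_stack([-tangents[:, 1], tangents[:, 0]])  # ring e2 axis
    pts, nrm = [], []
    psi = np.linspace(0.0, 2 * np.pi, params.points_per_tooth, endpoint=False)
    for i in range(params.n_teeth):
        e1 = np.array([tangents[i, 0], tangents[i, 1], 0.0])
        e2 = np.array([normals_xy90[i, 0], normals_xy90[i, 1], 0.0])
        c = np.array([centers[i, 0], centers[i, 1], 0.0]) + jitter[i]
        rho = radii[i] * (
            1.0
            + harm_amp[i, 0] * np.cos(2 * psi + harm_phase[i, 0])
            + harm_amp[i, 1] * np.cos(3 * psi + harm_phase[i, 1])
        )
        a = rho * (1.0 + ecc[i])
        b = rho * (1.0 - ecc[i])
        z = 0.5 * undulation[i] * np.sin(2 * psi + harm_phase[i, 2])
        ring = (
            c
            + a[:, None] * np.cos(psi)[:, None] * e1
            + b[:, None] * np.sin(psi)[:, None] * e2
            + z[:, None] * np.array([0.0, 0.0, 1.0])
        )
        radial = normalize_rows(
            np.cos(psi)[:, None] * e1 + np.sin(psi)[:, None] * e2
        )
        tilt = 0.15 * np.sin(2 * psi + harm_phase[i, 2])
        n = radial * (0.8 + tilt[:, None]) + np.array([0.0, 0.0, 0.6])
        pts.append(ring)
        nrm.append(normalize_rows(n))
    return PointCloud(
        np.vstack(pts), np.vstack(nrm), label=f"subject_{params.subject_seed}"
    )


def _sample_grid(rng: np.random.Generator, extent_u, extent_v, spacing):
    """Jittered 2-D grid covering [0,extent_u]×[0,extent_v]."""
    nu = max(1, int(np.ceil(extent_u / spacing)))
    nv = max(1, int(np.ceil(extent_v / spacing)))
    u, v = np.meshgrid(
        (np.arange(nu) + 0.5) * extent_u / nu, (np.arange(nv) + 0.5) * extent_v / nv
    )
    u = u.ravel() + rng.uniform(-0.2, 0.2, u.size) * extent_u / nu
    v = v.ravel() + rng.uniform(-0.2, 0.2, v.size) * extent_v / nv
    return u, v


def generate_arch(params: ArchParams) -> PointCloud:
    """Full synthetic arch surface with analytic unit normals.

    Composition per tooth: a spherical crown cap (mean curvature ≈ −1/r,
    above the −0.6 threshold) ringed by a convex margin roll (quarter-torus
    tube, fitted curvature ≈ −1 mm⁻¹, below the threshold), all sitting on
    a flat gingiva sheet (curvature ≈ 0).  Thresholding the fitted mean
    curvature at −0.6 therefore extracts one concave-looking ring per
    crown.  Deterministic in ``params.subject_seed``.
    """
    rng = np.random.default_rng(params.subject_seed)
    centers, _ = _tooth_frames(params)
    radii, _, jitter, _, _, _ = _subject_teeth(params, rng)
    centers = centers + jitter[:, :2] * 0.5
    spacing = _SURFACE_SPACING
    rt = _TUBE_RADIUS
    pts, nrm = [], []
    for i in range(params.n_teeth):
        r = radii[i]
        c = np.array([centers[i, 0], centers[i, 1], 0.0])
        # crown cap: sphere of radius r centred on the gingiva plane, sampled
        # row-by-row from the pole down to just above the margin roll so the
        # spacing is ~uniform in arc length in both directions
        polar_max = np.arccos(min(1.0, 1.6 * rt / r))
        n_rows = max(2, int(np.ceil(polar_max * r / spacing)))
        for row in range(n_rows):
            u = (row + 0.5) / n_rows * polar_max
            circ = 2 * np.pi * r * np.sin(u)
            n_col = max(4, int(np.ceil(circ / spacing)))
            v = (np.arange(n_col) + rng.uniform(0.0, 1.0)) / n_col * 2 * np.pi
            uj = u + rng.uniform(-0.3, 0.3, n_col) * polar_max / n_rows
            dirs = np.column_stack(
                [np.sin(uj) * np.cos(v), np.sin(uj) * np.sin(v), np.cos(uj)]
            )
            pts.append(c + r * dirs)
            nrm.append(dirs)
        # margin roll: upper part of a torus tube hugging the crown base
        R_ring = r + 0.55 * rt
        tau_lo, tau_hi = np.radians(15.0), np.radians(160.0)
        n_rows = max(3, int(np.ceil((tau_hi - tau_lo) * rt / spacing)))
        for row in range(n_rows):
            tau = tau_lo + (row + 0.5) / n_rows * (tau_hi - tau_lo)
            ring_r = R_ring + rt * np.cos(tau)
            n_col = max(8, int(np.ceil(2 * np.pi * ring_r / spacing)))
            v = (np.arange(n_col) + rng.uniform(0.0, 1.0)) / n_col * 2 * np.pi
            tj = tau + rng.uniform(-0.3, 0.3, n_col) * (tau_hi - tau_lo) / n_rows
            n_roll = np.column_stack(
                [np.cos(tj) * np.cos(v), np.cos(tj) * np.sin(v), np.sin(tj)]
            )
            ring = np.column_stack(
                [
                    (R_ring + rt * np.cos(tj)) * np.cos(v),
                    (R_ring + rt * np.cos(tj)) * np.sin(v),
                    rt * np.sin(tj) - 0.45 * rt,
                ]
            )
            pts.append(c + ring)
            nrm.append(n_roll)
    # gingiva sheet: band around the arch curve, holes under the teeth
    curve = _arch_curve(params, 400)
    band = 2.0 * (params.tooth_radius_mean + 2.0)
    lo = curve.min(axis=0) - band / 2
    hi = curve.max(axis=0) + band / 2
    u, v = _sample_grid(rng, hi[0] - lo[0], hi[1] - lo[1], spacing * 1.6)
    sheet = np.column_stack([lo[0] + u, lo[1] + v])
    d_curve = np.min(
        np.linalg.norm(sheet[:, None, :] - curve[None, ::8, :], axis=2), axis=1
    )
    keep = d_curve < band / 2
    d_teeth = np.min(
        np.linalg.norm(sheet[:, None, :] - centers[None, :, :], axis=2)
        - (radii[None, :] + 1.35 * rt),
        axis=1,
    )
    keep &= d_teeth > 0.1
    sheet = sheet[keep]
    pts.append(np.column_stack([sheet, np.full(len(sheet), -0.45 * rt)]))
    nrm.append(np.tile([0.0, 0.0, 1.0], (len(sheet), 1)))
    return PointCloud(
        np.vstack(pts), np.vstack(nrm), label=f"subject_{params.subject_seed}"
    )


def _sector_masks(points: np.ndarray, anterior_half_angle_deg: float = 30.0):
    """Angular-sector membership about the cloud centroid (canonical pose);
    the same geometry rule used by subregion segmentation."""
    rel = points - points.mean(axis=0)
    ang = np.degrees(np.arctan2(np.abs(rel[:, 0]), np.abs(rel[:, 1])))
    anterior = ang <= anterior_half_angle_deg
    return {
        "anterior": anterior,
        "left_posterior": ~anterior & (rel[:, 0] < 0),
        "right_posterior": ~anterior & (rel[:, 0] >= 0),
    }


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_deg))
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def perturb(
    cloud: PointCloud, params: PerturbationParams
) -> tuple[PointCloud, RigidTransform]:
    """Emulate a repeat scan of ``cloud``.

    Applies, in order: angular-sector regional deletion (if requested),
    uniform random dropout of ``floor(n · dropout_fraction)`` points without
    replacement, i.i.d. Gaussian coordinate noise, and a random rigid pose
    change with rotation angle ≤ ``max_rotation`` and translation norm
    ≤ ``max_translation``.  Returns the perturbed cloud and the exact
    applied transform; deterministic in ``scan_seed``.
    """
    rng = np.random.default_rng(params.scan_seed)
    out = cloud.copy()
    if params.removed_region is not None:
        masks = _sector_masks(out.points)
        out = out.select(~masks[params.removed_region])
    n = len(out)
    n_drop = int(np.floor(n * params.dropout_fraction))
    if n_drop > 0:
        drop = rng.choice(n, size=n_drop, replace=False)
        keep = np.ones(n, dtype=bool)
        keep[drop] = False
        out = out.select(keep)
    if len(out) < 10:
        raise ValueError("perturbation left fewer than 10 points")
    if params.noise_sigma > 0:
        out = PointCloud(
            out.points + rng.normal(0.0, params.noise_sigma, out.points.shape),
            out.normals,
            out.label,
        )
    if params.max_rotation > 0 or params.max_translation > 0:
        R = _random_rotation(rng, params.max_rotation)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        T = direction * rng.uniform(0.0, params.max_translation)
    else:
        R, T = np.eye(3), np.zeros(3)
    transform = RigidTransform(R, T)
    return out.transformed(R, T), transform


def derive_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary labelled parts."""
    key = "|".join(str(p) for p in parts)
    return zlib.crc32(key.encode()) & 0x7FFFFFFF


def build_benchmark(
    n_subjects: int,
    arch_base: ArchParams | None = None,
    pert: PerturbationParams | None = None,
    master_seed: int = 42,
):
    """Gallery/query identification benchmark, fully seeded.

    Generates ``n_subjects`` contour clouds (gallery), perturbs each into a
    repeat-scan query, and returns ``(gallery, queries, truth,
    transforms)`` where ``truth`` maps query label → gallery label and
    ``transforms`` maps query label → the applied ground-truth pose change.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    arch_base = arch_base or ArchParams()
    pert = pert or PerturbationParams()
    gallery, queries, truth, transforms = [], [], {}, {}
    for i in range(n_subjects):
        subject_seed = derive_seed(master_seed, "subject", i)
        g = generate_contour(replace(arch_base, subject_seed=subject_seed))
        g.label = f"subject{i:03d}"
        scan_seed = derive_seed(master_seed, "scan", i)
        q, tf = perturb(g, replace(pert, scan_seed=scan_seed))
        q.label = f"subject{i:03d}_q"
        gallery.append(g)
        queries.append(q)
        truth[q.label] = g.label
        transforms[q.label] = tf
    return gallery, queries, truth, transforms
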