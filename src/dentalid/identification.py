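"""Stage 3 harness — registration-based identity assignment and reporting.

A query scan is registered against every gallery entry with the
coarse-to-fine scheme; the gallery subject with the smallest RMSE is the
assigned identity.  RMSE decides because genuine and impostor fitness
distributions overlap while the RMSE distributions separate; fitness is
reported and used only as a tie-breaker.  The harness also produces the
standard biometric bookkeeping: query×gallery score matrices, Rank-k
(CMC) rates, and genuine/impostor distribution statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .cloud import PointCloud
from .features import compute_fpfh
from .preprocess import PreprocessParams, estimate_normals, voxel_downsample
from .registration import RegistrationParams, icp, sac_ia
from .synthetic import derive_seed

__all__ = [
    "ScoreMatrix",
    "IdentificationReport",
    "identify",
    "score_matrix",
    "rank_k_rate",
    "genuine_impostor_stats",
    "export_pixmap",
]


@dataclass
class ScoreMatrix:
    """Query×gallery RMSE (mm, +inf allowed) and fitness matrices."""

    query_ids: list[str]
    gallery_ids: list[str]
    rmse: np.ndarray
    fitness: np.ndarray

    def __post_init__(self) -> None:
        self.rmse = np.asarray(self.rmse, dtype=np.float64)
        self.fitness = np.asarray(self.fitness, dtype=np.float64)
        shape = (len(self.query_ids), len(self.gallery_ids))
        if self.rmse.shape != shape or self.fitness.shape != shape:
            raise ValueError("matrix shapes must match id lists")
        finite = self.fitness[np.isfinite(self.fitness)]
        if np.any(finite < 0) or np.any(finite > 1):
            raise ValueError("fitness entries must lie in [0, 1]")

    def to_csv(self, path_rmse: str | Path, path_fitness: str | Path) -> None:
        for mat, path in ((self.rmse, path_rmse), (self.fitness, path_fitness)):
            pd.DataFrame(mat, index=self.query_ids, columns=self.gallery_ids).to_csv(path)

    @classmethod
    def from_csv(cls, path_rmse: str | Path, path_fitness: str | Path) -> "ScoreMatrix":
        r = pd.read_csv(path_rmse, index_col=0)
        f = pd.read_csv(path_fitness, index_col=0)
        if list(r.index) != list(f.index) or list(r.columns) != list(f.columns):
            raise ValueError("rmse and fitness files disagree on ids")
        return cls(list(r.index), list(r.columns), r.to_numpy(), f.to_numpy())

    def row_ranking(self, i: int) -> np.ndarray:
        """Gallery order for query row ``i``: RMSE asc, fitness desc, label asc."""
        labels = np.asarray(self.gallery_ids)
        return np.lexsort((labels, -self.fitness[i], self.rmse[i]))


@dataclass
class IdentificationReport:
    """Ranked identities, Rank-k (CMC) rates, genuine/impostor statistics."""

    ranked: dict[str, list[str]]
    rank_k_rates: dict[int, float]
    genuine: dict[str, float]
    impostor: dict[str, float]
    n_genuine_pairs: int
    n_impostor_pairs: int

    def to_text(self) -> str:
        lines = [
            f"The number of query models\t{len(self.ranked)}",
            f"Genuine match pairs\t{self.n_genuine_pairs}",
            f"Impostor match pairs\t{self.n_impostor_pairs}",
        ]
        for k in sorted(self.rank_k_rates):
            lines.append(f"Rank-{k} recognition rate\t{self.rank_k_rates[k] * 100:.2f}%")
        for part, stats in (("Genuine", self.genuine), ("Impostor", self.impostor)):
            for metric in ("rmse", "fitness"):
                for agg in ("maximum", "minimum", "average"):
                    key = f"{metric}_{agg[:3]}"
                    unit = " (mm)" if metric == "rmse" else ""
                    val = stats.get(key, float("nan"))
                    lines.append(
                        f"{part} match {metric.upper() if metric == 'rmse' else metric.capitalize()}"
                        f" {agg}{unit}\t{val:.3f}"
                    )
        return "\n".join(lines) + "\n"


def _prepared(cloud: PointCloud, pre: PreprocessParams, reg: RegistrationParams):
    """Downsampled cloud + FPFH descriptors (the per-cloud invariant part)."""
    d = voxel_downsample(cloud, pre.voxel_size)
    if not d.has_normals:
        d = estimate_normals(d, max(min(pre.normal_k, len(d) - 1), 3))
    return d, compute_fpfh(d, reg.fpfh_radius)


def _register_pair(query, gallery, q_prep, g_prep, reg):
    coarse = sac_ia(
        q_prep[0], g_prep[0], q_prep[1], g_prep[1], reg,
        full_source=query, full_target=gallery,
    )
    fine = icp(query, gallery, coarse.transform, params=reg)
    fine.coarse = coarse
    return fine


def identify(
    query: PointCloud,
    gallery: list[PointCloud],
    pre: PreprocessParams | None = None,
    reg: RegistrationParams | None = None,
) -> list[tuple[str, float, float]]:
    """Register ``query`` against every gallery entry; rank by RMSE.

    Returns ``(gallery label, rmse, fitness)`` tuples sorted ascending by
    RMSE (ties: fitness descending, then label); the top entry is the
    assigned identity.  Per-pair random streams are derived from
    ``reg.seed`` and the pair's labels, so evaluation order cannot change
    the outcome.
    """
    if not gallery:
        raise ValueError("gallery must be non-empty")
    if any(g.label is None for g in gallery):
        raise ValueError("every gallery entry must be labelled")
    pre = pre or PreprocessParams()
    reg = reg or RegistrationParams()
    q_prep = _prepared(query, pre, reg)
    rows = []
    for g in gallery:
        pair_reg = replace(reg, seed=derive_seed(reg.seed, query.label, g.label))
        res = _register_pair(query, g, q_prep, _prepared(g, pre, reg), pair_reg)
        rows.append((g.label, res.rmse, res.fitness))
    rows.sort(key=lambda r: (r[1], -r[2], r[0]))
    return rows


def score_matrix(
    queries: list[PointCloud],
    gallery: list[PointCloud],
    pre: PreprocessParams | None = None,
    reg: RegistrationParams | None = None,
    progress: bool = False,
) -> ScoreMatrix:
    """Full query×gallery grid of registrations.

    Element (i, j) holds the RMSE/fitness of registering query i to gallery
    j.  Deterministic for a fixed ``reg.seed`` regardless of evaluation
    order (per-pair seeds are derived from the global seed and the labels).
    """
    if not queries or not gallery:
        raise ValueError("queries and gallery must be non-empty")
    pre = pre or PreprocessParams()
    reg = reg or RegistrationParams()
    g_preps = [_prepared(g, pre, reg) for g in gallery]
    n_q, n_g = len(queries), len(gallery)
    rmse_m = np.zeros((n_q, n_g))
    fit_m = np.zeros((n_q, n_g))
    for i, q in enumerate(queries):
        q_prep = _prepared(q, pre, reg)
        for j, g in enumerate(gallery):
            pair_reg = replace(reg, seed=derive_seed(reg.seed, q.label, g.label))
            res = _register_pair(q, g, q_prep, g_preps[j], pair_reg)
            rmse_m[i, j] = res.rmse
            fit_m[i, j] = res.fitness
        if progress:
            print(f"query {i + 1}/{n_q} ({q.label}) done", flush=True)
    return ScoreMatrix(
        [q.label for q in queries], [g.label for g in gallery], rmse_m, fit_m
    )


def _check_truth(matrix: ScoreMatrix, truth: dict[str, str]) -> None:
    gal = set(matrix.gallery_ids)
    for q in matrix.query_ids:
        if q not in truth:
            raise ValueError(f"no truth entry for query {q!r}")
        if truth[q] not in gal:
            raise ValueError(f"truth identity {truth[q]!r} for query {q!r} absent from gallery")


def rank_k_rate(matrix: ScoreMatrix, truth: dict[str, str], k: int = 1) -> float:
    """Fraction of queries whose true identity is among the k best-ranked
    (smallest-RMSE) gallery entries of their row."""
    _check_truth(matrix, truth)
    if k < 1:
        raise ValueError("k must be >= 1")
    hits = 0
    gallery = np.asarray(matrix.gallery_ids)
    for i, q in enumerate(matrix.query_ids):
        top = gallery[matrix.row_ranking(i)[:k]]
        hits += truth[q] in top
    return hits / len(matrix.query_ids)


def genuine_impostor_stats(
    matrix: ScoreMatrix, truth: dict[str, str], n_bins: int = 50
) -> IdentificationReport:
    """Partition all pairs into genuine/impostor and summarize both.

    Emits min/max/mean of RMSE and fitness per partition (computed over
    finite entries), distribution histograms, per-query rankings, and the
    Rank-k rate for every k up to the gallery size.
    """
    _check_truth(matrix, truth)
    gallery = np.asarray(matrix.gallery_ids)
    genuine_mask = np.array(
        [[truth[q] == g for g in matrix.gallery_ids] for q in matrix.query_ids]
    )
    ranked = {}
    for i, q in enumerate(matrix.query_ids):
        ranked[q] = list(gallery[matrix.row_ranking(i)])
    n_g = len(matrix.gallery_ids)
    ranks = {}
    for k in range(1, n_g + 1):
        ranks[k] = float(
            np.mean([truth[q] in ranked[q][:k] for q in matrix.query_ids])
        )

    def summary(mask):
        out = {}
        for name, mat in (("rmse", matrix.rmse), ("fitness", matrix.fitness)):
            vals = mat[mask]
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                out.update({f"{name}_max": np.nan, f"{name}_min": np.nan, f"{name}_ave": np.nan})
                out[f"{name}_hist"] = (np.zeros(n_bins), np.linspace(0, 1, n_bins + 1))
                continue
            out[f"{name}_max"] = float(vals.max())
            out[f"{name}_min"] = float(vals.min())
            out[f"{name}_ave"] = float(vals.mean())
            counts, edges = np.histogram(vals, bins=n_bins)
            out[f"{name}_hist"] = (counts, edges)
        return out

    return IdentificationReport(
        ranked=ranked,
        rank_k_rates=ranks,
        genuine=summary(genuine_mask),
        impostor=summary(~genuine_mask),
        n_genuine_pairs=int(genuine_mask.sum()),
        n_impostor_pairs=int((~genuine_mask).sum()),
    )


def export_pixmap(matrix: ScoreMatrix, which: str, out: str | Path) -> None:
    """Write the score matrix as a grayscale image, one pixel per cell.

    Entries are min–max scaled to 0–255 (infinite RMSE entries are capped
    to their row's finite maximum first); a constant matrix maps to 0.
    """
    if which not in ("rmse", "fitness"):
        raise ValueError("which must be 'rmse' or 'fitness'")
    mat = (matrix.rmse if which == "rmse" else matrix.fitness).copy()
    for i in range(mat.shape[0]):
        row = mat[i]
        bad = ~np.isfinite(row)
        if bad.any():
            finite = row[~bad]
            row[bad] = finite.max() if len(finite) else 0.0
    lo, hi = mat.min(), mat.max()
    if hi - lo <= 0:
        scaled = np.zeros_like(mat)
    else:
        scaled = (mat - lo) / (hi - lo) * 255.0
    Image.fromarray(scaled.round().astype(np.uint8), mode="L").save(out)
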