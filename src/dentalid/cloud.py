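"""Core point-cloud container shared by every pipeline stage.

Coordinates are millimetres throughout; no unit metadata is stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PointCloud"]

_NORMAL_TOL = 1e-6


@dataclass
class PointCloud:
    """An ordered set of 3D points with optional unit normals and a label.

    Parameters
    ----------
    points
        ``(n, 3)`` float array of coordinates in mm.
    normals
        Optional ``(n, 3)`` array of unit vectors, aligned index-for-index
        with ``points``.
    label
        Optional subject/sample identifier carried through the pipeline.
    """

    points: np.ndarray
    normals: np.ndarray | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"points must be (n, 3), got {self.points.shape}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("points contain non-finite coordinates")
        if self.normals is not None:
            self.normals = np.ascontiguousarray(self.normals, dtype=np.float64)
            if self.normals.shape != self.points.shape:
                raise ValueError(
                    "normals shape %s does not match points shape %s"
                    % (self.normals.shape, self.points.shape)
                )
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.all(np.abs(norms - 1.0) <= 1e-4):
                raise ValueError("normals must be unit length")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_normals(self) -> bool:
        return self.normals is not None

    def select(self, index: np.ndarray) -> "PointCloud":
        """Sub-cloud at integer or boolean ``index``, order preserved."""
        normals = self.normals[index] if self.normals is not None else None
        return PointCloud(self.points[index], normals, self.label)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "PointCloud":
        """Rigidly transformed copy; normals rotate, points rotate + translate."""
        pts = self.points @ np.asarray(rotation).T + np.asarray(translation)
        normals = self.normals @ np.asarray(rotation).T if self.normals is not None else None
        return PointCloud(pts, normals, self.label)

    def copy(self) -> "PointCloud":
        normals = None if self.normals is None else self.normals.copy()
        return PointCloud(self.points.copy(), normals, self.label)


def normalize_rows(v: np.ndarray) -> np.ndarray:
    """Rows scaled to unit length; zero rows raise."""
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(n == 0):
        raise ValueError("cannot normalize zero-length vector")
    return v / n
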