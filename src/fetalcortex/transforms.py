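"""Planar rigid transforms for slice-to-slice alignment.

Coordinate convention: pixel indices are 0-based ``(row, col)``; internally
transforms act on homogeneous ``(x, y) = (col, row)`` coordinates, matching
``skimage.transform``. Rotations are counterclockwise in degrees about the
image centre unless an explicit centre is given.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktf


def _rotation_matrix(rotation_deg: float, tx: float, ty: float,
                     center: tuple[float, float]) -> np.ndarray:
    th = np.deg2rad(rotation_deg)
    c, s = np.cos(th), np.sin(th)
    cx, cy = center
    m = np.eye(3)
    m[0, 0], m[0, 1] = c, -s
    m[1, 0], m[1, 1] = s, c
    # rotate about (cx, cy), then translate
    m[0, 2] = cx - c * cx + s * cy + tx
    m[1, 2] = cy - s * cx - c * cy + ty
    return m


@dataclass(frozen=True)
class RigidTransform2D:
    """Rotation + translation in the section plane.

    ``matrix`` maps source (x, y, 1) to destination coordinates.  Use
    :meth:`from_params` to build from a rotation angle (degrees, CCW about
    ``center``) and a pixel translation ``(tx, ty)`` in (col, row) order.
    """

    matrix: np.ndarray = field(default_factory=lambda: np.eye(3))

    @classmethod
    def identity(cls) -> "RigidTransform2D":
        return cls(np.eye(3))

    @classmethod
    def from_params(cls, rotation_deg: float, tx: float, ty: float,
                    center: tuple[float, float] = (0.0, 0.0)) -> "RigidTransform2D":
        return cls(_rotation_matrix(rotation_deg, tx, ty, center))

    @property
    def rotation_deg(self) -> float:
        return float(np.rad2deg(np.arctan2(self.matrix[1, 0], self.matrix[0, 0])))

    def translation(self, center: tuple[float, float] = (0.0, 0.0)) -> tuple[float, float]:
        """Translation component w.r.t. a rotation about ``center``."""
        pure = _rotation_matrix(self.rotation_deg, 0.0, 0.0, center)
        return (float(self.matrix[0, 2] - pure[0, 2]),
                float(self.matrix[1, 2] - pure[1, 2]))

    def compose(self, other: "RigidTransform2D") -> "RigidTransform2D":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform2D(self.matrix @ other.matrix)

    def __matmul__(self, other: "RigidTransform2D") -> "RigidTransform2D":
        return self.compose(other)

    def inverse(self) -> "RigidTransform2D":
        return RigidTransform2D(np.linalg.inv(self.matrix))

    def apply_points(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        ones = np.ones((*xy.shape[:-1], 1))
        h = np.concatenate([xy, ones], axis=-1)
        out = h @ self.matrix.T
        return out[..., :2]

    def apply_image(self, image: np.ndarray, *, order: int = 1,
                    cval: float = 0.0) -> np.ndarray:
        """Warp ``image`` forward by this transform.

        ``order=1`` bilinear for intensity images, ``order=0`` nearest
        neighbour for label rasters (label vocabulary preserved exactly).
        """
        tf = sktf.ProjectiveTransform(matrix=np.linalg.inv(self.matrix))
        out = sktf.warp(image.astype(float), tf, order=order, cval=cval,
                        preserve_range=True)
        if np.issubdtype(image.dtype, np.integer):
            out = np.rint(out).astype(image.dtype)
        return out


def image_center(shape: tuple[int, ...]) -> tuple[float, float]:
    """Centre of an image in (x, y) = (col, row) coordinates."""
    h, w = shape[:2]
    return ((w - 1) / 2.0, (h - 1) / 2.0)
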