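"""Core in-memory data model for 4D-flow analysis.

Conventions used everywhere in this package:

* Array axis order is ``(timeframe, z, y, x[, component])``, 0-based.
* The component axis holds ``(vx, vy, vz)`` in world coordinates.
* World coordinates are millimetres, voxel-*center* convention: voxel
  index ``(iz, iy, ix)`` sits at ``origin + (ix*dx, iy*dy, iz*dz)`` where
  ``origin`` is the world position of voxel (0, 0, 0).
* Velocities are stored in cm/s (the unit VENC is quoted in); the particle
  tracer converts to mm/ms internally.
* Time is periodic over the cardiac cycle: frame ``k`` represents time
  ``k * timeframe_duration`` ms, and frame ``nt`` wraps to frame 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "VelocityField4D",
    "SegmentationSet",
    "ValvePlane",
    "PlanarROI",
    "FlowCurve",
    "plane_basis",
]


@dataclass
class VelocityField4D:
    """Periodic time-resolved three-component velocity volume.

    Parameters
    ----------
    velocities
        Array of shape ``(nt, nz, ny, nx, 3)`` in cm/s; components are
        ``(vx, vy, vz)`` in world axes.
    spacing
        Voxel edge lengths ``(dz, dy, dx)`` in mm, aligned with the array
        axes.
    timeframe_duration
        Duration of one reconstructed heart phase in ms (cycle length / nt).
    venc
        Velocity-encoding limit in cm/s.  Stored velocities alias by
        multiples of ``2 * venc``; magnitudes may exceed ``venc`` only
        after unwrapping.
    origin
        World position (x, y, z) in mm of the center of voxel (0, 0, 0).
    """

    velocities: np.ndarray
    spacing: tuple[float, float, float]
    timeframe_duration: float
    venc: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=np.float64)
        if self.velocities.ndim != 5 or self.velocities.shape[-1] != 3:
            raise ValueError(
                f"velocities must have shape (nt, nz, ny, nx, 3), "
                f"got {self.velocities.shape}"
            )
        if self.velocities.shape[0] < 2:
            raise ValueError("need at least 2 timeframes")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if self.timeframe_duration <= 0:
            raise ValueError("timeframe_duration must be positive")
        if self.venc <= 0:
            raise ValueError("venc must be positive")
        self.origin = tuple(float(o) for o in self.origin)

    # -- derived geometry ---------------------------------------------------

    @property
    def nt(self) -> int:
        return self.velocities.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """Spatial shape (nz, ny, nx)."""
        return self.velocities.shape[1:4]

    @property
    def cycle_length(self) -> float:
        """Cardiac cycle length in ms."""
        return self.nt * self.timeframe_duration

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm^3 (product of spacings)."""
        dz, dy, dx = self.spacing
        return dz * dy * dx

    def frame_times(self) -> np.ndarray:
        """Times (ms) represented by each frame."""
        return np.arange(self.nt) * self.timeframe_duration

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """1-D world coordinates (x, y, z) of voxel centers along each axis."""
        nz, ny, nx = self.grid_shape
        dz, dy, dx = self.spacing
        x0, y0, z0 = self.origin
        return (
            x0 + dx * np.arange(nx),
            y0 + dy * np.arange(ny),
            z0 + dz * np.arange(nz),
        )

    def world_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (z, y, x)-shaped world coordinate arrays X, Y, Z."""
        xs, ys, zs = self.voxel_centers()
        Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
        return X, Y, Z

    def copy(self) -> "VelocityField4D":
        return VelocityField4D(
            self.velocities.copy(),
            self.spacing,
            self.timeframe_duration,
            self.venc,
            self.origin,
        )


@dataclass
class SegmentationSet:
    """Per-timeframe binary left-ventricular masks on the velocity grid.

    ``ed_index`` / ``es_index`` are the timeframes of maximal / minimal
    segmented LV volume (end-diastole / end-systole).  When not supplied
    they are derived with :meth:`from_masks`.
    """

    lv_masks: np.ndarray  # (nt, nz, ny, nx) bool
    ed_index: int
    es_index: int

    def __post_init__(self) -> None:
        self.lv_masks = np.asarray(self.lv_masks, dtype=bool)
        if self.lv_masks.ndim != 4:
            raise ValueError("lv_masks must have shape (nt, nz, ny, nx)")
        nt = self.lv_masks.shape[0]
        if not (0 <= self.ed_index < nt and 0 <= self.es_index < nt):
            raise ValueError("ed/es indices out of range")
        counts = self.lv_masks.reshape(nt, -1).sum(axis=1)
        if counts[self.ed_index] < counts[self.es_index]:
            raise ValueError("ED mask volume must be >= ES mask volume")

    @classmethod
    def from_masks(cls, lv_masks: np.ndarray) -> "SegmentationSet":
        """Build a set with ED/ES found as argmax/argmin of mask volume."""
        lv_masks = np.asarray(lv_masks, dtype=bool)
        counts = lv_masks.reshape(lv_masks.shape[0], -1).sum(axis=1)
        return cls(lv_masks, int(np.argmax(counts)), int(np.argmin(counts)))

    def volumes_ml(self, voxel_volume: float) -> np.ndarray:
        """Mask volume per timeframe in ml given the voxel volume in mm^3."""
        counts = self.lv_masks.reshape(self.lv_masks.shape[0], -1).sum(axis=1)
        return counts * voxel_volume / 1000.0


def _unit(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length normal")
    return v / n


@dataclass
class ValvePlane:
    """Oriented valve plane used to classify particle fates.

    ``normal`` is a unit vector pointing toward the *basal* side (atrium
    for the mitral plane, aorta for the aortic plane): a particle at world
    position ``y`` is basal iff ``(y - point) . normal >= 0``.
    """

    point: np.ndarray
    normal: np.ndarray
    label: Literal["mitral", "aortic"]

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=np.float64)
        self.normal = np.asarray(self.normal, dtype=np.float64)
        if self.point.shape != (3,) or self.normal.shape != (3,):
            raise ValueError("point and normal must be 3-vectors")
        if abs(np.linalg.norm(self.normal) - 1.0) > 1e-9:
            raise ValueError("normal must be a unit vector (|n| = 1 within 1e-9)")
        if self.label not in ("mitral", "aortic"):
            raise ValueError(f"unknown valve label {self.label!r}")

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        """Signed distance of points (N, 3) to the plane; positive = basal."""
        return (np.atleast_2d(points) - self.point) @ self.normal


def plane_basis(normal: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal in-plane basis (e1, e2) for a plane normal.

    e1 is the normalized projection of the world axis least aligned with the
    normal; e2 = normal x e1.  (e1, e2, normal) is right-handed.
    """
    n = _unit(normal)
    axis = np.eye(3)[int(np.argmin(np.abs(n)))]
    e1 = axis - np.dot(axis, n) * n
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    return e1, e2


@dataclass
class PlanarROI:
    """Planar region of interest with one closed contour per timeframe.

    The plane is given by a point and unit normal in world mm.  Contours
    are simple closed polygons in 2-D plane coordinates (mm) relative to
    ``point``, expressed in the basis from :func:`plane_basis`.
    """

    point: np.ndarray
    normal: np.ndarray
    contours: list[np.ndarray]  # one (K, 2) polygon per timeframe

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=np.float64)
        self.normal = _unit(self.normal)
        self.contours = [np.asarray(c, dtype=np.float64) for c in self.contours]
        for i, c in enumerate(self.contours):
            if c.ndim != 2 or c.shape[1] != 2 or c.shape[0] < 3:
                raise ValueError(f"contour {i} must be (K>=3, 2)")
            if _polygon_self_intersects(c):
                raise ValueError(f"contour {i} is self-intersecting")

    @property
    def nt(self) -> int:
        return len(self.contours)

    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        return plane_basis(self.normal)

    def contour_world(self, t: int) -> np.ndarray:
        """Contour at timeframe t as (K, 3) world coordinates."""
        e1, e2 = self.basis()
        c = self.contours[t]
        return self.point + c[:, :1] * e1 + c[:, 1:2] * e2


def _segments_cross(p1, p2, q1, q2) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(q1, q2, p1), orient(q1, q2, p2)
    d3, d4 = orient(p1, p2, q1), orient(p1, p2, q2)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _polygon_self_intersects(poly: np.ndarray) -> bool:
    """True if any two non-adjacent edges of the closed polygon cross."""
    k = len(poly)
    edges = [(poly[i], poly[(i + 1) % k]) for i in range(k)]
    for i in range(k):
        for j in range(i + 2, k):
            if i == 0 and j == k - 1:  # adjacent through closure
                continue
            if _segments_cross(*edges[i], *edges[j]):
                return True
    return False


@dataclass
class FlowCurve:
    """Scalar per-timeframe series (flux in ml/s or KE in mJ)."""

    values: np.ndarray
    timeframe_duration: float
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ValueError("values must be 1-D (one per timeframe)")
        if self.timeframe_duration <= 0:
            raise ValueError("timeframe_duration must be positive")

    @property
    def nt(self) -> int:
        return len(self.values)

    def integral(self) -> float:
        """Rectangle-rule integral over the cycle (value units x seconds)."""
        return float(self.values.sum() * self.timeframe_duration / 1000.0)
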