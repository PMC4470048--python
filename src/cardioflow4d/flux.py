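"""Stroke volume from through-plane flux on 2D flow series and 4D planes.

Stroke volume is measured the way it is done clinically: a vessel ROI is
delineated over time on a through-plane velocity image series, the flux is
the sum of velocity times pixel area over pixels inside the contour, and
SV is the time integral of the flux over the cardiac cycle (rectangle rule
with the timeframe duration, matching retrospective reconstruction
semantics).  For 4D data the same plane is resampled from the volume on a
fine in-plane lattice and the identical ROI machinery is applied, so the
2D-vs-4D comparison isolates the data, not the method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath

from .datamodel import PlanarROI, VelocityField4D
from .tracer import sample_velocity

__all__ = [
    "Plane2DFlowSeries",
    "FluxSeries",
    "flux_2d",
    "resample_plane_from_4d",
    "circular_roi",
]


@dataclass
class Plane2DFlowSeries:
    """Through-plane velocity image series on a planar lattice.

    ``images`` has shape (nt, nv, nu) in cm/s, positive along the plane
    normal.  ``u0, v0`` are the in-plane coordinates (mm) of pixel (0, 0),
    in the same plane basis the ROI contours use.
    """

    images: np.ndarray
    pixel_spacing: tuple[float, float]  # (dv, du) mm
    timeframe_duration: float  # ms
    u0: float = 0.0
    v0: float = 0.0

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=np.float64)
        if self.images.ndim != 3:
            raise ValueError("images must have shape (nt, nv, nu)")

    @property
    def nt(self) -> int:
        return self.images.shape[0]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nv, nu = self.images.shape[1:]
        dv, du = self.pixel_spacing
        return self.u0 + du * np.arange(nu), self.v0 + dv * np.arange(nv)


@dataclass
class FluxSeries:
    """Per-timeframe flux (ml/s) and ROI area (mm^2), with the cycle SV."""

    flux: np.ndarray
    roi_area: np.ndarray
    timeframe_duration: float

    @property
    def sv(self) -> float:
        """Stroke volume in ml: rectangle-rule time integral of the flux."""
        return float(self.flux.sum() * self.timeframe_duration / 1000.0)


def flux_2d(series: Plane2DFlowSeries, roi: PlanarROI) -> FluxSeries:
    """Through-plane flux over time inside the ROI contours.

    Pixel membership is by center inclusion in the frame's polygon.  A
    missing contour for any timeframe is an error naming the frame.
    """
    if roi.nt != series.nt:
        missing = list(range(min(roi.nt, series.nt), max(roi.nt, series.nt)))
        raise ValueError(
            f"ROI has {roi.nt} contours for {series.nt} timeframes "
            f"(missing frame(s) {missing})"
        )
    us, vs = series.pixel_centers()
    V, U = np.meshgrid(vs, us, indexing="ij")
    pts = np.column_stack((U.ravel(), V.ravel()))
    dv, du = series.pixel_spacing
    pixel_area = dv * du
    flux = np.zeros(series.nt)
    area = np.zeros(series.nt)
    for k in range(series.nt):
        inside = MplPath(roi.contours[k]).contains_points(pts)
        inside = inside.reshape(V.shape)
        area[k] = inside.sum() * pixel_area
        # cm/s -> mm/s is *10; mm^3/s -> ml/s is /1000
        flux[k] = series.images[k][inside].sum() * 10.0 * pixel_area / 1000.0
    return FluxSeries(flux, area, series.timeframe_duration)


def resample_plane_from_4d(
    field: VelocityField4D,
    roi: PlanarROI,
    lattice_spacing: float = 1.0,
    roi_shift: tuple[float, float] = (0.0, 0.0),
    margin: float = 3.0,
) -> Plane2DFlowSeries:
    """Resample the ROI's plane from the 4D field as a through-plane series.

    The plane is sampled on a regular in-plane lattice (default 1 mm,
    finer than the voxel size so polygon rasterization is not the dominant
    error) via space-time linear interpolation; the through-plane
    component is the velocity dotted with the plane normal.  ``roi_shift``
    applies a rigid in-plane translation of the copied ROI, mirroring
    manual ROI-position correction.
    """
    e1, e2 = roi.basis()
    all_pts = np.vstack(roi.contours)
    u_min, v_min = all_pts.min(axis=0) - margin
    u_max, v_max = all_pts.max(axis=0) + margin
    us = np.arange(u_min, u_max + 1e-9, lattice_spacing)
    vs = np.arange(v_min, v_max + 1e-9, lattice_spacing)
    V, U = np.meshgrid(vs, us, indexing="ij")
    su, sv_ = roi_shift
    world = (
        roi.point
        + (U.ravel() + su)[:, None] * e1
        + (V.ravel() + sv_)[:, None] * e2
    )
    images = np.zeros((field.nt, len(vs), len(us)))
    any_inside = False
    for k in range(field.nt):
        v_mm_ms = sample_velocity(field, world, k * field.timeframe_duration)
        through = v_mm_ms @ roi.normal  # mm/ms
        finite = np.isfinite(through)
        any_inside |= bool(finite.any())
        through[~finite] = 0.0
        images[k] = (through * 100.0).reshape(V.shape)  # mm/ms -> cm/s
    if not any_inside:
        raise ValueError("plane lattice lies entirely outside the velocity grid")
    return Plane2DFlowSeries(
        images,
        (lattice_spacing, lattice_spacing),
        field.timeframe_duration,
        u0=float(us[0]),
        v0=float(vs[0]),
    )


def circular_roi(
    point: np.ndarray,
    normal: np.ndarray,
    radius: float,
    nt: int,
    n_vertices: int = 96,
) -> PlanarROI:
    """Planar ROI whose contour is the same circle at every timeframe."""
    ang = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    poly = np.column_stack((radius * np.cos(ang), radius * np.sin(ang)))
    return PlanarROI(np.asarray(point, float), np.asarray(normal, float),
                     [poly.copy() for _ in range(nt)])
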