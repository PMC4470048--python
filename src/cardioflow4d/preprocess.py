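"""Velocity preprocessing: phase unwrapping and background correction.

Phase-contrast velocities alias by multiples of 2*VENC; unwrapping restores
them by minimizing jumps along the periodic time axis, with an optional
manual-correction hook.  Eddy-current phase offsets appear as a static,
spatially slowly varying velocity bias; it is estimated as a first-order
spatial polynomial fitted to the time-averaged velocity of stationary
tissue and subtracted from all voxels and timeframes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .datamodel import SegmentationSet, VelocityField4D

__all__ = [
    "StationaryMask",
    "unwrap_velocity",
    "find_stationary_tissue",
    "correct_background",
]


@dataclass
class StationaryMask:
    """Voxels classified as stationary tissue, with the selection settings."""

    mask: np.ndarray  # (nz, ny, nx) bool
    sd_threshold: float  # cm/s

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("stationary mask is empty")


def unwrap_velocity(
    field: VelocityField4D,
    manual_corrections: Iterable[tuple[tuple[int, int, int], int, int, int]] = (),
    max_passes: int = 3,
) -> tuple[VelocityField4D, int]:
    """Unwrap aliased velocities along the periodic time axis.

    For each voxel/component series, whenever the jump to the temporal
    predecessor exceeds VENC, a multiple of 2*VENC is added to minimize the
    jump; passes repeat over the periodic cycle until stable (at most
    ``max_passes``).  After the automatic pass, user-supplied manual
    corrections ``((iz, iy, ix), timeframe, component, k)`` add ``k * 2 *
    venc`` to single samples.

    Returns the corrected field and the number of voxel samples changed.
    A series that cannot be made jump-free within the pass limit triggers a
    warning with the count of unresolved voxels.
    """
    venc = field.venc
    period = 2.0 * venc
    v = field.velocities.copy()
    for _ in range(max_passes):
        # minimize each jump to the temporal predecessor (frame 0's
        # predecessor is the last frame: time is a circle)
        jumps = np.diff(v, axis=0, prepend=v[-1:])
        k = np.round(jumps / period)
        if not k.any():
            break
        corr = np.cumsum(k, axis=0) * period
        v = v - corr

    closure = np.abs(v[0] - v[-1]) > venc
    unresolved = int(closure.sum())
    if unresolved:
        warnings.warn(
            f"unwrapping did not converge for {unresolved} voxel components",
            stacklevel=2,
        )

    # re-center series whose every sample shifted by a common 2*venc multiple
    offset = np.round(v.mean(axis=0) / period) * period
    v = v - offset[None]

    for (iz, iy, ix), t, comp, k in manual_corrections:
        v[t, iz, iy, ix, comp] += k * period

    changed = int((np.abs(v - field.velocities) > 1e-9).sum())
    out = VelocityField4D(
        v, field.spacing, field.timeframe_duration, field.venc, field.origin
    )
    return out, changed


def find_stationary_tissue(
    field: VelocityField4D,
    seg: SegmentationSet | None = None,
    sd_threshold: float = 2.0,
    dilate_lv: int = 1,
) -> StationaryMask:
    """Select stationary-tissue voxels for the background fit.

    A voxel qualifies if the temporal standard deviation of its speed is
    below ``sd_threshold`` (cm/s) and it lies outside every LV mask
    (dilated by ``dilate_lv`` voxels to keep partial-volume blood out).
    """
    if sd_threshold <= 0:
        raise ValueError(
            "sd_threshold must be positive; an empty selection would result"
        )
    speed = np.linalg.norm(field.velocities, axis=-1)  # (nt, nz, ny, nx)
    quiet = speed.std(axis=0) < sd_threshold
    if seg is not None:
        lv_any = seg.lv_masks.any(axis=0)
        if dilate_lv > 0:
            lv_any = ndimage.binary_dilation(lv_any, iterations=dilate_lv)
        quiet &= ~lv_any
    if not quiet.any():
        raise ValueError(
            "no stationary voxels found; increase sd_threshold or check masks"
        )
    return StationaryMask(quiet, sd_threshold)


def correct_background(
    field: VelocityField4D, stationary: StationaryMask
) -> tuple[VelocityField4D, np.ndarray]:
    """Subtract a fitted static affine velocity background per component.

    For each component the time-averaged velocity over the stationary
    voxels is fitted by least squares to ``c0 + c1 x + c2 y + c3 z`` (world
    mm) and the fitted plane is subtracted from all voxels and timeframes.
    Returns the corrected field and the (3, 4) coefficient matrix.
    """
    mask = stationary.mask
    n_vox = int(mask.sum())
    if n_vox < 40:  # 10x the 4 fit parameters
        raise ValueError(
            f"only {n_vox} stationary voxels; need >= 40 for a stable fit"
        )
    Xw, Yw, Zw = field.world_coords()
    design = np.column_stack(
        (np.ones(n_vox), Xw[mask], Yw[mask], Zw[mask])
    )
    if np.linalg.matrix_rank(design) < 4:
        raise ValueError("degenerate stationary-mask geometry (rank-deficient fit)")
    mean_v = field.velocities.mean(axis=0)  # (nz, ny, nx, 3)
    coeffs, *_ = np.linalg.lstsq(design, mean_v[mask], rcond=None)  # (4, 3)
    coeffs = coeffs.T  # (3, 4)
    background = (
        coeffs[:, 0][None, None, None]
        + coeffs[:, 1][None, None, None] * Xw[..., None]
        + coeffs[:, 2][None, None, None] * Yw[..., None]
        + coeffs[:, 3][None, None, None] * Zw[..., None]
    )
    out = field.copy()
    out.velocities -= background[None]
    return out, coeffs
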