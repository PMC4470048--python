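"""Particle path integration through the periodic 4D velocity field.

Pathlines are integrated with the classic fixed-step 4th-order Runge-Kutta
scheme (default step 5 ms), sampling the measured field by linear
interpolation in space (trilinear between the 8 surrounding voxel centers)
and in time (between the two surrounding timeframes, wrapping periodically
between the last and first frame).  Velocities are converted to mm/ms
internally, so positions stay in world mm throughout.

Particles that leave the voxel-center bounding box are frozen at their last
in-grid position and flagged ``left_grid`` rather than dropped, so the
volume each particle carries is conserved and every fate is auditable.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Literal

import numpy as np

from .datamodel import VelocityField4D

__all__ = [
    "IntegrationConfig",
    "ParticleSet",
    "sample_velocity",
    "trace",
    "emit_particles",
    "export_trajectories_csv",
    "export_trajectories_vtk",
]

CM_PER_S_TO_MM_PER_MS = 0.01  # 100 cm/s = 1 mm/ms


@dataclass
class IntegrationConfig:
    """Fixed-step RK4 integration settings.

    ``t_start``/``t_end`` are times in ms within the cardiac cycle; the
    integration duration is the periodic distance from start to end in the
    chosen direction, so a backward trace from end-diastole to end-systole
    crosses the cycle boundary when needed.
    """

    t_start: float
    t_end: float
    timestep: float = 5.0
    direction: Literal["forward", "backward"] = "forward"

    def __post_init__(self) -> None:
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def duration(self, cycle_length: float) -> float:
        """Integration duration in ms (periodic distance start -> end)."""
        if self.direction == "forward":
            d = (self.t_end - self.t_start) % cycle_length
        else:
            d = (self.t_start - self.t_end) % cycle_length
        if d == 0.0:
            raise ValueError("t_start and t_end coincide modulo the cycle")
        return d


@dataclass
class ParticleSet:
    """Traced particles with carried volume and fate bookkeeping."""

    initial_positions: np.ndarray  # (n, 3) world mm
    positions: np.ndarray  # (n, 3) final world mm
    carried_volume: float  # mm^3 per particle (= source voxel volume)
    left_grid: np.ndarray  # (n,) bool
    times: np.ndarray = dc_field(default_factory=lambda: np.zeros(0))  # (steps+1,) ms
    trajectories: np.ndarray | None = None  # (n, steps+1, 3) if recorded

    @property
    def n(self) -> int:
        return len(self.positions)

    @property
    def status(self) -> np.ndarray:
        return np.where(self.left_grid, "left_grid", "active")


class _Sampler:
    """Vectorized space-time linear interpolation of a velocity field."""

    def __init__(self, field: VelocityField4D):
        self.vel = field.velocities * CM_PER_S_TO_MM_PER_MS  # (nt,nz,ny,nx,3) mm/ms
        self.nt = field.nt
        self.nz, self.ny, self.nx = field.grid_shape
        self.dz, self.dy, self.dx = field.spacing
        self.x0, self.y0, self.z0 = field.origin
        self.dt_frame = field.timeframe_duration

    def __call__(self, pos: np.ndarray, t: float) -> np.ndarray:
        """Velocities (N, 3) in mm/ms at world positions; NaN outside grid."""
        pos = np.atleast_2d(pos)
        fx = (pos[:, 0] - self.x0) / self.dx
        fy = (pos[:, 1] - self.y0) / self.dy
        fz = (pos[:, 2] - self.z0) / self.dz
        inside = (
            (fx >= 0.0) & (fx <= self.nx - 1)
            & (fy >= 0.0) & (fy <= self.ny - 1)
            & (fz >= 0.0) & (fz <= self.nz - 1)
        )
        out = np.full((len(pos), 3), np.nan)
        if not inside.any():
            return out
        fx, fy, fz = fx[inside], fy[inside], fz[inside]
        ix = np.minimum(fx.astype(np.intp), self.nx - 2)
        iy = np.minimum(fy.astype(np.intp), self.ny - 2)
        iz = np.minimum(fz.astype(np.intp), self.nz - 2)
        wx, wy, wz = fx - ix, fy - iy, fz - iz

        tt = (t / self.dt_frame) % self.nt
        k0 = int(tt) % self.nt
        k1 = (k0 + 1) % self.nt
        wt = tt - int(tt)

        def trilinear(v3):
            c000 = v3[iz, iy, ix]
            c001 = v3[iz, iy, ix + 1]
            c010 = v3[iz, iy + 1, ix]
            c011 = v3[iz, iy + 1, ix + 1]
            c100 = v3[iz + 1, iy, ix]
            c101 = v3[iz + 1, iy, ix + 1]
            c110 = v3[iz + 1, iy + 1, ix]
            c111 = v3[iz + 1, iy + 1, ix + 1]
            wxc = wx[:, None]
            c00 = c000 + (c001 - c000) * wxc
            c01 = c010 + (c011 - c010) * wxc
            c10 = c100 + (c101 - c100) * wxc
            c11 = c110 + (c111 - c110) * wxc
            wyc = wy[:, None]
            c0 = c00 + (c01 - c00) * wyc
            c1 = c10 + (c11 - c10) * wyc
            return c0 + (c1 - c0) * wz[:, None]

        v = trilinear(self.vel[k0])
        if wt != 0.0:
            v = v + (trilinear(self.vel[k1]) - v) * wt
        out[inside] = v
        return out


def sample_velocity(
    field: VelocityField4D, positions: np.ndarray, time_ms: float
) -> np.ndarray:
    """Sample the field at world positions (mm) and a time (ms), in mm/ms.

    Time is wrapped periodically into the cardiac cycle.  Positions outside
    the voxel-center bounding box return NaN rows (the out-of-grid sentinel).
    """
    return _Sampler(field)(positions, time_ms)


def trace(
    field: VelocityField4D,
    seeds: np.ndarray,
    cfg: IntegrationConfig,
    record: bool = False,
) -> ParticleSet:
    """Integrate particle paths with fixed-step RK4.

    The final step is shortened so trajectories end exactly at ``t_end``.
    Backward tracing integrates the same field with time running in the
    negative direction.  An empty seed array yields an empty set.
    """
    seeds = np.atleast_2d(np.asarray(seeds, dtype=np.float64))
    if seeds.size == 0:
        seeds = seeds.reshape(0, 3)
    sampler = _Sampler(field)
    cycle = field.cycle_length
    duration = cfg.duration(cycle)
    sign = 1.0 if cfg.direction == "forward" else -1.0

    n_full = int(duration // cfg.timestep)
    steps = [cfg.timestep] * n_full
    remainder = duration - n_full * cfg.timestep
    if remainder > 1e-9:
        steps.append(remainder)

    pos = seeds.copy()
    left = np.zeros(len(pos), dtype=bool)
    t = cfg.t_start
    times = [t]
    traj = [pos.copy()] if record else None

    for h_abs in steps:
        h = sign * h_abs
        active = ~left
        if active.any():
            p = pos[active]
            k1 = sampler(p, t)
            k2 = sampler(p + 0.5 * h * k1, t + 0.5 * h)
            k3 = sampler(p + 0.5 * h * k2, t + 0.5 * h)
            k4 = sampler(p + h * k3, t + h)
            delta = (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            bad = ~np.isfinite(delta).all(axis=1)
            delta[bad] = 0.0
            new_p = p + delta
            # an RK4 stage may stay finite while the endpoint exits
            fx = (new_p[:, 0] - sampler.x0) / sampler.dx
            fy = (new_p[:, 1] - sampler.y0) / sampler.dy
            fz = (new_p[:, 2] - sampler.z0) / sampler.dz
            exited = bad | ~(
                (fx >= 0) & (fx <= sampler.nx - 1)
                & (fy >= 0) & (fy <= sampler.ny - 1)
                & (fz >= 0) & (fz <= sampler.nz - 1)
            )
            new_p[exited] = p[exited]
            pos[active] = new_p
            idx = np.flatnonzero(active)
            left[idx[exited]] = True
        t += sign * h_abs
        times.append(t)
        if record:
            traj.append(pos.copy())

    return ParticleSet(
        initial_positions=seeds,
        positions=pos,
        carried_volume=field.voxel_volume,
        left_grid=left,
        times=np.asarray(times),
        trajectories=np.stack(traj, axis=1) if record else None,
    )


def mask_voxel_centers(field: VelocityField4D, mask: np.ndarray) -> np.ndarray:
    """World coordinates (N, 3) of the centers of the True voxels of a mask."""
    iz, iy, ix = np.nonzero(mask)
    dz, dy, dx = field.spacing
    x0, y0, z0 = field.origin
    return np.column_stack((x0 + ix * dx, y0 + iy * dy, z0 + iz * dz))


def emit_particles(
    field: VelocityField4D,
    region: np.ndarray,
    window: tuple[float, float],
    interval: float = 25.0,
    timestep: float = 5.0,
) -> list[tuple[float, ParticleSet]]:
    """Emit particles from a region at regular intervals and trace each cohort
    forward to the end of the window.

    Intended for flow visualization export: seeds are placed at the voxel
    centers of ``region`` at each emission time within ``window`` (ms), one
    cohort per emission.  An interval longer than the window yields a single
    emission at the window start; an empty region yields no particles.
    """
    if interval <= 0:
        raise ValueError("interval must be positive")
    t0, t1 = window
    seeds = mask_voxel_centers(field, region)
    cohorts: list[tuple[float, ParticleSet]] = []
    t_emit = t0
    while t_emit < t1 or not cohorts:
        cfg = IntegrationConfig(
            t_start=t_emit, t_end=t1, timestep=timestep, direction="forward"
        )
        if seeds.size == 0:
            cohorts.append(
                (t_emit, ParticleSet(seeds.reshape(0, 3), seeds.reshape(0, 3),
                                     field.voxel_volume, np.zeros(0, dtype=bool)))
            )
        else:
            cohorts.append((t_emit, trace(field, seeds, cfg, record=True)))
        t_emit += interval
        if t_emit >= t1:
            break
    return cohorts


def export_trajectories_csv(path: str | Path, particles: ParticleSet) -> None:
    """Write recorded trajectories as CSV rows (particle, step, t, x, y, z)."""
    if particles.trajectories is None:
        raise ValueError("particle set was traced without record=True")
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["particle", "step", "t_ms", "x_mm", "y_mm", "z_mm"])
        for i in range(particles.n):
            for s, t in enumerate(particles.times):
                x, y, z = particles.trajectories[i, s]
                w.writerow([i, s, f"{t:.6g}", f"{x:.6g}", f"{y:.6g}", f"{z:.6g}"])


def read_trajectories_csv(path: str | Path) -> ParticleSet:
    """Inverse of :func:`export_trajectories_csv` (volume metadata not stored)."""
    rows = {}
    times = {}
    with open(path) as f:
        for rec in csv.DictReader(f):
            i, s = int(rec["particle"]), int(rec["step"])
            rows.setdefault(i, {})[s] = (
                float(rec["x_mm"]), float(rec["y_mm"]), float(rec["z_mm"])
            )
            times[s] = float(rec["t_ms"])
    n = len(rows)
    nsteps = len(times)
    traj = np.zeros((n, nsteps, 3))
    for i in range(n):
        for s in range(nsteps):
            traj[i, s] = rows[i][s]
    return ParticleSet(
        initial_positions=traj[:, 0].copy(),
        positions=traj[:, -1].copy(),
        carried_volume=float("nan"),
        left_grid=np.zeros(n, dtype=bool),
        times=np.array([times[s] for s in range(nsteps)]),
        trajectories=traj,
    )


def export_trajectories_vtk(path: str | Path, particles: ParticleSet) -> None:
    """Write recorded trajectories as a legacy-ASCII VTK polyline file."""
    if particles.trajectories is None:
        raise ValueError("particle set was traced without record=True")
    n, nsteps, _ = particles.trajectories.shape
    pts = particles.trajectories.reshape(-1, 3)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nparticle pathlines\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {len(pts)} float\n")
        for x, y, z in pts:
            f.write(f"{x:.6g} {y:.6g} {z:.6g}\n")
        f.write(f"LINES {n} {n * (nsteps + 1)}\n")
        for i in range(n):
            ids = " ".join(str(i * nsteps + s) for s in range(nsteps))
            f.write(f"{nsteps} {ids}\n")
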