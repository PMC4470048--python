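"""Analytic 4D velocity phantoms with known ground truth.

Three phantom families emulate the features of intracardiac 4D-flow data
that the quantification pipeline relies on:

``plug_tube``
    A straight tube with a smooth-rimmed plug profile and a half-sine
    systolic velocity waveform.  The through-plane flux and stroke volume
    have closed forms, so it validates flux integration and kinetic energy.

``contracting_ellipsoid``
    A beating-ventricle stand-in: an ellipsoidal chamber whose volume curve
    prescribes the stroke volume, with divergence-free orifice jets through
    a mitral and an aortic plane on the basal side.  Because the jet fields
    are solenoidal, the Lagrangian volume crossing each valve plane equals
    the prescribed time-integrated flux, which is exactly what particle
    tracing measures.

``hill_vortex``
    A steady spherical vortex (a smoothly tapered variant of the classical
    Hill vortex whose velocity vanishes continuously on the sphere, leaving
    the surround quiescent).  The recirculation region is the sphere, so
    the vortex volume is (4/3)*pi*a^3 exactly.

Every generator is deterministic given its spec and emits a
:class:`GroundTruth` record alongside the dataset.  :func:`corrupt` applies
the measurement imperfections the preprocessing stage must undo: velocity
aliasing at VENC, Gaussian velocity noise, and a static per-component
affine background offset.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Literal

import numpy as np
from scipy import integrate

from .datamodel import SegmentationSet, ValvePlane, VelocityField4D

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "make_plug_tube",
    "make_contracting_ellipsoid",
    "make_hill_vortex",
    "corrupt",
    "uniform_field",
    "linear_strain_field",
    "rotation_field",
]

BLOOD_DENSITY = 1060.0  # kg/m^3


@dataclass
class PhantomSpec:
    """Parameters of a synthetic dataset.

    Defaults mirror a typical whole-heart acquisition: 3 mm isotropic
    voxels, 40 reconstructed heart phases over a 1000 ms cycle, VENC
    chosen above the phantom's peak speed unless aliasing is requested.
    """

    kind: Literal["plug_tube", "contracting_ellipsoid", "hill_vortex"]
    shape: tuple[int, int, int] = (0, 0, 0)  # (nz, ny, nx); 0 -> per-kind default
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    nt: int = 40
    cycle_length: float = 1000.0
    venc: float = 200.0
    seed: int = 0
    # ventricle phantom
    target_sv: float = 80.0  # ml
    ed_volume: float = 140.0  # ml
    systole_duration: float = 300.0  # ms
    # isovolumic phases: ejection ends this long before end-systole, and the
    # early filling wave starts this long after it
    isovolumic_contraction: float = 50.0  # ms
    isovolumic_relaxation: float = 100.0  # ms
    # plug tube
    tube_radius: float = 15.0  # mm, radius of the uniform core
    rim_width: float = 3.0  # mm, half-width of the smooth rim
    peak_velocity: float = 50.0  # cm/s (tube peak / vortex center speed)
    # hill vortex
    vortex_radius: float = 20.0  # mm

    def __post_init__(self) -> None:
        if self.nt < 2:
            raise ValueError("nt must be >= 2")
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")


@dataclass
class GroundTruth:
    """Analytically known truth emitted with every phantom."""

    true_sv: float | None = None  # ml
    true_ke_curve: np.ndarray | None = None  # mJ per timeframe
    true_vortex_volume: float | None = None  # ml
    background_coeffs: np.ndarray | None = None  # (3, 4): c0 + c1 x + c2 y + c3 z
    wrap_mask: np.ndarray | None = None  # bool, (nt, nz, ny, nx, 3)
    meta: dict = dc_field(default_factory=dict)


# ---------------------------------------------------------------------------
# temporal envelopes


def _half_sine_primitive(t: np.ndarray, t_on: float, dur: float, amp: float) -> np.ndarray:
    """Integral from 0 to t of amp * sin(pi (t - t_on)/dur) on [t_on, t_on+dur]."""
    tau = np.clip(t - t_on, 0.0, dur)
    return amp * dur / np.pi * (1.0 - np.cos(np.pi * tau / dur))


def bin_averaged_half_sine(
    nt: int, frame_dt: float, t_on: float, dur: float, amp: float
) -> np.ndarray:
    """Per-frame temporal-bin averages of a half-sine burst.

    Each reconstructed heart phase represents the average over its temporal
    bin, so rectangle-rule integration of the frame values recovers the
    continuous time integral exactly.
    """
    edges = np.arange(nt + 1) * frame_dt
    prim = _half_sine_primitive(edges, t_on, dur, amp)
    return np.diff(prim) / frame_dt


# ---------------------------------------------------------------------------
# plug tube


def _rim_profile(r: np.ndarray, radius: float, w: float) -> np.ndarray:
    """Radial plug profile: 1 in the core, cosine rim over [R-w, R+w], 0 outside."""
    p = np.zeros_like(r)
    p[r <= radius - w] = 1.0
    rim = (r > radius - w) & (r < radius + w)
    p[rim] = 0.5 * (1.0 + np.cos(np.pi * (r[rim] - (radius - w)) / (2.0 * w)))
    return p


def tube_effective_area(radius: float, w: float) -> float:
    """Lumen area weighted by the rim profile, mm^2 (2*pi*int r p(r) dr)."""
    ring, _ = integrate.quad(
        lambda r: r * 0.5 * (1.0 + np.cos(np.pi * (r - (radius - w)) / (2.0 * w))),
        radius - w,
        radius + w,
    )
    return np.pi * (radius - w) ** 2 + 2.0 * np.pi * ring


def make_plug_tube(
    spec: PhantomSpec, density: float = BLOOD_DENSITY
) -> tuple[VelocityField4D, GroundTruth, SegmentationSet]:
    """Tube along +z with a half-sine systolic plug flow.

    The true stroke volume is ``A_eff * (2/pi) * v_peak * T_sys`` with
    ``A_eff`` the rim-weighted lumen area.  The segmentation marks core
    voxels only (profile exactly 1), so the kinetic-energy curve inside the
    mask has the closed form ``0.5 * rho * V_mask * v(t)^2``.
    """
    shape = spec.shape if all(spec.shape) else (16, 26, 26)
    nz, ny, nx = shape
    dz, dy, dx = spec.spacing
    radius, w = spec.tube_radius, spec.rim_width
    if radius + w > min((nx - 1) * dx, (ny - 1) * dy) / 2.0:
        raise ValueError("tube radius (incl. rim) exceeds the grid extent")

    origin = (-(nx - 1) * dx / 2.0, -(ny - 1) * dy / 2.0, -(nz - 1) * dz / 2.0)
    xs = origin[0] + dx * np.arange(nx)
    ys = origin[1] + dy * np.arange(ny)
    Y, X = np.meshgrid(ys, xs, indexing="ij")
    r = np.hypot(X, Y)
    profile = _rim_profile(r, radius, w)  # (ny, nx)

    frame_dt = spec.cycle_length / spec.nt
    v_t = bin_averaged_half_sine(
        spec.nt, frame_dt, 0.0, spec.systole_duration, spec.peak_velocity
    )  # cm/s per frame

    vel = np.zeros((spec.nt, nz, ny, nx, 3))
    vel[..., 2] = v_t[:, None, None, None] * profile[None, None, :, :]
    field = VelocityField4D(vel, spec.spacing, frame_dt, spec.venc, origin)

    area_eff = tube_effective_area(radius, w)
    true_sv = area_eff * (2.0 / np.pi) * (spec.peak_velocity * 10.0) * (
        spec.systole_duration / 1000.0
    ) / 1000.0  # mm^2 * mm/s * s -> mm^3 -> ml

    core = r <= radius - w - 0.5 * max(dx, dy)  # strictly inside the uniform core
    masks = np.broadcast_to(core[None, None], (spec.nt, nz, ny, nx)).copy()
    seg = SegmentationSet(masks, ed_index=0, es_index=spec.nt // 2)

    mask_vol_mm3 = core.sum() * nz * field.voxel_volume
    ke = 0.5 * density * (mask_vol_mm3 * 1e-9) * (v_t * 0.01) ** 2 * 1000.0  # mJ
    lumen = np.broadcast_to((r < radius + w)[None], (nz, ny, nx))
    gt = GroundTruth(
        true_sv=true_sv,
        true_ke_curve=ke,
        meta={
            "effective_area_mm2": area_eff,
            "frame_velocities_cm_s": v_t,
            "axis": "z",
            "core_radius_mm": radius,
            "rim_width_mm": w,
            # full flowing region; everything outside is exactly stationary
            "lumen_mask": lumen.copy(),
        },
    )
    return field, gt, seg


# ---------------------------------------------------------------------------
# contracting ellipsoid with orifice jets


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _smoothstep_d(u: np.ndarray) -> np.ndarray:
    inside = (u > 0.0) & (u < 1.0)
    return np.where(inside, 6.0 * u * (1.0 - u), 0.0)


def make_contracting_ellipsoid(
    spec: PhantomSpec, density: float = BLOOD_DENSITY
) -> tuple[VelocityField4D, GroundTruth, SegmentationSet, dict[str, ValvePlane]]:
    """Beating-ventricle phantom: an ellipsoidal chamber traversed by
    divergence-free valve jets carrying exactly ``target_sv`` per beat.

    The chamber is the ellipsoidal region between two valve planes on a
    common axis: the mitral plane bounds it basally (blood enters downward
    through it during diastole) and the aortic plane bounds it apically
    (blood leaves through it during systole).  Both jets share a radial
    bump profile ``g(r) = (1 - (r/rj)^2)^2`` and a vertical envelope whose
    derivative is proportional to the chamber's local annular capacity, so
    inflowing blood decelerates and deposits in a shell that fills the
    chamber from the inside out -- and the systolic jet drains that same
    shell.  Because each jet field is solenoidal, the Lagrangian volume
    crossing each valve plane per half-cycle equals the prescribed
    time-integrated flux, i.e. ``target_sv`` by construction, and all of
    it lies within the end-diastolic mask.

    Per-timeframe masks rank chamber voxels by normalized ellipsoid radius
    and keep exactly the count matching the volume curve (``ed_volume``
    down by ``target_sv`` and back), so counted mask volumes track the
    curve to within one voxel.
    """
    frame_dt = spec.cycle_length / spec.nt
    t_sys = spec.systole_duration
    if abs(t_sys / frame_dt - round(t_sys / frame_dt)) > 1e-9:
        raise ValueError("systole_duration must be a whole number of timeframes")
    t_dia = spec.cycle_length - t_sys
    sv_mm3 = spec.target_sv * 1000.0
    ved_mm3 = spec.ed_volume * 1000.0
    if sv_mm3 >= ved_mm3:
        raise ValueError("target_sv must be smaller than the ED volume")

    # fixed shape prior; the mask count adapts to the requested volumes
    a_xy, a_z, cz = 42.0, 26.0, -10.0
    rj = 18.0
    z_mitral, z_aortic = 10.0, -30.0
    if z_mitral - z_aortic <= 2.0 * spec.spacing[0]:
        raise ValueError("orifice regions overlap (valve planes too close)")
    area_eff = np.pi * rj**2 / 3.0

    shape = spec.shape if all(spec.shape) else (30, 33, 33)
    nz, ny, nx = shape
    dz, dy, dx = spec.spacing
    origin = (-(nx - 1) * dx / 2.0, -(ny - 1) * dy / 2.0, -52.0)
    xs = origin[0] + dx * np.arange(nx)
    ys = origin[1] + dy * np.arange(ny)
    zs = origin[2] + dz * np.arange(nz)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")

    # masks: rank voxels inside the valve-plane slab by normalized radius
    rho_norm = np.sqrt((X / a_xy) ** 2 + (Y / a_xy) ** 2 + ((Z - cz) / a_z) ** 2)
    slab = (Z >= z_aortic) & (Z <= z_mitral)
    rho_rank = np.where(slab, rho_norm, np.inf)
    order = np.argsort(rho_rank.ravel(), kind="stable")
    n_ed = int(round(ved_mm3 / (dz * dy * dx)))
    if n_ed > slab.sum():
        raise ValueError("ed_volume exceeds the chamber capacity of this grid")
    lam_ed = float(np.sort(rho_rank.ravel())[n_ed - 1])  # ED mask boundary

    edges = np.arange(spec.nt + 1) * frame_dt
    t_ej = t_sys - spec.isovolumic_contraction
    t_fi = t_dia - spec.isovolumic_relaxation
    s_sys = _half_sine_primitive(edges[:-1], 0.0, t_ej, 1.0) / (2.0 * t_ej / np.pi)
    s_dia = _half_sine_primitive(
        edges[:-1], t_sys + spec.isovolumic_relaxation, t_fi, 1.0
    ) / (2.0 * t_fi / np.pi)
    ejected = s_sys - s_dia  # 0 at ED, 1 at ES, back to 0
    volume_curve = ved_mm3 - sv_mm3 * ejected
    voxel_volume = dz * dy * dx
    masks = np.zeros((spec.nt,) + shape, dtype=bool)
    for k in range(spec.nt):
        n_vox = int(round(volume_curve[k] / voxel_volume))
        flat = np.zeros(rho_rank.size, dtype=bool)
        flat[order[:n_vox]] = True
        masks[k] = flat.reshape(shape)
    seg = SegmentationSet(masks, ed_index=0, es_index=int(round(t_sys / frame_dt)))

    # capacity-shaped deposition envelope: f_dep' ~ annular room inside the
    # ED mask at height z, truncated below the mitral plane
    def _width2(z):
        w2 = a_xy**2 * (lam_ed**2 - ((z - cz) / a_z) ** 2)
        return np.clip(w2 - rj**2, 0.0, None)

    band_hi = min(6.0, z_mitral - dz)
    band_lo = cz - a_z * np.sqrt(max(lam_ed**2 - (rj / a_xy) ** 2, 0.0))

    def _cap(z):  # cumulative capacity integral of _width2 from band_lo
        z = np.clip(z, band_lo, band_hi)
        c2 = a_xy**2 * lam_ed**2 - rj**2
        term = lambda u: c2 * u - a_xy**2 * (u - cz) ** 3 / (3.0 * a_z**2)
        return term(z) - term(band_lo)

    cap_total = float(_cap(band_hi))

    def f_dep(z):
        return np.clip(_cap(z) / cap_total, 0.0, 1.0)

    def f_dep_d(z):
        inside = (z > band_lo) & (z < band_hi)
        return np.where(inside, _width2(z) / cap_total, 0.0)

    # smooth cutoffs that park exiting blood before the grid boundary
    def _down(z, z0, z1):  # 1 below z0, 0 above z1
        return 1.0 - _smoothstep((z - z0) / (z1 - z0))

    def _down_d(z, z0, z1):
        return -_smoothstep_d((z - z0) / (z1 - z0)) / (z1 - z0)

    atr0, atr1 = 14.0, 30.0  # atrial feed band above the mitral plane
    ao0, ao1 = -34.0, -50.0  # aortic runoff band below the aortic plane

    def jet_field(f, fp):
        r = np.hypot(X, Y)
        rho2 = (r / rj) ** 2
        g = np.where(rho2 < 1.0, (1.0 - rho2) ** 2, 0.0)
        G = rj**2 / 6.0 * (1.0 - np.where(rho2 < 1.0, (1.0 - rho2) ** 3, 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            ur_over_r = np.where(
                r > 1e-9, -fp * G / np.maximum(r, 1e-9) ** 2, -fp * 0.5
            )
        return np.stack((ur_over_r * X, ur_over_r * Y, f * g), axis=-1)

    # mitral jet: unit downward flow, full above the plane, depositing in the
    # chamber band; aortic jet: drains the same band out the bottom
    fm = f_dep(Z) * _down(Z, atr0, atr1)
    fmp = f_dep_d(Z) * _down(Z, atr0, atr1) + f_dep(Z) * _down_d(Z, atr0, atr1)
    fa = (1.0 - f_dep(Z)) * _down(-Z, -ao0, -ao1)
    fap = -f_dep_d(Z) * _down(-Z, -ao0, -ao1) - (1.0 - f_dep(Z)) * _down_d(
        -Z, -ao0, -ao1
    )
    um = jet_field(fm, fmp)
    ua = jet_field(fa, fap)

    # peak axial velocities (mm/ms) delivering sv_mm3 per half-sine window;
    # isovolumic gaps keep flow away from the trace endpoints
    t_eject = t_sys - spec.isovolumic_contraction
    t_fill = t_dia - spec.isovolumic_relaxation
    if t_eject <= 0 or t_fill <= 0:
        raise ValueError("isovolumic phases exceed the systole/diastole durations")
    w_mitral = sv_mm3 * np.pi / (2.0 * t_fill * area_eff)
    w_aortic = sv_mm3 * np.pi / (2.0 * t_eject * area_eff)
    env_a = bin_averaged_half_sine(spec.nt, frame_dt, 0.0, t_eject, -w_aortic)
    env_m = bin_averaged_half_sine(
        spec.nt, frame_dt, t_sys + spec.isovolumic_relaxation, t_fill, -w_mitral
    )

    vel = (
        env_a[:, None, None, None, None] * ua[None]
        + env_m[:, None, None, None, None] * um[None]
    ) * 100.0  # mm/ms -> cm/s
    field = VelocityField4D(vel, spec.spacing, frame_dt, spec.venc, origin)

    planes = {
        "mitral": ValvePlane(
            np.array([0.0, 0.0, z_mitral]), np.array([0.0, 0.0, 1.0]), "mitral"
        ),
        "aortic": ValvePlane(
            np.array([0.0, 0.0, z_aortic]), np.array([0.0, 0.0, -1.0]), "aortic"
        ),
    }

    speed2 = (vel**2).sum(axis=-1)  # (cm/s)^2
    ke = np.array(
        [
            0.5 * density * field.voxel_volume * 1e-9
            * (speed2[k][masks[k]] * 1e-4).sum() * 1000.0
            for k in range(spec.nt)
        ]
    )
    gt = GroundTruth(
        true_sv=spec.target_sv,
        true_ke_curve=ke,
        meta={
            "volume_curve_mm3": volume_curve,
            "jet_area_mm2": area_eff,
            "peak_aortic_mm_ms": w_aortic,
            "peak_mitral_mm_ms": w_mitral,
            "z_mitral_mm": z_mitral,
            "z_aortic_mm": z_aortic,
            "semi_axes_mm": (a_xy, a_xy, a_z),
            "ed_lambda": lam_ed,
        },
    )
    return field, gt, seg, planes


# ---------------------------------------------------------------------------
# spherical vortex


def hill_vortex_velocity(
    X: np.ndarray, Y: np.ndarray, Z: np.ndarray, a: float, peak: float
) -> np.ndarray:
    """Closed-form smooth spherical-vortex velocity (cm/s) at world points.

    Stokes streamfunction psi = (peak/2) r^2 (1 - s^2/a^2)^2 inside s < a,
    zero outside; velocity is continuous (vanishing) on the sphere and the
    surround is exactly quiescent.  ``peak`` is the axial speed at the
    sphere center.
    """
    C = peak / 2.0
    r2 = (X**2 + Y**2) / a**2
    s2 = r2 + Z**2 / a**2
    q = np.clip(1.0 - s2, 0.0, None)
    uz = 2.0 * C * q * (q - 2.0 * r2)
    ur_over_r = 4.0 * C * Z * q / a**2  # u_r / r, finite on the axis
    return np.stack((ur_over_r * X, ur_over_r * Y, uz), axis=-1)


def make_hill_vortex(spec: PhantomSpec) -> tuple[VelocityField4D, GroundTruth]:
    """Steady spherical vortex of radius ``vortex_radius`` centered in the grid.

    The recirculating region is the sphere, so the true vortex volume is
    (4/3) pi a^3 regardless of the circulation strength.
    """
    a = spec.vortex_radius
    shape = spec.shape if all(spec.shape) else (31, 31, 31)
    nz, ny, nx = shape
    dz, dy, dx = spec.spacing
    half = (min((nx - 1) * dx, (ny - 1) * dy, (nz - 1) * dz)) / 2.0
    if a >= half:
        raise ValueError("vortex sphere does not fit inside the grid")
    origin = (-(nx - 1) * dx / 2.0, -(ny - 1) * dy / 2.0, -(nz - 1) * dz / 2.0)
    xs = origin[0] + dx * np.arange(nx)
    ys = origin[1] + dy * np.arange(ny)
    zs = origin[2] + dz * np.arange(nz)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    v = hill_vortex_velocity(X, Y, Z, a, spec.peak_velocity)
    vel = np.broadcast_to(v[None], (spec.nt,) + v.shape).copy()
    field = VelocityField4D(
        vel, spec.spacing, spec.cycle_length / spec.nt, spec.venc, origin
    )
    gt = GroundTruth(
        true_vortex_volume=4.0 / 3.0 * np.pi * a**3 / 1000.0,
        meta={"radius_mm": a, "center_mm": (0.0, 0.0, 0.0)},
    )
    return field, gt


# ---------------------------------------------------------------------------
# measurement corruption


def corrupt(
    field: VelocityField4D,
    ground_truth: GroundTruth | None = None,
    wrap: bool = False,
    noise_sigma: float = 0.0,
    background_coeffs: np.ndarray | None = None,
    seed: int = 0,
    resp_amplitude_mm: float = 0.0,
    resp_period_ms: float = 4000.0,
) -> tuple[VelocityField4D, GroundTruth]:
    """Apply measurement imperfections to a phantom field.

    Order of application mirrors acquisition physics: optional respiratory
    through-plane displacement of the whole field, static per-component
    affine background offset ``c0 + c1 x + c2 y + c3 z`` (cm/s, cm/s/mm),
    Gaussian velocity noise, then aliasing that maps each component to
    ``((v + venc) mod 2 venc) - venc``.  The returned ground truth records
    the coefficients and the wrap mask.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    out = field.copy()
    rng = np.random.default_rng(seed)

    if resp_amplitude_mm != 0.0:
        from scipy.ndimage import shift as nd_shift

        dzv = field.spacing[0]
        times = field.frame_times()
        for k in range(field.nt):
            dz_mm = resp_amplitude_mm * np.sin(2.0 * np.pi * times[k] / resp_period_ms)
            for c in range(3):
                out.velocities[k, ..., c] = nd_shift(
                    out.velocities[k, ..., c], (dz_mm / dzv, 0, 0),
                    order=1, mode="nearest",
                )

    if background_coeffs is not None:
        coeffs = np.asarray(background_coeffs, dtype=np.float64).reshape(3, 4)
        Xw, Yw, Zw = field.world_coords()
        for c in range(3):
            c0, c1, c2, c3 = coeffs[c]
            out.velocities[..., c] += c0 + c1 * Xw + c2 * Yw + c3 * Zw
    else:
        coeffs = np.zeros((3, 4))

    if noise_sigma > 0:
        out.velocities += rng.normal(0.0, noise_sigma, size=out.velocities.shape)

    wrap_mask = None
    if wrap:
        wrap_mask = np.abs(out.velocities) > field.venc
        out.velocities = (
            np.mod(out.velocities + field.venc, 2.0 * field.venc) - field.venc
        )

    gt = replace(ground_truth) if ground_truth is not None else GroundTruth()
    gt.background_coeffs = coeffs
    gt.wrap_mask = wrap_mask
    return out, gt


# ---------------------------------------------------------------------------
# elementary analytic fields (oracles for the tracer and FTLE stages)


def _centered_grid(shape, spacing):
    nz, ny, nx = shape
    dz, dy, dx = spacing
    origin = (-(nx - 1) * dx / 2.0, -(ny - 1) * dy / 2.0, -(nz - 1) * dz / 2.0)
    xs = origin[0] + dx * np.arange(nx)
    ys = origin[1] + dy * np.arange(ny)
    zs = origin[2] + dz * np.arange(nz)
    Z, Y, X = np.meshgrid(zs, ys, xs, indexing="ij")
    return origin, X, Y, Z


def uniform_field(
    v_cm_s: tuple[float, float, float],
    shape=(12, 12, 12),
    spacing=(3.0, 3.0, 3.0),
    nt: int = 4,
    cycle_length: float = 1000.0,
    venc: float = 200.0,
) -> VelocityField4D:
    """Spatially and temporally uniform velocity field."""
    origin, *_ = _centered_grid(shape, spacing)
    vel = np.zeros((nt,) + tuple(shape) + (3,))
    vel[...] = np.asarray(v_cm_s)
    return VelocityField4D(vel, spacing, cycle_length / nt, venc, origin)


def linear_strain_field(
    strain_rate_per_s: float = 1.0,
    shape=(64, 64, 64),
    spacing=(1.0, 1.0, 1.0),
    nt: int = 2,
    cycle_length: float = 1000.0,
    venc: float = 1000.0,
) -> VelocityField4D:
    """Steady pure-strain field v = (s x, -s y, 0); FTLE equals s exactly."""
    origin, X, Y, _ = _centered_grid(shape, spacing)
    s = strain_rate_per_s / 1000.0  # 1/ms; v in mm/ms = s * x -> cm/s = *100
    vel = np.zeros((nt,) + tuple(shape) + (3,))
    vel[..., 0] = 100.0 * s * X
    vel[..., 1] = -100.0 * s * Y
    return VelocityField4D(vel, spacing, cycle_length / nt, venc, origin)


def rotation_field(
    omega_per_s: float = 1.0,
    shape=(64, 64, 64),
    spacing=(1.0, 1.0, 1.0),
    nt: int = 2,
    cycle_length: float = 1000.0,
    venc: float = 1000.0,
) -> VelocityField4D:
    """Steady rigid rotation v = (w y, -w x, 0) about the z axis."""
    origin, X, Y, _ = _centered_grid(shape, spacing)
    w = omega_per_s / 1000.0
    vel = np.zeros((nt,) + tuple(shape) + (3,))
    vel[..., 0] = 100.0 * w * Y
    vel[..., 1] = -100.0 * w * X
    return VelocityField4D(vel, spacing, cycle_length / nt, venc, origin)
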