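"""Synthetic 4D flow phantoms with known ground truth.

Generates time-resolved three-component velocity fields on regular voxel
grids, emulating 4D flow MRI of a total cavopulmonary connection (TCPC) and
simple analytic fields (uniform flow, Poiseuille tube, solid-body rotation)
for which kinetic energy, viscous dissipation, and pathline behaviour have
closed forms.  Also provides the MRI corruption model (Gaussian velocity
noise, smooth phase-offset polynomials, venc wrap-around) that the
preprocessing stage is designed to undo.

The TCPC phantom is a planar cross junction -- IVC entering from below, SVC
from above, LPA exiting left, RPA right -- built from a 2D streamfunction
extruded over a slab.  Because the in-plane velocity is the rotated gradient
of a streamfunction, the field is exactly divergence-free, and the caval
flow split to each pulmonary artery is known exactly from the
streamfunction level of the junction's interior stagnation (saddle) point:
flux between two streamlines equals their streamfunction difference, so
placing the saddle level prescribes how much IVC and SVC flow leaves
through the LPA.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import brentq

from .geometry import AnalysisPlane, Centerline, RegionModel, REGION_LABELS

DEFAULT_SEED = 20260928  # documented default for all phantom randomness


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Regular voxel grid with temporal sampling.

    shape : (nx, ny, nz) voxels; spacing : mm; frame_duration : ms;
    origin : mm world coordinate of voxel (0, 0, 0)'s center.
    """

    shape: tuple
    spacing: tuple = (1.0, 1.0, 1.0)
    n_frames: int = 1
    frame_duration: float = 40.0
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("all spacings must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be > 0")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def covered_duration_s(self) -> float:
        return self.n_frames * self.frame_duration / 1000.0

    def axes(self):
        return [self.origin[i] + np.arange(self.shape[i]) * self.spacing[i] for i in range(3)]

    def coords(self):
        """Broadcastable world-coordinate volumes (mm)."""
        return np.meshgrid(*self.axes(), indexing="ij")

    def center(self) -> np.ndarray:
        """World coordinate of the central voxel (snapped to a voxel center)."""
        idx = (np.asarray(self.shape) - 1) // 2
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    @classmethod
    def centered(cls, shape, spacing, **kw) -> "GridSpec":
        """Grid whose world origin (0,0,0) is the central voxel."""
        shape = tuple(int(n) for n in shape)
        spacing = tuple(float(s) for s in spacing)
        idx = (np.asarray(shape) - 1) // 2
        origin = tuple(-idx * np.asarray(spacing))
        return cls(shape=shape, spacing=spacing, origin=origin, **kw)


@dataclass
class FluidProperties:
    """Newtonian blood: density kg/m^3, dynamic viscosity Pa*s."""

    density: float = 1060.0
    viscosity: float = 3.2e-3

    def __post_init__(self) -> None:
        if self.density <= 0 or self.viscosity <= 0:
            raise ValueError("density and viscosity must be > 0")


@dataclass
class VelocitySeries:
    """Time-resolved 3-component velocity field plus magnitude images.

    velocity : (n_frames, 3, nx, ny, nz) array, m/s
    magnitude : (n_frames, nx, ny, nz) array, arbitrary units, >= 0
    venc : velocity-encoding limit, cm/s
    cycle_fraction_covered : fraction of the cardiac cycle the frames span
    mask : optional label volume (0 background, 1..5 regions); out-of-mask
        voxels carry zero velocity and zero magnitude in clean phantoms.
    """

    grid: GridSpec
    velocity: np.ndarray
    magnitude: np.ndarray
    venc: float = 120.0
    cycle_fraction_covered: float = 1.0
    mask: np.ndarray | None = None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = (self.grid.n_frames, 3) + self.grid.shape
        if self.velocity.shape != expected:
            raise ValueError(f"velocity shape {self.velocity.shape} != {expected}")
        if self.magnitude.shape != (self.grid.n_frames,) + self.grid.shape:
            raise ValueError("magnitude shape mismatch")
        if not np.all(np.isfinite(self.velocity)):
            raise ValueError("velocity must be finite everywhere")
        if np.any(self.magnitude < 0):
            raise ValueError("magnitude must be >= 0")
        if not (0 < self.cycle_fraction_covered <= 1):
            raise ValueError("cycle_fraction_covered must be in (0, 1]")

    @property
    def n_frames(self) -> int:
        return self.grid.n_frames

    @property
    def venc_ms(self) -> float:
        return self.venc / 100.0

    def speed(self) -> np.ndarray:
        return np.sqrt((self.velocity ** 2).sum(axis=1))

    def lumen_mask(self) -> np.ndarray:
        if self.mask is None:
            return np.ones(self.grid.shape, dtype=bool)
        return self.mask > 0

    def copy(self) -> "VelocitySeries":
        return VelocitySeries(
            grid=dataclasses.replace(self.grid),
            velocity=self.velocity.copy(),
            magnitude=self.magnitude.copy(),
            venc=self.venc,
            cycle_fraction_covered=self.cycle_fraction_covered,
            mask=None if self.mask is None else self.mask.copy(),
            info=dict(self.info),
        )


@dataclass
class PhantomTruth:
    """Ground truth carried alongside a generated phantom."""

    split_fraction_lpa_from_ivc: float | None = None
    split_fraction_lpa_from_svc: float | None = None
    analytic_el_rate: float | None = None  # W, total over the segment
    analytic_ke: float | None = None       # J, total over the segment
    mask_labels: np.ndarray | None = None
    warnings: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in (self.split_fraction_lpa_from_ivc, self.split_fraction_lpa_from_svc):
            if f is not None and not (0.0 <= f <= 1.0):
                raise ValueError("split fractions must lie in [0, 1]")


# ---------------------------------------------------------------------------
# analytic oracle fields
# ---------------------------------------------------------------------------

def make_uniform_flow(grid: GridSpec, velocity_vector) -> VelocitySeries:
    """Spatially and temporally constant velocity field over the full grid."""
    vec = np.asarray(velocity_vector, dtype=float)
    if vec.shape != (3,) or not np.all(np.isfinite(vec)):
        raise ValueError("velocity_vector must be a finite 3-vector")
    vel = np.broadcast_to(vec[None, :, None, None, None],
                          (grid.n_frames, 3) + grid.shape).copy()
    mag = np.ones((grid.n_frames,) + grid.shape)
    mask = np.ones(grid.shape, dtype=np.int16)
    return VelocitySeries(grid=grid, velocity=vel, magnitude=mag, mask=mask)


def make_poiseuille_tube(grid: GridSpec, radius: float, length: float,
                         mean_velocity: float, axis=(0.0, 0.0, 1.0),
                         fluid: FluidProperties | None = None):
    """Steady Poiseuille tube centered in the grid.

    Axial velocity v(r) = 2*Vbar*(1 - r^2/R^2) inside the tube, zero outside.
    The returned truth carries the analytic total dissipation rate
    8*mu*L*Q^2/(pi*R^4) with Q = pi*R^2*Vbar, and the analytic kinetic
    energy (2*pi/3)*rho*Vbar^2*R^2*L.
    """
    fluid = fluid or FluidProperties()
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    center = grid.center()

    xs, ys, zs = grid.coords()
    rel = np.stack([xs - center[0], ys - center[1], zs - center[2]], axis=-1)
    a = rel @ ax                                    # axial coordinate, mm
    r2 = (rel ** 2).sum(axis=-1) - a ** 2
    r2 = np.clip(r2, 0.0, None)
    inside = (r2 <= radius ** 2) & (np.abs(a) <= length / 2.0)

    truth = PhantomTruth(mask_labels=inside.astype(np.int16))
    if radius < 3.0 * max(grid.spacing):
        truth.warnings.append(
            f"tube radius {radius} mm under-resolved at spacing {grid.spacing} mm")

    v_axial = np.where(inside, 2.0 * mean_velocity * (1.0 - r2 / radius ** 2), 0.0)
    vel = np.zeros((grid.n_frames, 3) + grid.shape)
    for c in range(3):
        vel[:, c] = v_axial[None] * ax[c]
    mag = np.where(inside, 1.0, 0.0)[None].repeat(grid.n_frames, axis=0)

    # The discrete tube's axial extent is a whole number of slices; the
    # closed-form truth uses that achieved length so it describes the
    # phantom actually generated (for axis-aligned tubes).
    L_eff = length
    ax_dim = int(np.argmax(np.abs(ax)))
    if abs(abs(ax[ax_dim]) - 1.0) < 1e-12:
        other = tuple(i for i in range(3) if i != ax_dim)
        n_slices = int(inside.any(axis=other).sum())
        if n_slices:
            L_eff = n_slices * grid.spacing[ax_dim]
    R_m, L_m = radius / 1000.0, L_eff / 1000.0
    Q = np.pi * R_m ** 2 * mean_velocity
    truth.analytic_el_rate = 8.0 * fluid.viscosity * L_m * Q ** 2 / (np.pi * R_m ** 4)
    truth.analytic_ke = (2.0 * np.pi / 3.0) * fluid.density * mean_velocity ** 2 * R_m ** 2 * L_m
    truth.extra.update({"achieved_length_mm": L_eff, "mean_velocity": mean_velocity,
                        "radius_mm": radius})
    series = VelocitySeries(grid=grid, velocity=vel, magnitude=mag,
                            mask=inside.astype(np.int16))
    return series, truth


def make_solid_body_rotation(grid: GridSpec, omega: float,
                             axis=(0.0, 0.0, 1.0)) -> VelocitySeries:
    """Rigid rotation v = omega x r inside a cylindrical mask.

    Rigid rotation has a purely antisymmetric velocity gradient, so the
    symmetric strain rate -- and hence the viscous dissipation -- is zero.
    """
    if not np.isfinite(omega):
        raise ValueError("omega must be finite")
    ax = np.asarray(axis, dtype=float)
    ax = ax / np.linalg.norm(ax)
    center = grid.center()

    xs, ys, zs = grid.coords()
    rel_mm = np.stack([xs - center[0], ys - center[1], zs - center[2]], axis=-1)
    a = rel_mm @ ax
    r_perp_mm = np.sqrt(np.clip((rel_mm ** 2).sum(axis=-1) - a ** 2, 0.0, None))

    half_extent = np.array([(grid.shape[i] - 1) * grid.spacing[i] / 2.0 for i in range(3)])
    perp = [i for i in range(3) if abs(ax[i]) < 0.99]
    R_mask = 0.9 * min(half_extent[i] for i in perp) if perp else 0.9 * half_extent.min()
    inside = r_perp_mm <= R_mask

    v = omega * np.cross(np.broadcast_to(ax, rel_mm.shape), rel_mm / 1000.0)  # m/s
    v[~inside] = 0.0
    vel = np.moveaxis(v, -1, 0)[None].repeat(grid.n_frames, axis=0)
    mag = np.where(inside, 1.0, 0.0)[None].repeat(grid.n_frames, axis=0)
    return VelocitySeries(grid=grid, velocity=vel, magnitude=mag,
                          mask=inside.astype(np.int16))


# ---------------------------------------------------------------------------
# TCPC junction streamfunction
# ---------------------------------------------------------------------------

_RAMP_A, _RAMP_B = 0.5, 1.5  # saturation of the junction blending map


def _sat(xi):
    """Odd C^2 saturating map: identity for |xi|<=0.5, exactly +-1 beyond 1.5."""
    xi = np.asarray(xi, dtype=float)
    s = np.sign(xi)
    u = np.abs(xi)
    core = np.minimum(u, _RAMP_A)
    w = np.clip(u - _RAMP_A, 0.0, _RAMP_B - _RAMP_A)
    ramp = 0.5 * w + 0.5 * (_RAMP_B - _RAMP_A) / np.pi * np.sin(np.pi * w / (_RAMP_B - _RAMP_A))
    return s * (core + ramp)


def _sat_prime(xi):
    xi = np.asarray(xi, dtype=float)
    u = np.abs(xi)
    out = np.zeros_like(u)
    out[u <= _RAMP_A] = 1.0
    mid = (u > _RAMP_A) & (u < _RAMP_B)
    out[mid] = 0.5 * (1.0 + np.cos(np.pi * (u[mid] - _RAMP_A) / (_RAMP_B - _RAMP_A)))
    return out


class _JunctionPatch:
    """Streamfunction on the unit square: bilinear corner interpolation plus
    a sine bump whose amplitude places the interior saddle at a prescribed
    streamfunction level (which fixes the caval flow splits)."""

    def __init__(self, c_sw, c_se, c_nw, c_ne, lam=0.0):
        self.c = (c_sw, c_se, c_nw, c_ne)
        self.lam = lam

    def value(self, s, t):
        c_sw, c_se, c_nw, c_ne = self.c
        return (c_sw * (1 - s) * (1 - t) + c_se * s * (1 - t)
                + c_nw * (1 - s) * t + c_ne * s * t
                + self.lam * np.sin(np.pi * s) * np.sin(np.pi * t))

    def grad(self, s, t):
        c_sw, c_se, c_nw, c_ne = self.c
        ds = (-c_sw * (1 - t) + c_se * (1 - t) - c_nw * t + c_ne * t
              + self.lam * np.pi * np.cos(np.pi * s) * np.sin(np.pi * t))
        dt = (-c_sw * (1 - s) - c_se * s + c_nw * (1 - s) + c_ne * s
              + self.lam * np.pi * np.sin(np.pi * s) * np.cos(np.pi * t))
        return ds, dt

    def _hessian(self, s, t):
        c_sw, c_se, c_nw, c_ne = self.c
        cross = c_sw - c_se - c_nw + c_ne + self.lam * np.pi ** 2 * np.cos(np.pi * s) * np.cos(np.pi * t)
        diag = -self.lam * np.pi ** 2 * np.sin(np.pi * s) * np.sin(np.pi * t)
        return np.array([[diag, cross], [cross, diag]])

    def saddle(self):
        """Locate the interior critical point by Newton iteration."""
        p = np.array([0.5, 0.5])
        for _ in range(60):
            g = np.array(self.grad(*p))
            H = self._hessian(*p)
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            p = p - step
            p = np.clip(p, 1e-3, 1 - 1e-3)
            if np.linalg.norm(g) < 1e-13:
                break
        return p, float(self.value(*p))


def _solve_junction(q_ivc, q_svc, split_ivc_to_lpa, split_svc_to_lpa):
    """Build the junction patch whose saddle level realizes the desired splits."""
    q_lpa = split_ivc_to_lpa * q_ivc + split_svc_to_lpa * q_svc
    q_rpa = (1 - split_ivc_to_lpa) * q_ivc + (1 - split_svc_to_lpa) * q_svc
    corners = (q_ivc, 0.0, q_ivc - q_lpa, q_rpa)  # SW, SE, NW, NE
    target = (1.0 - split_ivc_to_lpa) * q_ivc     # saddle streamfunction level

    def residual(lam):
        patch = _JunctionPatch(*corners, lam=lam)
        _, val = patch.saddle()
        return val - target

    r0 = residual(0.0)
    if abs(r0) < 1e-12 * max(q_ivc + q_svc, 1e-30):
        lam = 0.0
    else:
        scale = q_ivc + q_svc
        lam = None
        for hi in (0.1, 0.2, 0.4, 0.8, 1.2):
            lo_b, hi_b = -hi * scale, hi * scale
            if residual(lo_b) * residual(hi_b) < 0:
                lam = brentq(residual, lo_b, hi_b, xtol=1e-14 * scale)
                break
        if lam is None:
            raise RuntimeError("could not place the junction saddle for the requested splits")
    patch = _JunctionPatch(*corners, lam=lam)
    _, val = patch.saddle()
    return patch, {"saddle_level": val, "target_level": target, "lambda": lam,
                   "q_ivc": q_ivc, "q_svc": q_svc, "q_lpa": q_lpa, "q_rpa": q_rpa}


def default_tcpc_grid(spacing=(2.4, 2.0, 2.4), n_frames=20, frame_duration=40.0,
                      half_width=12.0, limb_length=40.0, slab=24.0) -> GridSpec:
    """Study-like acquisition grid for the TCPC phantom (anisotropic ~2 mm
    voxels, 20 frames at 40 ms)."""
    extent_xy = 2 * (half_width + limb_length) + 2 * max(spacing[:2])
    extent_z = slab + 4 * spacing[2]
    shape = tuple(int(np.ceil(e / s)) // 2 * 2 + 1
                  for e, s in zip((extent_xy, extent_xy, extent_z), spacing))
    return GridSpec.centered(shape, spacing, n_frames=n_frames, frame_duration=frame_duration)


def make_tcpc_phantom(grid: GridSpec | None = None,
                      split_ivc_to_lpa: float = 0.5,
                      split_svc_to_lpa: float = 0.5,
                      pulsatility: float = 0.3,
                      n_frames: int | None = None,
                      mean_ivc_speed: float = 0.3,
                      svc_flow_ratio: float = 2.0 / 3.0,
                      half_width: float = 12.0,
                      limb_length: float = 40.0,
                      slab: float = 24.0,
                      venc: float = 120.0,
                      tissue_shell: bool = False):
    """Cross-shaped TCPC phantom with exact, streamfunction-derived flow splits.

    Geometry (mm, grid-centered): a vertical channel of half-width
    ``half_width`` carries the IVC (bottom, flowing up) and SVC (top,
    flowing down); a horizontal channel carries the LPA (left) and RPA
    (right) outflows.  The 2D in-plane field is extruded over a slab of
    thickness ``slab``; the out-of-plane velocity component is zero.
    Temporal modulation is a global factor 1 + pulsatility*sin(2*pi*t/T).

    Returns ``(VelocitySeries, PhantomTruth, RegionModel)``.
    """
    if not (0.0 <= split_ivc_to_lpa <= 1.0 and 0.0 <= split_svc_to_lpa <= 1.0):
        raise ValueError("splits must lie in [0, 1]")
    if not (0.0 <= pulsatility < 1.0):
        raise ValueError("pulsatility must lie in [0, 1)")
    if grid is None:
        grid = default_tcpc_grid(half_width=half_width, limb_length=limb_length, slab=slab)
    if n_frames is not None:
        grid = dataclasses.replace(grid, n_frames=n_frames)

    W = half_width
    W_m = W / 1000.0
    U = mean_ivc_speed
    q_ivc = U * 2.0 * W_m                 # 2D flux per unit depth, m^2/s
    q_svc = svc_flow_ratio * q_ivc
    patch, jinfo = _solve_junction(q_ivc, q_svc, split_ivc_to_lpa, split_svc_to_lpa)

    xs, ys, zs = grid.coords()
    extent = W + limb_length
    # tolerance keeps wall-voxel inclusion mirror-symmetric despite floating
    # point (e.g. a voxel center at 12.000000000000004 vs -12.0)
    eps = 1e-6
    vertical = (np.abs(xs) <= W + eps) & (np.abs(ys) <= extent + eps)
    horizontal = (np.abs(ys) <= W + eps) & (np.abs(xs) <= extent + eps)
    in_slab = np.abs(zs) <= slab / 2.0 + eps
    lumen = (vertical | horizontal) & in_slab

    # Streamfunction sampled on the grid; in-plane velocity from *discrete*
    # central differences of psi, so the discrete central divergence vanishes
    # identically (mixed central differences commute).  psi is linear across
    # the limbs, where central differencing is exact plug flow.
    s = (_sat(xs / W) + 1.0) / 2.0
    t = (_sat(ys / W) + 1.0) / 2.0
    psi = patch.value(s, t)                      # m^2/s
    hx_m, hy_m = grid.spacing[0] / 1000.0, grid.spacing[1] / 1000.0
    u = np.gradient(psi, hy_m, axis=1)           # dpsi/dy, m/s
    v = -np.gradient(psi, hx_m, axis=0)
    u = np.where(lumen, u, 0.0)
    v = np.where(lumen, v, 0.0)

    labels = np.zeros(grid.shape, dtype=np.int16)
    labels[lumen & (ys < -W - eps)] = REGION_LABELS["IVC"]
    labels[lumen & (ys > W + eps)] = REGION_LABELS["SVC"]
    labels[lumen & (xs < -W - eps)] = REGION_LABELS["LPA"]
    labels[lumen & (xs > W + eps)] = REGION_LABELS["RPA"]
    labels[lumen & (np.abs(xs) <= W + eps) & (np.abs(ys) <= W + eps)] = REGION_LABELS["connection"]

    T = grid.covered_duration_s
    times = np.arange(grid.n_frames) * grid.frame_duration / 1000.0
    modulation = 1.0 + pulsatility * np.sin(2.0 * np.pi * times / T)
    vel = np.zeros((grid.n_frames, 3) + grid.shape)
    vel[:, 0] = modulation[:, None, None, None] * u[None]
    vel[:, 1] = modulation[:, None, None, None] * v[None]

    mag = np.where(lumen, 1.0, 0.0)
    if tissue_shell:
        shell = ndimage.binary_dilation(lumen, iterations=3) & ~lumen
        mag = mag + np.where(shell, 0.4, 0.0)
    mag = mag[None].repeat(grid.n_frames, axis=0)

    series = VelocitySeries(grid=grid, velocity=vel, magnitude=mag, venc=venc,
                            mask=labels, info={"junction": jinfo})
    truth = PhantomTruth(split_fraction_lpa_from_ivc=split_ivc_to_lpa,
                         split_fraction_lpa_from_svc=split_svc_to_lpa,
                         mask_labels=labels, extra=jinfo)
    region = _tcpc_region_model(grid, labels, W, extent, slab)
    return series, truth, region


def _tcpc_region_model(grid, labels, W, extent, slab) -> RegionModel:
    radius = float(np.hypot(W, slab / 2.0)) + 2.0
    # Entrance (counting) planes sit a couple of voxels distal of the
    # junction, inside the straight limb, so that every pulmonary-artery
    # pathline -- including wall-hugging ones that cut the junction corner --
    # crosses them within the plane radius.
    off = W + 2.0 * max(grid.spacing[0], grid.spacing[1])
    planes = [
        AnalysisPlane(origin=(-off, 0.0, 0.0), normal=(-1.0, 0.0, 0.0),
                      in_plane_radius=radius, role="LPA_entrance"),
        AnalysisPlane(origin=(off, 0.0, 0.0), normal=(1.0, 0.0, 0.0),
                      in_plane_radius=radius, role="RPA_entrance"),
        AnalysisPlane(origin=(-W, 0.0, 0.0), normal=(-1.0, 0.0, 0.0),
                      in_plane_radius=radius, role="region_boundary"),
        AnalysisPlane(origin=(W, 0.0, 0.0), normal=(1.0, 0.0, 0.0),
                      in_plane_radius=radius, role="region_boundary"),
        AnalysisPlane(origin=(0.0, -W, 0.0), normal=(0.0, -1.0, 0.0),
                      in_plane_radius=radius, role="region_boundary"),
        AnalysisPlane(origin=(0.0, W, 0.0), normal=(0.0, 1.0, 0.0),
                      in_plane_radius=radius, role="region_boundary"),
    ]

    def straight(p0, p1):
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        n = max(2, int(np.linalg.norm(p1 - p0)) + 1)
        pts = np.linspace(p0, p1, n)
        s = np.linalg.norm(pts - p0, axis=1)
        tang = np.tile((p1 - p0) / np.linalg.norm(p1 - p0), (n, 1))
        return Centerline(points=pts, arclength=s, tangents=tang)

    centerlines = {
        "IVC": straight((0.0, -extent, 0.0), (0.0, 0.0, 0.0)),
        "SVC": straight((0.0, extent, 0.0), (0.0, 0.0, 0.0)),
        "LPA": straight((0.0, 0.0, 0.0), (-extent, 0.0, 0.0)),
        "RPA": straight((0.0, 0.0, 0.0), (extent, 0.0, 0.0)),
    }
    return RegionModel(labels=labels, centerlines=centerlines, boundary_planes=planes,
                       spacing=grid.spacing, origin=grid.origin)


# ---------------------------------------------------------------------------
# MRI corruption model
# ---------------------------------------------------------------------------

POLY_TERMS_ORDER1 = ("1", "x", "y", "z")
POLY_TERMS_ORDER2 = POLY_TERMS_ORDER1 + ("x2", "y2", "z2", "xy", "xz", "yz")


def polynomial_design_matrix(xs, ys, zs, order: int) -> np.ndarray:
    """Spatial polynomial basis evaluated at world mm coordinates (flattened)."""
    x, y, z = (np.ravel(a).astype(float) for a in (xs, ys, zs))
    cols = [np.ones_like(x), x, y, z]
    if order == 2:
        cols += [x * x, y * y, z * z, x * y, x * z, y * z]
    elif order != 1:
        raise ValueError("poly order must be 1 or 2")
    return np.stack(cols, axis=1)


def corrupt(series: VelocitySeries, noise_sd: float = 0.0,
            offset_poly_coeffs=None, alias: bool = False,
            seed: int = DEFAULT_SEED) -> VelocitySeries:
    """Apply the MRI corruption model: Gaussian velocity noise, a smooth
    per-component spatial polynomial phase offset, and venc wrap-around.

    Aliasing maps each stored component to v - 2*venc*round(v / (2*venc)),
    so wrapped values always land in [-venc, +venc].  The number of entries
    wrapped is recorded in ``out.info["n_aliased"]``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    out = series.copy()
    rng = np.random.default_rng(seed)

    if offset_poly_coeffs is not None:
        coeffs = np.asarray(offset_poly_coeffs, dtype=float)
        if coeffs.ndim != 2 or coeffs.shape[0] != 3 or coeffs.shape[1] not in (4, 10):
            raise ValueError("offset_poly_coeffs must have shape (3, 4) or (3, 10)")
        order = 1 if coeffs.shape[1] == 4 else 2
        xs, ys, zs = out.grid.coords()
        X = polynomial_design_matrix(xs, ys, zs, order)
        for c in range(3):
            out.velocity[:, c] += (X @ coeffs[c]).reshape(out.grid.shape)[None]

    if noise_sd > 0:
        out.velocity += rng.normal(0.0, noise_sd, size=out.velocity.shape)

    n_aliased = 0
    if alias:
        venc = out.venc_ms
        wraps = np.round(out.velocity / (2.0 * venc))
        n_aliased = int(np.count_nonzero(wraps))
        out.velocity = out.velocity - 2.0 * venc * wraps

    out.info.update({"noise_sd": noise_sd, "n_aliased": n_aliased,
                     "aliased": bool(alias), "corruption_seed": seed})
    return out


# ---------------------------------------------------------------------------
# synthetic longitudinal cohort (statistics-stage plumbing)
# ---------------------------------------------------------------------------

COHORT_METRICS = ("peak_velocity", "stasis", "kinetic_energy", "el_tot", "el_mean")
COHORT_REGIONS = ("IVC", "SVC", "connection", "LPA", "RPA")

# Annualized peak-velocity drift (m/s/year): mean and SD for the groups with
# unequal vs equal baseline IVC flow distribution.
_DRIFT_UNEQUAL = (0.024, 0.066)
_DRIFT_EQUAL = (0.003, 0.038)


def make_longitudinal_cohort(n_subjects: int = 10, seed: int = DEFAULT_SEED,
                             n_unequal: int = 5) -> pd.DataFrame:
    """Synthetic per-subject regional metrics at baseline and follow-up.

    Emulates the longitudinal study design: ``n_subjects`` Fontan patients,
    half with unequal baseline IVC flow distribution; unequal-flow subjects
    drift faster in peak velocity, and annualized energy-loss changes are
    linearly coupled to annualized peak-velocity changes with noise.  Output
    is long-format: (subject, region, metric, timepoint, value,
    followup_years, fd_ivc_baseline).
    """
    rng = np.random.default_rng(seed)
    base_scale = {"peak_velocity": (0.6, 0.12), "stasis": (20.0, 6.0),
                  "kinetic_energy": (2.0e-3, 0.5e-3), "el_tot": (3.0e-3, 0.8e-3),
                  "el_mean": (2.0e-3, 0.5e-3)}
    rows = []
    for i in range(n_subjects):
        unequal = i < n_unequal
        fd = rng.uniform(0.72, 0.85) if unequal else rng.uniform(0.35, 0.65)
        years = rng.uniform(1.0, 5.0)
        drift_mu, drift_sd = _DRIFT_UNEQUAL if unequal else _DRIFT_EQUAL
        for region in COHORT_REGIONS:
            dv = rng.normal(drift_mu, drift_sd)
            baseline = {m: max(rng.normal(*base_scale[m]), 0.05 * base_scale[m][0])
                        for m in COHORT_METRICS}
            follow = dict(baseline)
            follow["peak_velocity"] = baseline["peak_velocity"] + dv * years
            # EL changes track peak-velocity changes (linear with noise)
            follow["el_tot"] = baseline["el_tot"] + (0.010 * dv + rng.normal(0, 4.1e-4)) * years
            follow["el_mean"] = baseline["el_mean"] + (0.008 * dv + rng.normal(0, 3.5e-4)) * years
            follow["kinetic_energy"] = baseline["kinetic_energy"] + (
                0.004 * dv + rng.normal(0, 3.0e-4)) * years
            follow["stasis"] = max(baseline["stasis"] + rng.normal(-0.5, 1.5) * years, 0.0)
            for tp, vals in (("baseline", baseline), ("followup", follow)):
                for m in COHORT_METRICS:
                    rows.append({"subject": f"S{i:02d}", "region": region, "metric": m,
                                 "timepoint": tp, "value": vals[m],
                                 "followup_years": years, "fd_ivc_baseline": fd})
    return pd.DataFrame(rows)
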