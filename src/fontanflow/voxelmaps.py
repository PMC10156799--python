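"""Voxel-wise hemodynamic maps and regional summaries.

Implements the five metrics computed per voxel over the (resampled,
cycle-fraction-truncated) 4D flow series:

==============  =============================================================
peak velocity   max over frames of the speed; regional value = 98th
                percentile over the ROI
stasis          percent of frames with speed < 0.1 m/s; regional mean
KE              kinetic energy 0.5 * rho * voxel_volume * |v|^2 per frame,
                summed over frames (J); regional mean
EL_tot          viscous energy loss rate mu * voxel_volume * phi_v
                integrated over the covered cycle (J); regional mean
EL_mean         time-averaged energy-loss rate (W); regional mean
==============  =============================================================

phi_v is the viscous dissipation function
``0.5 * sum_ij [(dv_j/dx_i + dv_i/dx_j) - (2/3)(div V) delta_ij]^2`` with
velocity gradients taken by central differences at interior lumen voxels
and one-sided differences at the lumen boundary (out-of-mask neighbors are
excluded, not zero-filled, to avoid spurious wall shear).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import LABEL_NAMES, RegionModel
from .phantom import FluidProperties, GridSpec, VelocitySeries

STASIS_THRESHOLD_MS = 0.1   # m/s
PEAK_PERCENTILE = 98.0


@dataclass
class HemodynamicMaps:
    """Voxel-wise metric volumes on a common grid."""

    peak_velocity: np.ndarray   # m/s
    stasis: np.ndarray          # percent of frames
    kinetic_energy: np.ndarray  # J, summed over frames
    el_tot: np.ndarray          # J, time integral of EL rate
    el_mean: np.ndarray         # W, time average of EL rate
    voxel_volume: float         # m^3
    covered_duration: float     # s
    lumen: np.ndarray | None = None


@dataclass
class RegionalSummary:
    """Per-region reductions of the voxel-wise maps."""

    region: str
    peak_velocity_p98: float
    stasis_mean: float
    ke_mean: float
    el_tot_mean: float
    el_mean_mean: float
    n_voxels: int = 0


# ---------------------------------------------------------------------------
# harmonization across scans
# ---------------------------------------------------------------------------

def truncate_to_common_fraction(series_list):
    """Truncate scans to the cardiac-cycle fraction covered by all of them.

    The minimum covered fraction across the scans is selected, and each
    series keeps its first ``floor(common / per-frame fraction)`` frames (at
    least one), so all outputs cover the same fraction within one frame.
    Late-cycle frames (end-diastole) are the ones dropped.
    """
    if not series_list:
        raise ValueError("series list is empty")
    common = min(s.cycle_fraction_covered for s in series_list)
    out = []
    for s in series_list:
        per_frame = s.cycle_fraction_covered / s.n_frames
        keep = max(1, int(np.floor(common / per_frame + 1e-9)))
        if keep >= s.n_frames:
            out.append(s)
            continue
        grid = dataclasses.replace(s.grid, n_frames=keep)
        out.append(VelocitySeries(
            grid=grid, velocity=s.velocity[:keep].copy(),
            magnitude=s.magnitude[:keep].copy(), venc=s.venc,
            cycle_fraction_covered=keep * per_frame,
            mask=None if s.mask is None else s.mask.copy(), info=dict(s.info)))
    return out


def resample_isotropic(series: VelocitySeries, target: float = 1.0) -> VelocitySeries:
    """Trilinear resampling onto an isotropic grid covering the same extent.

    Velocity components and magnitude are interpolated linearly per frame;
    the label mask is resampled nearest-neighbor.
    """
    if target <= 0:
        raise ValueError("target spacing must be > 0")
    g = series.grid
    extent = [(g.shape[i] - 1) * g.spacing[i] for i in range(3)]
    new_shape = tuple(int(np.floor(e / target + 1e-9)) + 1 for e in extent)
    new_grid = GridSpec(shape=new_shape, spacing=(target,) * 3, n_frames=g.n_frames,
                        frame_duration=g.frame_duration, origin=g.origin)
    # sample coordinates of the new voxel centers in old index space
    axes = [np.arange(n) * target / g.spacing[i] for i, n in enumerate(new_shape)]
    mesh = np.meshgrid(*axes, indexing="ij")
    coords = np.stack([m.ravel() for m in mesh])

    vel = np.empty((g.n_frames, 3) + new_shape)
    mag = np.empty((g.n_frames,) + new_shape)
    for f in range(g.n_frames):
        for c in range(3):
            vel[f, c] = ndimage.map_coordinates(
                series.velocity[f, c], coords, order=1, mode="nearest").reshape(new_shape)
        mag[f] = ndimage.map_coordinates(
            series.magnitude[f], coords, order=1, mode="nearest").reshape(new_shape)
    mask = None
    if series.mask is not None:
        mask = ndimage.map_coordinates(
            series.mask.astype(np.int16), coords, order=0, mode="nearest").reshape(new_shape)
    return VelocitySeries(grid=new_grid, velocity=vel, magnitude=mag, venc=series.venc,
                          cycle_fraction_covered=series.cycle_fraction_covered,
                          mask=mask, info=dict(series.info))


# ---------------------------------------------------------------------------
# masked velocity gradients
# ---------------------------------------------------------------------------

def masked_gradient(vol: np.ndarray, mask: np.ndarray, spacing_m: float,
                    axis: int) -> np.ndarray:
    """d(vol)/dx_axis restricted to the mask.

    Central differences where both neighbors are in the mask; second-order
    (three-point, exact for quadratics) or two-point one-sided differences
    at the mask boundary; zero where no in-mask neighbor exists.
    """
    def shift(arr, n):
        out = np.zeros_like(arr)
        src = [slice(None)] * arr.ndim
        dst = [slice(None)] * arr.ndim
        if n > 0:
            src[axis] = slice(n, None)
            dst[axis] = slice(None, -n)
        elif n < 0:
            src[axis] = slice(None, n)
            dst[axis] = slice(-n, None)
        out[tuple(dst)] = arr[tuple(src)]
        return out

    m = mask.astype(bool)
    f = np.where(m, vol, 0.0)
    mp1, mm1 = shift(m, 1), shift(m, -1)
    mp2, mm2 = shift(m, 2), shift(m, -2)
    fp1, fm1 = shift(f, 1), shift(f, -1)
    fp2, fm2 = shift(f, 2), shift(f, -2)

    grad = np.zeros_like(f)
    central = m & mp1 & mm1
    fwd2 = m & mp1 & mp2 & ~mm1
    bwd2 = m & mm1 & mm2 & ~mp1
    fwd1 = m & mp1 & ~mm1 & ~mp2
    bwd1 = m & mm1 & ~mp1 & ~mm2

    grad[central] = (fp1[central] - fm1[central]) / (2 * spacing_m)
    grad[fwd2] = (-3 * f[fwd2] + 4 * fp1[fwd2] - fp2[fwd2]) / (2 * spacing_m)
    grad[bwd2] = (3 * f[bwd2] - 4 * fm1[bwd2] + fm2[bwd2]) / (2 * spacing_m)
    grad[fwd1] = (fp1[fwd1] - f[fwd1]) / spacing_m
    grad[bwd1] = (f[bwd1] - fm1[bwd1]) / spacing_m
    return grad


def viscous_dissipation(velocity_frame: np.ndarray, mask: np.ndarray,
                        spacing_mm) -> np.ndarray:
    """Viscous dissipation function phi_v (1/s^2) for one frame.

    phi_v = 0.5 * sum_ij [(dv_j/dx_i + dv_i/dx_j) - (2/3)(div V) d_ij]^2.
    The divergence term is retained even though measured fields are not
    exactly divergence-free.
    """
    sp_m = [s / 1000.0 for s in spacing_mm]
    G = np.empty((3, 3) + velocity_frame.shape[1:])
    for i in range(3):        # derivative axis
        for j in range(3):    # component
            G[i, j] = masked_gradient(velocity_frame[j], mask, sp_m[i], axis=i)
    div = G[0, 0] + G[1, 1] + G[2, 2]
    phi = np.zeros(velocity_frame.shape[1:])
    for i in range(3):
        for j in range(3):
            term = G[i, j] + G[j, i] - (2.0 / 3.0) * div * (1.0 if i == j else 0.0)
            phi += term ** 2
    phi *= 0.5
    return np.where(mask, phi, 0.0)


# ---------------------------------------------------------------------------
# the five maps
# ---------------------------------------------------------------------------

def peak_velocity_map(series: VelocitySeries) -> np.ndarray:
    """Per-voxel maximum speed over all frames (m/s), zero outside the lumen."""
    lum = series.lumen_mask()
    return np.where(lum, series.speed().max(axis=0), 0.0)


def stasis_map(series: VelocitySeries, threshold: float = STASIS_THRESHOLD_MS) -> np.ndarray:
    """Percent of frames with speed below ``threshold``, per voxel."""
    if threshold <= 0:
        raise ValueError("stasis threshold must be > 0")
    lum = series.lumen_mask()
    frac = (series.speed() < threshold).mean(axis=0) * 100.0
    return np.where(lum, frac, 0.0)


def kinetic_energy_map(series: VelocitySeries,
                       fluid: FluidProperties | None = None) -> np.ndarray:
    """Voxel-wise kinetic energy 0.5*rho*V*|v|^2 summed over frames (J)."""
    fluid = fluid or FluidProperties()
    vox_m3 = series.grid.voxel_volume_mm3 * 1e-9
    lum = series.lumen_mask()
    ke = 0.5 * fluid.density * vox_m3 * (series.speed() ** 2).sum(axis=0)
    return np.where(lum, ke, 0.0)


def energy_loss_maps(series: VelocitySeries, fluid: FluidProperties | None = None):
    """Total (J) and mean (W) viscous energy loss per voxel.

    The per-frame EL rate is mu * voxel_volume * phi_v.  EL_tot integrates
    the rate over the covered cycle by the midpoint rule in time (each frame
    weighted by the frame duration, equivalent to a trapezoid on frame
    midtimes with constant end extension); EL_mean is the frame average, so
    EL_mean * covered duration == EL_tot identically.
    """
    fluid = fluid or FluidProperties()
    lum = series.lumen_mask()
    spans = [np.ptp(np.nonzero(lum.any(axis=tuple(j for j in range(3) if j != i)))[0])
             for i in range(3)] if lum.any() else [0, 0, 0]
    if lum.sum() < 8 or min(spans) < 1:
        raise ValueError("lumen mask is degenerate (needs >= 2 voxels span per axis)")
    vox_m3 = series.grid.voxel_volume_mm3 * 1e-9
    rate = np.empty((series.n_frames,) + series.grid.shape)
    for f in range(series.n_frames):
        phi = viscous_dissipation(series.velocity[f], lum, series.grid.spacing)
        rate[f] = fluid.viscosity * vox_m3 * phi
    dt_s = series.grid.frame_duration / 1000.0
    el_tot = rate.sum(axis=0) * dt_s
    el_mean = rate.mean(axis=0)
    return el_tot, el_mean


def compute_hemodynamic_maps(series: VelocitySeries,
                             fluid: FluidProperties | None = None,
                             stasis_threshold: float = STASIS_THRESHOLD_MS) -> HemodynamicMaps:
    """All five voxel-wise maps for one series (expects isotropic ~1 mm input)."""
    fluid = fluid or FluidProperties()
    el_tot, el_mean = energy_loss_maps(series, fluid)
    return HemodynamicMaps(
        peak_velocity=peak_velocity_map(series),
        stasis=stasis_map(series, stasis_threshold),
        kinetic_energy=kinetic_energy_map(series, fluid),
        el_tot=el_tot,
        el_mean=el_mean,
        voxel_volume=series.grid.voxel_volume_mm3 * 1e-9,
        covered_duration=series.grid.covered_duration_s,
        lumen=series.lumen_mask(),
    )


def regional_summary(maps: HemodynamicMaps, regions: RegionModel):
    """Table-style reductions over each of the five regions.

    Peak velocity is summarized by its 98th percentile (linear interpolation
    between order statistics); the other maps by their ROI mean.
    """
    if maps.peak_velocity.shape != regions.labels.shape:
        raise ValueError("maps and region labels must share a grid")
    out = []
    for value in sorted(LABEL_NAMES):
        name = LABEL_NAMES[value]
        sel = regions.labels == value
        if not sel.any():
            raise ValueError(f"region {name} is empty")
        out.append(RegionalSummary(
            region=name,
            peak_velocity_p98=float(np.percentile(maps.peak_velocity[sel], PEAK_PERCENTILE)),
            stasis_mean=float(maps.stasis[sel].mean()),
            ke_mean=float(maps.kinetic_energy[sel].mean()),
            el_tot_mean=float(maps.el_tot[sel].mean()),
            el_mean_mean=float(maps.el_mean[sel].mean()),
            n_voxels=int(sel.sum()),
        ))
    return out


def summary_table(summaries) -> pd.DataFrame:
    """Regional summaries as a tidy DataFrame (region, metric, value, units)."""
    rows = []
    units = {"peak_velocity_p98": "m/s", "stasis_mean": "%", "ke_mean": "J",
             "el_tot_mean": "J", "el_mean_mean": "W"}
    for s in summaries:
        for metric, unit in units.items():
            rows.append({"region": s.region, "metric": metric,
                         "value": getattr(s, metric), "units": unit})
    return pd.DataFrame(rows)
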