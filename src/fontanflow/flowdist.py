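"""Pathline-based caval flow distribution.

Particles ("emitters") are seeded throughout the segmented IVC or SVC at a
prescribed density, advected through the time-resolved velocity field by
4th-order Runge-Kutta integration with trilinear spatial and linear
(periodic) temporal interpolation, and counted as they first cross the
analysis plane at the entrance of the LPA or RPA.  The flow distribution to
each pulmonary artery is the fraction of counted pathlines reaching its
plane; a distribution below 30% or above 70% to the LPA is classified as
unequal (strict inequalities).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import AnalysisPlane, RegionModel, REGION_LABELS
from .phantom import DEFAULT_SEED, VelocitySeries

LOW_SPEED_MS = 1e-3        # m/s; below this for 5 straight steps = stagnant
LOW_SPEED_STEPS = 5


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class EmitterSet:
    """Quasi-uniform particle seeds inside a caval source region."""

    positions: np.ndarray          # (n, 3) world mm
    source_label: str              # "IVC" or "SVC"
    density: float                 # requested emitters per cm^3
    achieved_density: float = np.nan

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class PathlineSet:
    """Traced particle trajectories with termination bookkeeping.

    termination_reason entries are one of ``{"left_mask", "low_velocity",
    "crossed_plane", "max_time"}``; first_plane_crossed entries are
    ``{"LPA", "RPA", "none"}``.
    """

    times: list                    # per trajectory: (k,) seconds
    positions: list                # per trajectory: (k, 3) mm
    termination_reason: list
    first_plane_crossed: list
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class FlowDistributionResult:
    """Pathline counts, Eq.-style fractions, and the 30-70% classification."""

    n_lpa: int = 0
    n_rpa: int = 0
    fraction_lpa: float = np.nan
    fraction_rpa: float = np.nan
    classification: str = "undefined"
    validity_fraction: float = np.nan
    n_pathlines: int = 0


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def seed_emitters(region: RegionModel, source: str, density: float = 30.0,
                  seed: int = DEFAULT_SEED) -> EmitterSet:
    """Jittered-grid seeding of a caval source region at ``density``/cm^3.

    One candidate point is drawn uniformly inside each cell of a cubic
    lattice with pitch (1000/density)^(1/3) mm covering the region's
    bounding box; candidates whose nearest voxel carries the source label
    are kept, so the expected achieved density equals the request.
    """
    if source not in ("IVC", "SVC"):
        raise ValueError("source must be 'IVC' or 'SVC'")
    label = REGION_LABELS[source]
    vox = np.argwhere(region.labels == label)
    if len(vox) == 0:
        raise ValueError(f"source region {source} is empty")
    volume_cm3 = len(vox) * region.voxel_volume_cm3()
    if density <= 0:
        return EmitterSet(positions=np.empty((0, 3)), source_label=source,
                          density=density, achieved_density=0.0)

    spacing = np.asarray(region.spacing)
    origin = np.asarray(region.origin)
    lo = vox.min(axis=0) * spacing + origin - spacing / 2
    hi = vox.max(axis=0) * spacing + origin + spacing / 2
    pitch = (1000.0 / density) ** (1.0 / 3.0)   # mm
    rng = np.random.default_rng(seed)

    n_cells = np.maximum(np.ceil((hi - lo) / pitch).astype(int), 1)
    cells = np.stack(np.meshgrid(*[np.arange(n) for n in n_cells], indexing="ij"),
                     axis=-1).reshape(-1, 3)
    pts = lo + (cells + rng.uniform(0.0, 1.0, size=cells.shape)) * pitch

    idx = np.round((pts - origin) / spacing).astype(int)
    ok = np.all((idx >= 0) & (idx < region.labels.shape), axis=1)
    keep = np.zeros(len(pts), dtype=bool)
    keep[ok] = region.labels[tuple(idx[ok].T)] == label
    pts = pts[keep]
    return EmitterSet(positions=pts, source_label=source, density=density,
                      achieved_density=len(pts) / volume_cm3)


# ---------------------------------------------------------------------------
# field sampling
# ---------------------------------------------------------------------------

class _FieldSampler:
    """Trilinear-in-space, linear-in-time (periodic) velocity interpolation."""

    def __init__(self, series: VelocitySeries):
        self.vel = series.velocity                    # (F, 3, nx, ny, nz)
        self.grid = series.grid
        self.spacing = np.asarray(series.grid.spacing)
        self.origin = np.asarray(series.grid.origin)
        self.shape = np.asarray(series.grid.shape)
        self.period = series.grid.covered_duration_s
        self.n_frames = series.n_frames
        self.lumen = series.lumen_mask()

    def _frame_weights(self, t: float):
        if self.n_frames == 1:
            return 0, 0, 0.0
        tau = (t % self.period) / (self.period / self.n_frames)
        k = int(np.floor(tau)) % self.n_frames
        return k, (k + 1) % self.n_frames, tau - np.floor(tau)

    def velocity_at(self, pts_mm: np.ndarray, t: float) -> np.ndarray:
        """Velocity (m/s) at world points; zero outside the grid."""
        k0, k1, w = self._frame_weights(t)
        idx = (pts_mm - self.origin) / self.spacing
        inside = np.all((idx >= 0) & (idx <= self.shape - 1), axis=1)
        out = np.zeros((len(pts_mm), 3))
        if not inside.any():
            return out
        f = idx[inside]
        i0 = np.floor(f).astype(int)
        i0 = np.minimum(i0, self.shape - 2)
        d = f - i0
        acc = np.zeros((inside.sum(), 3))
        for dx in (0, 1):
            wx = d[:, 0] if dx else 1 - d[:, 0]
            for dy in (0, 1):
                wy = d[:, 1] if dy else 1 - d[:, 1]
                for dz in (0, 1):
                    wz = d[:, 2] if dz else 1 - d[:, 2]
                    wgt = (wx * wy * wz)[:, None]
                    ix, iy, iz = i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz
                    v = self.vel[k0, :, ix, iy, iz]
                    if w > 0:
                        v = (1 - w) * v + w * self.vel[k1, :, ix, iy, iz]
                    acc += wgt * v
        out[inside] = acc
        return out

    def in_lumen(self, pts_mm: np.ndarray) -> np.ndarray:
        idx = np.round((pts_mm - self.origin) / self.spacing).astype(int)
        ok = np.all((idx >= 0) & (idx < self.shape), axis=1)
        res = np.zeros(len(pts_mm), dtype=bool)
        res[ok] = self.lumen[tuple(idx[ok].T)]
        return res


# ---------------------------------------------------------------------------
# tracing
# ---------------------------------------------------------------------------

def trace_pathlines(series: VelocitySeries, emitters: EmitterSet,
                    dt: float | None = None, max_cycles: int = 3,
                    stop_planes: list | None = None) -> PathlineSet:
    """Integrate dx/dt = V(x, t) with RK4 from every emitter.

    ``dt`` is in milliseconds (default frame_duration / 5).  Time wraps
    periodically over the covered cardiac cycle for up to ``max_cycles``
    cycles.  A trajectory terminates on leaving the lumen, on sustained
    near-zero speed, on crossing one of ``stop_planes`` (entrance planes,
    recorded with the plane role's artery), or at the time horizon.
    """
    if max_cycles < 1:
        raise ValueError("max_cycles must be >= 1")
    dt_ms = series.grid.frame_duration / 5.0 if dt is None else float(dt)
    if dt_ms > series.grid.frame_duration + 1e-9:
        raise ValueError("dt must not exceed the frame duration")
    dt_s = dt_ms / 1000.0
    sampler = _FieldSampler(series)
    stop_planes = stop_planes or []
    plane_artery = []
    for pl in stop_planes:
        if pl.role not in ("LPA_entrance", "RPA_entrance"):
            raise ValueError("stop planes must have entrance roles")
        plane_artery.append(pl.role.split("_")[0])

    n = len(emitters)
    pos = emitters.positions.astype(float).copy()
    if n and not sampler.in_lumen(pos).all():
        raise ValueError("emitter outside the lumen at t = 0")

    max_time = max_cycles * sampler.period
    max_steps = int(np.ceil(max_time / dt_s))
    history = np.full((max_steps + 1, n, 3), np.nan)
    history[0] = pos
    alive = np.ones(n, dtype=bool)
    n_pts = np.ones(n, dtype=int)
    reason = np.array(["max_time"] * n, dtype=object)
    crossed = np.array(["none"] * n, dtype=object)
    slow_count = np.zeros(n, dtype=int)

    for step in range(max_steps):
        if not alive.any():
            break
        t = step * dt_s
        idx = np.flatnonzero(alive)
        p0 = pos[idx]
        k1 = sampler.velocity_at(p0, t)
        k2 = sampler.velocity_at(p0 + 0.5 * dt_s * k1 * 1000.0, t + 0.5 * dt_s)
        k3 = sampler.velocity_at(p0 + 0.5 * dt_s * k2 * 1000.0, t + 0.5 * dt_s)
        k4 = sampler.velocity_at(p0 + dt_s * k3 * 1000.0, t + dt_s)
        slope = (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
        p1 = p0 + dt_s * slope * 1000.0

        # entrance-plane crossings (checked first: crossing beats leaving)
        hit = np.full(len(idx), -1)
        hit_frac = np.full(len(idx), np.inf)
        for ip, pl in enumerate(stop_planes):
            d0 = (p0 - pl.origin) @ pl.normal
            d1 = (p1 - pl.origin) @ pl.normal
            sign_change = (d0 < 0) != (d1 < 0)
            denom = d0 - d1
            safe = sign_change & (np.abs(denom) > 0)
            frac = np.zeros_like(d0)
            frac[safe] = d0[safe] / denom[safe]
            pc = p0 + frac[:, None] * (p1 - p0)
            within = pl.in_plane_distance(pc) <= pl.in_plane_radius
            better = safe & within & (frac < hit_frac)
            hit[better] = ip
            hit_frac[better] = frac[better]

        speed = np.linalg.norm(slope, axis=1)
        slow_count[idx] = np.where(speed < LOW_SPEED_MS, slow_count[idx] + 1, 0)
        in_lum = sampler.in_lumen(p1)

        for j, i in enumerate(idx):
            if hit[j] >= 0:
                history[step + 1, i] = p0[j] + hit_frac[j] * (p1[j] - p0[j])
                n_pts[i] = step + 2
                alive[i] = False
                reason[i] = "crossed_plane"
                crossed[i] = plane_artery[hit[j]]
            elif not in_lum[j]:
                alive[i] = False
                reason[i] = "left_mask"
            elif slow_count[i] >= LOW_SPEED_STEPS:
                history[step + 1, i] = p1[j]
                n_pts[i] = step + 2
                alive[i] = False
                reason[i] = "low_velocity"
            else:
                history[step + 1, i] = p1[j]
                n_pts[i] = step + 2
                pos[i] = p1[j]

    times_all = np.arange(max_steps + 1) * dt_s
    return PathlineSet(
        times=[times_all[:n_pts[i]] for i in range(n)],
        positions=[history[:n_pts[i], i] for i in range(n)],
        termination_reason=list(reason),
        first_plane_crossed=list(crossed),
        source_label=emitters.source_label,
    )


# ---------------------------------------------------------------------------
# counting and fractions
# ---------------------------------------------------------------------------

def count_crossings(pathlines: PathlineSet, lpa_plane: AnalysisPlane,
                    rpa_plane: AnalysisPlane) -> FlowDistributionResult:
    """Count first crossings of the LPA/RPA entrance planes.

    A crossing is a sign change of the signed distance to the plane between
    consecutive trajectory points whose interpolated crossing point lies
    within the plane radius; only the first plane crossed counts for each
    pathline.  The validity fraction is computed over pathlines with more
    than 3 time points.
    """
    if lpa_plane.role != "LPA_entrance" or rpa_plane.role != "RPA_entrance":
        raise ValueError("planes must carry LPA_entrance / RPA_entrance roles")
    n_lpa = n_rpa = 0
    n_long = n_long_reaching = 0
    for traj in pathlines.positions:
        first = None
        first_idx = np.inf
        first_frac = np.inf
        if len(traj) >= 2:
            p0, p1 = traj[:-1], traj[1:]
            for name, pl in (("LPA", lpa_plane), ("RPA", rpa_plane)):
                d0 = (p0 - pl.origin) @ pl.normal
                d1 = (p1 - pl.origin) @ pl.normal
                sign_change = (d0 < 0) != (d1 < 0)
                if not sign_change.any():
                    continue
                denom = d0 - d1
                safe = sign_change & (np.abs(denom) > 0)
                frac = np.zeros_like(d0)
                frac[safe] = d0[safe] / denom[safe]
                pc = p0 + frac[:, None] * (p1 - p0)
                ok = safe & (pl.in_plane_distance(pc) <= pl.in_plane_radius)
                if not ok.any():
                    continue
                k = int(np.flatnonzero(ok)[0])
                if k < first_idx or (k == first_idx and frac[k] < first_frac):
                    first, first_idx, first_frac = name, k, frac[k]
        if first == "LPA":
            n_lpa += 1
        elif first == "RPA":
            n_rpa += 1
        if len(traj) > 3:
            n_long += 1
            if first is not None:
                n_long_reaching += 1
    validity = n_long_reaching / n_long if n_long else np.nan
    return FlowDistributionResult(n_lpa=n_lpa, n_rpa=n_rpa,
                                  validity_fraction=validity,
                                  n_pathlines=len(pathlines))


def flow_distribution(counts: FlowDistributionResult) -> FlowDistributionResult:
    """Fill in the LPA/RPA fractions and the equal/unequal classification.

    fraction_lpa = n_lpa / (n_lpa + n_rpa); the distribution is classified
    unequal iff fraction_lpa < 0.30 or > 0.70 (boundary values are equal --
    the rule uses strict inequalities).  Zero total crossings leaves the
    fractions undefined and flags the result.
    """
    total = counts.n_lpa + counts.n_rpa
    if total == 0:
        counts.fraction_lpa = np.nan
        counts.fraction_rpa = np.nan
        counts.classification = "undefined"
        return counts
    counts.fraction_lpa = counts.n_lpa / total
    counts.fraction_rpa = counts.n_rpa / total
    unequal = counts.fraction_lpa < 0.30 or counts.fraction_lpa > 0.70
    counts.classification = "unequal" if unequal else "equal"
    return counts


def measure_flow_distribution(series: VelocitySeries, region: RegionModel,
                              source: str = "IVC", density: float = 30.0,
                              seed: int = DEFAULT_SEED, dt: float | None = None,
                              max_cycles: int = 3):
    """Full flow-distribution measurement for one caval vein.

    Seeds emitters, traces pathlines (terminating at the entrance planes),
    counts crossings, and returns ``(FlowDistributionResult, PathlineSet)``.
    """
    lpa = region.entrance_plane("LPA_entrance")
    rpa = region.entrance_plane("RPA_entrance")
    emitters = seed_emitters(region, source, density=density, seed=seed)
    paths = trace_pathlines(series, emitters, dt=dt, max_cycles=max_cycles,
                            stop_planes=[lpa, rpa])
    result = flow_distribution(count_crossings(paths, lpa, rpa))
    return result, paths
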