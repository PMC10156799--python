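"""Phase-contrast velocity preprocessing.

Deterministic re-implementations of the manual 4D flow cleanup steps:
static-tissue detection, eddy-current/Maxwell phase-offset correction by a
spatial polynomial fit over static tissue, neighborhood-median velocity
anti-aliasing, noise masking, and the PC-MRA used for lumen segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu

from .phantom import VelocitySeries, polynomial_design_matrix


@dataclass
class PreprocessReport:
    """What the preprocessing stage did to a series."""

    offset_coefficients: np.ndarray | None = None  # (3, n_terms) per component
    poly_order: int | None = None
    n_aliased_voxels_fixed: int = 0
    noise_mask: np.ndarray | None = None
    static_mask: np.ndarray | None = None
    notes: list = field(default_factory=list)


def detect_static_tissue(series: VelocitySeries, std_threshold: float = 0.01,
                         magnitude_floor_fraction: float = 0.1) -> np.ndarray:
    """Flag voxels that are static over the cardiac cycle.

    A voxel is static iff the temporal standard deviation of every velocity
    component is below ``std_threshold`` (m/s) *and* its time-mean magnitude
    is above a noise floor (a fraction of the maximum mean magnitude), which
    excludes air.  Requires at least two frames.
    """
    if series.n_frames < 2:
        raise ValueError("static-tissue detection needs n_frames >= 2")
    std = series.velocity.std(axis=0)            # (3, nx, ny, nz)
    mean_mag = series.magnitude.mean(axis=0)
    floor = magnitude_floor_fraction * float(mean_mag.max())
    return np.all(std < std_threshold, axis=0) & (mean_mag > floor)


def correct_phase_offsets(series: VelocitySeries, static_mask: np.ndarray,
                          poly_order: int = 1):
    """Fit and subtract a per-component spatial polynomial phase offset.

    The polynomial (order 1 or 2, world-mm basis) is fit by least squares to
    the *time-averaged* velocity over static-tissue voxels -- eddy-current
    offsets are static in time -- and subtracted from every frame
    everywhere.  Returns ``(corrected_series, PreprocessReport)``.
    """
    if poly_order not in (1, 2):
        raise ValueError("poly_order must be 1 or 2")
    report = PreprocessReport(poly_order=poly_order, static_mask=np.asarray(static_mask, bool))
    out = series.copy()
    static = np.asarray(static_mask, dtype=bool)
    if not static.any():
        warnings.warn("empty static mask: phase-offset correction skipped")
        report.notes.append("empty static mask; correction skipped")
        return out, report

    xs, ys, zs = series.grid.coords()
    X_full = polynomial_design_matrix(xs, ys, zs, poly_order)
    X_static = X_full[static.ravel()]
    mean_vel = series.velocity.mean(axis=0)      # (3, nx, ny, nz)
    coeffs = np.empty((3, X_full.shape[1]))
    for c in range(3):
        coeffs[c], *_ = np.linalg.lstsq(X_static, mean_vel[c][static], rcond=None)
        out.velocity[:, c] -= (X_full @ coeffs[c]).reshape(series.grid.shape)[None]
    report.offset_coefficients = coeffs
    return out, report


def _neighborhood_median(vol: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Median over the 6-neighborhood (center excluded), ignoring invalid
    neighbors; NaN where no valid neighbor exists."""
    stacked = np.full((6,) + vol.shape, np.nan)
    masked = np.where(valid, vol, np.nan)
    stacked[0, 1:, :, :] = masked[:-1, :, :]
    stacked[1, :-1, :, :] = masked[1:, :, :]
    stacked[2, :, 1:, :] = masked[:, :-1, :]
    stacked[3, :, :-1, :] = masked[:, 1:, :]
    stacked[4, :, :, 1:] = masked[:, :, :-1]
    stacked[5, :, :, :-1] = masked[:, :, 1:]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        return np.nanmedian(stacked, axis=0)


def unalias(series: VelocitySeries, max_sweeps: int = 10):
    """Velocity anti-aliasing by neighborhood-median unwrapping.

    Per component and frame, a voxel whose value differs from the median of
    its (lumen-restricted) 6-neighborhood by more than venc is shifted by
    +-2*venc toward that median; sweeps repeat to a fixed point (capped).
    Resolves isolated or thin wrapped structures; large compact wrapped
    cores where a voxel's neighborhood is itself mostly wrapped are not
    recoverable by local medians.  Returns ``(series, n_corrections)``.
    """
    out = series.copy()
    venc = out.venc_ms
    valid = out.lumen_mask()
    total = 0
    for _ in range(max_sweeps):
        changed = 0
        for f in range(out.n_frames):
            for c in range(3):
                vol = out.velocity[f, c]
                med = _neighborhood_median(vol, valid)
                diff = med - vol
                fix = valid & np.isfinite(med) & (np.abs(diff) > venc)
                if fix.any():
                    vol[fix] += 2.0 * venc * np.sign(diff[fix])
                    changed += int(fix.sum())
        total += changed
        if changed == 0:
            break
    out.info["n_unaliased"] = total
    return out, total


def compute_pcmra(series: VelocitySeries) -> np.ndarray:
    """Phase-contrast MR angiogram: time-mean of magnitude-weighted speed.

    PCMRA(x) = (1/T) * sum_t mag_t(x) * sqrt(sum_i v_i,t(x)^2).  Nonnegative
    and invariant to velocity sign flips; bright where blood moves.
    """
    return (series.magnitude * series.speed()).mean(axis=0)


def segment_lumen_otsu(pcmra: np.ndarray) -> np.ndarray:
    """Utility: threshold a PC-MRA at the Otsu level to get a lumen mask."""
    return pcmra > threshold_otsu(pcmra)


def apply_noise_masking(series: VelocitySeries, lumen_mask: np.ndarray | None = None,
                        percentile: float = 5.0):
    """Zero the velocity of low-signal voxels.

    Voxels whose time-mean magnitude falls below the given percentile of the
    in-lumen magnitude distribution are treated as noise and their velocity
    is zeroed.  Returns ``(series, noise_mask)``.
    """
    out = series.copy()
    lum = out.lumen_mask() if lumen_mask is None else np.asarray(lumen_mask, bool)
    mean_mag = out.magnitude.mean(axis=0)
    cutoff = np.percentile(mean_mag[lum], percentile) if lum.any() else np.inf
    noise = lum & (mean_mag < cutoff)
    out.velocity[:, :, noise] = 0.0
    return out, noise


def run_preprocess(series: VelocitySeries, poly_order: int = 1,
                   std_threshold: float = 0.01):
    """Full preprocessing chain: static tissue -> offset fit -> anti-aliasing
    -> noise masking.  Returns ``(series, PreprocessReport)``."""
    static = detect_static_tissue(series, std_threshold=std_threshold)
    corrected, report = correct_phase_offsets(series, static, poly_order=poly_order)
    corrected, n_fixed = unalias(corrected)
    report.n_aliased_voxels_fixed = n_fixed
    corrected, noise = apply_noise_masking(corrected)
    report.noise_mask = noise
    return corrected, report
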