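"""NIfTI / JSON / CSV serialization of series, region models and results.

Layout of a dataset directory:

* ``velocity.nii.gz``  -- 5-D (x, y, z, frame, component) velocity, m/s
* ``magnitude.nii.gz`` -- 4-D (x, y, z, frame) magnitude
* ``labels.nii.gz``    -- 3-D region label volume (optional)
* ``meta.json``        -- venc, frame duration, cycle fraction, origin

The NIfTI affine is diagonal with the voxel spacing and the world origin,
so world mm coordinates round-trip exactly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .flowdist import FlowDistributionResult, PathlineSet
from .geometry import AnalysisPlane, Centerline, RegionModel
from .phantom import GridSpec, VelocitySeries


def _affine(grid_or_region) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = grid_or_region.spacing
    aff[:3, 3] = grid_or_region.origin
    return aff


def save_velocity_series(series: VelocitySeries, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(series.grid)
    vel = np.moveaxis(series.velocity, (0, 1), (3, 4))     # (x,y,z,frame,comp)
    nib.save(nib.Nifti1Image(vel.astype(np.float32), aff), out / "velocity.nii.gz")
    mag = np.moveaxis(series.magnitude, 0, 3)
    nib.save(nib.Nifti1Image(mag.astype(np.float32), aff), out / "magnitude.nii.gz")
    if series.mask is not None:
        nib.save(nib.Nifti1Image(series.mask.astype(np.int16), aff), out / "labels.nii.gz")
    meta = {"venc_cms": series.venc,
            "frame_duration_ms": series.grid.frame_duration,
            "cycle_fraction_covered": series.cycle_fraction_covered,
            "spacing_mm": list(series.grid.spacing),
            "origin_mm": list(series.grid.origin)}
    (out / "meta.json").write_text(json.dumps(meta, indent=2))
    return out


def load_velocity_series(in_dir) -> VelocitySeries:
    src = Path(in_dir)
    meta = json.loads((src / "meta.json").read_text())
    vel_img = nib.load(src / "velocity.nii.gz")
    vel = np.moveaxis(np.asarray(vel_img.dataobj, dtype=np.float64), (3, 4), (0, 1))
    mag = np.moveaxis(np.asarray(nib.load(src / "magnitude.nii.gz").dataobj,
                                 dtype=np.float64), 3, 0)
    mask = None
    if (src / "labels.nii.gz").exists():
        mask = np.asarray(nib.load(src / "labels.nii.gz").dataobj, dtype=np.int16)
    grid = GridSpec(shape=vel.shape[2:], spacing=tuple(meta["spacing_mm"]),
                    n_frames=vel.shape[0], frame_duration=meta["frame_duration_ms"],
                    origin=tuple(meta["origin_mm"]))
    return VelocitySeries(grid=grid, velocity=vel, magnitude=mag,
                          venc=meta["venc_cms"],
                          cycle_fraction_covered=meta["cycle_fraction_covered"],
                          mask=mask)


def save_region_model(region: RegionModel, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(region.labels.astype(np.int16), _affine(region)),
             out / "region_labels.nii.gz")
    doc = {
        "spacing_mm": list(region.spacing),
        "origin_mm": list(region.origin),
        "planes": [{"origin": list(p.origin), "normal": list(p.normal),
                    "in_plane_radius": p.in_plane_radius, "role": p.role}
                   for p in region.boundary_planes],
        "centerlines": {name: {"points": cl.points.tolist(),
                               "arclength": cl.arclength.tolist(),
                               "tangents": cl.tangents.tolist()}
                        for name, cl in region.centerlines.items()},
    }
    (out / "region_model.json").write_text(json.dumps(doc))
    return out


def load_region_model(in_dir) -> RegionModel:
    src = Path(in_dir)
    labels = np.asarray(nib.load(src / "region_labels.nii.gz").dataobj, dtype=np.int16)
    doc = json.loads((src / "region_model.json").read_text())
    planes = [AnalysisPlane(origin=np.array(p["origin"]), normal=np.array(p["normal"]),
                            in_plane_radius=p["in_plane_radius"], role=p["role"])
              for p in doc["planes"]]
    centerlines = {name: Centerline(points=np.array(c["points"]),
                                    arclength=np.array(c["arclength"]),
                                    tangents=np.array(c["tangents"]))
                   for name, c in doc["centerlines"].items()}
    return RegionModel(labels=labels, centerlines=centerlines, boundary_planes=planes,
                       spacing=tuple(doc["spacing_mm"]), origin=tuple(doc["origin_mm"]))


def pathlines_to_csv(paths: PathlineSet, out_file) -> Path:
    """Trajectories as tidy CSV: trajectory id, t (s), x, y, z (mm)."""
    rows = []
    for i, (t, p) in enumerate(zip(paths.times, paths.positions)):
        rows.append(pd.DataFrame({"trajectory": i, "t": t, "x": p[:, 0],
                                  "y": p[:, 1], "z": p[:, 2]}))
    out = Path(out_file)
    pd.concat(rows, ignore_index=True).to_csv(out, index=False)
    return out


def pathlines_to_vtk(paths: PathlineSet, out_file) -> Path:
    """Trajectories as legacy ASCII VTK polydata with a per-point time scalar."""
    pts, lines, times = [], [], []
    offset = 0
    for t, p in zip(paths.times, paths.positions):
        n = len(p)
        pts.append(p)
        times.append(t)
        lines.append([n] + list(range(offset, offset + n)))
        offset += n
    all_pts = np.concatenate(pts) if pts else np.empty((0, 3))
    all_t = np.concatenate(times) if times else np.empty(0)
    out = Path(out_file)
    with open(out, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\npathlines\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(all_pts)} float\n")
        for p in all_pts:
            fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
        total = sum(len(l) for l in lines)
        fh.write(f"LINES {len(lines)} {total}\n")
        for l in lines:
            fh.write(" ".join(str(v) for v in l) + "\n")
        fh.write(f"POINT_DATA {len(all_t)}\nSCALARS time float 1\nLOOKUP_TABLE default\n")
        for t in all_t:
            fh.write(f"{t:.6f}\n")
    return out


def flow_distribution_to_json(result: FlowDistributionResult, out_file) -> Path:
    out = Path(out_file)
    doc = dataclasses.asdict(result)
    doc = {k: (None if isinstance(v, float) and np.isnan(v) else v)
           for k, v in doc.items()}
    out.write_text(json.dumps(doc, indent=2))
    return out


def save_maps(maps, grid_like, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(grid_like)
    for name in ("peak_velocity", "stasis", "kinetic_energy", "el_tot", "el_mean"):
        nib.save(nib.Nifti1Image(getattr(maps, name).astype(np.float32), aff),
                 out / f"{name}.nii.gz")
    return out
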