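"""File I/O: NIfTI-1 volumes with JSON sidecars, BIDS-style b-value tables,
ROI JSON and tidy metric CSVs."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .acquisition import DWIStack
from .geometry import FOVGeometry
from .phantom import Phantom
from .roi import ROISpec


def _geometry_dict(geom: FOVGeometry) -> dict:
    return {
        "name": geom.name,
        "field_of_view_mm": list(geom.field_of_view_mm),
        "voxel_size_mm": list(geom.voxel_size_mm),
        "n_slices": geom.n_slices,
    }


def _geometry_from_dict(d: dict) -> FOVGeometry:
    return FOVGeometry(
        name=d["name"],
        field_of_view_mm=tuple(d["field_of_view_mm"]),
        voxel_size_mm=tuple(d["voxel_size_mm"]),
        n_slices=int(d["n_slices"]),
    )


def save_stack(stack: DWIStack, path) -> Path:
    """Write a stack as 4D float32 NIfTI plus a ``.json`` sidecar.

    The sidecar records b-values, averages, the Rician sigma, the seed and
    the geometry, so the stack round-trips exactly (up to float32).
    """
    path = Path(path)
    img = nib.Nifti1Image(stack.signal.astype(np.float32), stack.geometry.affine)
    nib.save(img, path)
    sidecar = {
        "b_values": list(stack.b_values),
        "averages": list(stack.averages) if stack.averages else None,
        "noise_sigma": stack.noise_sigma,
        "seed": stack.seed,
        "geometry": _geometry_dict(stack.geometry),
    }
    path.with_suffix("").with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_stack(path) -> DWIStack:
    """Load a 4D NIfTI + JSON sidecar written by :func:`save_stack`."""
    path = Path(path)
    img = nib.load(path)
    sidecar = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    return DWIStack(
        signal=np.asarray(img.dataobj, dtype=np.float64),
        b_values=tuple(sidecar["b_values"]),
        geometry=_geometry_from_dict(sidecar["geometry"]),
        noise_sigma=float(sidecar.get("noise_sigma", 0.0)),
        seed=int(sidecar.get("seed", 0)),
        averages=tuple(sidecar["averages"]) if sidecar.get("averages") else None,
    )


def load_stack_with_bval(nifti_path, bval_path, geometry: FOVGeometry) -> DWIStack:
    """Load any conforming 4D NIfTI with a whitespace-separated .bval table."""
    img = nib.load(nifti_path)
    b_values = tuple(float(x) for x in Path(bval_path).read_text().split())
    return DWIStack(
        signal=np.asarray(img.dataobj, dtype=np.float64),
        b_values=b_values,
        geometry=geometry,
        noise_sigma=0.0,
        seed=0,
    )


def save_label_map(phantom: Phantom, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(phantom.label_map.astype(np.int16), phantom.geometry.affine)
    nib.save(img, path)
    return path


def save_volume(volume: np.ndarray, geometry: FOVGeometry, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), geometry.affine), path)
    return path


def save_rois(rois, path) -> Path:
    path = Path(path)
    payload = [
        {
            "roi_id": r.roi_id,
            "tissue": r.tissue,
            "center_mm": list(r.center_mm),
            "diameter_mm": r.diameter_mm,
            "slice_index": r.slice_index,
        }
        for r in rois
    ]
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_rois(path) -> list[ROISpec]:
    data = json.loads(Path(path).read_text())
    return [
        ROISpec(
            roi_id=d["roi_id"],
            tissue=d["tissue"],
            center_mm=tuple(d["center_mm"]),
            diameter_mm=float(d.get("diameter_mm", 5.0)),
            slice_index=d.get("slice_index"),
        )
        for d in data
    ]


def save_metrics(metrics, path) -> Path:
    """Tidy CSV with one metric record per row."""
    path = Path(path)
    df = metrics if isinstance(metrics, pd.DataFrame) else pd.DataFrame([m.__dict__ for m in metrics])
    df.to_csv(path, index=False)
    return path
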