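"""ROI definition, cross-grid propagation, and image contrast metrics.

Implements the quantitative readout of the study: circular in-plane regions
of interest (default 5 mm diameter) placed in the tumor and in the proximal
and distal normal parenchyma, and the derived apparent SNR/CNR and contrast
ratio:

    aSNR = SI_parenchyma / SD_parenchyma
    aCNR = (SI_tumor − SI_parenchyma) / SD_parenchyma
    CR   = SI_tumor / SI_parenchyma        (per parenchyma ROI)

Noise is estimated from the tissue-ROI standard deviation itself (hence the
"apparent" prefix), not from background air.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import FOVGeometry, GeometryError

TISSUE_ROLES = ("tumor", "parenchyma_proximal", "parenchyma_distal")


class UndefinedMetricError(ValueError):
    """A metric's denominator is zero (degenerate ROI statistics)."""


@dataclass(frozen=True)
class ROISpec:
    """A circular single-slice ROI in world coordinates (mm)."""

    roi_id: str
    tissue: str
    center_mm: tuple[float, float, float]
    diameter_mm: float = 5.0
    slice_index: int | None = None  # in the defining grid, informational

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise ValueError("diameter_mm must be > 0")


@dataclass(frozen=True)
class ROIStats:
    """Mean / SD (population convention) / voxel count of an ROI sample."""

    mean_si: float
    sd_si: float
    n_voxels: int

    def __post_init__(self) -> None:
        if self.sd_si < 0 or self.n_voxels < 1:
            raise ValueError("sd_si must be >= 0 and n_voxels >= 1")


@dataclass(frozen=True)
class MetricRecord:
    """Per-patient, per-dataset contrast metrics (one analysis row)."""

    patient_id: str
    dataset_id: str
    asnr: float
    acnr: float
    cr_proximal: float
    cr_distal: float


def propagate_roi(
    roi: ROISpec, source_geometry: FOVGeometry, target_geometry: FOVGeometry
) -> np.ndarray:
    """Rasterize an ROI (defined on the source grid) onto the target grid.

    Returns the (n, 3) integer indices of all target voxels whose in-plane
    centres lie within ``diameter/2`` of the ROI centre, on the slice nearest
    the ROI centre.  At least one voxel (the nearest) is always returned,
    mirroring the copy-paste transfer of ROIs between co-registered datasets.
    """
    center = np.asarray(roi.center_mm, dtype=float)
    for geom in (source_geometry, target_geometry):
        if not geom.contains(center):
            raise GeometryError(f"ROI centre {center} outside FOV of {geom.name}")

    zc = target_geometry.axis_coords(2)
    k = int(np.argmin(np.abs(zc - center[2])))

    xs = target_geometry.axis_coords(0)
    ys = target_geometry.axis_coords(1)
    r = roi.diameter_mm / 2.0
    ii = np.where(np.abs(xs - center[0]) <= r)[0]
    jj = np.where(np.abs(ys - center[1]) <= r)[0]
    out = []
    for i in ii:
        for j in jj:
            if (xs[i] - center[0]) ** 2 + (ys[j] - center[1]) ** 2 <= r**2 + 1e-12:
                out.append((i, j, k))
    if not out:
        i = int(np.argmin(np.abs(xs - center[0])))
        j = int(np.argmin(np.abs(ys - center[1])))
        out.append((i, j, k))
    return np.asarray(out, dtype=int)


def roi_stats(volume: np.ndarray, roi_voxels: np.ndarray) -> ROIStats:
    """Mean and population SD of a volume over a voxel index set."""
    vox = np.asarray(roi_voxels, dtype=int)
    if vox.size == 0:
        raise ValueError("roi_voxels must be non-empty")
    if np.any(vox < 0) or np.any(vox >= np.asarray(volume.shape)[None, :]):
        raise IndexError("roi voxel index out of bounds")
    vals = volume[vox[:, 0], vox[:, 1], vox[:, 2]]
    return ROIStats(
        mean_si=float(vals.mean()), sd_si=float(vals.std(ddof=0)), n_voxels=len(vals)
    )


def pool_stats(a: ROIStats, b: ROIStats) -> ROIStats:
    """Combine two ROI samples into one (exact pooled mean and population SD)."""
    n = a.n_voxels + b.n_voxels
    mean = (a.n_voxels * a.mean_si + b.n_voxels * b.mean_si) / n
    ex2 = (
        a.n_voxels * (a.sd_si**2 + a.mean_si**2)
        + b.n_voxels * (b.sd_si**2 + b.mean_si**2)
    ) / n
    return ROIStats(mean_si=mean, sd_si=float(np.sqrt(max(ex2 - mean**2, 0.0))), n_voxels=n)


def compute_metrics(
    tumor: ROIStats,
    parenchyma_proximal: ROIStats,
    parenchyma_distal: ROIStats,
    reference: str = "proximal",
    patient_id: str = "",
    dataset_id: str = "",
) -> MetricRecord:
    """aSNR, aCNR and contrast ratios from the three tissue ROIs.

    ``reference`` selects the parenchyma sample feeding aSNR/aCNR: the
    proximal ROI (default), the distal ROI, or both pooled.
    """
    if reference == "proximal":
        ref = parenchyma_proximal
    elif reference == "distal":
        ref = parenchyma_distal
    elif reference == "pooled":
        ref = pool_stats(parenchyma_proximal, parenchyma_distal)
    else:
        raise ValueError(f"reference must be proximal|distal|pooled, got {reference!r}")

    if ref.sd_si == 0:
        raise UndefinedMetricError("parenchyma SD is zero; aSNR/aCNR undefined")
    if parenchyma_proximal.mean_si <= 0 or parenchyma_distal.mean_si <= 0:
        raise UndefinedMetricError("parenchyma mean is not positive; CR undefined")

    return MetricRecord(
        patient_id=patient_id,
        dataset_id=dataset_id,
        asnr=ref.mean_si / ref.sd_si,
        acnr=(tumor.mean_si - ref.mean_si) / ref.sd_si,
        cr_proximal=tumor.mean_si / parenchyma_proximal.mean_si,
        cr_distal=tumor.mean_si / parenchyma_distal.mean_si,
    )


def correct_roi_placement(
    roi: ROISpec,
    label_map: np.ndarray,
    geometry: FOVGeometry,
    allowed_labels,
    max_shift_mm: float = 8.0,
    step_mm: float = 1.0,
) -> ROISpec:
    """Deterministic stand-in for the reader's manual ROI correction.

    If any rasterized ROI voxel falls on a label outside ``allowed_labels``,
    the centre is moved to the nearest offset (grid search in-plane, nearest
    first) where the ROI is pure; if none is pure within ``max_shift_mm`` the
    offset with the highest purity is used.
    """
    allowed = set(int(a) for a in allowed_labels)

    def purity(center):
        cand = replace(roi, center_mm=tuple(center))
        try:
            vox = propagate_roi(cand, geometry, geometry)
        except GeometryError:
            return -1.0, None
        labs = label_map[vox[:, 0], vox[:, 1], vox[:, 2]]
        return float(np.mean([l in allowed for l in labs])), cand

    p, cand = purity(roi.center_mm)
    if p == 1.0:
        return cand
    steps = np.arange(-max_shift_mm, max_shift_mm + step_mm / 2, step_mm)
    offsets = sorted(
        ((dx, dy) for dx in steps for dy in steps),
        key=lambda o: (o[0] ** 2 + o[1] ** 2, o),
    )
    best_p, best = p, cand
    cx, cy, cz = roi.center_mm
    for dx, dy in offsets:
        p, cand = purity((cx + dx, cy + dy, cz))
        if p == 1.0:
            return cand
        if p > best_p:
            best_p, best = p, cand
    return best
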