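"""Digital abdominal phantom: a curved pancreas band with an embedded lesion.

The phantom assigns every voxel a tissue label; each tissue carries a signal
at b=0 (``s0``) and an apparent diffusion coefficient (``adc``, mm²/s) so a
noiseless diffusion-weighted signal S(b) = S0·exp(−b·ADC) is defined
everywhere.  No anatomical realism is attempted beyond what the downstream
analysis needs: labelled tumor / proximal-parenchyma / distal-parenchyma
compartments, a fluid-filled duct, and a body background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import FOVGeometry, GeometryError

ADC_MAX = 4.0e-3  # mm^2/s, physically plausible upper bound for abdominal tissue


class ConfigurationError(ValueError):
    """Inconsistent phantom or model configuration."""


# fixed integer codes for the label map
LABELS = {
    "air": 0,
    "background": 1,
    "parenchyma_proximal": 2,
    "parenchyma_distal": 3,
    "duct_fluid": 4,
    "lesion": 5,
}


@dataclass(frozen=True)
class TissueParams:
    """Signal model of one tissue.

    By default purely mono-exponential, S(b) = s0·exp(−b·adc).  An optional
    perfusion (IVIM) component contaminates the low-b signal:
    S(b) = s0·[(1−f)·exp(−b·adc) + f·exp(−b·(adc + D*))] with
    f = ``perfusion_fraction`` and D* = ``pseudo_diffusion`` (mm²/s).
    The default is no perfusion (f = 0), i.e. the pure mono-exponential model.
    """

    label: str
    s0: float
    adc: float
    perfusion_fraction: float = 0.0
    pseudo_diffusion: float = 0.0

    def __post_init__(self) -> None:
        if self.s0 <= 0:
            raise ConfigurationError(f"{self.label}: s0 must be > 0, got {self.s0}")
        if not (0.0 <= self.adc <= ADC_MAX):
            raise ConfigurationError(
                f"{self.label}: adc must be in [0, {ADC_MAX}] mm^2/s, got {self.adc}"
            )
        if not (0.0 <= self.perfusion_fraction <= 1.0):
            raise ConfigurationError(f"{self.label}: perfusion_fraction must be in [0, 1]")
        if self.pseudo_diffusion < 0:
            raise ConfigurationError(f"{self.label}: pseudo_diffusion must be >= 0")

    def decay(self, b_values) -> np.ndarray:
        """S(b) for an array of b-values."""
        b = np.asarray(b_values, dtype=float)
        f = self.perfusion_fraction
        tissue = (1.0 - f) * np.exp(-b * self.adc)
        perf = f * np.exp(-b * (self.adc + self.pseudo_diffusion)) if f > 0 else 0.0
        return self.s0 * (tissue + perf)


def default_tissues(
    lesion_adc: float = 1.2e-3,
    parenchyma_adc: float = 1.8e-3,
    s0: float = 1000.0,
) -> list[TissueParams]:
    """Default tissue set: hypo-diffusive lesion in normo-diffusive parenchyma.

    Equal S0 across lesion/parenchyma/duct so that contrast at b>0 is purely
    diffusion-driven (lesion-to-parenchyma ratio exp((ADC_p - ADC_l)·b)).
    """
    return [
        TissueParams("background", s0=0.6 * s0, adc=2.0e-3),
        TissueParams("parenchyma_proximal", s0=s0, adc=parenchyma_adc),
        TissueParams("parenchyma_distal", s0=s0, adc=parenchyma_adc),
        TissueParams("duct_fluid", s0=s0, adc=3.0e-3),
        TissueParams("lesion", s0=s0, adc=lesion_adc),
    ]


@dataclass(frozen=True)
class AnatomyParams:
    """World-mm dimensions of the synthetic pancreas.

    The gland is a curved band along x: its centreline is
    y = curvature·((x/half_length)² − 1/2), with half-width (y), half-thickness
    (z) and a thin duct running parallel to the centreline at ``duct_offset``.
    """

    band_half_length_mm: float = 55.0
    band_half_width_mm: float = 11.0
    band_half_thickness_mm: float = 9.0
    curvature_mm: float = 10.0
    duct_offset_mm: float = 6.0
    duct_radius_mm: float = 1.5
    body_fraction: float = 0.92  # body ellipse axes as a fraction of the FOV


def default_anatomy(geometry: FOVGeometry) -> AnatomyParams:
    """Anatomy sized to the geometry: the gland spans ~72% of the FOV width."""
    half = 0.36 * min(geometry.field_of_view_mm)
    return AnatomyParams(band_half_length_mm=half)


@dataclass
class Phantom:
    geometry: FOVGeometry
    label_map: np.ndarray  # int16, geometry.shape
    tissues: list[TissueParams]
    lesion_center_mm: np.ndarray
    lesion_diameter_mm: float
    anatomy: AnatomyParams

    def tissue(self, label: str) -> TissueParams:
        for t in self.tissues:
            if t.label == label:
                return t
        raise ConfigurationError(f"no TissueParams for label {label!r}")

    def centerline_y(self, x) -> np.ndarray:
        a = self.anatomy
        return a.curvature_mm * ((np.asarray(x) / a.band_half_length_mm) ** 2 - 0.5)

    def s0_of_label(self) -> np.ndarray:
        """Lookup table label-code -> S0 (air = 0)."""
        lut = np.zeros(max(LABELS.values()) + 1)
        for t in self.tissues:
            lut[LABELS[t.label]] = t.s0
        return lut

    def adc_of_label(self) -> np.ndarray:
        lut = np.zeros(max(LABELS.values()) + 1)
        for t in self.tissues:
            lut[LABELS[t.label]] = t.adc
        return lut

    def signal_lut(self, b_values) -> np.ndarray:
        """Noiseless S(b) per label code, shape (n_labels, n_b); air = 0."""
        b = np.asarray(b_values, dtype=float)
        lut = np.zeros((max(LABELS.values()) + 1, len(b)))
        for t in self.tissues:
            lut[LABELS[t.label]] = t.decay(b)
        return lut


def make_phantom(
    geometry: FOVGeometry,
    tissues: list[TissueParams] | None = None,
    lesion_center_mm=(0.0, None, 0.0),
    lesion_diameter_mm: float = 14.0,
    seed: int = 0,
    anatomy: AnatomyParams | None = None,
) -> Phantom:
    """Rasterize the synthetic abdomen onto a geometry's grid.

    The lesion is an ellipsoid embedded in the gland; parenchyma on the
    negative-x side of the lesion centre is labelled proximal, the other side
    distal.  If ``lesion_center_mm[1]`` is None the lesion is centred on the
    gland centreline.  Deterministic given its arguments (``seed`` is stored
    for provenance; the anatomy itself is analytic).
    """
    if lesion_diameter_mm <= 0:
        raise GeometryError("lesion_diameter_mm must be > 0")
    tissues = list(tissues) if tissues is not None else default_tissues()
    present = {t.label for t in tissues}
    missing = (set(LABELS) - {"air"}) - present
    if missing:
        raise ConfigurationError(f"missing TissueParams for labels: {sorted(missing)}")
    anatomy = anatomy or default_anatomy(geometry)
    a = anatomy

    xl, yl, zl = lesion_center_mm
    if yl is None:
        yl = float(a.curvature_mm * ((xl / a.band_half_length_mm) ** 2 - 0.5))
    center = np.array([xl, yl, zl], dtype=float)
    rx = ry = lesion_diameter_mm / 2.0
    rz = min(lesion_diameter_mm / 2.0, a.band_half_thickness_mm - 1.0)
    rz = max(rz, 0.5)

    if not geometry.contains(center):
        raise GeometryError(f"lesion centre {center} outside FOV of {geometry.name}")
    if abs(xl) + rx > a.band_half_length_mm or rx > a.band_half_width_mm:
        raise GeometryError("lesion does not fit inside the pancreas band")

    x = geometry.axis_coords(0)[:, None, None]
    y = geometry.axis_coords(1)[None, :, None]
    z = geometry.axis_coords(2)[None, None, :]

    lab = np.zeros(geometry.shape, dtype=np.int16)

    # body background: in-plane ellipse through all slices
    ex = a.body_fraction * geometry.field_of_view_mm[0] / 2.0
    ey = a.body_fraction * geometry.field_of_view_mm[1] / 2.0
    body = (x / ex) ** 2 + (y / ey) ** 2 <= 1.0
    lab[np.broadcast_to(body, geometry.shape)] = LABELS["background"]

    yc = a.curvature_mm * ((x / a.band_half_length_mm) ** 2 - 0.5)
    in_band = (
        (np.abs(x) <= a.band_half_length_mm)
        & (np.abs(y - yc) <= a.band_half_width_mm)
        & (np.abs(z) <= a.band_half_thickness_mm)
    )
    proximal = in_band & (x <= xl)
    lab[np.broadcast_to(proximal, geometry.shape)] = LABELS["parenchyma_proximal"]
    lab[np.broadcast_to(in_band & (x > xl), geometry.shape)] = LABELS["parenchyma_distal"]

    duct = in_band & (np.abs(y - yc - a.duct_offset_mm) <= a.duct_radius_mm) & (
        np.abs(z - 3.0) <= a.duct_radius_mm
    )
    lab[np.broadcast_to(duct, geometry.shape)] = LABELS["duct_fluid"]

    lesion = ((x - xl) / rx) ** 2 + ((y - yl) / ry) ** 2 + ((z - zl) / rz) ** 2 <= 1.0
    lesion = np.broadcast_to(lesion, geometry.shape)
    lab[lesion] = LABELS["lesion"]
    if not lesion.any():
        # guarantee a minimal one-voxel lesion even when the ellipsoid falls
        # between voxel centres
        ijk = np.clip(
            np.round(geometry.world_to_voxel(center)).astype(int)[0],
            0,
            np.array(geometry.shape) - 1,
        )
        lab[tuple(ijk)] = LABELS["lesion"]

    return Phantom(
        geometry=geometry,
        label_map=lab,
        tissues=tissues,
        lesion_center_mm=center,
        lesion_diameter_mm=float(lesion_diameter_mm),
        anatomy=anatomy,
    )
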