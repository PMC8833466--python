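"""Acquisition protocols and the Rician magnitude-noise DWI simulator.

The simulator evaluates the noiseless mono-exponential signal per voxel and
b-value, optionally applies an in-plane acquisition point-spread blur to the
tissue occupancy (partial-volume model), then draws per-excitation Rician
magnitude samples and averages them as the scanner does (magnitude NSA
averaging, which preserves the Rician noise floor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import FOVGeometry
from .phantom import LABELS, Phantom

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class AcquisitionProtocol:
    """b-value scheme, per-b averaging (NSA) and timing of one DWI sequence.

    ``noise_scale`` optionally multiplies the per-excitation noise sigma per
    b-value; it models the extra signal instability of strong diffusion
    weighting (motion sensitivity of large gradients) on acquired high-b
    images.  ``None`` means unit scale everywhere.
    """

    name: str
    b_values: tuple[float, ...]
    averages: tuple[int, ...]
    tr_s: float = 0.0
    te_s: float = 0.0
    respiratory_period_s: float = 3.0
    scan_time_s: float = 0.0
    noise_scale: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        b = self.b_values
        if len(b) < 1 or any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError(f"b_values must be strictly increasing, got {b}")
        if b[0] < 0:
            raise ValueError("b_values must be non-negative")
        if len(self.averages) != len(b):
            raise ValueError("averages must have one entry per b-value")
        if any(int(n) != n or n < 1 for n in self.averages):
            raise ValueError(f"averages must be positive integers, got {self.averages}")
        if self.noise_scale is not None and len(self.noise_scale) != len(b):
            raise ValueError("noise_scale must have one entry per b-value")

    @property
    def n_b(self) -> int:
        return len(self.b_values)

    def scales(self) -> np.ndarray:
        if self.noise_scale is None:
            return np.ones(self.n_b)
        return np.asarray(self.noise_scale, dtype=float)


# The study's protocols: b (averages) = 0 (1), 50 (1), 300 (2), 600 (5), and
# the reduced-FOV variant adds b=1000 (11).  Scan times: full-FOV 4:30 min,
# reduced-FOV 3:18 min up to b=600 and 15:00 min including b=1000.
FFOV_PROTOCOL = AcquisitionProtocol(
    "f-b600", b_values=(0.0, 50.0, 300.0, 600.0), averages=(1, 1, 2, 5),
    tr_s=1.850, te_s=0.072, scan_time_s=270.0,
)
RFOV_PROTOCOL_600 = AcquisitionProtocol(
    "r-b600", b_values=(0.0, 50.0, 300.0, 600.0), averages=(1, 1, 2, 5),
    tr_s=1.627, te_s=0.067, scan_time_s=198.0,
)
RFOV_PROTOCOL_1000 = AcquisitionProtocol(
    "r-b1000", b_values=(0.0, 50.0, 300.0, 600.0, 1000.0), averages=(1, 1, 2, 5, 11),
    tr_s=1.627, te_s=0.067, scan_time_s=900.0,
    noise_scale=(1.0, 1.0, 1.0, 1.0, 1.8),
)


@dataclass
class DWIStack:
    """A 4D magnitude DWI volume (i, j, k, b) with acquisition metadata.

    ``noiseless`` retains the partial-volume-mixed truth used to generate the
    noisy signal, for testing and oracle comparisons.
    """

    signal: np.ndarray
    b_values: tuple[float, ...]
    geometry: FOVGeometry
    noise_sigma: float
    seed: int
    averages: tuple[int, ...] | None = None
    noiseless: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.signal.shape[-1] != len(self.b_values):
            raise ValueError("4th dimension must match number of b-values")
        if np.any(self.signal < 0):
            raise ValueError("magnitude signal must be non-negative")

    def volume(self, b: float) -> np.ndarray:
        """The 3D volume acquired at one b-value."""
        try:
            idx = self.b_values.index(b) if isinstance(self.b_values, tuple) else list(self.b_values).index(b)
        except ValueError:
            raise KeyError(f"b={b} not in stack b-values {self.b_values}") from None
        return self.signal[..., idx]


def occupancy_weights(
    phantom: Phantom, psf_fwhm_mm: float | None = None
) -> tuple[np.ndarray, list[int]]:
    """Per-tissue fractional occupancy volumes, optionally PSF-blurred in-plane.

    Returns (weights, codes) with ``weights`` of shape (n_tissues, *grid)
    summing to 1 over tissues at every voxel (air included).
    """
    codes = sorted(int(c) for c in set(np.unique(phantom.label_map)) | {0})
    w = np.stack([(phantom.label_map == c) for c in codes]).astype(np.float32)
    if psf_fwhm_mm is not None and psf_fwhm_mm > 0:
        vx, vy, _ = phantom.geometry.voxel_size_mm
        sig = psf_fwhm_mm * _FWHM_TO_SIGMA
        for i in range(w.shape[0]):
            w[i] = gaussian_filter(w[i], sigma=(sig / vx, sig / vy, 0.0), mode="nearest")
        w /= np.maximum(w.sum(axis=0, keepdims=True), 1e-12)
    return w, codes


def noiseless_signal(
    phantom: Phantom, b_values, psf_fwhm_mm: float | None = None
) -> np.ndarray:
    """Noiseless (partial-volume mixed) signal, shape (*grid, n_b).

    Partial-volume mixing is linear in signal, so the blurred occupancy
    weights multiply each tissue's decay curve (perfusion component
    included when the tissue defines one).
    """
    b = np.asarray(b_values, dtype=float)
    w, codes = occupancy_weights(phantom, psf_fwhm_mm)
    decay = phantom.signal_lut(b)[codes]  # (n_tissues, n_b)
    grid = w.shape[1:]
    flat = w.reshape(len(codes), -1).T @ decay  # (n_vox, n_b), float64 result
    return np.ascontiguousarray(flat.reshape(*grid, len(b)))


def rician_average(
    truth: np.ndarray, sigma: float, n_averages: int, rng: np.random.Generator
) -> np.ndarray:
    """Mean of ``n_averages`` Rician magnitude samples around ``truth``.

    Each excitation adds independent Gaussian noise of SD ``sigma`` to both
    quadrature channels before the magnitude is taken (magnitude averaging,
    as scanners combine NSA).
    """
    if sigma == 0:
        return truth.copy()
    g = rng.standard_normal((2, n_averages) + truth.shape, dtype=np.float32)
    mag = np.sqrt(
        (truth[None, :].astype(np.float32) + sigma * np.float32(1.0) * g[0]) ** 2
        + (sigma * np.float32(1.0) * g[1]) ** 2
    )
    return mag.mean(axis=0, dtype=np.float64)


def simulate_dwi(
    phantom: Phantom,
    protocol: AcquisitionProtocol,
    noise_sigma: float,
    seed: int,
    psf_fwhm_mm: float | None = None,
) -> DWIStack:
    """Simulate a multi-b-value magnitude DWI acquisition of a phantom.

    Deterministic given ``seed``.  With ``noise_sigma == 0`` and no PSF the
    output equals the closed form S0·exp(−b·ADC) exactly.
    """
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be >= 0, got {noise_sigma}")
    truth = noiseless_signal(phantom, protocol.b_values, psf_fwhm_mm)
    rng = np.random.default_rng(seed)
    scales = protocol.scales()
    signal = np.empty_like(truth)
    for i, n_avg in enumerate(protocol.averages):
        signal[..., i] = rician_average(
            truth[..., i], noise_sigma * scales[i], int(n_avg), rng
        )
    return DWIStack(
        signal=signal,
        b_values=tuple(protocol.b_values),
        geometry=phantom.geometry,
        noise_sigma=float(noise_sigma),
        seed=int(seed),
        averages=tuple(protocol.averages),
        noiseless=truth,
    )
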