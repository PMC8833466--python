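"""Voxel-wise mono-exponential fitting and computed-DWI synthesis.

The computed-DWI step: fit ln S(b) = ln S0 − b·ADC per voxel over the
acquired b-values, then synthesize the signal at an arbitrary (typically
higher) target b-value as S0·exp(−b_target·ADC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import FOVGeometry
from .acquisition import DWIStack

DEFAULT_ADC_BOUNDS = (0.0, 4.0e-3)
DEFAULT_MIN_SIGNAL = 1e-6

FIT_METHODS = ("ols", "wls", "nlls")


@dataclass
class DiffusionFit:
    """Voxel-wise S0 and ADC maps of a fitted mono-exponential decay.

    ``valid_mask`` is False where fewer than two usable b-values remained
    (degenerate voxels get ADC = 0 and S0 = the first-b signal).
    """

    s0_map: np.ndarray
    adc_map: np.ndarray
    valid_mask: np.ndarray
    b_values_used: tuple[float, ...]
    fit_method: str
    geometry: FOVGeometry | None = None


@dataclass
class ComputedVolume:
    """A synthetic DWI volume extrapolated to ``b_target`` from a fit."""

    signal: np.ndarray
    b_target: float
    provenance: DiffusionFit


def _weighted_loglinear(S, b, w):
    """Closed-form weighted LS of ln S on b; returns (ln S0, slope)."""
    y = np.log(np.maximum(S, 1e-300))
    sw = w.sum(axis=-1)
    swx = (w * b).sum(axis=-1)
    swy = (w * y).sum(axis=-1)
    swxx = (w * b * b).sum(axis=-1)
    swxy = (w * b * y).sum(axis=-1)
    denom = sw * swxx - swx**2
    denom = np.where(denom <= 0, np.nan, denom)
    slope = (sw * swxy - swx * swy) / denom
    intercept = (swy - slope * swx) / sw
    return intercept, slope


def fit_monoexponential(
    stack: DWIStack,
    b_subset=None,
    method: str = "ols",
    adc_bounds: tuple[float, float] = DEFAULT_ADC_BOUNDS,
    min_signal: float = DEFAULT_MIN_SIGNAL,
) -> DiffusionFit:
    """Fit S(b) = S0·exp(−b·ADC) at every voxel of a 4D stack.

    Parameters
    ----------
    b_subset
        b-values to fit over (default: all in the stack).  Each must be
        present in ``stack.b_values``; at least two distinct values required.
    method
        ``"ols"``  log-linear ordinary least squares (default),
        ``"wls"``  log-linear weighted LS with weights ∝ S² (first-order
        correction for the log transform's noise distortion),
        ``"nlls"`` nonlinear LS (Gauss–Newton from the OLS start).
    adc_bounds
        Fitted ADC is clamped into this range; negative decay rates become 0
        so computed images can never grow with b.
    min_signal
        Samples at or below this value are excluded from the log transform.
        Voxels left with fewer than two usable samples are masked invalid.
    """
    if method not in FIT_METHODS:
        raise ValueError(f"method must be one of {FIT_METHODS}, got {method!r}")
    if min_signal <= 0:
        raise ValueError("min_signal must be > 0")
    stack_b = list(stack.b_values)
    if b_subset is None:
        b_subset = stack_b
    idx = []
    for b in b_subset:
        if b not in stack_b:
            raise KeyError(f"b={b} not present in stack b-values {stack_b}")
        idx.append(stack_b.index(b))
    b = np.asarray([stack_b[i] for i in idx], dtype=float)
    if len(np.unique(b)) < 2:
        raise ValueError("b_subset must contain at least 2 distinct b-values")

    S = stack.signal[..., idx].astype(np.float64)
    shape = S.shape[:-1]
    S = S.reshape(-1, len(b))
    usable = S > min_signal
    valid = usable.sum(axis=-1) >= 2

    w = usable.astype(np.float64)
    if method == "wls":
        w = w * S**2
    with np.errstate(invalid="ignore", divide="ignore"):
        intercept, slope = _weighted_loglinear(S, b, w)

    adc = np.clip(-slope, adc_bounds[0], adc_bounds[1])
    s0 = np.exp(intercept)

    if method == "nlls":
        adc, s0 = _gauss_newton(S, b, usable, s0, adc, adc_bounds)

    bad = ~valid | ~np.isfinite(adc) | ~np.isfinite(s0)
    adc = np.where(bad, 0.0, adc)
    s0 = np.where(bad, S[:, 0], s0)
    valid = valid & ~bad

    return DiffusionFit(
        s0_map=s0.reshape(shape),
        adc_map=adc.reshape(shape),
        valid_mask=valid.reshape(shape),
        b_values_used=tuple(b),
        fit_method=method,
        geometry=stack.geometry,
    )


def _gauss_newton(S, b, usable, s0, adc, adc_bounds, n_iter: int = 15):
    """Vectorized Gauss–Newton refinement of (S0, ADC) per voxel."""
    s0 = s0.copy()
    adc = adc.copy()
    m = usable.astype(np.float64)
    for _ in range(n_iter):
        model = s0[:, None] * np.exp(-adc[:, None] * b[None, :])
        r = (S - model) * m
        j0 = model / np.maximum(s0[:, None], 1e-12)  # d/dS0
        j1 = -b[None, :] * model  # d/dADC
        a00 = (j0 * j0 * m).sum(-1)
        a01 = (j0 * j1 * m).sum(-1)
        a11 = (j1 * j1 * m).sum(-1)
        g0 = (j0 * r).sum(-1)
        g1 = (j1 * r).sum(-1)
        det = a00 * a11 - a01**2
        det = np.where(np.abs(det) < 1e-30, np.nan, det)
        d0 = (a11 * g0 - a01 * g1) / det
        d1 = (a00 * g1 - a01 * g0) / det
        step_ok = np.isfinite(d0) & np.isfinite(d1)
        s0 = np.where(step_ok, np.maximum(s0 + d0, 1e-12), s0)
        adc = np.where(step_ok, np.clip(adc + d1, adc_bounds[0], adc_bounds[1]), adc)
    return adc, s0


def compute_dwi(fit: DiffusionFit, b_target: float) -> ComputedVolume:
    """Synthesize the DWI volume at ``b_target`` from a mono-exponential fit.

    Invalid voxels are set to 0.  At an acquired b-value of a noiseless
    mono-exponential stack this reproduces the acquisition exactly.
    """
    if b_target < 0:
        raise ValueError(f"b_target must be >= 0, got {b_target}")
    signal = fit.s0_map * np.exp(-b_target * fit.adc_map)
    signal = np.where(fit.valid_mask, signal, 0.0)
    return ComputedVolume(signal=signal, b_target=float(b_target), provenance=fit)
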