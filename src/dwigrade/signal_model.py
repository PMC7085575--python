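"""Mono-exponential diffusion-weighted signal model.

The diffusion-weighted signal at weighting ``b`` (s/mm^2) decays as

    S(b) = S0 * exp(-b * D)

where ``S0`` is the signal without diffusion weighting and ``D`` is the
apparent diffusion coefficient (ADC, mm^2/s). Cancerous prostate tissue
shows a lower ADC than surrounding healthy tissue, so it is hypointense on
ADC maps and hyperintense on (computed) high-b images.

This module provides the forward model, per-pixel (S0, D) estimation from a
multi-b acquisition (log-linear least squares or Gaussian maximum
likelihood), and computed high-b-value (CHB) synthesis: extrapolation of the
fitted decay from a low-b reference image to an arbitrary target b-value.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "BValueProtocol",
    "MultiBVolume",
    "ADCMap",
    "forward_signal",
    "fit_adc",
    "synthesize_chb",
    "load_multib_nifti",
    "save_multib_nifti",
]


@dataclass(frozen=True)
class BValueProtocol:
    """Ordered list of diffusion weightings (s/mm^2) of one acquisition."""

    b_values: tuple[float, ...]

    def __init__(self, b_values: Sequence[float]) -> None:
        bv = tuple(float(b) for b in b_values)
        if len(set(bv)) < 2:
            raise ValueError("protocol needs at least 2 distinct b-values")
        if any(b < 0 for b in bv):
            raise ValueError("b-values must be >= 0")
        object.__setattr__(self, "b_values", bv)

    def __len__(self) -> int:
        return len(self.b_values)


@dataclass
class MultiBVolume:
    """Stack of aligned DWI intensity arrays, one per b-value."""

    signals: list[np.ndarray]
    protocol: BValueProtocol

    def __post_init__(self) -> None:
        if len(self.signals) != len(self.protocol):
            raise ValueError("one signal array per b-value required")
        shapes = {s.shape for s in self.signals}
        if len(shapes) != 1:
            raise ValueError("all signal arrays must share one shape")
        for s in self.signals:
            if np.any(s < 0):
                raise ValueError("signal intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.signals[0].shape

    def stack(self) -> np.ndarray:
        """Signals as one (n_b, *spatial) array."""
        return np.stack(self.signals, axis=0)


@dataclass
class ADCMap:
    """Per-pixel fitted (S0, D) with the method tag that produced it."""

    d_map: np.ndarray          # ADC, mm^2/s, clipped to >= 0
    s0_map: np.ndarray         # fitted zero-b signal
    fit_method: str            # "loglinear" or "mle"
    n_clamped: int = 0         # pixels floored before the log transform

    def __post_init__(self) -> None:
        if self.d_map.shape != self.s0_map.shape:
            raise ValueError("d_map and s0_map shapes differ")


def forward_signal(s0, d, b):
    """Noise-free DWI signal ``s0 * exp(-b * d)``.

    Accepts scalars or broadcastable arrays; all inputs must be >= 0.
    """
    s0 = np.asarray(s0, dtype=float)
    d = np.asarray(d, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(s0 < 0) or np.any(d < 0) or np.any(b < 0):
        raise ValueError("forward_signal requires s0, d, b >= 0")
    out = s0 * np.exp(-b * d)
    return out if out.ndim else float(out)


def _loglinear_fit(stack: np.ndarray, b: np.ndarray, floor_frac: float):
    """Weighted-free least squares of log S against b, vectorized per pixel."""
    floor = floor_frac * max(float(stack.max()), np.finfo(float).tiny)
    n_clamped = int(np.count_nonzero(stack < floor))
    logs = np.log(np.maximum(stack, floor))
    # slope/intercept of log S = log S0 - b D via closed-form least squares
    bm = b.mean()
    bc = b - bm
    denom = float(np.dot(bc, bc))
    slope = np.tensordot(bc, logs, axes=(0, 0)) / denom
    intercept = logs.mean(axis=0) - slope * bm
    d_map = np.clip(-slope, 0.0, None)
    s0_map = np.exp(intercept)
    return d_map, s0_map, n_clamped


def _mle_fit(stack: np.ndarray, b: np.ndarray, floor_frac: float):
    """Per-pixel Gaussian maximum likelihood (flat prior).

    For i.i.d. Gaussian noise on intensities the likelihood product reduces
    to least squares on the *linear* signals; S0 is profiled out in closed
    form given D, leaving a 1-D minimization per pixel.
    """
    d0, s0_init, n_clamped = _loglinear_fit(stack, b, floor_frac)
    d_map = np.empty_like(d0)
    s0_map = np.empty_like(s0_init)
    flat = stack.reshape(len(b), -1)
    d0f = d0.ravel()
    for i in range(flat.shape[1]):
        y = flat[:, i]

        def nll(d):
            e = np.exp(-b * d)
            s0 = float(np.dot(y, e) / np.dot(e, e))
            r = y - s0 * e
            return float(np.dot(r, r))

        hi = max(5.0 * d0f[i], 1e-2)
        res = minimize_scalar(nll, bounds=(0.0, hi), method="bounded",
                              options={"xatol": 1e-12})
        d = float(res.x) if res.fun <= nll(d0f[i]) else float(d0f[i])
        e = np.exp(-b * d)
        d_map.flat[i] = max(d, 0.0)
        s0_map.flat[i] = float(np.dot(y, e) / np.dot(e, e))
    return d_map, s0_map, n_clamped


def fit_adc(volume: MultiBVolume, method: str = "loglinear",
            floor_frac: float = 1e-6) -> ADCMap:
    """Estimate per-pixel (S0, D) from a multi-b acquisition.

    Parameters
    ----------
    volume
        Aligned signals, one array per b-value.
    method
        ``"loglinear"`` (default): least squares on log intensities —
        exact for noise-free data and fast. ``"mle"``: maximum likelihood
        under i.i.d. Gaussian intensity noise, initialised from loglinear.
    floor_frac
        Nonpositive intensities are floored at ``floor_frac * max(signal)``
        before the log transform; the count is recorded on the result.
    """
    b = np.asarray(volume.protocol.b_values, dtype=float)
    if np.ptp(b) == 0:
        raise ValueError("all b-values identical; ADC is unidentifiable")
    stack = volume.stack().astype(float)
    if method == "loglinear":
        d, s0, nc = _loglinear_fit(stack, b, floor_frac)
    elif method == "mle":
        d, s0, nc = _mle_fit(stack, b, floor_frac)
    else:
        raise ValueError(f"unknown fit method {method!r}")
    return ADCMap(d_map=d, s0_map=s0, fit_method=method, n_clamped=nc)


def synthesize_chb(adc: ADCMap, reference: np.ndarray, b_alpha: float,
                   b_target: float) -> np.ndarray:
    """Computed high-b image: extrapolate the fitted decay from b_alpha.

    Returns ``reference * exp(-(b_target - b_alpha) * D)`` per pixel. With
    ``b_target == b_alpha`` this is the reference image itself. The
    reference is conventionally the lowest acquired b-value (highest SNR).
    """
    reference = np.asarray(reference, dtype=float)
    if b_target < 0:
        raise ValueError("b_target must be >= 0")
    if reference.shape != adc.d_map.shape:
        raise ValueError(
            f"reference shape {reference.shape} != ADC map shape {adc.d_map.shape}")
    return reference * np.exp(-(b_target - b_alpha) * adc.d_map)


# ---------------------------------------------------------------------------
# NIfTI interchange: 4D volume + JSON sidecar listing b_values in order.

def save_multib_nifti(volume: MultiBVolume, path: str | Path) -> None:
    import nibabel as nib

    path = Path(path)
    data = np.stack([np.atleast_3d(s) for s in volume.signals], axis=-1)
    nib.save(nib.Nifti1Image(data.astype(np.float64), np.eye(4)), str(path))
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".gz" else path.with_suffix(".json")
    sidecar.write_text(json.dumps({"b_values": list(volume.protocol.b_values)}))


def load_multib_nifti(path: str | Path) -> MultiBVolume:
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".gz" else path.with_suffix(".json")
    b_values = json.loads(sidecar.read_text())["b_values"]
    signals = [np.squeeze(data[..., i]) for i in range(data.shape[-1])]
    return MultiBVolume(signals=signals, protocol=BValueProtocol(b_values))
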