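"""Offline signal conditioning: baseline correction, HRF pre-coloring,
wavelet-MDL detrending.

These steps serve the offline analysis path; the real-time path classifies
raw concentration changes and relies on the classifier-level rest-bias
correction instead.  All operations are per-channel and channel-order
preserving; 1-D input gives 1-D output, 2-D input is treated as
(n_samples, n_channels).

The detrender decomposes each channel with a periodized orthogonal db4
wavelet transform, treats candidate low-frequency approximations as trend
models, and picks the model minimizing a two-part minimum-description-
length score (parameter cost + residual code length).  The chosen trend is
subtracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .synth import HemoParams, canonical_hrf

# Daubechies-4 (8-tap) orthonormal decomposition low-pass filter.
_DB4_LO = np.array(
    [
        -0.010597401784997278,
        0.032883011666982945,
        0.030841381835986965,
        -0.18703481171888114,
        -0.02798376941698385,
        0.6308807679295904,
        0.7148465705525415,
        0.23037781330885523,
    ]
)
_DB4_HI = np.array([(-1) ** k * _DB4_LO[len(_DB4_LO) - 1 - k] for k in range(len(_DB4_LO))])


@dataclass(frozen=True)
class PreprocConfig:
    baseline_window: str = "preceding_rest"   # or "run_start"
    precolor_len_s: float = 30.0
    wavelet: str = "db4"
    depth: int | None = None                  # None: floor(log2 n) - 4
    mdl: bool = True

    def __post_init__(self) -> None:
        if self.precolor_len_s <= 0:
            raise ValueError("precolor kernel length must be positive")
        if self.depth is not None and self.depth < 1:
            raise ValueError("decomposition depth must be >= 1")


def _as_2d(series: np.ndarray) -> tuple[np.ndarray, bool]:
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        return x[:, None], True
    if x.ndim == 2:
        return x, False
    raise ValueError(f"expected a 1-D or 2-D series, got ndim={x.ndim}")


def baseline_correct(series: np.ndarray, window: slice | np.ndarray) -> np.ndarray:
    """Subtract the per-channel mean over ``window`` (a slice or index array)."""
    x, squeeze = _as_2d(series)
    ref = x[window]
    if ref.size == 0:
        raise ValueError("baseline window is empty")
    out = x - ref.mean(axis=0, keepdims=True)
    return out[:, 0] if squeeze else out


def precolor_kernel(fs: float, params: HemoParams | None = None, length_s: float = 30.0) -> np.ndarray:
    """Canonical-HRF low-pass kernel sampled at ``fs``, normalized to unit sum."""
    if fs <= 0:
        raise ValueError(f"sampling frequency must be positive, got {fs}")
    k = canonical_hrf(np.arange(0.0, length_s, 1.0 / fs), params)
    s = k.sum()
    if s == 0:
        raise ValueError("degenerate pre-coloring kernel")
    return k / s


def hrf_precolor(
    series: np.ndarray,
    fs: float,
    params: HemoParams | None = None,
    length_s: float = 30.0,
) -> np.ndarray:
    """Causal convolution with the unit-DC-gain HRF kernel ("same" length).

    The input is padded at the start with its per-channel mean so a
    constant series maps to itself exactly and the start-up transient is
    unbiased.  Series shorter than the kernel are returned unchanged with a
    warning.
    """
    x, squeeze = _as_2d(series)
    kern = precolor_kernel(fs, params, length_s)
    if len(x) < len(kern):
        warnings.warn(
            f"series of {len(x)} samples is shorter than the {len(kern)}-tap "
            "pre-coloring kernel; returning input unchanged",
            stacklevel=2,
        )
        return series.copy() if hasattr(series, "copy") else np.asarray(series)
    pad = np.repeat(x.mean(axis=0, keepdims=True), len(kern) - 1, axis=0)
    padded = np.vstack([pad, x])
    out = np.empty_like(x)
    for c in range(x.shape[1]):
        out[:, c] = np.convolve(padded[:, c], kern, mode="valid")
    return out[:, 0] if squeeze else out


def _dwt_step(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(x)
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(len(_DB4_LO))[None, :]) % n
    win = x[idx]
    return win @ _DB4_LO, win @ _DB4_HI


def _idwt_step(a: np.ndarray, d: np.ndarray) -> np.ndarray:
    n = 2 * len(a)
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(len(_DB4_LO))[None, :]) % n
    x = np.zeros(n)
    np.add.at(x, idx.ravel(), (a[:, None] * _DB4_LO[None, :]).ravel())
    np.add.at(x, idx.ravel(), (d[:, None] * _DB4_HI[None, :]).ravel())
    return x


def wavedec_periodized(x: np.ndarray, depth: int) -> list[np.ndarray]:
    """Periodized orthogonal db4 decomposition: [cA_D, cD_D, ..., cD_1]."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if len(x) % (2**depth) != 0:
        raise ValueError(f"length {len(x)} is not divisible by 2^{depth}")
    details: list[np.ndarray] = []
    a = np.asarray(x, dtype=float)
    for _ in range(depth):
        a, d = _dwt_step(a)
        details.append(d)
    return [a] + details[::-1]


def waverec_periodized(coeffs: list[np.ndarray]) -> np.ndarray:
    a = coeffs[0]
    for d in coeffs[1:]:
        a = _idwt_step(a, d)
    return a


def _mdl_score(n: int, n_params: int, rss: float) -> float:
    rss = max(rss, n * np.finfo(float).tiny)
    return 0.5 * n_params * np.log2(n) + 0.5 * n * np.log2(rss / n)


def _detrend_channel(x: np.ndarray, depth: int, use_mdl: bool) -> np.ndarray:
    n = len(x)
    if np.allclose(x, 0.0):
        return np.zeros_like(x)

    # pad to a multiple of 2^depth by point-reflection about the last sample,
    # which continues linear trends smoothly
    block = 2**depth
    n_pad = (-n) % block
    if n_pad:
        tail = 2.0 * x[-1] - x[-2 : -2 - n_pad : -1]
        if len(tail) < n_pad:  # very short series: fall back to edge padding
            tail = np.concatenate([tail, np.full(n_pad - len(tail), x[-1])])
        xp = np.concatenate([x, tail])
    else:
        xp = x

    coeffs = wavedec_periodized(xp, depth)

    # candidate trends: the approximation at depth, depth-1, or nothing
    def trend_of(level_drop: int) -> tuple[np.ndarray, int]:
        kept = [c.copy() for c in coeffs]
        n_params = len(kept[0])
        for j in range(1, 1 + level_drop):
            n_params += len(kept[j])
        zeroed = [kept[0]] + [
            c if j <= level_drop else np.zeros_like(c)
            for j, c in enumerate(kept[1:], start=1)
        ]
        return waverec_periodized(zeroed), n_params

    candidates: list[tuple[float, np.ndarray]] = []
    none_score = _mdl_score(len(xp), 0, float(xp @ xp))
    candidates.append((none_score, np.zeros_like(xp)))
    for drop in (0, 1):
        trend, n_params = trend_of(drop)
        rss = float(((xp - trend) ** 2).sum())
        candidates.append((_mdl_score(len(xp), n_params, rss), trend))

    if use_mdl:
        _, trend = min(candidates, key=lambda c: c[0])
    else:
        trend = candidates[1][1]  # always remove the deepest approximation
    return (xp - trend)[:n]


def wavelet_mdl_detrend(
    series: np.ndarray, config: PreprocConfig | None = None
) -> np.ndarray:
    """Remove slow global trends via db4 decomposition and MDL model choice."""
    cfg = config if config is not None else PreprocConfig()
    x, squeeze = _as_2d(series)
    n = len(x)
    depth = cfg.depth if cfg.depth is not None else max(1, int(np.floor(np.log2(max(n, 2)))) - 4)
    # keep at least 8 approximation coefficients so the filter does not wrap onto itself
    while depth > 1 and (n + (-n) % (2**depth)) // (2**depth) < len(_DB4_LO):
        depth -= 1
    if n < 2**depth:
        raise ValueError(f"series of {n} samples is too short for depth {depth}")
    out = np.empty_like(x)
    for c in range(x.shape[1]):
        out[:, c] = _detrend_channel(x[:, c], depth, cfg.mdl)
    return out[:, 0] if squeeze else out


def preprocess_run(
    hbo: np.ndarray,
    fs: float,
    config: PreprocConfig | None = None,
    baseline_window: slice | np.ndarray | None = None,
) -> np.ndarray:
    """Baseline-correct, pre-color and detrend a (n_samples, n_channels) block."""
    cfg = config if config is not None else PreprocConfig()
    x = np.asarray(hbo, dtype=float)
    window = baseline_window if baseline_window is not None else slice(0, max(1, int(round(fs))))
    x = baseline_correct(x, window)
    x = hrf_precolor(x, fs, length_s=cfg.precolor_len_s)
    return wavelet_mdl_detrend(x, cfg)
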