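"""Signal conditioning for sampled process data.

Spike-suppressing moving-average filtering, five-point numerical
differentiation, channel normalization with frozen statistics, and
local least-squares alignment of offline assay samples onto a finer grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SampledSeries",
    "FilterConfig",
    "NormalizationStats",
    "moving_average_filter",
    "five_point_derivative",
    "normalize",
    "denormalize",
    "align_offline_samples",
]


@dataclass
class SampledSeries:
    """Uniformly sampled single-channel series."""

    t: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape or self.t.ndim != 1:
            raise ValueError("t and values must be 1-D arrays of equal length")
        if len(self.t) >= 2:
            steps = np.diff(self.t)
            h = steps[0]
            if h <= 0 or np.any(np.abs(steps - h) > 1e-9 * max(abs(h), 1.0)):
                raise ValueError("sampling must be uniform and increasing")

    @property
    def spacing(self) -> float:
        if len(self.t) < 2:
            raise ValueError("spacing undefined for fewer than 2 samples")
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class FilterConfig:
    """Moving-average filter settings: outlier threshold D (channel units)
    and window length m (samples)."""

    D: float
    m: int

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"outlier threshold D must be > 0, got {self.D}")
        if not isinstance(self.m, (int, np.integer)) or self.m < 1:
            raise ValueError(f"window length m must be an integer >= 1, got {self.m}")


def moving_average_filter(series: SampledSeries, cfg: FilterConfig) -> SampledSeries:
    """Moving-average filter with innovation clamping.

    For each sample k: if |x(k) - xhat(k-1)| < D the raw value enters the
    window and xhat(k) is the mean of the last m (possibly replaced) raw
    samples; otherwise the sample is treated as a spike and replaced by
    xhat(k-1) + D*sign(x(k) - xhat(k-1)) before the window mean is
    recomputed. The first min(m, k+1) samples average over the available
    history (warm-up).
    """
    x = series.values
    n = len(x)
    buf = np.empty(n)   # raw stream after spike replacement
    out = np.empty(n)
    if n == 0:
        return SampledSeries(series.t.copy(), out)
    buf[0] = x[0]
    out[0] = x[0]
    for k in range(1, n):
        innov = x[k] - out[k - 1]
        if abs(innov) < cfg.D:
            buf[k] = x[k]
        else:
            buf[k] = out[k - 1] + cfg.D * math.copysign(1.0, innov)
        lo = max(0, k - cfg.m + 1)
        out[k] = buf[lo : k + 1].mean()
    return SampledSeries(series.t.copy(), out)


def _fd_weights(offsets: Sequence[float], order: int) -> np.ndarray:
    """Finite-difference weights on the given integer/real offsets for the
    requested derivative order, exact for polynomials up to degree
    len(offsets)-1 (Vandermonde solve; spacing applied by the caller)."""
    o = np.asarray(offsets, dtype=float)
    n = len(o)
    V = np.vander(o, n, increasing=True).T  # V[p, j] = o_j**p
    rhs = np.zeros(n)
    rhs[order] = math.factorial(order)
    return np.linalg.solve(V, rhs)


def five_point_derivative(series: SampledSeries, order: int = 1) -> SampledSeries:
    """First or second derivative by five-point stencils.

    Interior points use the standard central five-point formulas, e.g.
    (-f[k+2] + 8 f[k+1] - 8 f[k-1] + f[k-2]) / (12 h) for the first
    derivative; the two points at each boundary use one-sided five-point
    stencils of the same polynomial exactness (degree <= 4).
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    n = len(series)
    if n < 5:
        raise ValueError(f"five-point differentiation needs >= 5 samples, got {n}")
    h = series.spacing
    f = series.values
    out = np.empty(n)
    for i in range(n):
        lo = min(max(i - 2, 0), n - 5)
        offsets = np.arange(lo, lo + 5) - i
        w = _fd_weights(offsets, order)
        out[i] = w @ f[lo : lo + 5] / h**order
    return SampledSeries(series.t.copy(), out)


@dataclass
class NormalizationStats:
    """Frozen per-channel affine normalization: (x - offset) / scale."""

    offset: np.ndarray
    scale: np.ndarray
    method: str = "minmax"

    def __post_init__(self) -> None:
        self.offset = np.atleast_1d(np.asarray(self.offset, dtype=float))
        self.scale = np.atleast_1d(np.asarray(self.scale, dtype=float))
        if np.any(self.scale <= 0):
            raise ValueError("normalization scale must be > 0")

    @classmethod
    def fit(cls, data: np.ndarray, method: str = "minmax") -> "NormalizationStats":
        """Compute stats from training data only (columns = channels).
        Degenerate (constant) channels get scale 1 with a warning."""
        import warnings

        data = np.atleast_2d(np.asarray(data, dtype=float))
        if method == "minmax":
            offset = data.min(axis=0)
            scale = data.max(axis=0) - offset
        elif method == "zscore":
            offset = data.mean(axis=0)
            scale = data.std(axis=0, ddof=1) if data.shape[0] > 1 else np.zeros(data.shape[1])
        else:
            raise ValueError(f"unknown normalization method {method!r}")
        degenerate = scale <= 0
        if degenerate.any():
            warnings.warn(
                f"degenerate (constant) channel(s) {np.where(degenerate)[0].tolist()}: scale set to 1",
                stacklevel=2,
            )
            scale = np.where(degenerate, 1.0, scale)
        return cls(offset=offset, scale=scale, method=method)

    def apply(self, data: np.ndarray) -> np.ndarray:
        return (np.asarray(data, dtype=float) - self.offset) / self.scale

    def invert(self, data: np.ndarray) -> np.ndarray:
        return np.asarray(data, dtype=float) * self.scale + self.offset

    def to_dict(self) -> dict:
        return {"offset": self.offset.tolist(), "scale": self.scale.tolist(), "method": self.method}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(offset=np.array(d["offset"]), scale=np.array(d["scale"]), method=d["method"])


def normalize(data: np.ndarray, method: str = "minmax") -> tuple[np.ndarray, NormalizationStats]:
    """Fit stats on ``data`` and return (normalized data, stats)."""
    stats = NormalizationStats.fit(data, method=method)
    return stats.apply(data), stats


def denormalize(data: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    return stats.invert(data)


def align_offline_samples(
    offline: SampledSeries,
    target_t: np.ndarray,
    window: int = 5,
    degree: int = 2,
) -> np.ndarray:
    """Map offline assay samples onto a target grid by sliding-window local
    least-squares polynomial fits (default: 5-point quadratic).

    Interpolation only: target times outside the offline span raise.
    """
    target_t = np.asarray(target_t, dtype=float)
    t, y = offline.t, offline.values
    if len(t) < window:
        raise ValueError(f"need at least window={window} offline samples, got {len(t)}")
    if target_t.min() < t[0] - 1e-12 or target_t.max() > t[-1] + 1e-12:
        raise ValueError(
            f"extrapolation requested: target grid [{target_t.min()}, {target_t.max()}] "
            f"outside offline span [{t[0]}, {t[-1]}]"
        )
    out = np.empty(len(target_t))
    for j, tt in enumerate(target_t):
        center = int(np.argmin(np.abs(t - tt)))
        lo = min(max(center - window // 2, 0), len(t) - window)
        ts = t[lo : lo + window]
        ys = y[lo : lo + window]
        # center the abscissa for conditioning
        coeffs = np.polyfit(ts - tt, ys, degree)
        out[j] = np.polyval(coeffs, 0.0)
    return out
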