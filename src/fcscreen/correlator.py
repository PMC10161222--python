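"""Auto-/cross-correlation of binned photon-count traces.

The estimator is the normalized fluctuation correlation

    G(tau) = <F_a(t) F_b(t + tau)> / (<F_a> <F_b>)

with the means taken over the shifted overlap (symmetric normalization,
which suppresses slow-drift/bleaching bias) and the +1 baseline convention
of :mod:`fcscreen.fcs_model`.  Cross-correlations are averaged over the two
lag directions so that the result is invariant to channel order.

Two estimators are provided:

* :func:`direct_correlate` — brute-force evaluation at explicit integer
  lags; O(n·lags); the reference implementation and test oracle.
* multi-tau (:func:`autocorrelate` / :func:`cross_correlate`) — the
  quasi-logarithmic lag grid of hardware correlators: ``points_per_stage``
  linear lags at the raw bin width, then stages of bin-doubled (coarsened)
  traces contributing lags at 2x, 4x, ... spacing.

Per-lag standard errors come from splitting the trace into contiguous
segments, correlating each and taking the standard error over segments;
lags too long for a segment get NaN errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "PhotonTrace",
    "CorrelationCurve",
    "autocorrelate",
    "cross_correlate",
    "direct_correlate",
    "multitau_lag_grid",
    "count_rate",
]

DEFAULT_POINTS_PER_STAGE = 16
DEFAULT_N_SEGMENTS = 10


@dataclass(frozen=True)
class PhotonTrace:
    """Binned photon counts, one column per detection channel.

    counts has shape (n_bins, n_channels), non-negative integers.
    """

    bin_time: float
    counts: np.ndarray
    channels: tuple[str, ...] = ("A",)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.bin_time > 0.0:
            raise ValueError(f"bin time must be positive, got {self.bin_time}")
        counts = np.asarray(self.counts)
        if counts.ndim == 1:
            counts = counts[:, None]
        if counts.ndim != 2 or counts.shape[0] == 0:
            raise ValueError("counts must be a nonempty (n_bins, n_channels) array")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(counts == np.round(counts)):
                raise ValueError("photon counts must be integers")
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            idx = int(np.flatnonzero((counts < 0).any(axis=1))[0])
            raise ValueError(f"negative photon count at bin {idx}")
        object.__setattr__(self, "counts", counts)
        channels = tuple(self.channels)
        if len(channels) != counts.shape[1]:
            raise ValueError(
                f"{len(channels)} channel labels for {counts.shape[1]} columns"
            )
        object.__setattr__(self, "channels", channels)

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def duration(self) -> float:
        return self.n_bins * self.bin_time

    def channel_index(self, channel: str | int) -> int:
        if isinstance(channel, (int, np.integer)):
            if not 0 <= channel < len(self.channels):
                raise KeyError(f"channel index {channel} out of range")
            return int(channel)
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(
                f"unknown channel {channel!r}; trace has {self.channels}"
            ) from None


@dataclass(frozen=True)
class CorrelationCurve:
    """Correlation amplitudes on a strictly increasing positive lag grid."""

    lags: np.ndarray
    g: np.ndarray
    se: np.ndarray | None = None
    channel_pair: tuple[str, str] = ("A", "A")
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=float)
        g = np.asarray(self.g, dtype=float)
        if lags.shape != g.shape or lags.ndim != 1 or lags.size == 0:
            raise ValueError("lags and g must be matching nonempty 1-D arrays")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        if np.any(np.isinf(g)):
            raise ValueError(
                "correlation amplitudes must not be infinite "
                "(NaN is tolerated as a missing/corrupted-data marker)"
            )
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "g", g)
        if self.se is not None:
            se = np.asarray(self.se, dtype=float)
            if se.shape != lags.shape:
                raise ValueError("se must match the lag grid")
            if np.any(se[np.isfinite(se)] < 0):
                raise ValueError("standard errors must be non-negative")
            object.__setattr__(self, "se", se)

    @property
    def is_auto(self) -> bool:
        return self.channel_pair[0] == self.channel_pair[1]


def _pair_estimate(a: np.ndarray, b: np.ndarray, lag: int) -> float:
    """Symmetrized, locally normalized correlation at one integer lag."""
    n = a.size
    if lag >= n:
        return np.nan
    m = n - lag
    num_ab = float(a[:m] @ b[lag:]) / m
    den_ab = (a[:m].mean()) * (b[lag:].mean())
    num_ba = float(b[:m] @ a[lag:]) / m
    den_ba = (b[:m].mean()) * (a[lag:].mean())
    vals = []
    for num, den in ((num_ab, den_ab), (num_ba, den_ba)):
        vals.append(num / den if den > 0 else np.nan)
    return float(np.nanmean(vals)) if not np.all(np.isnan(vals)) else np.nan


def direct_correlate(
    a: np.ndarray, b: np.ndarray, lag_bins: np.ndarray
) -> np.ndarray:
    """Brute-force correlation estimate at explicit integer lags (in bins)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("signals must be matching 1-D arrays")
    return np.array([_pair_estimate(a, b, int(k)) for k in lag_bins])


def multitau_lag_grid(
    n_bins: int, points_per_stage: int = DEFAULT_POINTS_PER_STAGE
) -> list[tuple[int, int]]:
    """Lag grid as (coarsening factor, lag in coarse bins) pairs.

    Stage 0 holds lags 1..m at the raw bin width; each further stage halves
    the time resolution and contributes lags m/2+1..m at its own width.
    The grid stops once the coarsened trace is shorter than twice the
    longest stage lag.
    """
    m = int(points_per_stage)
    if m < 2 or m % 2:
        raise ValueError("points per stage must be an even integer >= 2")
    grid: list[tuple[int, int]] = []
    factor = 1
    n = n_bins
    lags0 = [k for k in range(1, m + 1) if 2 * k <= n]
    grid.extend((1, k) for k in lags0)
    if len(lags0) < m:
        return grid
    while True:
        n //= 2
        factor *= 2
        stage = [k for k in range(m // 2 + 1, m + 1) if 2 * k <= n]
        grid.extend((factor, k) for k in stage)
        if len(stage) < m // 2:
            break
    return grid


def _coarsen(a: np.ndarray) -> np.ndarray:
    n = a.size // 2 * 2
    return a[:n:2] + a[1:n:2]


def _multitau(
    a: np.ndarray,
    b: np.ndarray,
    bin_time: float,
    points_per_stage: int,
    max_lag: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    grid = multitau_lag_grid(a.size, points_per_stage)
    if max_lag is not None:
        grid = [(f, k) for f, k in grid if f * k * bin_time <= max_lag]
    lags = np.empty(len(grid))
    g = np.empty(len(grid))
    ca, cb = a.astype(float), b.astype(float)
    factor = 1
    for i, (f, k) in enumerate(grid):
        while factor < f:
            ca, cb = _coarsen(ca), _coarsen(cb)
            factor *= 2
        lags[i] = f * k * bin_time
        g[i] = _pair_estimate(ca, cb, k)
    return lags, g


def _correlate(
    trace: PhotonTrace,
    ch_a: str | int,
    ch_b: str | int,
    points_per_stage: int,
    n_segments: int,
) -> CorrelationCurve:
    ia, ib = trace.channel_index(ch_a), trace.channel_index(ch_b)
    a = trace.counts[:, ia]
    b = trace.counts[:, ib]
    for idx, sig in ((ia, a), (ib, b)):
        if not sig.any():
            raise ValueError(
                f"channel {trace.channels[idx]!r} has zero total counts; "
                "the correlation normalization is undefined"
            )
    lags, g = _multitau(a, b, trace.bin_time, points_per_stage)
    keep = np.isfinite(g)
    lags, g = lags[keep], g[keep]

    se = np.full(lags.size, np.nan)
    if n_segments >= 2 and trace.n_bins >= 4 * n_segments:
        seg_len = trace.n_bins // n_segments
        seg_g = []
        for s in range(n_segments):
            sa = a[s * seg_len : (s + 1) * seg_len]
            sb = b[s * seg_len : (s + 1) * seg_len]
            if sa.any() and sb.any():
                slags, sg = _multitau(
                    sa, sb, trace.bin_time, points_per_stage,
                    max_lag=float(lags[-1]),
                )
                row = np.full(lags.size, np.nan)
                take = min(slags.size, lags.size)
                match = np.isclose(slags[:take], lags[:take])
                row[:take][match] = sg[:take][match]
                seg_g.append(row)
        if len(seg_g) >= 2:
            seg_arr = np.vstack(seg_g)
            ok = np.isfinite(seg_arr).all(axis=0)
            se[ok] = seg_arr[:, ok].std(axis=0, ddof=1) / np.sqrt(len(seg_g))

    pair = (trace.channels[ia], trace.channels[ib])
    meta = {
        "estimator": "multitau",
        "points_per_stage": points_per_stage,
        "n_segments": n_segments,
        "bin_time_s": trace.bin_time,
    }
    return CorrelationCurve(lags=lags, g=g, se=se, channel_pair=pair, metadata=meta)


def autocorrelate(
    trace: PhotonTrace,
    channel: str | int = 0,
    points_per_stage: int = DEFAULT_POINTS_PER_STAGE,
    n_segments: int = DEFAULT_N_SEGMENTS,
) -> CorrelationCurve:
    """Multi-tau autocorrelation of one detection channel."""
    return _correlate(trace, channel, channel, points_per_stage, n_segments)


def cross_correlate(
    trace: PhotonTrace,
    channel_a: str | int,
    channel_b: str | int,
    points_per_stage: int = DEFAULT_POINTS_PER_STAGE,
    n_segments: int = DEFAULT_N_SEGMENTS,
) -> CorrelationCurve:
    """Multi-tau cross-correlation between two channels (order-invariant)."""
    return _correlate(trace, channel_a, channel_b, points_per_stage, n_segments)


def count_rate(trace: PhotonTrace, channel: str | int = 0) -> float:
    """Mean detected count rate (counts/s) of one channel."""
    idx = trace.channel_index(channel)
    return float(trace.counts[:, idx].sum()) / trace.duration


def count_rates(trace: PhotonTrace) -> Mapping[str, float]:
    """Count rate per channel label."""
    return {ch: count_rate(trace, ch) for ch in trace.channels}
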