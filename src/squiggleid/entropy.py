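"""Entropy-space signal mapping via a windowed correlation integral.

An alternative to exact fingerprint matching: a current signal is converted
to *entropy space* by sliding a short window along it and estimating, for
each window, an order-2 entropy from the correlation integral
``C(r) = 2/(m(m-1)) * #{pairs i<j : |x_i - x_j| < r}`` as ``H = -ln C(r)``.
Regions where the signal revisits similar current levels score low entropy;
erratic regions score high.  Reads and candidate reference regions are
compared in entropy space by Pearson correlation after smoothing and
resampling the reference trace to the read's length — tolerant of the level
shifts and amplitude differences that defeat direct signal comparison,
though not of heavy time distortion from stays (hence the stay-rate gate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pore_model import EventSignal

__all__ = [
    "EntropyParams",
    "EntropySignal",
    "MappingScore",
    "correlation_integral",
    "entropy_signal",
    "smooth_mean",
    "resample_to_length",
    "map_entropy",
    "stay_rate_gate",
]

_R_FLOOR = 1e-6  # pA; keeps the radius positive on zero-variance signals


@dataclass(frozen=True)
class EntropyParams:
    """Windowed correlation-integral estimator settings.

    ``window`` samples slide by ``step`` (window 20 with step 1 corresponds
    to an overlap of 19); the pair-counting radius is
    ``radius_fraction`` times the standard deviation of the whole input
    signal; ``smooth_window`` is the moving-average width applied before
    trace comparison.
    """

    window: int = 20
    step: int = 1
    radius_fraction: float = 0.2
    smooth_window: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window:
            raise ValueError("need 0 < step <= window")
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.radius_fraction <= 0:
            raise ValueError("radius_fraction must be positive")

    @property
    def overlap(self) -> int:
        return self.window - self.step

    @property
    def epsilon(self) -> float:
        """One-pair-equivalent floor keeping H finite when C(r) = 0."""
        m = self.window
        return 2.0 / (m * (m - 1))


@dataclass
class EntropySignal:
    """Per-position order-2 entropy trace of a current signal (nats)."""

    values: np.ndarray
    params: EntropyParams
    source_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)) or (self.values < 0).any():
            raise ValueError("entropy values must be finite and nonnegative")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class MappingScore:
    """Pearson similarity of two aligned entropy traces.

    ``pearson_r`` is NaN (with ``defined`` False) when either trace has zero
    variance; the p-value is two-sided from the exact null of the sample
    correlation between independent Gaussian sequences (t with n-2 df).
    """

    pearson_r: float
    p_value: float
    n: int
    region: tuple[int, int] | None = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.pearson_r)


def correlation_integral(window_values: np.ndarray, r: float) -> float:
    """Fraction of point pairs within distance r: C(r) = 2/(m(m-1)) #{|xi-xj| < r}."""
    x = np.asarray(window_values, dtype=np.float64)
    m = len(x)
    if m < 2:
        raise ValueError("correlation integral needs at least 2 values")
    if r <= 0:
        raise ValueError("radius must be positive")
    diff = np.abs(x[:, None] - x[None, :]) < r
    n_pairs = (int(diff.sum()) - m) // 2  # remove diagonal, halve symmetric count
    return 2.0 * n_pairs / (m * (m - 1))


def entropy_signal(
    signal: EventSignal | np.ndarray,
    params: EntropyParams | None = None,
    source_id: str = "",
) -> EntropySignal:
    """Convert a current signal to its entropy-space trace.

    For each window position, ``H = -ln(max(C(r), eps))`` with
    ``eps = 2/(m(m-1))`` and ``r = radius_fraction * sd(whole signal)``
    (floored at 1e-6 pA for constant signals).  Output length is
    ``floor((n - window)/step) + 1``.
    """
    params = params or EntropyParams()
    x = signal.values if isinstance(signal, EventSignal) else np.asarray(signal, float)
    if len(x) < params.window:
        raise ValueError(f"signal length {len(x)} shorter than window {params.window}")
    r = max(params.radius_fraction * float(np.std(x)), _R_FLOOR)
    m = params.window
    windows = np.lib.stride_tricks.sliding_window_view(x, m)[:: params.step]
    # pairwise counts per window, chunked to bound the (n, m, m) temporary
    n_pairs = np.empty(len(windows), dtype=np.int64)
    chunk = max(1, 4_000_000 // (m * m))
    for start in range(0, len(windows), chunk):
        w = windows[start : start + chunk]
        within = np.abs(w[:, :, None] - w[:, None, :]) < r
        n_pairs[start : start + len(w)] = (within.sum(axis=(1, 2)) - m) // 2
    c = 2.0 * n_pairs / (m * (m - 1))
    h = -np.log(np.maximum(c, params.epsilon))
    h[h < 0] = 0.0  # guard against -0.0 from C = 1
    if not isinstance(signal, EventSignal) or not source_id:
        src = source_id
    else:
        src = signal.source_id
    return EntropySignal(values=h, params=params, source_id=src or source_id)


def smooth_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Valid-mode moving average; output length len(values) - window + 1."""
    x = np.asarray(values, dtype=np.float64)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(x) < window:
        raise ValueError(f"input length {len(x)} shorter than window {window}")
    return np.convolve(x, np.full(window, 1.0 / window), mode="valid")


def resample_to_length(values: np.ndarray, target_length: int) -> np.ndarray:
    """Linearly interpolate a sequence onto a uniform grid of the target length.

    Endpoints are preserved exactly; ``target_length == len(values)`` is the
    identity.
    """
    x = np.asarray(values, dtype=np.float64)
    if len(x) < 2 or target_length < 2:
        raise ValueError("resampling needs source and target lengths >= 2")
    if target_length == len(x):
        return x.copy()
    src = np.linspace(0.0, 1.0, num=len(x))
    dst = np.linspace(0.0, 1.0, num=target_length)
    return np.interp(dst, src, x)


def map_entropy(
    read_entropy: EntropySignal,
    reference_entropy: EntropySignal,
    smooth_window: int | None = None,
    region: tuple[int, int] | None = None,
) -> MappingScore:
    """Score a read's entropy trace against a candidate reference region.

    Both traces are smoothed by a moving average, the reference is resampled
    to the read's smoothed length, and the Pearson correlation at zero lag
    is reported with its two-sided t-test p-value.  Zero-variance traces
    yield an undefined (NaN) correlation rather than 0.
    """
    w = smooth_window if smooth_window is not None else read_entropy.params.smooth_window
    read = smooth_mean(read_entropy.values, w)
    ref = smooth_mean(reference_entropy.values, w)
    ref = resample_to_length(ref, len(read))
    n = len(read)
    if np.std(read) == 0 or np.std(ref) == 0:
        return MappingScore(pearson_r=math.nan, p_value=math.nan, n=n, region=region)
    r, p = stats.pearsonr(read, ref)
    return MappingScore(pearson_r=float(r), p_value=float(p), n=n, region=region)


def stay_rate_gate(read_qc, threshold: float = 0.1) -> bool:
    """True iff the read's stay rate is strictly below the threshold.

    Accepts a ``ReadQC`` (uses its ``stays_per_base``) or a bare rate.
    Stays stretch the event signal in time, which entropy mapping (no
    elastic alignment) cannot absorb; reads at or above 0.1 stays per base
    called are excluded by default.
    """
    rate = getattr(read_qc, "stays_per_base", read_qc)
    if rate is None or math.isnan(rate):
        raise ValueError("stays_per_base is unavailable for this read")
    return rate < threshold
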