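"""Scalar observables and detectors on simulated tissue.

Everything the pacing protocols and the analysis need to *see* about
the tissue lives here:

- the spatial-mean transmembrane potential (the single scalar signal
  the feedback controller observes),
- its dominant frequency (peak of the power spectral density),
- upward-deflection statistics (time from each local minimum of the
  mean potential to the consecutive local maximum),
- the termination test (maximum potential below a small threshold),
- a phase-singularity counter via time-delay phase embedding and
  topological charge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

__all__ = [
    "MeanVmTrace",
    "DeflectionStats",
    "mean_vm",
    "dominant_frequency",
    "power_spectrum",
    "deflection_stats",
    "is_terminated",
    "count_phase_singularities",
]


@dataclass
class MeanVmTrace:
    """Uniformly sampled spatial-mean potential; ``t`` in ms."""

    t: np.ndarray
    value: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.value.shape:
            raise ValueError("t and value must be matching 1D arrays")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("t must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("t must be uniformly sampled")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("trace values must be finite")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def last(self, window_ms: float) -> "MeanVmTrace":
        """The trailing ``window_ms`` of the trace."""
        mask = self.t >= self.t[-1] - window_ms
        return MeanVmTrace(self.t[mask], self.value[mask])


@dataclass
class DeflectionStats:
    """Minimum-to-next-maximum rise times of the mean potential."""

    minima_times: np.ndarray
    maxima_times: np.ndarray
    dt_up: np.ndarray
    dt_median: float


def mean_vm(field: np.ndarray) -> float:
    """Arithmetic mean of the potential over all N^2 nodes."""
    return float(np.mean(field))


def power_spectrum(trace: MeanVmTrace, method: str = "welch"):
    """One-sided PSD of the mean-removed trace.

    ``method="welch"`` averages Hann-windowed segments (smooth spectrum
    for band detection); ``method="periodogram"`` uses a single
    zero-padded Hann periodogram (fine frequency grid for peak
    location).

    Returns ``(freqs_hz, psd)``.
    """
    x = trace.value - trace.value.mean()
    fs = 1000.0 / trace.dt  # Hz
    n = len(x)
    if method == "welch":
        nperseg = min(n, 2048)
        f, p = _signal.welch(x, fs=fs, nperseg=nperseg)
    elif method == "periodogram":
        nfft = int(2 ** np.ceil(np.log2(8 * n)))
        f, p = _signal.periodogram(x, fs=fs, window="hann", nfft=nfft)
    else:
        raise ValueError(f"unknown method {method!r}")
    return f, p


def dominant_frequency(trace: MeanVmTrace, min_duration_ms: float = 2000.0,
                       return_spectrum: bool = False):
    """Frequency with the largest PSD amplitude, in Hz.

    The PSD is a Welch estimate (Hann segments), which suppresses the
    slow drift of chaotic mean-potential traces; the peak location is
    refined by parabolic interpolation of log power across the peak's
    neighbours (sub-bin accuracy for narrowband peaks).  Requires at
    least ``min_duration_ms`` of data.
    """
    if trace.duration < min_duration_ms:
        raise ValueError(
            f"trace of {trace.duration:.0f} ms is too short; "
            f"need >= {min_duration_ms:.0f} ms"
        )
    f, p = power_spectrum(trace, method="welch")
    # ignore the zero-frequency bin (mean already removed, but guard)
    i = int(np.argmax(p[1:])) + 1
    if p[i] <= 0:
        raise ValueError("degenerate spectrum: no spectral peak")
    fpk = f[i]
    if 1 <= i < len(p) - 1 and p[i - 1] > 0 and p[i + 1] > 0:
        # parabolic refinement on log-power
        la, lb, lc = np.log(p[i - 1]), np.log(p[i]), np.log(p[i + 1])
        denom = la - 2 * lb + lc
        if denom < 0:
            fpk = f[i] + 0.5 * (la - lc) / denom * (f[1] - f[0])
    if return_spectrum:
        return float(fpk), (f, p)
    return float(fpk)


def _smooth(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    k = np.ones(window) / window
    # reflect-pad so the smoothed trace keeps its length and endpoints
    pad = window // 2
    xp = np.pad(x, pad, mode="reflect")
    out = np.convolve(xp, k, mode="valid")
    return out[: len(x)]


def _extrema(x: np.ndarray):
    """Indices of local minima and maxima with plateau handling.

    Zero first-differences inherit the preceding non-zero slope sign,
    so a descent -> plateau -> rise counts as one minimum at the
    plateau's end (and symmetrically for maxima).
    """
    d = np.diff(x)
    s = np.sign(d)
    nz = s != 0
    if not nz.any():
        return np.array([], dtype=int), np.array([], dtype=int)
    idx = np.where(nz, np.arange(len(s)), -1)
    np.maximum.accumulate(idx, out=idx)
    filled = np.where(idx >= 0, s[np.maximum(idx, 0)], 0.0)
    flips = np.nonzero((filled[:-1] != 0) & (filled[1:] != 0)
                       & (filled[:-1] != filled[1:]))[0]
    minima = flips[filled[flips] < 0] + 1
    maxima = flips[filled[flips] > 0] + 1
    return minima, maxima


def deflection_stats(trace: MeanVmTrace, window_s: float = 2.0,
                     smooth_window: int = 3) -> DeflectionStats:
    """Upward-deflection times on the trailing ``window_s`` seconds.

    The trace is lightly smoothed (moving average of ``smooth_window``
    samples) before strict extremum detection; each local minimum is
    paired with the next local maximum and the rise times and their
    median are returned.
    """
    tail = trace.last(window_s * 1000.0)
    x = _smooth(tail.value, smooth_window)
    minima, maxima = _extrema(x)
    if len(minima) + len(maxima) < 2:
        raise ValueError("fewer than two extrema in the analysis window")
    t = tail.t
    dt_up = []
    pairs_min, pairs_max = [], []
    j = 0
    for i in minima:
        while j < len(maxima) and maxima[j] <= i:
            j += 1
        if j == len(maxima):
            break
        pairs_min.append(i)
        pairs_max.append(maxima[j])
        dt_up.append(t[maxima[j]] - t[i])
    if not dt_up:
        raise ValueError("no minimum-to-maximum pair in the analysis window")
    dt_up = np.asarray(dt_up)
    return DeflectionStats(
        minima_times=t[np.asarray(pairs_min, dtype=int)],
        maxima_times=t[np.asarray(pairs_max, dtype=int)],
        dt_up=dt_up,
        dt_median=float(np.median(dt_up)),
    )


def is_terminated(field: np.ndarray, threshold: float = 0.01) -> bool:
    """True iff the maximum of the potential is below ``threshold``."""
    return bool(np.max(field) < threshold)


def _wrap(x):
    return (x + np.pi) % (2 * np.pi) - np.pi


def count_phase_singularities(fields, delay: int = 1):
    """Phase-singularity count per usable snapshot.

    Parameters
    ----------
    fields : sequence of N x N arrays (ordered in time)
    delay : int
        Embedding delay in snapshot strides; ideally about a quarter
        of the dominant period.

    The phase at each node is ``atan2(vm(t) - m, vm(t - delay) - m)``
    with ``m`` the node's temporal mean over the sequence; the
    topological charge of every 2 x 2 plaquette is the winding number
    of the phase around it, and the count per snapshot is the sum of
    absolute charges.

    Returns ``(counts, mean_count)`` where ``counts`` has one entry per
    snapshot from index ``delay`` on.
    """
    stack = np.asarray(fields, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < delay + 1:
        raise ValueError("need at least delay+1 snapshots")
    m = stack.mean(axis=0)
    counts = []
    for i in range(delay, stack.shape[0]):
        phase = np.arctan2(stack[i] - m, stack[i - delay] - m)
        d1 = _wrap(phase[:-1, 1:] - phase[:-1, :-1])
        d2 = _wrap(phase[1:, 1:] - phase[:-1, 1:])
        d3 = _wrap(phase[1:, :-1] - phase[1:, 1:])
        d4 = _wrap(phase[:-1, :-1] - phase[1:, :-1])
        q = np.rint((d1 + d2 + d3 + d4) / (2 * np.pi))
        counts.append(int(np.abs(q).sum()))
    counts = np.asarray(counts, dtype=int)
    return counts, float(counts.mean())
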