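"""Pacing protocols: SinglePulse, EquiDist, ADP and Local Minima Pacing.

The open-loop protocols fix every pulse time before pacing starts:

- ``SinglePulse``: one pulse (conventional single-shock defibrillation
  at low energy).
- ``EquiDist(c)``: ten pulses at the constant period ``1/(c f_dom)``
  derived from the dominant frequency of the pre-pacing dynamics.
- ``ADP`` (adaptive deceleration pacing): ten pulses whose periods
  grow linearly across the half-height band of the pre-pacing
  spectral peak, from ``1/f_hi`` to ``1/f_lo``.

Local Minima Pacing (LMP) is closed-loop: a pulse fires at time
``t_c`` when the spatial-mean potential has been rising throughout the
window ``[t_c - a*dt_median, t_c]`` (i.e. shortly after a local
minimum, the moment of highest tissue excitability), subject to a
refractory gate ``t_c - t_last_pulse > t_pause`` and a pulse budget.
After every pulse the timing scale is updated as
``a <- clamp(a*b, dt_start/dt_median, dt_end/dt_median)``, which
allows pulse timings to drift from ``dt_start`` to ``dt_end`` over the
attempt; with ``dt_start == dt_end`` the scale is constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .electrodes import AVELayout

__all__ = [
    "PulseSchedule",
    "single_pulse_schedule",
    "equidist_schedule",
    "adp_schedule",
    "LMPConfig",
    "LMPController",
    "lmp_update_scale",
    "ScheduledStimulus",
    "FeedbackStimulus",
]


@dataclass
class PulseSchedule:
    """Open-loop pulse onsets [ms] with a common amplitude [a.u./ms]."""

    onsets: np.ndarray
    amplitude: float

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.ndim != 1:
            raise ValueError("onsets must be 1D")
        if len(self.onsets) > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("onsets must be strictly increasing")


def single_pulse_schedule(t0: float, A_max: float) -> PulseSchedule:
    """One pulse at ``t0``."""
    return PulseSchedule(onsets=np.array([t0]), amplitude=A_max)


def equidist_schedule(f_dom: float, c: float, n_pulses: int, t0: float = 0.0,
                      A_max: float = 1.0) -> PulseSchedule:
    """``n_pulses`` pulses at the constant frequency ``c * f_dom`` [Hz]."""
    if f_dom <= 0 or c <= 0:
        raise ValueError("f_dom and c must be positive")
    period = 1000.0 / (c * f_dom)
    return PulseSchedule(onsets=t0 + period * np.arange(n_pulses),
                         amplitude=A_max)


def adp_schedule(spectrum, n_pulses: int = 10, t0: float = 0.0,
                 A_max: float = 1.0) -> PulseSchedule:
    """Decelerating pulse sequence from a pre-pacing power spectrum.

    ``spectrum`` is ``(freqs_hz, psd)``.  The pacing band is the
    half-height band around the PSD peak; pulse periods interpolate
    linearly from ``1/f_hi`` (first pair) to ``1/f_lo`` (last pair).
    A monochromatic spectrum collapses to EquiDist at the peak.
    """
    f, p = (np.asarray(a, dtype=float) for a in spectrum)
    if len(f) != len(p) or len(f) < 3:
        raise ValueError("spectrum must be matching (freqs, psd) arrays")
    pos = f > 0
    if not pos.any() or np.max(p[pos]) <= 0:
        raise ValueError("degenerate spectrum: no positive-frequency peak")
    ipk = int(np.argmax(np.where(pos, p, -np.inf)))
    half = p[ipk] / 2.0
    lo = ipk
    while lo > 0 and p[lo - 1] >= half and f[lo - 1] > 0:
        lo -= 1
    hi = ipk
    while hi < len(p) - 1 and p[hi + 1] >= half:
        hi += 1
    f_lo, f_hi = f[lo], f[hi]
    if f_lo <= 0:
        raise ValueError("degenerate spectrum: band reaches zero frequency")
    periods = np.linspace(1000.0 / f_hi, 1000.0 / f_lo, max(n_pulses - 1, 1))
    onsets = t0 + np.concatenate([[0.0], np.cumsum(periods[: n_pulses - 1])])
    return PulseSchedule(onsets=onsets[:n_pulses], amplitude=A_max)


def lmp_update_scale(current_a: float, b: float, dt_start: float,
                     dt_end: float, dt_median: float) -> float:
    """Post-pulse update ``a <- clamp(a*b, dt_start/dtm, dt_end/dtm)``."""
    lo = min(dt_start, dt_end) / dt_median
    hi = max(dt_start, dt_end) / dt_median
    return float(min(max(current_a * b, lo), hi))


def _default_b(dt_start: float, dt_end: float) -> float:
    if dt_start > dt_end:
        return 0.8
    if dt_start < dt_end:
        return 1.25
    return 1.0


@dataclass
class LMPConfig:
    """Parameters of the feedback controller.

    ``dt_start``/``dt_end`` are the intended delays [ms] between a
    detected minimum and the first / last pulse; the initial scale is
    ``a = dt_start/dt_median`` and the adjustment factor ``b`` follows
    from their ordering (0.8 decelerating the delay, 1.25 growing it,
    1 when equal) unless given explicitly.  ``t_pause`` defaults to
    ``dt_median``, long enough to skip the upward deflection a pulse
    itself causes.  ``eps`` is the termination threshold on the
    maximum potential.  The derivative condition on the observed mean
    potential uses >= by default (``strict=False``).
    """

    dt_median: float
    dt_start: float
    dt_end: float
    b: float | None = None
    t_pause: float | None = None
    max_pulses: int = 10
    eps: float = 0.01
    strict: bool = False

    def __post_init__(self):
        if self.dt_median <= 0:
            raise ValueError("dt_median must be positive")
        for name, v in (("dt_start", self.dt_start), ("dt_end", self.dt_end)):
            if not 0.1 * self.dt_median - 1e-9 <= v <= 1.0 * self.dt_median + 1e-9:
                raise ValueError(
                    f"{name} = {v} ms outside [0.1, 1.0] * dt_median "
                    f"(dt_median = {self.dt_median} ms)"
                )
        if self.max_pulses < 1:
            raise ValueError("max_pulses must be >= 1")
        if self.b is None:
            self.b = _default_b(self.dt_start, self.dt_end)
        if self.t_pause is None:
            self.t_pause = self.dt_median

    @classmethod
    def fixed_scale(cls, dt_median: float, a: float = 0.2, **kw) -> "LMPConfig":
        """Constant-scale configuration (``dt_start == dt_end == a*dtm``)."""
        return cls(dt_median=dt_median, dt_start=a * dt_median,
                   dt_end=a * dt_median, **kw)


class LMPController:
    """Online state machine deciding fire/hold/done per observed sample.

    Feed it the mean-potential trace as it grows; it remembers the
    last pulse time, the pulse count and the current timing scale.
    """

    def __init__(self, config: LMPConfig):
        self.config = config
        self.current_a = config.dt_start / config.dt_median
        self.t_last_p: float | None = None
        self.num_p = 0

    def decide(self, t_c: float, trace_t: np.ndarray, trace_v: np.ndarray,
               vm_max: float) -> str:
        """One Algorithm step at current time ``t_c``.

        Returns ``"fire"`` (and updates the internal state), ``"hold"``
        or ``"done"``.  ``trace_t``/``trace_v`` must contain the
        samples recorded up to and including ``t_c``.
        """
        cfg = self.config
        if vm_max < cfg.eps or self.num_p >= cfg.max_pulses:
            return "done"
        if self.t_last_p is not None and t_c - self.t_last_p <= cfg.t_pause:
            return "hold"
        window = self.current_a * cfg.dt_median
        i0 = int(np.searchsorted(trace_t, t_c - window - 1e-9))
        seg = trace_v[i0:]
        if len(seg) < 2:
            return "hold"
        d = np.diff(seg)
        rising = np.all(d > 0) if cfg.strict else np.all(d >= 0)
        if not rising:
            return "hold"
        self.t_last_p = t_c
        self.num_p += 1
        self.current_a = lmp_update_scale(
            self.current_a, cfg.b, cfg.dt_start, cfg.dt_end, cfg.dt_median
        )
        return "fire"


def lmp_decide(ctrl: LMPController, trace_t, trace_v, t_c, vm_max=np.inf):
    """Functional wrapper around :meth:`LMPController.decide`."""
    return ctrl.decide(t_c, np.asarray(trace_t), np.asarray(trace_v), vm_max)


class ScheduledStimulus:
    """Adapter feeding an open-loop schedule into the tissue integrator.

    Callable with the ``run`` stimulus signature; returns the AVE
    current field while a scheduled pulse window is open.  Onset times
    are quantized to the recording cadence by construction of the call
    times; emitted onsets are logged in ``pulse_log``.
    """

    def __init__(self, schedule: PulseSchedule, layout: AVELayout, Cm=1.0):
        self.schedule = schedule
        self.layout = layout
        self.Cm = Cm
        self.pulse_log: list[float] = []
        self._field = layout.amp_field * schedule.amplitude / Cm

    def __call__(self, t, trace_t, trace_v, vm_max):
        on = self.schedule.onsets
        active = (on <= t + 1e-9) & (t < on + self.layout.t_pulse - 1e-9)
        if active.any():
            onset = float(on[active][0])
            if not self.pulse_log or self.pulse_log[-1] != onset:
                self.pulse_log.append(onset)
            return self._field
        return None


class FeedbackStimulus:
    """Adapter running an :class:`LMPController` against live dynamics."""

    def __init__(self, controller: LMPController, layout: AVELayout,
                 A_max: float, Cm=1.0):
        self.controller = controller
        self.layout = layout
        self.A_max = A_max
        self.pulse_log: list[float] = []
        self._field = layout.amp_field * A_max / Cm
        self._pulse_until: float | None = None

    @property
    def done(self) -> bool:
        c = self.controller
        return c.num_p >= c.config.max_pulses

    def __call__(self, t, trace_t, trace_v, vm_max):
        if self._pulse_until is not None and t < self._pulse_until - 1e-9:
            return self._field
        self._pulse_until = None
        verdict = self.controller.decide(t, trace_t, trace_v, vm_max)
        if verdict == "fire":
            self.pulse_log.append(float(t))
            self._pulse_until = t + self.layout.t_pulse
            return self._field
        return None
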