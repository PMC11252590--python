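"""Study drivers: chaos initialization, termination attempts, statistics.

This module glues the simulator, the electrodes and the protocols into
the experiments the analysis needs:

- :func:`make_initial_conditions` creates independent sustained
  spiral-wave-chaos states (cross-field spiral creation, spatially
  randomized stimulation, relaxation, and a self-termination screen)
  and annotates each with its dominant frequency, phase-singularity
  count and upward-deflection statistics.
- :func:`run_attempt` performs one termination attempt with any
  protocol and evaluates success (maximum potential below threshold
  after a waiting time of five dominant periods).
- :func:`dose_response` scans pulse amplitudes to estimate success
  rates; :func:`e90` extracts the smallest amplitude with >= 90%
  success.
- :func:`timing_scan` maps E90 over the (dt_start, dt_end) timing
  plane of the feedback controller; :func:`period_histogram` analyses
  a-posteriori inter-pulse periods; :func:`coverage_sensitivity`
  repeats dose-response at reduced electrode coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import observables as obs
from .cell_models import CellModel
from .electrodes import AVELayout, TABLE_AVE, generate_layout
from .protocols import (
    FeedbackStimulus,
    LMPConfig,
    LMPController,
    ScheduledStimulus,
    adp_schedule,
    equidist_schedule,
    single_pulse_schedule,
)
from .tissue_sim import SimGrid, TissueState, run

__all__ = [
    "InitialConditionSet",
    "AttemptResult",
    "DoseResponseCurve",
    "make_initial_conditions",
    "make_fixture",
    "run_attempt",
    "dose_response",
    "e90",
    "timing_scan",
    "period_histogram",
    "coverage_sensitivity",
]

TERMINATION_THRESHOLD = 0.01


@dataclass
class InitialConditionSet:
    """Screened chaotic states of one model with their characteristics."""

    model_name: str
    states: list
    f_dom: np.ndarray          # Hz, per state
    n_ps: np.ndarray           # mean phase-singularity count, per state
    dt_median: np.ndarray      # ms, per state
    dt_up_pooled: np.ndarray   # ms, all upward deflections pooled

    @property
    def n(self) -> int:
        return len(self.states)

    @property
    def dt_median_overall(self) -> float:
        """Median upward-deflection time pooled over all states."""
        return float(np.median(self.dt_up_pooled))

    @property
    def f_dom_mean(self) -> float:
        return float(np.mean(self.f_dom))


@dataclass
class AttemptResult:
    """Outcome of one termination attempt."""

    success: bool
    pulses: list
    amplitude: float
    protocol: str
    ic_index: int = -1
    layout_seed: int = -1
    final_vm_max: float = np.nan

    @property
    def n_pulses(self) -> int:
        return len(self.pulses)


@dataclass
class DoseResponseCurve:
    """Success rate vs pulse amplitude for one (model, protocol)."""

    amplitudes: np.ndarray
    success_rate: np.ndarray
    n_attempts: int
    protocol: str
    model_name: str
    results: list = field(default_factory=list)  # AttemptResult per (amp, ic, layout)

    def results_at(self, amplitude: float) -> list:
        return [r for r in self.results if r.amplitude == amplitude]


def _s1s2_base(model: CellModel, grid: SimGrid, settle_ms: float = 1000.0,
               timeout_ms: float = 4000.0) -> TissueState:
    """One spiral via cross-field (S1-S2) stimulation.

    S1 launches a plane wave from the left edge; when its repolarizing
    back crosses the domain centre, S2 excites the lower half, leaving
    a free wave end that curls into a spiral.
    """
    st = TissueState.resting(grid, model)
    st.vm[:, :5] = 1.0
    c = grid.N // 2
    fired = False
    applied = False
    for _ in range(int(timeout_ms)):
        st, _, _ = run(st, grid, model, duration=1.0)
        vc = st.vm[c, c]
        if not fired and vc > 0.8:
            fired = True
        if fired and vc < 0.05:
            st.vm[grid.N // 2:, :] = 1.0
            applied = True
            break
    if not applied:
        raise RuntimeError(
            "S1-S2 initialization failed: S1 wave never crossed the centre; "
            "review model/grid parameters"
        )
    st, _, _ = run(st, grid, model, duration=settle_ms)
    return st


def _randomized_stimulation(state: TissueState, rng, n_spots: int,
                            radius_nodes: int) -> TissueState:
    """Depolarize ``n_spots`` random discs to break up the wave pattern."""
    st = state.copy()
    N = st.vm.shape[0]
    ii, jj = np.ogrid[:N, :N]
    for _ in range(n_spots):
        i, j = rng.integers(0, N, 2)
        st.vm[(ii - i) ** 2 + (jj - j) ** 2 <= radius_nodes ** 2] = 1.0
    return st


def _characterize(trace: obs.MeanVmTrace, snapshots, smooth_window: int = 3):
    """(f_dom, deflection stats, mean PS count) of one recording."""
    f_dom = obs.dominant_frequency(trace)
    stats = obs.deflection_stats(trace, smooth_window=smooth_window)
    stack = np.asarray([s[1] for s in snapshots])
    snap_dt = snapshots[1][0] - snapshots[0][0]
    delay = max(1, int(round(1000.0 / f_dom / 4.0 / snap_dt)))
    if len(stack) > delay:
        _, n_ps = obs.count_phase_singularities(stack, delay=delay)
    else:
        n_ps = np.nan
    return f_dom, stats, n_ps


def make_initial_conditions(
    model: CellModel,
    grid: SimGrid,
    n_states: int = 10,
    rng: np.random.Generator | None = None,
    relax_ms: float = 5000.0,
    screen_ms: float = 5000.0,
    n_spots: int = 20,
    spot_radius_nodes: int = 3,
    max_tries: int | None = None,
) -> InitialConditionSet:
    """Generate screened, annotated spiral-wave-chaos states.

    Starting from one cross-field spiral, each candidate applies
    ``n_spots`` spatially random suprathreshold stimuli, relaxes for
    ``relax_ms`` (decorrelation) and is screened for ``screen_ms``
    more; candidates that self-terminate anywhere in that window are
    rejected.  The screen recording (mean potential at 1 ms cadence,
    snapshots every 10 ms) doubles as the characterization window for
    ``f_dom``, ``N_PS`` and the upward-deflection statistics.
    """
    rng = np.random.default_rng() if rng is None else rng
    if max_tries is None:
        max_tries = 10 * n_states
    base = _s1s2_base(model, grid)
    states, fdoms, nps, dtm, pooled = [], [], [], [], []
    tries = 0
    while len(states) < n_states:
        if tries >= max_tries:
            raise RuntimeError(
                f"only {len(states)}/{n_states} sustained states after "
                f"{tries} tries; chaos not sustained at this "
                "parameterization — review model parameters"
            )
        tries += 1
        st = _randomized_stimulation(base, rng, n_spots, spot_radius_nodes)
        st, _, _ = run(st, grid, model, duration=relax_ms)
        if obs.is_terminated(st.vm, TERMINATION_THRESHOLD):
            continue
        st, (tt, vv), snaps = run(
            st, grid, model, duration=screen_ms, snapshot_every=10.0
        )
        if obs.is_terminated(st.vm, TERMINATION_THRESHOLD):
            continue
        trace = obs.MeanVmTrace(tt, vv)
        f_dom, stats, n_ps = _characterize(trace, snaps)
        states.append(st)
        fdoms.append(f_dom)
        nps.append(n_ps)
        dtm.append(stats.dt_median)
        pooled.extend(stats.dt_up.tolist())
    return InitialConditionSet(
        model_name=model.name,
        states=states,
        f_dom=np.asarray(fdoms),
        n_ps=np.asarray(nps),
        dt_median=np.asarray(dtm),
        dt_up_pooled=np.asarray(pooled),
    )


def make_fixture(model: CellModel, grid: SimGrid | None = None,
                 n_states: int = 2, rng=None, **kw) -> InitialConditionSet:
    """Miniature initial-condition set on a reduced grid for fast tests."""
    if grid is None:
        from .tissue_sim import TABLE_GRIDS

        cfg = dict(TABLE_GRIDS[model.name])
        cfg["N"] = max(100, cfg["N"] // 2)
        grid = SimGrid.from_units(N=cfg["N"], dx=cfg["dx"], dt=cfg["dt"],
                                  D_cm2_s=cfg["D_cm2_s"], Cm=cfg["Cm"])
    rng = np.random.default_rng(0) if rng is None else rng
    return make_initial_conditions(model, grid, n_states=n_states, rng=rng, **kw)


def _protocol_name(protocol) -> str:
    return protocol[0] if isinstance(protocol, tuple) else str(protocol)


def run_attempt(
    state: TissueState,
    model: CellModel,
    grid: SimGrid,
    layout: AVELayout,
    protocol,
    A_max: float,
    f_dom: float,
    dt_median: float | None = None,
    ic_index: int = -1,
    layout_seed: int = -1,
    record_every: float = 1.0,
) -> AttemptResult:
    """One termination attempt.

    ``protocol`` is one of ``("single",)``, ``("equidist", c)``,
    ``("adp",)`` or ``("lmp", LMPConfig)`` / ``("lmp",)`` (the latter
    builds the constant-scale a = 0.2 configuration from
    ``dt_median``).  Open-loop protocols observe the unperturbed
    dynamics for 5 s to estimate their pacing frequency/spectrum; the
    feedback protocol observes 2 s.  After the pacing phase the
    dynamics evolves unperturbed for five dominant periods
    (``5000/f_dom`` ms) and the attempt is successful iff the maximum
    potential is then below the termination threshold.

    ``f_dom`` [Hz] sets the success waiting time (and the EquiDist
    fallback frequency if the attempt's own observation fails to show
    a peak).
    """
    name = _protocol_name(protocol)
    st = state.copy()
    pre_ms = {"single": 0.0, "equidist": 5000.0, "adp": 5000.0, "lmp": 2000.0}[name]
    trace_t = trace_v = None
    if pre_ms > 0:
        st, (trace_t, trace_v), _ = run(st, grid, model, duration=pre_ms,
                                        record_every=record_every)

    t0 = st.t
    if name == "single":
        stim = ScheduledStimulus(single_pulse_schedule(t0, A_max), layout,
                                 Cm=grid.Cm)
        pace_ms = layout.t_pulse
    elif name == "equidist":
        c = protocol[1] if len(protocol) > 1 else 0.8
        tr = obs.MeanVmTrace(trace_t, trace_v)
        try:
            f_obs = obs.dominant_frequency(tr)
        except ValueError:
            f_obs = f_dom
        sched = equidist_schedule(f_obs, c, n_pulses=10, t0=t0, A_max=A_max)
        stim = ScheduledStimulus(sched, layout, Cm=grid.Cm)
        pace_ms = sched.onsets[-1] - t0 + layout.t_pulse
    elif name == "adp":
        tr = obs.MeanVmTrace(trace_t, trace_v)
        _, spectrum = obs.dominant_frequency(tr, return_spectrum=True)
        sched = adp_schedule(spectrum, n_pulses=10, t0=t0, A_max=A_max)
        stim = ScheduledStimulus(sched, layout, Cm=grid.Cm)
        pace_ms = sched.onsets[-1] - t0 + layout.t_pulse
    elif name == "lmp":
        if len(protocol) > 1 and isinstance(protocol[1], LMPConfig):
            cfg = protocol[1]
        else:
            if dt_median is None:
                raise ValueError("LMP needs dt_median (per-model median)")
            cfg = LMPConfig.fixed_scale(dt_median, a=0.2,
                                        eps=TERMINATION_THRESHOLD)
        ctrl = LMPController(cfg)
        stim = FeedbackStimulus(ctrl, layout, A_max, Cm=grid.Cm)
        pace_ms = (cfg.max_pulses + 2) * max(2.0 * cfg.dt_median,
                                             1000.0 / f_dom)
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    if name == "lmp":
        # chunked pacing so the attempt can stop early once the
        # controller is done or the tissue has terminated
        chunk = 100.0
        elapsed = 0.0
        tt, vv = ((trace_t, trace_v) if trace_t is not None
                  else (np.array([st.t]), np.array([st.vm.mean()])))

        def stim_with_history(t, seg_t, seg_v, vm_max):
            full_t = np.concatenate([tt[:-1], seg_t])
            full_v = np.concatenate([vv[:-1], seg_v])
            return stim(t, full_t, full_v, vm_max)

        while elapsed < pace_ms:
            st, (seg_t, seg_v), _ = run(st, grid, model, duration=chunk,
                                        stimulus=stim_with_history,
                                        record_every=record_every)
            tt = np.concatenate([tt[:-1], seg_t])
            vv = np.concatenate([vv[:-1], seg_v])
            elapsed += chunk
            if stim.done or obs.is_terminated(st.vm, TERMINATION_THRESHOLD):
                # let an in-flight pulse window close
                break
    else:
        pace_frames = max(1.0, np.ceil(pace_ms / record_every) * record_every)
        st, _, _ = run(st, grid, model, duration=pace_frames, stimulus=stim,
                       record_every=record_every)

    wait_ms = max(record_every, np.ceil(5000.0 / f_dom / record_every)
                  * record_every)
    st, _, _ = run(st, grid, model, duration=wait_ms)
    final_max = float(st.vm.max())
    return AttemptResult(
        success=bool(final_max < TERMINATION_THRESHOLD),
        pulses=list(stim.pulse_log),
        amplitude=A_max,
        protocol=name,
        ic_index=ic_index,
        layout_seed=layout_seed,
        final_vm_max=final_max,
    )


def _layout_seeds(rng: np.random.Generator, n: int) -> list[int]:
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def dose_response(
    model: CellModel,
    grid: SimGrid,
    protocol,
    amplitudes,
    ic_set: InitialConditionSet,
    n_layouts: int = 10,
    rng: np.random.Generator | None = None,
    coverage_scale: float = 1.0,
    keep_results: bool = True,
) -> DoseResponseCurve:
    """Success rate per amplitude over ICs x electrode layouts.

    Layout seeds are drawn once and shared across amplitudes (variance
    reduction: each amplitude sees the same electrode configurations).
    """
    amplitudes = np.asarray(list(amplitudes), dtype=float)
    if len(amplitudes) == 0:
        raise ValueError("need at least one amplitude")
    rng = np.random.default_rng() if rng is None else rng
    seeds = _layout_seeds(rng, n_layouts)
    ave = TABLE_AVE[model.name]
    dtm = ic_set.dt_median_overall
    rates = []
    results = []
    for amp in amplitudes:
        ok = 0
        for i, (st, fd) in enumerate(zip(ic_set.states, ic_set.f_dom)):
            for seed in seeds:
                layout = generate_layout(
                    grid, A_cov=ave["A_cov"] * coverage_scale,
                    S_ave=ave["S_ave"], rng=np.random.default_rng(seed),
                    t_pulse=ave["t_pulse"],
                )
                res = run_attempt(st, model, grid, layout, protocol, amp,
                                  f_dom=fd, dt_median=dtm, ic_index=i,
                                  layout_seed=seed)
                ok += res.success
                if keep_results:
                    results.append(res)
        rates.append(ok / (ic_set.n * n_layouts))
    return DoseResponseCurve(
        amplitudes=amplitudes,
        success_rate=np.asarray(rates),
        n_attempts=ic_set.n * n_layouts,
        protocol=_protocol_name(protocol),
        model_name=model.name,
        results=results,
    )


def e90(curve: DoseResponseCurve):
    """Smallest tested amplitude with success rate >= 0.9, else None."""
    hits = np.nonzero(curve.success_rate >= 0.9)[0]
    if len(hits) == 0:
        return None
    return float(curve.amplitudes[hits[0]])


def timing_scan(
    model: CellModel,
    grid: SimGrid,
    ic_set: InitialConditionSet,
    dt_start_grid,
    dt_end_grid,
    amplitudes,
    n_layouts: int = 10,
    rng: np.random.Generator | None = None,
):
    """E90 over the (dt_start, dt_end) timing plane of the controller.

    Grid values are delays in ms and must lie in
    ``[0.1, 1.0] * dt_median``.  Returns ``(E90 array with NaN for
    unattained cells, dt_start_grid, dt_end_grid)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    dtm = ic_set.dt_median_overall
    dt_start_grid = np.asarray(list(dt_start_grid), dtype=float)
    dt_end_grid = np.asarray(list(dt_end_grid), dtype=float)
    emap = np.full((len(dt_start_grid), len(dt_end_grid)), np.nan)
    base_seed = int(rng.integers(0, 2 ** 31 - 1))
    for i, ds in enumerate(dt_start_grid):
        for j, de in enumerate(dt_end_grid):
            cfg = LMPConfig(dt_median=dtm, dt_start=float(ds),
                            dt_end=float(de), eps=TERMINATION_THRESHOLD)
            curve = dose_response(
                model, grid, ("lmp", cfg), amplitudes, ic_set,
                n_layouts=n_layouts, rng=np.random.default_rng(base_seed),
                keep_results=False,
            )
            val = e90(curve)
            emap[i, j] = np.nan if val is None else val
    return emap, dt_start_grid, dt_end_grid


def period_histogram(results, max_pulses: int = 10):
    """A-posteriori inter-pulse periods per pulse pair.

    For each attempt, pair ``j`` is the period between pulses ``j``
    and ``j+1``.  Successful attempts that stopped early contribute a
    0 ms marker for every absent pair (early termination).  Returns a
    dict with ``periods`` (list over pairs of ndarray) and
    ``median_pulses_successful``.
    """
    pairs = [[] for _ in range(max_pulses - 1)]
    n_success_pulses = []
    for r in results:
        on = np.asarray(r.pulses, dtype=float)
        d = np.diff(on)
        for j in range(max_pulses - 1):
            if j < len(d):
                pairs[j].append(d[j])
            elif r.success:
                pairs[j].append(0.0)
        if r.success:
            n_success_pulses.append(len(on))
    med = float(np.median(n_success_pulses)) if n_success_pulses else np.nan
    return {
        "periods": [np.asarray(p) for p in pairs],
        "median_pulses_successful": med,
    }


def coverage_sensitivity(
    model: CellModel,
    grid: SimGrid,
    protocol,
    amplitudes,
    ic_set: InitialConditionSet,
    coverage_scales=(1.0, 0.8, 0.6),
    n_layouts: int = 10,
    rng: np.random.Generator | None = None,
):
    """Dose-response at reduced electrode coverage (same patch size).

    Returns ``{scale: DoseResponseCurve}``; identical layout seeds are
    used at every scale.
    """
    rng = np.random.default_rng() if rng is None else rng
    base_seed = int(rng.integers(0, 2 ** 31 - 1))
    out = {}
    for s in coverage_scales:
        out[s] = dose_response(
            model, grid, protocol, amplitudes, ic_set, n_layouts=n_layouts,
            rng=np.random.default_rng(base_seed), coverage_scale=s,
            keep_results=False,
        )
    return out
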