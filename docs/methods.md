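# Methods

## Model and discretization

The tissue is a homogeneous, isotropic 2D monodomain sheet:

    dVm/dt = D lap(Vm) - I_ion(Vm, h)/C_m + I_ext/C_m
    dh/dt  = g(Vm, h)

with no-flux boundaries.  `Vm` is dimensionless (model-native units,
roughly [0, 1]); internal units are mm and ms; diffusion coefficients
quoted in cm²/s are converted by ×0.1.  The integrator is explicit
FTCS: a 5-point Laplacian whose boundary ghost nodes replicate the
edge node (mirror across the cell face — the discretely conservative
form of the zero-normal-gradient condition) and a forward-Euler update
of `Vm`.  Gating variables with relaxation form
`dh/dt = (h_inf(V) - h)/tau(V)` are advanced with the exponential
(Rush–Larsen) update, which is exact for frozen `V` and
unconditionally stable per gate; the Aliev–Panfilov recovery variable
has no relaxation form and uses explicit Euler.  Grid construction
enforces the FTCS bound `4 D dt / dx² ≤ 1`.

Two code paths implement the same update: a transparent numpy `step`
(the reference, used by the 0D utilities and in tests) and per-model
numba kernels driven by `run` (the production path; both paths are
cross-checked to 1e-10 in the suite).  The kernels precompute the
Rush–Larsen decay factors for gates with piecewise-constant time
constants, and saturate `tanh` activation terms to ±1 beyond
|argument| > 8 (error < 3e-7) so that each model's resting state is an
exact fixed point of the discrete update.  `run` records the
spatial-mean potential every 1 ms (the controller's sampling cadence;
much finer than every upward-deflection time scale in play) and
queries the stimulus source once per recording frame, so pulse onsets
are quantized to 1 ms.  Integration is deterministic: splitting a run
into consecutive calls reproduces the final state bit for bit.

## Cell models

Four phenomenological models are shipped as YAML presets
(`lmpace/presets/`), every scalar overridable:

- **FK** (Fenton–Karma, 3 variables): fast inward, slow outward and
  slow inward currents with two gates.  The preset uses the original
  three-current model's modified-Luo–Rudy-I kinetics
  (τ_d=0.1724, τ_r=130, τ_si=127, τ_0=12.5, τ_v+=10, τ_v−=18.2,
  τ_w+=1020, τ_w−=80, u_c=0.13, u_csi=0.85, κ=10), which sustain
  spiral-wave breakup on the published 200×200, Δx=1 mm grid.
- **MSA** (Mitchell–Schaeffer, ischaemic adaptation, 1 gate): the
  preset slows depolarization and prolongs recovery relative to the
  textbook set (τ_in=0.72, τ_out=7, τ_open=100, τ_close=210,
  v_gate=0.13).
- **BOCF** (Bueno-Orovio–Cherry–Fenton minimal ventricular model,
  3 gates): epicardial parameter set.
- **AP** (Aliev–Panfilov, 1 recovery variable): breakup regime
  (K=8, a=b=0.1, ε0=0.01, μ1=0.12, μ2=0.3) with a configurable
  time scale (ms per native unit, default 1.0).

### Parameter calibration

The FK and MSA presets were calibrated against the tabulated
characteristics of the chaotic state on the published grids (dominant
frequency of the mean potential; median upward-deflection time),
since those characteristics — not raw parameters — are the
reproducible surface of the original experiments.  The calibration
outcome:

- FK: f_dom ≈ 5.7–5.9 Hz over 10-state sets (tabulated 6.28 ± 0.44)
  and pooled Δt_median ≈ 60–75 ms (tabulated 90).  Widely used
  breakup sets with dome-shaped action potentials reproduce
  Δt_median well but yield only *transient* chaos on this grid
  (self-termination within ~5 s, incompatible with the 10 s survival
  screen); sets that sustain turbulence trade away part of the rise
  time.  The shipped preset is the best sustained compromise found.
- MSA: the attainable (f_dom, Δt_median) pairs lie on a tight
  trade-off frontier under every parameter direction explored;
  matching f_dom = 3.37 exactly forces Δt_median ≈ 136–148, and
  matching Δt_median = 168 forces f_dom ≈ 3.16.  The preset matches
  the dominant frequency exactly (f_dom ≈ 3.38 Hz with inter-state
  spread < 0.01) and under-shoots the deflection median
  (≈ 136 ms).  A minority of MSA states carry two or three
  phase-staggered waves whose genuine sub-deflections shorten the
  pooled median further when they occur.
- AP and BOCF are not quantitative targets here.  The AP preset
  sustains turbulence with Δt_median ≈ 26 ms (tabulated 24) but its
  dominant frequency (~8 Hz) stays below the tabulated 22.46 Hz; the
  BOCF preset is validated by plane-wave propagation and single-cell
  behaviour only (its published 576×576 grid is outside desk scale).

Phase-singularity counts are reported for orientation only: the
detector (time-delay phase embedding, winding numbers) is our own
construction and the calibrated FK/MSA regimes carry fewer, larger
coherent structures (N_PS ~ 1–2) than the tabulated 10–15.

## Observables

- **Mean potential** V̄m: arithmetic mean over all N² nodes, sampled
  every 1 ms.
- **Dominant frequency**: peak of a Welch PSD (Hann windows,
  segment length ≤ 2048 samples) of the mean-removed trace, refined
  by parabolic interpolation of log-power across the peak's
  neighbours.  A finely resolved single periodogram is *not* used:
  chaotic mean-potential traces carry a slow amplitude envelope that
  dominates it below 1 Hz.  Requires ≥ 2 s of data.
- **Upward deflections**: on the trailing 2 s of the trace, after a
  3-sample moving average, strict local minima and maxima are
  detected with plateau handling (zero differences inherit the
  preceding slope sign, so a descent–plateau–rise counts one minimum
  at the plateau's end); each minimum is paired with the next
  maximum; Δt_up is their time difference and Δt_median its median.
  The detector is invariant under affine rescaling of the trace.
- **Termination**: max Vm < 0.01 (model-native units).
- **Phase singularities**: per-node phase
  `atan2(vm(t) − m, vm(t − delay) − m)` with `m` the node's temporal
  mean and delay ≈ a quarter dominant period; topological charge is
  the ±2π winding of the phase around each 2×2 plaquette; the count
  sums |charge|.

## Electrodes

Far-field pulses act at conductivity heterogeneities; this is
abstracted as N_ave non-overlapping square patches ("artificial
virtual electrodes") of the node-block size closest to the configured
patch area S_ave, placed uniformly at random (rejection sampling with
a retry budget) until the covered fraction matches A_cov to within
one patch.  The patch count is derived from A_cov and the realized
patch area — the tabulated (N_ave, S_ave, A_cov) triples are mutually
inconsistent under area arithmetic, and A_cov is the governing
quantity (it is the one varied in the sensitivity analysis).  Each
patch draws an amplitude fraction from U[0, 1] once per layout and
keeps it for all pulses of that attempt: the strength of a
heterogeneity is a static tissue property.  During a 2 ms pulse
window a patch injects `fraction × A_max`; elsewhere the field is
zero.

## Protocols

- **SinglePulse**: one pulse.
- **EquiDist(c)**: ten pulses at period 1/(c·f_dom), f_dom measured
  on the attempt's own 5 s pre-pacing window (c defaults to 0.8).
- **ADP**: ten pulses whose periods grow linearly from 1/f_hi to
  1/f_lo, where [f_lo, f_hi] is the half-height band around the peak
  of the 5 s pre-pacing Welch spectrum.  The upstream publication's
  exact schedule construction is not restated in our source; this
  half-height/linear-deceleration rule is our documented stand-in and
  reproduces the qualitative bundled, decelerating period pattern.
- **LMP** (local minima pacing, closed loop): at each 1 ms sample
  t_c, fire iff (i) fewer than max_pulses (10) pulses were given,
  (ii) t_c − t_last_pulse > t_pause, and (iii) every sampled
  difference of V̄m in [t_c − a·Δt_median, t_c] is ≥ 0 (configurably
  strict >; ≥ is the default).  After
  each pulse, a ← clamp(a·b, Δt_start/Δt_median, Δt_end/Δt_median)
  with b = 0.8 if Δt_start > Δt_end, 1.25 if smaller, 1 if equal.
  The baseline configuration is constant a = 0.2.  t_pause has no
  prescribed numerical value; it defaults to Δt_median, the
  typical duration of the upward deflection a pulse itself triggers,
  which fulfils its stated purpose (one pulse per deflection).
  Δt_median is the pooled per-model median over the initial-condition
  set, observed over 2 s.

## Experiments

**Initial conditions.**  One spiral is created by cross-field (S1–S2)
stimulation: a plane wave from the left edge; when its repolarizing
back crosses the domain centre (detected on the centre node), the
lower half-domain is depolarized, leaving a free wave end that curls
up.  Each candidate state then receives 20 random disc-shaped
suprathreshold stimuli (radius 3 nodes, Vm set to 1), relaxes 5 s,
and is screened 5 s more; candidates terminating anywhere in that
window are rejected.  The screen recording doubles as the
characterization window (f_dom, Δt_up statistics, N_PS).  The random
stimulation recipe has no canonical quantitative form; ours is
validated only through the resulting chaos characteristics.

**Termination attempts.**  Open-loop protocols observe 5 s of
unperturbed dynamics (their spectra are computed per attempt), the
feedback protocol 2 s.  After the pacing phase the tissue evolves
unperturbed for five dominant periods (5000/f_dom ms) and the
attempt succeeds iff max Vm < 0.01.

**Dose-response and E90.**  Success rate per amplitude over
initial conditions × electrode layouts, with layout seeds shared
across amplitudes (variance reduction).  E90 is the smallest tested
amplitude with rate ≥ 0.9, undefined if none.  Amplitude grids are
geometric ladders (no canonical amplitude grid exists), so
E90 carries the ladder's resolution.

**Scaled-down designs.**  The reference experimental design runs
10 ICs × 10 layouts per amplitude on cluster hardware.  The test suite uses a
144×144 FK fixture with D = 1.0 cm²/s (half the published value, so
that the spiral wavelength fits the reduced domain), 2–3 initial
conditions, 2–6 layouts and a 3-rung amplitude ladder; the
acceptance script uses the full published grids with 10 ICs per
model.  These sizes are the package's chosen desk-scale design
points.

## Numerical and degenerate-input choices

- Pulse onsets and all controller decisions are quantized to the 1 ms
  recording cadence.
- The ADP band walk stops at the first bin below half height; a
  single-bin band collapses to equidistant pacing.
- `deflection_stats` raises on traces with fewer than two extrema;
  `dominant_frequency` raises below 2 s of data; layout generation
  raises when the requested coverage cannot be placed.
- The blow-up guard raises naming the simulation time at which
  non-finite values appeared.
- The numba kernels use fastmath; runs are deterministic for a fixed
  seed and build, and all randomness flows from explicit
  `numpy.random.Generator` seeds (no global RNG).

## Known limitations

- 2D, isotropic, homogeneous monodomain only; no fibre orientation,
  no electromechanics, no scar or pinning heterogeneities.
- The FK/MSA presets reproduce the tabulated dominant frequencies and
  deflection medians only to the degree stated above; the exact
  parameterizations behind the tabulated values were not available.
- The phase-singularity detector and the ADP schedule construction
  are documented stand-ins for methods whose details live outside the
  study's text.
- Passing tests on synthetic chaos demonstrate the control algorithm
  and machinery, not clinical efficacy; amplitudes are in model
  units and map to no particular defibrillator energy.
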