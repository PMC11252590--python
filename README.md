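# lmpace

Low-energy defibrillation experiments in 2D excitable media:
monodomain simulation of spiral-wave chaos in four phenomenological
cardiac cell models, artificial-virtual-electrode stimulation, and a
feedback pacing protocol — **local minima pacing (LMP)** — that times
each pulse to the tissue's own recovery, together with the open-loop
protocols it is compared against.

## The problem

Ventricular fibrillation is spatiotemporal chaos of the cardiac
transmembrane potential `V_m`: many meandering spiral waves instead of
one coherent activation. Conventional defibrillation terminates every
wave with one large shock; low-energy protocols try to do the same
with sequences of small pulses. Most of them (single pulse, pacing at
a fixed fraction of the dominant frequency, decelerating pacing) fix
all pulse times *before* pacing starts. LMP instead watches a single
scalar observable — the spatial mean of the transmembrane potential,

    V̄_m(t) = (1/N²) Σ_ij V_m(i, j, t)

— and fires a pulse a short delay `a·Δt_median` after each local
*minimum* of `V̄_m`, where `Δt_median` is the median time from a local
minimum to the next maximum of the unperturbed signal and `a ≈ 0.2`.
At those moments the recovery variables are near their maxima, the
excitable fraction of the tissue is largest, and a small pulse excites
the most area. After each pulse the delay scale is updated as
`a ← clamp(a·b, Δt_start/Δt_median, Δt_end/Δt_median)`.

The tissue model is the 2D monodomain equation

    ∂t V_m = D ∇²V_m − I_ion(V_m, h)/C_m + I_ext/C_m,   ∂t h = g(V_m, h)

with no-flux boundaries, solved by explicit finite differences (FTCS)
with Rush–Larsen updates for the gating variables. Four reaction
models are included: Aliev–Panfilov (AP), Bueno-Orovio–Cherry–Fenton
(BOCF), Fenton–Karma (FK) and Mitchell–Schaeffer with an ischaemic
adaptation (MSA). Pulses act through *artificial virtual electrodes*:
randomly placed, non-overlapping patches covering a fraction `A_cov`
of the domain, each responding with its own random fraction of the
commanded amplitude `A_max` — a stand-in for field-induced
depolarization at tissue heterogeneities.

See `docs/methods.md` for the numerical scheme, parameter presets,
calibration notes and known limitations.

## Worked example

Create a chaotic state of the Fenton–Karma model on a reduced
144×144 grid, then attempt termination with LMP and with adaptive
deceleration pacing (ADP) at the same pulse amplitude:

```python
import numpy as np
from lmpace import cell_models, experiments, tissue_sim
from lmpace.electrodes import TABLE_AVE, generate_layout

model = cell_models.get_model("FK")
grid = tissue_sim.SimGrid.from_units(N=144, dx=1.0, dt=0.1, D_cm2_s=1.0)
ics = experiments.make_initial_conditions(
    model, grid, n_states=1, rng=np.random.default_rng(99))
print(f"chaos: f_dom = {ics.f_dom[0]:.2f} Hz, "
      f"dt_median = {ics.dt_median_overall:.0f} ms")

ave = TABLE_AVE["FK"]
layout = generate_layout(grid, ave["A_cov"], ave["S_ave"],
                         np.random.default_rng(5))
for protocol in (("lmp",), ("adp",)):
    r = experiments.run_attempt(
        ics.states[0], model, grid, layout, protocol, A_max=0.2,
        f_dom=float(ics.f_dom[0]), dt_median=ics.dt_median_overall)
    print(f"{protocol[0]}: success = {r.success}, pulses = {r.n_pulses}")
```

Output:

```
chaos: f_dom = 5.73 Hz, dt_median = 70 ms
lmp: success = True, pulses = 5
adp: success = False, pulses = 10
```

The feedback protocol terminated the chaos with five well-timed
pulses at an amplitude where the ten predetermined decelerating
pulses failed — the central observation this package reproduces. `dose_response`
sweeps amplitudes over initial conditions × electrode layouts to
estimate success rates, and `e90` extracts the smallest amplitude
with ≥ 90% success.

A CLI wraps the experiment drivers
(`lmpace characterize|init-states|dose-response|coverage-scan|timing-scan`,
YAML configs, CSV results).

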