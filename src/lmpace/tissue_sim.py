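"""2D monodomain tissue integrator.

Forward-time centred-space (FTCS) finite differences on an N x N
isotropic grid with no-flux boundaries:

    Vm <- Vm + dt * ( D lap(Vm) - I_ion/C_m + I_ext/C_m )

Gating variables are advanced with the Rush-Larsen exponential update
where they have relaxation form, explicit Euler otherwise.  A slow,
transparent numpy path (:func:`step`) serves as the reference
implementation; :func:`run` drives the jitted per-model kernels in
:mod:`lmpace._kernels` and records the spatial-mean potential at a
fixed cadence, querying an optional stimulus source (pre-computed
schedule or online feedback controller) between recording frames.

Internal units: mm, ms, potentials in model-native arbitrary units.
Diffusion coefficients quoted in cm^2/s (the conventional unit) are
converted with ``D[mm^2/ms] = 0.1 * D[cm^2/s]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell_models import CellModel

__all__ = [
    "SimGrid",
    "TissueState",
    "IntegrationBlowupError",
    "stability_factor",
    "laplacian_no_flux",
    "step",
    "run",
    "TABLE_GRIDS",
    "d_mm2_per_ms",
]

#: Published grid parameterizations per model: nodes per side, spacing
#: [mm], time step [ms], diffusion coefficient [cm^2/s], C_m.
TABLE_GRIDS = {
    "AP": dict(N=200, dx=0.8, dt=0.1, D_cm2_s=1.5, Cm=1.0),
    "BOCF": dict(N=576, dx=0.8, dt=0.1, D_cm2_s=2.0, Cm=1.0),
    "FK": dict(N=200, dx=1.0, dt=0.1, D_cm2_s=2.0, Cm=1.0),
    "MSA": dict(N=150, dx=0.8, dt=0.1, D_cm2_s=0.5, Cm=1.0),
}


def d_mm2_per_ms(d_cm2_per_s: float) -> float:
    """Convert a diffusion coefficient from cm^2/s to mm^2/ms."""
    return 0.1 * d_cm2_per_s


def stability_factor(D: float, dt: float, dx: float) -> float:
    """FTCS stability number ``4 D dt / dx^2`` (must be <= 1 in 2D)."""
    if dt <= 0 or dx <= 0 or D < 0:
        raise ValueError("require D >= 0, dt > 0, dx > 0")
    return 4.0 * D * dt / (dx * dx)


@dataclass(frozen=True)
class SimGrid:
    """Spatial/temporal discretization. ``D`` is stored in mm^2/ms."""

    N: int
    dx: float
    dt: float
    D: float
    Cm: float = 1.0

    def __post_init__(self):
        if self.N < 3:
            raise ValueError("N must be >= 3")
        if self.dx <= 0 or self.dt <= 0:
            raise ValueError("dx and dt must be positive")
        if self.D < 0 or self.Cm <= 0:
            raise ValueError("D must be >= 0 and Cm > 0")
        s = stability_factor(self.D, self.dt, self.dx)
        if s > 1.0:
            raise ValueError(
                f"FTCS stability violated: 4*D*dt/dx^2 = {s:.4g} > 1"
            )

    @classmethod
    def from_units(cls, N, dx, dt, D_cm2_s, Cm=1.0):
        """Build a grid from a diffusion coefficient quoted in cm^2/s."""
        return cls(N=N, dx=dx, dt=dt, D=d_mm2_per_ms(D_cm2_s), Cm=Cm)

    @classmethod
    def for_model(cls, name: str, **overrides):
        """The published grid for a model, with optional overrides."""
        cfg = dict(TABLE_GRIDS[name.upper()])
        cfg.update(overrides)
        return cls.from_units(
            N=cfg["N"], dx=cfg["dx"], dt=cfg["dt"],
            D_cm2_s=cfg["D_cm2_s"], Cm=cfg["Cm"],
        )

    @property
    def domain_area(self) -> float:
        """Domain area in mm^2."""
        return (self.N * self.dx) ** 2

    @property
    def stability(self) -> float:
        return stability_factor(self.D, self.dt, self.dx)


@dataclass
class TissueState:
    """Potential field, gate fields and the simulation clock."""

    vm: np.ndarray
    gates: tuple
    t: float = 0.0

    def copy(self) -> "TissueState":
        return TissueState(
            vm=self.vm.copy(), gates=tuple(g.copy() for g in self.gates), t=self.t
        )

    @classmethod
    def resting(cls, grid: SimGrid, model: CellModel) -> "TissueState":
        v0, g0 = model.resting_state()
        shape = (grid.N, grid.N)
        return cls(
            vm=np.full(shape, float(v0)),
            gates=tuple(np.full(shape, float(g)) for g in g0),
            t=0.0,
        )

    def validate(self, grid: SimGrid, model: CellModel):
        shape = (grid.N, grid.N)
        if self.vm.shape != shape:
            raise ValueError(f"vm shape {self.vm.shape} != {shape}")
        if len(self.gates) != model.k:
            raise ValueError(f"expected {model.k} gate fields, got {len(self.gates)}")
        for g in self.gates:
            if g.shape != shape:
                raise ValueError("gate field shape mismatch")


class IntegrationBlowupError(RuntimeError):
    """Non-finite values appeared during integration."""

    def __init__(self, t):
        self.t = t
        super().__init__(f"integration blew up (non-finite values) at t = {t:.3f} ms")


def laplacian_no_flux(u: np.ndarray, dx: float) -> np.ndarray:
    """5-point Laplacian with zero-normal-gradient (edge-mirror) boundaries.

    The boundary ghost node replicates the edge node (mirror across the
    cell face), which makes the discrete operator conservative: the sum
    of the result over all nodes vanishes for any field.
    """
    if u.shape[0] < 3 or u.shape[1] < 3:
        raise ValueError("grid must be at least 3x3")
    p = np.pad(u, 1, mode="edge")
    return (
        p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:] - 4.0 * u
    ) / (dx * dx)


def step(
    state: TissueState,
    grid: SimGrid,
    model: CellModel,
    ext_current=None,
) -> TissueState:
    """One FTCS step (reference numpy path); returns a new state.

    ``ext_current`` is an N x N field (or None) added as
    ``ext_current/Cm`` to dVm/dt.
    """
    state.validate(grid, model)
    vm, gates = state.vm, state.gates
    rate = model.ionic_current(vm, gates)
    lap = laplacian_no_flux(vm, grid.dx)
    new_vm = vm + grid.dt * (grid.D * lap + rate)
    if ext_current is not None:
        if ext_current.shape != vm.shape:
            raise ValueError("ext_current shape mismatch")
        new_vm = new_vm + grid.dt * ext_current / grid.Cm
    new_gates = model.step_gates(vm, gates, grid.dt)
    if not np.all(np.isfinite(new_vm)):
        raise IntegrationBlowupError(state.t + grid.dt)
    return TissueState(vm=new_vm, gates=tuple(np.asarray(g) for g in new_gates),
                       t=state.t + grid.dt)


def run(
    state: TissueState,
    grid: SimGrid,
    model: CellModel,
    duration: float,
    stimulus=None,
    record_every: float = 1.0,
    snapshot_every: float | None = None,
):
    """Advance ``duration`` ms with the jitted kernel, recording V-bar_m.

    Parameters
    ----------
    stimulus : callable or None
        Called once per recording frame as
        ``stimulus(t_ms, trace_t, trace_v, vm_max) -> ndarray | None``
        where ``trace_t``/``trace_v`` are the mean-potential samples
        recorded so far (including the sample at ``t_ms``) and
        ``vm_max`` is the current maximum of the potential field.  The
        returned N x N field (units of A/C_m, i.e. 1/ms) is applied
        during the coming frame.  Pulse bookkeeping lives inside the
        stimulus object.
    record_every : float
        Recording cadence in ms; must be an integer multiple of dt.
    snapshot_every : float or None
        If set, store a copy of the potential field every so many ms.

    Returns
    -------
    state : TissueState (new object; input not modified)
    trace : (t, value) pair of ndarrays, the mean-potential samples
    snapshots : list of (t, vm copy), empty unless requested

    The chunked integration is deterministic: splitting one call into
    consecutive shorter calls with the same cadence reproduces the
    final state bit for bit.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    state.validate(grid, model)
    nsub = int(round(record_every / grid.dt))
    if abs(nsub * grid.dt - record_every) > 1e-9 or nsub < 1:
        raise ValueError("record_every must be a positive multiple of dt")
    nframes = int(round(duration / record_every))
    if abs(nframes * record_every - duration) > 1e-6:
        raise ValueError("duration must be a multiple of record_every")
    snap_stride = None
    if snapshot_every is not None:
        snap_stride = max(1, int(round(snapshot_every / record_every)))

    kernel = model.kernel()
    p = model.kernel_params(grid.dt)
    dfac = grid.D * grid.dt / (grid.dx * grid.dx)

    vm = np.ascontiguousarray(state.vm, dtype=np.float64).copy()
    gates = [np.ascontiguousarray(g, dtype=np.float64).copy() for g in state.gates]
    dummy = np.zeros((1, 1))
    g1 = gates[0] if model.k >= 1 else dummy
    g2 = gates[1] if model.k >= 2 else dummy
    g3 = gates[2] if model.k >= 3 else dummy
    buf = np.empty_like(vm)

    times = np.empty(nframes + 1)
    values = np.empty(nframes + 1)
    snapshots = []
    t0 = state.t
    for f in range(nframes + 1):
        t = t0 + f * record_every
        times[f] = t
        values[f] = vm.mean()
        if not np.isfinite(values[f]):
            raise IntegrationBlowupError(t)
        if snap_stride is not None and f % snap_stride == 0:
            snapshots.append((t, vm.copy()))
        if f == nframes:
            break
        ext = None
        if stimulus is not None:
            ext = stimulus(t, times[: f + 1], values[: f + 1], float(vm.max()))
        if ext is None:
            ext = _ZERO_CACHE.setdefault(vm.shape, np.zeros_like(vm))
        kernel(vm, g1, g2, g3, buf, ext, nsub, grid.dt, dfac, p)

    out = TissueState(vm=vm, gates=tuple(gates[: model.k]), t=t0 + duration)
    return out, (times, values), snapshots


_ZERO_CACHE: dict = {}
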