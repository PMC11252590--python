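"""Phenomenological cardiac cell models.

Four two-to-four-variable reaction models of cardiac action-potential
dynamics, each exposing the reaction term of the monodomain equation

    dVm/dt = div(D grad Vm) - I_ion(Vm, h)/C_m,      dh/dt = g(Vm, h),

where ``Vm`` is the (dimensionless) transmembrane potential and
``h = (h_1, ..., h_k)`` are gating variables.  The models are:

``AP``
    Aliev-Panfilov two-variable model; the recovery variable is not a
    voltage-gated relaxation variable and is integrated with explicit
    Euler.  Native time is dimensionless; a ``time_scale`` parameter
    (ms per native time unit) converts all rates to 1/ms.
``FK``
    Fenton-Karma three-variable model (fast inward, slow outward, slow
    inward currents; two gates) in a spiral-breakup parameterization.
``BOCF``
    Bueno-Orovio-Cherry-Fenton minimal ventricular model, epicardial
    parameter set (three gates).
``MSA``
    Mitchell-Schaeffer two-current model with a shortened closing time
    constant emulating ischaemic tissue (one gate).

All rates returned by model methods are per millisecond.  Gating
variables with relaxation form ``dh/dt = (h_inf(V) - h)/tau(V)`` are
advertised as such so that the integrator can apply the exponential
(Rush-Larsen) update; other recovery variables are advanced with
explicit Euler.

Parameter presets live in ``lmpace/presets/<model>.yaml``; every scalar
can be overridden at construction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "CellModel",
    "get_model",
    "MODEL_NAMES",
    "ionic_current",
    "gate_dynamics",
    "resting_state",
    "simulate_single_cell",
]

MODEL_NAMES = ("AP", "BOCF", "FK", "MSA")


def _tanh_sat(x):
    """tanh saturated to +/-1 beyond |x| > 8 (error < 3e-7).

    Keeps model resting states exact fixed points of the discrete
    update; matches the jitted tissue kernels.
    """
    x = np.asarray(x, dtype=float)
    return np.where(
        x > 8.0, 1.0, np.where(x < -8.0, -1.0, np.tanh(np.clip(x, -8.0, 8.0)))
    )


def _load_preset(name: str) -> dict:
    ref = resources.files("lmpace") / "presets" / f"{name.lower()}.yaml"
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


@dataclass
class CellModel:
    """Base class: one reaction model with a named parameter table.

    Attributes
    ----------
    name : str
        One of ``AP``, ``BOCF``, ``FK``, ``MSA``.
    k : int
        Number of gating/recovery variables.
    params : dict
        Scalar parameter table (preset merged with overrides).
    gate_names : tuple of str
    rl_gates : tuple of bool
        Per gate, whether it has the relaxation form usable by the
        Rush-Larsen exponential update.
    """

    name: str = ""
    k: int = 0
    params: dict = field(default_factory=dict)
    gate_names: tuple = ()
    rl_gates: tuple = ()

    # -- interface -----------------------------------------------------
    def ionic_current(self, vm, gates):
        """Reaction contribution ``-I_ion/C_m`` to dVm/dt, in 1/ms."""
        raise NotImplementedError

    def gate_dynamics(self, vm, gates):
        """Per-gate update description.

        Returns a list with one entry per gating variable, either
        ``("rl", h_inf, tau)`` for relaxation gates or
        ``("euler", dh_dt)`` for plain-derivative variables.
        """
        raise NotImplementedError

    def resting_state(self):
        """Stable resting point ``(vm, gates)`` of the 0D model."""
        raise NotImplementedError

    # -- shared machinery ----------------------------------------------
    def _check_gates(self, gates):
        if len(gates) != self.k:
            raise ValueError(
                f"{self.name} expects {self.k} gating variables, got {len(gates)}"
            )

    def step_gates(self, vm, gates, dt, method="rl"):
        """Advance the gating variables by one step of length ``dt`` ms.

        ``method="rl"`` uses the exponential update for relaxation
        gates and explicit Euler otherwise; ``method="euler"`` forces
        explicit Euler for every variable.
        """
        self._check_gates(gates)
        out = []
        for spec, g in zip(self.gate_dynamics(vm, gates), gates):
            if spec[0] == "rl":
                _, hinf, tau = spec
                if method == "rl":
                    out.append(hinf + (g - hinf) * np.exp(-dt / tau))
                else:
                    out.append(g + dt * (hinf - g) / tau)
            else:
                out.append(g + dt * spec[1])
        return tuple(out)

    def kernel(self):
        """(jitted chunk function, packed parameter vector factory).

        Returns the numba tissue kernel for this model; see
        :mod:`lmpace._kernels`.
        """
        from . import _kernels

        return _kernels.KERNELS[self.name]

    def kernel_params(self, dt):
        """Packed float64 parameter vector consumed by the jitted kernel."""
        from . import _kernels

        return _kernels.PACKERS[self.name](self.params, dt)


class AlievPanfilov(CellModel):
    """Aliev-Panfilov model: cubic excitation plus one recovery variable.

    du/dt = -K u (u - a)(u - 1) - u v
    dv/dt = (eps0 + mu1 v / (u + mu2)) * (-v - K u (u - b - 1))

    Native time is dimensionless; rates are divided by ``time_scale``
    (ms per time unit) so the tissue integrator can work in ms.
    """

    def __init__(self, params):
        super().__init__(
            name="AP", k=1, params=params, gate_names=("v",), rl_gates=(False,)
        )

    def ionic_current(self, vm, gates):
        self._check_gates(gates)
        p = self.params
        v = gates[0]
        rate = -p["K"] * vm * (vm - p["a"]) * (vm - 1.0) - vm * v
        return rate / p["time_scale"]

    def gate_dynamics(self, vm, gates):
        self._check_gates(gates)
        p = self.params
        v = gates[0]
        eps = p["eps0"] + p["mu1"] * v / (vm + p["mu2"])
        dv = eps * (-v - p["K"] * vm * (vm - p["b"] - 1.0))
        return [("euler", dv / p["time_scale"])]

    def resting_state(self):
        return 0.0, (0.0,)


class FentonKarma(CellModel):
    """Fenton-Karma three-current model; gates ``(v, w)``.

    J_fi = -v H(u - u_c)(1 - u)(u - u_c)/tau_d        (fast inward)
    J_so =  u H(u_c - u)/tau_0 + H(u - u_c)/tau_r     (slow outward)
    J_si = -w (1 + tanh(kappa (u - u_csi)))/(2 tau_si)  (slow inward)

    Both gates relax piecewise-exponentially and are advanced with the
    Rush-Larsen update.
    """

    def __init__(self, params):
        super().__init__(
            name="FK", k=2, params=params, gate_names=("v", "w"),
            rl_gates=(True, True),
        )

    def ionic_current(self, vm, gates):
        self._check_gates(gates)
        p = self.params
        v, w = gates
        u = np.asarray(vm, dtype=float)
        exc = u >= p["u_c"]
        j_fi = np.where(exc, -v * (1.0 - u) * (u - p["u_c"]) / p["tau_d"], 0.0)
        j_so = np.where(exc, 1.0 / p["tau_r"], u / p["tau_0"])
        j_si = -w * (1.0 + _tanh_sat(p["kappa"] * (u - p["u_csi"]))) / (2.0 * p["tau_si"])
        return -(j_fi + j_so + j_si)

    def gate_dynamics(self, vm, gates):
        self._check_gates(gates)
        p = self.params
        u = np.asarray(vm, dtype=float)
        exc = u >= p["u_c"]
        tau_vm = np.where(u >= p["u_v"], p["tau_v1m"], p["tau_v2m"])
        v_inf = np.where(exc, 0.0, 1.0)
        tau_v = np.where(exc, p["tau_vp"], tau_vm)
        w_inf = np.where(exc, 0.0, 1.0)
        tau_w = np.where(exc, p["tau_wp"], p["tau_wm"])
        return [("rl", v_inf, tau_v), ("rl", w_inf, tau_w)]

    def resting_state(self):
        return 0.0, (1.0, 1.0)


class BuenoOrovio(CellModel):
    """Bueno-Orovio-Cherry-Fenton minimal model, gates ``(v, w, s)``."""

    def __init__(self, params):
        super().__init__(
            name="BOCF", k=3, params=params, gate_names=("v", "w", "s"),
            rl_gates=(True, True, True),
        )

    def _currents(self, u, v, w, s):
        p = self.params
        hv = u >= p["theta_v"]
        hw = u >= p["theta_w"]
        ho = u >= p["theta_o"]
        tau_o = np.where(ho, p["tau_o2"], p["tau_o1"])
        tau_so = p["tau_so1"] + (p["tau_so2"] - p["tau_so1"]) * (
            1.0 + _tanh_sat(p["k_so"] * (u - p["u_so"]))
        ) / 2.0
        j_fi = np.where(
            hv, -v * (u - p["theta_v"]) * (p["u_u"] - u) / p["tau_fi"], 0.0
        )
        j_so = np.where(hw, 1.0 / tau_so, (u - p["u_o"]) / tau_o)
        j_si = np.where(hw, -w * s / p["tau_si"], 0.0)
        return j_fi, j_so, j_si

    def ionic_current(self, vm, gates):
        self._check_gates(gates)
        u = np.asarray(vm, dtype=float)
        j_fi, j_so, j_si = self._currents(u, *gates)
        return -(j_fi + j_so + j_si)

    def gate_dynamics(self, vm, gates):
        self._check_gates(gates)
        p = self.params
        u = np.asarray(vm, dtype=float)
        v, w, s = gates
        hv = u >= p["theta_v"]
        hw = u >= p["theta_w"]
        ho = u >= p["theta_o"]
        v_inf = np.where(u < p["theta_vm"], 1.0, 0.0)
        tau_vm = np.where(u < p["theta_vm"], p["tau_v1m"], p["tau_v2m"])
        tau_v = np.where(hv, p["tau_vp"], tau_vm)
        v_target = np.where(hv, 0.0, v_inf)
        w_inf = np.where(ho, p["w_inf_star"], 1.0 - u / p["tau_winf"])
        tau_wm = p["tau_w1m"] + (p["tau_w2m"] - p["tau_w1m"]) * (
            1.0 + _tanh_sat(p["k_wm"] * (u - p["u_wm"]))
        ) / 2.0
        tau_w = np.where(hw, p["tau_wp"], tau_wm)
        w_target = np.where(hw, 0.0, w_inf)
        s_inf = (1.0 + _tanh_sat(p["k_s"] * (u - p["u_s"]))) / 2.0
        tau_s = np.where(hw, p["tau_s2"], p["tau_s1"])
        return [
            ("rl", v_target, tau_v),
            ("rl", w_target, tau_w),
            ("rl", s_inf, tau_s),
        ]

    def resting_state(self):
        p = self.params
        s0 = (1.0 + _tanh_sat(p["k_s"] * (0.0 - p["u_s"]))) / 2.0
        return 0.0, (1.0, 1.0, float(s0))


class MitchellSchaeffer(CellModel):
    """Mitchell-Schaeffer two-current model, one gate ``h``.

    du/dt = h u^2 (1 - u)/tau_in - u/tau_out
    dh/dt = (1 - h)/tau_open  if u < v_gate  else  -h/tau_close
    """

    def __init__(self, params):
        super().__init__(
            name="MSA", k=1, params=params, gate_names=("h",), rl_gates=(True,)
        )

    def ionic_current(self, vm, gates):
        self._check_gates(gates)
        p = self.params
        u = np.asarray(vm, dtype=float)
        h = gates[0]
        return h * u * u * (1.0 - u) / p["tau_in"] - u / p["tau_out"]

    def gate_dynamics(self, vm, gates):
        self._check_gates(gates)
        p = self.params
        u = np.asarray(vm, dtype=float)
        below = u < p["v_gate"]
        h_inf = np.where(below, 1.0, 0.0)
        tau = np.where(below, p["tau_open"], p["tau_close"])
        return [("rl", h_inf, tau)]

    def resting_state(self):
        return 0.0, (1.0,)


_CLASSES = {
    "AP": AlievPanfilov,
    "FK": FentonKarma,
    "BOCF": BuenoOrovio,
    "MSA": MitchellSchaeffer,
}


def get_model(name: str, **overrides) -> CellModel:
    """Build a cell model from its named preset, with scalar overrides."""
    name = name.upper()
    if name not in _CLASSES:
        raise ValueError(f"unknown model {name!r}; choose from {MODEL_NAMES}")
    params = _load_preset(name)
    unknown = set(overrides) - set(params)
    if unknown:
        raise ValueError(f"unknown parameter overrides for {name}: {sorted(unknown)}")
    params.update(overrides)
    return _CLASSES[name](params)


# -- functional wrappers (convenience mirrors of the methods) ----------

def ionic_current(model: CellModel, vm, gates):
    """``-I_ion/C_m`` reaction rate at a node (1/ms); pure function."""
    return model.ionic_current(vm, gates)


def gate_dynamics(model: CellModel, vm, gates):
    return model.gate_dynamics(vm, gates)


def resting_state(model: CellModel):
    return model.resting_state()


def simulate_single_cell(
    model: CellModel,
    stim=None,
    total_time: float = 500.0,
    dt: float = 0.1,
    method: str = "rl",
):
    """Integrate the 0D (space-clamped) model.

    Parameters
    ----------
    stim : tuple or None
        ``(onset_ms, duration_ms, amplitude)`` square current pulse
        added to dVm/dt, or None for an unstimulated run.
    method : str
        ``"rl"`` (Rush-Larsen for relaxation gates) or ``"euler"``.

    Returns
    -------
    t : (n,) ndarray of ms
    vm : (n,) ndarray
    gates : (n, k) ndarray
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(total_time / dt)) + 1
    t = np.arange(n) * dt
    vm = np.empty(n)
    gates = np.empty((n, model.k))
    v0, g0 = model.resting_state()
    vm[0] = v0
    gates[0] = g0
    g = tuple(float(x) for x in g0)
    v = float(v0)
    for i in range(1, n):
        tc = t[i - 1]
        ext = 0.0
        if stim is not None:
            onset, dur, amp = stim
            if onset <= tc < onset + dur:
                ext = amp
        dv = model.ionic_current(v, g) + ext
        g = model.step_gates(v, g, dt, method=method)
        v = v + dt * float(dv)
        vm[i] = v
        gates[i] = g
    return t, vm, gates
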