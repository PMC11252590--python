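"""Artificial virtual electrodes (AVEs).

Far-field defibrillation pulses depolarize cardiac tissue at
conductivity heterogeneities (blood vessels, intercellular coupling
discontinuities, curved boundaries).  This module abstracts that
mechanism as a set of small, non-overlapping current-injection patches
("artificial virtual electrodes") placed uniformly at random so that a
fraction ``A_cov`` of the domain is covered.  Each patch responds to a
pulse command of global amplitude ``A_max`` with its own fixed
fraction of the amplitude, drawn once per layout from U[0, 1] — small
heterogeneities depolarize only at high field strengths, and which
heterogeneity is strong is a static property of the tissue.

A layout converts a pulse command into an N x N current field: during
a pulse window of length ``t_pulse`` every node of patch ``i`` carries
``amp_fraction[i] * A_max`` and all other nodes zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tissue_sim import SimGrid

__all__ = ["AVELayout", "generate_layout", "stimulus_current"]

#: Published AVE parameters per model: patch area S_ave [mm^2],
#: covered fraction A_cov, pulse length t_pulse [ms].
TABLE_AVE = {
    "AP": dict(S_ave=0.5, A_cov=0.30, t_pulse=2.0),
    "BOCF": dict(S_ave=0.8, A_cov=0.20, t_pulse=2.0),
    "FK": dict(S_ave=2.0, A_cov=0.25, t_pulse=2.0),
    "MSA": dict(S_ave=0.8, A_cov=0.30, t_pulse=2.0),
}


@dataclass
class AVELayout:
    """Non-overlapping square stimulation patches on the node grid.

    ``patches`` holds ``(i0, j0)`` upper-left corners; every patch is
    ``side`` x ``side`` nodes.  ``amp_field`` is the precomputed N x N
    field of per-node amplitude fractions (zero off-patch).
    """

    N: int
    side: int
    patches: np.ndarray          # (n_ave, 2) int corners
    amp_fraction: np.ndarray     # (n_ave,) in [0, 1]
    A_cov: float                 # requested coverage fraction
    t_pulse: float               # ms
    dx: float                    # mm

    def __post_init__(self):
        amp = np.zeros((self.N, self.N))
        s = self.side
        for (i0, j0), a in zip(self.patches, self.amp_fraction):
            amp[i0:i0 + s, j0:j0 + s] = a
        self.amp_field = amp

    @property
    def n_ave(self) -> int:
        return len(self.patches)

    @property
    def patch_area(self) -> float:
        """Realized area of one patch [mm^2]."""
        return (self.side * self.dx) ** 2

    @property
    def realized_coverage(self) -> float:
        return self.n_ave * self.side ** 2 / self.N ** 2

    def covered_mask(self) -> np.ndarray:
        return self.amp_field > 0


def generate_layout(
    grid: SimGrid,
    A_cov: float,
    S_ave: float,
    rng: np.random.Generator,
    t_pulse: float = 2.0,
    max_tries: int = 200,
) -> AVELayout:
    """Place disjoint square patches covering ``A_cov`` of the domain.

    The patch side is the node count whose square area is closest to
    ``S_ave`` (at least one node); the patch count is chosen so the
    realized coverage matches ``A_cov`` to within one patch.  Patches
    are placed by rejection sampling of uniformly random corners; if a
    patch cannot be placed within ``max_tries * n_ave`` attempts the
    requested coverage is infeasible and an error is raised.

    Amplitude fractions are drawn once per layout from U[0, 1].
    """
    if not 0.0 < A_cov < 1.0:
        raise ValueError("A_cov must be in (0, 1)")
    node_area = grid.dx ** 2
    if S_ave < node_area:
        raise ValueError("S_ave must be at least one node's area")
    # node-block size closest to S_ave
    side = max(1, int(round(np.sqrt(S_ave) / grid.dx)))
    if abs((side + 1) ** 2 * node_area - S_ave) < abs(side ** 2 * node_area - S_ave):
        side += 1
    if side > grid.N:
        raise ValueError("S_ave larger than the domain")
    n_ave = int(np.ceil(A_cov * grid.N ** 2 / side ** 2))
    occupied = np.zeros((grid.N, grid.N), dtype=bool)
    corners = np.empty((n_ave, 2), dtype=np.int64)
    budget = max_tries * n_ave
    placed = 0
    hi = grid.N - side + 1
    while placed < n_ave:
        if budget <= 0:
            raise RuntimeError(
                f"could not place {n_ave} patches of side {side} at "
                f"coverage {A_cov:.2f}; coverage too high for patch size"
            )
        i0, j0 = rng.integers(0, hi, size=2)
        budget -= 1
        if occupied[i0:i0 + side, j0:j0 + side].any():
            continue
        occupied[i0:i0 + side, j0:j0 + side] = True
        corners[placed] = (i0, j0)
        placed += 1
    amp = rng.uniform(0.0, 1.0, size=n_ave)
    return AVELayout(
        N=grid.N, side=side, patches=corners, amp_fraction=amp,
        A_cov=A_cov, t_pulse=t_pulse, dx=grid.dx,
    )


def layout_for_model(model_name: str, grid: SimGrid, rng,
                     coverage_scale: float = 1.0) -> AVELayout:
    """Published AVE layout for a model, optionally scaling coverage.

    ``coverage_scale`` multiplies A_cov with the patch size held fixed
    (fewer electrodes, same electrode size).
    """
    cfg = TABLE_AVE[model_name.upper()]
    return generate_layout(
        grid, A_cov=cfg["A_cov"] * coverage_scale, S_ave=cfg["S_ave"],
        rng=rng, t_pulse=cfg["t_pulse"],
    )


def stimulus_current(layout: AVELayout, A_max: float, pulse_onset: float,
                     t: float) -> np.ndarray:
    """Current field at time ``t`` for a pulse starting at ``pulse_onset``.

    Returns ``amp_fraction_i * A_max`` on patch nodes while
    ``pulse_onset <= t < pulse_onset + t_pulse``, zero otherwise.
    """
    if pulse_onset <= t < pulse_onset + layout.t_pulse:
        return layout.amp_field * A_max
    return np.zeros((layout.N, layout.N))
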