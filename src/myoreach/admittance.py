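"""First-order admittance (mass-damper) cursor dynamics.

The controller output, multiplied by a 1 N conversion gain, acts as a force on
a virtual mass-damper per axis: ``A v' + B v = F``, i.e. the transfer function
from force to velocity is ``1/(A s + B)``.  ``A`` is the virtual inertia and
``B`` the virtual damping; their ratio ``A/B`` is the velocity time constant
and ``1/B`` the terminal speed per newton.

Study presets: healthy ``A = 6.6e-4, B = 4e-4`` (time constant 1.65 s) and a
DMD-personalised ``A = 5e-4, B = 6e-4`` (lower inertia, higher damping, time
constant ~0.83 s).  These raw values imply enormous speeds in the normalised
[-1, 1]^2 workspace (1/B = 2500 units/s), because the original screen units
are unspecified; :func:`scale_to_max_speed` rescales both parameters by the
same factor, preserving the time constant exactly while pinning the terminal
speed at full effort to a configured value (default 2 workspace units/s).

The step update is the exact zero-order-hold discretisation, so trajectories
are independent of the integration step for piecewise-constant force.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

FORCE_GAIN_N = 1.0
DEFAULT_MAX_SPEED = 2.0  # workspace units/s at |F| = 1 N, after rescaling
WORKSPACE_HALF = 1.0


@dataclass(frozen=True)
class AdmittanceParams:
    """Virtual inertia A and damping B (force·s²/unit, force·s/unit)."""

    A: float
    B: float

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B <= 0:
            raise ValueError("A and B must be positive")

    @property
    def time_constant(self) -> float:
        return self.A / self.B

    @property
    def terminal_speed(self) -> float:
        """Steady-state velocity per unit force, 1/B."""
        return 1.0 / self.B


HEALTHY = AdmittanceParams(A=6.6e-4, B=4e-4)
DMD = AdmittanceParams(A=5e-4, B=6e-4)
PRESETS = {"healthy": HEALTHY, "dmd": DMD}


def get_params(name: str) -> AdmittanceParams:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown admittance preset '{name}'") from None


@dataclass
class CursorState:
    """Cursor position/velocity in normalised workspace units, plus time."""

    pos: np.ndarray
    vel: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.vel = np.asarray(self.vel, dtype=float)

    @classmethod
    def origin(cls) -> "CursorState":
        return cls(pos=np.zeros(2), vel=np.zeros(2), t=0.0)


def force_from_control(u: np.ndarray) -> np.ndarray:
    """Controller output -> estimated force, via the 1 N conversion gain."""
    u = np.asarray(u, dtype=float)
    if np.any(np.abs(u) > 1.0 + 1e-12):
        raise ValueError("control output must lie in [-1, 1] per axis")
    return FORCE_GAIN_N * u


def velocity_scale(p: AdmittanceParams, gain_to_workspace: float) -> AdmittanceParams:
    """Rescale A and B by 1/gain so velocities scale by ``gain_to_workspace``.

    The time constant A/B is untouched — it is the behaviourally meaningful
    quantity — while the terminal speed becomes ``gain / B``.
    """
    if gain_to_workspace <= 0:
        raise ValueError("gain_to_workspace must be positive")
    return AdmittanceParams(A=p.A / gain_to_workspace, B=p.B / gain_to_workspace)


def scale_to_max_speed(
    p: AdmittanceParams, max_speed: float = DEFAULT_MAX_SPEED
) -> AdmittanceParams:
    """Rescale so that full effort (|F| = 1 N) yields ``max_speed`` units/s."""
    return velocity_scale(p, max_speed * p.B)


def admittance_step(
    state: CursorState,
    force: np.ndarray,
    p: AdmittanceParams,
    dt: float,
    clamp: bool = True,
) -> CursorState:
    """Advance the cursor one step under constant force (exact ZOH).

    Per axis, with k = B/A:

        v(dt) = v0 e^{-k dt} + (F/B) (1 - e^{-k dt})
        x(dt) = x0 + (F/B) dt + (v0 - F/B) (A/B) (1 - e^{-k dt})

    Positions are clamped to the [-1, 1]^2 workspace; on contact the velocity
    component into the wall is zeroed (the screen edge is rigid).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    force = np.asarray(force, dtype=float)
    if not np.all(np.isfinite(force)):
        raise ValueError("force must be finite")
    v_ss = force / p.B
    decay = np.exp(-(p.B / p.A) * dt)
    vel = v_ss + (state.vel - v_ss) * decay
    pos = state.pos + v_ss * dt + (state.vel - v_ss) * p.time_constant * (1.0 - decay)
    if clamp:
        hit = np.abs(pos) > WORKSPACE_HALF
        pos = np.clip(pos, -WORKSPACE_HALF, WORKSPACE_HALF)
        vel = np.where(hit, 0.0, vel)
    return CursorState(pos=pos, vel=vel, t=state.t + dt)
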