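"""Direct (antagonist-pair proportional) myocontrol with DOF mode switching.

One flexor/extensor muscle pair drives one cursor axis at a time.  Each
channel's voluntary envelope is normalised to its MVC level, the flexor signal
is subtracted from the extensor signal, and the signed result moves the cursor
along the currently active axis.  Switching between axes is a discrete event:
co-contraction of the pair (healthy users) or a burst on a dedicated trigger
channel (users who cannot co-contract without fatigue, e.g. with advanced
Duchenne muscular dystrophy).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mapping import MotionMapping
from .processing import CalibrationProfile


@dataclass
class DcConfig:
    """Direct-control parameters.

    The co-contraction threshold and refractory interval have no prescribed
    values — in practice they are tuned per user to a comfortable level; the
    defaults here let the simulated user switch reliably without false
    positives from ordinary reaching movements.
    """

    mapping: MotionMapping
    cocontraction_threshold: float = 0.45  # fraction of MVC, on min(U_e, U_f)
    switch_refractory_s: float = 0.5
    trigger_threshold: float = 0.30  # fraction of trigger-channel MVC
    deadband: float = 0.02  # fraction of MVC, on |U|
    switch_source: str = "cocontraction"  # or "trigger"
    extensor_role: str = "ecu"
    flexor_role: str = "fcu"

    def __post_init__(self) -> None:
        if not 0.0 < self.cocontraction_threshold < 1.0:
            raise ValueError("cocontraction_threshold must lie in (0, 1)")
        if self.switch_refractory_s <= 0:
            raise ValueError("switch_refractory_s must be positive")
        if not 0.0 <= self.deadband <= 0.2:
            raise ValueError("deadband must lie in [0, 0.2]")
        if self.switch_source not in ("cocontraction", "trigger"):
            raise ValueError("switch_source must be 'cocontraction' or 'trigger'")


@dataclass
class DcState:
    """Mode-switch memory: which axis is live, and when it last toggled."""

    active_axis: int = 0  # 0 = x, 1 = y
    last_switch_time: float = -np.inf


def normalized_activation(env: float, rest: float, mvc: float) -> float:
    """Single-channel voluntary activation in [0, 1]: (env - rest)/mvc."""
    if mvc - rest <= 0:
        raise ValueError("invalid calibration: MVC does not exceed rest")
    return float(np.clip((env - rest) / mvc, 0.0, 1.0))


def dc_signal(
    env_e: float, env_f: float, calib: CalibrationProfile, cfg: DcConfig
) -> float:
    """Signed control signal U = U_e - U_f in [-1, 1].

    ``env_e``/``env_f`` are the current extensor/flexor envelope samples in
    mV.  Values inside the deadband return exactly 0 so that rest-level noise
    cannot drift the cursor.
    """
    rest_e, mvc_e = calib.for_role(cfg.extensor_role)
    rest_f, mvc_f = calib.for_role(cfg.flexor_role)
    u = normalized_activation(env_e, rest_e, mvc_e) - normalized_activation(
        env_f, rest_f, mvc_f
    )
    if abs(u) < cfg.deadband:
        return 0.0
    return u


def activation_pair(
    env_e: float, env_f: float, calib: CalibrationProfile, cfg: DcConfig
) -> tuple[float, float]:
    """(U_e, U_f) normalised activations, for switch detection."""
    rest_e, mvc_e = calib.for_role(cfg.extensor_role)
    rest_f, mvc_f = calib.for_role(cfg.flexor_role)
    return (
        normalized_activation(env_e, rest_e, mvc_e),
        normalized_activation(env_f, rest_f, mvc_f),
    )


def switch_condition(
    u_e: float,
    u_f: float,
    trigger_env_norm: float | None,
    cfg: DcConfig,
) -> bool:
    """Is the switch gesture currently being performed?"""
    if cfg.switch_source == "cocontraction":
        return min(u_e, u_f) >= cfg.cocontraction_threshold
    if trigger_env_norm is None:
        raise ValueError("trigger switch source configured but no trigger channel")
    return trigger_env_norm >= cfg.trigger_threshold


def detect_switch(
    u_e: float,
    u_f: float,
    trigger_env_norm: float | None,
    t: float,
    cfg: DcConfig,
    state: DcState,
) -> tuple[DcState, bool]:
    """Advance the mode-switch state machine by one tick.

    Returns ``(new_state, switching)`` where ``switching`` is True whenever
    the switch gesture is active this tick (the control output is zeroed for
    such ticks, so switching never drags the cursor).  The axis toggles on the
    gesture only after the refractory interval since the last toggle.
    """
    active = switch_condition(u_e, u_f, trigger_env_norm, cfg)
    if active and (t - state.last_switch_time) >= cfg.switch_refractory_s:
        return DcState(active_axis=1 - state.active_axis, last_switch_time=t), True
    return state, active


def dc_output(u: float, state: DcState, mapping: MotionMapping) -> np.ndarray:
    """Map the signed control signal onto the active cursor axis.

    Exactly one component is nonzero (sequential one-DOF contract); the sign
    convention comes from the mapping preset (extension positive for
    right-handed, reversed for left-handed and the DMD variant).
    """
    if abs(u) > 1.0:
        raise ValueError("control signal must lie in [-1, 1]")
    out = np.zeros(2)
    out[state.active_axis] = mapping.dc_axis_sign[state.active_axis] * u
    return out


class DirectController:
    """Tick-wise direct controller: envelopes in, 2-vector control out."""

    def __init__(self, calib: CalibrationProfile, cfg: DcConfig):
        if cfg.switch_source == "trigger" and "trigger" not in calib.channel_roles:
            raise ValueError("trigger switch source configured but no trigger channel")
        self.calib = calib
        self.cfg = cfg
        self.state = DcState()
        self.n_switches = 0

    def reset(self) -> None:
        self.state = DcState()
        self.n_switches = 0

    def tick(self, env_sample: np.ndarray, t: float) -> np.ndarray:
        """One control tick from the current per-channel envelope sample (mV)."""
        roles = self.calib.channel_roles
        env_e = float(env_sample[roles.index(self.cfg.extensor_role)])
        env_f = float(env_sample[roles.index(self.cfg.flexor_role)])
        trigger_norm = None
        if "trigger" in roles:
            rest_t, mvc_t = self.calib.for_role("trigger")
            trigger_norm = normalized_activation(
                float(env_sample[roles.index("trigger")]), rest_t, mvc_t
            )
        u_e, u_f = activation_pair(env_e, env_f, self.calib, self.cfg)
        prev_axis = self.state.active_axis
        self.state, switching = detect_switch(
            u_e, u_f, trigger_norm, t, self.cfg, self.state
        )
        if self.state.active_axis != prev_axis:
            self.n_switches += 1
        if switching:
            return np.zeros(2)
        u = dc_signal(env_e, env_f, self.calib, self.cfg)
        return dc_output(u, self.state, self.cfg.mapping)
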