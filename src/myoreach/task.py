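"""Closed-loop target-reaching task: protocol, virtual user, trial loop.

The task is a screen-based reaching game: a cursor starts at the workspace
centre, a circular target appears, and the trial succeeds when the cursor
stays inside the target for a continuous 2 s dwell.  Reaching time is the
interval from target appearance to the *start* of the completing dwell.

Eight targets: 1-4 lie on the axes (one-DOF trials), 5-8 on the diagonals
(two-DOF trials).  Healthy sessions present four targets per DOF condition,
ten trials each, first two per target discarded as familiarisation; the
reduced DMD protocol uses targets {1, 2} and {6, 8} only.

Because no human sits in the loop, a :class:`VirtualUser` closes it: a
feedback policy that watches the cursor, picks the motion command that shrinks
the dominant error coordinate, brakes by reversing when the virtual inertia
would overshoot, emits co-contraction (or trigger) bursts when direct control
needs the other axis, and rests inside the target.  Its commands drive the
synthetic-sEMG generator, whose output runs through the genuine envelope
pipeline, controller and admittance model — the same code path a recorded
signal would take.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .admittance import (
    AdmittanceParams,
    CursorState,
    admittance_step,
    force_from_control,
    get_params,
    scale_to_max_speed,
)
from .direct_control import DcConfig, DirectController
from .mapping import MotionClass, MotionMapping, get_mapping
from .pattern_recognition import (
    PatternController,
    PrModel,
    build_training_set,
    train,
)
from .processing import CalibrationProfile, StreamingPipeline, calibrate
from .synthetic import (
    SWITCH_COMMAND,
    TRIGGER_COMMAND,
    EmgSynthesizer,
    SubjectProfile,
    get_profile,
    make_calibration_kit,
)


# ------------------------------------------------------------------ layout


@dataclass(frozen=True)
class Target:
    id: int
    center: tuple[float, float]
    radius: float

    @property
    def dof(self) -> int:
        return 1 if self.id <= 4 else 2


@dataclass(frozen=True)
class TargetLayout:
    """The eight-target layout: axis targets 1-4, diagonal targets 5-8."""

    targets: tuple[Target, ...]

    def __post_init__(self) -> None:
        if len({t.id for t in self.targets}) != len(self.targets):
            raise ValueError("duplicate target ids")
        for t in self.targets:
            if t.radius <= 0:
                raise ValueError(f"target {t.id}: radius must be positive")
            if max(abs(t.center[0]), abs(t.center[1])) + t.radius > 1.0:
                raise ValueError(f"target {t.id} extends outside the workspace")
        for a in self.targets:
            for b in self.targets:
                if a.id < b.id:
                    d = np.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
                    if d < a.radius + b.radius:
                        raise ValueError(f"targets {a.id} and {b.id} overlap")

    def get(self, target_id: int) -> Target:
        for t in self.targets:
            if t.id == target_id:
                return t
        raise KeyError(f"no target with id {target_id}")

    def dof_of(self, target_id: int) -> int:
        return self.get(target_id).dof


def make_layout(distance: float = 0.55, radius: float = 0.08) -> TargetLayout:
    """Default layout: 1-DOF targets on the axes, 2-DOF on the diagonals."""
    d = distance
    centers = {
        1: (d, 0.0),
        2: (-d, 0.0),
        3: (0.0, d),
        4: (0.0, -d),
        5: (d, d),
        6: (-d, d),
        7: (-d, -d),
        8: (d, -d),
    }
    return TargetLayout(
        targets=tuple(Target(i, centers[i], radius) for i in range(1, 9))
    )


DMD_TARGETS = {1: (1, 2), 2: (6, 8)}  # reduced protocol per DOF condition


def targets_for(cohort: str, dof: int) -> tuple[int, ...]:
    if dof not in (1, 2):
        raise ValueError("dof must be 1 or 2")
    if cohort == "dmd":
        return DMD_TARGETS[dof]
    return (1, 2, 3, 4) if dof == 1 else (5, 6, 7, 8)


# ------------------------------------------------------------ virtual user


@dataclass
class VirtualUser:
    """Feedback policy standing in for a participant.

    The policy runs on visual feedback of the cursor: it chooses, per
    decision (every ``decision_interval_s``), the motion command that reduces
    the dominant error coordinate, with effort proportional to the force a
    mass-damper needs to approach and then brake.  Commands take effect after
    ``reaction_delay_s``; each class decision is corrupted with probability
    ``class_error_rate``.  Inside ``stop_deadband`` of the target centre (and
    slow enough), the user relaxes.
    """

    reaction_delay_s: float = 0.15
    pr_extra_reaction_s: float = 0.10  # discrete gesture choice is slower (Hick's law)
    activation_level: float = 0.7  # effort ceiling, fraction of MVC
    class_error_rate: float = 0.02
    stop_deadband: float = 0.05  # workspace units
    decision_interval_s: float = 0.10
    approach_time_s: float = 0.8  # error -> desired-velocity horizon
    brake_time_s: float = 1.0  # velocity-correction horizon
    lead_s: float = 0.45  # anticipates envelope + reaction latency
    effort_calibration: float = 1.0  # multiplies the learned intensity-per-force
    pr_min_intensity: float = 0.35  # crisp-contraction floor the decoder needs
    switch_intensity: float = 0.6
    axis_tol: float = 0.04  # per-axis "done" tolerance (DC)
    vel_tol: float = 0.03  # residual speed tolerance (coast drift is v x A/B)

    def __post_init__(self) -> None:
        if not 0.0 < self.activation_level <= 1.0:
            raise ValueError("activation_level must lie in (0, 1]")
        if not 0.0 <= self.class_error_rate < 0.5:
            raise ValueError("class_error_rate must lie in [0, 0.5)")


def _desired_force(
    err: np.ndarray, vel: np.ndarray, params: AdmittanceParams, user: VirtualUser
) -> np.ndarray:
    """Per-axis force tracking v_des = err_pred/t_go, braking overshoot.

    The error is extrapolated by ``lead_s`` at the current velocity: the
    plant answers commands only after the envelope-filter and reaction
    latencies, and a policy that ignores that delay limit-cycles around the
    target instead of settling (as a naive first-time user would).
    """
    v_cap = user.activation_level / params.B  # attainable terminal speed
    err_pred = err - vel * user.lead_s
    v_des = np.clip(err_pred / user.approach_time_s, -v_cap, v_cap)
    f = params.B * v_des + (params.A / user.brake_time_s) * (v_des - vel)
    return np.clip(f, -1.0, 1.0)


def control_gain(profile: SubjectProfile, method: str) -> float:
    """Expected control signal per unit commanded intensity, from the
    profile's synergy and gain structure.

    This is what a participant internalises during familiarisation: how much
    cursor drive a given effort produces.  Channel-wise the envelope is
    proportional to gain x activation with a common carrier factor, so the
    factor cancels between the numerator and the MVC normaliser.
    """
    act_mvc = profile.activation_for(SWITCH_COMMAND)[:6]
    g = profile.channel_gain
    if method == "pr":
        ratios = [
            np.mean(g * profile.activation_for(cls)[:6]) / np.mean(g * act_mvc)
            for cls in _MOVING
        ]
        return float(np.mean(ratios))
    if method == "dc":
        act_ext = profile.activation_for(MotionClass.WRIST_EXTENSION)[:6]
        i_f, i_e = 0, 1  # CHANNEL_ORDER starts (fcu, ecu)
        return float(act_ext[i_e] / act_mvc[i_e] - act_ext[i_f] / act_mvc[i_f])
    raise ValueError(f"unknown method '{method}'")


def user_intent(
    user: VirtualUser,
    cursor: CursorState,
    target: Target,
    mapping: MotionMapping,
    method: str,
    params: AdmittanceParams,
    dc_state=None,
    has_trigger: bool = False,
    rng: np.random.Generator | None = None,
    intensity_per_force: float = 1.5,
) -> tuple[MotionClass | str, float]:
    """One decision: (command, intensity in [0, 1]).

    ``params`` are the (workspace-scaled) admittance parameters the cursor
    actually obeys and ``intensity_per_force`` the learned effort required per
    unit of control drive — the user has internalised the plant through
    practice (see :func:`control_gain`).
    """
    err = np.asarray(target.center) - cursor.pos
    dist = float(np.hypot(*err))
    speed = float(np.hypot(*cursor.vel))
    f_des = _desired_force(err, cursor.vel, params, user)
    k = intensity_per_force * user.effort_calibration

    if method == "pr":
        if dist < user.stop_deadband and speed < user.vel_tol:
            return MotionClass.NO_MOTION, 0.0
        axis = int(np.argmax(np.abs(f_des)))
        if abs(f_des[axis]) < 1e-3:
            return MotionClass.NO_MOTION, 0.0
        cls = mapping.class_for_direction(axis, np.sign(f_des[axis]))
        cls = _maybe_corrupt(cls, user, rng)
        # contractions weaker than the training level decode as rest; a
        # practiced user keeps commands crisp instead of feathering them
        intensity = min(
            user.activation_level, max(abs(f_des[axis]) * k, user.pr_min_intensity)
        )
        return cls, intensity

    if method == "dc":
        a = dc_state.active_axis if dc_state is not None else 0
        o = 1 - a
        if abs(err[a]) > user.axis_tol or abs(cursor.vel[a]) > user.vel_tol:
            sign = np.sign(f_des[a]) if f_des[a] != 0 else 0.0
            if sign == 0.0:
                return MotionClass.NO_MOTION, 0.0
            # extension moves the cursor along dc_axis_sign[a]; flexion opposes
            cls = (
                MotionClass.WRIST_EXTENSION
                if sign == mapping.dc_axis_sign[a]
                else MotionClass.WRIST_FLEXION
            )
            cls = _maybe_corrupt(cls, user, rng, dc=True)
            intensity = min(user.activation_level, abs(f_des[a]) * k)
            return cls, intensity
        if abs(err[o]) > user.axis_tol:
            return (TRIGGER_COMMAND if has_trigger else SWITCH_COMMAND), user.switch_intensity
        return MotionClass.NO_MOTION, 0.0

    raise ValueError(f"unknown method '{method}'")


_MOVING = [c for c in MotionClass if c is not MotionClass.NO_MOTION]
_DC_PAIR = [MotionClass.WRIST_EXTENSION, MotionClass.WRIST_FLEXION]


def _maybe_corrupt(
    cls: MotionClass, user: VirtualUser, rng: np.random.Generator | None, dc: bool = False
) -> MotionClass:
    if rng is None or user.class_error_rate == 0.0:
        return cls
    if rng.random() >= user.class_error_rate:
        return cls
    pool = _DC_PAIR if dc else _MOVING
    others = [c for c in pool if c is not cls]
    return others[int(rng.integers(len(others)))]


# -------------------------------------------------------------- trial loop


@dataclass
class TrialResult:
    """Outcome of one reaching trial."""

    target_id: int
    method: str
    cohort: str
    dof: int
    trial_index: int = 0
    discarded: bool = False
    success: bool = False
    reaching_time_s: float = float("nan")
    completed_at_s: float = float("nan")
    n_switches: int = 0
    timeseries: dict | None = None


class DwellTracker:
    """Continuous-dwell bookkeeping for one trial.

    Success requires an uninterrupted inside-target run of ``dwell_s``; any
    exit resets the clock.  The reaching time is the start of the completing
    dwell, so the settling period itself is excluded.
    """

    def __init__(self, dwell_s: float):
        self.dwell_s = dwell_s
        self.dwell_start: float | None = None
        self.reaching_time_s = float("nan")
        self.completed_at_s = float("nan")
        self.done = False

    def update(self, t: float, inside: bool) -> bool:
        """Advance to time t; returns True once the dwell completes."""
        if self.done:
            return True
        if not inside:
            self.dwell_start = None
            return False
        if self.dwell_start is None:
            self.dwell_start = t
        elif t - self.dwell_start >= self.dwell_s:
            self.done = True
            self.reaching_time_s = self.dwell_start
            self.completed_at_s = t
        return self.done


def reaching_time_from_trace(
    ts: np.ndarray, xy: np.ndarray, target: Target, dwell_s: float = 2.0
) -> tuple[bool, float, float]:
    """Apply the dwell rule to a recorded cursor trace.

    Returns (success, reaching_time_s, completed_at_s); useful for scoring
    externally produced trajectories with the same rule the simulator uses.
    """
    tracker = DwellTracker(dwell_s)
    center = np.asarray(target.center)
    for t, pos in zip(ts, np.atleast_2d(xy)):
        if tracker.update(float(t), bool(np.hypot(*(pos - center)) <= target.radius)):
            break
    return tracker.done, tracker.reaching_time_s, tracker.completed_at_s


@dataclass
class SessionSpec:
    """The per-condition protocol schedule."""

    method: str  # "dc" | "pr"
    cohort: str  # "healthy" | "dmd"
    dof: int  # 1 | 2
    trials_per_target: int = 10
    discard_first: int = 2
    dwell_s: float = 2.0
    inter_trial_s: float = 2.0
    timeout_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("dc", "pr"):
            raise ValueError("method must be 'dc' or 'pr'")
        if self.cohort not in ("healthy", "dmd"):
            raise ValueError("cohort must be 'healthy' or 'dmd'")
        if self.discard_first >= self.trials_per_target:
            raise ValueError("discard_first must be smaller than trials_per_target")

    @property
    def target_ids(self) -> tuple[int, ...]:
        return targets_for(self.cohort, self.dof)


class TrialRunner:
    """Everything fixed across trials of one subject: profile, calibration,
    trained model, controller and admittance configuration."""

    def __init__(
        self,
        profile: SubjectProfile,
        calib: CalibrationProfile,
        method: str,
        mapping: MotionMapping | None = None,
        pr_model: PrModel | None = None,
        admittance: AdmittanceParams | None = None,
        max_speed: float | None = None,
        scaled_params: AdmittanceParams | None = None,
        user: VirtualUser | None = None,
        dc_config: DcConfig | None = None,
        fs: float = 1000.0,
        dt: float = 0.01,
    ):
        self.profile = profile
        self.calib = calib
        self.method = method
        self.fs = fs
        self.dt = dt
        self.user = user or VirtualUser()
        if mapping is None:
            mapping = get_mapping("dmd" if profile.cohort == "dmd" else "right_handed")
        self.mapping = mapping
        if scaled_params is not None:
            # explicit workspace-unit parameters, bypassing the rescaling step
            self.params = scaled_params
        else:
            raw = admittance or get_params(profile.cohort)
            self.params = (
                scale_to_max_speed(raw)
                if max_speed is None
                else scale_to_max_speed(raw, max_speed)
            )
        if method == "dc":
            cfg = dc_config or DcConfig(
                mapping=mapping,
                switch_source="trigger" if profile.has_trigger else "cocontraction",
            )
            self.controller = DirectController(calib, cfg)
        elif method == "pr":
            if pr_model is None:
                raise ValueError("pattern-recognition runner needs a trained model")
            self.controller = PatternController(pr_model, calib, mapping, fs)
        else:
            raise ValueError(f"unknown method '{method}'")
        self.intensity_per_force = 1.0 / control_gain(profile, method)

    def run_trial(
        self,
        target: Target,
        seed: int,
        dwell_s: float = 2.0,
        timeout_s: float = 30.0,
        record_timeseries: bool = False,
    ) -> TrialResult:
        """Simulate one trial: intent -> sEMG -> envelopes -> controller ->
        admittance -> cursor, until dwell success or timeout."""
        rng = np.random.default_rng(seed)
        synth = EmgSynthesizer(self.profile, self.fs, int(rng.integers(2**31 - 1)))
        pipe = StreamingPipeline(self.profile.n_channels, self.fs)
        self.controller.reset()

        n_sub = int(round(self.dt * self.fs))
        alpha = 1.0 - np.exp(-1.0 / (self.fs * self.profile.activation_lag_s))
        decay_pow = (1.0 - alpha) ** np.arange(1, n_sub + 1)
        act_state = np.zeros(self.profile.n_channels)

        cursor = CursorState.origin()
        pending: deque[tuple[float, MotionClass | str, float]] = deque()
        command: MotionClass | str = MotionClass.NO_MOTION
        intensity = 0.0
        next_decision = 0.0
        dwell = DwellTracker(dwell_s)
        center = np.asarray(target.center)
        trace: list[tuple[float, float, float]] = []

        t = 0.0
        while t < timeout_s:
            if t >= next_decision:
                dc_state = self.controller.state if self.method == "dc" else None
                cmd, inten = user_intent(
                    self.user,
                    cursor,
                    target,
                    self.mapping,
                    self.method,
                    self.params,
                    dc_state=dc_state,
                    has_trigger=self.profile.has_trigger,
                    rng=rng,
                    intensity_per_force=self.intensity_per_force,
                )
                delay = self.user.reaction_delay_s
                if self.method == "pr":
                    delay += self.user.pr_extra_reaction_s
                pending.append((t + delay, cmd, inten))
                next_decision = t + self.user.decision_interval_s
            while pending and pending[0][0] <= t:
                _, command, intensity = pending.popleft()

            target_act = self.profile.activation_for(command) * intensity
            # first-order activation lag, vectorised over the tick's samples
            act_chunk = target_act[:, None] + np.outer(
                act_state - target_act, decay_pow
            )
            act_state = act_chunk[:, -1]
            raw = synth.render(np.clip(act_chunk, 0.0, 1.0))
            hp, env = pipe.push(raw)
            if self.method == "pr":
                self.controller.push_samples(hp)
            u = self.controller.tick(env[:, -1], t + self.dt)
            cursor = admittance_step(cursor, force_from_control(u), self.params, self.dt)
            t = cursor.t

            if record_timeseries:
                trace.append((t, cursor.pos[0], cursor.pos[1]))

            inside = bool(np.hypot(*(cursor.pos - center)) <= target.radius)
            if dwell.update(t, inside):
                return TrialResult(
                    target_id=target.id,
                    method=self.method,
                    cohort=self.profile.cohort,
                    dof=target.dof,
                    success=True,
                    reaching_time_s=dwell.reaching_time_s,
                    completed_at_s=dwell.completed_at_s,
                    n_switches=getattr(self.controller, "n_switches", 0),
                    timeseries={"t_x_y": trace} if record_timeseries else None,
                )

        return TrialResult(
            target_id=target.id,
            method=self.method,
            cohort=self.profile.cohort,
            dof=target.dof,
            success=False,
            n_switches=getattr(self.controller, "n_switches", 0),
            timeseries={"t_x_y": trace} if record_timeseries else None,
        )


def prepare_runner(
    spec: SessionSpec,
    user: VirtualUser | None = None,
    layout: TargetLayout | None = None,
) -> tuple[TrialRunner, TargetLayout]:
    """Calibrate (and for PR, train) a fresh subject for a session spec."""
    profile = get_profile(spec.cohort)
    kit = make_calibration_kit(profile, seed=spec.seed)
    calib = calibrate(kit.mvc, kit.rest)
    pr_model = None
    if spec.method == "pr":
        X, y = build_training_set(kit.training)
        pr_model = train(X, y, seed=spec.seed)
    runner = TrialRunner(
        profile=profile, calib=calib, method=spec.method, pr_model=pr_model, user=user
    )
    return runner, layout or make_layout()


def run_session(
    spec: SessionSpec,
    user: VirtualUser | None = None,
    layout: TargetLayout | None = None,
    runner: TrialRunner | None = None,
) -> list[TrialResult]:
    """Run one full protocol condition.

    Targets cycle in numerical order; each target is presented
    ``trials_per_target`` times with the first ``discard_first`` presentations
    flagged as discarded (familiarisation).  The cursor resets to the centre
    between trials; the 2 s inter-trial interval is bookkeeping, not
    simulated.  Fully deterministic for a fixed spec seed.
    """
    if runner is None:
        runner, layout = prepare_runner(spec, user=user, layout=layout)
    else:
        layout = layout or make_layout()
    rng = np.random.default_rng(spec.seed + 1)
    results: list[TrialResult] = []
    for cycle in range(spec.trials_per_target):
        for tid in spec.target_ids:
            res = runner.run_trial(
                layout.get(tid),
                seed=int(rng.integers(2**31 - 1)),
                dwell_s=spec.dwell_s,
                timeout_s=spec.timeout_s,
            )
            res.trial_index = cycle
            res.discarded = cycle < spec.discard_first
            results.append(res)
    return results
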