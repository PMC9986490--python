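"""Deterministic 60 Hz simulator of the locomotor-interception task.

An agent and a moving target travel along straight converging paths toward a
fixed (invisible) interception point.  The agent starts from standstill and
controls its speed through a foot pedal coupled to the vehicle by a first-order
lag; the target approaches at one of three initial speeds and, partway through
the approach, ramps linearly over 500 ms to a final speed drawn from a
truncated normal distribution (mean 15 m/s, sd 5 m/s, truncated at one sd).
The episode succeeds when agent and target are simultaneously within the
capture radius of the interception point.

State is kept as scalar distances-to-point rather than 2-D coordinates: the
observation consumed by the agent is the 4-vector
``<target distance, target speed, agent distance, agent speed>``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

__all__ = [
    "EnvConfig",
    "EpisodeSetup",
    "EnvState",
    "InterceptionEnv",
    "ConfigError",
    "PEDAL_SPEEDS",
    "TARGET_INIT_SPEEDS",
    "target_speed_at",
    "pedal_update",
    "first_order_ttc",
    "actual_ttc_from_onset",
]

#: Discrete pedal positions (m/s); action index i selects PEDAL_SPEEDS[i].
PEDAL_SPEEDS: tuple[float, ...] = (2.0, 4.0, 8.0, 10.0, 12.0, 14.0)

#: The three target initial speeds (m/s) used in the human study.
TARGET_INIT_SPEEDS: tuple[float, ...] = (11.25, 9.47, 8.18)

# Phase labels
PRE_CHANGE = "pre_change"
RAMPING = "ramping"
POST_CHANGE = "post_change"

# Outcome labels
ONGOING = "ongoing"
SUCCESS = "success"
MISS = "miss"


class ConfigError(ValueError):
    """Raised for invalid environment configuration."""


@dataclass(frozen=True)
class EnvConfig:
    """Task parameters.

    ``lag_base`` is the per-step pedal lag constant K' = 0.017; the effective
    lag is ``K = lag_multiplier * lag_base`` (multiplier 1.0 for the responsive
    vehicle, 0.5 for the sluggish one).  The target's initial distance is not
    pinned down by the task description; the default of 45 m places the speed
    change (2.5-3.25 s) partway through target first-order approach times of
    4.0-5.5 s.
    """

    dt: float = 1.0 / 60.0
    lag_base: float = 0.017
    lag_multiplier: float = 1.0
    pedal_speeds: tuple[float, ...] = PEDAL_SPEEDS
    agent_init_distance_range: tuple[float, float] = (25.0, 30.0)
    target_init_speeds: tuple[float, ...] = TARGET_INIT_SPEEDS
    target_init_distance: float = 45.0
    change_onset_range: tuple[float, float] = (2.5, 3.25)
    final_speed_mean: float = 15.0
    final_speed_sd: float = 5.0
    ramp_duration: float = 0.5
    capture_radius: float = 1.0
    max_episode_duration: float = 15.0

    @property
    def K(self) -> float:
        """Effective pedal lag coefficient."""
        return self.lag_multiplier * self.lag_base

    @property
    def final_speed_bounds(self) -> tuple[float, float]:
        """Truncation bounds of the final-speed distribution (mean +- 1 sd)."""
        return (self.final_speed_mean - self.final_speed_sd,
                self.final_speed_mean + self.final_speed_sd)

    def validate(self) -> None:
        if not self.dt > 0:
            raise ConfigError(f"dt must be positive, got {self.dt}")
        if not 0 < self.K <= 1:
            raise ConfigError(f"effective lag K must be in (0, 1], got {self.K}")
        if any(v <= 0 for v in self.pedal_speeds):
            raise ConfigError("pedal speeds must be positive")
        if any(v <= 0 for v in self.target_init_speeds):
            raise ConfigError("target initial speeds must be positive")
        lo, hi = self.agent_init_distance_range
        if not 0 < lo <= hi:
            raise ConfigError("invalid agent_init_distance_range")
        lo, hi = self.change_onset_range
        if not (0 <= lo <= hi <= self.max_episode_duration):
            raise ConfigError("change onset range must lie within "
                              "[0, max_episode_duration]")
        if self.final_speed_sd <= 0 or self.ramp_duration <= 0:
            raise ConfigError("final_speed_sd and ramp_duration must be positive")
        if self.capture_radius <= 0 or self.target_init_distance <= 0:
            raise ConfigError("capture_radius and target_init_distance "
                              "must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pedal_speeds"] = list(d["pedal_speeds"])
        d["target_init_speeds"] = list(d["target_init_speeds"])
        d["agent_init_distance_range"] = list(d["agent_init_distance_range"])
        d["change_onset_range"] = list(d["change_onset_range"])
        return d


@dataclass(frozen=True)
class EpisodeSetup:
    """Sampled initial conditions and target speed schedule for one episode."""

    agent_init_distance: float
    target_init_speed: float
    target_final_speed: float
    change_onset: float
    ramp_duration: float
    target_init_distance: float


@dataclass
class EnvState:
    """Instantaneous simulator state."""

    t: float
    x_t: float  # target distance to interception point (m)
    v_t: float  # target speed (m/s)
    x_s: float  # agent distance to interception point (m)
    v_s: float  # agent speed (m/s)
    phase: str = PRE_CHANGE
    terminal: bool = False
    outcome: str = ONGOING

    def observation(self) -> np.ndarray:
        return np.array([self.x_t, self.v_t, self.x_s, self.v_s], dtype=float)


def target_speed_at(setup: EpisodeSetup, t: float) -> float:
    """Target speed (m/s) at episode time ``t`` under the linear ramp schedule.

    Initial speed before onset, linear interpolation over the ramp, final
    speed afterwards.
    """
    if t < 0:
        raise ValueError(f"time must be non-negative, got {t}")
    onset, tau = setup.change_onset, setup.ramp_duration
    if t < onset:
        return setup.target_init_speed
    if t >= onset + tau:
        return setup.target_final_speed
    frac = (t - onset) / tau
    return setup.target_init_speed + frac * (
        setup.target_final_speed - setup.target_init_speed)


def pedal_update(v_s: float, pedal_speed: float, K: float) -> float:
    """One 60 Hz step of the first-order pedal lag: v + K * (V_p - v)."""
    return v_s + K * (pedal_speed - v_s)


def first_order_ttc(distance: float, speed: float) -> float:
    """First-order time to contact: distance / current speed.

    Assumes constant speed from now on; returns ``inf`` for a stationary
    object.
    """
    if distance < 0 or speed < 0:
        raise ValueError("distance and speed must be non-negative")
    if speed == 0.0:
        return math.inf
    return distance / speed


def actual_ttc_from_onset(x: float, v0: float, v1: float, tau: float) -> float:
    """Arrival time of the target measured from ramp onset.

    Closed-form kinematics of the linear speed ramp from ``v0`` to ``v1``
    over ``tau`` seconds: if the ramp covers the remaining distance ``x``,
    solve ``v0*t + (v1 - v0) * t**2 / (2*tau) = x`` on [0, tau]; otherwise
    add the post-ramp leg at constant ``v1``.
    """
    if x < 0 or v0 <= 0 or v1 <= 0 or tau <= 0:
        raise ValueError("require x >= 0, v0 > 0, v1 > 0, tau > 0")
    ramp_distance = 0.5 * (v0 + v1) * tau
    if ramp_distance >= x:
        a = 0.5 * (v1 - v0) / tau
        if abs(a) < 1e-12:  # degenerate ramp: constant speed
            return x / v0
        disc = v0 * v0 + 4.0 * a * x
        if disc < 0:
            raise ArithmeticError("no real arrival time on the ramp")
        t = (-v0 + math.sqrt(disc)) / (2.0 * a)
        if not -1e-9 <= t <= tau + 1e-9:
            # other root (decelerating ramp edge cases)
            t = (-v0 - math.sqrt(disc)) / (2.0 * a)
        return min(max(t, 0.0), tau)
    return tau + (x - ramp_distance) / v1


class InterceptionEnv:
    """Episodic interception task with a gym-style ``reset``/``step`` API.

    Actions are integers 0-5 indexing the pedal speeds.  The environment is
    reward-free: agents derive their own reward signals (instrumental,
    epistemic, or sparse terminal) from observations and outcomes, so ``step``
    returns the conventional 5-tuple with a reward slot fixed at 0.0 and the
    outcome reported in ``info``.
    """

    def __init__(self, config: Optional[EnvConfig] = None,
                 rng: Optional[np.random.Generator] = None,
                 record: bool = False):
        self.config = config or EnvConfig()
        self.config.validate()
        self.rng = rng if rng is not None else np.random.default_rng()
        self.record = record
        self.state: Optional[EnvState] = None
        self.setup: Optional[EpisodeSetup] = None
        self._trace: list[tuple] = []

    @property
    def n_actions(self) -> int:
        return len(self.config.pedal_speeds)

    def sample_setup(self) -> EpisodeSetup:
        """Draw one episode's initial conditions from the task distributions."""
        cfg = self.config
        rng = self.rng
        d_lo, d_hi = cfg.agent_init_distance_range
        agent_d = rng.uniform(d_lo, d_hi)
        v0 = float(rng.choice(np.asarray(cfg.target_init_speeds)))
        o_lo, o_hi = cfg.change_onset_range
        onset = rng.uniform(o_lo, o_hi)
        lo, hi = cfg.final_speed_bounds
        while True:  # rejection sampling of the truncated normal
            vf = rng.normal(cfg.final_speed_mean, cfg.final_speed_sd)
            if lo <= vf <= hi:
                break
        return EpisodeSetup(
            agent_init_distance=float(agent_d),
            target_init_speed=v0,
            target_final_speed=float(vf),
            change_onset=float(onset),
            ramp_duration=cfg.ramp_duration,
            target_init_distance=cfg.target_init_distance,
        )

    def reset(self, setup: Optional[EpisodeSetup] = None):
        """Start a new episode; returns ``(observation, info)``.

        The agent begins stationary.  ``info`` carries the sampled
        :class:`EpisodeSetup` and the full :class:`EnvState`.
        """
        self.setup = setup if setup is not None else self.sample_setup()
        self.state = EnvState(
            t=0.0,
            x_t=self.setup.target_init_distance,
            v_t=self.setup.target_init_speed,
            x_s=self.setup.agent_init_distance,
            v_s=0.0,
        )
        self._trace = []
        if self.record:
            self._record_row(action=-1)
        return self.state.observation(), {"setup": self.setup,
                                          "state": self.state}

    def step(self, action: int):
        """Advance one 60 Hz tick under pedal ``action``.

        Returns ``(observation, reward, terminated, truncated, info)`` with
        ``reward`` always 0.0 (see class docstring); the episode outcome is in
        ``info['outcome']``.
        """
        if self.state is None:
            raise RuntimeError("call reset() before step()")
        if self.state.terminal:
            raise RuntimeError("cannot step a terminal episode; call reset()")
        if not 0 <= int(action) < self.n_actions:
            raise ValueError(f"action index out of range: {action}")
        cfg, st, setup = self.config, self.state, self.setup

        pedal = cfg.pedal_speeds[int(action)]
        st.v_s = max(0.0, pedal_update(st.v_s, pedal, cfg.K))
        st.x_s -= st.v_s * cfg.dt
        st.t += cfg.dt
        st.v_t = target_speed_at(setup, st.t)
        st.x_t -= st.v_t * cfg.dt

        if st.t < setup.change_onset:
            st.phase = PRE_CHANGE
        elif st.t < setup.change_onset + setup.ramp_duration:
            st.phase = RAMPING
        else:
            st.phase = POST_CHANGE

        r = cfg.capture_radius
        if abs(st.x_s) <= r and abs(st.x_t) <= r:
            st.terminal, st.outcome = True, SUCCESS
        elif st.x_t < -r or st.t > cfg.max_episode_duration:
            st.terminal, st.outcome = True, MISS

        if self.record:
            self._record_row(action=int(action))
        info = {"outcome": st.outcome, "setup": setup, "state": st}
        return st.observation(), 0.0, st.terminal, False, info

    # -- episode trace export ------------------------------------------------

    def _record_row(self, action: int) -> None:
        st = self.state
        self._trace.append((st.t, st.x_t, st.v_t, st.x_s, st.v_s,
                            action, st.phase, st.outcome))

    def trace_dataframe(self):
        """The recorded episode trace as a DataFrame (requires record=True)."""
        import pandas as pd

        return pd.DataFrame(
            self._trace,
            columns=["t", "x_t", "v_t", "x_s", "v_s",
                     "action", "phase", "outcome"],
        )

    def trace_to_csv(self, path) -> None:
        self.trace_dataframe().to_csv(path, index=False)
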