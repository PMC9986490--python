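"""Prior preference over the one-dimensional "speed difference" space.

The prior mapping function reduces the 4-D observation to a single
task-meaningful variable: the difference between the agent's speed and the
speed it would need to arrive at the interception point exactly when the
target does, assuming the target keeps its current speed (first-order time to
contact).  The instrumental reward is the log-likelihood of that speed
difference under a Gaussian prior preference centred on zero: matching the
first-order required speed is the preferred outcome, and the reward falls off
quadratically with the mismatch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .env import pedal_update

__all__ = [
    "PriorConfig",
    "required_speed",
    "speed_difference",
    "instrumental_reward",
    "prior_over_actions",
]

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class PriorConfig:
    """Shape of the prior preference distribution.

    prior_sd
        Width (m/s) of the Gaussian preference over speed difference.
    drop_constant
        Drop the log-normalizer so the reward is exactly -d^2 / (2 sd^2),
        with maximum 0 at zero speed difference.
    instrumental_scale
        Multiplier applied to the log-density.
    reward_floor
        Optional lower clip on the instrumental reward.  Near the end of an
        episode the first-order required speed diverges as the target closes
        on the interception point, so the raw log-density can spike to large
        negative values on a handful of terminal-adjacent steps; a floor keeps
        bootstrap targets bounded without reordering actions elsewhere.
    """

    prior_sd: float = 1.0
    drop_constant: bool = True
    instrumental_scale: float = 1.0
    reward_floor: Optional[float] = -50.0

    def validate(self) -> None:
        if self.prior_sd <= 0:
            raise ValueError(f"prior_sd must be positive, got {self.prior_sd}")


def required_speed(obs: Sequence[float]) -> float:
    """Speed the agent needs to reach the point at the target's first-order TTC.

    ``x_s / (x_t / v_t)``.  Once the target is at (or past) the interception
    point no finite speed suffices; the target TTC is floored at one
    simulation tick (1/60 s) so the required speed stays finite but large in
    that degenerate regime.
    """
    x_t, v_t, x_s = float(obs[0]), float(obs[1]), float(obs[2])
    if v_t <= 0:
        raise ValueError("required_speed needs a moving target (v_t > 0)")
    ttc_target = max(x_t / v_t, 1.0 / 60.0)
    return x_s / ttc_target


def speed_difference(agent_speed: float, obs: Sequence[float]) -> float:
    """Signed mismatch: agent speed minus first-order required speed."""
    return float(agent_speed) - required_speed(obs)


def instrumental_reward(obs_next: Sequence[float],
                        config: PriorConfig = PriorConfig()) -> float:
    """Log-likelihood of the realized speed difference under the prior.

    Evaluated on the post-action observation: the agent's new speed against
    the required speed implied by the new target state.  Maximal (0 with the
    normalizer dropped) at zero speed difference, strictly decreasing in its
    magnitude.
    """
    d = speed_difference(obs_next[3], obs_next)
    var = config.prior_sd ** 2
    logp = -0.5 * d * d / var
    if not config.drop_constant:
        logp -= 0.5 * _LOG_2PI + math.log(config.prior_sd)
    r = config.instrumental_scale * logp
    if config.reward_floor is not None:
        r = max(r, config.reward_floor)
    return r


def prior_over_actions(obs: Sequence[float],
                       pedal_speeds: Sequence[float],
                       K: float,
                       config: PriorConfig = PriorConfig()) -> np.ndarray:
    """Instrumental value of each candidate pedal, one step ahead.

    For each pedal speed the agent's speed after one lag step is computed and
    scored against the required speed implied by the current observation.
    Used for inspection and figures, not inside the training loop.
    """
    req = required_speed(obs)
    v_s = float(obs[3])
    var = config.prior_sd ** 2
    values = np.empty(len(pedal_speeds), dtype=float)
    for i, pedal in enumerate(pedal_speeds):
        v_next = pedal_update(v_s, pedal, K)
        d = v_next - req
        logp = -0.5 * d * d / var
        if not config.drop_constant:
            logp -= 0.5 * _LOG_2PI + math.log(config.prior_sd)
        values[i] = config.instrumental_scale * logp
        if config.reward_floor is not None:
            values[i] = max(values[i], config.reward_floor)
    return values
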