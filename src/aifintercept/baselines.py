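"""Comparison agents: sparse-reward DQN and the instrumental-only ablation.

Both reuse the joint-agent machinery so the contrast is isolated to the
reward signal and the exploration scheme:

* ``dqn_sparse`` — same trunk and action head, transition head's loss weight
  set to 0, reward equal to the sparse terminal success indicator, and
  epsilon-greedy exploration with a linear decay schedule.
* ``aif_instrumental_only`` — the AIF agent with the epistemic component
  switched off (epistemic weight 0); everything else identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .agent import ActiveInferenceAgent, AgentConfig
from .env import ONGOING, SUCCESS
from .priors import PriorConfig

__all__ = [
    "BaselineConfig",
    "DQNAgent",
    "sparse_reward",
    "epsilon_schedule",
    "build_agent",
]

KINDS = ("aif_full", "aif_instrumental_only", "dqn_sparse")


@dataclass
class BaselineConfig:
    """Baseline selector plus the shared agent hyperparameters."""

    kind: str = "dqn_sparse"
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    epsilon_decay_episodes: int = 500
    sparse_reward_success: float = 1.0
    sparse_reward_miss: float = 0.0
    agent: AgentConfig = field(default_factory=AgentConfig)

    def validate(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown agent kind {self.kind!r}; "
                             f"expected one of {KINDS}")
        if self.epsilon_end > self.epsilon_start:
            raise ValueError("epsilon schedule must be non-increasing")
        if self.epsilon_decay_episodes < 0:
            raise ValueError("epsilon_decay_episodes must be >= 0")


def sparse_reward(outcome: str, success_value: float = 1.0,
                  miss_value: float = 0.0) -> float:
    """Terminal-only reward: success -> 1, miss -> 0 by default.

    Non-terminal steps carry zero reward; calling this with an ongoing
    outcome is a usage error (the training loop emits 0 for those directly).
    """
    if outcome == ONGOING:
        raise ValueError("sparse_reward is defined on terminal outcomes only")
    return success_value if outcome == SUCCESS else miss_value


def epsilon_schedule(episode_index: int, config: BaselineConfig) -> float:
    """Linear decay from epsilon_start to epsilon_end over
    epsilon_decay_episodes, constant afterwards."""
    if episode_index < 0:
        raise ValueError("episode_index must be >= 0")
    n = config.epsilon_decay_episodes
    if n == 0 or episode_index >= n:
        return config.epsilon_end
    frac = episode_index / n
    return config.epsilon_start + frac * (config.epsilon_end -
                                          config.epsilon_start)


class DQNAgent(ActiveInferenceAgent):
    """Deep Q-network on the sparse terminal reward.

    Identical network and G-learning update, with the observation head
    disabled (``obs_loss_weight = 0``) and reward replaced by the terminal
    success indicator.  Epsilon is set per-episode by the runner via
    :func:`epsilon_schedule`.
    """

    def __init__(self, baseline: BaselineConfig,
                 rng: Optional[np.random.Generator] = None):
        baseline.validate()
        cfg = replace(baseline.agent,
                      use_epistemic=False,
                      epistemic_weight=0.0,
                      obs_loss_weight=0.0,
                      epsilon=baseline.epsilon_start)
        super().__init__(config=cfg, rng=rng)
        self.baseline = baseline

    def compute_reward(self, obs_next, outcome: str,
                       terminal: bool) -> tuple[float, float, float]:
        if not terminal:
            return 0.0, 0.0, 0.0
        r = sparse_reward(outcome,
                          self.baseline.sparse_reward_success,
                          self.baseline.sparse_reward_miss)
        return r, r, 0.0

    def begin_episode(self, episode_index: int) -> None:
        self.epsilon = epsilon_schedule(episode_index, self.baseline)


def build_agent(config: BaselineConfig,
                prior: Optional[PriorConfig] = None,
                rng: Optional[np.random.Generator] = None):
    """Construct an agent by kind: full AIF, instrumental-only AIF, or DQN."""
    config.validate()
    if config.kind == "dqn_sparse":
        return DQNAgent(config, rng=rng)
    if config.kind == "aif_instrumental_only":
        cfg = replace(config.agent, use_epistemic=False, epistemic_weight=0.0)
        return ActiveInferenceAgent(config=cfg, prior=prior, rng=rng)
    return ActiveInferenceAgent(config=config.agent, prior=prior, rng=rng)
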