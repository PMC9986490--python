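"""G-learning active inference agent.

The agent estimates negative expected free energy (EFE) per action with the
joint two-headed network and learns by a Q-learning-style bootstrap ("G-
learning"): each step it stores the transition (o_t, a_t, r_t, o_{t+1}) in a
replay buffer and takes one gradient step on a uniformly sampled batch, with
bootstrap targets computed through a periodically synchronized frozen copy of
the network.  The per-step reward is the sum of an instrumental term (prior
preference log-likelihood over speed difference) and an epistemic term (the
transition head's squared prediction error on the realized next observation).
Action selection is greedy on the G-values — maximal negative EFE, i.e.,
minimal EFE — with an optional epsilon-greedy mixture.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .network import JointModel, Adam
from .priors import PriorConfig, instrumental_reward
from .replay import ReplayBuffer

__all__ = [
    "AgentConfig",
    "ActiveInferenceAgent",
    "select_action",
    "epistemic_reward",
    "efe_target",
]

#: Per-coordinate observation normalization: distances / 50 m, speeds / 20 m/s.
OBS_SCALE = np.array([50.0, 20.0, 50.0, 20.0], dtype=np.float32)


@dataclass
class AgentConfig:
    """Learning hyperparameters of the G-learning agent."""

    gamma: float = 0.99
    learning_rate: float = 1e-3
    batch_size: int = 64
    buffer_capacity: int = 100_000
    target_sync_interval: int = 1000
    warmup_transitions: int = 1000
    epistemic_weight: float = 1.0
    use_epistemic: bool = True
    hidden_sizes: tuple[int, int] = (128, 64)
    sigma_a: float = 1.0
    sigma_o: float = 1.0
    obs_loss_weight: float = 1.0
    epsilon: float = 0.05
    bias: bool = True
    update_every: int = 1
    seed: Optional[int] = None

    def validate(self) -> None:
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError(f"gamma must be in [0, 1), got {self.gamma}")
        if self.buffer_capacity < self.batch_size:
            raise ValueError("buffer_capacity must be >= batch_size")
        if self.sigma_a <= 0 or self.sigma_o <= 0:
            raise ValueError("sigma_a and sigma_o must be positive")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")
        if self.update_every < 1:
            raise ValueError("update_every must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_sizes"] = list(d["hidden_sizes"])
        return d


def select_action(g_values: np.ndarray,
                  rng: Optional[np.random.Generator] = None,
                  epsilon: float = 0.0) -> int:
    """Greedy action on G-values (ties to the lowest index), optionally
    epsilon-greedy."""
    g = np.asarray(g_values).ravel()
    if g.size == 0:
        raise ValueError("empty G-value vector")
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite G-values")
    if epsilon > 0.0:
        if rng is None:
            raise ValueError("epsilon-greedy selection needs an rng")
        if rng.random() < epsilon:
            return int(rng.integers(0, g.size))
    return int(np.argmax(g))


def epistemic_reward(predicted_obs: np.ndarray, actual_obs: np.ndarray,
                     weight: float = 1.0) -> float:
    """Squared prediction error of the transition head (both inputs in the
    same normalization), scaled by ``weight``."""
    p = np.asarray(predicted_obs, dtype=float).ravel()
    a = np.asarray(actual_obs, dtype=float).ravel()
    if p.shape != a.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {a.shape}")
    d = p - a
    return float(weight * np.dot(d, d))


def efe_target(g_online: np.ndarray, g_frozen_next: np.ndarray,
               actions: np.ndarray, rewards: np.ndarray,
               terminal: np.ndarray, gamma: float) -> np.ndarray:
    """Bootstrap target matrix for a batch.

    For the taken action: ``r + gamma * max_a g_frozen(o_next)``, with no
    bootstrap at terminal transitions.  For non-taken actions the target is
    the online network's own current estimate, so their residual is zero and
    only the taken action drives the G-head loss.
    """
    if g_online.ndim != 2:
        raise ValueError("g_online must be (batch, n_actions)")
    T = g_online.copy()
    boot = np.max(g_frozen_next, axis=1)
    tj = rewards + gamma * boot * (~np.asarray(terminal, dtype=bool))
    T[np.arange(T.shape[0]), np.asarray(actions, dtype=int)] = tj
    return T


class ActiveInferenceAgent:
    """Full AIF agent: joint model + replay + target network + G-learning.

    The instrumental-only ablation is the same agent with
    ``use_epistemic=False`` (equivalently epistemic weight 0); the reward
    bookkeeping is the only code path that differs.
    """

    def __init__(self, config: Optional[AgentConfig] = None,
                 prior: Optional[PriorConfig] = None,
                 rng: Optional[np.random.Generator] = None):
        self.config = config or AgentConfig()
        self.config.validate()
        self.prior = prior or PriorConfig()
        self.prior.validate()
        if rng is None:
            rng = np.random.default_rng(self.config.seed)
        self.rng = rng
        self.model = JointModel(hidden_sizes=self.config.hidden_sizes,
                                bias=self.config.bias, rng=self.rng)
        self.target_model = self.model.copy()
        self.optimizer = Adam(self.model.n_params,
                              lr=self.config.learning_rate)
        self.buffer = ReplayBuffer(self.config.buffer_capacity,
                                   obs_dim=self.model.obs_dim)
        self.step_count = 0       # environment transitions observed
        self.update_count = 0     # gradient updates taken
        self._last_prediction: Optional[np.ndarray] = None
        self.epsilon = self.config.epsilon

    # -- acting --------------------------------------------------------------

    def normalize(self, obs) -> np.ndarray:
        return np.asarray(obs, dtype=np.float32) / OBS_SCALE

    def act(self, obs, greedy: bool = False) -> int:
        """Select a pedal action for a raw observation.

        Caches the transition head's prediction of the next (normalized)
        observation for the epistemic reward of the upcoming transition.
        """
        x = self.normalize(obs)
        g, o_pred = self.model.forward(x)
        self._last_prediction = o_pred[0]
        eps = 0.0 if greedy else self.epsilon
        return select_action(g[0], rng=self.rng, epsilon=eps)

    # -- rewards -------------------------------------------------------------

    def compute_reward(self, obs_next, outcome: str,
                       terminal: bool) -> tuple[float, float, float]:
        """Total, instrumental, epistemic reward for the realized transition."""
        r_i = instrumental_reward(obs_next, self.prior)
        if self.config.use_epistemic and self._last_prediction is not None:
            r_e = epistemic_reward(self._last_prediction,
                                   self.normalize(obs_next),
                                   self.config.epistemic_weight)
        else:
            r_e = 0.0
        return r_i + r_e, r_i, r_e

    # -- learning ------------------------------------------------------------

    def observe(self, obs, action: int, reward: float, obs_next,
                terminal: bool, train: bool = True) -> None:
        """Store a transition (normalized observations) and learn.

        One gradient update per environment step once the warm-up fill is
        reached; the frozen target network is re-synchronized every
        ``target_sync_interval`` environment steps.
        """
        self.buffer.store(self.normalize(obs), action, reward,
                          self.normalize(obs_next), terminal)
        self.step_count += 1
        if (train
                and len(self.buffer) >= max(self.config.warmup_transitions,
                                            self.config.batch_size)
                and self.step_count % self.config.update_every == 0):
            self.train_step()
        if self.step_count % self.config.target_sync_interval == 0:
            self.sync_target()

    def train_step(self, batch=None) -> float:
        """One gradient update on a replayed batch; returns the batch loss."""
        cfg = self.config
        if batch is None:
            if len(self.buffer) < cfg.batch_size:
                raise RuntimeError("replay buffer below batch size; "
                                   "agent still warming up")
            batch = self.buffer.sample(cfg.batch_size, self.rng)
        obs, actions, rewards, next_obs, terminal = batch
        B = obs.shape[0]

        G, O, cache = self.model.forward(obs, cache=True)
        g_frozen_next = self.target_model.g_values(next_obs)
        T = efe_target(G, g_frozen_next, actions, rewards, terminal,
                       cfg.gamma)

        dG = (G - T) / (cfg.sigma_a ** 2 * B)
        dO = cfg.obs_loss_weight * (O - next_obs) / (cfg.sigma_o ** 2 * B)
        grad = self.model.backward(cache, dG, dO)
        self.optimizer.step(self.model.theta, grad)
        self.update_count += 1

        ra = G[np.arange(B), actions] - T[np.arange(B), actions]
        ro = O - next_obs
        la = float(np.dot(ra, ra)) / (2.0 * cfg.sigma_a ** 2)
        lo = cfg.obs_loss_weight * float(np.sum(ro * ro)) / (2.0 * cfg.sigma_o ** 2)
        return (la + lo) / B

    def sync_target(self) -> None:
        """Copy online parameters into the frozen target network."""
        self.target_model.load_theta(self.model.theta)

    # -- checkpointing -------------------------------------------------------

    def save(self, path) -> None:
        """Write a checkpoint (weights, optimizer, counters, config echo,
        rng state) that round-trips bit-exactly."""
        meta = {
            "config": self.config.to_dict(),
            "prior": asdict(self.prior),
            "step_count": self.step_count,
            "update_count": self.update_count,
            "epsilon": self.epsilon,
            "rng_state": self.rng.bit_generator.state,
        }
        np.savez(path,
                 theta=self.model.theta,
                 target_theta=self.target_model.theta,
                 adam_m=self.optimizer.m,
                 adam_v=self.optimizer.v,
                 adam_t=np.array(self.optimizer.t),
                 meta=np.frombuffer(
                     json.dumps(meta).encode(), dtype=np.uint8))

    @classmethod
    def load(cls, path) -> "ActiveInferenceAgent":
        with np.load(path) as ckpt:
            meta = json.loads(bytes(ckpt["meta"]).decode())
            cfg_d = dict(meta["config"])
            cfg_d["hidden_sizes"] = tuple(cfg_d["hidden_sizes"])
            config = AgentConfig(**cfg_d)
            prior = PriorConfig(**meta["prior"])
            agent = cls(config=config, prior=prior)
            agent.model.load_theta(ckpt["theta"].copy())
            agent.target_model.load_theta(ckpt["target_theta"].copy())
            agent.optimizer.load_state_dict({"m": ckpt["adam_m"].copy(),
                                             "v": ckpt["adam_v"].copy(),
                                             "t": int(ckpt["adam_t"])})
            agent.step_count = int(meta["step_count"])
            agent.update_count = int(meta["update_count"])
            agent.epsilon = float(meta["epsilon"])
            agent.rng.bit_generator.state = meta["rng_state"]
        return agent
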