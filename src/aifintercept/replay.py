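"""FIFO experience replay buffer with uniform sampling."""

from __future__ import annotations

import numpy as np

__all__ = ["ReplayBuffer"]


class ReplayBuffer:
    """Ring buffer over transitions (o_t, a_t, r_t, o_{t+1}, terminal).

    Stores up to ``capacity`` transitions (default 1e5); the oldest is
    evicted first once full.  Batches are drawn uniformly with replacement
    from the current contents.
    """

    def __init__(self, capacity: int = 100_000, obs_dim: int = 4,
                 dtype=np.float32):
        if capacity <= 0:
            raise ValueError("capacity must be positive")
        self.capacity = int(capacity)
        self.obs = np.zeros((self.capacity, obs_dim), dtype=dtype)
        self.actions = np.zeros(self.capacity, dtype=np.int64)
        self.rewards = np.zeros(self.capacity, dtype=dtype)
        self.next_obs = np.zeros((self.capacity, obs_dim), dtype=dtype)
        self.terminal = np.zeros(self.capacity, dtype=bool)
        self._next = 0
        self._size = 0

    def __len__(self) -> int:
        return self._size

    def store(self, o, a: int, r: float, o_next, terminal: bool) -> None:
        i = self._next
        self.obs[i] = o
        self.actions[i] = a
        self.rewards[i] = r
        self.next_obs[i] = o_next
        self.terminal[i] = terminal
        self._next = (i + 1) % self.capacity
        self._size = min(self._size + 1, self.capacity)

    def sample_indices(self, batch_size: int,
                       rng: np.random.Generator) -> np.ndarray:
        if self._size == 0:
            raise RuntimeError("cannot sample from an empty replay buffer")
        return rng.integers(0, self._size, size=batch_size)

    def sample(self, batch_size: int, rng: np.random.Generator):
        """Uniform-with-replacement batch: (obs, actions, rewards, next_obs,
        terminal)."""
        idx = self.sample_indices(batch_size, rng)
        return (self.obs[idx], self.actions[idx], self.rewards[idx],
                self.next_obs[idx], self.terminal[idx])
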