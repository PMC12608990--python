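"""Policy contract and shared configuration."""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np

from menurec.catalog import MenuDay
from menurec.env import HistoryState, Transition


@dataclass
class PolicyConfig:
    """Hyperparameters shared by the learnable policies.

    ``epsilon`` is the exploration rate of the epsilon-greedy policies
    (default 0.15); ``sarsa_alpha`` the SARSA learning rate; ``gamma`` the
    discount factor. DQN-specific settings live in
    :class:`menurec.policies.dqn.DQNConfig`.
    """

    epsilon: float = 0.15
    sarsa_alpha: float = 0.1
    gamma: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must be in [0, 1], got {self.epsilon}")
        if not 0.0 < self.sarsa_alpha <= 1.0:
            raise ValueError(f"sarsa_alpha must be in (0, 1], got {self.sarsa_alpha}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")


class Policy(ABC):
    """A per-course tag recommender that learns from logged interactions."""

    name: str = "policy"

    @abstractmethod
    def recommend(
        self,
        user_id: str,
        state: HistoryState,
        menu: MenuDay,
        rng: np.random.Generator,
    ) -> dict[str, str]:
        """Return one recommended tag per course, all offered on ``menu``."""

    def observe(self, user_id: str, transition: Transition) -> None:
        """Update internal state from a completed user-day interaction."""
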