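"""DQN recommender: LSTM state encoder, replay memory, target network.

The state is the user's selected tags over the last ``d`` days (default 3),
one-hot encoded per course position and padded with zeros for early days.
An action is a (course, tag) pair, encoded as one-hot course plus one-hot
tag. The online network is trained every ``train_every`` recommendations on
a random replay sample against bootstrap targets

    y = r + gamma * max_{a' offered next day} Q_target(s', a'),

the target network is synced every ``target_update_every`` trainings, and
the exploration rate decays by 1 percentage point per training down to a
floor. One network is shared by all users of a group: personalization
enters through the selection history in the state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from menurec.catalog import MenuDay
from menurec.env import HistoryState, Transition
from menurec.policies.base import Policy
from menurec.policies.nets import Adam, LSTMQNetwork
from menurec.tags import COURSES, TAGS

logger = logging.getLogger(__name__)

_TAG_INDEX = {t: i for i, t in enumerate(TAGS)}
_COURSE_INDEX = {c: i for i, c in enumerate(COURSES)}

STATE_DIM = 3 * len(TAGS)  # one-hot tag per course position, per day
ACTION_DIM = len(COURSES) + len(TAGS)


def encode_window(window: tuple[tuple[str, str, str], ...], d: int) -> np.ndarray:
    """(d, 36) encoding of the last ``d`` days; missing days are zero rows."""
    out = np.zeros((d, STATE_DIM))
    recent = window[-d:]
    offset = d - len(recent)
    for row, day in enumerate(recent):
        for c, tag in enumerate(day):
            out[offset + row, c * len(TAGS) + _TAG_INDEX[tag]] = 1.0
    return out


def encode_action(course: str, tag: str) -> np.ndarray:
    out = np.zeros(ACTION_DIM)
    out[_COURSE_INDEX[course]] = 1.0
    out[len(COURSES) + _TAG_INDEX[tag]] = 1.0
    return out


@dataclass(frozen=True)
class StoredTransition:
    """A completed interaction ready for replay."""

    state: np.ndarray  # (d, 36)
    action: np.ndarray  # (15,)
    reward: float  # training-scale reward
    next_state: np.ndarray  # (d, 36)
    next_actions: tuple[np.ndarray, ...]  # candidate encodings offered next day


class ReplayMemory:
    """Bounded transition store with sampling without replacement."""

    def __init__(self, capacity: int | None = None):
        self.capacity = capacity
        self._items: list[StoredTransition] = []

    def __len__(self) -> int:
        return len(self._items)

    def push(self, item: StoredTransition) -> None:
        self._items.append(item)
        if self.capacity is not None and len(self._items) > self.capacity:
            self._items.pop(0)

    def sample(self, k: int, rng: np.random.Generator) -> list[StoredTransition]:
        k = min(k, len(self._items))
        idx = rng.choice(len(self._items), size=k, replace=False)
        return [self._items[i] for i in idx]


@dataclass
class DQNConfig:
    window_days: int = 3
    lstm_neurons: int = 32
    hidden_neurons: int = 16
    learning_rate: float = 5e-4
    train_every: int = 20  # recommendations between training passes
    epochs_per_training: int = 24  # minibatch updates per training pass
    batch_size: int = 64  # transitions per gradient step
    replay_sample_size: int = 30
    target_update_every: int = 3  # trainings between target syncs
    positive_reward: float = 1.0
    negative_reward: float = 0.0
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    gamma: float = 0.25
    epsilon: float = 0.15
    epsilon_decay: float = 0.01  # per training
    epsilon_floor: float = 0.01
    burn_in_day: int = 10  # first day on which training may run
    max_train_steps: int = 15000  # cap on total gradient steps
    replay_capacity: int | None = None
    dropout_rate: float = 0.2

    def __post_init__(self) -> None:
        if not 0 <= self.epsilon <= 1:
            raise ValueError(f"epsilon must be in [0, 1], got {self.epsilon}")
        if not 0 <= self.gamma <= 1:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        for name in ("window_days", "lstm_neurons", "hidden_neurons", "train_every",
                     "replay_sample_size", "target_update_every", "max_train_steps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class DQNPolicy(Policy):
    name = "dqn"

    def __init__(self, config: DQNConfig | None = None, rng: np.random.Generator | None = None):
        self.config = config if config is not None else DQNConfig()
        init_rng = rng if rng is not None else np.random.default_rng()
        self.net = LSTMQNetwork(
            STATE_DIM,
            ACTION_DIM,
            lstm_units=self.config.lstm_neurons,
            hidden_units=self.config.hidden_neurons,
            rng=init_rng,
        )
        self.target_net = self.net.copy()
        self.optimizer = Adam(
            self.net.params,
            lr=self.config.learning_rate,
            beta1=self.config.adam_beta1,
            beta2=self.config.adam_beta2,
        )
        self.memory = ReplayMemory(self.config.replay_capacity)
        self.epsilon = self.config.epsilon
        self.rec_count = 0
        self.train_count = 0  # training passes (drives epsilon decay / target sync)
        self.grad_steps = 0  # total gradient steps (capped by max_train_steps)
        self.current_day = 0
        # pending[(user_id, course)] = (state, action, reward) awaiting next state
        self._pending: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, float]] = {}

    # -- acting ---------------------------------------------------------

    def q_values(self, state_enc: np.ndarray, action_encs: list[np.ndarray],
                 network: LSTMQNetwork | None = None) -> np.ndarray:
        net = network if network is not None else self.net
        B = len(action_encs)
        states = np.repeat(state_enc[None, :, :], B, axis=0)
        return net.forward(states, np.stack(action_encs))

    def recommend(self, user_id, state: HistoryState, menu: MenuDay, rng: np.random.Generator) -> dict[str, str]:
        self.current_day = state.day
        state_enc = encode_window(state.window, self.config.window_days)
        out: dict[str, str] = {}
        for course in COURSES:
            offered = sorted(set(menu.tags(course)))
            self._finalize_pending(user_id, course, state_enc, offered)
            if rng.random() < self.epsilon:
                out[course] = offered[int(rng.integers(len(offered)))]
            else:
                encs = [encode_action(course, t) for t in offered]
                q = self.q_values(state_enc, encs)
                out[course] = offered[int(np.argmax(q))]  # first max = alphabetical tie-break
            self.rec_count += 1
            if self.rec_count % self.config.train_every == 0:
                self.train_step(rng)
        return out

    def observe(self, user_id, transition: Transition) -> None:
        state_enc = encode_window(transition.state.window, self.config.window_days)
        for course in COURSES:
            action_enc = encode_action(course, transition.recommended[course])
            reward = (
                self.config.positive_reward
                if transition.reward[course]
                else self.config.negative_reward
            )
            self._pending[(user_id, course)] = (state_enc, action_enc, reward)

    def _finalize_pending(self, user_id: str, course: str, next_state_enc: np.ndarray,
                          offered: list[str]) -> None:
        key = (user_id, course)
        pend = self._pending.pop(key, None)
        if pend is None:
            return
        s, a, r = pend
        next_actions = tuple(encode_action(course, t) for t in offered)
        self.memory.push(StoredTransition(s, a, r, next_state_enc, next_actions))

    # -- learning -------------------------------------------------------

    def train_step(self, rng: np.random.Generator) -> bool:
        """One optimization pass on a replay sample; returns False when skipped."""
        cfg = self.config
        if (
            len(self.memory) < cfg.replay_sample_size
            or self.current_day < cfg.burn_in_day
            or self.grad_steps >= cfg.max_train_steps
        ):
            logger.debug("training skipped (memory=%d, day=%d, steps=%d)",
                         len(self.memory), self.current_day, self.grad_steps)
            return False
        for _ in range(cfg.epochs_per_training):
            if self.grad_steps >= cfg.max_train_steps:
                break
            batch = self.memory.sample(cfg.batch_size, rng)
            states = np.stack([t.state for t in batch])
            actions = np.stack([t.action for t in batch])
            rewards = np.array([t.reward for t in batch])

            # bootstrap: max over each transition's next-day candidate actions
            if cfg.gamma > 0:
                flat_states, flat_actions, owner = [], [], []
                for i, t in enumerate(batch):
                    for a2 in t.next_actions:
                        flat_states.append(t.next_state)
                        flat_actions.append(a2)
                        owner.append(i)
                q_next = self.target_net.forward(np.stack(flat_states), np.stack(flat_actions))
                max_next = np.full(len(batch), -np.inf)
                for qi, i in zip(q_next, owner):
                    max_next[i] = max(max_next[i], qi)
                targets = rewards + cfg.gamma * max_next
            else:
                targets = rewards

            _, grads = self.net.mse_gradients(states, actions, targets,
                                              dropout_rate=cfg.dropout_rate, rng=rng)
            self.optimizer.step(self.net.params, grads)
            self.grad_steps += 1
        self.train_count += 1
        self.epsilon = max(self.epsilon - cfg.epsilon_decay, cfg.epsilon_floor)
        if self.train_count % cfg.target_update_every == 0:
            self.target_net.sync_from(self.net)
        return True
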