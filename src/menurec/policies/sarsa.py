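"""Tabular SARSA over (last selected tag, candidate tag) per course.

The state for each course is the tag the user last selected for that course
(a reserved "none" row before the first day). The on-policy update

    Q(s, a) <- Q(s, a) + alpha * (r + gamma * Q(s', a') - Q(s, a))

needs the *next* chosen action a', so each observed day is held pending and
applied when the next day's recommendation for that course is drawn.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from menurec.catalog import MenuDay
from menurec.env import HistoryState, Transition
from menurec.policies.base import Policy, PolicyConfig
from menurec.tags import COURSES

NONE_TAG = "__none__"


def sarsa_update(
    q: dict[tuple[str, str], float],
    s: str,
    a: str,
    reward: float,
    s2: str,
    a2: str,
    alpha: float,
    gamma: float,
) -> None:
    """In-place SARSA temporal-difference update on one table."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    td_target = reward + gamma * q.get((s2, a2), 0.0)
    q[(s, a)] = q.get((s, a), 0.0) + alpha * (td_target - q.get((s, a), 0.0))


class SarsaPolicy(Policy):
    name = "sarsa"

    def __init__(self, config: PolicyConfig | None = None, scope: str = "per_user"):
        if scope not in ("per_user", "shared"):
            raise ValueError(f"scope must be 'per_user' or 'shared', got {scope!r}")
        self.config = config if config is not None else PolicyConfig()
        self.scope = scope
        # tables[scope_key][course][(s_tag, a_tag)] -> Q
        self.tables: dict[str, dict[str, dict[tuple[str, str], float]]] = defaultdict(
            lambda: {c: {} for c in COURSES}
        )
        # pending[scope_key][course] = (s, a, r, s')
        self.pending: dict[str, dict[str, tuple[str, str, float, str]]] = defaultdict(dict)
        self.last_selected: dict[str, dict[str, str]] = defaultdict(lambda: {c: NONE_TAG for c in COURSES})

    def _key(self, user_id: str) -> str:
        return user_id if self.scope == "per_user" else "__shared__"

    def recommend(self, user_id, state: HistoryState, menu: MenuDay, rng: np.random.Generator) -> dict[str, str]:
        key = self._key(user_id)
        tables = self.tables[key]
        out: dict[str, str] = {}
        for course in COURSES:
            offered = sorted(set(menu.tags(course)))
            s = self.last_selected[key][course]
            if rng.random() < self.config.epsilon:
                action = offered[int(rng.integers(len(offered)))]
            else:
                q = tables[course]
                best = max(q.get((s, t), 0.0) for t in offered)
                action = min(t for t in offered if q.get((s, t), 0.0) == best)
            out[course] = action
            # the freshly chosen action completes the pending (s, a, r, s') tuple
            if course in self.pending[key]:
                ps, pa, pr, ps2 = self.pending[key].pop(course)
                sarsa_update(tables[course], ps, pa, pr, ps2, action, self.config.sarsa_alpha, self.config.gamma)
        return out

    def observe(self, user_id, transition: Transition) -> None:
        key = self._key(user_id)
        for course in COURSES:
            s = self.last_selected[key][course]
            a = transition.recommended[course]
            r = float(transition.reward[course])
            s2 = transition.selected[course]
            self.pending[key][course] = (s, a, r, s2)
            self.last_selected[key][course] = s2
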