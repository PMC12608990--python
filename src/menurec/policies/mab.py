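"""Epsilon-greedy multi-armed bandit over (course, tag) propensities.

Two update rules are available. The default, ``"match"``, is bandit
feedback: ``p_i`` is the empirical match rate of tag ``i`` when it was
recommended — only a match between recommendation and selection increases
``p_i``. The alternative, ``"selection"``, is full information: ``p_i`` is
the running frequency with which the user selected tag ``i``, regardless of
what was recommended (it converges to the same argmax because selections do
not depend on the recommendation, but it learns faster). Recommendations
are epsilon-greedy over the tags offered each day; updates happen daily.
The bandit keeps one state per user by default (``scope="shared"`` pools
all users).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from menurec.catalog import MenuDay
from menurec.env import HistoryState, Transition
from menurec.policies.base import Policy, PolicyConfig
from menurec.tags import COURSES


@dataclass
class MABState:
    """Per-(course, tag) counts for one scope (user or pooled)."""

    rec_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {c: defaultdict(int) for c in COURSES}
    )
    match_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {c: defaultdict(int) for c in COURSES}
    )
    sel_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {c: defaultdict(int) for c in COURSES}
    )
    days: dict[str, int] = field(default_factory=lambda: {c: 0 for c in COURSES})

    def propensity(self, course: str, tag: str, update_rule: str = "match") -> float:
        if update_rule == "match":
            n = self.rec_counts[course][tag]
            return self.match_counts[course][tag] / n if n else 0.0
        n = self.days[course]
        return self.sel_counts[course][tag] / n if n else 0.0

    def update(self, course: str, recommended_tag: str, selected_tag: str) -> None:
        self.rec_counts[course][recommended_tag] += 1
        if recommended_tag == selected_tag:
            self.match_counts[course][recommended_tag] += 1
        self.sel_counts[course][selected_tag] += 1
        self.days[course] += 1


class MABPolicy(Policy):
    name = "mab"

    def __init__(self, config: PolicyConfig | None = None, scope: str = "per_user",
                 update_rule: str = "match"):
        if scope not in ("per_user", "shared"):
            raise ValueError(f"scope must be 'per_user' or 'shared', got {scope!r}")
        if update_rule not in ("match", "selection"):
            raise ValueError(f"update_rule must be 'match' or 'selection', got {update_rule!r}")
        self.config = config if config is not None else PolicyConfig()
        self.scope = scope
        self.update_rule = update_rule
        self.states: dict[str, MABState] = defaultdict(MABState)

    def _state(self, user_id: str) -> MABState:
        return self.states[user_id if self.scope == "per_user" else "__shared__"]

    def recommend(self, user_id, state: HistoryState, menu: MenuDay, rng: np.random.Generator) -> dict[str, str]:
        mab = self._state(user_id)
        out: dict[str, str] = {}
        for course in COURSES:
            offered = sorted(set(menu.tags(course)))
            if rng.random() < self.config.epsilon:
                out[course] = offered[int(rng.integers(len(offered)))]
            else:
                # greedy; ties (typically the all-zero start) broken at random
                p = np.array([mab.propensity(course, t, self.update_rule) for t in offered])
                ties = np.flatnonzero(p == p.max())
                out[course] = offered[int(ties[rng.integers(len(ties))])]
        return out

    def observe(self, user_id, transition: Transition) -> None:
        mab = self._state(user_id)
        for course in COURSES:
            mab.update(course, transition.recommended[course], transition.selected[course])
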