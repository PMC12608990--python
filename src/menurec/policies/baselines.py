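"""Random baseline and the Optimum oracle."""

from __future__ import annotations

import numpy as np

from menurec.catalog import MenuDay
from menurec.env import HistoryState, selection_weights
from menurec.policies.base import Policy
from menurec.profiles import UserProfile
from menurec.tags import COURSES


class RandomPolicy(Policy):
    """Recommends the tag of a uniformly chosen option per course.

    Under 3/3/2 option menus with distinct tags per course, the expected
    daily reward against any user is 1/3 + 1/3 + 1/2 = 7/6, independent of
    the user's preferences.
    """

    name = "random"

    def recommend(self, user_id, state: HistoryState, menu: MenuDay, rng: np.random.Generator) -> dict[str, str]:
        return {
            course: menu.options[course][int(rng.integers(len(menu.options[course])))].tag
            for course in COURSES
        }


class OptimumPolicy(Policy):
    """Oracle: recommends the offered tag with the maximal true selection weight.

    Uses the same effective weights as the selection simulator (taste times
    the innovation multiplier, diet permission included), so it upper-bounds
    the expected reward of any policy that can only recommend offered tags.
    Ties are broken by tag alphabetical order; fully deterministic.
    """

    name = "optimum"

    def __init__(self, profiles: dict[str, UserProfile]):
        self.profiles = profiles

    def recommend(self, user_id, state: HistoryState, menu: MenuDay, rng: np.random.Generator) -> dict[str, str]:
        profile = self.profiles[user_id]
        out: dict[str, str] = {}
        for course in COURSES:
            options = menu.options[course]
            weights = selection_weights(profile, options)
            # argmax with alphabetical tie-break on the tag
            order = sorted(range(len(options)), key=lambda i: (-weights[i], options[i].tag))
            best = order[0]
            out[course] = options[best].tag
        return out
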