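"""Daily selection simulation, match rewards, and the history-window state.

Users choose one option per course with probability proportional to their
taste for the option's tag, with innovative dishes' weights multiplied by
``(0.5 + innovation)`` before renormalization. Vegetarian and vegan users
only consider vegetarian-flagged dishes (vegan strictness beyond that is
already expressed by their zeroed animal-tag tastes). A recommendation earns
reward 1 per course when the recommended tag equals the tag of the dish the
user actually selected, so the daily reward lies in {0, 1, 2, 3}.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from menurec.catalog import Dish, MenuDay
from menurec.profiles import UserProfile
from menurec.tags import COURSES


class NoPermittedOptionError(RuntimeError):
    """A user's diet permits none of the offered options (should not occur
    under the menu sampler's vegetarian guarantee)."""


@dataclass(frozen=True)
class HistoryState:
    """Rolling window of a user's last ``w`` daily selections (3 tags per day)."""

    user_id: str
    window: tuple[tuple[str, str, str], ...] = ()
    day: int = 0
    w: int = 3

    def __post_init__(self) -> None:
        if len(self.window) > self.w:
            raise ValueError(f"window length {len(self.window)} exceeds w={self.w}")


@dataclass(frozen=True)
class Transition:
    """One user-day interaction: recommendations, selections, per-course rewards."""

    state: HistoryState
    recommended: dict[str, str]  # course -> tag
    selected: dict[str, str]  # course -> selected dish tag
    reward: dict[str, int]  # course -> 0/1
    next_state: HistoryState


def selection_weights(profile: UserProfile, options: tuple[Dish, ...]) -> np.ndarray:
    """Unnormalized selection weights for one course's options."""
    weights = np.empty(len(options))
    for i, dish in enumerate(options):
        permitted = dish.vegetarian if profile.diet in ("vegetarian", "vegan") else True
        w = profile.tastes[dish.tag] if permitted else 0.0
        if dish.innovative:
            w *= 0.5 + profile.innovation
        weights[i] = w
    return weights


def simulate_selection(
    profile: UserProfile,
    menu: MenuDay,
    rng: np.random.Generator,
) -> dict[str, Dish]:
    """One dish per course, sampled from the renormalized taste weights.

    Options with weight 0 are never chosen unless every option has weight 0,
    in which case the user picks uniformly among diet-permitted options.
    """
    chosen: dict[str, Dish] = {}
    for course in COURSES:
        options = menu.options[course]
        weights = selection_weights(profile, options)
        total = weights.sum()
        if total > 0:
            p = weights / total
        else:
            permitted = np.array(
                [d.vegetarian if profile.diet in ("vegetarian", "vegan") else True for d in options],
                dtype=float,
            )
            if permitted.sum() == 0:
                raise NoPermittedOptionError(
                    f"user {profile.user_id} ({profile.diet}): no permitted option for course {course!r}"
                )
            p = permitted / permitted.sum()
        chosen[course] = options[int(rng.choice(len(options), p=p))]
    return chosen


def compute_reward(recommended: dict[str, str], selected: dict[str, Dish]) -> dict[str, int]:
    """Per-course match reward: 1 if the recommended tag equals the selected dish's tag."""
    return {course: int(recommended[course] == selected[course].tag) for course in COURSES}


def advance_state(state: HistoryState, selections: dict[str, Dish]) -> HistoryState:
    """Append the day's 3 selected tags, dropping the oldest beyond the window size."""
    entry = tuple(selections[c].tag for c in COURSES)
    window = (*state.window, entry)[-state.w :]
    return replace(state, window=window, day=state.day + 1)
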