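"""Exhaustive grid search over policy hyperparameters.

Generic on purpose: the caller supplies an evaluation function mapping a
configuration dict to an accumulated reward (typically a reduced benchmark
run); the grid is the cartesian product of the listed values; each point is
evaluated over ``repetitions`` seeded runs and the mean decides the winner.
"""

from __future__ import annotations

from itertools import product
from typing import Callable

import numpy as np
import pandas as pd


def grid_search(
    space: dict[str, list],
    evaluate: Callable[[dict, np.random.Generator], float],
    repetitions: int = 3,
    rng: np.random.Generator | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Return the configuration maximizing mean accumulated reward, plus all results.

    ``space`` maps parameter name to candidate values; the search is
    exhaustive over the cartesian product. The returned DataFrame holds one
    row per configuration with per-repetition rewards and their mean.
    """
    if not space or any(len(v) == 0 for v in space.values()):
        raise ValueError("search space must be non-empty")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    rng = rng if rng is not None else np.random.default_rng()
    names = list(space)
    rows = []
    best_config: dict | None = None
    best_mean = -np.inf
    for values in product(*(space[n] for n in names)):
        config = dict(zip(names, values))
        rewards = [evaluate(config, np.random.default_rng(rng.integers(2**31))) for _ in range(repetitions)]
        mean = float(np.mean(rewards))
        rows.append({**config, "mean_reward": mean, **{f"rep_{i}": r for i, r in enumerate(rewards)}})
        if mean > best_mean:
            best_mean = mean
            best_config = config
    return best_config, pd.DataFrame(rows)
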