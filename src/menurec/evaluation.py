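"""Evaluation metrics and pairwise population comparisons.

From a run log (one row per algorithm x group x user x day x course) the
suite computes, per algorithm and group: the accumulated reward (mean and
sample standard deviation of per-user total matches), the improvement over
the random baseline, the efficiency (mean correct courses per day, out of
3), and macro-averaged precision / recall / F1 treating the recommended tag
as the predicted label and the selected tag as the true label. Populations
are compared pairwise with a two-sided Mann-Whitney U test and Cliff's
delta, both on absolute per-user rewards and on per-user (Optimum - algorithm)
gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support

from menurec.tags import COURSES

REQUIRED_COLUMNS = ("algorithm", "group", "user_id", "day", "course", "recommended_tag", "selected_tag", "match")


def _subset(log: pd.DataFrame, algorithm: str | None = None, group: str | None = None) -> pd.DataFrame:
    sub = log
    if algorithm is not None:
        sub = sub[sub["algorithm"] == algorithm]
    if group is not None:
        sub = sub[sub["group"] == group]
    if sub.empty:
        raise ValueError(f"run log has no rows for algorithm={algorithm!r}, group={group!r}")
    return sub


def per_user_totals(log: pd.DataFrame, algorithm: str, group: str) -> pd.Series:
    """Total matches per user over all days and courses."""
    sub = _subset(log, algorithm, group)
    return sub.groupby("user_id")["match"].sum().astype(float)


def accumulated_reward_stats(log: pd.DataFrame, algorithm: str, group: str) -> tuple[float, float]:
    """Mean and sample standard deviation (ddof=1) of per-user total rewards.

    With a single user the standard deviation is undefined; 0.0 is returned
    by convention.
    """
    totals = per_user_totals(log, algorithm, group)
    mean = float(totals.mean())
    std = float(totals.std(ddof=1)) if len(totals) > 1 else 0.0
    return mean, std


def improvement(reward_alg: float, reward_random: float) -> float:
    """Percent increase of an algorithm's accumulated reward over the random baseline."""
    if reward_random <= 0:
        raise ValueError(f"random baseline must be positive, got {reward_random}")
    return 100.0 * (reward_alg - reward_random) / reward_random


def efficiency(log: pd.DataFrame, algorithm: str, group: str) -> float:
    """Mean number of correctly recommended courses per user-day, in [0, 3]."""
    sub = _subset(log, algorithm, group)
    n_user_days = len(sub[["user_id", "day"]].drop_duplicates())
    return float(sub["match"].sum() / n_user_days)


def classification_metrics(
    log: pd.DataFrame,
    algorithm: str | None = None,
    group: str | None = None,
    average: str = "macro",
) -> tuple[float, float, float]:
    """(precision, recall, F1), macro-averaged over tags within each course
    and then averaged over courses (``average="micro"`` pools instances
    instead)."""
    sub = _subset(log, algorithm, group)
    per_course = []
    for course in COURSES:
        rows = sub[sub["course"] == course]
        if rows.empty:
            continue
        y_true = rows["selected_tag"]
        y_pred = rows["recommended_tag"]
        p, r, f1, _ = precision_recall_fscore_support(
            y_true, y_pred, average=average, zero_division=0
        )
        per_course.append((p, r, f1))
    arr = np.array(per_course)
    p, r, f1 = arr.mean(axis=0)
    return float(p), float(r), float(f1)


def cliffs_delta(x, y) -> float:
    """Cliff's delta: (#{x_i > y_j} - #{x_i < y_j}) / (|x| * |y|), in [-1, 1].

    Positive when values in ``x`` tend to be larger than values in ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    diff = x[:, None] - y[None, :]
    return float((np.sign(diff)).sum() / (x.size * y.size))


@dataclass(frozen=True)
class PairwiseStats:
    """Symmetric p-value matrix and antisymmetric Cliff's-delta matrix over groups."""

    groups: tuple[str, ...]
    p_values: pd.DataFrame
    deltas: pd.DataFrame


def _pairwise(samples: dict[str, np.ndarray], test: str = "mannwhitney") -> PairwiseStats:
    groups = tuple(samples)
    p = pd.DataFrame(np.ones((len(groups), len(groups))), index=groups, columns=groups)
    d = pd.DataFrame(np.zeros((len(groups), len(groups))), index=groups, columns=groups)
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            if i >= j:
                continue
            x, y = samples[gi], samples[gj]
            if test == "mannwhitney":
                res = stats.mannwhitneyu(x, y, alternative="two-sided")
                pij = float(res.pvalue)
            elif test == "welch":
                pij = float(stats.ttest_ind(x, y, equal_var=False).pvalue)
            else:
                raise ValueError(f"unknown test {test!r}")
            dij = cliffs_delta(x, y)
            p.loc[gi, gj] = p.loc[gj, gi] = pij
            d.loc[gi, gj] = dij
            d.loc[gj, gi] = -dij
    return PairwiseStats(groups=groups, p_values=p, deltas=d)


def pairwise_comparison(
    totals_by_group: dict[str, np.ndarray],
    optimum_by_group: dict[str, np.ndarray] | None = None,
    test: str = "mannwhitney",
) -> dict[str, PairwiseStats]:
    """Pairwise stats on absolute per-user rewards and, when Optimum totals are
    given, on per-user (Optimum - algorithm) gaps.

    Requires at least two groups with at least two users each; gap
    comparisons require per-user alignment (equal lengths, same order).
    """
    if len(totals_by_group) < 2:
        raise ValueError("need at least two groups")
    for g, v in totals_by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 users")
    out = {"absolute": _pairwise({g: np.asarray(v, float) for g, v in totals_by_group.items()}, test)}
    if optimum_by_group is not None:
        gaps = {}
        for g, v in totals_by_group.items():
            opt = np.asarray(optimum_by_group[g], dtype=float)
            alg = np.asarray(v, dtype=float)
            if opt.shape != alg.shape:
                raise ValueError(f"group {g!r}: optimum and algorithm totals misaligned")
            gaps[g] = opt - alg
        out["gap"] = _pairwise(gaps, test)
    return out


def metrics_table(log: pd.DataFrame, baseline_algorithm: str = "random") -> pd.DataFrame:
    """Per (algorithm, group) summary table: accumulated reward mean/std,
    improvement over the same group's random run, efficiency, F1/recall/precision."""
    algorithms = [a for a in log["algorithm"].unique() if a != baseline_algorithm]
    groups = list(log["group"].unique())
    rows = []
    for alg in [*algorithms, baseline_algorithm]:
        for group in groups:
            mean, std = accumulated_reward_stats(log, alg, group)
            base_mean, _ = accumulated_reward_stats(log, baseline_algorithm, group)
            p, r, f1 = classification_metrics(log, alg, group)
            rows.append(
                {
                    "algorithm": alg,
                    "group": group,
                    "accumulated_reward": round(mean, 2),
                    "std_dev": round(std, 2),
                    "improvement_pct": round(improvement(mean, base_mean), 2) if base_mean > 0 else np.nan,
                    "efficiency": round(efficiency(log, alg, group), 2),
                    "f1": round(f1, 4),
                    "recall": round(r, 4),
                    "precision": round(p, 4),
                }
            )
    return pd.DataFrame(rows)
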