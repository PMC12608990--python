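"""Mamdani inference (min-implication, max-aggregation) and centroid defuzzification."""

from __future__ import annotations

import numpy as np

from menurec.fuzzy.rules import Rule, RuleBlock
from menurec.fuzzy.sets import FuzzyVariable


class FuzzyConfigError(ValueError):
    """A rule references a variable or label that is not available."""


class ZeroMassError(ValueError):
    """The aggregated output area has zero mass; the centroid is undefined."""


def infer(
    block: RuleBlock,
    memberships: dict[str, dict[str, float]],
    output: FuzzyVariable,
) -> np.ndarray:
    """Aggregate the clipped consequent sets of all rules targeting ``output``.

    Each rule fires at its weighted antecedent degree (AND = min, OR = max of
    the term degrees); its consequent set is clipped at that degree
    (min-implication); clipped sets are combined by pointwise maximum. The
    result is the aggregated membership sampled on the output variable's
    grid, values in [0, 1]. If no rule fires the area is identically zero.
    """
    rules = block.rules_for_output(output.name)
    area = np.zeros(int(output.universe[2]))
    for rule in rules:
        try:
            degree = rule.firing_degree(memberships)
        except KeyError as exc:
            raise FuzzyConfigError(str(exc)) from exc
        if degree <= 0.0:
            continue
        _, label = rule.consequent
        if label not in output.sets:
            raise FuzzyConfigError(f"output variable {output.name!r} has no set {label!r}")
        np.maximum(area, np.minimum(degree, output.set_on_grid(label)), out=area)
    return area


def defuzzify_centroid(area: np.ndarray, grid: np.ndarray) -> float:
    """Centroid (center of mass) of an aggregated output area.

    Computes ``∫ x·μ(x) dx / ∫ μ(x) dx`` by trapezoidal quadrature over the
    grid. Raises :class:`ZeroMassError` for a zero-mass area; callers
    typically fall back to the universe midpoint.
    """
    area = np.asarray(area, dtype=float)
    mass = np.trapezoid(area, grid)
    if mass <= 0.0:
        raise ZeroMassError("aggregated area has zero mass")
    return float(np.trapezoid(grid * area, grid) / mass)
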