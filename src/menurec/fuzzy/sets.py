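"""Fuzzy variables and membership functions.

A :class:`FuzzyVariable` is a named universe of discourse carrying a family
of overlapping linguistic sets, each with a trapezoidal (or, as a degenerate
case, triangular) membership function. Membership shapes are stored as four
vertices ``(a, b, c, d)``: zero below ``a``, rising linearly to 1 at ``b``,
a plateau to ``c``, falling to zero at ``d``. A triangle is a trapezoid with
``b == c``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def trapezoid_mf(x: np.ndarray, a: float, b: float, c: float, d: float) -> np.ndarray:
    """Trapezoidal membership, vectorized. Vertical edges (a == b) allowed."""
    x = np.asarray(x, dtype=float)
    y = np.zeros_like(x)
    if b > a:
        rising = (x > a) & (x < b)
        y[rising] = (x[rising] - a) / (b - a)
    core = (x >= b) & (x <= c)
    y[core] = 1.0
    if d > c:
        falling = (x > c) & (x < d)
        y[falling] = (d - x[falling]) / (d - c)
    return y


@dataclass(frozen=True)
class FuzzyVariable:
    """A named universe with labelled trapezoidal sets.

    Parameters
    ----------
    name:
        Variable name as referenced by rules (e.g. ``"age"``).
    universe:
        ``(lo, hi, n_points)`` — bounds and grid resolution used for
        aggregation and defuzzification.
    sets:
        Mapping label -> trapezoid vertices ``(a, b, c, d)`` (triangles as
        ``(a, b, b, c)``).
    """

    name: str
    universe: tuple[float, float, int]
    sets: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi, n = self.universe
        if not (hi > lo and n >= 2):
            raise ValueError(f"invalid universe {self.universe} for variable {self.name!r}")
        for label, verts in self.sets.items():
            if len(verts) != 4 or sorted(verts) != list(verts):
                raise ValueError(f"set {label!r} of {self.name!r}: vertices {verts} must be 4 non-decreasing numbers")

    @property
    def grid(self) -> np.ndarray:
        lo, hi, n = self.universe
        return np.linspace(lo, hi, int(n))

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.sets)

    def membership(self, label: str, x) -> np.ndarray:
        """Degree of membership of ``x`` (scalar or array) in set ``label``."""
        a, b, c, d = self.sets[label]
        return trapezoid_mf(np.atleast_1d(x), a, b, c, d)

    def set_on_grid(self, label: str) -> np.ndarray:
        """Membership function of ``label`` sampled on the variable's grid."""
        return self.membership(label, self.grid)


def fuzzify(value: float, variable: FuzzyVariable) -> dict[str, float]:
    """Map a crisp value to its membership degree in every set of ``variable``.

    Raises
    ------
    ValueError
        If ``value`` lies outside the variable's universe.
    """
    lo, hi, _ = variable.universe
    if not (lo <= value <= hi):
        raise ValueError(f"value {value} outside universe [{lo}, {hi}] of variable {variable.name!r}")
    return {label: float(variable.membership(label, value)[0]) for label in variable.sets}


def crisp_memberships(value: str, vocabulary: tuple[str, ...] | list[str]) -> dict[str, float]:
    """Singleton fuzzification of a categorical attribute (degree 1 on its label)."""
    if value not in vocabulary:
        raise ValueError(f"value {value!r} not in vocabulary {tuple(vocabulary)}")
    return {label: 1.0 if label == value else 0.0 for label in vocabulary}
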