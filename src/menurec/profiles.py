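"""Individual food-preference profiles inferred from demographic attributes.

A :class:`ProfileGenerator` wires the three rule blocks (diet, tastes,
innovation) to the input variables (age, gender, coastal/inland region,
locality size) and produces :class:`UserProfile` objects:

* ``diet`` — one of omnivore / flexitarian / vegetarian / vegan, obtained by
  defuzzifying the diet block onto a [0, 1] axis, adding a Gaussian
  perturbation, and partitioning the axis at 0.25 / 0.5 / 0.75;
* ``tastes`` — a probability in [0, 1] for each of the 12 dish tags, with
  hard diet constraints applied afterwards (vegans: all animal-derived tags
  set to 0; vegetarians: meat and fish tags set to 0; flexitarians: meat and
  fish tags damped);
* ``innovation`` — a score in [0, 1]; a user counts as "innovative" at >= 0.5.

The age variable uses five overlapping trapezoids: children (0-16),
teenagers (14-25), youths (22-32), adults (42-70) and seniors (68+). The
published category ranges leave 32-42 uncovered, so the youth and adult
shoulders are extended linearly to cross at 37 so that the universe is
covered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from menurec.fuzzy import (
    FuzzyVariable,
    RuleBlock,
    ZeroMassError,
    crisp_memberships,
    defuzzify_centroid,
    fuzzify,
    infer,
    load_rule_blocks,
)
from menurec.fuzzy.rules import validate_blocks
from menurec.tags import MEAT_TAGS, OVO_LACTO_TAGS, TAGS

logger = logging.getLogger(__name__)

DIET_CLASSES: tuple[str, ...] = ("omnivore", "flexitarian", "vegetarian", "vegan")

GENDERS: tuple[str, ...] = ("female", "male")
REGIONS: tuple[str, ...] = ("coastal", "inland")
LOCALITY_SIZES: tuple[str, ...] = ("small", "medium", "large")

#: Tags forbidden (zeroed) per diet class.
DIET_FORBIDDEN: dict[str, frozenset[str]] = {
    "omnivore": frozenset(),
    "flexitarian": frozenset(),
    "vegetarian": MEAT_TAGS,
    "vegan": MEAT_TAGS | OVO_LACTO_TAGS,
}

#: Diet-axis thresholds: vegan < 0.25 <= vegetarian < 0.5 <= flexitarian < 0.75 <= omnivore.
DIET_THRESHOLDS: tuple[float, float, float] = (0.25, 0.5, 0.75)


def default_variables() -> dict[str, FuzzyVariable]:
    """Input and output fuzzy variables used by the default rule base."""
    unit = (0.0, 1.0, 1001)
    level_sets = {
        "low": (0.0, 0.0, 0.15, 0.35),
        "medium": (0.25, 0.5, 0.5, 0.75),
        "high": (0.65, 0.85, 1.0, 1.0),
    }
    variables: dict[str, FuzzyVariable] = {
        "age": FuzzyVariable(
            name="age",
            universe=(0.0, 100.0, 1001),
            sets={
                "children": (0.0, 0.0, 14.0, 16.0),
                "teenagers": (14.0, 16.0, 22.0, 25.0),
                "youths": (22.0, 25.0, 32.0, 42.0),
                "adults": (32.0, 42.0, 68.0, 71.0),
                "seniors": (68.0, 70.0, 100.0, 100.0),
            },
        ),
        "diet": FuzzyVariable(
            name="diet",
            universe=unit,
            sets={
                "vegan": (0.0, 0.0, 0.08, 0.22),
                "vegetarian": (0.15, 0.3, 0.4, 0.55),
                "flexitarian": (0.45, 0.55, 0.65, 0.8),
                "omnivore": (0.7, 0.85, 1.0, 1.0),
            },
        ),
        "innovation": FuzzyVariable(name="innovation", universe=unit, sets=dict(level_sets)),
    }
    for tag in TAGS:
        name = f"taste_{tag}"
        variables[name] = FuzzyVariable(name=name, universe=unit, sets=dict(level_sets))
    return variables


def default_rule_base_path() -> Path:
    return Path(str(resources.files("menurec.data") / "rulebase.yaml"))


@dataclass(frozen=True)
class UserAttributes:
    """Demographic attributes of a simulated user."""

    age: float
    gender: str
    region: str
    locality_size: str

    def __post_init__(self) -> None:
        if not 0 <= self.age <= 100:
            raise ValueError(f"age {self.age} outside [0, 100]")
        if self.gender not in GENDERS:
            raise ValueError(f"gender {self.gender!r} not in {GENDERS}")
        if self.region not in REGIONS:
            raise ValueError(f"region {self.region!r} not in {REGIONS}")
        if self.locality_size not in LOCALITY_SIZES:
            raise ValueError(f"locality_size {self.locality_size!r} not in {LOCALITY_SIZES}")


@dataclass(frozen=True)
class UserProfile:
    """A generated preference profile: the environment's ground truth for one user."""

    user_id: str
    diet: str
    tastes: dict[str, float]
    innovation: float
    attributes: UserAttributes

    def __post_init__(self) -> None:
        if self.diet not in DIET_CLASSES:
            raise ValueError(f"diet {self.diet!r} not in {DIET_CLASSES}")
        if set(self.tastes) != set(TAGS):
            raise ValueError("tastes must cover exactly the 12 tags")
        for tag, value in self.tastes.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"taste[{tag}] = {value} outside [0, 1]")
        for tag in DIET_FORBIDDEN[self.diet]:
            if self.tastes[tag] != 0.0:
                raise ValueError(f"diet {self.diet}: taste[{tag}] must be 0, got {self.tastes[tag]}")
        if not 0.0 <= self.innovation <= 1.0:
            raise ValueError(f"innovation {self.innovation} outside [0, 1]")

    @property
    def innovative(self) -> bool:
        return self.innovation >= 0.5


@dataclass
class ProfileGenerator:
    """Fuzzy inference pipeline from attributes to profiles.

    Parameters
    ----------
    variables, blocks:
        The fuzzy variables and the three rule blocks (``diet``, ``tastes``,
        ``innovation``). Defaults load the shipped rule base.
    taste_sigma:
        Std. dev. of the zero-mean truncated-Gaussian perturbation applied to
        nonzero taste probabilities (default 0.05).
    diet_sigma:
        Std. dev. of the Gaussian perturbation added to the defuzzified diet
        score before thresholding (default 0.065; calibrated so a national
        population reproduces the reference diet shares).
    innovation_sigma:
        Std. dev. of the perturbation on the innovation score (default 0.08).
    flexitarian_damping:
        Multiplier applied to flexitarians' meat/fish tastes (default 0.5).
    """

    variables: dict[str, FuzzyVariable] = field(default_factory=default_variables)
    blocks: dict[str, RuleBlock] = field(default_factory=lambda: load_rule_blocks(default_rule_base_path()))
    taste_sigma: float = 0.05
    diet_sigma: float = 0.065
    innovation_sigma: float = 0.08
    flexitarian_damping: float = 0.5
    diet_thresholds: tuple[float, float, float] = DIET_THRESHOLDS

    def __post_init__(self) -> None:
        expected = {"diet": 17, "tastes": 30, "innovation": 15}
        for block_id in expected:
            if block_id not in self.blocks:
                raise ValueError(f"missing rule block {block_id!r}")
        vocab: dict[str, tuple[str, ...]] = {name: var.labels for name, var in self.variables.items()}
        vocab["gender"] = GENDERS
        vocab["region"] = REGIONS
        vocab["locality"] = LOCALITY_SIZES
        validate_blocks(self.blocks, vocab)

    # -- fuzzification -------------------------------------------------

    def fuzzify_attributes(self, attributes: UserAttributes) -> dict[str, dict[str, float]]:
        return {
            "age": fuzzify(attributes.age, self.variables["age"]),
            "gender": crisp_memberships(attributes.gender, GENDERS),
            "region": crisp_memberships(attributes.region, REGIONS),
            "locality": crisp_memberships(attributes.locality_size, LOCALITY_SIZES),
        }

    def _defuzzify_output(self, block_id: str, memberships, output_name: str) -> float:
        output = self.variables[output_name]
        area = infer(self.blocks[block_id], memberships, output)
        try:
            return defuzzify_centroid(area, output.grid)
        except ZeroMassError:
            lo, hi, _ = output.universe
            midpoint = 0.5 * (lo + hi)
            # expected for taste tags no rule addresses (neutral preference);
            # anomalous for diet/innovation, whose rules cover the universe
            log = logger.debug if block_id == "tastes" else logger.warning
            log("zero-mass area for %s; falling back to universe midpoint %.3f", output_name, midpoint)
            return midpoint

    # -- inference operations ------------------------------------------

    def infer_diet(self, attributes: UserAttributes, rng: np.random.Generator | None = None) -> str:
        """Diet class from the diet block: defuzzify, perturb, threshold."""
        score = self.diet_score(attributes)
        if rng is not None and self.diet_sigma > 0:
            score = float(np.clip(score + rng.normal(0.0, self.diet_sigma), 0.0, 1.0))
        return self.classify_diet_score(score)

    def diet_score(self, attributes: UserAttributes) -> float:
        """Unperturbed defuzzified position on the [0, 1] diet axis."""
        memberships = self.fuzzify_attributes(attributes)
        return self._defuzzify_output("diet", memberships, "diet")

    def classify_diet_score(self, score: float) -> str:
        t_vegan, t_vegetarian, t_flex = self.diet_thresholds
        if score < t_vegan:
            return "vegan"
        if score < t_vegetarian:
            return "vegetarian"
        if score < t_flex:
            return "flexitarian"
        return "omnivore"

    def infer_tastes(
        self,
        attributes: UserAttributes,
        diet: str,
        rng: np.random.Generator | None = None,
    ) -> dict[str, float]:
        """Taste probabilities for all 12 tags, with diet constraints applied last."""
        memberships = self.fuzzify_attributes(attributes)
        tastes = {
            tag: self._defuzzify_output("tastes", memberships, f"taste_{tag}")
            for tag in TAGS
        }
        if rng is not None:
            tastes = perturb_tastes(tastes, self.taste_sigma, rng)
        return apply_diet_constraints(tastes, diet, self.flexitarian_damping)

    def infer_innovation(self, attributes: UserAttributes, rng: np.random.Generator | None = None) -> float:
        """Innovation score in [0, 1]; >= 0.5 counts as innovative."""
        memberships = self.fuzzify_attributes(attributes)
        score = self._defuzzify_output("innovation", memberships, "innovation")
        if rng is not None and self.innovation_sigma > 0:
            score = float(np.clip(score + rng.normal(0.0, self.innovation_sigma), 0.0, 1.0))
        return score

    def generate_profile(
        self,
        user_id: str,
        attributes: UserAttributes,
        rng: np.random.Generator | None = None,
        diet: str | None = None,
        innovation: float | None = None,
    ) -> UserProfile:
        """Full profile; ``diet``/``innovation`` may be overridden (quota assignment)."""
        if diet is None:
            diet = self.infer_diet(attributes, rng)
        if innovation is None:
            innovation = self.infer_innovation(attributes, rng)
        tastes = self.infer_tastes(attributes, diet, rng)
        return UserProfile(
            user_id=user_id,
            diet=diet,
            tastes=tastes,
            innovation=innovation,
            attributes=attributes,
        )


def perturb_tastes(
    tastes: dict[str, float],
    sigma: float,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Zero-mean truncated-Gaussian perturbation of nonzero tastes.

    The noise is symmetric around each original value and clipped to [0, 1]
    by resampling (truncation, not saturation, so the mean is preserved up to
    boundary effects); tastes that are exactly 0 (diet-forbidden or
    degenerate) are left untouched.
    """
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return dict(tastes)
    out: dict[str, float] = {}
    for tag, value in tastes.items():
        if value == 0.0:
            out[tag] = 0.0
            continue
        # symmetric truncation window keeps the perturbation mean at `value`
        half = min(value, 1.0 - value, 3.0 * sigma)
        if half <= 1e-12:  # value pinned at a boundary: no symmetric window exists
            out[tag] = value
            continue
        lo, hi = value - half, value + half
        draw = rng.normal(value, sigma)
        while not lo <= draw <= hi:
            draw = rng.normal(value, sigma)
        out[tag] = float(draw)
    return out


def apply_diet_constraints(tastes: dict[str, float], diet: str, flexitarian_damping: float = 0.5) -> dict[str, float]:
    """Zero forbidden tags for vegetarians/vegans; damp meat/fish for flexitarians."""
    if diet not in DIET_CLASSES:
        raise ValueError(f"unknown diet {diet!r}")
    out = dict(tastes)
    for tag in DIET_FORBIDDEN[diet]:
        out[tag] = 0.0
    if diet == "flexitarian":
        for tag in MEAT_TAGS:
            out[tag] = out[tag] * flexitarian_damping
    return out
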