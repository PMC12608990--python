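"""Population synthesis: national demographic sampling and quota-based subgroups.

Two generation regimes are supported, mirroring how reference populations
and target groups are specified:

* a :class:`DemographicSpec` (national population): attributes are sampled
  from the demographic distributions and the diet class *emerges* from fuzzy
  inference — this is the regime whose running omnivore share converges to
  the reference value (~87%) as more users are generated;
* a :class:`GroupSpec` (target group, e.g. "Veggies"): diet shares and the
  percentage of innovative users are specifications, enforced exactly by
  stratified assignment — users are ranked by their inferred scores and the
  stated quotas are imposed on the ranking, preserving the attribute-score
  correlation while pinning the marginals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from menurec.profiles import (
    DIET_CLASSES,
    GENDERS,
    LOCALITY_SIZES,
    REGIONS,
    ProfileGenerator,
    UserAttributes,
    UserProfile,
)
from menurec.tags import TAGS


@dataclass(frozen=True)
class DemographicSpec:
    """National population spec: attribute distributions + reference statistics."""

    name: str
    age_bin_width: float
    age_weights: tuple[float, ...]  # relative density at 5-year bin midpoints
    gender: dict[str, float]
    region: dict[str, float]
    locality: dict[str, float]
    reference: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for dist, vocab in ((self.gender, GENDERS), (self.region, REGIONS), (self.locality, LOCALITY_SIZES)):
            if set(dist) != set(vocab):
                raise ValueError(f"distribution keys {set(dist)} != vocabulary {set(vocab)}")
            if abs(sum(dist.values()) - 1.0) > 1e-6:
                raise ValueError(f"distribution {dist} does not sum to 1")

    def age_grid(self, step: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
        """Piecewise-linear age density interpolated from bin-midpoint weights."""
        midpoints = (np.arange(len(self.age_weights)) + 0.5) * self.age_bin_width
        grid = np.arange(0.0, midpoints[-1] + self.age_bin_width / 2 + step, step)
        density = np.interp(grid, midpoints, self.age_weights)
        return grid, density / density.sum()

    def sample_attributes(self, rng: np.random.Generator) -> UserAttributes:
        grid, pdf = self.age_grid()
        age = float(np.clip(rng.choice(grid, p=pdf) + rng.uniform(-0.25, 0.25), 0.0, 100.0))
        gender = str(rng.choice(GENDERS, p=[self.gender[g] for g in GENDERS]))
        region = str(rng.choice(REGIONS, p=[self.region[r] for r in REGIONS]))
        locality = str(rng.choice(LOCALITY_SIZES, p=[self.locality[s] for s in LOCALITY_SIZES]))
        return UserAttributes(age=age, gender=gender, region=region, locality_size=locality)


@dataclass(frozen=True)
class GroupSpec:
    """A target-group row: quotas on gender, age range, diet shares and innovators."""

    name: str
    n_users: int = 50
    pct_female: float = 50.0
    age_rule: str | tuple[float, float] = "any"  # "demographic" | "any" | (lo, hi)
    diet_shares: dict[str, float] = field(default_factory=lambda: {"omnivore": 100.0, "flexitarian": 0.0, "vegetarian": 0.0, "vegan": 0.0})
    pct_innovative: float = 50.0

    def __post_init__(self) -> None:
        if self.n_users <= 0:
            raise ValueError(f"n_users must be > 0, got {self.n_users}")
        if set(self.diet_shares) != set(DIET_CLASSES):
            raise ValueError(f"diet_shares must cover {DIET_CLASSES}")
        total = sum(self.diet_shares.values())
        if abs(total - 100.0) > 0.5:
            raise ValueError(f"diet_shares sum to {total}, expected 100")

    def sample_age(self, rng: np.random.Generator, demographic: DemographicSpec | None) -> float:
        if self.age_rule == "demographic":
            if demographic is None:
                raise ValueError("age_rule 'demographic' requires a DemographicSpec")
            return demographic.sample_attributes(rng).age
        if self.age_rule == "any":
            return float(rng.uniform(16.0, 80.0))
        lo, hi = self.age_rule  # type: ignore[misc]
        return float(rng.uniform(float(lo), float(hi)))


def _quota_counts(shares: dict[str, float], n: int, order: tuple[str, ...]) -> dict[str, int]:
    """Largest-remainder apportionment of n users to classes by percentage shares."""
    raw = {k: shares[k] * n / 100.0 for k in order}
    counts = {k: int(np.floor(raw[k])) for k in order}
    remainder = n - sum(counts.values())
    by_frac = sorted(order, key=lambda k: (-(raw[k] - counts[k]), order.index(k)))
    for k in by_frac[:remainder]:
        counts[k] += 1
    return counts


def generate_population(
    spec: DemographicSpec | GroupSpec,
    n: int | None = None,
    rng: np.random.Generator | None = None,
    generator: ProfileGenerator | None = None,
    demographic: DemographicSpec | None = None,
    id_prefix: str | None = None,
) -> list[UserProfile]:
    """Generate ``n`` user profiles from a national or group specification.

    For a :class:`DemographicSpec` diets and innovation emerge from
    inference. For a :class:`GroupSpec`, gender, diet shares and the share
    of innovative users are quota-enforced exactly: users are ranked by
    their inferred diet score (resp. innovation score) and classes are
    assigned in rank order so that class counts match the spec.
    """
    rng = rng if rng is not None else np.random.default_rng()
    generator = generator if generator is not None else ProfileGenerator()
    if isinstance(spec, DemographicSpec):
        n = n if n is not None else 100
        prefix = id_prefix if id_prefix is not None else spec.name
        if n <= 0:
            raise ValueError(f"n must be > 0, got {n}")
        return [
            generator.generate_profile(f"{prefix}-{i:05d}", spec.sample_attributes(rng), rng)
            for i in range(n)
        ]

    group = spec
    n = n if n is not None else group.n_users
    if n <= 0:
        raise ValueError(f"n must be > 0, got {n}")
    prefix = id_prefix if id_prefix is not None else group.name
    demographic = demographic if demographic is not None else load_demographic_spec()

    # attributes: quota-enforced gender, age per age_rule, national region/locality
    n_female = int(round(group.pct_female * n / 100.0))
    genders = ["female"] * n_female + ["male"] * (n - n_female)
    rng.shuffle(genders)
    attrs = []
    for i in range(n):
        age = group.sample_age(rng, demographic)
        region = str(rng.choice(REGIONS, p=[demographic.region[r] for r in REGIONS]))
        locality = str(rng.choice(LOCALITY_SIZES, p=[demographic.locality[s] for s in LOCALITY_SIZES]))
        attrs.append(UserAttributes(age=age, gender=genders[i], region=region, locality_size=locality))

    # diet quota by rank on the perturbed diet score (low scores -> plant-based classes)
    diet_scores = np.array(
        [
            np.clip(generator.diet_score(a) + rng.normal(0.0, generator.diet_sigma), 0.0, 1.0)
            for a in attrs
        ]
    )
    counts = _quota_counts(group.diet_shares, n, ("vegan", "vegetarian", "flexitarian", "omnivore"))
    order = np.argsort(diet_scores, kind="stable")
    diets = [""] * n
    cursor = 0
    for cls in ("vegan", "vegetarian", "flexitarian", "omnivore"):
        for idx in order[cursor : cursor + counts[cls]]:
            diets[idx] = cls
        cursor += counts[cls]

    # innovation quota by rank on the perturbed innovation score
    innov_scores = np.array([generator.infer_innovation(a, rng) for a in attrs])
    n_innovative = int(round(group.pct_innovative * n / 100.0))
    innov_order = np.argsort(-innov_scores, kind="stable")
    innovations = np.empty(n)
    for rank, idx in enumerate(innov_order):
        s = innov_scores[idx]
        if rank < n_innovative:
            innovations[idx] = 0.5 + 0.5 * s  # monotone rescale into [0.5, 1]
        else:
            innovations[idx] = min(0.499 * s, 0.4995)  # strictly below the 0.5 cut

    return [
        generator.generate_profile(f"{prefix}-{i:05d}", attrs[i], rng, diet=diets[i], innovation=float(innovations[i]))
        for i in range(n)
    ]


_STATISTICS = {
    "pct_omnivore": lambda p: 100.0 * float(p.diet == "omnivore"),
    "pct_veg_over15": None,  # handled separately (conditional on age)
    "pct_female": lambda p: 100.0 * float(p.attributes.gender == "female"),
    "pct_innovative": lambda p: 100.0 * float(p.innovative),
}


def calibration_curve(
    spec: DemographicSpec,
    n_max: int,
    reference: dict[str, float],
    rng: np.random.Generator | None = None,
    generator: ProfileGenerator | None = None,
) -> pd.DataFrame:
    """Running shares of calibrated statistics as the population grows.

    Returns a DataFrame indexed by ``n`` (1..n_max) with one column per
    statistic named in ``reference``; ``pct_veg_over15`` is the running
    combined vegetarian+vegan share among users older than 15.
    """
    if n_max < 100:
        raise ValueError(f"n_max must be >= 100, got {n_max}")
    unknown = set(reference) - set(_STATISTICS)
    if unknown:
        raise ValueError(f"unknown statistics {sorted(unknown)}; known: {sorted(_STATISTICS)}")
    profiles = generate_population(spec, n_max, rng, generator)
    out: dict[str, np.ndarray] = {}
    counts = np.arange(1, n_max + 1, dtype=float)
    for stat in reference:
        if stat == "pct_veg_over15":
            eligible = np.array([p.attributes.age > 15 for p in profiles], dtype=float)
            veg = np.array([p.diet in ("vegetarian", "vegan") for p in profiles], dtype=float)
            denom = np.maximum(np.cumsum(eligible), 1.0)
            out[stat] = 100.0 * np.cumsum(veg * eligible) / denom
        else:
            values = np.array([_STATISTICS[stat](p) for p in profiles])
            out[stat] = np.cumsum(values) / counts
    return pd.DataFrame(out, index=pd.Index(np.arange(1, n_max + 1), name="n"))


# -- config and serialization ------------------------------------------


def load_demographic_spec(path: str | Path | None = None) -> DemographicSpec:
    """Load a demographic spec YAML (default: the shipped Spanish-like spec)."""
    if path is None:
        path = Path(str(resources.files("menurec.data") / "demographics_spain.yaml"))
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return DemographicSpec(
        name=raw["name"],
        age_bin_width=float(raw["age_density"]["bin_width"]),
        age_weights=tuple(float(w) for w in raw["age_density"]["weights"]),
        gender={k: float(v) for k, v in raw["gender"].items()},
        region={k: float(v) for k, v in raw["region"].items()},
        locality={k: float(v) for k, v in raw["locality"].items()},
        reference={k: float(v) for k, v in raw.get("reference", {}).items()},
    )


def load_group_specs(path: str | Path | None = None) -> list[GroupSpec]:
    """Load group specs from YAML (default: the four shipped target groups)."""
    if path is None:
        path = Path(str(resources.files("menurec.data") / "groups.yaml"))
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs = []
    for row in raw:
        age_rule = row.get("age_rule", "any")
        if isinstance(age_rule, (list, tuple)):
            age_rule = (float(age_rule[0]), float(age_rule[1]))
        specs.append(
            GroupSpec(
                name=row["name"],
                n_users=int(row.get("n_users", 50)),
                pct_female=float(row.get("pct_female", 50.0)),
                age_rule=age_rule,
                diet_shares={k: float(v) for k, v in row["diet_shares"].items()},
                pct_innovative=float(row.get("pct_innovative", 50.0)),
            )
        )
    return specs


def population_to_frame(profiles: list[UserProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "user_id": p.user_id,
            "age": p.attributes.age,
            "gender": p.attributes.gender,
            "region": p.attributes.region,
            "locality_size": p.attributes.locality_size,
            "diet": p.diet,
            "innovation": p.innovation,
        }
        row.update({f"taste_{tag}": p.tastes[tag] for tag in TAGS})
        rows.append(row)
    return pd.DataFrame(rows)


def save_population(profiles: list[UserProfile], path: str | Path, meta: dict | None = None) -> None:
    """Write population CSV plus a JSON sidecar with generation metadata."""
    path = Path(path)
    population_to_frame(profiles).to_csv(path, index=False)
    sidecar = path.with_suffix(".json")
    with open(sidecar, "w") as fh:
        json.dump(meta or {}, fh, indent=2, default=str)


def load_population(path: str | Path) -> list[UserProfile]:
    frame = pd.read_csv(path)
    profiles = []
    for _, row in frame.iterrows():
        profiles.append(
            UserProfile(
                user_id=str(row["user_id"]),
                diet=str(row["diet"]),
                tastes={tag: float(row[f"taste_{tag}"]) for tag in TAGS},
                innovation=float(row["innovation"]),
                attributes=UserAttributes(
                    age=float(row["age"]),
                    gender=str(row["gender"]),
                    region=str(row["region"]),
                    locality_size=str(row["locality_size"]),
                ),
            )
        )
    return profiles
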