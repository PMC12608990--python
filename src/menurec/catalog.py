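"""The dish database, daily menu sampling, and the (course, tag) action space.

The default catalog mirrors the benchmark's database description: 60 first
courses over 5 tags (10 innovative), 60 second courses over 8 tags (23
innovative), and 25 desserts over 2 tags (4 innovative). Dish names are
synthetic, templated from their tag. A daily menu offers 3 / 3 / 2 options
per course with distinct tags within each course, and guarantees at least
one vegetarian and one vegan-permitted option among the first and second
courses (desserts always include fruit, which is vegan).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from menurec.tags import (
    AMBIGUOUS_TAGS,
    COURSE_TAGS,
    COURSES,
    MEAT_TAGS,
    OVO_LACTO_TAGS,
    PLANT_TAGS,
    validate_course,
    validate_tag,
)

#: options offered per course each day
MENU_SIZES: dict[str, int] = {"first": 3, "second": 3, "dessert": 2}


class MenuInfeasibleError(RuntimeError):
    """The catalog cannot produce a menu satisfying the vegetarian guarantee."""


@dataclass(frozen=True)
class Dish:
    dish_id: str
    name: str
    course: str
    tag: str
    innovative: bool = False
    vegetarian: bool = False
    vegan: bool = False

    def __post_init__(self) -> None:
        validate_course(self.course)
        validate_tag(self.tag)
        if self.vegan and not self.vegetarian:
            raise ValueError(f"dish {self.dish_id}: vegan implies vegetarian")


@dataclass(frozen=True)
class Action:
    """A recommendation target: a course index (1-3) and a tag available for it."""

    course: int  # 1 = first, 2 = second, 3 = dessert
    tag: str

    @property
    def course_name(self) -> str:
        return COURSES[self.course - 1]


@dataclass(frozen=True)
class CatalogSpec:
    counts: dict[str, int] = field(default_factory=lambda: {"first": 60, "second": 60, "dessert": 25})
    innovative_counts: dict[str, int] = field(default_factory=lambda: {"first": 10, "second": 23, "dessert": 4})
    course_tags: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(COURSE_TAGS))
    #: share of vegetarian dishes among ambiguous tags (rice, pasta, potato, fried)
    ambiguous_vegetarian_share: float = 0.6
    #: share of vegan dishes among vegetarian dishes of ambiguous tags
    ambiguous_vegan_share: float = 0.5


@dataclass(frozen=True)
class Catalog:
    dishes: tuple[Dish, ...]
    course_tags: dict[str, tuple[str, ...]] = field(default_factory=lambda: dict(COURSE_TAGS))

    def __post_init__(self) -> None:
        pools: dict[tuple[str, str], tuple[Dish, ...]] = {}
        for d in self.dishes:
            pools.setdefault((d.course, d.tag), ())
        for d in self.dishes:
            pools[(d.course, d.tag)] = (*pools[(d.course, d.tag)], d)
        object.__setattr__(self, "_pools", pools)

    def by_course(self, course: str) -> tuple[Dish, ...]:
        return tuple(d for d in self.dishes if d.course == course)

    def by_course_tag(self, course: str, tag: str) -> tuple[Dish, ...]:
        return self._pools.get((course, tag), ())

    def validate(self) -> None:
        for dish in self.dishes:
            if dish.tag not in self.course_tags[dish.course]:
                raise ValueError(f"dish {dish.dish_id}: tag {dish.tag!r} unavailable for course {dish.course!r}")
        if len({d.dish_id for d in self.dishes}) != len(self.dishes):
            raise ValueError("duplicate dish_id in catalog")


@dataclass(frozen=True)
class MenuDay:
    day: int
    options: dict[str, tuple[Dish, ...]]  # course -> offered dishes

    def __post_init__(self) -> None:
        for course, k in MENU_SIZES.items():
            opts = self.options.get(course, ())
            if len(opts) != k:
                raise ValueError(f"course {course!r} must offer {k} options, got {len(opts)}")
            if len({d.dish_id for d in opts}) != len(opts):
                raise ValueError(f"course {course!r} offers duplicate dishes")

    def tags(self, course: str) -> tuple[str, ...]:
        return tuple(d.tag for d in self.options[course])


def _dish_flags(tag: str, rng: np.random.Generator, spec: CatalogSpec) -> tuple[bool, bool]:
    """(vegetarian, vegan) flags for a dish of the given tag."""
    if tag in MEAT_TAGS:
        return False, False
    if tag in PLANT_TAGS:
        return True, True
    if tag in OVO_LACTO_TAGS:
        return True, False
    # ambiguous: a rice dish may be plain (vegetarian) or e.g. a paella
    vegetarian = bool(rng.random() < spec.ambiguous_vegetarian_share)
    vegan = vegetarian and bool(rng.random() < spec.ambiguous_vegan_share)
    return vegetarian, vegan


_NAME_TEMPLATES = (
    "{tag} of the house",
    "traditional {tag}",
    "seasonal {tag} plate",
    "chef's {tag}",
    "{tag} special",
    "rustic {tag}",
    "{tag} del dia",
    "market {tag}",
)


def generate_catalog(spec: CatalogSpec | None = None, rng: np.random.Generator | None = None) -> Catalog:
    """Build a catalog matching the spec counts, with synthetic dish names.

    Dishes are spread as evenly as possible over each course's available
    tags; innovative flags are assigned to a random subset of exactly the
    specified size; every vegetarian-capable tag keeps at least one
    vegetarian dish (so menus can honor the vegetarian guarantee).
    """
    spec = spec if spec is not None else CatalogSpec()
    rng = rng if rng is not None else np.random.default_rng()
    dishes: list[Dish] = []
    for course in COURSES:
        tags = spec.course_tags[course]
        count = spec.counts[course]
        if count < len(tags):
            raise ValueError(f"course {course!r}: count {count} below number of tags {len(tags)}")
        n_innovative = spec.innovative_counts[course]
        if n_innovative > count:
            raise ValueError(f"course {course!r}: innovative count {n_innovative} exceeds count {count}")
        base, extra = divmod(count, len(tags))
        per_tag = {tag: base + (1 if i < extra else 0) for i, tag in enumerate(tags)}
        innovative_slots = set(rng.choice(count, size=n_innovative, replace=False).tolist())
        slot = 0
        for tag in tags:
            veg_seen = False
            for j in range(per_tag[tag]):
                vegetarian, vegan = _dish_flags(tag, rng, spec)
                if j == per_tag[tag] - 1 and not veg_seen and tag not in MEAT_TAGS:
                    vegetarian, vegan = True, tag not in OVO_LACTO_TAGS
                veg_seen = veg_seen or vegetarian
                name = _NAME_TEMPLATES[j % len(_NAME_TEMPLATES)].format(tag=tag.replace("_", " "))
                dishes.append(
                    Dish(
                        dish_id=f"{course[0]}{slot:03d}",
                        name=name,
                        course=course,
                        tag=tag,
                        innovative=slot in innovative_slots,
                        vegetarian=vegetarian,
                        vegan=vegan,
                    )
                )
                slot += 1
    catalog = Catalog(dishes=tuple(dishes), course_tags=dict(spec.course_tags))
    catalog.validate()
    return catalog


def enumerate_actions(catalog: Catalog) -> list[Action]:
    """All (course, tag) pairs in the availability map, course-major, tags alphabetical."""
    actions = []
    for i, course in enumerate(COURSES, start=1):
        for tag in sorted(catalog.course_tags[course]):
            actions.append(Action(course=i, tag=tag))
    return actions


def sample_daily_menu(
    catalog: Catalog,
    rng: np.random.Generator,
    day: int = 0,
    max_resamples: int = 1000,
) -> MenuDay:
    """Sample a daily menu: distinct tags per course, one uniform dish per tag.

    Resamples until the first and second courses each contain at least one
    vegetarian option (the dessert pair always includes fruit when both
    dessert tags are available, so it needs no separate guarantee).
    """
    for _ in range(max_resamples):
        options: dict[str, tuple[Dish, ...]] = {}
        for course in COURSES:
            k = MENU_SIZES[course]
            tags = [t for t in catalog.course_tags[course] if catalog.by_course_tag(course, t)]
            if len(tags) < k:
                raise MenuInfeasibleError(f"course {course!r}: only {len(tags)} populated tags, need {k}")
            chosen_tags = rng.choice(len(tags), size=k, replace=False)
            opts = []
            for ti in chosen_tags:
                pool = catalog.by_course_tag(course, tags[ti])
                opts.append(pool[rng.integers(len(pool))])
            options[course] = tuple(opts)
        ok = all(any(d.vegetarian for d in options[c]) for c in ("first", "second"))
        if ok:
            return MenuDay(day=day, options=options)
    raise MenuInfeasibleError(f"no menu satisfying the vegetarian guarantee after {max_resamples} resamples")


# -- serialization ------------------------------------------------------


def catalog_to_frame(catalog: Catalog) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dish_id": d.dish_id,
                "name": d.name,
                "course": d.course,
                "tag": d.tag,
                "innovative": d.innovative,
                "vegetarian": d.vegetarian,
                "vegan": d.vegan,
            }
            for d in catalog.dishes
        ]
    )


def save_catalog(catalog: Catalog, csv_path: str | Path, map_path: str | Path | None = None) -> None:
    """Write the dish table as CSV and the availability map as JSON."""
    catalog_to_frame(catalog).to_csv(csv_path, index=False)
    if map_path is not None:
        with open(map_path, "w") as fh:
            json.dump({c: list(t) for c, t in catalog.course_tags.items()}, fh, indent=2)


def load_catalog(csv_path: str | Path, map_path: str | Path | None = None) -> Catalog:
    frame = pd.read_csv(csv_path)
    dishes = tuple(
        Dish(
            dish_id=str(r["dish_id"]),
            name=str(r["name"]),
            course=str(r["course"]),
            tag=str(r["tag"]),
            innovative=bool(r["innovative"]),
            vegetarian=bool(r["vegetarian"]),
            vegan=bool(r["vegan"]),
        )
        for _, r in frame.iterrows()
    )
    if map_path is not None:
        with open(map_path) as fh:
            course_tags = {c: tuple(t) for c, t in json.load(fh).items()}
    else:
        course_tags = dict(COURSE_TAGS)
    catalog = Catalog(dishes=dishes, course_tags=course_tags)
    catalog.validate()
    return catalog
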