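"""Dish category tags, courses, and the course-tag availability map.

Twelve tags describe every dish in the catalog and double as the coordinates
of a user's taste vector. A daily menu offers three first-course options,
three second-course options and two desserts; not every tag is available for
every course (desserts, for instance, are only fruit or dairy). The default
availability map gives 5 first-course tags, 8 second-course tags and 2
dessert tags, for an action space of 15 (course, tag) pairs.
"""

from __future__ import annotations

TAGS: tuple[str, ...] = (
    "rice",
    "pasta",
    "potato",
    "legume",
    "vegetables",
    "white_meat",
    "red_meat",
    "fish",
    "fried",
    "egg",
    "dairy",
    "fruit",
)

COURSES: tuple[str, ...] = ("first", "second", "dessert")

# Default course -> available tags. Three tags (potato, legume, vegetables)
# can appear as either a first or a second course.
COURSE_TAGS: dict[str, tuple[str, ...]] = {
    "first": ("rice", "pasta", "potato", "legume", "vegetables"),
    "second": ("white_meat", "red_meat", "fish", "fried", "egg", "legume", "vegetables", "potato"),
    "dessert": ("fruit", "dairy"),
}

#: Tags that are never vegetarian.
MEAT_TAGS: frozenset[str] = frozenset({"white_meat", "red_meat", "fish"})

#: Tags that are vegetarian but not vegan.
OVO_LACTO_TAGS: frozenset[str] = frozenset({"egg", "dairy"})

#: Tags that are always plant-based (vegan-friendly by default).
PLANT_TAGS: frozenset[str] = frozenset({"legume", "vegetables", "fruit"})

#: Tags whose dishes may or may not be vegetarian (e.g. plain rice vs. paella).
AMBIGUOUS_TAGS: frozenset[str] = frozenset({"rice", "pasta", "potato", "fried"})


def validate_tag(tag: str) -> str:
    if tag not in TAGS:
        raise ValueError(f"unknown tag {tag!r}; valid tags: {TAGS}")
    return tag


def validate_course(course: str) -> str:
    if course not in COURSES:
        raise ValueError(f"unknown course {course!r}; valid courses: {COURSES}")
    return course
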