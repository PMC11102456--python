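"""Registry of the bilateral category-selective region set used throughout.

Nine region names per hemisphere (18 regions total): three face regions,
one body region, three scene regions, and two object regions. Each entry
carries the preferred stimulus category and the contrast category used to
localize it (objects, except for object regions which contrast against
scrambled objects).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["FROIDef", "FROIRegistry", "default_registry", "CONDITIONS", "CATEGORY_TO_CONDITION"]

#: Stimulus conditions of the localizer task, in canonical order.
CONDITIONS = ("faces", "bodies", "scenes", "objects", "scrambled")

#: Map from a region's preferred category to the localizer condition name.
CATEGORY_TO_CONDITION = {
    "face": "faces",
    "body": "bodies",
    "scene": "scenes",
    "object": "objects",
}

_BASE_NAMES = (
    ("FFA", "face"),
    ("OFA", "face"),
    ("STS", "face"),
    ("EBA", "body"),
    ("PPA", "scene"),
    ("RSC", "scene"),
    ("TOS", "scene"),
    ("LO", "object"),
    ("PFS", "object"),
)


@dataclass(frozen=True)
class FROIDef:
    """One region: name, hemisphere, categories and its search-space id."""

    name: str            # e.g. "FFA"
    hemisphere: str      # "lh" or "rh"
    category: str        # preferred category: face/body/scene/object
    contrast_category: str  # "object" or "scrambled"
    search_space: str    # search-space label, e.g. "lh_FFA"

    @property
    def froi_id(self) -> str:
        """Short id in the lFFA / rFFA style."""
        return self.hemisphere[0] + self.name

    @property
    def preferred_condition(self) -> str:
        return CATEGORY_TO_CONDITION[self.category]

    @property
    def contrast_condition(self) -> str:
        if self.contrast_category == "scrambled":
            return "scrambled"
        return "objects"


class FROIRegistry:
    """Ordered collection of the 18 region definitions.

    Invariants checked at construction: 9 names x 2 hemispheres, with
    3 face, 1 body, 3 scene and 2 object regions per hemisphere.
    """

    def __init__(self, entries: tuple[FROIDef, ...]):
        names = {e.name for e in entries}
        if len(entries) != 2 * len(names):
            raise ValueError("registry must contain each name in both hemispheres")
        for hemi in ("lh", "rh"):
            cats = [e.category for e in entries if e.hemisphere == hemi]
            counts = {c: cats.count(c) for c in set(cats)}
            if counts != {"face": 3, "body": 1, "scene": 3, "object": 2}:
                raise ValueError(f"bad category composition in {hemi}: {counts}")
        self.entries = entries

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, froi_id: str) -> FROIDef:
        for e in self.entries:
            if e.froi_id == froi_id:
                return e
        raise KeyError(froi_id)

    @property
    def froi_ids(self) -> list[str]:
        return [e.froi_id for e in self.entries]

    def by_hemisphere(self, hemi: str) -> list[FROIDef]:
        return [e for e in self.entries if e.hemisphere == hemi]


def default_registry() -> FROIRegistry:
    """The default 18-region bilateral registry."""
    entries = []
    for hemi in ("lh", "rh"):
        for name, category in _BASE_NAMES:
            contrast = "scrambled" if category == "object" else "object"
            entries.append(
                FROIDef(
                    name=name,
                    hemisphere=hemi,
                    category=category,
                    contrast_category=contrast,
                    search_space=f"{hemi}_{name}",
                )
            )
    return FROIRegistry(tuple(entries))
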