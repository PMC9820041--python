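"""POI category taxonomy for functional land-use classification.

Thirteen first-level POI categories map onto three land-use classes:
residential (2 categories), working (6) and entertainment (5).  The
working and entertainment classes are further resolved into sectors,
one sector per first-level category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Canonical land-use class order used everywhere (share vectors, CSVs).
LAND_USE_CLASSES = ("residential", "working", "entertainment")

#: Residual labels a cell can receive instead of a land-use class.
MIXED = "mixed"
OTHER = "other"  # has POIs, but none of the three classes
NON_HUMAN_ACTIVITY = "non_human_activity"  # no POIs at all
MIXED_SECTOR = "mixed_sector"

DEFAULT_TAXONOMY = {
    "residential": (
        "Residential community",
        "Community service",
    ),
    "working": (
        "Private company",
        "Office building",
        "Financial sector",
        "Legal sector",
        "Government institution",
        "Education institution",
    ),
    "entertainment": (
        "Commercial site",
        "Hotel",
        "Tourism",
        "Sport/gym",
        "Catering site",
    ),
}


@dataclass(frozen=True)
class CategoryTaxonomy:
    """Mapping from land-use class to its first-level POI categories.

    Categories must be disjoint across classes and nonempty per class.
    ``sector_classes`` lists the classes that admit a sector-level
    (sub-category) classification.
    """

    classes: dict = field(default_factory=lambda: dict(DEFAULT_TAXONOMY))
    sector_classes: tuple = ("working", "entertainment")

    def __post_init__(self):
        seen = set()
        for cls, cats in self.classes.items():
            if not cats:
                raise ValueError(f"class {cls!r} has no categories")
            for c in cats:
                if c in seen:
                    raise ValueError(f"category {c!r} appears in two classes")
                seen.add(c)
        for cls in self.sector_classes:
            if cls not in self.classes:
                raise ValueError(f"unknown sector class {cls!r}")

    @property
    def categories(self) -> tuple:
        """All first-level categories, class order then in-class order."""
        return tuple(c for cls in LAND_USE_CLASSES if cls in self.classes
                     for c in self.classes[cls])

    def class_of(self, category: str) -> str:
        for cls, cats in self.classes.items():
            if category in cats:
                return cls
        raise KeyError(category)

    def sectors(self, land_use: str) -> tuple:
        """Sector names (the first-level categories) of a sectorable class."""
        if land_use not in self.sector_classes:
            raise ValueError(
                f"{land_use!r} has no sector-level classification"
            )
        return tuple(self.classes[land_use])
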