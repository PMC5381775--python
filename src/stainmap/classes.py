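"""Stain classes and display palette.

Micrographs of dual-stained mesenchymal stem-cell colonies are segmented
pixel by pixel into three classes: Oil Red O positive lipid droplets
(adipogenic lineage), Fast Blue positive alkaline-phosphatase activity
(osteogenic lineage), and stain-negative area (undifferentiated cells
inside a confinement, background outside).
"""

from __future__ import annotations

from enum import IntEnum


class StainClass(IntEnum):
    """Pixel class of a stained micrograph."""

    ADIPOGENIC = 1
    OSTEOGENIC = 2
    NEGATIVE = 3


#: Class codes in ascending order; the canonical column order everywhere.
CLASS_CODES: tuple[int, ...] = tuple(int(c) for c in StainClass)

#: Lower-case names matching CLASS_CODES order, used in tables and configs.
CLASS_NAMES: tuple[str, ...] = tuple(c.name.lower() for c in StainClass)

#: Overlay colors: adipogenic red, osteogenic blue, negative white.
DEFAULT_PALETTE: dict[StainClass, tuple[int, int, int]] = {
    StainClass.ADIPOGENIC: (255, 0, 0),
    StainClass.OSTEOGENIC: (0, 0, 255),
    StainClass.NEGATIVE: (255, 255, 255),
}


def class_from_name(name: str) -> StainClass:
    """Resolve a class from its name (case-insensitive) or integer code."""
    try:
        return StainClass(int(name))
    except (ValueError, TypeError):
        pass
    try:
        return StainClass[str(name).strip().upper()]
    except KeyError:
        raise ValueError(f"unknown stain class: {name!r}") from None
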