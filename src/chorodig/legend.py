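"""Legend definitions: density classes, display colors, density values.

A choropleth legend maps each map class to the color it is drawn in and to
the numeric value (here animals per square kilometre) used when converting
class areas into populations.  Two special classes are always present: a
no-data class (regions the map leaves blank) and a black "ink" class for
cartographic line work and labels, which is removed during cleanup.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence


@dataclass(frozen=True)
class LegendClass:
    """One legend entry.

    Parameters
    ----------
    class_id : int
        Unique small-integer identifier used in class rasters.
    name : str
        Human-readable label, e.g. ``"5.8-11.6 deer/km2"``.
    color : tuple of int
        Display color (R, G, B), 8-bit.
    density_value : float
        Animals per km2 attributed to the class when estimating populations.
    presence : bool
        Whether the class indicates the species is present.  No-data and
        ink classes are ``presence=False`` with density 0.
    """

    class_id: int
    name: str
    color: tuple[int, int, int]
    density_value: float = 0.0
    presence: bool = False

    def __post_init__(self) -> None:
        if self.density_value < 0:
            raise ValueError(f"density_value must be >= 0, got {self.density_value}")
        if not self.presence and self.density_value != 0:
            raise ValueError(
                f"class {self.class_id!r}: absence classes must carry density 0"
            )
        if len(self.color) != 3 or any(not (0 <= c <= 255) for c in self.color):
            raise ValueError(f"color must be 3 values in [0, 255], got {self.color}")


@dataclass
class Legend:
    """Ordered collection of legend classes.

    Exactly one class must be flagged as no-data (``nodata_id``); an ink
    class (``black_id``) is optional but required by the cleanup stage.
    Density classes are ordered by ``class_id``; class indices used in
    change analysis follow that order.
    """

    classes: list[LegendClass]
    nodata_id: int
    black_id: int | None = None
    _by_id: dict[int, LegendClass] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [c.class_id for c in self.classes]
        if len(set(ids)) != len(ids):
            raise ValueError("legend class ids must be unique")
        self._by_id = {c.class_id: c for c in self.classes}
        if self.nodata_id not in self._by_id:
            raise ValueError(f"nodata_id {self.nodata_id} not among classes")
        if self.black_id is not None and self.black_id not in self._by_id:
            raise ValueError(f"black_id {self.black_id} not among classes")

    def __iter__(self) -> Iterator[LegendClass]:
        return iter(self.classes)

    def __getitem__(self, class_id: int) -> LegendClass:
        return self._by_id[class_id]

    def __contains__(self, class_id: int) -> bool:
        return class_id in self._by_id

    @property
    def class_ids(self) -> list[int]:
        return [c.class_id for c in self.classes]

    @property
    def presence_ids(self) -> list[int]:
        """Ids of classes that indicate the species is present."""
        return [c.class_id for c in self.classes if c.presence]

    @property
    def density_ids(self) -> list[int]:
        """Ids of the thematic density classes (presence classes), in legend order."""
        return self.presence_ids

    def class_index(self, class_id: int) -> int:
        """Ordinal position of a density class (0 = lowest), for change analysis."""
        try:
            return self.density_ids.index(class_id)
        except ValueError:
            raise KeyError(f"class {class_id} is not a density class") from None

    def density_values(self) -> dict[int, float]:
        return {c.class_id: c.density_value for c in self.classes}

    def colors(self) -> dict[int, tuple[int, int, int]]:
        return {c.class_id: c.color for c in self.classes}

    def with_density(self, class_id: int, value: float) -> "Legend":
        """Return a copy with one class's density value replaced."""
        new = [
            LegendClass(c.class_id, c.name, c.color, value, c.presence)
            if c.class_id == class_id
            else c
            for c in self.classes
        ]
        return Legend(new, nodata_id=self.nodata_id, black_id=self.black_id)

    # ------------------------------------------------------------------ I/O
    def to_json(self, path: str | Path) -> None:
        payload = {
            "nodata_id": self.nodata_id,
            "black_id": self.black_id,
            "classes": [
                {
                    "class_id": c.class_id,
                    "name": c.name,
                    "color": list(c.color),
                    "density_value": c.density_value,
                    "presence": c.presence,
                }
                for c in self.classes
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Legend":
        payload = json.loads(Path(path).read_text())
        classes = [
            LegendClass(
                int(c["class_id"]),
                str(c["name"]),
                tuple(int(v) for v in c["color"]),
                float(c.get("density_value", 0.0)),
                bool(c.get("presence", False)),
            )
            for c in payload["classes"]
        ]
        black = payload.get("black_id")
        return cls(
            classes,
            nodata_id=int(payload["nodata_id"]),
            black_id=None if black is None else int(black),
        )


#: Class ids of the stock white-tailed deer density legend.
NODATA, LOW, MID_LOW, MID_HIGH, HIGH, BLACK = 0, 1, 2, 3, 4, 5


def deer_density_legend(low_density: float = 1.85) -> Legend:
    """The four-class white-tailed deer density legend.

    Classes <5.8, 5.8-11.6, 11.6-17.4 and >17.4 deer/km2.  The upper three
    classes carry the lower bound of their interval as density value; the
    open-ended low class carries a calibrated value (default 1.85 deer/km2,
    solvable per map with :func:`chorodig.demography.calibrate_free_class`).
    Colors are a well-separated yellow-to-dark-red ramp; borders and county
    names are black ink; blank regions are white no-data.
    """
    return Legend(
        [
            LegendClass(NODATA, "no data", (255, 255, 255)),
            LegendClass(LOW, "<5.8 deer/km2", (255, 255, 178), low_density, True),
            LegendClass(MID_LOW, "5.8-11.6 deer/km2", (254, 178, 76), 5.8, True),
            LegendClass(MID_HIGH, "11.6-17.4 deer/km2", (240, 59, 32), 11.6, True),
            LegendClass(HIGH, ">17.4 deer/km2", (128, 0, 38), 17.4, True),
            LegendClass(BLACK, "ink (borders/labels)", (0, 0, 0)),
        ],
        nodata_id=NODATA,
        black_id=BLACK,
    )
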