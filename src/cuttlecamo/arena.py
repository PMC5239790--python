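"""Virtual experimental arenas.

The experimental tank is an elongated 200 x 40 cm basin whose bottom is
painted a uniform 18% reflectance gray; dichromic treatments add a black
(3% reflectance) band of a chosen width across the full tank width.
Reflectance is expressed in percent of a white standard (0 = black,
100 = white), anchored by an 18% gray card.

Coordinate conventions shared by every downstream module:

* the long (swimming) axis is the *column* axis of the rasterized field,
  column 0 at the end of the tank where crossings start;
* the across-tank axis is the *row* axis;
* the raster scale is ``px_per_cm`` (default 10 px/cm, close to the
  overhead-camera scale of the original footage);
* ``cm_to_px`` rounds half away from zero; ``px_to_cm`` maps an index to
  its column-center coordinate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArenaSpec",
    "ReflectanceField",
    "ArenaGeometryError",
    "build_arena",
    "cm_to_px",
    "px_to_cm",
    "field_to_png",
    "PATCH_WIDTHS_CM",
]

#: black patch widths used in the experimental design (cm); 0 denotes control
PATCH_WIDTHS_CM = (3.0, 7.0, 10.0, 19.0, 29.0, 60.0)


class ArenaGeometryError(ValueError):
    """Raised when a patch does not fit inside the tank."""


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry and photometry of one arena.

    ``patch_width_cm = 0`` is the uniform-gray control.  ``patch_center_cm``
    defaults to the tank center.  The patch spans the full tank width.
    """

    length_cm: float = 200.0
    width_cm: float = 40.0
    gray_reflectance: float = 18.0
    black_reflectance: float = 3.0
    patch_width_cm: float = 0.0
    patch_center_cm: float | None = None
    px_per_cm: float = 10.0

    def __post_init__(self) -> None:
        if self.length_cm <= 0 or self.width_cm <= 0 or self.px_per_cm <= 0:
            raise ValueError("tank dimensions and px_per_cm must be positive")
        for v in (self.gray_reflectance, self.black_reflectance):
            if not 0.0 <= v <= 100.0:
                raise ValueError("reflectances must be in [0, 100]")
        if self.black_reflectance >= self.gray_reflectance:
            raise ValueError("black_reflectance must be below gray_reflectance")
        if self.patch_width_cm < 0:
            raise ValueError("patch_width_cm must be non-negative")
        if self.patch_center_cm is None:
            object.__setattr__(self, "patch_center_cm", self.length_cm / 2.0)
        if self.patch_width_cm > 0:
            left, right = self.patch_interval_cm
            if left < 0 or right > self.length_cm:
                raise ArenaGeometryError(
                    f"patch [{left:g}, {right:g}) cm extends outside the "
                    f"{self.length_cm:g} cm tank"
                )

    @property
    def patch_interval_cm(self) -> tuple[float, float]:
        """Half-open [left, right) extent of the black band along the tank."""
        half = self.patch_width_cm / 2.0
        return (self.patch_center_cm - half, self.patch_center_cm + half)

    @property
    def shape_px(self) -> tuple[int, int]:
        """(rows, columns) of the rasterized field."""
        return (
            int(round(self.width_cm * self.px_per_cm)),
            int(round(self.length_cm * self.px_per_cm)),
        )

    def to_dict(self) -> dict:
        return {
            "length_cm": self.length_cm,
            "width_cm": self.width_cm,
            "gray_reflectance": self.gray_reflectance,
            "black_reflectance": self.black_reflectance,
            "patch_width_cm": self.patch_width_cm,
            "patch_center_cm": self.patch_center_cm,
            "px_per_cm": self.px_per_cm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaSpec":
        return cls(**d)


@dataclass(frozen=True)
class ReflectanceField:
    """Rasterized background reflectance (percent of white).

    Row axis = across the tank, column axis = along the tank, column 0 at
    the crossing-start end.
    """

    values: np.ndarray = field(repr=False)
    px_per_cm: float = 10.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("field must be 2-D")
        if v.min() < 0.0 or v.max() > 100.0:
            raise ValueError("reflectance values must lie in [0, 100]")
        object.__setattr__(self, "values", v)

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def column_values(self) -> np.ndarray:
        """Per-column reflectance (fields built here are constant per column)."""
        return self.values[0, :].copy()


def cm_to_px(x_cm: float, px_per_cm: float) -> int:
    """Map a cm coordinate to a column index, rounding half away from zero."""
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    x = x_cm * px_per_cm
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def px_to_cm(col: int, px_per_cm: float) -> float:
    """Map a column index to the cm coordinate of its pixel center."""
    if px_per_cm <= 0:
        raise ValueError("px_per_cm must be positive")
    return col / px_per_cm


def build_arena(spec: ArenaSpec) -> ReflectanceField:
    """Rasterize an :class:`ArenaSpec` into a :class:`ReflectanceField`.

    A pixel column is black when its center coordinate lies inside the
    half-open patch interval ``[left, right)``; the band spans all rows.
    """
    n_rows, n_cols = spec.shape_px
    vals = np.full((n_rows, n_cols), spec.gray_reflectance, dtype=float)
    if spec.patch_width_cm > 0:
        left, right = spec.patch_interval_cm
        centers = (np.arange(n_cols) + 0.5) / spec.px_per_cm
        black = (centers >= left) & (centers < right)
        vals[:, black] = spec.black_reflectance
    return ReflectanceField(values=vals, px_per_cm=spec.px_per_cm)


def field_to_png(fld: ReflectanceField, path: str) -> None:
    """Export a field as 16-bit PNG, gray value = reflectance% * 655.35."""
    import imageio.v3 as iio

    img = np.round(fld.values * 655.35).astype(np.uint16)
    iio.imwrite(path, img)
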