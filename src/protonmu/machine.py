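"""Machine option catalog, beam specifications, and geometric conventions.

A compact double-scattered proton delivery system exposes a discrete set of
*options* (combinations of scatterers and modulation wheels), grouped into
``large`` (options 1-12, large applicator), ``deep`` (13-17) and ``small``
(18-24) field types.  A deliverable beam is an option together with a range
``R`` (depth of the distal 90% dose, g/cm2), a modulation width ``M``
(distal-90% to proximal-95% width, g/cm2), a collimated field, and a gantry
angle on the machine's 190-degree arc.

Everything downstream (commissioning tables, the output models) shares the
conventions defined here: the gantry-arc coordinate, the field-descriptor
reduction to an equivalent square, and the calibration-point geometry used by
the inverse-square/off-center correction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable, Iterator, Optional

__all__ = [
    "FieldSize",
    "OptionSpec",
    "BeamSpec",
    "CalibrationGeometry",
    "OptionCatalog",
    "BeamValidationError",
    "BoundsError",
    "ModulationExceedsRangeError",
    "GantryAngleError",
    "GROUPS",
    "GROUP_RANGE_BOUNDS",
    "GROUP_MODULATION_BOUNDS",
    "ESAD_MIN",
    "ESAD_MAX",
    "arc_position",
    "angle_distance",
    "validate_beam",
    "default_catalog",
]

#: Option groups and their member option ids.
GROUPS = {
    "large": tuple(range(1, 13)),
    "deep": tuple(range(13, 18)),
    "small": tuple(range(18, 25)),
}

#: Clinical range span (g/cm2) per group.
GROUP_RANGE_BOUNDS = {"large": (5.0, 25.0), "deep": (20.1, 32.0), "small": (5.0, 20.0)}

#: Modulation-width span (g/cm2) per group.
GROUP_MODULATION_BOUNDS = {"large": (2.0, 20.0), "deep": (2.0, 10.0), "small": (2.0, 20.0)}

#: Effective source-to-axis distance extremes (cm) observed across options.
ESAD_MIN = 171.9
ESAD_MAX = 180.8

#: Gantry arc: 190 degrees of rotation from 355 through 0 (beam facing down)
#: to 185.  Angles are stored in [0, 360).
ARC_START = 355.0
ARC_END = 185.0

_GRID_STEP = 0.1  # R and M are selectable in 0.1 g/cm2 steps


class BeamValidationError(ValueError):
    """A beam specification violates the machine's constraints."""


class BoundsError(BeamValidationError):
    """Range or modulation outside the option's commissioned window."""


class ModulationExceedsRangeError(BeamValidationError):
    """M > R: the proximal end of the SOBP would fall outside the patient."""


class GantryAngleError(BeamValidationError):
    """Angle outside the machine's rotation arc."""


@dataclass(frozen=True)
class FieldSize:
    """Collimated open field at the isocenter plane.

    ``shape`` is ``"square"`` (``size`` = side, cm) or ``"circular"``
    (``size`` = diameter, cm).  Mixed square/circular field-size tables are
    interpolated in the *equivalent square* side: the side of the square with
    the same area, ``D*sqrt(pi)/2`` for a circle of diameter D.
    """

    shape: str
    size: float

    def __post_init__(self) -> None:
        if self.shape not in ("square", "circular"):
            raise ValueError(f"unknown field shape {self.shape!r}")
        if not self.size > 0:
            raise ValueError("field size must be positive")

    @property
    def equivalent_square(self) -> float:
        """Equivalent-square side length in cm."""
        if self.shape == "square":
            return self.size
        return self.size * math.sqrt(math.pi) / 2.0

    @classmethod
    def parse(cls, text: str) -> "FieldSize":
        """Parse ``"10x10"`` (square, cm) or ``"14d"`` (circular diameter)."""
        s = text.strip().lower().replace(" ", "")
        if "x" in s:
            a, b = s.split("x")
            if float(a) != float(b):
                raise ValueError(f"only square NxN fields supported, got {text!r}")
            return cls("square", float(a))
        if s.endswith("d"):
            return cls("circular", float(s[:-1]))
        raise ValueError(f"cannot parse field descriptor {text!r}")

    def __str__(self) -> str:
        if self.shape == "square":
            return f"{self.size:g}x{self.size:g}"
        return f"{self.size:g}d"


@dataclass(frozen=True)
class OptionSpec:
    """Static description of one beamline option.

    ``rof_range``/``rof_modulation`` are the (R, M) at which the option's
    relative output factor is measured (the deepest commissioned range with a
    near-reference modulation).  ``esad`` is the option's effective
    source-to-axis distance in cm; ``None`` means not yet commissioned.
    """

    option_id: int
    group: str
    r_min: float
    r_max: float
    m_min: float
    m_max: float
    applicator_cm: float
    reference_field: FieldSize
    rof_range: float
    rof_modulation: float
    esad: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.option_id not in GROUPS[self.group]:
            raise ValueError(
                f"option {self.option_id} is not a member of group {self.group!r}"
            )
        if not self.r_min < self.r_max:
            raise ValueError("require r_min < r_max")
        if self.esad is not None and not (ESAD_MIN <= self.esad <= ESAD_MAX):
            raise ValueError(
                f"esad {self.esad} outside [{ESAD_MIN}, {ESAD_MAX}] cm"
            )

    @property
    def r_lowest(self) -> float:
        """Lowest commissioned range R_L in the option (g/cm2)."""
        return self.r_min


@dataclass(frozen=True)
class BeamSpec:
    """One deliverable beam: option, range, modulation, field, gantry angle."""

    option_id: int
    r: float
    m: float
    field: FieldSize
    gantry_angle: float = 0.0


@dataclass(frozen=True)
class CalibrationGeometry:
    """Geometry of the MU calibration point relative to the SOBP and isocenter.

    ``dz_p`` is the signed longitudinal distance (cm, parallel to the beam) of
    the calibration point from the center of the SOBP: negative downstream,
    positive upstream.  ``dz`` is the signed offset between the SOBP center
    and the isocenter.  ``x``/``y`` are lateral offsets (cm) in beam's-eye
    view at the point's plane.  Legacy source distances (SAD, SPD, SSD and
    depths d_p, d_c) used by the separate SOBP-off-center and inverse-square
    factors may be attached for comparison work.
    """

    esad: float
    dz_p: float = 0.0
    dz: float = 0.0
    x: float = 0.0
    y: float = 0.0
    dz_p_limit: float = 5.0
    sad: Optional[float] = None
    spd: Optional[float] = None
    ssd: Optional[float] = None
    d_p: Optional[float] = None
    d_c: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.esad > 0:
            raise ValueError("ESAD must be positive")
        if abs(self.dz_p) > self.dz_p_limit:
            raise ValueError(
                f"|dz_p| = {abs(self.dz_p)} cm exceeds the configured "
                f"{self.dz_p_limit} cm off-center limit"
            )


def arc_position(angle: float) -> float:
    """Map a gantry angle to its signed position on the rotation arc.

    The arc runs 190 degrees from 355 through 0 (beam facing down) to 185.
    Positions are measured from 0: angles in [355, 360) map to [-5, 0),
    angles in [0, 185] map to themselves.
    """
    if 0.0 <= angle <= ARC_END:
        return angle
    if ARC_START <= angle < 360.0:
        return angle - 360.0
    raise GantryAngleError(
        f"gantry angle {angle} outside the valid arc "
        f"[{ARC_START}, 360) U [0, {ARC_END}]"
    )


def angle_distance(a: float, b: float) -> float:
    """Arc length (degrees) between two gantry angles along the rotation path.

    Both angles must lie on the valid arc; the result is a metric on it.
    """
    return abs(arc_position(a) - arc_position(b))


def _on_grid(value: float, step: float = _GRID_STEP, tol: float = 1e-6) -> bool:
    q = value / step
    return abs(q - round(q)) < tol


def validate_beam(beam: BeamSpec, catalog: "OptionCatalog") -> BeamSpec:
    """Check a beam against its option's commissioned window.

    Returns the beam unchanged if valid; raises a :class:`BoundsError`,
    :class:`ModulationExceedsRangeError` or :class:`GantryAngleError`
    naming the violated limit otherwise.
    """
    opt = catalog.get(beam.option_id)
    if not (opt.r_min - 1e-9 <= beam.r <= opt.r_max + 1e-9):
        raise BoundsError(
            f"option {opt.option_id}: R = {beam.r} g/cm2 outside commissioned "
            f"range window [{opt.r_min}, {opt.r_max}]"
        )
    if not (opt.m_min - 1e-9 <= beam.m <= opt.m_max + 1e-9):
        raise BoundsError(
            f"option {opt.option_id}: M = {beam.m} g/cm2 outside modulation "
            f"window [{opt.m_min}, {opt.m_max}]"
        )
    if beam.m > beam.r + 1e-9:
        raise ModulationExceedsRangeError(
            f"M = {beam.m} exceeds R = {beam.r}: the proximal SOBP would "
            "extend outside the patient; not an allowable parameter entry"
        )
    if not (_on_grid(beam.r) and _on_grid(beam.m)):
        raise BoundsError(
            f"R = {beam.r}, M = {beam.m}: the delivery system accepts R and M "
            f"in {_GRID_STEP} g/cm2 steps only"
        )
    arc_position(beam.gantry_angle)  # raises GantryAngleError if invalid
    return beam


class OptionCatalog:
    """The machine's option catalog: a mapping option_id -> OptionSpec."""

    def __init__(self, options: Iterable[OptionSpec]):
        self._options = {o.option_id: o for o in options}

    def get(self, option_id: int) -> OptionSpec:
        try:
            return self._options[option_id]
        except KeyError:
            raise KeyError(f"option {option_id} not in catalog") from None

    def __contains__(self, option_id: int) -> bool:
        return option_id in self._options

    def __iter__(self) -> Iterator[OptionSpec]:
        return iter(self._options.values())

    def __len__(self) -> int:
        return len(self._options)

    @property
    def option_ids(self) -> list[int]:
        return sorted(self._options)

    def group_of(self, option_id: int) -> str:
        return self.get(option_id).group

    def with_esad(self, esads: dict[int, float]) -> "OptionCatalog":
        """Return a copy with per-option ESADs filled in."""
        return OptionCatalog(
            replace(o, esad=esads.get(o.option_id, o.esad)) for o in self
        )

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "options": [
                {
                    "option_id": o.option_id,
                    "group": o.group,
                    "r_min": o.r_min,
                    "r_max": o.r_max,
                    "m_min": o.m_min,
                    "m_max": o.m_max,
                    "applicator_cm": o.applicator_cm,
                    "reference_field": str(o.reference_field),
                    "rof_range": o.rof_range,
                    "rof_modulation": o.rof_modulation,
                    "esad": o.esad,
                }
                for o in sorted(self, key=lambda o: o.option_id)
            ]
        }

    @classmethod
    def from_dict(cls, data: dict) -> "OptionCatalog":
        try:
            records = data["options"]
        except KeyError as exc:
            raise ValueError("catalog file lacks an 'options' block") from exc
        opts = []
        for rec in records:
            rec = dict(rec)
            rec["reference_field"] = FieldSize.parse(rec["reference_field"])
            opts.append(OptionSpec(**rec))
        return cls(opts)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "OptionCatalog":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_catalog() -> OptionCatalog:
    """The default 24-option catalog shipped with the package.

    Option windows are machine specific; the shipped defaults give each
    option a window of up to 2.4 g/cm2 (the maximum in-option range shift of
    the final absorber plates) below its deepest commissioned range, clamped
    at the group's clinical minimum.  ESADs are filled only where known;
    commissioning a real machine replaces this file.
    """
    ref = resources.files("protonmu.data").joinpath("default_catalog.json")
    return OptionCatalog.from_dict(json.loads(ref.read_text()))
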