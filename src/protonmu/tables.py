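"""Commissioning-table storage and interpolation for the correction-based model.

The correction-based output model predicts dose per monitor unit as a product
of a reference output and tabulated correction factors, each measured during
commissioning:

* ROF  - relative output factor, one scalar per option;
* SOBPF - SOBP factor vs modulation width (1-D, per option);
* RSF  - range-shifter factor over range x modulation (2-D, per option);
* OCR  - off-center ratio over the lateral plane (2-D, per option);
* FSF  - field-size factor vs equivalent-square side (1-D, measured for a
  subset of options per group);
* GACF - gantry-angle correction factor along the rotation arc (1-D, per
  group).

All interpolation is piecewise linear (1-D) or bilinear (2-D), exact at grid
nodes.  Queries outside a measured grid raise - the single sanctioned
extrapolation is the log-fit fill of RSF cells that cannot be measured
because the modulation would exceed the range (``fill_rsf_placeholders``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np

from .machine import FieldSize, GROUPS, arc_position

__all__ = [
    "Grid1D",
    "RSFGrid",
    "OCRGrid",
    "ReferenceConditions",
    "CommissioningTables",
    "TableLookupError",
    "ExtrapolationError",
    "SmallFieldError",
    "TableFormatError",
    "resample_ocr",
    "load_published_tables",
]

#: Fields at or below this equivalent-square side (cm) require direct output
#: measurement; interpolating below the smallest measured field is refused.
SMALL_FIELD_LIMIT = 5.0


class TableLookupError(KeyError):
    """A required table entry or option is missing."""


class ExtrapolationError(ValueError):
    """Query outside the measured grid; no silent extrapolation."""


class SmallFieldError(ExtrapolationError):
    """Field smaller than the smallest measured field size.

    Outputs for such fields should be measured directly; pass
    ``allow_small_field=True`` to extrapolate anyway (flagged).
    """


class TableFormatError(ValueError):
    """Table file violates the documented schema."""


def _ascending(x: np.ndarray, what: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2 or np.any(np.diff(x) <= 0):
        raise TableFormatError(f"{what}: axis must be strictly increasing, length >= 2")
    return x


@dataclass
class Grid1D:
    """A measured 1-D factor table: strictly increasing axis, one factor each."""

    x: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.x = _ascending(self.x, "Grid1D")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.x.shape:
            raise TableFormatError("Grid1D: values shape mismatch")

    def interp(self, xq: float, what: str = "grid") -> float:
        if xq < self.x[0] - 1e-9 or xq > self.x[-1] + 1e-9:
            raise ExtrapolationError(
                f"{what}: query {xq:g} outside measured span "
                f"[{self.x[0]:g}, {self.x[-1]:g}]"
            )
        return float(np.interp(xq, self.x, self.values))


@dataclass
class RSFGrid:
    """Range-shifter factors on a range x modulation rectangle.

    ``placeholder`` marks cells that were extrapolated (modulation exceeding
    the range at that row) rather than measured; they participate in bilinear
    interpolation but taint the result's flag.
    """

    r_axis: np.ndarray
    m_axis: np.ndarray
    values: np.ndarray
    placeholder: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.r_axis = _ascending(self.r_axis, "RSFGrid R")
        self.m_axis = _ascending(self.m_axis, "RSFGrid M")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.r_axis), len(self.m_axis)):
            raise TableFormatError("RSFGrid: values shape mismatch")
        if self.placeholder is None:
            self.placeholder = np.zeros(self.values.shape, dtype=bool)
        else:
            self.placeholder = np.asarray(self.placeholder, dtype=bool)
            if self.placeholder.shape != self.values.shape:
                raise TableFormatError("RSFGrid: placeholder mask shape mismatch")


@dataclass
class OCRGrid:
    """Off-center ratios on a lateral (x, y) grid at the calibration plane."""

    x_axis: np.ndarray
    y_axis: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.x_axis = _ascending(self.x_axis, "OCRGrid x")
        self.y_axis = _ascending(self.y_axis, "OCRGrid y")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.x_axis), len(self.y_axis)):
            raise TableFormatError("OCRGrid: values shape mismatch")


@dataclass(frozen=True)
class ReferenceConditions:
    """The calibration beam to which every factor is normalized."""

    option_id: int = 20
    r: float = 15.0
    m: float = 10.0
    field: FieldSize = dc_field(default_factory=lambda: FieldSize("square", 10.0))
    gantry_angle: float = 0.0


def _bilinear(x_axis, y_axis, values, xq, yq, what):
    """Bilinear interpolation with node-exact behaviour; raises off-grid."""
    if xq < x_axis[0] - 1e-9 or xq > x_axis[-1] + 1e-9:
        raise ExtrapolationError(
            f"{what}: query {xq:g} outside [{x_axis[0]:g}, {x_axis[-1]:g}]"
        )
    if yq < y_axis[0] - 1e-9 or yq > y_axis[-1] + 1e-9:
        raise ExtrapolationError(
            f"{what}: query {yq:g} outside [{y_axis[0]:g}, {y_axis[-1]:g}]"
        )
    i = int(np.clip(np.searchsorted(x_axis, xq, side="right") - 1, 0, len(x_axis) - 2))
    j = int(np.clip(np.searchsorted(y_axis, yq, side="right") - 1, 0, len(y_axis) - 2))
    tx = (xq - x_axis[i]) / (x_axis[i + 1] - x_axis[i])
    ty = (yq - y_axis[j]) / (y_axis[j + 1] - y_axis[j])
    tx = min(max(tx, 0.0), 1.0)
    ty = min(max(ty, 0.0), 1.0)
    v = (
        values[i, j] * (1 - tx) * (1 - ty)
        + values[i + 1, j] * tx * (1 - ty)
        + values[i, j + 1] * (1 - tx) * ty
        + values[i + 1, j + 1] * tx * ty
    )
    return float(v), (i, j)


@dataclass
class CommissioningTables:
    """All correction-factor tables for one machine.

    ``psi_o`` is the measured absolute output (cGy/MU) of the calibration
    beam; every other entry is a dimensionless ratio to the appropriate
    reference condition.  ``option_groups`` maps option id to its field-type
    group so per-group tables (GACF) and per-group fallbacks (FSF) resolve
    without a separate catalog.
    """

    psi_o: float
    rof: dict[int, float]
    sobpf: dict[int, Grid1D] = dc_field(default_factory=dict)
    rsf: dict[int, RSFGrid] = dc_field(default_factory=dict)
    ocr: dict[int, OCRGrid] = dc_field(default_factory=dict)
    fsf: dict[int, Grid1D] = dc_field(default_factory=dict)
    gacf: dict[str, Grid1D] = dc_field(default_factory=dict)
    option_groups: dict[int, str] = dc_field(
        default_factory=lambda: {o: g for g, ids in GROUPS.items() for o in ids}
    )
    reference: ReferenceConditions = dc_field(default_factory=ReferenceConditions)

    # -- lookups ---------------------------------------------------------

    def lookup_rof(self, option_id: int) -> float:
        """Relative output factor: exact per-option scalar, no interpolation."""
        try:
            return self.rof[option_id]
        except KeyError:
            raise TableLookupError(f"no ROF for option {option_id}") from None

    def interp_sobpf(self, option_id: int, m: float) -> float:
        """SOBP factor at modulation ``m``, linear on the measured M grid."""
        try:
            grid = self.sobpf[option_id]
        except KeyError:
            raise TableLookupError(f"no SOBPF table for option {option_id}") from None
        return grid.interp(m, what=f"SOBPF option {option_id}")

    def interp_rsf(self, option_id: int, r: float, m: float) -> float:
        """Range-shifter factor at (R, M), bilinear on the commissioned grid."""
        return self.interp_rsf_flagged(option_id, r, m)[0]

    def interp_rsf_flagged(self, option_id: int, r: float, m: float) -> tuple[float, bool]:
        """As :meth:`interp_rsf`, also reporting whether any corner of the
        interpolation cell is an extrapolated placeholder."""
        try:
            grid = self.rsf[option_id]
        except KeyError:
            raise TableLookupError(f"no RSF grid for option {option_id}") from None
        v, (i, j) = _bilinear(
            grid.r_axis, grid.m_axis, grid.values, r, m, f"RSF option {option_id}"
        )
        tainted = bool(grid.placeholder[i : i + 2, j : j + 2].any())
        return v, tainted

    def interp_ocr(self, option_id: int, x: float, y: float) -> float:
        """Off-center ratio at lateral offsets (x, y) cm, bilinear."""
        try:
            grid = self.ocr[option_id]
        except KeyError:
            raise TableLookupError(f"no OCR grid for option {option_id}") from None
        v, _ = _bilinear(
            grid.x_axis, grid.y_axis, grid.values, x, y, f"OCR option {option_id}"
        )
        return v

    def _fsf_grid(self, option_id: int) -> Grid1D:
        if option_id in self.fsf:
            return self.fsf[option_id]
        group = self.option_groups.get(option_id)
        if group is None:
            raise TableLookupError(f"option {option_id} has no group assignment")
        measured = [o for o in self.fsf if self.option_groups.get(o) == group]
        if not measured:
            raise TableLookupError(
                f"no FSF measured for any option in group {group!r}"
            )
        nearest = min(measured, key=lambda o: (abs(o - option_id), o))
        return self.fsf[nearest]

    def interp_fsf(
        self, option_id: int, field: FieldSize, *, allow_small_field: bool = False
    ) -> float:
        """Field-size factor, linear in equivalent-square side.

        Options without their own measured FSF use the nearest measured
        option within their group.  Fields smaller than the smallest measured
        one raise :class:`SmallFieldError` (their output should be measured
        directly) unless ``allow_small_field`` is set, in which case the
        first measured segment is extended.
        """
        grid = self._fsf_grid(option_id)
        eq = field.equivalent_square
        if eq < grid.x[0] - 1e-9:
            if not allow_small_field:
                raise SmallFieldError(
                    f"field {field} (equivalent square {eq:.2f} cm) is smaller "
                    f"than the smallest measured field ({grid.x[0]:.2f} cm); "
                    "measure its output directly or pass allow_small_field=True"
                )
            slope = (grid.values[1] - grid.values[0]) / (grid.x[1] - grid.x[0])
            return float(grid.values[0] + slope * (eq - grid.x[0]))
        return grid.interp(eq, what=f"FSF option {option_id}")

    def interp_gacf(self, group: str, angle: float) -> float:
        """Gantry-angle correction factor, linear along the rotation arc."""
        try:
            grid = self.gacf[group]
        except KeyError:
            raise TableLookupError(f"no GACF table for group {group!r}") from None
        return grid.interp(arc_position(angle), what=f"GACF group {group!r}")

    def gacf_for_option(self, option_id: int, angle: float) -> float:
        group = self.option_groups.get(option_id)
        if group is None:
            raise TableLookupError(f"option {option_id} has no group assignment")
        return self.interp_gacf(group, angle)

    # -- placeholder fill ------------------------------------------------

    def fill_rsf_placeholders(self, option_id: int) -> "CommissioningTables":
        """Fill unmeasurable RSF cells (M > R) by a log fit, in place.

        For each grid row whose range is smaller than some modulation
        columns, the measured cells of that row are fit with
        ``f(M) = c0 + c1*ln(M)`` and the fit is evaluated at the missing
        columns.  Filled cells are flagged as placeholders: they exist only
        so 2-D interpolation has a complete rectangle and are never valid
        predictions themselves.  Requires >= 3 measured cells per row.
        Returns ``self`` for chaining.
        """
        grid = self.rsf[option_id]
        for i, r_row in enumerate(grid.r_axis):
            already = grid.placeholder[i]
            fill = (grid.m_axis > r_row + 1e-9) & ~already
            if not fill.any():
                continue
            measured = ~(grid.m_axis > r_row + 1e-9) & ~already
            if measured.sum() < 3:
                raise ValueError(
                    f"RSF option {option_id}, row R = {r_row:g}: need >= 3 "
                    "measured modulation points for the log-fit extrapolation"
                )
            lx = np.log(grid.m_axis[measured])
            c1, c0 = np.polyfit(lx, grid.values[i, measured], 1)
            grid.values[i, fill] = c0 + c1 * np.log(grid.m_axis[fill])
            grid.placeholder[i, fill] = True
        return self

    # -- validation ------------------------------------------------------

    def validate(self, atol: float = 5e-4) -> list[str]:
        """Check normalization invariants; return a list of warnings.

        The calibration option's ROF must be 1.00; each SOBPF is 1 at its
        option's ROF modulation; each RSF row at the largest commissioned
        range is 1; OCR is 1 on the central axis; each GACF is 1 at gantry 0.
        """
        warnings: list[str] = []
        ref = self.reference
        rof_ref = self.rof.get(ref.option_id)
        if rof_ref is None:
            warnings.append(f"missing ROF for calibration option {ref.option_id}")
        elif abs(rof_ref - 1.0) > atol:
            warnings.append(
                f"ROF of calibration option {ref.option_id} is {rof_ref:.4f}, "
                "expected 1.00"
            )
        for oid, grid in self.rsf.items():
            if np.max(np.abs(grid.values[-1] - 1.0)) > atol:
                warnings.append(
                    f"RSF option {oid}: row at largest R must be 1.00 for all M"
                )
        for oid, grid in self.ocr.items():
            try:
                v = self.interp_ocr(oid, 0.0, 0.0)
            except ExtrapolationError:
                warnings.append(f"OCR option {oid}: grid does not cover the axis")
                continue
            if abs(v - 1.0) > atol:
                warnings.append(f"OCR option {oid}: central-axis value {v:.4f} != 1.00")
        for group, grid in self.gacf.items():
            try:
                v = grid.interp(0.0, what=f"GACF {group}")
            except ExtrapolationError:
                warnings.append(f"GACF group {group}: grid does not cover angle 0")
                continue
            if abs(v - 1.0) > atol:
                warnings.append(f"GACF group {group}: value at 0 deg {v:.4f} != 1.00")
        return warnings

    # -- serialisation ---------------------------------------------------

    def to_dict(self, decimals: Optional[int] = None) -> dict:
        def f(x):
            v = float(x)
            return round(v, decimals) if decimals is not None else v

        def arr(a):
            return [f(v) for v in np.asarray(a).ravel().tolist()]

        def arr2(a):
            return [[f(v) for v in row] for row in np.asarray(a).tolist()]

        return {
            "psi_o": f(self.psi_o),
            "rof": {str(k): f(v) for k, v in sorted(self.rof.items())},
            "sobpf": {
                str(k): {"m": arr(g.x), "values": arr(g.values)}
                for k, g in sorted(self.sobpf.items())
            },
            "rsf": {
                str(k): {
                    "r_axis": arr(g.r_axis),
                    "m_axis": arr(g.m_axis),
                    "values": arr2(g.values),
                    "placeholder": np.asarray(g.placeholder).tolist(),
                }
                for k, g in sorted(self.rsf.items())
            },
            "ocr": {
                str(k): {
                    "x_axis": arr(g.x_axis),
                    "y_axis": arr(g.y_axis),
                    "values": arr2(g.values),
                }
                for k, g in sorted(self.ocr.items())
            },
            "fsf": {
                str(k): {"equivalent_square": arr(g.x), "values": arr(g.values)}
                for k, g in sorted(self.fsf.items())
            },
            "gacf": {
                k: {"arc_deg": arr(g.x), "values": arr(g.values)}
                for k, g in sorted(self.gacf.items())
            },
            "option_groups": {str(k): v for k, v in sorted(self.option_groups.items())},
            "reference": {
                "option_id": self.reference.option_id,
                "r": self.reference.r,
                "m": self.reference.m,
                "field": str(self.reference.field),
                "gantry_angle": self.reference.gantry_angle,
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CommissioningTables":
        try:
            psi_o = float(data["psi_o"])
            rof = {int(k): float(v) for k, v in data["rof"].items()}
        except KeyError as exc:
            raise TableFormatError(f"tables file lacks required block: {exc}") from exc
        sobpf = {
            int(k): Grid1D(np.array(v["m"]), np.array(v["values"]))
            for k, v in data.get("sobpf", {}).items()
        }
        rsf = {
            int(k): RSFGrid(
                np.array(v["r_axis"]),
                np.array(v["m_axis"]),
                np.array(v["values"]),
                np.array(v.get("placeholder"))
                if v.get("placeholder") is not None
                else None,
            )
            for k, v in data.get("rsf", {}).items()
        }
        ocr = {
            int(k): OCRGrid(
                np.array(v["x_axis"]), np.array(v["y_axis"]), np.array(v["values"])
            )
            for k, v in data.get("ocr", {}).items()
        }
        fsf = {
            int(k): Grid1D(np.array(v["equivalent_square"]), np.array(v["values"]))
            for k, v in data.get("fsf", {}).items()
        }
        gacf = {
            k: Grid1D(np.array(v["arc_deg"]), np.array(v["values"]))
            for k, v in data.get("gacf", {}).items()
        }
        groups = {
            int(k): v
            for k, v in data.get(
                "option_groups",
                {str(o): g for g, ids in GROUPS.items() for o in ids},
            ).items()
        }
        refd = data.get("reference", {})
        reference = ReferenceConditions(
            option_id=int(refd.get("option_id", 20)),
            r=float(refd.get("r", 15.0)),
            m=float(refd.get("m", 10.0)),
            field=FieldSize.parse(refd.get("field", "10x10")),
            gantry_angle=float(refd.get("gantry_angle", 0.0)),
        )
        return cls(
            psi_o=psi_o,
            rof=rof,
            sobpf=sobpf,
            rsf=rsf,
            ocr=ocr,
            fsf=fsf,
            gacf=gacf,
            option_groups=groups,
            reference=reference,
        )

    def write(self, path, decimals: Optional[int] = None) -> None:
        """Write a JSON bundle.  ``decimals=4`` reproduces the conventional
        4-decimal commissioning-report precision; default keeps full precision
        so write-then-read is the identity."""
        with open(path, "w") as fh:
            json.dump(self.to_dict(decimals), fh)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "CommissioningTables":
        with open(path) as fh:
            try:
                data = json.load(fh)
            except json.JSONDecodeError as exc:
                raise TableFormatError(f"{path}: not valid JSON ({exc})") from exc
        return cls.from_dict(data)


def resample_ocr(grid: OCRGrid, spacing: float = 0.05) -> OCRGrid:
    """Resample a raw lateral profile grid to a finer uniform spacing.

    Detector arrays sample the profile coarsely (typically 10 mm pitch); the
    tabulated OCR is conventionally stored at 0.5 mm/pixel (``spacing`` in
    cm).  Resampling is bilinear, so the resampled grid agrees with the raw
    grid exactly at coincident points and, because a bilinear patch restricted
    to a sub-rectangle is still bilinear, interpolating either grid yields the
    same surface.
    """
    dx = np.diff(grid.x_axis)
    dy = np.diff(grid.y_axis)
    if not (np.allclose(dx, dx[0]) and np.allclose(dy, dy[0])):
        raise TableFormatError("resample_ocr: raw grid spacing must be uniform")
    nx = int(round((grid.x_axis[-1] - grid.x_axis[0]) / spacing))
    ny = int(round((grid.y_axis[-1] - grid.y_axis[0]) / spacing))
    xf = grid.x_axis[0] + spacing * np.arange(nx + 1)
    yf = grid.y_axis[0] + spacing * np.arange(ny + 1)
    xf[-1] = min(xf[-1], grid.x_axis[-1])
    yf[-1] = min(yf[-1], grid.y_axis[-1])
    # separable bilinear resampling: interpolate along x, then along y
    tmp = np.empty((len(xf), grid.values.shape[1]))
    for j in range(grid.values.shape[1]):
        tmp[:, j] = np.interp(xf, grid.x_axis, grid.values[:, j])
    out = np.empty((len(xf), len(yf)))
    for i in range(len(xf)):
        out[i, :] = np.interp(yf, grid.y_axis, tmp[i, :])
    return OCRGrid(xf, yf, out)


def load_published_tables() -> CommissioningTables:
    """The published commissioning excerpts shipped with the package.

    Contains the full 24-option ROF table, the RSF grids for options 1, 13
    and 20 (including the extrapolated placeholder cells), and the measured
    FSF rows for nine options, with the reference output 1.06 cGy/MU.  SOBPF,
    OCR and GACF are not reproduced in the publication and are absent.
    """
    from importlib import resources

    ref = resources.files("protonmu.data").joinpath("published_tables.json")
    data = json.loads(ref.read_text())
    rof = {int(k): float(v) for k, v in data["rof"].items()}
    rsf = {
        int(k): RSFGrid(
            np.array(v["r_axis"]),
            np.array(v["m_axis"]),
            np.array(v["values"]),
            np.array(v["placeholder"]),
        )
        for k, v in data["rsf"].items()
    }
    fields = [FieldSize.parse(s) for s in data["fsf"]["fields"]]
    eq = np.array([f.equivalent_square for f in fields])
    order = np.argsort(eq)
    fsf = {
        int(k): Grid1D(eq[order], np.array(vals)[order])
        for k, vals in data["fsf"]["rows"].items()
    }
    refd = data["reference"]
    return CommissioningTables(
        psi_o=float(data["psi_o"]),
        rof=rof,
        rsf=rsf,
        fsf=fsf,
        reference=ReferenceConditions(
            option_id=int(refd["option_id"]),
            r=float(refd["r"]),
            m=float(refd["m"]),
            field=FieldSize.parse(refd["field"]),
            gantry_angle=float(refd["gantry_angle"]),
        ),
    )
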