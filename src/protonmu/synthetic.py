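"""Virtual machine and synthetic measurement campaigns.

No commissioning dataset for a double-scattered system is publicly deposited,
so every model and fitter here is exercised against a *virtual machine*: a
smooth ground-truth output function (analytical-model shaped, optionally
warped so that no model is exactly true) plus truth lateral-profile,
field-size and gantry-angle surfaces, sampled by a campaign that mirrors a
real commissioning effort:

* 24 relative-output measurements (one per option, at its deepest range),
* 182 SOBP-factor measurements (modulation sweeps at the deepest range),
* 324 range-shifter measurements (three ranges per option, modulation
  columns truncated where the modulation would exceed the range),
* 54 field-size measurements (three options per group, six apertures),
* 75 gantry-angle measurements (five options, 15-degree steps over the arc),
* one lateral-profile array acquisition per option, and
* 272 independent validation outputs, 60 of them off the SOBP center and/or
  the isocenter.

Measurement noise is multiplicative Gaussian truncated at three sigma
(readings further out would be re-measured), 0.5% by default for chamber
readings and 0.1% for the 2-D array's relative profile.  Repeating a
commissioning measurement at identical physical conditions returns the same
reading (a physicist does not re-measure a point), which makes the factor
chain telescope the way a real campaign does; validation outputs are always
independent draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
from scipy.stats import truncnorm

from .machine import (
    BeamSpec,
    CalibrationGeometry,
    FieldSize,
    OptionCatalog,
    OptionSpec,
    arc_position,
    default_catalog,
)
from .tables import CommissioningTables, Grid1D, OCRGrid, RSFGrid, ReferenceConditions
from .correction import isf_ocf
from .analytical import RConversion, compute_r

__all__ = [
    "TruthOption",
    "TruthMachine",
    "MeasurementRecord",
    "Campaign",
    "generate_campaign",
    "tables_from_campaign",
    "fitting_dataset",
    "fit_all_options",
    "validation_study",
]

#: Relative output factors of a representative 24-option machine, used to
#: scale the truth amplitudes so the virtual machine resembles a real one.
_TRUTH_ROF = {
    1: 1.22, 2: 1.17, 3: 1.13, 4: 1.08, 5: 1.02, 6: 0.97, 7: 0.89, 8: 0.82,
    9: 0.83, 10: 0.87, 11: 0.79, 12: 0.86, 13: 1.35, 14: 1.32, 15: 1.29,
    16: 1.26, 17: 1.21, 18: 1.12, 19: 1.06, 20: 1.00, 21: 0.94, 22: 0.94,
    23: 0.95, 24: 0.96,
}

_REFERENCE_OUTPUT = 1.06  # cGy/MU at the calibration beam

#: Gantry-angle deviation amplitude and peak arc position per group: large
#: options hardly deviate; deep peak near 135 deg, small near 150 deg.
_GACF_SHAPE = {"large": (0.004, 90.0), "deep": (0.023, 135.0), "small": (0.036, 150.0)}

#: Options whose shallow depths see a slit-scattering output bump at small
#: fields, and the bump amplitude.
_SLIT_BUMP = {11: 0.08, 12: 0.28, 23: 0.10, 24: 0.30}

_FSF_OPTIONS = (1, 6, 12, 13, 15, 17, 18, 20, 24)
_GACF_OPTIONS = {"large": (3, 5), "deep": (17,), "small": (18, 20)}
_GACF_ANGLES = (355.0, *np.arange(0.0, 185.0, 15.0), 185.0)  # 15 angles


@dataclass(frozen=True)
class TruthOption:
    """Ground-truth analytical constants of one option."""

    option_id: int
    group: str
    a0: float
    a1: float
    beta: float  # source-shift slope, per g/cm2 of range below the maximum
    amplitude: float  # K: plateau output at r -> 0, source shift excluded
    esad: float


def _truth_esad(r_max: float) -> float:
    lo, hi = 171.9, 180.8
    e = lo + (hi - lo) * (r_max - 11.1) / (32.0 - 11.1)
    return float(min(max(e, lo), hi))


@dataclass
class TruthMachine:
    """A smooth, fully known output function emulating one machine.

    The per-option output at the SOBP center/isocenter is analytical-model
    shaped, ``K * (1 + a0 r^a1)^-1 * (1 + beta (R - R_max))``, scaled so the
    calibration beam delivers 1.06 cGy/MU and the per-option relative outputs
    span a realistic range.  ``warped=True`` multiplies a smooth <=0.8%
    perturbation onto it so that no model under study is exactly true.
    Lateral profiles are asymmetric smooth bumps (no radial symmetry), the
    field-size curve approaches 1 above a 5x5 cm2 equivalent with a
    small-field falloff and, for the shallowest options, a slit-scatter bump,
    and gantry-angle curves deviate up to 0.4/2.3/3.6% for the large/deep/
    small groups.
    """

    catalog: OptionCatalog
    options: dict[int, TruthOption]
    sigma: float = 0.005
    sigma_ocr: float = 0.001
    warped: bool = False
    conv: RConversion = dc_field(default_factory=RConversion)

    @classmethod
    def default(cls, sigma: float = 0.005, warped: bool = False) -> "TruthMachine":
        """The deterministic default virtual machine (no randomness here;
        noise enters only when a campaign is generated)."""
        cat = default_catalog()
        conv = RConversion()
        opts = {}
        for spec in cat:
            i = spec.option_id
            a0 = 0.02 + 0.04 * ((i * 7) % 24) / 23.0
            a1 = 0.45 + 0.15 * ((i * 5) % 24) / 23.0
            beta = 0.006 + 0.014 * ((i * 11) % 24) / 23.0
            r_rof = compute_r(spec.rof_range, spec.rof_modulation, conv)
            g_rof = 1.0 / (1.0 + a0 * r_rof**a1)
            amp = _REFERENCE_OUTPUT * _TRUTH_ROF[i] / g_rof
            opts[i] = TruthOption(
                option_id=i, group=spec.group, a0=a0, a1=a1, beta=beta,
                amplitude=amp, esad=_truth_esad(spec.r_max),
            )
        cat = cat.with_esad({i: o.esad for i, o in opts.items()})
        return cls(catalog=cat, options=opts, sigma=sigma, warped=warped, conv=conv)

    # -- truth factors ---------------------------------------------------

    def bare_output(self, option_id: int, r_range: float, m: float) -> float:
        """Output (cGy/MU) at SOBP center, isocenter, reference field, 0 deg."""
        t = self.options[option_id]
        spec = self.catalog.get(option_id)
        r = compute_r(r_range, m, self.conv)
        g = 1.0 / (1.0 + t.a0 * r**t.a1)
        s = 1.0 + t.beta * (r_range - spec.r_max)
        psi = t.amplitude * g * s
        if self.warped:
            psi *= 1.0 + 0.008 * math.sin(1.3 * r + 0.7 * option_id) * math.cos(
                0.5 * (r_range - spec.r_min)
            )
        return psi

    def _ocr_raw(self, option_id: int, x, y):
        i = option_id
        a1 = 0.010 + 0.010 * ((i * 3) % 24) / 23.0
        a2 = 0.008 + 0.008 * ((i * 13) % 24) / 23.0
        cx1, cy1 = 2.0 + (i % 5), -3.0 + (i % 7)
        cx2, cy2 = -4.0 + (i % 3), 2.0 - (i % 5)
        w1 = 6.0 + (i % 4)
        w2 = 5.0 + ((i * 7) % 5)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        f = (
            1.0
            + a1 * np.exp(-(((x - cx1) ** 2 + (y - cy1) ** 2) / (2 * w1**2)))
            - a2 * np.exp(-(((x - cx2) ** 2 + (y - cy2) ** 2) / (2 * w2**2)))
        )
        return f

    def ocr(self, option_id: int, x, y):
        """Truth off-center ratio, normalized to the central axis."""
        return self._ocr_raw(option_id, x, y) / float(self._ocr_raw(option_id, 0.0, 0.0))

    def fsf(self, option_id: int, field: FieldSize) -> float:
        """Truth field-size factor, normalized to the option's reference field."""
        spec = self.catalog.get(option_id)

        def f(e):
            drop = 0.35 * math.exp(-(e - 2.0) / 1.8)
            bump = _SLIT_BUMP.get(option_id, 0.0) * math.exp(-(((e - 3.0) / 2.0) ** 2))
            return 1.0 - drop + bump

        return f(field.equivalent_square) / f(spec.reference_field.equivalent_square)

    def gacf(self, group: str, angle: float) -> float:
        """Truth gantry-angle correction factor for a group."""
        amp, peak = _GACF_SHAPE[group]
        t = arc_position(angle)
        return 1.0 - amp * math.sin(math.pi * t / (2.0 * peak)) ** 2

    def output(
        self,
        beam: BeamSpec,
        geom: Optional[CalibrationGeometry] = None,
    ) -> float:
        """Full truth output for a beam at an arbitrary calibration geometry."""
        spec = self.catalog.get(beam.option_id)
        if geom is None:
            geom = CalibrationGeometry(esad=self.options[beam.option_id].esad)
        psi = self.bare_output(beam.option_id, beam.r, beam.m)
        psi *= isf_ocf(geom)
        psi *= float(self.ocr(beam.option_id, geom.x, geom.y))
        psi *= self.fsf(beam.option_id, beam.field)
        psi *= self.gacf(spec.group, beam.gantry_angle)
        return psi

    def geometry(self, option_id: int, **kwargs) -> CalibrationGeometry:
        return CalibrationGeometry(esad=self.options[option_id].esad, **kwargs)


@dataclass(frozen=True)
class MeasurementRecord:
    """One measured output: the beam, the point geometry, the reading."""

    beam: BeamSpec
    geom: CalibrationGeometry
    psi_measured: float
    tag: str  # ROF | SOBPF | RSF | FSF | GACF | source_shift | validation

    def __post_init__(self) -> None:
        if not self.psi_measured > 0:
            raise ValueError("measured output must be positive")


@dataclass
class Campaign:
    """A complete synthetic commissioning + validation measurement set."""

    truth: TruthMachine
    records: list[MeasurementRecord]
    ocr_grids: dict[int, OCRGrid]
    sigma: float
    seed: Optional[int]

    @property
    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for rec in self.records:
            out[rec.tag] = out.get(rec.tag, 0) + 1
        out["OCR"] = len(self.ocr_grids)
        return out

    def select(self, tag: str, option_id: Optional[int] = None):
        return [
            r
            for r in self.records
            if r.tag == tag and (option_id is None or r.beam.option_id == option_id)
        ]


# ----------------------------------------------------------------------
# campaign design


def _sobpf_m_grid(m_max: float) -> list[float]:
    """Modulation sweep: 2, 3, then even steps, appending the terminal
    modulation when it extends the even grid by more than 0.75 g/cm2."""
    grid = [2.0, 3.0]
    m = 4.0
    while m <= m_max + 1e-9:
        grid.append(m)
        m += 2.0
    if m_max - grid[-1] > 0.75:
        grid.append(round(m_max, 1))
    return grid


def _rsf_design(spec: OptionSpec) -> tuple[list[float], list[float]]:
    """Ranges (min/median/max) and modulation columns for the RSF campaign.

    Columns are denser at low modulation where the SOBP factor changes
    fastest; rows whose range is below a column leave that cell unmeasured
    (filled later by the sanctioned log-fit extrapolation).
    """
    r_min, r_max = spec.r_min, spec.r_max
    rows = [r_min, round((r_min + r_max) / 2.0, 1), r_max]
    m_top = min(spec.m_max, r_max)
    tops = sorted({round(min(spec.m_max, r), 1) for r in rows})
    top_min = tops[0]
    if spec.group == "deep" or spec.option_id in (1, 2):
        k = 5 if spec.option_id in (1, 2) else 4
        if k == 5:
            mids = [3.0, round(0.45 * m_top, 1), round(0.75 * m_top, 1)]
        else:
            mids = [3.0, round(0.6 * m_top, 1)]
        cols = sorted({2.0, *mids, m_top})
    elif spec.group == "large":
        m2 = round(0.6 * top_min, 1)
        if m2 <= 3.05:
            m2 = round((3.0 + top_min) / 2.0, 1)
        cols = sorted({2.0, 3.0, m2, *tops})
    else:  # small group: sparser per-row design
        m1 = round(0.75 * top_min, 1)
        cols = sorted({2.0, m1, *tops})
    return rows, cols


def _validation_design(spec: OptionSpec, n_points: int, n_off: int, rng):
    """Randomized validation points for one option: mostly at the SOBP
    center/isocenter with the reference field at gantry 0, plus off-center/
    off-isocenter points and a sprinkling of non-reference fields/angles.
    Modulations stay within the span the commissioning sweep covers (the
    models refuse to extrapolate beyond it)."""
    pts = []
    m_covered = _sobpf_m_grid(spec.m_max)[-1]
    grid01 = lambda lo, hi: round(float(rng.uniform(lo, hi)) * 10) / 10.0
    for j in range(n_points):
        r = grid01(spec.r_min, spec.r_max)
        m = grid01(2.0, min(m_covered, r))
        field = spec.reference_field
        angle = 0.0
        if j % 4 == 3:
            t = round(float(rng.uniform(-5.0, 185.0)) / 5.0) * 5.0
            angle = t if t >= 0 else 360.0 + t
        if j % 5 == 4:
            field = FieldSize("circular", 14.0)
        dz_p = dz = x = y = 0.0
        if j < n_off:
            # the calibration point must stay on the flat SOBP plateau:
            # cap the longitudinal offset at (most of) the half-width of the
            # effective modulation, and at the 5 cm commissioning limit
            h = min(5.0, 0.9 * 0.81 * m / 2.0)
            draw = float(rng.uniform(-h, h))
            dz_p = math.copysign(math.floor(abs(draw) * 2) / 2.0, draw)
            # |dz| >= 0.5 so every one of these points is genuinely off-geometry
            dz = float(rng.choice([-1.0, 1.0])) * round(
                float(rng.uniform(0.5, 3.0)) * 2
            ) / 2.0
            if j % 2 == 1:
                x = round(float(rng.uniform(-4.0, 4.0)) * 2) / 2.0
                y = round(float(rng.uniform(-4.0, 4.0)) * 2) / 2.0
        pts.append((r, m, field, angle, dz_p, dz, x, y))
    return pts


class _Noise:
    """Truncated-Gaussian multiplicative noise with a measurement registry:
    identical commissioning conditions yield the identical reading."""

    def __init__(self, sigma: float, rng):
        self.sigma = sigma
        self.rng = rng
        self.registry: dict = {}

    def draw(self) -> float:
        if self.sigma == 0:
            return 1.0
        return 1.0 + float(
            truncnorm.rvs(-3.0, 3.0, scale=self.sigma, random_state=self.rng)
        )

    def measure(self, key, truth_value: float) -> float:
        if key not in self.registry:
            self.registry[key] = self.draw()
        return truth_value * self.registry[key]


def _key(beam: BeamSpec, geom: CalibrationGeometry, phantom: str = "water"):
    return (
        beam.option_id, round(beam.r, 3), round(beam.m, 3), str(beam.field),
        round(beam.gantry_angle, 3), round(geom.x, 3), round(geom.y, 3),
        round(geom.dz_p, 3), round(geom.dz, 3), phantom,
    )


def generate_campaign(
    truth: TruthMachine,
    sigma: Optional[float] = None,
    seed: Optional[int] = None,
    n_validation: int = 272,
) -> Campaign:
    """Generate the full commissioning + validation campaign.

    ``sigma`` overrides the truth machine's chamber noise (relative, 1-sigma);
    ``seed`` makes the campaign reproducible.  The default design sizes are
    (ROF, SOBPF, RSF, FSF, GACF, validation) = (24, 182, 324, 54, 75, 272).
    """
    if sigma is None:
        sigma = truth.sigma
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng(seed)
    noise = _Noise(sigma, rng)
    ocr_scale = 0.0 if sigma == 0 else truth.sigma_ocr
    records: list[MeasurementRecord] = []
    cat = truth.catalog

    def measure(tag, beam, geom, phantom="water"):
        psi = truth.output(beam, geom)
        val = noise.measure(_key(beam, geom, phantom), psi)
        records.append(MeasurementRecord(beam, geom, val, tag))

    # ROF: one measurement per option at its deepest commissioned range
    for spec in sorted(cat, key=lambda s: s.option_id):
        beam = BeamSpec(spec.option_id, spec.rof_range, spec.rof_modulation,
                        spec.reference_field)
        measure("ROF", beam, truth.geometry(spec.option_id))

    # SOBPF: modulation sweep at the deepest range
    for spec in sorted(cat, key=lambda s: s.option_id):
        for m in _sobpf_m_grid(spec.m_max):
            beam = BeamSpec(spec.option_id, spec.rof_range, m, spec.reference_field)
            measure("SOBPF", beam, truth.geometry(spec.option_id))

    # RSF: three ranges per option, modulation columns truncated at each range
    for spec in sorted(cat, key=lambda s: s.option_id):
        rows, cols = _rsf_design(spec)
        for r in rows:
            for m in cols:
                if m <= min(spec.m_max, r) + 1e-9:
                    beam = BeamSpec(spec.option_id, r, m, spec.reference_field)
                    measure("RSF", beam, truth.geometry(spec.option_id))

    # FSF: three options per group, six apertures each
    fields = [FieldSize("circular", 3.5), FieldSize("square", 5.0),
              FieldSize("square", 10.0), FieldSize("circular", 14.0),
              FieldSize("square", 20.0), FieldSize("circular", 25.0)]
    for oid in _FSF_OPTIONS:
        spec = cat.get(oid)
        for fld in fields:
            beam = BeamSpec(oid, spec.rof_range, spec.rof_modulation, fld)
            measure("FSF", beam, truth.geometry(oid))

    # GACF: five options, every 15 degrees over the arc (acrylic phantom)
    for group, oids in _GACF_OPTIONS.items():
        for oid in oids:
            spec = cat.get(oid)
            for ang in _GACF_ANGLES:
                beam = BeamSpec(oid, spec.rof_range, spec.rof_modulation,
                                spec.reference_field, gantry_angle=float(ang))
                measure("GACF", beam, truth.geometry(oid), phantom="acrylic")

    # source-shift triplets for the analytical models: max/median/min range
    # at the modulation giving (nearest the 0.1 grid) the same r
    for spec in sorted(cat, key=lambda s: s.option_id):
        r_star = compute_r(spec.rof_range, spec.rof_modulation, truth.conv)
        rows = [spec.r_max, round((spec.r_min + spec.r_max) / 2.0, 1), spec.r_min]
        for r in rows:
            m = (r - truth.conv.delta_r) / (truth.conv.rho_m * (1.0 + r_star))
            m = round(min(max(m, 2.0), min(spec.m_max, r)), 1)
            beam = BeamSpec(spec.option_id, r, m, spec.reference_field)
            measure("source_shift", beam, truth.geometry(spec.option_id))

    # OCR: one 2-D array acquisition per option, 10 mm pitch over +-10 cm
    ocr_grids: dict[int, OCRGrid] = {}
    axis = np.arange(-10.0, 10.0 + 1e-9, 1.0)
    xg, yg = np.meshgrid(axis, axis, indexing="ij")
    for spec in sorted(cat, key=lambda s: s.option_id):
        vals = truth._ocr_raw(spec.option_id, xg, yg)
        if ocr_scale > 0:
            eps = truncnorm.rvs(-3.0, 3.0, scale=ocr_scale, size=vals.shape,
                                random_state=rng)
            vals = vals * (1.0 + eps)
        ocr_grids[spec.option_id] = OCRGrid(axis.copy(), axis.copy(), vals)

    # validation: independent outputs, never drawn from the registry
    quota = {oid: (12 if oid <= 8 else 11) for oid in cat.option_ids}
    off_quota = {oid: (3 if oid <= 12 else 2) for oid in cat.option_ids}
    total = sum(quota.values())
    if total != n_validation:  # rescale for non-default sizes
        ids = cat.option_ids
        quota = {oid: n_validation // len(ids) for oid in ids}
        for oid in ids[: n_validation % len(ids)]:
            quota[oid] += 1
        off_quota = {oid: max(1, quota[oid] // 5) for oid in ids}
    for spec in sorted(cat, key=lambda s: s.option_id):
        pts = _validation_design(spec, quota[spec.option_id],
                                 off_quota[spec.option_id], rng)
        for r, m, fld, ang, dz_p, dz, x, y in pts:
            beam = BeamSpec(spec.option_id, r, m, fld, gantry_angle=ang)
            geom = truth.geometry(spec.option_id, dz_p=dz_p, dz=dz, x=x, y=y)
            psi = truth.output(beam, geom) * noise.draw()
            records.append(MeasurementRecord(beam, geom, psi, "validation"))

    return Campaign(truth=truth, records=records, ocr_grids=ocr_grids,
                    sigma=sigma, seed=seed)


# ----------------------------------------------------------------------
# table construction


def tables_from_campaign(campaign: Campaign) -> CommissioningTables:
    """Build the correction-model tables from a campaign, factor by factor:
    each entry is the ratio of a measured output to its reference condition,
    and unmeasurable range-shifter cells are filled by the log-fit
    extrapolation."""
    cat = campaign.truth.catalog
    by = {}
    for rec in campaign.records:
        by.setdefault(rec.tag, {}).setdefault(rec.beam.option_id, []).append(rec)

    def _require(tag):
        if tag not in by:
            raise ValueError(f"campaign is missing the {tag} measurements")
        return by[tag]

    rof_recs = _require("ROF")
    ref_opt = 20
    if ref_opt not in rof_recs:
        raise ValueError("campaign lacks the calibration option's ROF measurement")
    psi_o = rof_recs[ref_opt][0].psi_measured
    rof = {oid: recs[0].psi_measured / psi_o for oid, recs in rof_recs.items()}

    sobpf = {}
    for oid, recs in _require("SOBPF").items():
        spec = cat.get(oid)
        ms = np.array([r.beam.m for r in recs])
        vals = np.array([r.psi_measured for r in recs])
        order = np.argsort(ms)
        ms, vals = ms[order], vals[order]
        iref = int(np.argmin(np.abs(ms - spec.rof_modulation)))
        if abs(ms[iref] - spec.rof_modulation) > 1e-6:
            raise ValueError(
                f"option {oid}: SOBPF sweep lacks the reference modulation"
            )
        sobpf[oid] = Grid1D(ms, vals / vals[iref])

    rsf = {}
    for oid, recs in _require("RSF").items():
        spec = cat.get(oid)
        rows = sorted({round(r.beam.r, 3) for r in recs})
        cols = sorted({round(r.beam.m, 3) for r in recs})
        vals = np.full((len(rows), len(cols)), np.nan)
        for rec in recs:
            i = rows.index(round(rec.beam.r, 3))
            j = cols.index(round(rec.beam.m, 3))
            vals[i, j] = rec.psi_measured
        if np.isnan(vals[-1]).any():
            raise ValueError(f"option {oid}: RSF row at the largest range incomplete")
        vals = vals / vals[-1]  # ratio to the largest-range row, column-wise
        placeholder = np.isnan(vals)
        vals[placeholder] = 1.0  # overwritten by the log fit below
        grid = RSFGrid(np.array(rows), np.array(cols), vals, placeholder)
        # reset mask so fill_rsf_placeholders recognises cells M > R as missing
        grid.placeholder = np.zeros_like(placeholder)
        rsf[oid] = grid

    fsf = {}
    for oid, recs in _require("FSF").items():
        spec = cat.get(oid)
        eq = np.array([r.beam.field.equivalent_square for r in recs])
        vals = np.array([r.psi_measured for r in recs])
        order = np.argsort(eq)
        eq, vals = eq[order], vals[order]
        iref = int(np.argmin(np.abs(eq - spec.reference_field.equivalent_square)))
        fsf[oid] = Grid1D(eq, vals / vals[iref])

    gacf = {}
    gacf_by_group: dict[str, list] = {}
    for oid, recs in _require("GACF").items():
        gacf_by_group.setdefault(cat.group_of(oid), []).append(recs)
    for group, option_sets in gacf_by_group.items():
        curves = []
        for recs in option_sets:
            t = np.array([arc_position(r.beam.gantry_angle) for r in recs])
            vals = np.array([r.psi_measured for r in recs])
            order = np.argsort(t)
            t, vals = t[order], vals[order]
            izero = int(np.argmin(np.abs(t)))
            curves.append((t, vals / vals[izero]))
        t0 = curves[0][0]
        mean = np.mean([c[1] for c in curves], axis=0)
        gacf[group] = Grid1D(t0, mean)

    ocr = {}
    for oid, grid in campaign.ocr_grids.items():
        i0 = int(np.argmin(np.abs(grid.x_axis)))
        j0 = int(np.argmin(np.abs(grid.y_axis)))
        ocr[oid] = OCRGrid(grid.x_axis, grid.y_axis, grid.values / grid.values[i0, j0])

    ref_spec = cat.get(ref_opt)
    tables = CommissioningTables(
        psi_o=psi_o,
        rof=rof,
        sobpf=sobpf,
        rsf=rsf,
        ocr=ocr,
        fsf=fsf,
        gacf=gacf,
        option_groups={s.option_id: s.group for s in cat},
        reference=ReferenceConditions(
            option_id=ref_opt, r=ref_spec.rof_range, m=ref_spec.rof_modulation,
            field=ref_spec.reference_field,
        ),
    )
    for oid in rsf:
        tables.fill_rsf_placeholders(oid)
    return tables


def fitting_dataset(campaign: Campaign, option_id: int):
    """(R, M, psi) arrays for fitting the analytical models of one option.

    The same absolute outputs that build the correction-model tables are
    reused (repeated conditions carry the same reading): the modulation
    sweep and every range-shifter measurement, which together cover the
    deepest range densely (stage 1) and the median/minimum ranges (the
    across-range stage-2 data), plus the matched-r source-shift triplet.
    """
    recs = campaign.select("SOBPF", option_id) + campaign.select(
        "source_shift", option_id
    )
    seen = {(round(r.beam.r, 3), round(r.beam.m, 3)) for r in recs}
    for rec in campaign.select("RSF", option_id):
        key = (round(rec.beam.r, 3), round(rec.beam.m, 3))
        if key not in seen:
            recs.append(rec)
            seen.add(key)
    r = np.array([rec.beam.r for rec in recs])
    m = np.array([rec.beam.m for rec in recs])
    psi = np.array([rec.psi_measured for rec in recs])
    return r, m, psi


def fit_all_options(campaign: Campaign):
    """Fit model B for every option and derive model C from it.

    Returns ``(params_b, params_c)`` dicts keyed by option id.  Model C is
    obtained by the mathematical conversion from the fitted model B over the
    option's commissioned r span (the stable construction; a direct quartic
    fit is available as :func:`protonmu.analytical.fit_model_C`).
    """
    from .analytical import convert_B_to_C, fit_model_B

    params_b, params_c = {}, {}
    for spec in sorted(campaign.truth.catalog, key=lambda s: s.option_id):
        oid = spec.option_id
        r, m, psi = fitting_dataset(campaign, oid)
        params_b[oid] = fit_model_B(
            r, m, psi, r_l=spec.r_lowest, r_max=spec.rof_range, option_id=oid,
            conv=campaign.truth.conv,
        )
        lo = compute_r(spec.rof_range, min(spec.m_max, spec.rof_range),
                       campaign.truth.conv)
        hi = compute_r(spec.rof_range, 2.0, campaign.truth.conv)
        params_c[oid] = convert_B_to_C(params_b[oid], (lo, hi))
    return params_b, params_c


def validation_study(
    truth: Optional[TruthMachine] = None,
    seed: Optional[int] = 0,
    sigma: Optional[float] = None,
):
    """One full end-to-end study: campaign -> tables -> fits -> validation.

    Returns a dict with per-model percent-difference arrays (``"A"``,
    ``"B"``, ``"C"``), the built ``"tables"``, the fitted ``"params_b"``/
    ``"params_c"`` and the ``"campaign"`` itself.
    """
    from .correction import predict_output_A
    from .analytical import predict_output_B, predict_output_C
    from .stats import percent_diff

    if truth is None:
        truth = TruthMachine.default()
    campaign = generate_campaign(truth, sigma=sigma, seed=seed)
    tables = tables_from_campaign(campaign)
    params_b, params_c = fit_all_options(campaign)
    diffs: dict[str, list] = {"A": [], "B": [], "C": []}
    for rec in campaign.select("validation"):
        oid = rec.beam.option_id
        preds = {
            "A": predict_output_A(rec.beam, rec.geom, tables),
            "B": predict_output_B(rec.beam, rec.geom, params_b[oid], tables),
            "C": predict_output_C(rec.beam, rec.geom, params_c[oid], tables),
        }
        for name, pred in preds.items():
            diffs[name].append(percent_diff(pred.psi, rec.psi_measured))
    return {
        "A": np.array(diffs["A"]),
        "B": np.array(diffs["B"]),
        "C": np.array(diffs["C"]),
        "tables": tables,
        "params_b": params_b,
        "params_c": params_c,
        "campaign": campaign,
    }
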