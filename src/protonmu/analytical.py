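"""Analytical SOBP output models in the shape variable r, and their fitting.

A passively modulated SOBP is characterised by the dimensionless variable

    r = (R' - M') / M'

with R' the depth of the distal 100% dose (range straggling included) and M'
the distal-100%-to-proximal-100% width.  On a machine that specifies range
and modulation by the vendor convention (R at the distal 90%, M from distal
90% to proximal 95%), the mean conversion over a large body of measured
depth-dose scans is R' = R - 0.31 g/cm2 and M' = 0.81 * M, so

    r = ((R - 0.31) - 0.81 M) / (0.81 M).

Model B predicts the output as an option-specific analytical form::

    psi_B = CF * psi_o * Dc * 100 / (1 + a0 * r**a1)
            * (s0 + s1 * (R - R_L))
            * ISF_OCF * OCR * FSF * GACF

with the first bracket the *basic model* (plateau output vs SOBP shape) and
the second the *source-shift* term (the effective source moves slightly when
absorbers shift the range within an option; R_L is the option's lowest
commissioned range).  Model C replaces the basic model's rational form by a
quartic polynomial in r - a truncated series expansion of the same shape::

    psi_C = (p0 + p1 r + p2 r^2 + p3 r^3 + p4 r^4)
            * (s2 + s3 * (R - R_L)) * ISF_OCF * OCR * FSF * GACF

Both are fit per option from the same absolute-output modulation sweep used
to build the SOBP-factor table (stage 1, at the option's largest range) plus
a small set of measurements across ranges (stage 2, fit on the ratio of each
measurement to the stage-1 basic term evaluated at that measurement's own r).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .machine import BeamSpec, CalibrationGeometry
from .tables import CommissioningTables
from .correction import OutputPrediction, isf_ocf

__all__ = [
    "RConversion",
    "FitDiagnostics",
    "AnalyticalParams",
    "FitError",
    "compute_r",
    "fit_model_B",
    "fit_model_C",
    "convert_B_to_C",
    "predict_output_B",
    "predict_output_C",
    "basic_term_B",
    "basic_term_C",
    "write_params",
    "read_params",
]


class FitError(RuntimeError):
    """Insufficient or degenerate data, or the optimizer failed to converge."""


@dataclass(frozen=True)
class RConversion:
    """Vendor-to-physical conversion of (R, M) into the shape variable r.

    ``delta_r`` is the mean R - R' offset (g/cm2) and ``rho_m`` the mean
    M'/M ratio; the defaults are the values derived for this machine class
    from 230 measured SOBP scans.  Other machines may override them.
    """

    delta_r: float = 0.31
    rho_m: float = 0.81

    def __post_init__(self) -> None:
        if not (self.delta_r > 0 and self.rho_m > 0):
            raise ValueError("conversion constants must be positive")


def compute_r(r_range: float, m: float, conv: RConversion = RConversion()) -> float:
    """The SOBP shape variable r = ((R - delta_r) - rho_m*M) / (rho_m*M).

    r = 0 at full modulation (plateau reaching the surface); it grows as the
    plateau narrows relative to the range.
    """
    if m <= 0:
        raise ValueError("modulation must be positive")
    m_eff = conv.rho_m * m
    return ((r_range - conv.delta_r) - m_eff) / m_eff


@dataclass
class FitDiagnostics:
    n_points: int
    residual_norm: float
    n_restarts_used: int = 0
    degenerate: bool = False
    message: str = ""


@dataclass
class AnalyticalParams:
    """Per-option fitted constants for the analytical models.

    Model-B fields: ``a0, a1, s0, s1`` with the amplitude split across
    ``cf * psi_o * d_c * 100``.  When the amplitude is not separately
    measured it is absorbed into ``cf`` (``d_c = 1`` in this normalized
    mode).  Model-C fields: ``p`` (quintuple p0..p4) and ``s2, s3``.
    """

    option_id: int
    r_l: float
    r_max: float
    cf: float = 1.0
    psi_o: float = 1.0
    d_c: float = 1.0
    a0: Optional[float] = None
    a1: Optional[float] = None
    s0: Optional[float] = None
    s1: Optional[float] = None
    p: Optional[tuple[float, float, float, float, float]] = None
    s2: Optional[float] = None
    s3: Optional[float] = None
    conv: RConversion = dc_field(default_factory=RConversion)
    diagnostics_b: Optional[FitDiagnostics] = None
    diagnostics_c: Optional[FitDiagnostics] = None

    @property
    def amplitude(self) -> float:
        """CF * psi_o * Dc * 100 - the basic model's scale (cGy/MU)."""
        return self.cf * self.psi_o * self.d_c * 100.0


def basic_term_B(r, params: AnalyticalParams):
    """Basic model of model B: amplitude / (1 + a0 * r**a1)."""
    if params.a0 is None:
        raise FitError(f"option {params.option_id}: model B not fitted")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) and params.a1 != int(params.a1):
        raise ValueError(
            "r < 0 (modulation wider than the physical range): outside the "
            "model's domain"
        )
    return params.amplitude / (1.0 + params.a0 * np.power(r, params.a1))


def basic_term_C(r, params: AnalyticalParams):
    """Basic model of model C: quartic polynomial in r."""
    if params.p is None:
        raise FitError(f"option {params.option_id}: model C not fitted")
    r = np.asarray(r, dtype=float)
    p0, p1, p2, p3, p4 = params.p
    return p0 + r * (p1 + r * (p2 + r * (p3 + r * p4)))


def _source_shift(r_range, s_a: float, s_b: float, r_l: float):
    return s_a + s_b * (np.asarray(r_range, dtype=float) - r_l)


# ----------------------------------------------------------------------
# fitting


def _split_stages(r_range, m, psi, r_max):
    r_range = np.asarray(r_range, dtype=float)
    m = np.asarray(m, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if not (len(r_range) == len(m) == len(psi)):
        raise FitError("R, M, psi must have equal length")
    at_max = np.isclose(r_range, r_max, atol=1e-6)
    return r_range, m, psi, at_max


def _fit_source_shift(r_range, ratio, r_l):
    """Weighted-equal linear fit of the source-shift line s(R)."""
    if len(np.unique(np.round(r_range, 6))) < 2:
        raise FitError("source-shift fit needs measurements at >= 2 ranges")
    A = np.column_stack([np.ones_like(r_range), r_range - r_l])
    coef, *_ = np.linalg.lstsq(A, ratio, rcond=None)
    return float(coef[0]), float(coef[1])


def fit_model_B(
    r_range: Sequence[float],
    m: Sequence[float],
    psi: Sequence[float],
    *,
    r_l: float,
    r_max: float,
    option_id: int = 0,
    conv: RConversion = RConversion(),
    psi_o: float = 1.0,
    d_c: float = 1.0,
    max_restarts: int = 5,
) -> AnalyticalParams:
    """Fit model B's option-specific constants from absolute outputs.

    Stage 1 fits the basic model ``A / (1 + a0 r**a1)`` by nonlinear least
    squares to the modulation sweep at the option's largest range (>= 4
    points), multi-starting a0 on a log grid.  Stage 2 fits the source-shift
    line to the ratio of every off-maximum measurement to the stage-1 basic
    term at its own r.  The amplitude is stored as ``cf`` relative to the
    supplied ``psi_o`` and ``d_c`` (both default 1: fully absorbed mode).
    """
    r_range, m, psi, at_max = _split_stages(r_range, m, psi, r_max)
    if at_max.sum() < 4:
        raise FitError(
            f"option {option_id}: stage 1 needs >= 4 modulation points at "
            f"the largest range ({at_max.sum()} found)"
        )
    r1 = np.array([compute_r(R, M, conv) for R, M in zip(r_range[at_max], m[at_max])])
    y1 = psi[at_max]
    if np.any(r1 < 0):
        raise FitError("stage 1 contains r < 0 points (M' wider than R')")

    # degenerate branch: no modulation dependence at all
    spread = np.ptp(y1) / np.mean(y1)
    if spread < 1e-12:
        amp = float(np.mean(y1))
        params = AnalyticalParams(
            option_id=option_id, r_l=r_l, r_max=r_max,
            cf=amp / (psi_o * d_c * 100.0), psi_o=psi_o, d_c=d_c,
            a0=0.0, a1=1.0, conv=conv,
        )
        diag = FitDiagnostics(
            n_points=int(at_max.sum()), residual_norm=0.0, degenerate=True,
            message="outputs constant across modulation: a0 = 0 branch",
        )
        params.diagnostics_b = diag
        s0, s1 = _fit_stage2_b(params, r_range, m, psi, at_max, conv)
        params.s0, params.s1 = s0, s1
        return params

    def resid(theta):
        amp_, a0_, a1_ = theta
        return amp_ / (1.0 + a0_ * np.power(r1, a1_)) - y1

    best = None
    restarts = 0
    a0_grid = np.logspace(-3, 1, max_restarts)
    lower = np.array([1e-9, 0.0, 0.05])
    upper = np.array([np.inf, np.inf, 10.0])
    for a0_init in [0.1, *a0_grid]:
        theta0 = np.array([np.max(y1) * 1.05, a0_init, 0.6])
        sol = least_squares(resid, theta0, method="trf", bounds=(lower, upper),
                            xtol=2.3e-16, ftol=2.3e-16, gtol=1e-15, max_nfev=20000)
        if best is None or sol.cost < best.cost - 1e-18:
            if best is not None:
                restarts += 1
            best = sol
        if best.cost < 1e-24:
            break
    if best is None or (not best.success and best.cost > 1e-12):
        raise FitError(f"option {option_id}: stage 1 did not converge")
    amp, a0, a1 = best.x
    params = AnalyticalParams(
        option_id=option_id, r_l=r_l, r_max=r_max,
        cf=float(amp) / (psi_o * d_c * 100.0), psi_o=psi_o, d_c=d_c,
        a0=float(a0), a1=float(a1), conv=conv,
    )
    params.diagnostics_b = FitDiagnostics(
        n_points=int(at_max.sum()),
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        n_restarts_used=restarts,
    )
    s0, s1 = _fit_stage2_b(params, r_range, m, psi, at_max, conv)
    params.s0, params.s1 = s0, s1
    return params


def _fit_stage2_b(params, r_range, m, psi, at_max, conv):
    if at_max.all():
        # single-range dataset: no source shift resolvable; identity line
        return 1.0, 0.0
    rr = np.array([compute_r(R, M, conv) for R, M in zip(r_range, m)])
    ratio = psi / basic_term_B(rr, params)
    return _fit_source_shift(r_range, ratio, params.r_l)


def fit_model_C(
    r_range: Sequence[float],
    m: Sequence[float],
    psi: Sequence[float],
    *,
    r_l: float,
    r_max: float,
    option_id: int = 0,
    conv: RConversion = RConversion(),
) -> AnalyticalParams:
    """Fit model C: linear least squares on the quartic in r (stage 1) plus
    the same ratio-based source-shift line (stage 2).

    The quartic is solved on a scaled variable r/max|r| for conditioning and
    the coefficients rescaled exactly, so noise-free quartic data is
    recovered to linear-algebra precision.
    """
    r_range, m, psi, at_max = _split_stages(r_range, m, psi, r_max)
    if at_max.sum() < 5:
        raise FitError(
            f"option {option_id}: quartic fit needs >= 5 points at the "
            f"largest range ({at_max.sum()} found)"
        )
    r1 = np.array([compute_r(R, M, conv) for R, M in zip(r_range[at_max], m[at_max])])
    y1 = psi[at_max]
    scale = np.max(np.abs(r1))
    if scale == 0 or len(np.unique(np.round(r1, 12))) < 5:
        raise FitError(
            f"option {option_id}: rank-deficient quartic design "
            "(need 5 distinct r values)"
        )
    V = np.vander(r1 / scale, 5, increasing=True)
    coef, res, rank, _ = np.linalg.lstsq(V, y1, rcond=None)
    if rank < 5:
        raise FitError(f"option {option_id}: rank-deficient quartic design")
    p = tuple(float(c / scale**k) for k, c in enumerate(coef))
    params = AnalyticalParams(
        option_id=option_id, r_l=r_l, r_max=r_max, p=p, conv=conv,
    )
    fitted = basic_term_C(r1, params)
    params.diagnostics_c = FitDiagnostics(
        n_points=int(at_max.sum()),
        residual_norm=float(np.linalg.norm(fitted - y1)),
    )
    if at_max.all():
        params.s2, params.s3 = 1.0, 0.0
    else:
        rr = np.array([compute_r(R, M, conv) for R, M in zip(r_range, m)])
        ratio = psi / basic_term_C(rr, params)
        params.s2, params.s3 = _fit_source_shift(r_range, ratio, r_l)
    return params


def convert_B_to_C(
    params_b: AnalyticalParams,
    r_span: tuple[float, float],
    n_samples: int = 200,
) -> AnalyticalParams:
    """Derive model C from a fitted model B (the *mathematical conversion*).

    The quartic is the least-squares fit to model B's basic term sampled
    densely over the option's commissioned r span — a truncated-series
    stand-in for the rational form.  This is the stable way to obtain model
    C: a direct quartic fit to raw outputs is ill conditioned for options
    whose modulation sweep covers few distinct r values.  The source-shift
    line carries over unchanged.
    """
    if params_b.a0 is None or params_b.s0 is None:
        raise FitError("model B must be fitted before conversion")
    lo, hi = r_span
    if not hi > lo:
        raise ValueError("need a non-degenerate r span")
    rs = np.linspace(lo, hi, n_samples)
    ys = basic_term_B(rs, params_b)
    scale = max(abs(lo), abs(hi))
    V = np.vander(rs / scale, 5, increasing=True)
    coef, *_ = np.linalg.lstsq(V, ys, rcond=None)
    p = tuple(float(c / scale**k) for k, c in enumerate(coef))
    params = AnalyticalParams(
        option_id=params_b.option_id, r_l=params_b.r_l, r_max=params_b.r_max,
        p=p, s2=params_b.s0, s3=params_b.s1, conv=params_b.conv,
    )
    params.diagnostics_c = FitDiagnostics(
        n_points=n_samples,
        residual_norm=float(np.linalg.norm(basic_term_C(rs, params) - ys)),
        message=f"converted from model B over r in [{lo:.3g}, {hi:.3g}]",
    )
    return params


# ----------------------------------------------------------------------
# prediction


def _geometric_factors(beam, geom, tables, allow_small_field):
    factors = {"ISF_OCF": isf_ocf(geom)}
    flags = []
    factors["OCR"] = tables.interp_ocr(beam.option_id, geom.x, geom.y)
    factors["FSF"] = tables.interp_fsf(
        beam.option_id, beam.field, allow_small_field=allow_small_field
    )
    if beam.field.equivalent_square <= 5.0 + 1e-9:
        flags.append(
            "field at or below 5x5 cm2 equivalent: direct output measurement "
            "recommended"
        )
    factors["GACF"] = tables.gacf_for_option(beam.option_id, beam.gantry_angle)
    return factors, flags


def predict_output_B(
    beam: BeamSpec,
    geom: CalibrationGeometry,
    params: AnalyticalParams,
    tables: CommissioningTables,
    *,
    allow_small_field: bool = False,
) -> OutputPrediction:
    """Predict output with model B for a fitted option."""
    if params.a0 is None or params.s0 is None:
        raise FitError(f"option {beam.option_id}: model B not fitted")
    r = compute_r(beam.r, beam.m, params.conv)
    basic = float(basic_term_B(r, params))
    shift = float(_source_shift(beam.r, params.s0, params.s1, params.r_l))
    factors, flags = _geometric_factors(beam, geom, tables, allow_small_field)
    psi = basic * shift
    for v in factors.values():
        psi *= v
    breakdown = {"basic_model": basic, "source_shift": shift, **factors}
    return OutputPrediction(psi=psi, psi_o=1.0, factors=breakdown, flags=flags)


def predict_output_C(
    beam: BeamSpec,
    geom: CalibrationGeometry,
    params: AnalyticalParams,
    tables: CommissioningTables,
    *,
    allow_small_field: bool = False,
) -> OutputPrediction:
    """Predict output with model C for a fitted option."""
    if params.p is None or params.s2 is None:
        raise FitError(f"option {beam.option_id}: model C not fitted")
    r = compute_r(beam.r, beam.m, params.conv)
    basic = float(basic_term_C(r, params))
    shift = float(_source_shift(beam.r, params.s2, params.s3, params.r_l))
    factors, flags = _geometric_factors(beam, geom, tables, allow_small_field)
    psi = basic * shift
    for v in factors.values():
        psi *= v
    breakdown = {"basic_model": basic, "source_shift": shift, **factors}
    return OutputPrediction(psi=psi, psi_o=1.0, factors=breakdown, flags=flags)


# ----------------------------------------------------------------------
# serialisation


def write_params(params: dict[int, AnalyticalParams], path) -> None:
    out = {}
    for oid, p in sorted(params.items()):
        rec = {
            "option_id": p.option_id, "r_l": p.r_l, "r_max": p.r_max,
            "cf": p.cf, "psi_o": p.psi_o, "d_c": p.d_c,
            "a0": p.a0, "a1": p.a1, "s0": p.s0, "s1": p.s1,
            "p": list(p.p) if p.p is not None else None,
            "s2": p.s2, "s3": p.s3,
            "conv": {"delta_r": p.conv.delta_r, "rho_m": p.conv.rho_m},
            "diagnostics_b": asdict(p.diagnostics_b) if p.diagnostics_b else None,
            "diagnostics_c": asdict(p.diagnostics_c) if p.diagnostics_c else None,
        }
        out[str(oid)] = rec
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)
        fh.write("\n")


def read_params(path) -> dict[int, AnalyticalParams]:
    with open(path) as fh:
        data = json.load(fh)
    params = {}
    for k, rec in data.items():
        p = AnalyticalParams(
            option_id=rec["option_id"], r_l=rec["r_l"], r_max=rec["r_max"],
            cf=rec["cf"], psi_o=rec["psi_o"], d_c=rec["d_c"],
            a0=rec["a0"], a1=rec["a1"], s0=rec["s0"], s1=rec["s1"],
            p=tuple(rec["p"]) if rec["p"] is not None else None,
            s2=rec["s2"], s3=rec["s3"],
            conv=RConversion(**rec.get("conv", {})),
        )
        if rec.get("diagnostics_b"):
            p.diagnostics_b = FitDiagnostics(**rec["diagnostics_b"])
        if rec.get("diagnostics_c"):
            p.diagnostics_c = FitDiagnostics(**rec["diagnostics_c"])
        params[int(k)] = p
    return params
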