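"""Correction-based output model (model A) and dose-to-MU conversion.

The predicted output at the MU calibration point is a product of the
measured reference output and independent correction factors::

    psi_A = psi_o * ROF * SOBPF * RSF * ISF_OCF * OCR * FSF * GACF

where ``ISF_OCF = [(ESAD - dz_p) / (ESAD - dz_p - dz)]^2`` combines the
inverse-square correction for an off-isocenter calibration point with the
SOBP off-center correction; on the flat SOBP plateau, sliding the point along
the beam axis changes the output only through the inverse-square distance to
the effective source.  The legacy pair of a PDD-based SOBP off-center factor
and a plain inverse-square factor is provided for comparison with older
workflows.

Monitor units for a prescription follow as ``MU = D_vpnc / psi``, with
``D_vpnc`` the dose at the calibration point of a verification plan computed
in a water phantom without the range compensator (compensator and patient
scatter cancel between plan and verification geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from .machine import BeamSpec, CalibrationGeometry
from .tables import CommissioningTables

__all__ = [
    "OutputPrediction",
    "MUCalculation",
    "sobpocf",
    "isf",
    "isf_ocf",
    "predict_output_A",
    "dose_to_mu",
]


@dataclass
class OutputPrediction:
    """A predicted output with its multiplicative audit trail.

    ``psi`` equals ``psi_o`` times the product of every entry in
    ``factors``; ``flags`` carries warnings (placeholder RSF corner used,
    small-field FSF override, calibration point possibly off the SOBP
    plateau) that a physicist should review before using the number.
    """

    psi: float
    psi_o: float
    factors: dict[str, float]
    flags: list[str] = dc_field(default_factory=list)

    def product(self) -> float:
        p = self.psi_o
        for v in self.factors.values():
            p *= v
        return p


@dataclass(frozen=True)
class MUCalculation:
    mu: float
    mu_rounded: float
    resolution: float


def sobpocf(pdd_at_point: float, ssd: float, d_p: float, d_c: float) -> float:
    """Legacy SOBP off-center factor from a fixed-SDD PDD measurement.

    ``pdd_at_point`` is the percent depth dose at the calibration depth
    expressed as a fraction of the SOBP-center dose; ``ssd`` the
    source-to-surface distance of the PDD scan; ``d_p``/``d_c`` the depths of
    the calibration point and of the SOBP center.  Superseded by
    :func:`isf_ocf` in this package's own workflow.
    """
    if ssd <= 0 or d_p <= 0 or d_c <= 0:
        raise ValueError("distances must be positive")
    return pdd_at_point * (ssd + d_p) ** 2 / (ssd + d_c) ** 2


def isf(sad: float, spd: float) -> float:
    """Legacy inverse-square factor (SAD / source-to-point distance)^2."""
    if sad <= 0 or spd <= 0:
        raise ValueError("distances must be positive")
    return (sad / spd) ** 2


def isf_ocf(geom: CalibrationGeometry) -> float:
    """Combined inverse-square and SOBP off-center factor.

    ``[(ESAD - dz_p) / (ESAD - dz_p - dz)]^2`` with dz_p the signed
    longitudinal offset of the calibration point from the SOBP center
    (negative downstream, positive upstream) and dz the offset of the SOBP
    center from the isocenter.
    """
    num = geom.esad - geom.dz_p
    den = geom.esad - geom.dz_p - geom.dz
    if num <= 0 or den <= 0:
        raise ValueError(
            f"degenerate geometry: ESAD - dz_p = {num:g}, "
            f"ESAD - dz_p - dz = {den:g} must both be positive"
        )
    return (num / den) ** 2


def predict_output_A(
    beam: BeamSpec,
    geom: CalibrationGeometry,
    tables: CommissioningTables,
    *,
    allow_small_field: bool = False,
) -> OutputPrediction:
    """Predict the output (cGy/MU) with the correction-based model.

    The beam should already be validated against the machine catalog.  Any
    missing or out-of-grid table raises, naming the factor.
    """
    oid = beam.option_id
    flags: list[str] = []

    rof = tables.lookup_rof(oid)
    sobpf = tables.interp_sobpf(oid, beam.m)
    rsf, tainted = tables.interp_rsf_flagged(oid, beam.r, beam.m)
    if tainted:
        flags.append(
            "RSF interpolation cell includes an extrapolated placeholder corner"
        )
    geom_factor = isf_ocf(geom)
    ocr = tables.interp_ocr(oid, geom.x, geom.y)
    small = beam.field.equivalent_square <= 5.0 + 1e-9
    fsf = tables.interp_fsf(oid, beam.field, allow_small_field=allow_small_field)
    if small:
        flags.append(
            "field at or below 5x5 cm2 equivalent: direct output measurement "
            "recommended"
        )
    gacf = tables.gacf_for_option(oid, beam.gantry_angle)
    m_eff = 0.81 * beam.m
    if abs(geom.dz_p) > m_eff / 2.0:
        flags.append(
            f"|dz_p| = {abs(geom.dz_p):g} cm exceeds half the effective "
            f"modulation ({m_eff / 2:.2f} cm): point may be off the SOBP plateau"
        )

    factors = {
        "ROF": rof,
        "SOBPF": sobpf,
        "RSF": rsf,
        "ISF_OCF": geom_factor,
        "OCR": ocr,
        "FSF": fsf,
        "GACF": gacf,
    }
    psi = tables.psi_o
    for v in factors.values():
        psi *= v
    if not psi > 0:
        raise ValueError("predicted output must be positive")
    return OutputPrediction(psi=psi, psi_o=tables.psi_o, factors=factors, flags=flags)


def dose_to_mu(d_vpnc: float, psi: float, resolution: float = 0.1) -> MUCalculation:
    """Convert a verification-plan dose (cGy) to monitor units.

    Returns both the unrounded MU and the MU rounded to the delivery
    system's counting resolution (default 0.1 MU).
    """
    if d_vpnc <= 0 or psi <= 0:
        raise ValueError("dose and output must be positive")
    mu = d_vpnc / psi
    rounded = round(mu / resolution) * resolution
    # avoid float detritus like 139.79999999999998
    rounded = float(f"{rounded:.10g}")
    return MUCalculation(mu=mu, mu_rounded=rounded, resolution=resolution)
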