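"""CT dose bookkeeping: dose-length product and effective dose.

The effective dose uses the standard adult-abdomen conversion coefficient
k = 0.015 mSv/(mGy·cm).  Reported values are rounded half-up (commercial
rounding), which is what dose reports print: e.g. DLP 510.0 mGy·cm gives
7.65 mSv, reported as 7.7 mSv.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

ABDOMEN_CONVERSION_FACTOR = 0.015
"""mSv per mGy·cm for adult abdominal CT."""


@dataclass(frozen=True)
class DoseRecord:
    """One acquisition's dose summary.

    Attributes
    ----------
    ctdi_vol : float
        Volume CT dose index, mGy.
    scan_length : float
        Scan length, cm.
    dlp : float
        Dose-length product, mGy·cm.
    d_eff : float
        Effective dose, mSv (unrounded).
    d_eff_reported : float
        Effective dose rounded half-up for reporting.
    conversion_factor : float
        mSv/(mGy·cm) used.
    """

    ctdi_vol: float
    scan_length: float
    dlp: float
    d_eff: float
    d_eff_reported: float
    conversion_factor: float = ABDOMEN_CONVERSION_FACTOR


def dlp(ctdi_vol: float, scan_length: float) -> float:
    """Dose-length product DLP = CTDI_vol × scan length [mGy·cm]."""
    if ctdi_vol < 0 or scan_length < 0:
        raise ValueError("ctdi_vol and scan_length must be nonnegative")
    return ctdi_vol * scan_length


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as dose reports do (not banker's)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def effective_dose(
    dlp_value: float,
    factor: float = ABDOMEN_CONVERSION_FACTOR,
    rounding: int = 1,
) -> tuple[float, float]:
    """Effective dose D_eff = k × DLP [mSv].

    Returns ``(reported, unrounded)`` where *reported* is rounded half-up
    to ``rounding`` decimals.
    """
    if dlp_value < 0:
        raise ValueError("dlp must be nonnegative")
    raw = factor * dlp_value
    # Quantize the decimal product, not the binary float: 0.015 × 510.0
    # is exactly 7.65 and must report as 7.7, but the nearest double is
    # 7.6499999999999995.
    exact = Decimal(repr(factor)) * Decimal(repr(dlp_value))
    q = Decimal(1).scaleb(-rounding)
    return float(exact.quantize(q, rounding=ROUND_HALF_UP)), raw


def dose_record(
    ctdi_vol: float,
    scan_length: float,
    factor: float = ABDOMEN_CONVERSION_FACTOR,
) -> DoseRecord:
    """Full dose summary for one acquisition."""
    d = dlp(ctdi_vol, scan_length)
    reported, raw = effective_dose(d, factor)
    return DoseRecord(
        ctdi_vol=ctdi_vol,
        scan_length=scan_length,
        dlp=d,
        d_eff=raw,
        d_eff_reported=reported,
        conversion_factor=factor,
    )
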