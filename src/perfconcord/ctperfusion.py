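"""Deconvolution CT perfusion: BF, BV, PEM from an AIF and a tissue TAC.

Tissue enhancement during contrast passage is modelled as the convolution
of the arterial input function (AIF) with the flow-scaled residue function
BF·R(t), plus a slow leakage (permeability) component.  Deconvolution by
truncated singular-value decomposition (TSVD) of the discrete convolution
system recovers k(t) = BF·R(t); then

    BF  = max k(t)            [ml/(100 ml·min)]
    BV  = ∫ k(t) dt           [ml/100 ml], first-pass support only
    MTT = 60 · BV / BF        [s]

Permeability (PEM) is estimated separately from the post-first-pass
segment with a Patlak plot (tissue/AIF against cumulative-AIF/AIF), whose
slope is the leakage rate constant; the fitted leakage is subtracted from
the tissue curve before deconvolution so it does not contaminate BV.

HU curves are treated as linearly proportional to contrast concentration
with the same proportionality in artery and tissue (no hematocrit
correction), so all outputs are in the conventional per-100-ml units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Converts the per-second rate constants of the discrete system into
#: ml/(100 ml·min): 100 ml normalisation × 60 s/min.
PER_SECOND_TO_ML_100ML_MIN = 6000.0

DEFAULT_REGULARIZATION = 0.15
DEFAULT_FIRST_PASS_END = 30.0  # s; start of the Patlak window
DEFAULT_RESIDUE_CUTOFF = 0.02  # BV integration stops below this × peak


@dataclass
class PerfusionCurves:
    """Baseline-subtracted AIF and tissue time–attenuation curves."""

    time: np.ndarray
    aif: np.ndarray
    tissue: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.aif = np.asarray(self.aif, dtype=float)
        self.tissue = np.asarray(self.tissue, dtype=float)
        if not (len(self.time) == len(self.aif) == len(self.tissue)):
            raise ValueError("time, aif and tissue must have equal length")
        if len(self.time) < 10:
            raise ValueError("need at least 10 time points")
        dt = np.diff(self.time)
        if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError("time grid must be strictly increasing and uniform")

    @property
    def sampling_interval(self) -> float:
        return float(self.time[1] - self.time[0])


@dataclass
class PerfusionParams:
    """Deconvolution outputs in conventional CT-perfusion units."""

    BF: float  # ml/(100 ml·min)
    BV: float  # ml/100 ml
    PEM: float  # ml/(100 ml·min)
    MTT: float  # s
    residue: np.ndarray = field(default_factory=lambda: np.array([]))
    pem_clamped: bool = False
    subject_id: str = ""
    region_label: str = ""


def _convolution_matrix(aif: np.ndarray, dt: float) -> np.ndarray:
    n = len(aif)
    A = np.zeros((n, n))
    for i in range(n):
        A[i, : i + 1] = aif[i::-1]
    return A * dt


def estimate_pem(
    curves: PerfusionCurves,
    first_pass_end: float = DEFAULT_FIRST_PASS_END,
) -> tuple[float, bool]:
    """Patlak-plot permeability over the post-first-pass segment.

    Regresses tissue/AIF on cumulative-AIF/AIF for t >= ``first_pass_end``;
    the slope is the leakage rate constant, returned in ml/(100 ml·min).
    Negative slopes are clamped to zero and flagged.  The estimator is
    invariant under a common rescaling of both curves.
    """
    t = curves.time
    late = t >= first_pass_end
    if late.sum() < 4:
        raise ValueError("need >=4 samples after first_pass_end")
    if np.any(np.abs(curves.aif[late]) < 1e-12):
        raise ValueError("AIF vanishes in the Patlak window")
    dt = curves.sampling_interval
    cum_aif = np.cumsum(curves.aif) * dt
    x = cum_aif[late] / curves.aif[late]
    y = curves.tissue[late] / curves.aif[late]
    slope = np.polyfit(x, y, 1)[0]
    pem = slope * PER_SECOND_TO_ML_100ML_MIN
    clamped = pem < 0
    return (max(pem, 0.0), clamped)


def deconvolve(
    curves: PerfusionCurves,
    regularization: float = DEFAULT_REGULARIZATION,
    correct_leakage: bool = True,
    first_pass_end: float = DEFAULT_FIRST_PASS_END,
    residue_cutoff: float = DEFAULT_RESIDUE_CUTOFF,
) -> PerfusionParams:
    """TSVD deconvolution of the tissue curve by the AIF.

    Singular values below ``regularization`` × the largest are discarded.
    With ``correct_leakage`` the Patlak-estimated leakage component is
    subtracted from the tissue curve first, and reported as PEM.  BV
    integrates the recovered flow-scaled residue (trapezoid) over its
    first-pass support, i.e. from the start until the residue decays below
    ``residue_cutoff`` × its peak.
    """
    if not 0 < regularization < 1:
        raise ValueError("regularization must lie in (0, 1)")
    if not np.any(curves.aif != 0):
        raise ValueError("AIF is identically zero")
    dt = curves.sampling_interval
    tissue = curves.tissue.copy()

    pem, pem_clamped = 0.0, False
    if correct_leakage:
        pem, pem_clamped = estimate_pem(curves, first_pass_end)
        leak_rate = pem / PER_SECOND_TO_ML_100ML_MIN
        tissue = tissue - leak_rate * np.cumsum(curves.aif) * dt

    A = _convolution_matrix(curves.aif, dt)
    U, sv, Vt = np.linalg.svd(A)
    keep = sv >= regularization * sv[0]
    k = Vt.T[:, keep] @ ((U.T[keep] @ tissue) / sv[keep])

    peak = float(k.max())
    if peak <= 0:
        return PerfusionParams(BF=0.0, BV=0.0, PEM=pem, MTT=0.0, residue=k,
                               pem_clamped=pem_clamped)
    BF = peak * PER_SECOND_TO_ML_100ML_MIN
    ipk = int(k.argmax())
    below = np.where(k[ipk:] < residue_cutoff * peak)[0]
    end = ipk + (int(below[0]) if len(below) else len(k) - 1 - ipk)
    BV = float(np.trapezoid(k[: end + 1], dx=dt)) * 100.0
    BV = max(BV, 0.0)
    MTT = 60.0 * BV / BF
    return PerfusionParams(BF=BF, BV=BV, PEM=pem, MTT=MTT, residue=k,
                           pem_clamped=pem_clamped)


def delay_correct(
    curves: PerfusionCurves, tolerance_samples: float = 1.0
) -> PerfusionCurves:
    """Align the tissue curve onset with the AIF onset.

    Onsets are estimated by back-extrapolating the steepest rising
    tangent of each curve to its zero crossing (robust to the smearing
    of the tissue upslope by the residue convolution); the tissue curve
    is shifted backwards by the rounded onset difference.  Differences
    within ``tolerance_samples`` count as aligned, so the operation is
    idempotent.  If either onset is undetectable a warning is emitted
    and the curves are returned unchanged.
    """
    dt = curves.sampling_interval

    def onset_time(y: np.ndarray) -> float | None:
        if y.max() <= 0:
            return None
        dy = np.diff(y)
        i = int(np.argmax(dy))
        if dy[i] <= 0:
            return None
        # Tangent through (t_i, y_i) with slope dy/dt; zero crossing.
        return curves.time[i] - y[i] / (dy[i] / dt)

    t_a = onset_time(curves.aif)
    t_t = onset_time(curves.tissue)
    if t_a is None or t_t is None:
        warnings.warn("curve onset undetectable; no delay correction applied")
        return curves
    shift = int(round((t_t - t_a) / dt))
    if shift <= tolerance_samples:
        return curves
    tissue = np.empty_like(curves.tissue)
    tissue[:-shift] = curves.tissue[shift:]
    tissue[-shift:] = curves.tissue[-1]
    return PerfusionCurves(time=curves.time, aif=curves.aif.copy(), tissue=tissue)


# ---------------------------------------------------------------- CSV I/O

def load_curves_csv(path) -> PerfusionCurves:
    """Read a TAC table with columns ``time_s, aif_hu, tissue_hu``."""
    df = pd.read_csv(path)
    return PerfusionCurves(
        time=df["time_s"].to_numpy(),
        aif=df["aif_hu"].to_numpy(),
        tissue=df["tissue_hu"].to_numpy(),
    )


def save_curves_csv(curves: PerfusionCurves, path) -> None:
    pd.DataFrame(
        {"time_s": curves.time, "aif_hu": curves.aif, "tissue_hu": curves.tissue}
    ).to_csv(path, index=False)


def params_to_frame(fits: list[PerfusionParams]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [p.subject_id for p in fits],
            "region": [p.region_label for p in fits],
            "bf_ml_per_100ml_min": [p.BF for p in fits],
            "bv_ml_per_100ml": [p.BV for p in fits],
            "pem_ml_per_100ml_min": [p.PEM for p in fits],
            "mtt_s": [p.MTT for p in fits],
        }
    )
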