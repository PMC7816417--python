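"""Synthetic ground-truth cohort generator.

Emulates the study conditions of a pancreatic ductal adenocarcinoma (PDAC)
perfusion-concordance study: 19 subjects, each with a tumor region and
upstream (non-neoplastic) parenchyma, downstream parenchyma in 5 subjects,
and histological microvessel analysis in a 10-subject subset.

Each subject carries a latent vascularity score (standard normal).  Every
per-region perfusion-related parameter is generated from a log-normal
marginal whose median and interquartile range match the published
per-region reference values, coupled to the latent score through a
Gaussian copula.  The copula loading is the product of a per-parameter
weight (1 for f, BF, MVD, MVA; 0.95 for BV; 0.5 for PEM; 0.3 for D*;
0 for D — pure diffusion does not reflect vascularity) and a global
``latent_effect`` knob; setting ``latent_effect=0`` removes all
cross-modality correlations (null mode), while 1 makes the vascular
parameters comonotone.

From the per-region truth the generator renders the raw observables each
downstream analysis stage consumes: ROI-averaged DWI signal decays with
Rician noise, arterial + tissue time–attenuation curves from a
gamma-variate AIF, and stained vessel-ring raster images with dotted
distractor speckles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ctperfusion import PerfusionCurves
from .ivim import DEFAULT_B_VALUES, IvimSignal
from .microvessel import VesselImage

TUMOR, UPSTREAM, DOWNSTREAM = "tumor", "upstream", "downstream"

# Per-region marginal reference values: (median, q25, q75) in reporting
# units (f in %, D and D* in 1e-3 mm²/s, BF/PEM in ml/100ml/min, BV in
# ml/100ml, MVD in /mm², MVA as a fraction).
REGION_MARGINALS: dict[str, dict[str, tuple[float, float, float]]] = {
    TUMOR: {
        "f": (10.1, 8.9, 16.6),
        "D": (1.2, 1.2, 1.4),
        "Dstar": (17.4, 11.4, 131.9),
        "BF": (38.9, 29.0, 66.2),
        "BV": (2.4, 1.9, 4.6),
        "PEM": (17.8, 11.0, 28.3),
        "MVD": (33.2, 25.3, 61.8),
        "MVA": (0.014, 0.011, 0.029),
    },
    UPSTREAM: {
        "f": (21.1, 17.6, 24.0),
        "D": (1.5, 1.4, 1.7),
        "Dstar": (21.9, 11.8, 34.9),
        "BF": (117.0, 82.1, 154.0),
        "BV": (8.5, 5.7, 14.3),
        "PEM": (51.4, 40.4, 70.5),
        # Non-neoplastic parenchyma is more vascular than tumor; scaled
        # from the tumor reference in the published direction.
        "MVD": (73.0, 55.7, 136.0),
        "MVA": (0.035, 0.028, 0.073),
    },
    DOWNSTREAM: {
        "f": (22.5, 20.2, 25.3),
        "D": (1.7, 1.3, 1.7),
        "Dstar": (26.3, 13.7, 68.1),
        "BF": (141.8, 131.2, 173.0),
        "BV": (9.9, 8.7, 13.3),
        "PEM": (60.4, 53.5, 67.4),
        "MVD": (73.0, 55.7, 136.0),
        "MVA": (0.035, 0.028, 0.073),
    },
}

# Copula loading weight of each parameter on the latent vascularity.
LATENT_WEIGHTS = {
    "f": 1.0, "BF": 1.0, "BV": 0.95, "MVD": 1.0, "MVA": 1.0,
    "PEM": 0.5, "Dstar": 0.3, "D": 0.0,
}

#: Normal quantile of the upper quartile; log-IQR / (2 × this) is the
#: log-normal shape parameter.
_Z75 = 0.6744897501960817


@dataclass
class CohortConfig:
    """Cohort size, noise, and coupling knobs (seed fully determines output)."""

    rng_seed: int
    n_subjects: int = 19
    n_histology: int = 10
    n_downstream: int = 5
    noise_snr_dwi: float = 1000.0
    noise_sd_hu: float = 0.5
    reader_jitter: float = 0.16
    latent_effect: float = 0.95
    field_mm2: float = 2.0
    px_per_mm: float = 500.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not 0 <= self.n_histology <= self.n_subjects:
            raise ValueError("n_histology must lie in [0, n_subjects]")
        if not 0 <= self.n_downstream <= self.n_subjects:
            raise ValueError("n_downstream must lie in [0, n_subjects]")
        if not 0 <= self.reader_jitter <= 0.5:
            raise ValueError("reader_jitter must lie in [0, 0.5]")
        if not 0 <= self.latent_effect <= 1:
            raise ValueError("latent_effect must lie in [0, 1]")


@dataclass
class SubjectTruth:
    """Ground-truth parameters of one region of one subject.

    Internal units: f and MVA as fractions, D/D* in mm²/s, BF/PEM in
    ml/(100 ml·min), BV in ml/100 ml, MVD in /mm².
    """

    subject_id: str
    region: str
    latent_v: float
    f_true: float
    D_true: float
    Dstar_true: float
    BF_true: float
    BV_true: float
    PEM_true: float
    MVD_true: float
    MVA_true: float
    has_histology: bool = False

    @property
    def MTT_true(self) -> float:
        return 60.0 * self.BV_true / self.BF_true


def lognormal_from_quartiles(median: float, q25: float, q75: float
                             ) -> tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and IQR."""
    if not 0 < q25 <= median <= q75:
        raise ValueError("need 0 < q25 <= median <= q75")
    sigma = (np.log(q75) - np.log(q25)) / (2 * _Z75)
    return np.log(median), max(sigma, 1e-6)


def sample_cohort(config: CohortConfig) -> list[SubjectTruth]:
    """Draw the ground-truth cohort (deterministic under the seed).

    One latent vascularity score per subject drives all regions; regional
    marginals come from :data:`REGION_MARGINALS`.  Returns tumor and
    upstream rows for every subject and downstream rows for the first
    ``n_downstream`` subjects; the first ``n_histology`` subjects carry
    the histology flag on their tumor row.
    """
    rng = np.random.default_rng(config.rng_seed)
    latent = rng.standard_normal(config.n_subjects)
    truths: list[SubjectTruth] = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:02d}"
        regions = [TUMOR, UPSTREAM] + ([DOWNSTREAM] if i < config.n_downstream else [])
        for region in regions:
            vals: dict[str, float] = {}
            for param, (med, q25, q75) in REGION_MARGINALS[region].items():
                mu, sigma = lognormal_from_quartiles(med, q25, q75)
                lam = config.latent_effect * LATENT_WEIGHTS[param]
                z = lam * latent[i] + np.sqrt(1 - lam**2) * rng.standard_normal()
                vals[param] = float(np.exp(mu + sigma * z))
            f = min(vals["f"] / 100.0, 0.95)
            D = vals["D"] * 1e-3
            Dstar = max(min(vals["Dstar"] * 1e-3, 0.3), 5e-3, 1.2 * D)
            BF, BV, PEM = vals["BF"], vals["BV"], vals["PEM"]
            mtt = 60.0 * BV / BF
            if not 1.5 <= mtt <= 15.0:
                BV = BF * float(np.clip(mtt, 1.5, 15.0)) / 60.0
            mva = min(vals["MVA"], 0.5)
            truths.append(
                SubjectTruth(
                    subject_id=sid, region=region, latent_v=float(latent[i]),
                    f_true=f, D_true=D, Dstar_true=Dstar, BF_true=BF,
                    BV_true=BV, PEM_true=PEM, MVD_true=vals["MVD"],
                    MVA_true=mva,
                    has_histology=(region == TUMOR and i < config.n_histology),
                )
            )
    return truths


def truths_to_frame(truths: list[SubjectTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [t.subject_id for t in truths],
            "region": [t.region for t in truths],
            "latent_v": [t.latent_v for t in truths],
            "f_true_percent": [100 * t.f_true for t in truths],
            "D_true_mm2_per_s": [t.D_true for t in truths],
            "Dstar_true_mm2_per_s": [t.Dstar_true for t in truths],
            "bf_true": [t.BF_true for t in truths],
            "bv_true": [t.BV_true for t in truths],
            "pem_true": [t.PEM_true for t in truths],
            "mvd_true": [t.MVD_true for t in truths],
            "mva_true": [t.MVA_true for t in truths],
            "has_histology": [t.has_histology for t in truths],
        }
    )


# ------------------------------------------------------------- DWI signal

def render_dwi_signal(
    truth: SubjectTruth,
    b_values: np.ndarray | None = None,
    snr: float | None = None,
    rng: np.random.Generator | int | None = None,
    s0: float = 1000.0,
) -> IvimSignal:
    """ROI-averaged DWI signal with Rician noise.

    Noise is the magnitude of a complex Gaussian whose per-channel SD is
    S_0 / ``snr`` (SNR referenced to the unweighted signal, the standard
    convention for magnitude MRI).  ``snr=None`` or ``inf`` reproduces the
    bi-exponential model exactly.
    """
    b = DEFAULT_B_VALUES if b_values is None else np.asarray(b_values, dtype=float)
    if len(b) == 0 or np.any(b < 0):
        raise ValueError("b_values must be nonempty and nonnegative")
    clean = s0 * (
        (1 - truth.f_true) * np.exp(-b * truth.D_true)
        + truth.f_true * np.exp(-b * (truth.D_true + truth.Dstar_true))
    )
    if snr is None or np.isinf(snr):
        noisy = clean
    else:
        if snr <= 0:
            raise ValueError("snr must be positive")
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        sd = s0 / snr
        noisy = np.sqrt(
            (clean + sd * rng.standard_normal(len(b))) ** 2
            + (sd * rng.standard_normal(len(b))) ** 2
        )
    return IvimSignal(b_values=b, mean_signal=noisy,
                      subject_id=truth.subject_id, region_label=truth.region)


# ------------------------------------------------------------------- TAC

@dataclass
class TacTiming:
    """Dynamic-acquisition timing (cycle time 1.5 s, >= 45 s coverage)."""

    sampling_interval: float = 1.5
    duration: float = 60.0
    onset_s: float = 8.0
    aif_peak_hu: float = 300.0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be positive")
        if self.duration < 45.0:
            raise ValueError("dynamic acquisition must cover >= 45 s")


def gamma_variate_aif(t: np.ndarray, timing: TacTiming,
                      alpha: float = 3.0, t_peak: float = 6.0,
                      tail_fraction: float = 0.15) -> np.ndarray:
    """Gamma-variate first pass plus a slow recirculation tail (HU)."""
    s = np.clip(t - timing.onset_s, 0.0, None)
    first_pass = np.where(
        s > 0, (s / t_peak) ** alpha * np.exp(alpha * (1 - s / t_peak)), 0.0
    )
    tail = tail_fraction * (1 - np.exp(-s / 10.0)) * np.exp(-s / 120.0)
    return timing.aif_peak_hu * (first_pass + tail)


def render_tac(
    truth: SubjectTruth,
    timing: TacTiming | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    aif: np.ndarray | None = None,
) -> PerfusionCurves:
    """Tissue and arterial TACs from the subject's BF, BV and PEM.

    The tissue curve is the discrete (rectangular-rule) convolution of the
    AIF with the flow-scaled exponential residue BF·exp(-t/MTT), plus a
    Patlak-type leakage term PEM·∫AIF.  With ``noise_sd=0`` the curve is
    exactly that discrete convolution; otherwise white Gaussian noise of
    the given SD (HU) is added to the tissue curve.
    """
    timing = timing or TacTiming()
    dt = timing.sampling_interval
    t = np.arange(0.0, timing.duration + dt / 2, dt)
    aif = gamma_variate_aif(t, timing) if aif is None else np.asarray(aif, float)
    bf_s = truth.BF_true / 6000.0
    leak_s = truth.PEM_true / 6000.0
    if truth.BF_true > 0:
        residue = np.exp(-t / truth.MTT_true)
        conv = np.array(
            [(aif[: i + 1] * residue[i::-1]).sum() * dt for i in range(len(t))]
        )
    else:
        conv = np.zeros_like(t)
    tissue = bf_s * conv + leak_s * np.cumsum(aif) * dt
    if noise_sd > 0:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        tissue = tissue + noise_sd * rng.standard_normal(len(t))
    return PerfusionCurves(time=t, aif=aif, tissue=tissue)


# ---------------------------------------------------------- vessel image

@dataclass
class VesselGroundTruth:
    """Bookkeeping of what was actually drawn into a tile."""

    vessel_count: int
    total_vessel_area_mm2: float
    centroids_px: list[tuple[float, float]] = field(default_factory=list)
    vessel_mask: np.ndarray | None = None

    def mvd(self, field_mm2: float) -> float:
        return self.vessel_count / field_mm2

    def mva(self, field_mm2: float) -> float:
        return self.total_vessel_area_mm2 / field_mm2


def render_vessel_image(
    truth: SubjectTruth,
    field_mm2: float = 2.0,
    px_per_mm: float = 500.0,
    rng: np.random.Generator | int | None = None,
    speckle_density_per_mm2: float = 50.0,
    radius_sigma_log: float = 0.25,
) -> tuple[VesselImage, VesselGroundTruth]:
    """Render a stained tile: vessel rings plus dotted distractor speckles.

    A Poisson(MVD_true × field) number of vessels is drawn, each as a
    stained annulus around an unstained lumen; outer radii are log-normal
    with median chosen so the expected total vessel area matches
    MVA_true × field.  Speckles mimic dotted single-cell stains and must
    not be counted by the segmenter.  Returns the raster together with
    the drawn ground truth (count, summed filled pixel area, centroids).
    """
    if field_mm2 <= 0:
        raise ValueError("field_mm2 must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    mpp = 1000.0 / px_per_mm  # microns per pixel
    side = int(round(np.sqrt(field_mm2) * px_per_mm))
    img = np.clip(rng.normal(0.06, 0.02, size=(side, side)), 0.0, 0.3)

    n_vessels = int(rng.poisson(truth.MVD_true * field_mm2)) if truth.MVD_true > 0 else 0
    if truth.MVD_true > 0:
        mean_area_um2 = truth.MVA_true / truth.MVD_true * 1e6
        r_med_um = np.sqrt(mean_area_um2 / (np.pi * np.exp(2 * radius_sigma_log**2)))
        r_med_um = max(r_med_um, 4.0)  # capillaries are no thinner than ~8 µm
    else:
        r_med_um = 0.0
    if n_vessels > 0 and 2 * r_med_um / mpp < 4:
        raise ValueError(
            "resolution too low to draw a vessel ring (< 4 px diameter); "
            "increase px_per_mm"
        )

    vessel_mask = np.zeros((side, side), dtype=bool)
    centroids: list[tuple[float, float]] = []
    placed: list[tuple[float, float, float]] = []

    def window(cy: float, cx: float, r: float):
        y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, side)
        x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, side)
        yy, xx = np.mgrid[y0:y1, x0:x1]
        return (slice(y0, y1), slice(x0, x1)), (yy - cy) ** 2 + (xx - cx) ** 2

    for _ in range(n_vessels):
        r_px = float(np.exp(np.log(r_med_um) + radius_sigma_log
                            * rng.standard_normal()) / mpp)
        r_px = max(r_px, 2.0)
        for _try in range(200):
            cy, cx = rng.uniform(r_px, side - r_px, size=2)
            if all((cy - py) ** 2 + (cx - px) ** 2 > (r_px + pr + 2) ** 2
                   for py, px, pr in placed):
                break
        sl, d2 = window(cy, cx, r_px)
        disk = d2 <= r_px**2
        lumen = d2 <= (0.45 * r_px) ** 2
        ring = disk & ~lumen
        patch = img[sl]
        patch[ring] = np.clip(
            0.85 + 0.05 * rng.standard_normal(int(ring.sum())), 0.6, 1.0
        )
        patch[lumen] = np.clip(rng.normal(0.08, 0.02, int(lumen.sum())), 0.0, 0.3)
        vessel_mask[sl] |= disk
        centroids.append((cy, cx))
        placed.append((cy, cx, r_px))

    n_speckles = int(rng.poisson(speckle_density_per_mm2 * field_mm2))
    for _ in range(n_speckles):
        cy, cx = rng.uniform(2, side - 2, size=2)
        r = rng.uniform(1.0, 2.0)
        sl, d2 = window(cy, cx, r)
        dot = (d2 <= r**2) & ~vessel_mask[sl]
        img[sl][dot] = np.clip(
            0.85 + 0.05 * rng.standard_normal(int(dot.sum())), 0.6, 1.0
        )

    area_mm2 = float(vessel_mask.sum()) * (mpp / 1000.0) ** 2
    return (
        VesselImage(raster=np.clip(img, 0, 1), microns_per_pixel=mpp),
        VesselGroundTruth(vessel_count=len(centroids),
                          total_vessel_area_mm2=area_mm2,
                          centroids_px=centroids, vessel_mask=vessel_mask),
    )


# -------------------------------------------------------------- readers

def simulate_readers(
    measurements: pd.DataFrame,
    reader_jitter: float,
    rng: np.random.Generator | int | None = None,
    parameter_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Duplicate per-region measurements into two simulated readers.

    Reader ROI placement differences are modelled as independent
    multiplicative log-normal perturbations of each reader's value:
    ``value_r = value · exp(jitter · eps_r)``.  ``reader_jitter=0`` makes
    the readers identical.  Columns not listed in ``parameter_columns``
    (identifiers, histology) are carried through unchanged.
    """
    if not 0 <= reader_jitter <= 0.5:
        raise ValueError("reader_jitter must lie in [0, 0.5]")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if parameter_columns is None:
        parameter_columns = [
            c for c in measurements.columns
            if measurements[c].dtype.kind == "f"
        ]
    out = []
    for reader in (1, 2):
        df = measurements.copy()
        df.insert(0, "reader", reader)
        if reader_jitter > 0:
            for c in parameter_columns:
                eps = rng.standard_normal(len(df))
                df[c] = df[c] * np.exp(reader_jitter * eps)
        else:
            for c in parameter_columns:
                rng.standard_normal(len(df))  # keep stream aligned
        out.append(df)
    return pd.concat(out, ignore_index=True)
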