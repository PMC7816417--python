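"""Statistical procedures for the concordance analysis.

Covers: Spearman rank correlation with the Campbell–Swinscow strength
bands; Meng–Rosenthal–Rubin Z (Steiger's Z family) for comparing two
dependent correlations sharing one variable; two-way random-effects
absolute-agreement ICC(2,1) with F-based confidence limits; ROC analysis
with the DeLong AUC variance, DeLong paired AUC comparison, and Youden
cut-offs; and the Mann–Whitney / Wilcoxon nonparametric group tests with
exact small-sample p-values.  All p-values are two-sided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

# Band lower bounds; a value on a boundary belongs to the higher band.
_CORRELATION_BANDS = [
    (0.80, "very strong"), (0.60, "strong"), (0.40, "moderate"),
    (0.20, "weak"), (0.00, "very weak"),
]
_ICC_BANDS = [
    (0.81, "excellent"), (0.61, "good"), (0.41, "moderate"),
    (0.21, "fair"), (-np.inf, "poor"),
]
_AUC_BANDS = [
    (0.90, "outstanding"), (0.80, "excellent"), (0.70, "acceptable"),
    (-np.inf, "none"),
]


def interpret(value: float, scale: str) -> str:
    """Map a correlation magnitude, ICC, or AUC to its strength band.

    Correlations are banded on |value| (very weak/weak/moderate/strong/
    very strong at 0.2/0.4/0.6/0.8); ICCs as poor/fair/moderate/good/
    excellent (0.21/0.41/0.61/0.81); AUCs as acceptable/excellent/
    outstanding (0.70/0.80/0.90) with "none" below 0.70.
    """
    if scale == "correlation":
        if not -1 <= value <= 1:
            raise ValueError("correlation must lie in [-1, 1]")
        v, bands = abs(value), _CORRELATION_BANDS
    elif scale == "icc":
        if value > 1:
            raise ValueError("ICC cannot exceed 1")
        v, bands = value, _ICC_BANDS
    elif scale == "auc":
        if not 0 <= value <= 1:
            raise ValueError("AUC must lie in [0, 1]")
        v, bands = value, _AUC_BANDS
    else:
        raise ValueError(f"unknown scale {scale!r}")
    for lo, name in bands:
        if v >= lo:
            return name
    raise AssertionError("unreachable")


# ------------------------------------------------------------- Spearman

@dataclass
class CorrelationResult:
    rho: float
    p_two_sided: float
    n: int
    band: str


#: Cached exact null |rho| distributions for untied ranks, keyed by n.
_EXACT_RHO_CACHE: dict[int, np.ndarray] = {}


def _exact_abs_rho_distribution(n: int) -> np.ndarray:
    """Sorted |rho| over all n! pairings of untied ranks 1..n."""
    if n not in _EXACT_RHO_CACHE:
        r = np.arange(n, dtype=float)
        r_c = r - r.mean()
        denom = (r_c**2).sum()
        chunk, vals = [], []
        for perm in itertools.permutations(range(n)):
            chunk.append(perm)
            if len(chunk) == 200_000:
                vals.append(np.abs((r_c[np.array(chunk)] * r_c).sum(1)) / denom)
                chunk = []
        if chunk:
            vals.append(np.abs((r_c[np.array(chunk)] * r_c).sum(1)) / denom)
        _EXACT_RHO_CACHE[n] = np.sort(np.concatenate(vals))
    return _EXACT_RHO_CACHE[n]


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation with midranks for ties.

    The two-sided p-value is exact (full permutation enumeration over the
    n! pairings) for n <= 10 — the t-approximation is anti-conservative
    at the 10-subject histology-subset size — and uses the
    t-approximation for larger n (or for tied data at n = 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for constant input")
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    has_ties = len(np.unique(rx)) < n or len(np.unique(ry)) < n
    if n <= 9 and has_ties:
        # Exact null with the observed midranks.
        perms = np.array(list(itertools.permutations(range(n))))
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        denom = math.sqrt((rx_c**2).sum() * (ry_c**2).sum())
        stat = (rx_c[perms] * ry_c).sum(axis=1) / denom
        p = float((np.abs(stat) >= abs(rho) - 1e-12).mean())
    elif n <= 10 and not has_ties:
        dist = _exact_abs_rho_distribution(n)
        idx = np.searchsorted(dist, abs(rho) - 1e-12, side="left")
        p = float((len(dist) - idx) / len(dist))
    else:
        t = rho * math.sqrt((n - 2) / max(1 - rho**2, 1e-300))
        p = float(2 * sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rho=rho, p_two_sided=min(p, 1.0), n=n,
                             band=interpret(rho, "correlation"))


# --------------------------------------------- dependent correlations

@dataclass
class DependentCorrComparison:
    z: float
    p_two_sided: float
    r_jh: float
    r_kh: float
    r_jk: float
    n: int

    @property
    def significant(self) -> bool:
        """|Z| > 1.96, the two-sided 5% normal criterion."""
        return abs(self.z) > 1.96


def meng_z(r_jh: float, r_kh: float, r_jk: float, n: int) -> DependentCorrComparison:
    """Meng–Rosenthal–Rubin Z for two dependent correlations.

    Tests whether variable h correlates differently with j than with k,
    given the j–k correlation, via Fisher z-transforms:

        Z = (z_jh - z_kh) sqrt((n-3) / (2 (1-r_jk) h)),
        h = (1 - fbar rbar²) / (1 - rbar²),
        rbar² = (r_jh² + r_kh²)/2,
        fbar = min(1, (1-r_jk) / (2 (1-rbar²))).
    """
    for r in (r_jh, r_kh, r_jk):
        if not -1 < r < 1:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("need n >= 4")
    z_jh = math.atanh(r_jh)
    z_kh = math.atanh(r_kh)
    rbar2 = (r_jh**2 + r_kh**2) / 2.0
    fbar = min(1.0, (1.0 - r_jk) / (2.0 * (1.0 - rbar2)))
    h = (1.0 - fbar * rbar2) / (1.0 - rbar2)
    z = (z_jh - z_kh) * math.sqrt((n - 3) / (2.0 * (1.0 - r_jk) * h))
    p = float(2 * sps.norm.sf(abs(z)))
    return DependentCorrComparison(z=z, p_two_sided=p, r_jh=r_jh, r_kh=r_kh,
                                   r_jk=r_jk, n=n)


# ------------------------------------------------------------------ ICC

@dataclass
class IccResult:
    icc: float
    ci95: tuple[float, float]
    band: str


def icc_two_way_random(ratings) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``ratings`` is a subjects × raters table (complete, >= 5 subjects,
    >= 2 raters).  Point estimate and the 95% confidence interval follow
    the standard two-way ANOVA mean-squares construction with
    F-distribution bounds (Shrout & Fleiss; McGraw & Wong).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("ratings must be a subjects x raters 2-D table")
    if x.shape[0] < 5:
        raise ValueError("need at least 5 subjects")
    if np.any(~np.isfinite(x)):
        raise ValueError("ratings table must be complete (no missing cells)")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)          # between-subjects
    msc = ss_cols / (k - 1)          # between-raters
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc = (msr - mse) / denom if denom > 0 else 0.0

    if icc >= 1 - 1e-12 or mse <= 0:
        # Degenerate perfect agreement: the F bounds collapse.
        return IccResult(icc=float(icc), ci95=(float(icc), 1.0),
                         band=interpret(float(icc), "icc"))

    # McGraw & Wong F-based bounds for ICC(A,1).
    alpha = 0.05
    a = k * icc / (n * (1 - icc)) if icc < 1 else np.inf
    b = 1 + k * icc * (n - 1) / (n * (1 - icc)) if icc < 1 else np.inf
    v = (a * msc + b * mse) ** 2 / (
        (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    )
    f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_l * mse) / (
        f_l * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_u * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_u * msr
    )
    return IccResult(icc=float(icc), ci95=(float(lower), float(upper)),
                     band=interpret(float(icc), "icc"))


# ------------------------------------------------------------------ ROC

@dataclass
class RocResult:
    auc: float
    ci95: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    direction: str
    band: str


def _placements(pos: np.ndarray, neg: np.ndarray):
    """DeLong placement values; AUC is the mean of either set."""
    gt = (pos[:, None] > neg[None, :]).astype(float)
    gt += 0.5 * (pos[:, None] == neg[None, :])
    return gt.mean(axis=1), gt.mean(axis=0)


def roc_analyze(values, labels, direction: str = "ge") -> RocResult:
    """ROC analysis with DeLong CI and Youden-optimal cut-off.

    ``labels`` are 1 for the positive class (tumor), 0 otherwise.
    ``direction='ge'`` calls values >= cutoff positive; ``'le'`` calls
    values <= cutoff positive (tumor-low markers).  The AUC is the
    tie-corrected Mann–Whitney concordance of the oriented marker.  Among
    cut-offs with equal Youden J, the one with the highest specificity is
    chosen.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if direction not in ("ge", "le"):
        raise ValueError("direction must be 'ge' or 'le'")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    oriented = values if direction == "ge" else -values
    pos = oriented[labels == 1]
    neg = oriented[labels == 0]
    v_pos, v_neg = _placements(pos, neg)
    auc = float(v_pos.mean())
    m, n_neg = len(pos), len(neg)
    var = (np.var(v_pos, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v_neg, ddof=1) / n_neg if n_neg > 1 else 0.0
    )
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    best = None  # (J, specificity, cutoff, sens, spec)
    for c in np.unique(values):
        if direction == "ge":
            called = values >= c
        else:
            called = values <= c
        sens = float(called[labels == 1].mean())
        spec = float((~called)[labels == 0].mean())
        j = sens + spec - 1
        key = (round(j, 12), round(spec, 12))
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, cutoff, sens, spec = best
    return RocResult(auc=auc, ci95=ci, cutoff=float(cutoff), sensitivity=sens,
                     specificity=spec, direction=direction,
                     band=interpret(auc, "auc"))


@dataclass
class DelongComparison:
    z: float
    p_two_sided: float
    auc_a: float
    auc_b: float


def delong_compare(values_a, values_b, labels,
                   direction_a: str = "ge", direction_b: str = "ge"
                   ) -> DelongComparison:
    """Paired DeLong test for the difference of two correlated AUCs.

    Both markers must be measured on the same subjects.  The variance of
    the AUC difference uses the placement-value covariance structure.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("markers must be paired on the same subjects")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    a = a if direction_a == "ge" else -a
    b = b if direction_b == "ge" else -b
    pos = labels == 1
    va_p, va_n = _placements(a[pos], a[~pos])
    vb_p, vb_n = _placements(b[pos], b[~pos])
    auc_a, auc_b = float(va_p.mean()), float(vb_p.mean())
    m, n = int(pos.sum()), int((~pos).sum())
    s_pos = np.cov(np.vstack([va_p, vb_p]), ddof=1) if m > 1 else np.zeros((2, 2))
    s_neg = np.cov(np.vstack([va_n, vb_n]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s_pos / m + s_neg / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return DelongComparison(z=0.0, p_two_sided=1.0, auc_a=auc_a, auc_b=auc_b)
    z = (auc_a - auc_b) / math.sqrt(var_diff)
    p = float(2 * sps.norm.sf(abs(z)))
    return DelongComparison(z=z, p_two_sided=p, auc_a=auc_a, auc_b=auc_b)


# ------------------------------------------------------- group tests

def mann_whitney(x, y) -> tuple[float, float]:
    """Mann–Whitney U with exact two-sided p for small samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both groups must be nonempty")
    method = "exact" if len(x) * len(y) <= 400 else "asymptotic"
    try:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_signed_rank(x, y) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples, exact for n <= 25."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.all(d == 0):
        raise ValueError("all paired differences are zero")
    method = "exact" if len(d) <= 25 else "approx"
    try:
        res = sps.wilcoxon(x, y, alternative="two-sided", method=method)
    except ValueError:
        res = sps.wilcoxon(x, y, alternative="two-sided", method="approx")
    return float(res.statistic), float(res.pvalue)
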