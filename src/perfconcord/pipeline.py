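"""End-to-end orchestration: simulate → fit → quantify → statistics.

The pipeline renders raw observables for a synthetic cohort, estimates
IVIM parameters from the DWI signals, perfusion parameters from the TACs,
and microvessel metrics from the stained tiles, assembles the per-subject
× region × reader cohort table, and runs the comparative statistics:
Spearman correlations (reader means, following the convention that
correlation analyses use the mean of both readers while ICC uses the
per-reader values), Meng Z comparisons of the dependent correlations,
tumor-vs-upstream ROC with pairwise DeLong tests, per-parameter ICC,
paired Wilcoxon group tests, and the linear regressions.

Downstream parenchyma enters the group tests only; its sample (n = 5) is
too small for ROC analysis, which is therefore restricted to
tumor-vs-upstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import __version__
from . import ctperfusion, ivim, microvessel, stats, synthetic_cohort
from .synthetic_cohort import (
    DOWNSTREAM, TUMOR, UPSTREAM, CohortConfig, SubjectTruth, TacTiming,
)

IVIM_PARAMS = ["f_percent", "D_mm2_per_s", "Dstar_mm2_per_s", "fDstar_mm2_per_s"]
CT_PARAMS = ["bf_ml_per_100ml_min", "bv_ml_per_100ml", "pem_ml_per_100ml_min"]
SHORT = {
    "f_percent": "f", "D_mm2_per_s": "D", "Dstar_mm2_per_s": "Dstar",
    "fDstar_mm2_per_s": "fDstar", "bf_ml_per_100ml_min": "BF",
    "bv_ml_per_100ml": "BV", "pem_ml_per_100ml_min": "PEM",
    "mvd_per_mm2": "MVD", "mva_fraction": "MVA",
}
ROC_PARAMS = ["f_percent", "D_mm2_per_s", "Dstar_mm2_per_s",
              "bf_ml_per_100ml_min", "bv_ml_per_100ml", "pem_ml_per_100ml_min"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and subject."""


@dataclass
class SimulatedCohort:
    """Ground truth plus rendered observables for every stage."""

    config: CohortConfig
    truths: list[SubjectTruth]
    signals: dict[tuple[str, str], ivim.IvimSignal]
    curves: dict[tuple[str, str], ctperfusion.PerfusionCurves]
    vessel_images: dict[str, microvessel.VesselImage]
    vessel_truths: dict[str, synthetic_cohort.VesselGroundTruth]


def simulate(config: CohortConfig) -> SimulatedCohort:
    """Sample the cohort and render all raw observables (seeded)."""
    truths = synthetic_cohort.sample_cohort(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 7]))
    signals, curves = {}, {}
    vessel_images, vessel_truths = {}, {}
    timing = TacTiming()
    for t in truths:
        key = (t.subject_id, t.region)
        signals[key] = synthetic_cohort.render_dwi_signal(
            t, snr=config.noise_snr_dwi, rng=rng
        )
        curves[key] = synthetic_cohort.render_tac(
            t, timing=timing, noise_sd=config.noise_sd_hu, rng=rng
        )
        if t.has_histology:
            img, gt = synthetic_cohort.render_vessel_image(
                t, field_mm2=config.field_mm2, px_per_mm=config.px_per_mm,
                rng=rng,
            )
            vessel_images[t.subject_id] = img
            vessel_truths[t.subject_id] = gt
    return SimulatedCohort(config=config, truths=truths, signals=signals,
                           curves=curves, vessel_images=vessel_images,
                           vessel_truths=vessel_truths)


def fit_cohort(sim: SimulatedCohort) -> pd.DataFrame:
    """Fit both modalities, simulate two readers, attach histology.

    Returns the cohort table: one row per subject × region × reader with
    IVIM and CT perfusion estimates; microvessel columns are present on
    tumor rows of the histology subset and identical across readers
    (single pathology measurement).
    """
    config = sim.config
    rows = []
    for t in sim.truths:
        key = (t.subject_id, t.region)
        try:
            ip = ivim.fit_segmented(sim.signals[key])
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"ivim: fit failed for {key}: {exc}") from exc
        try:
            pp = ctperfusion.deconvolve(sim.curves[key])
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"ctperfusion: fit failed for {key}: {exc}") from exc
        rows.append(
            {
                "subject_id": t.subject_id, "region": t.region,
                "f_percent": 100 * ip.f, "D_mm2_per_s": ip.D,
                "Dstar_mm2_per_s": ip.Dstar, "fDstar_mm2_per_s": ip.fd_product,
                "bf_ml_per_100ml_min": pp.BF, "bv_ml_per_100ml": pp.BV,
                "pem_ml_per_100ml_min": pp.PEM,
            }
        )
    measurements = pd.DataFrame(rows)
    rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, 11]))
    table = synthetic_cohort.simulate_readers(
        measurements, config.reader_jitter, rng=rng,
        parameter_columns=IVIM_PARAMS + CT_PARAMS,
    )

    mvd = {}
    mva = {}
    for sid, img in sim.vessel_images.items():
        objects = microvessel.segment_vessels(img)
        metrics = microvessel.compute_metrics(objects, img)
        mvd[sid] = metrics.MVD
        mva[sid] = metrics.MVA
    tumor_hist = (table["region"] == TUMOR) & table["subject_id"].isin(mvd)
    table["mvd_per_mm2"] = np.where(
        tumor_hist, table["subject_id"].map(mvd), np.nan
    )
    table["mva_fraction"] = np.where(
        tumor_hist, table["subject_id"].map(mva), np.nan
    )
    return table


# ------------------------------------------------------------- analysis

@dataclass
class AnalysisReport:
    """All statistics tables of one cohort analysis."""

    correlations: pd.DataFrame
    correlations_full: pd.DataFrame
    dependent_comparisons: pd.DataFrame
    roc: pd.DataFrame
    delong_pairs: pd.DataFrame
    icc: pd.DataFrame
    group_tests: pd.DataFrame
    regressions: pd.DataFrame
    n_subjects: int = 0
    n_histology: int = 0

    def save(self, outdir: Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("correlations", "correlations_full", "dependent_comparisons",
                     "roc", "delong_pairs", "icc", "group_tests", "regressions"):
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "report.json").write_text(self.to_json())

    def to_json(self) -> str:
        payload = {
            "n_subjects": self.n_subjects,
            "n_histology": self.n_histology,
        }
        for name in ("correlations", "correlations_full", "dependent_comparisons",
                     "roc", "delong_pairs", "icc", "group_tests", "regressions"):
            payload[name] = getattr(self, name).to_dict(orient="records")
        return json.dumps(payload, indent=2, default=float)


def reader_mean(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of the two readers per subject × region (correlation inputs)."""
    value_cols = [c for c in table.columns
                  if c not in ("subject_id", "region", "reader")]
    return (
        table.groupby(["subject_id", "region"], as_index=False)[value_cols]
        .mean()
    )


def _corr_row(df: pd.DataFrame, a: str, b: str) -> dict:
    sub = df[[a, b]].dropna()
    res = stats.spearman(sub[a], sub[b])
    return {
        "x": SHORT.get(a, a), "y": SHORT.get(b, b), "rho": res.rho,
        "p": res.p_two_sided, "n": res.n, "band": res.band,
        "significant": res.p_two_sided < 0.05,
    }


def run_analysis(table: pd.DataFrame) -> AnalysisReport:
    """Comparative statistics on a cohort table (see module docstring)."""
    mean_tbl = reader_mean(table)
    tum = mean_tbl[mean_tbl["region"] == TUMOR]
    hist = tum.dropna(subset=["mvd_per_mm2", "mva_fraction"])

    # Headline correlation table: f–BF / f–BV on all subjects, and the
    # 2 × 3 histology block on the histology subset.
    corr_rows = [
        _corr_row(tum, "f_percent", "bf_ml_per_100ml_min"),
        _corr_row(tum, "f_percent", "bv_ml_per_100ml"),
    ]
    for c in corr_rows:
        c["block"] = "all_subjects"
    if len(hist) >= 4:
        for h in ("mvd_per_mm2", "mva_fraction"):
            for p in ("f_percent", "bf_ml_per_100ml_min", "bv_ml_per_100ml"):
                row = _corr_row(hist, h, p)
                row["block"] = "histology"
                corr_rows.append(row)
    correlations = pd.DataFrame(corr_rows)

    # Full matrix (supplementary-style): all IVIM × CT pairs on all
    # subjects, all imaging × histology pairs on the subset.
    full_rows = []
    for a in IVIM_PARAMS:
        for b in CT_PARAMS:
            r = _corr_row(tum, a, b)
            r["block"] = "all_subjects"
            full_rows.append(r)
    if len(hist) >= 4:
        for h in ("mvd_per_mm2", "mva_fraction"):
            for p in IVIM_PARAMS + CT_PARAMS:
                r = _corr_row(hist, h, p)
                r["block"] = "histology"
                full_rows.append(r)
    correlations_full = pd.DataFrame(full_rows)

    # Dependent-correlation comparisons on the histology subset: does f
    # track MVD/MVA differently than BF does?  And BF versus BV?
    dep_rows = []
    if len(hist) >= 4:
        for h in ("mvd_per_mm2", "mva_fraction"):
            for (j, k) in (("f_percent", "bf_ml_per_100ml_min"),
                           ("bf_ml_per_100ml_min", "bv_ml_per_100ml")):
                r_jh = stats.spearman(hist[j], hist[h]).rho
                r_kh = stats.spearman(hist[k], hist[h]).rho
                r_jk = stats.spearman(hist[j], hist[k]).rho
                # Degenerate |rho| = 1 (tiny subsets) breaks the Fisher
                # transform; nudge inside the open interval.
                clip = lambda r: float(np.clip(r, -0.9999, 0.9999))  # noqa: E731
                cmp_ = stats.meng_z(clip(r_jh), clip(r_kh), clip(r_jk),
                                    len(hist))
                dep_rows.append(
                    {
                        "corr_a": f"{SHORT[j]}-{SHORT[h]}",
                        "corr_b": f"{SHORT[k]}-{SHORT[h]}",
                        "r_jh": r_jh, "r_kh": r_kh, "r_jk": r_jk,
                        "z": cmp_.z, "p": cmp_.p_two_sided,
                        "significant": cmp_.significant, "n": len(hist),
                    }
                )
    dependent_comparisons = pd.DataFrame(dep_rows)

    # ROC tumor vs upstream, reader 1, tumor-low direction.
    r1 = table[table["reader"] == 1]
    t1 = r1[r1["region"] == TUMOR].set_index("subject_id")
    u1 = r1[r1["region"] == UPSTREAM].set_index("subject_id")
    roc_rows, delong_rows = [], []
    roc_results = {}
    labels = np.concatenate(
        [np.ones(len(t1), dtype=int), np.zeros(len(u1), dtype=int)]
    )
    for p in ROC_PARAMS:
        v = np.concatenate([t1[p].to_numpy(), u1[p].to_numpy()])
        res = stats.roc_analyze(v, labels, direction="le")
        roc_results[p] = v
        roc_rows.append(
            {
                "parameter": SHORT[p], "auc": res.auc,
                "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                "cutoff": res.cutoff, "sensitivity": res.sensitivity,
                "specificity": res.specificity, "direction": res.direction,
                "band": res.band,
            }
        )
    for i, a in enumerate(ROC_PARAMS):
        for b in ROC_PARAMS[i + 1:]:
            cmp_ = stats.delong_compare(
                roc_results[a], roc_results[b], labels,
                direction_a="le", direction_b="le",
            )
            delong_rows.append(
                {
                    "parameter_a": SHORT[a], "parameter_b": SHORT[b],
                    "auc_a": cmp_.auc_a, "auc_b": cmp_.auc_b,
                    "z": cmp_.z, "p": cmp_.p_two_sided,
                }
            )
    roc = pd.DataFrame(roc_rows)
    delong_pairs = pd.DataFrame(delong_rows)

    # Inter-reader ICC on tumor values.
    icc_rows = []
    tum_wide = table[table["region"] == TUMOR].pivot(
        index="subject_id", columns="reader"
    )
    for p in ROC_PARAMS:
        res = stats.icc_two_way_random(tum_wide[p].to_numpy())
        icc_rows.append(
            {
                "parameter": SHORT[p], "icc": res.icc,
                "ci_low": res.ci95[0], "ci_high": res.ci95[1],
                "band": res.band,
            }
        )
    icc = pd.DataFrame(icc_rows)

    # Paired group tests (reader 1): tumor vs upstream / downstream.
    gt_rows = []
    d1 = r1[r1["region"] == DOWNSTREAM].set_index("subject_id")
    for p in ROC_PARAMS:
        common = t1.index.intersection(u1.index)
        w, pv = stats.wilcoxon_signed_rank(
            t1.loc[common, p], u1.loc[common, p]
        )
        gt_rows.append(
            {
                "parameter": SHORT[p], "comparison": "tumor_vs_upstream",
                "statistic": w, "p": pv, "n": len(common),
                "tumor_lower": bool(
                    t1.loc[common, p].median() < u1.loc[common, p].median()
                ),
            }
        )
        if len(d1) >= 5:
            common = t1.index.intersection(d1.index)
            w, pv = stats.wilcoxon_signed_rank(
                t1.loc[common, p], d1.loc[common, p]
            )
            gt_rows.append(
                {
                    "parameter": SHORT[p], "comparison": "tumor_vs_downstream",
                    "statistic": w, "p": pv, "n": len(common),
                    "tumor_lower": bool(
                        t1.loc[common, p].median() < d1.loc[common, p].median()
                    ),
                }
            )
    group_tests = pd.DataFrame(gt_rows)

    # Linear regressions on reader means (scatter-plot summaries).
    reg_rows = []
    reg_specs = [
        (tum, "f_percent", "bf_ml_per_100ml_min"),
        (tum, "f_percent", "bv_ml_per_100ml"),
        (hist, "f_percent", "mvd_per_mm2"),
        (hist, "f_percent", "mva_fraction"),
        (hist, "bf_ml_per_100ml_min", "mvd_per_mm2"),
        (hist, "bf_ml_per_100ml_min", "mva_fraction"),
        (hist, "bv_ml_per_100ml", "mvd_per_mm2"),
        (hist, "bv_ml_per_100ml", "mva_fraction"),
    ]
    for df, x, y in reg_specs:
        sub = df[[x, y]].dropna()
        if len(sub) < 3:
            continue
        res = sps.linregress(sub[x], sub[y])
        reg_rows.append(
            {
                "x": SHORT[x], "y": SHORT[y], "slope": res.slope,
                "intercept": res.intercept, "r_squared": res.rvalue**2,
                "n": len(sub),
            }
        )
    regressions = pd.DataFrame(reg_rows)

    return AnalysisReport(
        correlations=correlations, correlations_full=correlations_full,
        dependent_comparisons=dependent_comparisons, roc=roc,
        delong_pairs=delong_pairs, icc=icc, group_tests=group_tests,
        regressions=regressions,
        n_subjects=tum["subject_id"].nunique(), n_histology=len(hist),
    )


# ----------------------------------------------------------- end-to-end

def write_observables(sim: SimulatedCohort, outdir: Path) -> None:
    outdir = Path(outdir)
    (outdir / "signals").mkdir(parents=True, exist_ok=True)
    (outdir / "tacs").mkdir(exist_ok=True)
    (outdir / "vessels").mkdir(exist_ok=True)
    synthetic_cohort.truths_to_frame(sim.truths).to_csv(
        outdir / "cohort_truth.csv", index=False
    )
    for (sid, region), sig in sim.signals.items():
        ivim.save_signal_csv(sig, outdir / "signals" / f"{sid}_{region}.csv")
    for (sid, region), cur in sim.curves.items():
        ctperfusion.save_curves_csv(cur, outdir / "tacs" / f"{sid}_{region}.csv")
    for sid, img in sim.vessel_images.items():
        microvessel.save_vessel_image(img, outdir / "vessels" / f"{sid}.tiff")


def end_to_end(config: CohortConfig, outdir: Path,
               qc_plots: bool = True) -> AnalysisReport:
    """Run the full pipeline, persisting every intermediate artifact.

    Observables are written to disk first and the fitting stages read
    them back, so a missing or corrupt per-subject file aborts with a
    stage-tagged error naming the subject.  The manifest records the
    package version, seed, and configuration.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate(config)
    write_observables(sim, outdir)

    # Reload observables from disk: the fit stages consume the artifacts.
    for t in sim.truths:
        key = (t.subject_id, t.region)
        sig_path = outdir / "signals" / f"{t.subject_id}_{t.region}.csv"
        tac_path = outdir / "tacs" / f"{t.subject_id}_{t.region}.csv"
        if not sig_path.exists():
            raise StageError(f"ivim: missing DWI signal for {key}")
        if not tac_path.exists():
            raise StageError(f"ctperfusion: missing TAC for {key}")
        sig = ivim.load_signal_csv(sig_path)
        sig.subject_id, sig.region_label = t.subject_id, t.region
        sim.signals[key] = sig
        sim.curves[key] = ctperfusion.load_curves_csv(tac_path)

    table = fit_cohort(sim)
    table.to_csv(outdir / "cohort_table.csv", index=False)
    report = run_analysis(table)
    report.save(outdir / "report")
    if qc_plots:
        try:
            _qc_plots(table, report, outdir / "qc")
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"qc: plotting failed: {exc}") from exc
    manifest = {
        "package": "perfconcord",
        "version": __version__,
        "seed": config.rng_seed,
        "config": {k: getattr(config, k) for k in (
            "n_subjects", "n_histology", "n_downstream", "noise_snr_dwi",
            "noise_sd_hu", "reader_jitter", "latent_effect", "field_mm2",
            "px_per_mm",
        )},
        "artifacts": sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        ),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return report


def _qc_plots(table: pd.DataFrame, report: AnalysisReport, qcdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    qcdir = Path(qcdir)
    qcdir.mkdir(parents=True, exist_ok=True)
    mean_tbl = reader_mean(table)
    tum = mean_tbl[mean_tbl["region"] == TUMOR]

    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.scatter(tum["f_percent"], tum["bf_ml_per_100ml_min"], c="k", s=20)
    if len(report.regressions):
        row = report.regressions.iloc[0]
        xs = np.linspace(tum["f_percent"].min(), tum["f_percent"].max(), 50)
        ax.plot(xs, row["slope"] * xs + row["intercept"], "r-",
                label=f"R²={row['r_squared']:.2f}")
        ax.legend()
    ax.set_xlabel("f [%]")
    ax.set_ylabel("BF [ml/100ml/min]")
    fig.tight_layout()
    fig.savefig(qcdir / "scatter_f_bf.png", dpi=110)
    plt.close(fig)

    # Per-parameter region line diagrams (one line per subject).
    fig, axes = plt.subplots(2, 3, figsize=(11, 6))
    for ax, p in zip(axes.ravel(), ROC_PARAMS):
        wide = mean_tbl.pivot(index="subject_id", columns="region", values=p)
        order = [r for r in (TUMOR, DOWNSTREAM, UPSTREAM) if r in wide.columns]
        for _, row in wide.iterrows():
            ax.plot(range(len(order)), row[order], "o-", color="gray",
                    alpha=0.6, ms=3)
        ax.set_xticks(range(len(order)))
        ax.set_xticklabels(order, fontsize=7)
        ax.set_title(SHORT[p], fontsize=9)
    fig.tight_layout()
    fig.savefig(qcdir / "region_lines.png", dpi=110)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(4.5, 4))
    for _, row in report.roc.iterrows():
        ax.plot([], [], label=f"{row['parameter']}: AUC={row['auc']:.3f}")
    r1 = table[table["reader"] == 1]
    t1 = r1[r1["region"] == TUMOR]
    u1 = r1[r1["region"] == UPSTREAM]
    labels = np.r_[np.ones(len(t1), int), np.zeros(len(u1), int)]
    for p in ROC_PARAMS:
        v = -np.r_[t1[p].to_numpy(), u1[p].to_numpy()]  # tumor-low
        order = np.argsort(-v)
        tpr = np.cumsum(labels[order]) / labels.sum()
        fpr = np.cumsum(1 - labels[order]) / (1 - labels).sum()
        ax.plot(np.r_[0, fpr], np.r_[0, tpr], lw=1)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(qcdir / "roc_curves.png", dpi=110)
    plt.close(fig)
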