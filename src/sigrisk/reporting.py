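"""Publication-style outputs: Kaplan-Meier plot with at-risk counts,
risk-ordered expression heat map, per-gene box plots with group tests, the
PI-vs-group panel, and coefficient/PI tables.

Every figure is backed by a sidecar TSV containing exactly the numbers
drawn (plot-data parity), and :func:`export_report` produces a fixed file
layout with a machine-readable JSON summary, so a run is fully
reproducible from its output directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np
import pandas as pd
from scipy import stats

from .survival import km_estimate

__all__ = ["AnalysisReport", "gene_group_tests", "render_km",
           "render_heatmap", "export_report"]

GROUP_COLORS = ["#2ca02c", "#d62728", "#1f77b4", "#ff7f0e", "#9467bd"]


@dataclass
class AnalysisReport:
    """All inputs needed to render/export one analysis."""

    expr_values: np.ndarray          # signature genes x samples
    gene_ids: list
    sample_ids: list
    time: np.ndarray
    event: np.ndarray
    labels: np.ndarray               # risk group 1..k per sample
    pi: np.ndarray
    betas: dict
    coef_table: pd.DataFrame | None  # gene, beta, se, wald_p
    logrank: object | None
    hazard: tuple | None             # (hr, (lo, hi), p)
    concordance: object | None
    tdroc: object | None = None
    metadata: dict = field(default_factory=dict)

    def is_empty(self) -> bool:
        return len(self.sample_ids) == 0


# ---------------------------------------------------------------------------
# Per-gene differential tests between risk groups
# ---------------------------------------------------------------------------

def gene_group_tests(expr_values, gene_ids, labels) -> pd.DataFrame:
    """Per-gene test of expression difference across risk groups.

    Two groups: Welch's t-test; more: one-way F-test.  Returns a table
    with the statistic, p-value, and a Benjamini-Hochberg adjusted column;
    the count of genes at p < 0.05 (unadjusted) mirrors the usual
    "differentially expressed genes between risk groups" summary.
    """
    expr_values = np.asarray(expr_values, dtype=float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if levels.size < 2:
        raise ValueError("need at least 2 risk groups")
    for lv in levels:
        if (labels == lv).sum() < 2:
            raise ValueError(f"group {lv} has fewer than 2 samples")
    rows = []
    for g, row in zip(gene_ids, expr_values):
        groups = [row[labels == lv] for lv in levels]
        if all(np.ptp(grp) == 0 for grp in groups) and \
                len({grp[0] for grp in groups}) == 1:
            stat, p = 0.0, 1.0
        elif levels.size == 2:
            stat, p = stats.ttest_ind(groups[0], groups[1], equal_var=False)
        else:
            stat, p = stats.f_oneway(*groups)
        if not np.isfinite(p):
            stat, p = 0.0, 1.0
        means = {f"mean_group{lv}": float(np.mean(grp))
                 for lv, grp in zip(levels, groups)}
        rows.append({"gene": g, "statistic": float(stat), "p_value": float(p),
                     **means})
    table = pd.DataFrame(rows)
    table["p_adj_bh"] = _bh_adjust(table["p_value"].to_numpy())
    table.attrs["n_deg_p05"] = int((table["p_value"] < 0.05).sum())
    return table


def _bh_adjust(p):
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


# ---------------------------------------------------------------------------
# Figures with sidecar TSVs
# ---------------------------------------------------------------------------

def _km_table(time, event, labels):
    """Step-curve coordinates per group, for plotting and the sidecar TSV."""
    rows = []
    for lv in np.unique(labels):
        m = labels == lv
        curve = km_estimate(time[m], event[m])
        rows.append({"group": int(lv), "time": 0.0, "survival": 1.0,
                     "at_risk": int(m.sum()), "n_events": 0})
        for t, s, r, d in zip(curve.event_times, curve.survival,
                              curve.at_risk, curve.n_events):
            rows.append({"group": int(lv), "time": float(t),
                         "survival": float(s), "at_risk": int(r),
                         "n_events": int(d)})
    return pd.DataFrame(rows)


def render_km(report: AnalysisReport, path_png, path_tsv):
    """KM curves per risk group with censor ticks, at-risk table and
    annotation block (log-rank p, HR with CI, concordance)."""
    time, event, labels = report.time, report.event, report.labels
    table = _km_table(time, event, labels)
    table.to_csv(path_tsv, sep="\t", index=False)

    fig, ax = plt.subplots(figsize=(6.5, 5.5))
    levels = np.unique(labels)
    tmax = float(time.max())
    ticks = np.linspace(0, tmax, 6)
    for gi, lv in enumerate(levels):
        m = labels == lv
        curve = km_estimate(time[m], event[m])
        xs = np.concatenate([[0.0], np.repeat(curve.event_times, 2)])
        ys = np.concatenate([np.repeat(np.concatenate([[1.0], curve.survival[:-1]]), 2),
                             [curve.survival[-1]]]) if curve.event_times.size \
            else np.array([1.0])
        if curve.event_times.size:
            ax.plot(xs, ys, color=GROUP_COLORS[gi % len(GROUP_COLORS)],
                    label=f"group {lv} (n={m.sum()})")
        else:
            ax.plot([0, tmax], [1, 1], color=GROUP_COLORS[gi % len(GROUP_COLORS)],
                    label=f"group {lv} (n={m.sum()})")
        cens = time[m & (event == 0)]
        surv_at = km_estimate(time[m], event[m]).survival_at(cens) \
            if cens.size else np.array([])
        ax.plot(cens, surv_at, "+", color=GROUP_COLORS[gi % len(GROUP_COLORS)],
                markersize=6)
        # at-risk counts under the axis at each tick
        at_risk = [(time[m] >= t).sum() for t in ticks]
        for t, r in zip(ticks, at_risk):
            ax.annotate(str(r), xy=(t, -0.06 - 0.045 * gi),
                        xycoords=("data", "axes fraction"),
                        ha="center", fontsize=7,
                        color=GROUP_COLORS[gi % len(GROUP_COLORS)])
    lines = []
    if report.logrank is not None and levels.size >= 2:
        lines.append(f"log-rank p = {report.logrank.p_value:.3g}")
    if report.hazard is not None:
        hr, (lo, hi), p = report.hazard
        lines.append(f"HR = {hr:.2f} ({lo:.2f}-{hi:.2f})")
    if report.concordance is not None:
        lines.append(f"C-index = {100 * report.concordance.c_index:.1f}")
    if lines:
        ax.text(0.02, 0.05, "\n".join(lines), transform=ax.transAxes,
                fontsize=9, va="bottom")
    ax.set_xlabel(f"time ({report.metadata.get('time_unit', 'units')})")
    ax.set_ylabel("survival probability")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="upper right", fontsize=8)
    fig.subplots_adjust(bottom=0.22)
    fig.savefig(path_png, dpi=120)
    plt.close(fig)
    return table


def render_heatmap(report: AnalysisReport, path_png, path_tsv):
    """Gene x sample heat map, columns ordered by PI ascending within group,
    diverging scale centered at the per-gene median."""
    order = np.lexsort((report.pi, report.labels))
    vals = report.expr_values[:, order]
    samples = [report.sample_ids[i] for i in order]
    centered = vals - np.median(vals, axis=1, keepdims=True)
    df = pd.DataFrame(vals, index=report.gene_ids, columns=samples)
    df.to_csv(path_tsv, sep="\t")

    fig, ax = plt.subplots(figsize=(7, 0.35 * len(report.gene_ids) + 1.8))
    lim = float(np.max(np.abs(centered))) or 1.0
    im = ax.imshow(centered, aspect="auto", cmap="RdYlGn_r",
                   vmin=-lim, vmax=lim, interpolation="nearest")
    ax.set_yticks(range(len(report.gene_ids)), report.gene_ids, fontsize=7)
    ax.set_xticks([])
    ax.set_xlabel("samples (PI ascending within risk group)")
    # group boundaries
    sizes = np.bincount(report.labels)[1:]
    pos = 0
    for sz in sizes[:-1]:
        pos += sz
        ax.axvline(pos - 0.5, color="black", lw=1)
    fig.colorbar(im, ax=ax, label="expression - gene median")
    fig.tight_layout()
    fig.savefig(path_png, dpi=120)
    plt.close(fig)
    return df


def _render_boxplots(report, tests, path_png):
    levels = np.unique(report.labels)
    ng = len(report.gene_ids)
    ncol = min(4, ng)
    nrow = int(np.ceil(ng / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(2.6 * ncol, 2.4 * nrow),
                             squeeze=False)
    for i, g in enumerate(report.gene_ids):
        ax = axes[i // ncol][i % ncol]
        data = [report.expr_values[i, report.labels == lv] for lv in levels]
        ax.boxplot(data, tick_labels=[str(lv) for lv in levels])
        p = float(tests.loc[tests["gene"] == g, "p_value"].iloc[0])
        ax.set_title(f"{g}  p={p:.2g}", fontsize=8)
    for j in range(ng, nrow * ncol):
        axes[j // ncol][j % ncol].axis("off")
    fig.tight_layout()
    fig.savefig(path_png, dpi=120)
    plt.close(fig)


def _render_pi_groups(report, path_png, path_tsv):
    df = pd.DataFrame({"sample": report.sample_ids, "pi": report.pi,
                       "group": report.labels})
    df = df.sort_values("pi", kind="stable").reset_index(drop=True)
    df.to_csv(path_tsv, sep="\t", index=False)
    fig, ax = plt.subplots(figsize=(6, 3))
    for gi, lv in enumerate(np.unique(report.labels)):
        m = df["group"] == lv
        ax.plot(np.flatnonzero(m.to_numpy()), df.loc[m, "pi"], ".",
                color=GROUP_COLORS[gi % len(GROUP_COLORS)],
                label=f"group {lv}")
    ax.set_xlabel("samples ordered by prognostic index")
    ax.set_ylabel("prognostic index")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path_png, dpi=120)
    plt.close(fig)


def export_report(report: AnalysisReport, outdir) -> dict:
    """Write the full analysis to ``outdir``; returns the manifest.

    Layout: ``km.png``/``km.tsv``, ``heatmap.png``/``heatmap.tsv``,
    ``boxplots.png``/``gene_tests.tsv``, ``pi_groups.png``/``pi_groups.tsv``,
    ``coefficients.tsv``, ``tdroc.tsv`` (when present), ``summary.json``
    and ``manifest.json``.
    """
    if report.is_empty():
        raise ValueError("empty report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest = {"files": {}, "missing": [], "metadata": report.metadata}

    render_km(report, outdir / "km.png", outdir / "km.tsv")
    manifest["files"]["km"] = ["km.png", "km.tsv"]

    render_heatmap(report, outdir / "heatmap.png", outdir / "heatmap.tsv")
    manifest["files"]["heatmap"] = ["heatmap.png", "heatmap.tsv"]

    tests = gene_group_tests(report.expr_values, report.gene_ids, report.labels)
    tests.to_csv(outdir / "gene_tests.tsv", sep="\t", index=False)
    _render_boxplots(report, tests, outdir / "boxplots.png")
    manifest["files"]["gene_tests"] = ["boxplots.png", "gene_tests.tsv"]

    _render_pi_groups(report, outdir / "pi_groups.png", outdir / "pi_groups.tsv")
    manifest["files"]["pi_groups"] = ["pi_groups.png", "pi_groups.tsv"]

    if report.coef_table is not None:
        report.coef_table.to_csv(outdir / "coefficients.tsv", sep="\t",
                                 index=False)
        manifest["files"]["coefficients"] = ["coefficients.tsv"]
    else:
        manifest["missing"].append("coefficients")

    if report.tdroc is not None:
        roc = report.tdroc
        pd.DataFrame({"threshold": roc.thresholds,
                      "sensitivity": roc.sensitivity,
                      "specificity": roc.specificity}).to_csv(
            outdir / "tdroc.tsv", sep="\t", index=False)
        manifest["files"]["tdroc"] = ["tdroc.tsv"]
    else:
        manifest["missing"].append("tdroc")

    summary = _summary_dict(report, tests)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                    sort_keys=True))
    manifest["files"]["summary"] = ["summary.json"]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest


def _summary_dict(report, tests):
    s = {
        "n_samples": len(report.sample_ids),
        "n_genes": len(report.gene_ids),
        "group_sizes": {int(lv): int((report.labels == lv).sum())
                        for lv in np.unique(report.labels)},
        "betas": {g: round(float(b), 10) for g, b in report.betas.items()},
        "n_deg_p05": int(tests.attrs["n_deg_p05"]),
        "metadata": report.metadata,
    }
    if report.logrank is not None:
        s["logrank"] = {"statistic": round(float(report.logrank.statistic), 10),
                        "df": int(report.logrank.df),
                        "p_value": float(report.logrank.p_value)}
    if report.hazard is not None:
        hr, (lo, hi), p = report.hazard
        s["hazard_ratio"] = {"hr": round(float(hr), 10),
                             "ci95": [float(lo), float(hi)],
                             "p_value": float(p)}
    if report.concordance is not None:
        s["concordance"] = {
            "c_index": round(float(report.concordance.c_index), 10),
            "comparable_pairs": int(report.concordance.comparable_pairs)}
    if report.tdroc is not None:
        s["tdroc"] = {"auc": round(float(report.tdroc.auc), 10),
                      "horizon": float(report.tdroc.horizon),
                      "estimator": report.tdroc.estimator}
    return s
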