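"""Figure helpers: ICC-stiffness scatter with fit line, grid-study bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def save_correlation_figure(table, report, path: str | Path) -> None:
    """Scatter of stiffness vs ICC with least-squares line and the
    correlation verdict in the title."""
    x = table["icc_ml_per_cmH2O"].to_numpy()
    y = table["stiffness_N_per_m"].to_numpy()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=18, alpha=0.7, edgecolor="none")
    if np.ptp(x) > 0:
        b, a = np.polyfit(x, y, 1)
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, a + b * xs, "k--", lw=1)
    ax.set_xlabel("ICC (ml/cmH$_2$O)")
    ax.set_ylabel("FSI-based brain stiffness (N/m)")
    ax.set_title(
        f"r = {report.pearson_r:.3f} (p = {report.pearson_p:.3g}), "
        f"$\\rho$ = {report.spearman_rho:.3f} (p = {report.spearman_p:.3g})",
        fontsize=9,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_grid_study_figure(report, path: str | Path) -> None:
    """Bar chart of cycle-mean ICP per refinement level."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(range(len(report.levels)), report.icp_cmH2O, color="steelblue")
    ax.set_xticks(range(len(report.levels)))
    ax.set_xticklabels(report.levels, rotation=20)
    ax.set_ylabel("cycle-mean ICP (cmH$_2$O)")
    lo = min(report.icp_cmH2O)
    hi = max(report.icp_cmH2O)
    pad = max((hi - lo) * 2, 1e-6)
    ax.set_ylim(lo - pad, hi + pad)
    for i, d in enumerate(report.successive_diff_percent, start=1):
        ax.text(i, report.icp_cmH2O[i], f"{d:.2g}%", ha="center", va="bottom", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
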