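"""Diagnostic plots mirroring the classic codon-usage figures.

All functions draw on a head-less Agg canvas and write to file; they are
optional conveniences behind the CLI's ``--plots`` flag and never run in
the analytical path.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bias_diagnostics import expected_enc
from .pipeline import AnalysisResult


def enc_plot(result: AnalysisResult, path: str | Path) -> None:
    """ENc against GC3s with Wright's null curve."""
    t = result.index_table
    fig, ax = plt.subplots(figsize=(5, 4))
    s = np.linspace(0, 1, 200)
    ax.plot(s, expected_enc(s), "r-", lw=1.5, label="expected (mutation only)")
    ax.scatter(t["GC3s"], t["ENc"], s=4, alpha=0.4, label="genes")
    ref = t[t["flags"].map(lambda f: "reference" in f)]
    if len(ref):
        ax.scatter(ref["GC3s"], ref["ENc"], s=18, c="orange", label="reference")
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENc")
    ax.set_ylim(0, 62)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pr2_plot(result: AnalysisResult, path: str | Path) -> None:
    """A3/(A3+T3) against G3/(G3+C3) for the four-codon families."""
    p = result.pr2_points
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(p["x_g3_over_g3c3"], p["y_a3_over_a3t3"], s=4, alpha=0.4)
    ax.axhline(0.5, color="grey", lw=0.8)
    ax.axvline(0.5, color="grey", lw=0.8)
    ax.plot([result.pr2.mean_x], [result.pr2.mean_y], "ro", ms=6, mfc="none")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("G3 / (G3 + C3)")
    ax.set_ylabel("A3 / (A3 + T3)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def neutrality_plot(result: AnalysisResult, path: str | Path) -> None:
    """GC12 against GC3 with the OLS line and the diagonal."""
    t = result.index_table
    fit = result.neutrality
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.scatter(t["GC3"], t["GC12"], s=4, alpha=0.4)
    x = np.array([t["GC3"].min(), t["GC3"].max()])
    ax.plot(x, fit.intercept + fit.slope * x, "r-", lw=1.5,
            label=f"slope = {fit.slope:.4f}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="GC12 = GC3")
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def deviation_histogram_plot(result: AnalysisResult, path: str | Path) -> None:
    """Frequency distribution of (ENc_exp - ENc_obs) / ENc_exp."""
    edges, counts = result.deviation_histogram
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
           edgecolor="black", linewidth=0.5)
    ax.set_xlabel("(ENc_exp − ENc_obs) / ENc_exp")
    ax.set_ylabel("genes")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_all(result: AnalysisResult, outdir: str | Path) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    jobs = [
        (enc_plot, "enc_plot.png"),
        (pr2_plot, "pr2_plot.png"),
        (neutrality_plot, "neutrality_plot.png"),
        (deviation_histogram_plot, "enc_deviation_histogram.png"),
    ]
    written = []
    for func, name in jobs:
        func(result, outdir / name)
        written.append(outdir / name)
    return written
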