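"""End-to-end orchestration: from QC'd coding sequences to every report.

``analyze`` runs the full chain — per-gene indices, adaptiveness PCA with
the expression-axis test, expression-extreme pools and optimal-codon
calling, the ENc-GC3s deviation analysis, PR2 coordinates and the
neutrality regression — and returns an :class:`AnalysisResult` whose
``write`` method dumps every table as TSV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import floor
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import bias_diagnostics as bd
from . import codon_metrics as cm
from . import multivariate as mv
from . import optimal_codons as oc
from .sequence_io import CdsRecord, write_index_table


@dataclass
class AnalysisResult:
    """Everything the pipeline computes, ready for writing or inspection."""

    index_table: pd.DataFrame
    counts: dict[str, cm.CodonCountTable]
    reference_ids: list[str]
    weights: cm.ReferenceWeights | None
    pca: mv.PcaResult
    expression_test: mv.ExpressionAxisTest | None
    high_pool: list[str]
    low_pool: list[str]
    comparison: oc.PoolComparison | None
    optimal_report: oc.OptimalCodonReport | None
    neutrality: bd.NeutralityFit
    pr2_points: pd.DataFrame
    pr2: bd.Pr2Summary
    enc_deviation: pd.DataFrame
    deviation_histogram: tuple[np.ndarray, np.ndarray]
    correlations: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def save(name: str, df: pd.DataFrame, **kw) -> None:
            p = outdir / name
            df.to_csv(p, sep="\t", float_format="%.6f", **kw)
            paths[name] = p

        p = outdir / "gene_indices.tsv"
        write_index_table(self.index_table, p)
        paths["gene_indices.tsv"] = p
        save("pca_scores.tsv", self.pca.scores, index_label="id")
        save("pca_loadings.tsv", self.pca.loadings, index_label="codon")
        save(
            "pca_explained.tsv",
            pd.DataFrame(
                {"explained_fraction": self.pca.explained_fraction},
                index=self.pca.scores.columns,
            ),
            index_label="component",
        )
        if self.comparison is not None:
            save("optimal_codons.tsv", self.comparison.table, index_label="codon")
        save("pr2_points.tsv", self.pr2_points, index_label="id")
        save("enc_deviation.tsv", self.enc_deviation, index_label="id")
        edges, counts = self.deviation_histogram
        save(
            "enc_deviation_histogram.tsv",
            pd.DataFrame(
                {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
            ),
            index=False,
        )
        save("index_correlations.tsv", self.correlations, index=False)
        summary = self.summary()
        (outdir / "summary.tsv").write_text(
            "quantity\tvalue\n"
            + "\n".join(f"{k}\t{v}" for k, v in summary.items())
            + "\n"
        )
        paths["summary.tsv"] = outdir / "summary.tsv"
        return paths

    def summary(self) -> dict[str, object]:
        t = self.index_table
        out: dict[str, object] = {
            "n_genes": len(t),
            "mean_GC_percent": round(100 * t["GC"].mean(), 2),
            "mean_GC3_percent": round(100 * t["GC3"].mean(), 2),
            "mean_GC3s_percent": round(100 * t["GC3s"].mean(), 2),
            "mean_ENc": round(t["ENc"].mean(), 2),
            "sd_ENc": round(t["ENc"].std(), 2),
            "PC1_explained_percent": round(100 * self.pca.explained_fraction[0], 2),
            "neutrality_slope": round(self.neutrality.slope, 4),
            "neutrality_OP_percent": round(self.neutrality.op_point_percent, 2),
            "PR2_mean_x": round(self.pr2.mean_x, 4),
            "PR2_mean_y": round(self.pr2.mean_y, 4),
        }
        if self.expression_test is not None:
            out["expression_axis_mean_abs_z"] = round(
                self.expression_test.mean_abs_z, 2
            )
            out["expression_axis_labelled"] = self.expression_test.labelled_expression
        if self.optimal_report is not None:
            out["n_optimal_codons"] = self.optimal_report.n
            out["optimal_GC_AU"] = (
                f"{self.optimal_report.gc_nucleotides}:"
                f"{self.optimal_report.au_nucleotides}"
            )
        return out


def analyze(
    records: Sequence[CdsRecord],
    reference_ids: Iterable[str] | None = None,
    pool_fraction: float = 0.05,
    alpha: float = 0.01,
    pca_columns: str = "all59",
    correlation_method: str = "spearman",
    z_threshold: float = 5.17,
) -> AnalysisResult:
    """Run the complete codon-usage analysis on QC'd coding sequences.

    ``reference_ids`` defaults to the records flagged "reference"
    (ribosomal genes); without any reference, CAI, Fop, the expression
    test and pool orientation are skipped or fall back to score order.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 sequences")
    ids = [r.id for r in records]
    counts = {r.id: cm.count_codons(r) for r in records}

    if reference_ids is None:
        reference_ids = [r.id for r in records if "reference" in r.flags]
    reference_ids = [r for r in reference_ids if r in counts]

    weights = (
        cm.cai_weights([counts[i] for i in reference_ids], )
        if reference_ids
        else None
    )
    if weights is not None:
        weights = cm.ReferenceWeights(
            weights.weights, tuple(reference_ids), weights.pseudocount
        )

    rows = []
    for rec in records:
        c = counts[rec.id]
        g = cm.gc_position_stats(c)
        sb = cm.silent_base_composition(c)
        rows.append(
            {
                "id": rec.id,
                "length_codons": c.n_codons,
                "GC": g.gc, "GC1": g.gc1, "GC2": g.gc2, "GC12": g.gc12,
                "GC3": g.gc3, "GC3s": g.gc3s,
                "A3s": sb.a3s, "T3s": sb.t3s, "G3s": sb.g3s, "C3s": sb.c3s,
                "ENc": cm.enc(c),
                "CAI": cm.cai(c, weights) if weights else np.nan,
                "Fop": np.nan,  # filled after optimal codons are called
                "GRAVY": cm.gravy(rec),
                "Aromo": cm.aromaticity(rec),
                "flags": rec.flags,
            }
        )
    table = pd.DataFrame(rows)

    matrix = mv.adaptiveness_matrix(
        [counts[i] for i in ids], ids, columns=pca_columns
    )
    pca_res = mv.pca(matrix, gc3s=table.set_index("id")["GC3s"])
    table["PC1"] = pca_res.scores["PC1"].reindex(table["id"]).values
    table["PC2"] = (
        pca_res.scores["PC2"].reindex(table["id"]).values
        if "PC2" in pca_res.scores
        else np.nan
    )

    expr_test = (
        mv.expression_axis_test(pca_res, reference_ids, threshold=z_threshold)
        if reference_ids
        else None
    )

    high_pool: list[str] = []
    low_pool: list[str] = []
    comparison = None
    optimal_report = None
    if pool_fraction and floor(pool_fraction * len(ids)) >= 1:
        high_pool, low_pool = oc.extreme_pools(
            pca_res, pool_fraction, reference_ids
        )
        pooled_high = sum((counts[i] for i in high_pool), cm.CodonCountTable())
        pooled_low = sum((counts[i] for i in low_pool), cm.CodonCountTable())
        comparison = oc.codon_test(pooled_high, pooled_low, alpha=alpha)
        optimal_report = oc.optimal_set(comparison)
        if optimal_report.codons:
            table["Fop"] = [
                cm.fop(counts[i], optimal_report.codons) for i in table["id"]
            ]
    elif pool_fraction:
        warnings.warn(
            f"pool fraction {pool_fraction} of {len(ids)} genes is empty; "
            "optimal-codon stage skipped"
        )

    neutrality = bd.neutrality_fit(table["GC3"], table["GC12"])
    points = [bd.pr2_coordinates(counts[i]) for i in ids]
    pr2_points = pd.DataFrame(
        {
            "x_g3_over_g3c3": [p.x for p in points],
            "y_a3_over_a3t3": [p.y for p in points],
            "n_codons_used": [p.n_codons_used for p in points],
        },
        index=ids,
    )
    pr2 = bd.pr2_summary(points)

    dev = bd.enc_deviation(
        table.set_index("id")["ENc"], table.set_index("id")["GC3s"]
    )
    hist = bd.enc_deviation_histogram(dev["rel_dev"].dropna())

    corr_cols = [
        "length_codons", "GC", "GC1", "GC2", "GC3", "GC3s", "A3s", "T3s",
        "G3s", "C3s", "ENc", "CAI", "Fop", "GRAVY", "Aromo", "PC1", "PC2",
    ]
    usable = [c for c in corr_cols if table[c].notna().sum() >= 3]
    correlations = mv.correlate_indices(
        table[usable], method=correlation_method
    )

    return AnalysisResult(
        index_table=table,
        counts=counts,
        reference_ids=list(reference_ids),
        weights=weights,
        pca=pca_res,
        expression_test=expr_test,
        high_pool=high_pool,
        low_pool=low_pool,
        comparison=comparison,
        optimal_report=optimal_report,
        neutrality=neutrality,
        pr2_points=pr2_points,
        pr2=pr2,
        enc_deviation=dev,
        deviation_histogram=hist,
        correlations=correlations,
    )
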