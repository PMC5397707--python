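"""Multivariate trend analysis of codon usage.

PCA is run on the gene x relative-adaptiveness matrix (per-gene RSCU
normalised by the within-family maximum, after Sharp & Li), mean-centred
but not variance-scaled: adaptiveness entries already share a common
[0, 1] scale. A parallel PCA on amino-acid usage frequencies and an
expression-axis z-score test on reference (ribosomal) genes complete the
module, together with rank-correlation tables between indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA as _SkPCA

from .codon_metrics import CodonCountTable, count_codons, rscu, _protein
from .genetics import SYNONYMOUS_CODONS, AA_TO_CODONS, to_rna
from .sequence_io import CdsRecord

_SYN_RNA = [to_rna(c) for c in SYNONYMOUS_CODONS]


@dataclass
class AdaptivenessMatrix:
    """Gene x codon relative-adaptiveness matrix over the 59 degenerate codons.

    ``values`` holds NaN where a gene does not use the amino acid at all;
    ``imputed()`` fills those cells with the column mean (equivalently,
    they contribute nothing after centring). ``defined`` flags observed
    cells.
    """

    values: pd.DataFrame

    @property
    def defined(self) -> pd.DataFrame:
        return self.values.notna()

    def imputed(self) -> pd.DataFrame:
        filled = self.values.copy()
        means = filled.mean(axis=0)
        return filled.fillna(means.fillna(0.0))


def adaptiveness_matrix(
    genes: Sequence[CodonCountTable | CdsRecord],
    ids: Sequence[str] | None = None,
    columns: str = "all59",
) -> AdaptivenessMatrix:
    """Per-gene relative adaptiveness: RSCU / within-family max RSCU.

    Every represented family contributes at least one entry equal to 1.
    Genes with no degenerate codons are dropped with a warning.
    ``columns="drop-max"`` removes one codon per family (the one with the
    largest column mean), leaving 41 columns.
    """
    if len(genes) < 2:
        raise ValueError("need at least two genes")
    if ids is None:
        ids = [
            g.id if isinstance(g, CdsRecord) else f"g{i}"
            for i, g in enumerate(genes)
        ]
    rows, kept_ids = [], []
    for gid, g in zip(ids, genes):
        counts = g if isinstance(g, CodonCountTable) else count_codons(g)
        r = rscu(counts)[_SYN_RNA]
        if r.isna().all():
            warnings.warn(f"gene {gid}: no degenerate codons; row dropped")
            continue
        w = r.copy()
        for aa, cods in AA_TO_CODONS.items():
            if len(cods) < 2:
                continue
            fam = [to_rna(c) for c in cods]
            m = w[fam].max()
            if m > 0:
                w[fam] = w[fam] / m
        rows.append(w)
        kept_ids.append(gid)
    values = pd.DataFrame(rows, index=kept_ids)
    if columns == "drop-max":
        drop = []
        for aa, cods in AA_TO_CODONS.items():
            if len(cods) < 2:
                continue
            fam = [to_rna(c) for c in cods]
            drop.append(values[fam].mean().idxmax())
        values = values.drop(columns=drop)
    elif columns != "all59":
        raise ValueError(f"unknown column set {columns!r}")
    return AdaptivenessMatrix(values)


@dataclass
class PcaResult:
    """Scores, loadings and explained-variance fractions of a centred PCA."""

    scores: pd.DataFrame       # genes x components ("PC1", ...)
    loadings: pd.DataFrame     # original columns x components
    explained_fraction: np.ndarray
    column_means: pd.Series
    orientation: str = "svd"

    def reconstruct(self) -> pd.DataFrame:
        """scores @ loadings.T + column means (exact with all components)."""
        rec = self.scores.values @ self.loadings.values.T + self.column_means.values
        return pd.DataFrame(rec, index=self.scores.index, columns=self.loadings.index)


def pca(
    matrix: AdaptivenessMatrix | pd.DataFrame,
    n_components: int | None = None,
    gc3s: pd.Series | Sequence[float] | None = None,
) -> PcaResult:
    """Centred (covariance-basis) PCA with a fixed sign convention.

    If per-gene GC3s values are supplied, the first component's sign is
    chosen so that its correlation with GC3s is negative, matching the
    convention in which GC3-rich genes score negatively on PC1. Output is
    deterministic for a fixed input (full SVD solver).
    """
    X = matrix.imputed() if isinstance(matrix, AdaptivenessMatrix) else pd.DataFrame(matrix)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if float(X.var(axis=0, ddof=0).sum()) <= 1e-300:
        raise ValueError("no variance in input matrix")
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(X.values)
    loadings = model.components_.T.copy()
    orientation = "svd"
    if gc3s is not None:
        g = pd.Series(gc3s)
        if isinstance(gc3s, pd.Series):
            g = gc3s.reindex(X.index)
        gv = np.asarray(g, dtype=float)
        ok = ~np.isnan(gv)
        if ok.sum() >= 3 and np.std(scores[ok, 0]) > 0 and np.std(gv[ok]) > 0:
            r = np.corrcoef(scores[ok, 0], gv[ok])[0, 1]
            if r > 0:
                scores[:, 0] *= -1
                loadings[:, 0] *= -1
            orientation = "PC1 anti-correlated with GC3s"
    comp_names = [f"PC{i+1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=X.index, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=X.columns, columns=comp_names),
        explained_fraction=model.explained_variance_ratio_.copy(),
        column_means=pd.Series(model.mean_, index=X.columns),
        orientation=orientation,
    )


@dataclass
class ExpressionAxisTest:
    """z-score test labelling a component as the expression axis.

    Reference-gene scores are standardised against the all-gene mean and
    S.D. of the component; the axis is labelled "Expression" when the
    mean absolute z exceeds the threshold (default 5.17).
    """

    component: str
    z_scores: pd.Series
    mean_abs_z: float
    threshold: float
    labelled_expression: bool


def expression_axis_test(
    result: PcaResult,
    reference_ids: Iterable[str],
    component: str | int = "PC1",
    threshold: float = 5.17,
) -> ExpressionAxisTest:
    """Standardise reference-gene scores on one component and apply the test."""
    if isinstance(component, int):
        component = f"PC{component}"
    ref = list(reference_ids)
    missing = [r for r in ref if r not in result.scores.index]
    if missing:
        raise KeyError(f"reference ids missing from scores: {missing}")
    y = result.scores[component]
    z = (y[ref] - y.mean()) / y.std(ddof=0)
    mean_abs = float(z.abs().mean())
    return ExpressionAxisTest(
        component=component,
        z_scores=z,
        mean_abs_z=mean_abs,
        threshold=threshold,
        labelled_expression=mean_abs > threshold,
    )


def amino_acid_usage_matrix(
    records: Sequence[CdsRecord],
) -> pd.DataFrame:
    """Gene x 20 amino-acid frequency matrix (rows sum to 1)."""
    aas = sorted(AA_TO_CODONS)
    rows, ids = [], []
    for rec in records:
        prot = _protein(rec)
        if not prot:
            warnings.warn(f"gene {rec.id}: empty protein; row dropped")
            continue
        freqs = [prot.count(a) / len(prot) for a in aas]
        rows.append(freqs)
        ids.append(rec.id)
    return pd.DataFrame(rows, index=ids, columns=aas)


def correlate_indices(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] | None = None,
    method: str = "spearman",
) -> pd.DataFrame:
    """Pairwise correlations between index columns.

    Rank (Spearman) correlation by default, configurable to Pearson.
    NaN entries are handled pairwise-complete; pairs with fewer than three
    complete observations are returned as NaN and flagged.
    """
    numeric = table.select_dtypes(include=[np.number])
    if pairs is None:
        cols = list(numeric.columns)
        pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1 :]]
    func = {"spearman": stats.spearmanr, "pearson": stats.pearsonr}[method]
    rows = []
    for a, b in pairs:
        sub = numeric[[a, b]].dropna()
        if len(sub) < 3:
            rows.append((a, b, np.nan, np.nan, len(sub), method, False))
            continue
        r, p = func(sub[a], sub[b])
        rows.append((a, b, float(r), float(p), len(sub), method, True))
    return pd.DataFrame(
        rows, columns=["index_a", "index_b", "r", "p_value", "n", "method", "defined"]
    )
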