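"""Optimal-codon identification from expression-extreme gene pools.

Genes are ranked on PC1 of the adaptiveness PCA; the top/bottom fraction
(default 5%) form the high- and low-expression pools, the "high" pool
being the extreme closer to the reference (ribosomal) genes' mean score.
Pooled codon usage is compared per degenerate codon with a 2x2 chi-square
(codon vs other synonyms x high vs low pool) under Holm's sequential
Bonferroni correction; an optimal codon must be significant (P < alpha),
used at a higher within-family frequency in the high pool, and have
high-pool RSCU > 1.

The module also provides per-1000 codon frequency tables and the
cross-species frequency-ratio comparison (ratio > 2 or < 0.5 flags
divergent usage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from statsmodels.stats.multitest import multipletests

from .codon_metrics import CodonCountTable, rscu
from .genetics import (
    AA_TO_CODONS,
    CODON_INDEX,
    SENSE_CODONS,
    codon_gc_count,
    to_dna,
    to_rna,
)
from .multivariate import PcaResult

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


def extreme_pools(
    result: PcaResult,
    fraction: float = 0.05,
    reference_ids: Iterable[str] = (),
    component: str = "PC1",
) -> tuple[list[str], list[str]]:
    """Top and bottom ``fraction`` of genes on PC1 as (high_ids, low_ids).

    Pool size is floor(fraction * N); an empty pool is an error. Score
    ties break on gene ID. PCA signs being arbitrary, the "high"
    (expression) pool is the extreme whose mean score lies closer to the
    mean score of the reference genes.
    """
    scores = result.scores[component]
    n = len(scores)
    k = int(math.floor(fraction * n))
    if k < 1:
        raise ValueError(
            f"pool fraction {fraction} of {n} genes gives an empty pool"
        )
    order = sorted(scores.index, key=lambda g: (scores[g], g))
    bottom, top = order[:k], order[-k:]
    ref = [g for g in reference_ids if g in scores.index]
    if ref:
        ref_mean = float(scores[ref].mean())
        top_mean = float(scores[top].mean())
        bot_mean = float(scores[bottom].mean())
        if abs(ref_mean - bot_mean) < abs(ref_mean - top_mean):
            high, low = bottom, top
        else:
            high, low = top, bottom
    else:
        high, low = top, bottom
    return list(high), list(low)


@dataclass
class PoolComparison:
    """Per-codon comparison of the high- and low-expression pools."""

    table: pd.DataFrame  # indexed by RNA codon
    alpha: float

    def __getitem__(self, codon: str) -> pd.Series:
        return self.table.loc[to_rna(codon)]

    @property
    def optimal_codons(self) -> list[str]:
        return list(self.table.index[self.table["optimal"]])


def codon_test(
    high: CodonCountTable,
    low: CodonCountTable,
    alpha: float = 0.01,
    yates: bool = False,
) -> PoolComparison:
    """Chi-square test of every degenerate sense codon between the pools.

    Each codon is tested in a 2x2 table — this codon vs its other
    synonyms, high vs low pool — without continuity correction by default
    (pool counts are large). P-values are Holm-adjusted across all
    testable codons. Codons whose family is absent from either pool are
    marked untestable. Met and Trp are never tested.
    """
    high_rscu, low_rscu = rscu(high), rscu(low)
    rows = []
    for aa, cods in sorted(AA_TO_CODONS.items()):
        if len(cods) < 2:
            continue
        idx = [CODON_INDEX[c] for c in cods]
        th = int(high.counts[idx].sum())
        tl = int(low.counts[idx].sum())
        for c in cods:
            h, l = high[c], low[c]
            row = {
                "aa": _AA3[aa],
                "high_count": h,
                "low_count": l,
                "high_rscu": high_rscu[to_rna(c)],
                "low_rscu": low_rscu[to_rna(c)],
                "high_freq": h / th if th else math.nan,
                "low_freq": l / tl if tl else math.nan,
                "chi2": math.nan,
                "p_raw": math.nan,
                "testable": False,
            }
            # chi-square needs both pools to use the family and both
            # margins of the 2x2 table to be non-degenerate
            if th > 0 and tl > 0 and 0 < h + l < th + tl:
                chi2, p, _, _ = chi2_contingency(
                    [[h, th - h], [l, tl - l]], correction=yates
                )
                row.update(chi2=float(chi2), p_raw=float(p), testable=True)
            rows.append((to_rna(c), row))
    table = pd.DataFrame({k: v for k, v in rows}).T
    table = table.astype(
        {
            "high_count": int, "low_count": int, "high_rscu": float,
            "low_rscu": float, "high_freq": float, "low_freq": float,
            "chi2": float, "p_raw": float, "testable": bool,
        },
        errors="ignore",
    )
    table["p_adjusted"] = np.nan
    mask = table["testable"].astype(bool).values
    if mask.any():
        _, p_adj, _, _ = multipletests(
            table.loc[mask, "p_raw"].astype(float).values,
            alpha=alpha,
            method="holm",
        )
        table.loc[mask, "p_adjusted"] = p_adj
    table["optimal"] = (
        mask
        & (table["p_adjusted"].astype(float) < alpha)
        & (table["high_freq"].astype(float) > table["low_freq"].astype(float))
        & (table["high_rscu"].astype(float) > 1.0)
    )
    return PoolComparison(table=table, alpha=alpha)


@dataclass
class OptimalCodonReport:
    """The called optimal-codon set with its composition summary."""

    codons: frozenset[str]  # RNA alphabet
    gc_nucleotides: int
    au_nucleotides: int
    third_position_endings: dict[str, int]

    @property
    def n(self) -> int:
        return len(self.codons)


def optimal_set(comparison: PoolComparison) -> OptimalCodonReport:
    """Summarise the optimal codons: count, GC:AU tally, third-position bases."""
    codons = frozenset(comparison.optimal_codons)
    gc = sum(codon_gc_count(to_dna(c)) for c in codons)
    au = 3 * len(codons) - gc
    endings: dict[str, int] = {}
    for c in codons:
        endings[c[-1]] = endings.get(c[-1], 0) + 1
    return OptimalCodonReport(
        codons=codons,
        gc_nucleotides=gc,
        au_nucleotides=au,
        third_position_endings=endings,
    )


@dataclass
class FrequencyTable:
    """Codon usage of a species, per 1000 codons over the 61 sense codons."""

    label: str
    per_1000: pd.Series  # RNA-indexed

    def __getitem__(self, codon: str) -> float:
        return float(self.per_1000[to_rna(codon)])


def frequency_per_1000(
    counts: CodonCountTable, label: str = ""
) -> FrequencyTable:
    """1000 * N(c) / total sense codons, for every sense codon."""
    total = counts.n_codons
    if total == 0:
        raise ValueError("empty codon count table")
    freq = pd.Series(
        {to_rna(c): 1000.0 * counts[c] / total for c in SENSE_CODONS},
        name=label or "per_1000",
    )
    return FrequencyTable(label=label, per_1000=freq)


def read_frequency_table(path, label: str = "") -> FrequencyTable:
    """Read a TSV of (codon, frequency-per-1000) rows."""
    df = pd.read_csv(path, sep="\t", comment="#")
    codon_col, freq_col = df.columns[:2]
    freq = pd.Series(
        df[freq_col].astype(float).values,
        index=[to_rna(c) for c in df[codon_col]],
    )
    return FrequencyTable(label=label or str(path), per_1000=freq)


@dataclass
class SpeciesComparison:
    """Per-codon usage-frequency ratios between two species."""

    ratios: pd.Series
    divergent: pd.Series  # boolean per codon
    n_divergent: int
    labels: tuple[str, str]


def species_ratio_comparison(
    a: FrequencyTable, b: FrequencyTable
) -> SpeciesComparison:
    """Ratio a/b per codon; ratios > 2 or < 0.5 flag divergent usage.

    A codon used by ``a`` but absent from ``b`` has an undefined ratio and
    counts as divergent; a codon absent from both is left undefined but
    not counted (no evidence either way).
    """
    if set(a.per_1000.index) != set(b.per_1000.index):
        raise ValueError("frequency tables cover different codon sets")
    bv = b.per_1000.reindex(a.per_1000.index)
    ratios = a.per_1000 / bv.replace(0.0, np.nan)
    divergent = (ratios > 2.0) | (ratios < 0.5)
    divergent |= (bv == 0.0) & (a.per_1000 > 0.0)
    return SpeciesComparison(
        ratios=ratios,
        divergent=divergent,
        n_divergent=int(divergent.sum()),
        labels=(a.label, b.label),
    )
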