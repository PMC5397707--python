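"""Bundled codon-count tables from the *Taenia multiceps* transcriptome study.

Two published tables ship with the package so that the index and
optimal-codon machinery can be exercised on real counts without any
sequence download:

* genome-wide codon usage over the 59 degenerate sense codons of the
  8,620 analysed CDSs, with the published RSCU column;
* pooled codon counts of the 431-gene high- and low-expression pools
  (top/bottom 5% of the expression axis), with published RSCU values and
  the published optimal-codon calls.

Note: the published Phe row of the genome-wide table is internally
inconsistent (the printed counts 56781/56843 imply RSCU 1.00/1.00, not
0.97/1.03); the counts are shipped verbatim and the discrepancy is
documented here and in the tests.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .codon_metrics import CodonCountTable


def _read(name: str) -> pd.DataFrame:
    with resources.files("cubkit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def load_codon_usage() -> pd.DataFrame:
    """Genome-wide codon counts with the published RSCU column."""
    return _read("tmulticeps_codon_usage.tsv")


def load_expression_pools() -> pd.DataFrame:
    """High/low expression-pool codon counts with published RSCU and calls."""
    return _read("tmulticeps_expression_pools.tsv")


def codon_usage_counts() -> CodonCountTable:
    """Genome-wide counts as a :class:`CodonCountTable`."""
    df = load_codon_usage()
    return CodonCountTable.from_dict(dict(zip(df["codon"], df["count"])))


def pool_counts() -> tuple[CodonCountTable, CodonCountTable]:
    """(high, low) expression-pool counts as count tables."""
    df = load_expression_pools()
    high = CodonCountTable.from_dict(dict(zip(df["codon"], df["high_count"])))
    low = CodonCountTable.from_dict(dict(zip(df["codon"], df["low_count"])))
    return high, low
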