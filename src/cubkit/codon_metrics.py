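"""Codon counting and every per-gene codon-usage index.

Implements relative synonymous codon usage (RSCU), Wright's effective
number of codons (ENc), the Sharp-Li codon adaptation index (CAI),
positional GC statistics (GC, GC1, GC2, GC12, GC3, GC3s), silent base
composition (A3s/T3s/G3s/C3s), frequency of optimal codons (Fop), and the
protein-level GRAVY and aromaticity indices.

All synonymous-usage indices run over sense codons only; ATG (Met) and
TGG (Trp) are excluded wherever the index concerns synonymous choice.
Stop codons never contribute: the terminal stop is stripped on counting
and internal stops are removed upstream by QC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .genetics import (
    AA_TO_CODONS,
    CODON_INDEX,
    CODON_TO_AA,
    CODONS,
    DEGENERACY_CLASSES,
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYMOUS_CODONS,
    to_dna,
    to_rna,
)
from .sequence_io import CdsRecord

# ---------------------------------------------------------------------------
# precomputed masks over the fixed 64-codon order

_N = len(CODONS)
_SENSE = np.array([c not in STOP_CODONS for c in CODONS])
_SYN = np.array([c in SYNONYMOUS_CODONS for c in CODONS])
_GC_POS = [
    np.array([_SENSE[i] and CODONS[i][p] in "GC" for i in range(_N)])
    for p in range(3)
]
_ENDS = {b: np.array([_SENSE[i] and CODONS[i][2] == b for i in range(_N)]) for b in "ACGT"}

# families as index arrays, degenerate families only
_FAMILY_IDX: dict[str, np.ndarray] = {
    aa: np.array([CODON_INDEX[c] for c in cods])
    for aa, cods in AA_TO_CODONS.items()
}
_DEG_FAMILIES = {aa: idx for aa, idx in _FAMILY_IDX.items() if len(idx) >= 2}

# X3s denominators: synonymous codons whose family offers an X-ending synonym
_X3S_DENOM = {}
for _b in "ACGT":
    _has = {
        aa
        for aa, cods in AA_TO_CODONS.items()
        if len(cods) >= 2 and any(c[2] == _b for c in cods)
    }
    _X3S_DENOM[_b] = np.array(
        [_SYN[i] and CODON_TO_AA.get(CODONS[i]) in _has for i in range(_N)]
    )


class CodonCountTable:
    """A 64-cell codon count vector for one gene or a pooled gene set.

    Counts are stored in the fixed TCAG codon order; codons may be
    addressed in either the DNA or RNA alphabet. Tables add element-wise,
    so pooling genes is ``sum(tables, CodonCountTable())``.
    """

    __slots__ = ("counts",)

    def __init__(self, counts: np.ndarray | None = None):
        if counts is None:
            counts = np.zeros(_N, dtype=np.int64)
        counts = np.asarray(counts, dtype=np.int64)
        if counts.shape != (_N,) or (counts < 0).any():
            raise ValueError("counts must be 64 non-negative integers")
        self.counts = counts

    @classmethod
    def from_seq(cls, seq: str) -> "CodonCountTable":
        seq = to_dna(seq)
        if len(seq) % 3:
            raise ValueError("sequence length is not a multiple of 3")
        if len(seq) >= 3 and seq[-3:] in STOP_CODONS:
            seq = seq[:-3]
        counts = np.zeros(_N, dtype=np.int64)
        for i in range(0, len(seq), 3):
            counts[CODON_INDEX[seq[i : i + 3]]] += 1
        return cls(counts)

    @classmethod
    def from_dict(cls, mapping: Mapping[str, int]) -> "CodonCountTable":
        counts = np.zeros(_N, dtype=np.int64)
        for codon, n in mapping.items():
            counts[CODON_INDEX[to_dna(codon)]] += int(n)
        return cls(counts)

    def __getitem__(self, codon: str) -> int:
        return int(self.counts[CODON_INDEX[to_dna(codon)]])

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        return CodonCountTable(self.counts + other.counts)

    __radd__ = __add__

    def __eq__(self, other) -> bool:
        return isinstance(other, CodonCountTable) and bool(
            (self.counts == other.counts).all()
        )

    @property
    def n_codons(self) -> int:
        """Total sense codons (stop cells are not included)."""
        return int(self.counts[_SENSE].sum())

    def to_series(self) -> pd.Series:
        """Sense-codon counts indexed by RNA codon."""
        return pd.Series(
            {to_rna(c): int(self.counts[CODON_INDEX[c]]) for c in SENSE_CODONS},
            name="count",
        )


def count_codons(record: CdsRecord | str) -> CodonCountTable:
    """Count codons of a CDS; a terminal stop codon, if present, is stripped."""
    seq = record.seq if isinstance(record, CdsRecord) else record
    return CodonCountTable.from_seq(seq)


# ---------------------------------------------------------------------------
# RSCU and relative adaptiveness


def rscu(counts: CodonCountTable) -> pd.Series:
    """Relative synonymous codon usage per sense codon (RNA-indexed).

    RSCU(c) = deg(aa) * N(c) / sum over the synonymous family. Codons of
    amino acids absent from the gene are NaN (undefined, not zero);
    within any represented family the values sum to the degeneracy.
    """
    out = np.full(_N, np.nan)
    for aa, idx in _FAMILY_IDX.items():
        tot = counts.counts[idx].sum()
        if tot > 0:
            out[idx] = len(idx) * counts.counts[idx] / tot
    return pd.Series(
        {to_rna(c): out[CODON_INDEX[c]] for c in SENSE_CODONS}, name="RSCU"
    )


# ---------------------------------------------------------------------------
# positional GC statistics


class GcStats(NamedTuple):
    gc: float
    gc1: float
    gc2: float
    gc12: float
    gc3: float
    gc3s: float


def gc_position_stats(counts: CodonCountTable | CdsRecord | str) -> GcStats:
    """GC fractions over all positions and per codon position.

    GC1/GC2/GC3 run over all sense codons; GC3s over third positions of
    synonymous codons only (Met and Trp excluded). All values are NaN for
    an empty table.
    """
    if not isinstance(counts, CodonCountTable):
        counts = count_codons(counts)
    n = counts.n_codons
    if n == 0:
        return GcStats(*[math.nan] * 6)
    c = counts.counts
    gc_pos = [float(c[_GC_POS[p]].sum()) / n for p in range(3)]
    gc = sum(c[_GC_POS[p]].sum() for p in range(3)) / (3 * n)
    n_syn = c[_SYN].sum()
    gc3s = float(c[_SYN & (_GC_POS[2])].sum()) / n_syn if n_syn else math.nan
    return GcStats(
        gc=float(gc),
        gc1=gc_pos[0],
        gc2=gc_pos[1],
        gc12=(gc_pos[0] + gc_pos[1]) / 2.0,
        gc3=gc_pos[2],
        gc3s=gc3s,
    )


class SilentBaseComposition(NamedTuple):
    a3s: float
    t3s: float
    g3s: float
    c3s: float


def silent_base_composition(
    counts: CodonCountTable, method: str = "classic"
) -> SilentBaseComposition:
    """Silent base composition A3s, T3s, G3s, C3s.

    ``classic`` (default): X3s = synonymous codons ending in X divided by
    synonymous codons whose family contains an X-ending synonym — the
    definition used by classic codon-usage software, so that e.g. Lys/Gln/
    Glu codons (which cannot end in a pyrimidine) do not dilute T3s/C3s.
    ``simple``: plain share of X among synonymous third positions.
    Undefined (NaN) on an empty denominator.
    """
    vals = {}
    for b in "ATGC":
        num = counts.counts[_SYN & _ENDS[b]].sum()
        denom_mask = _X3S_DENOM[b] if method == "classic" else _SYN
        den = counts.counts[denom_mask].sum()
        vals[b] = float(num) / den if den else math.nan
    return SilentBaseComposition(vals["A"], vals["T"], vals["G"], vals["C"])


# ---------------------------------------------------------------------------
# effective number of codons (Wright)


def enc(counts: CodonCountTable) -> float:
    """Wright's effective number of codons.

    For each degenerate family with n >= 2 codons observed, the codon
    homozygosity is F = (n * sum p_i^2 - 1) / (n - 1); families with
    F <= 0 are not estimable. Class means F̄_k average F over k-fold
    families (k = 2, 3, 4, 6; Ile is the only 3-fold family) and

        ENc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6,

    capped at 61. A class with no estimable family borrows the mean of
    the estimable class means; NaN if fewer than two classes are
    estimable.
    """
    class_means: dict[int, float] = {}
    for k, aas in DEGENERACY_CLASSES.items():
        fs = []
        for aa in aas:
            fam = counts.counts[_DEG_FAMILIES[aa]]
            n = fam.sum()
            if n < 2:
                continue
            p = fam / n
            f = (n * float(np.square(p).sum()) - 1.0) / (n - 1.0)
            if f > 0:
                fs.append(f)
        if fs:
            class_means[k] = float(np.mean(fs))
    if len(class_means) < 2:
        return math.nan
    fallback = float(np.mean(list(class_means.values())))
    weights = {2: 9, 3: 1, 4: 5, 6: 3}
    total = 2.0
    for k, w in weights.items():
        total += w / class_means.get(k, fallback)
    return min(total, 61.0)


# ---------------------------------------------------------------------------
# CAI (Sharp & Li)


@dataclass(frozen=True)
class ReferenceWeights:
    """Relative adaptiveness w of each sense codon in a reference gene set.

    w(c) = RSCU(c) / max RSCU within the family, computed on the pooled
    reference counts; codons unobserved in the reference receive a
    pseudo-count (default 0.5) before RSCU so that w stays positive.
    """

    weights: pd.Series  # RNA-indexed, in (0, 1]
    reference_ids: tuple[str, ...] = ()
    pseudocount: float = 0.5

    def __getitem__(self, codon: str) -> float:
        return float(self.weights[to_rna(codon)])


def cai_weights(
    reference: Iterable[CdsRecord | CodonCountTable],
    pseudocount: float = 0.5,
) -> ReferenceWeights:
    """Pool a reference set (e.g. ribosomal-protein genes) into CAI weights."""
    pooled = np.zeros(_N, dtype=float)
    ids = []
    n_items = 0
    for item in reference:
        n_items += 1
        if isinstance(item, CdsRecord):
            ids.append(item.id)
            pooled += count_codons(item).counts
        else:
            pooled += item.counts
    if n_items == 0:
        raise ValueError("empty reference set")
    w = np.full(_N, np.nan)
    for aa, idx in _FAMILY_IDX.items():
        fam = pooled[idx].copy()
        fam[fam == 0] = pseudocount
        r = len(idx) * fam / fam.sum()
        w[idx] = r / r.max()
    series = pd.Series(
        {to_rna(c): w[CODON_INDEX[c]] for c in SENSE_CODONS}, name="w"
    )
    return ReferenceWeights(series, tuple(ids), pseudocount)


def cai(counts: CodonCountTable, weights: ReferenceWeights) -> float:
    """Codon adaptation index: geometric mean of w over the gene's codons.

    Met and Trp codons are excluded (their w is 1 by construction and
    carries no information about synonymous choice). NaN if the gene has
    no eligible codons.
    """
    w = np.array([weights.weights[to_rna(c)] for c in SYNONYMOUS_CODONS])
    n = np.array([counts.counts[CODON_INDEX[c]] for c in SYNONYMOUS_CODONS])
    total = n.sum()
    if total == 0:
        return math.nan
    return float(np.exp(np.dot(n, np.log(w)) / total))


# ---------------------------------------------------------------------------
# protein-level indices


def _protein(record: CdsRecord | str) -> str:
    seq = record.seq if isinstance(record, CdsRecord) else to_dna(record)
    if len(seq) >= 3 and len(seq) % 3 == 0 and seq[-3:] in STOP_CODONS:
        seq = seq[:-3]
    return str(Seq(seq).translate())


def gravy(record: CdsRecord | str) -> float:
    """Grand average of hydropathicity (Kyte-Doolittle) of the encoded protein."""
    prot = _protein(record)
    if not prot:
        return math.nan
    return ProteinAnalysis(prot).gravy()


def aromaticity(record: CdsRecord | str) -> float:
    """Frequency of aromatic residues (Phe, Tyr, Trp) in the encoded protein."""
    prot = _protein(record)
    if not prot:
        return math.nan
    return ProteinAnalysis(prot).aromaticity()


def fop(counts: CodonCountTable, optimal_set: Iterable[str]) -> float:
    """Frequency of optimal codons among synonymous codons of the gene."""
    optimal = {to_dna(c) for c in optimal_set}
    if not optimal:
        raise ValueError("empty optimal codon set")
    denom = counts.counts[_SYN].sum()
    if denom == 0:
        return math.nan
    num = sum(counts.counts[CODON_INDEX[c]] for c in optimal if c in CODON_INDEX)
    return float(num) / float(denom)
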