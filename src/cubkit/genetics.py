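"""Standard genetic code tables and codon bookkeeping shared by all modules.

Sequences are handled as DNA internally; codons are displayed in the RNA
alphabet (U for T) in all user-facing tables, following the convention of
codon-usage software. The standard nuclear code (NCBI table 1) is the
default and currently the only supported code.
"""

from __future__ import annotations

from itertools import product

from Bio.Data import CodonTable
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

# Fixed codon order: TCAG x TCAG x TCAG, the classic codon-table layout.
_BASES = "TCAG"
CODONS: tuple[str, ...] = tuple("".join(p) for p in product(_BASES, repeat=3))
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)  # sense codons only

SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _c in CODONS:
    if _c in STOP_CODONS:
        continue
    AA_TO_CODONS.setdefault(CODON_TO_AA[_c], ())
for _aa in AA_TO_CODONS:
    AA_TO_CODONS[_aa] = tuple(c for c in CODONS if CODON_TO_AA.get(c) == _aa)

DEGENERACY: dict[str, int] = {
    c: len(AA_TO_CODONS[CODON_TO_AA[c]]) for c in SENSE_CODONS
}

#: The 59 sense codons belonging to degenerate (>= 2-fold) families;
#: ATG (Met) and TGG (Trp) are excluded from every synonymous-usage index.
SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if DEGENERACY[c] >= 2
)

#: Degenerate amino acids grouped by family size: 9 two-fold, Ile the sole
#: three-fold, 5 four-fold and 3 six-fold (Leu, Ser, Arg kept whole).
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _cods in AA_TO_CODONS.items():
    if len(_cods) >= 2:
        DEGENERACY_CLASSES.setdefault(len(_cods), ())
for _aa, _cods in sorted(AA_TO_CODONS.items()):
    if len(_cods) >= 2:
        k = len(_cods)
        DEGENERACY_CLASSES[k] = DEGENERACY_CLASSES[k] + (_aa,)

# Parity-rule-2 analysis is restricted to the eight four-codon blocks:
# the five true four-fold families plus the four-codon halves of the
# six-fold families (Leu -> CTN, Ser -> TCN, Arg -> CGN).
PR2_FAMILIES: dict[str, tuple[str, ...]] = {
    "A": AA_TO_CODONS["A"],
    "G": AA_TO_CODONS["G"],
    "P": AA_TO_CODONS["P"],
    "T": AA_TO_CODONS["T"],
    "V": AA_TO_CODONS["V"],
    "L": tuple(c for c in AA_TO_CODONS["L"] if c.startswith("CT")),
    "S": tuple(c for c in AA_TO_CODONS["S"] if c.startswith("TC")),
    "R": tuple(c for c in AA_TO_CODONS["R"] if c.startswith("CG")),
}
PR2_CODONS: frozenset[str] = frozenset(
    c for cods in PR2_FAMILIES.values() for c in cods
)

AROMATIC_AAS = frozenset("FYW")
GC_BASES = frozenset("GC")


def to_rna(codon: str) -> str:
    """Display form of a codon (T -> U)."""
    return codon.upper().replace("T", "U")


def to_dna(codon: str) -> str:
    """Internal form of a codon (U -> T)."""
    return codon.upper().replace("U", "T")


def codon_gc_count(codon: str) -> int:
    return sum(b in GC_BASES for b in codon)
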