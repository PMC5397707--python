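"""Reading, validation and filtering of coding sequences; tabular output.

The QC model: a coding sequence enters the analysis only if, after optional
removal of its terminal stop codon, it is longer than ``min_length_nt - 1``
nucleotides (default: > 450 bp, i.e. > 150 codons), contains no ambiguity
characters, is an exact multiple of three, and carries no internal stop
codon. Every rejected record is counted under exactly the first rule it
fails, in the fixed order length -> ambiguity -> frame -> internal stop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

from .genetics import STOP_CODONS

_VALID_BASES = frozenset("ACGT")

#: Fixed column order of the per-gene index table.
INDEX_COLUMNS = (
    "id", "length_codons", "GC", "GC1", "GC2", "GC12", "GC3", "GC3s",
    "A3s", "T3s", "G3s", "C3s", "ENc", "CAI", "Fop", "GRAVY", "Aromo",
    "PC1", "PC2", "flags",
)


@dataclass(frozen=True)
class CdsRecord:
    """One coding sequence with its identifier and annotation flags.

    ``flags`` is a subset of {"ribosomal", "essential", "reference"};
    ribosomal genes are also flagged "reference" because they form the
    highly-expressed reference set for CAI.
    """

    id: str
    seq: str
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        object.__setattr__(self, "seq", self.seq.upper().replace("U", "T"))

    @property
    def length_nt(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class FilterConfig:
    """QC thresholds; defaults implement the > 450 bp inclusion rule."""

    min_length_nt: int = 451
    drop_ambiguous: bool = True
    drop_internal_stop: bool = True
    strip_terminal_stop: bool = True
    genetic_code: int = 1

    def __post_init__(self) -> None:
        if self.min_length_nt < 3:
            raise ValueError("min_length_nt must be >= 3")
        if self.genetic_code != 1:
            raise NotImplementedError("only the standard nuclear code is supported")


@dataclass
class QcReport:
    """Per-rule rejection counts; a partition of the dropped records."""

    n_in: int = 0
    n_kept: int = 0
    too_short: int = 0
    ambiguous: int = 0
    frame: int = 0
    internal_stop: int = 0
    excluded: int = 0

    @property
    def n_dropped(self) -> int:
        return self.too_short + self.ambiguous + self.frame + self.internal_stop + self.excluded


def _read_id_list(path: str | Path) -> set[str]:
    ids: set[str] = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            ids.add(line)
    return ids


def read_cds_fasta(
    path: str | Path,
    ribosomal_ids: str | Path | Iterable[str] | None = None,
    essential_ids: str | Path | Iterable[str] | None = None,
) -> list[CdsRecord]:
    """Read a multi-FASTA of coding sequences, preserving input order.

    ``ribosomal_ids`` / ``essential_ids`` may be paths to one-ID-per-line
    list files ("#" comments allowed) or iterables of IDs. Ribosomal genes
    additionally receive the "reference" flag. U is normalised to T and
    case is folded. Duplicate IDs and malformed FASTA raise ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    def as_set(x) -> set[str]:
        if x is None:
            return set()
        if isinstance(x, (str, Path)):
            return _read_id_list(x)
        return set(x)

    ribo, ess = as_set(ribosomal_ids), as_set(essential_ids)

    with path.open() as fh:
        first = fh.read(1)
        if first and first != ">":
            raise ValueError(f"malformed FASTA {path}: does not start with '>'")

    records: list[CdsRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise ValueError(f"malformed FASTA {path}: entry with empty header")
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        flags = set()
        if rec.id in ribo:
            flags |= {"ribosomal", "reference"}
        if rec.id in ess:
            flags.add("essential")
        records.append(CdsRecord(rec.id, str(rec.seq), frozenset(flags)))
    return records


def _strip_terminal_stop(seq: str) -> str:
    if len(seq) >= 3 and len(seq) % 3 == 0 and seq[-3:] in STOP_CODONS:
        return seq[:-3]
    return seq


def qc_filter(
    records: Sequence[CdsRecord],
    cfg: FilterConfig = FilterConfig(),
    exclude_ids: Iterable[str] | None = None,
) -> tuple[list[CdsRecord], QcReport]:
    """Apply QC to ``records``; return kept records and a rejection report.

    ``exclude_ids`` implements list-based exclusion (e.g. mitochondrial
    genes); excluded records are counted separately. The operation is
    idempotent: kept records pass unchanged on a second run. Raises if no
    sequence survives.
    """
    exclude = set(exclude_ids or ())
    report = QcReport(n_in=len(records))
    kept: list[CdsRecord] = []
    for rec in records:
        if rec.id in exclude:
            report.excluded += 1
            continue
        seq = _strip_terminal_stop(rec.seq) if cfg.strip_terminal_stop else rec.seq
        if len(seq) < cfg.min_length_nt:
            report.too_short += 1
            continue
        if cfg.drop_ambiguous and not set(seq) <= _VALID_BASES:
            report.ambiguous += 1
            continue
        if len(seq) % 3 != 0:
            report.frame += 1
            continue
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if cfg.drop_internal_stop and any(c in STOP_CODONS for c in codons):
            report.internal_stop += 1
            continue
        kept.append(replace(rec, seq=seq) if seq != rec.seq else rec)
    report.n_kept = len(kept)
    if not kept:
        raise ValueError("no sequences survived QC")
    return kept, report


def write_index_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-gene index table as TSV in the fixed column order.

    Floats are written at 6 decimals so that read(write(x)) round-trips
    at that precision. An empty table is an error.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty index table")
    out = table.copy()
    if "flags" in out.columns:
        out["flags"] = out["flags"].map(
            lambda f: ";".join(sorted(f)) if isinstance(f, (set, frozenset)) else (f or "")
        )
    cols = [c for c in INDEX_COLUMNS if c in out.columns]
    cols += [c for c in out.columns if c not in cols]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_index_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_index_table`."""
    df = pd.read_csv(path, sep="\t")
    if "flags" in df.columns:
        df["flags"] = df["flags"].map(
            lambda s: frozenset(s.split(";")) if isinstance(s, str) and s else frozenset()
        )
    return df
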