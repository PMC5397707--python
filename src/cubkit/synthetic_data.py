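"""Synthetic coding sequences with known ground truth.

The generator emulates the statistical structures the codon-usage
analysis is designed to detect, so that the whole pipeline is testable
without any download:

``mutation_only``
    Amino acids are drawn from a fixed average composition; the
    synonymous codon is chosen by sampling the third-position base with
    G+C probability ``gc3_target`` (uniform within the G/C and within the
    A/T alternatives of the family). Genes then scatter on Wright's
    ENc-GC3s null curve.

``selection``
    On top of the mutation draw, each gene g replaces the mutation draw
    by its family's preferred codon with probability
    p_g = min(1, selection_strength * expression_g), a Bulmer-style
    mixture: no selection at strength 0, a usage gradient across the
    expression range, preferred-codon fixation for the most highly
    expressed genes. Expression is log-normal.

``neutrality_coupled``
    Per-gene GC3 is Uniform(0.25, 0.75) and the amino-acid composition is
    interpolated between an AT-rich and a GC-rich pool so that the
    expected GC12 equals intercept_a + slope_b * GC3 + noise, giving a
    neutrality plot with a known slope.

Every generated CDS starts with ATG, ends with a single terminal stop,
and passes sequence QC by construction. The seed fully determines the
output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetics import AA_TO_CODONS, GC_BASES
from .sequence_io import CdsRecord

#: Average amino-acid composition of proteins (Swiss-Prot-like frequencies).
DEFAULT_AA_COMPOSITION: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}
_TOTAL = sum(DEFAULT_AA_COMPOSITION.values())
DEFAULT_AA_COMPOSITION = {k: v / _TOTAL for k, v in DEFAULT_AA_COMPOSITION.items()}


def default_preferred_codons() -> dict[str, str]:
    """One designated preferred codon per degenerate family.

    The C-ending synonym where one exists, else the G-ending one —
    mirroring the empirical tendency of optimal codons to end in G/C.
    """
    preferred = {}
    for aa, cods in AA_TO_CODONS.items():
        if len(cods) < 2:
            continue
        c_end = [c for c in cods if c[2] == "C"]
        g_end = [c for c in cods if c[2] == "G"]
        preferred[aa] = (c_end or g_end)[0]
    return preferred


# per-family split into G/C-ending and A/T-ending synonyms
_GC_SET = {
    aa: [c for c in cods if c[2] in "GC"] for aa, cods in AA_TO_CODONS.items()
}
_AT_SET = {
    aa: [c for c in cods if c[2] in "AT"] for aa, cods in AA_TO_CODONS.items()
}


def _gc12(codon: str) -> float:
    return (float(codon[0] in GC_BASES) + float(codon[1] in GC_BASES)) / 2.0


def _expected_gc12(comp: Mapping[str, float], g3: float) -> float:
    """Expected GC12 of a gene with composition ``comp`` under the mutation draw."""
    total = 0.0
    for aa, w in comp.items():
        gc_set, at_set = _GC_SET[aa], _AT_SET[aa]
        if gc_set and at_set:
            e = g3 * np.mean([_gc12(c) for c in gc_set]) + (1 - g3) * np.mean(
                [_gc12(c) for c in at_set]
            )
        else:
            e = np.mean([_gc12(c) for c in (gc_set or at_set)])
        total += w * e
    return total


# AT-rich / GC-rich amino-acid pools for the neutrality regime: the default
# composition reweighted away from / toward amino acids whose first two
# codon positions are GC.
def _polarised_compositions() -> tuple[dict[str, float], dict[str, float]]:
    base = DEFAULT_AA_COMPOSITION
    g = {aa: _expected_gc12(({aa: 1.0}), 0.5) for aa in base}
    low = {aa: base[aa] * (1.0 - g[aa]) for aa in base}
    high = {aa: base[aa] * g[aa] for aa in base}
    lo_t, hi_t = sum(low.values()), sum(high.values())
    return (
        {aa: v / lo_t for aa, v in low.items()},
        {aa: v / hi_t for aa, v in high.items()},
    )


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated CDS set; the seed determines everything.

    Lengths are in codons (normal, clipped at ``length_min``; the default
    minimum of 151 sense codons keeps every gene strictly above the
    450-bp QC threshold).
    ``gc3_target`` is a fraction or a (low, high) uniform range per gene.
    """

    n_genes: int = 500
    length_mean: float = 320.0
    length_sd: float = 100.0
    length_min: int = 151
    gc3_target: float | tuple[float, float] = (0.3, 0.7)
    regime: str = "mutation_only"
    selection_strength: float = 0.0
    expression_sdlog: float = 1.5
    preferred_codons: Mapping[str, str] | None = None
    slope_b: float = 0.11
    intercept_a: float = 0.425
    gc12_noise_sd: float = 0.03
    n_reference: int = 15
    seed: int = 0

    REGIMES = ("mutation_only", "selection", "neutrality_coupled")

    def __post_init__(self) -> None:
        if self.regime not in self.REGIMES:
            raise ValueError(
                f"unknown regime {self.regime!r}; valid: {', '.join(self.REGIMES)}"
            )
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if self.length_min < 151:
            raise ValueError(
                "length_min must be >= 151 codons (450-bp QC threshold)"
            )

    @classmethod
    def mutation_only(cls, n_genes: int = 2000, seed: int = 0, **kw) -> "SimConfig":
        """Pure compositional regime: the ENc-plot null condition."""
        return cls(n_genes=n_genes, seed=seed, regime="mutation_only", **kw)

    @classmethod
    def selection(
        cls,
        n_genes: int = 2000,
        seed: int = 0,
        selection_strength: float = 0.015,
        **kw,
    ) -> "SimConfig":
        """Translational-selection regime at a fixed GC3 (default 0.5)."""
        kw.setdefault("gc3_target", 0.5)
        return cls(
            n_genes=n_genes,
            seed=seed,
            regime="selection",
            selection_strength=selection_strength,
            **kw,
        )

    @classmethod
    def neutrality_coupled(
        cls, n_genes: int = 2000, seed: int = 0, **kw
    ) -> "SimConfig":
        """GC12 linearly coupled to GC3 with known slope and intercept."""
        return cls(n_genes=n_genes, seed=seed, regime="neutrality_coupled", **kw)


@dataclass
class SimResult:
    """Generated records plus the ground truth needed to score recovery."""

    records: list[CdsRecord]
    truth: pd.DataFrame
    reference_ids: list[str]
    preferred_codons: dict[str, str]
    config: SimConfig

    def to_fasta(self) -> str:
        lines = []
        for rec in self.records:
            lines.append(f">{rec.id}")
            for i in range(0, len(rec.seq), 70):
                lines.append(rec.seq[i : i + 70])
        return "\n".join(lines) + "\n"

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "simulated_cds.fasta",
            "truth": outdir / "truth.tsv",
            "reference_ids": outdir / "reference_ids.txt",
        }
        paths["fasta"].write_text(self.to_fasta())
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        paths["reference_ids"].write_text(
            "\n".join(self.reference_ids) + "\n"
        )
        return paths


def simulate(cfg: SimConfig) -> SimResult:
    """Generate a CDS set under ``cfg``; deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    lengths = np.clip(
        np.rint(rng.normal(cfg.length_mean, cfg.length_sd, n)),
        cfg.length_min,
        None,
    ).astype(int)
    expression = rng.lognormal(mean=0.0, sigma=cfg.expression_sdlog, size=n)

    if cfg.regime == "neutrality_coupled":
        g3 = rng.uniform(0.25, 0.75, n)
    elif isinstance(cfg.gc3_target, tuple):
        lo, hi = cfg.gc3_target
        g3 = rng.uniform(lo, hi, n)
    else:
        g3 = np.full(n, float(cfg.gc3_target))

    if cfg.regime == "selection":
        p_pref = np.minimum(1.0, cfg.selection_strength * expression)
    else:
        p_pref = np.zeros(n)

    preferred = dict(cfg.preferred_codons or default_preferred_codons())

    comp_low, comp_high = (
        _polarised_compositions() if cfg.regime == "neutrality_coupled" else (None, None)
    )
    gc12_target = np.full(n, np.nan)
    if cfg.regime == "neutrality_coupled":
        gc12_target = (
            cfg.intercept_a
            + cfg.slope_b * g3
            + rng.normal(0.0, cfg.gc12_noise_sd, n)
        )

    aas = sorted(DEFAULT_AA_COMPOSITION)
    base_probs = np.array([DEFAULT_AA_COMPOSITION[a] for a in aas])
    records: list[CdsRecord] = []
    lam = np.full(n, np.nan)
    for i in range(n):
        if cfg.regime == "neutrality_coupled":
            e_low = _expected_gc12(comp_low, g3[i])
            e_high = _expected_gc12(comp_high, g3[i])
            li = (gc12_target[i] - e_low) / (e_high - e_low)
            if not 0.0 <= li <= 1.0:
                raise ValueError(
                    "unsatisfiable neutrality coupling: target GC12 "
                    f"{gc12_target[i]:.3f} outside achievable "
                    f"[{e_low:.3f}, {e_high:.3f}]"
                )
            lam[i] = li
            probs = np.array(
                [(1 - li) * comp_low[a] + li * comp_high[a] for a in aas]
            )
        else:
            probs = base_probs
        L = lengths[i]
        aa_idx = rng.choice(len(aas), size=L - 1, p=probs)
        codons = np.empty(L - 1, dtype="<U3")
        for j, aa in enumerate(aas):
            pos = np.nonzero(aa_idx == j)[0]
            if pos.size == 0:
                continue
            gc_set, at_set = _GC_SET[aa], _AT_SET[aa]
            if not gc_set or not at_set:
                codons[pos] = (gc_set or at_set)[0]
            else:
                use_gc = rng.random(pos.size) < g3[i]
                pick = np.where(
                    use_gc,
                    np.array(gc_set)[rng.integers(0, len(gc_set), pos.size)],
                    np.array(at_set)[rng.integers(0, len(at_set), pos.size)],
                )
                codons[pos] = pick
            if p_pref[i] > 0 and aa in preferred:
                sel = rng.random(pos.size) < p_pref[i]
                codons[pos[sel]] = preferred[aa]
        seq = "ATG" + "".join(codons) + "TAA"
        records.append(CdsRecord(id=f"sim{i:05d}", seq=seq))

    ref_order = np.argsort(expression)[::-1][: cfg.n_reference]
    reference_ids = [records[i].id for i in sorted(ref_order)]
    ref_set = set(reference_ids)
    records = [
        replace(r, flags=frozenset({"ribosomal", "reference"}))
        if r.id in ref_set
        else r
        for r in records
    ]

    truth = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "length_codons": lengths,
            "expression": expression,
            "gc3_drawn": g3,
            "p_preferred": p_pref,
            "gc12_target": gc12_target,
            "aa_mix_lambda": lam,
            "is_reference": [r.id in ref_set for r in records],
        }
    )
    return SimResult(
        records=records,
        truth=truth,
        reference_ids=reference_ids,
        preferred_codons=preferred,
        config=cfg,
    )


def recovery_report(
    index_table: pd.DataFrame,
    truth: pd.DataFrame,
    optimal_codons: Sequence[str] | None = None,
    neutrality_slope: float | None = None,
    preferred: Mapping[str, str] | None = None,
    config: SimConfig | None = None,
    rel_dev: pd.Series | None = None,
) -> dict[str, float]:
    """Score pipeline outputs against the generator's ground truth.

    Reports the neutrality-slope error, the fraction of designated
    preferred codons recovered in the called optimal set, the rank
    correlation between CAI and true expression, and the mean relative
    ENc deviation. Raises on gene-ID mismatch.
    """
    from .genetics import to_rna  # local import to keep module deps light

    tab = index_table.set_index("id") if "id" in index_table.columns else index_table
    tru = truth.set_index("id") if "id" in truth.columns else truth
    common = tab.index.intersection(tru.index)
    if len(common) == 0:
        raise ValueError("no shared gene ids between index table and truth")
    report: dict[str, float] = {"n_genes": float(len(common))}
    if "CAI" in tab.columns:
        rho, _ = stats.spearmanr(
            tab.loc[common, "CAI"], tru.loc[common, "expression"]
        )
        report["cai_expression_rho"] = float(rho)
    if neutrality_slope is not None and config is not None:
        report["neutrality_slope"] = float(neutrality_slope)
        report["neutrality_slope_error"] = abs(neutrality_slope - config.slope_b)
    if optimal_codons is not None:
        pref = dict(preferred or (config.preferred_codons if config else None) or default_preferred_codons())
        pref_rna = {to_rna(c) for c in pref.values()}
        called = {to_rna(c) for c in optimal_codons}
        report["preferred_codons_total"] = float(len(pref_rna))
        report["preferred_codons_recovered"] = float(len(pref_rna & called))
    if rel_dev is not None:
        report["mean_rel_dev"] = float(np.nanmean(np.asarray(rel_dev, dtype=float)))
    return report
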