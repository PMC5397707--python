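import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubkit.codon_metrics import (
    CodonCountTable,
    aromaticity,
    cai,
    cai_weights,
    count_codons,
    enc,
    fop,
    gc_position_stats,
    gravy,
    rscu,
    silent_base_composition,
)
from cubkit.genetics import (
    AA_TO_CODONS,
    CODON_INDEX,
    CODONS,
    STOP_CODONS,
    SYNONYMOUS_CODONS,
    to_rna,
)

# -- independent oracles -----------------------------------------------------

TWOFOLD = ["F", "Y", "H", "Q", "N", "K", "D", "E", "C"]
FOURFOLD = ["V", "P", "T", "A", "G"]
SIXFOLD = ["L", "S", "R"]


def enc_oracle(table: CodonCountTable) -> float:
    """Textbook ENc, written independently: explicit family lists, plain sums."""

    def family_f(aa):
        ns = [table[c] for c in AA_TO_CODONS[aa]]
        n = sum(ns)
        if n < 2:
            return None
        f = (n * sum((x / n) ** 2 for x in ns) - 1) / (n - 1)
        return f if f > 0 else None

    means = {}
    for k, fams in [(2, TWOFOLD), (3, ["I"]), (4, FOURFOLD), (6, SIXFOLD)]:
        fs = [f for f in (family_f(a) for a in fams) if f is not None]
        if fs:
            means[k] = sum(fs) / len(fs)
    if len(means) < 2:
        return math.nan
    fallback = sum(means.values()) / len(means)
    total = 2.0
    for k, w in [(2, 9), (3, 1), (4, 5), (6, 3)]:
        total += w / means.get(k, fallback)
    return min(total, 61.0)


def gc_oracle(seq: str):
    """Per-character tally of GC at each codon position."""
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    codons = [c for c in codons if c not in STOP_CODONS]
    per_pos = [
        sum(c[p] in "GC" for c in codons) / len(codons) for p in range(3)
    ]
    syn = [c for c in codons if c in SYNONYMOUS_CODONS]
    gc3s = sum(c[2] in "GC" for c in syn) / len(syn)
    return per_pos, sum(per_pos) / 3, gc3s


def x3s_oracle(table: CodonCountTable, base: str):
    """Direct enumeration over families for one silent base."""
    num = den = 0
    for aa, cods in AA_TO_CODONS.items():
        if len(cods) < 2:
            continue
        if not any(c[2] == base for c in cods):
            continue
        den += sum(table[c] for c in cods)
        num += sum(table[c] for c in cods if c[2] == base)
    return num / den if den else math.nan


counts_vectors = st.lists(
    st.integers(min_value=0, max_value=60), min_size=64, max_size=64
).map(
    lambda v: CodonCountTable(
        np.array([0 if CODONS[i] in STOP_CODONS else v[i] for i in range(64)])
    )
)

# -- counting ----------------------------------------------------------------


class TestCountCodons:
    def test_simple_counts(self):
        t = count_codons("ATGGCC")
        assert t["AUG"] == 1 and t["GCC"] == 1 and t.n_codons == 2

    def test_terminal_stop_stripped(self):
        assert count_codons("ATGGCCTAA") == count_codons("ATGGCC")

    def test_pooling_is_elementwise_addition(self):
        genes = ["ATGGCCGCC", "ATGAAAGCC", "GCCTTTTAA"]
        pooled = sum((count_codons(g) for g in genes), CodonCountTable())
        concat = count_codons("".join(g[:-3] if g.endswith("TAA") else g for g in genes))
        assert pooled == concat


# -- RSCU --------------------------------------------------------------------


class TestRscu:
    def test_equal_family_counts_give_unity(self):
        t = CodonCountTable.from_dict({"GCU": 5, "GCC": 5, "GCA": 5, "GCG": 5})
        r = rscu(t)
        assert all(r[to_rna(c)] == pytest.approx(1.0) for c in AA_TO_CODONS["A"])

    def test_absent_family_is_undefined_not_zero(self):
        t = CodonCountTable.from_dict({"GCU": 3})
        r = rscu(t)
        assert math.isnan(r["UUU"])
        assert r["GCU"] == pytest.approx(4.0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(counts_vectors)
    def test_family_sums_equal_degeneracy(self, table):
        r = rscu(table)
        for aa, cods in AA_TO_CODONS.items():
            vals = [r[to_rna(c)] for c in cods]
            if sum(table[c] for c in cods) > 0:
                assert sum(vals) == pytest.approx(len(cods))
                if len(cods) == 1:
                    assert vals[0] == pytest.approx(1.0)
            else:
                assert all(math.isnan(v) for v in vals)


# -- positional GC and silent bases -----------------------------------------


class TestGcStats:
    def test_hand_counted_dipeptide(self):
        g = gc_position_stats(count_codons("ATGGCC"))
        assert (g.gc1, g.gc2, g.gc3) == (0.5, 0.5, 1.0)
        assert g.gc3s == 1.0  # only GCC is synonymous

    def test_all_gcg_gene(self):
        g = gc_position_stats(count_codons("GCG" * 10))
        assert g.gc == 1.0 and g.gc3s == 1.0

    def test_gc12_is_mean_of_gc1_gc2(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice([c for c in CODONS if c not in STOP_CODONS], 30))
        g = gc_position_stats(count_codons(seq))
        assert g.gc12 == pytest.approx((g.gc1 + g.gc2) / 2)

    def test_matches_character_tally_oracle(self):
        rng = np.random.default_rng(42)
        sense = [c for c in CODONS if c not in STOP_CODONS]
        for _ in range(5):
            seq = "".join(rng.choice(sense, 30))
            g = gc_position_stats(count_codons(seq))
            per_pos, gc, gc3s = gc_oracle(seq)
            assert (g.gc1, g.gc2, g.gc3) == pytest.approx(tuple(per_pos))
            assert g.gc == pytest.approx(gc)
            assert g.gc3s == pytest.approx(gc3s)


class TestSilentBaseComposition:
    def test_two_codon_gene(self):
        t = CodonCountTable.from_dict({"GCU": 4, "GCC": 4})
        sb = silent_base_composition(t)
        assert (sb.t3s, sb.c3s) == (0.5, 0.5)
        assert (sb.a3s, sb.g3s) == (0.0, 0.0)

    def test_met_trp_only_is_undefined(self):
        t = CodonCountTable.from_dict({"AUG": 5, "UGG": 5})
        sb = silent_base_composition(t)
        assert all(math.isnan(v) for v in sb)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(counts_vectors)
    def test_matches_family_enumeration_oracle(self, table):
        sb = silent_base_composition(table)
        for got, base in zip([sb.a3s, sb.t3s, sb.g3s, sb.c3s], "ATGC"):
            want = x3s_oracle(table, base)
            assert (math.isnan(got) and math.isnan(want)) or got == pytest.approx(want)


# -- ENc ---------------------------------------------------------------------


class TestEnc:
    def test_single_codon_per_family_gives_20(self):
        t = CodonCountTable.from_dict(
            {cods[0]: 10 for cods in AA_TO_CODONS.values()}
        )
        assert enc(t) == pytest.approx(20.0)

    def test_uniform_usage_capped_at_61(self):
        t = CodonCountTable.from_dict(
            {c: 1000 for cods in AA_TO_CODONS.values() for c in cods}
        )
        assert enc(t) == pytest.approx(61.0)

    def test_two_codon_family_symmetric_in_p(self):
        a = CodonCountTable.from_dict({"UUU": 30, "UUC": 10, "GCU": 20, "GCC": 20})
        b = CodonCountTable.from_dict({"UUU": 10, "UUC": 30, "GCU": 20, "GCC": 20})
        assert enc(a) == pytest.approx(enc(b))

    def test_range_and_agreement_with_independent_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            vec = rng.integers(0, 30, 64)
            vec[[CODON_INDEX[c] for c in STOP_CODONS]] = 0
            t = CodonCountTable(vec)
            got, want = enc(t), enc_oracle(t)
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-9)
                assert 20.0 <= got <= 61.0 or got == pytest.approx(20.0)

    def test_undefined_when_too_few_classes(self):
        assert math.isnan(enc(CodonCountTable.from_dict({"AUG": 3})))


# -- CAI ---------------------------------------------------------------------


class TestCai:
    def test_uniform_reference_gives_unit_weights(self):
        ref = CodonCountTable.from_dict(
            {c: 10 for cods in AA_TO_CODONS.values() for c in cods}
        )
        w = cai_weights([ref])
        assert np.allclose(w.weights.values, 1.0)

    def test_phe_pool_hand_calculation(self):
        ref = CodonCountTable.from_dict({"UUU": 10, "UUC": 30})
        w = cai_weights([ref])
        assert w["UUC"] == pytest.approx(1.0)
        assert w["UUU"] == pytest.approx(1 / 3)

    def test_absent_codon_gets_positive_pseudocount_weight(self):
        ref = CodonCountTable.from_dict({"UUU": 10})
        w = cai_weights([ref])
        assert 0 < w["UUC"] < 1
        assert w["UUC"] == pytest.approx(0.5 / 10)  # RSCU ratio = 0.5/10

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            cai_weights([])

    def test_geometric_mean_hand_case(self):
        ref = CodonCountTable.from_dict({"UUU": 10, "UUC": 30, "AAA": 10, "AAG": 30})
        w = cai_weights([ref])
        gene = CodonCountTable.from_dict({"UUU": 1, "AAG": 1})
        assert cai(gene, w) == pytest.approx(math.sqrt(1 / 3))

    def test_all_preferred_codons_give_cai_of_one(self):
        ref = CodonCountTable.from_dict({"UUU": 10, "UUC": 30})
        w = cai_weights([ref])
        gene = CodonCountTable.from_dict({"UUC": 17})
        assert cai(gene, w) == pytest.approx(1.0)

    def test_order_invariance_and_monotone_swap(self):
        ref = CodonCountTable.from_dict(
            {"GCU": 40, "GCC": 10, "GCA": 5, "GCG": 5, "UUU": 10, "UUC": 30}
        )
        w = cai_weights([ref])
        gene = CodonCountTable.from_dict({"GCC": 5, "UUU": 5})
        swapped = CodonCountTable.from_dict({"GCC": 4, "GCU": 1, "UUU": 5})
        assert cai(swapped, w) > cai(gene, w)  # GCU has the higher weight


# -- protein indices and Fop -------------------------------------------------


class TestProteinIndices:
    def test_gravy_scale_extremes(self):
        assert gravy("ATTATCATA") == pytest.approx(4.5)  # poly-Ile
        assert gravy("CGUCGCCGA".replace("U", "T")) == pytest.approx(-4.5)  # poly-Arg
        assert gravy("ATTCGT") == pytest.approx(0.0)  # Ile + Arg

    def test_aromaticity_fractions(self):
        assert aromaticity("TTTTACTGG") == pytest.approx(1.0)  # F, Y, W
        assert aromaticity("GCTGCAGCC") == pytest.approx(0.0)
        assert aromaticity("TTTGCTGCAGCC") == pytest.approx(0.25)


class TestFop:
    def test_all_optimal(self):
        t = CodonCountTable.from_dict({"GCC": 10})
        assert fop(t, {"GCC"}) == 1.0

    def test_no_overlap(self):
        t = CodonCountTable.from_dict({"GCU": 10})
        assert fop(t, {"GCC"}) == 0.0

    def test_met_trp_excluded_from_denominator(self):
        t = CodonCountTable.from_dict({"GCC": 5, "GCU": 5, "AUG": 7, "UGG": 2})
        assert fop(t, {"GCC"}) == pytest.approx(0.5)

    def test_pool_fixture_equals_direct_ratio(self, pools_df, pool_tables):
        high, _ = pool_tables
        optimal = set(pools_df.loc[pools_df["optimal_published"] == 1, "codon"])
        syn = pools_df[~pools_df["codon"].isin(["AUG", "UGG"])]
        expected = (
            syn.loc[syn["codon"].isin(optimal), "high_count"].sum()
            / syn["high_count"].sum()
        )
        assert fop(high, optimal) == pytest.approx(expected)
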