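import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonbias import (
    CodonCountTable,
    base_composition,
    effective_number_of_codons,
    gravy_and_aromaticity,
    rscu,
)
from codonbias.codon_metrics import family_homozygosity, pooled_rscu_table
from codonbias.gene_io import GeneRecord
from codonbias.genetic_code import (
    SENSE_CODONS,
    SYNONYMOUS_CODONS,
    SYNONYMOUS_FAMILIES,
)

from conftest import random_gene_codons, table_from_codons, wright_nc_oracle


class TestCountTable:
    def test_direct_count(self):
        t = CodonCountTable.from_gene(GeneRecord("g", "", "ATGAAATGA"))
        assert t.counts["ATG"] == t.counts["AAA"] == t.counts["TGA"] == 1
        assert t.n_codons == 3

    def test_empty(self):
        t = CodonCountTable()
        assert t.n_codons == 0

    def test_pooling_is_elementwise_addition(self):
        g1 = GeneRecord("a", "", "ATGAAATGA")
        g2 = GeneRecord("b", "", "ATGTTCTGA")
        pooled = CodonCountTable.from_genes([g1, g2])
        summed = CodonCountTable.from_gene(g1) + CodonCountTable.from_gene(g2)
        assert pooled.counts == summed.counts


class TestRscu:
    def test_two_fold_family(self):
        t = CodonCountTable.from_mapping({"TTT": 1795, "TTC": 15765})
        r = rscu(t)
        assert round(r["TTT"], 2) == 0.20
        assert round(r["TTC"], 2) == 1.80

    def test_six_fold_family(self):
        counts = {"TTA": 195, "TTG": 5037, "CTT": 2805, "CTC": 13867,
                  "CTA": 1400, "CTG": 22302}
        assert round(rscu(CodonCountTable.from_mapping(counts))["CTG"], 2) == 2.93

    def test_uniform_family_is_one(self):
        t = CodonCountTable.from_mapping({c: 7 for c in SYNONYMOUS_FAMILIES["A"]})
        r = rscu(t)
        assert all(r[c] == 1.0 for c in SYNONYMOUS_FAMILIES["A"])

    def test_absent_family_is_zero(self):
        r = rscu(CodonCountTable())
        assert all(r[c] == 0.0 for c in SYNONYMOUS_CODONS)

    def test_conventions_met_trp_stops(self):
        r = rscu(CodonCountTable())
        assert r["ATG"] == r["TGG"] == 1.0
        assert r["TAA"] == r["TAG"] == r["TGA"] == 0.0

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_family_sums_equal_degeneracy(self, seed):
        rng = np.random.default_rng(seed)
        t = table_from_codons(random_gene_codons(rng, 200))
        r = rscu(t)
        for aa, codons in SYNONYMOUS_FAMILIES.items():
            if t.family_total(aa) > 0:
                assert math.isclose(sum(r[c] for c in codons), len(codons))


class TestNc:
    def test_single_codon_per_family_gives_20(self):
        t = CodonCountTable.from_mapping(
            {codons[0]: 50 for codons in SYNONYMOUS_FAMILIES.values()}
        )
        assert effective_number_of_codons(t) == pytest.approx(20.0)

    def test_uniform_usage_gives_61(self):
        t = CodonCountTable.from_mapping({c: 10_000 for c in SENSE_CODONS})
        assert effective_number_of_codons(t) == pytest.approx(61.0, abs=1e-2)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            codons = random_gene_codons(rng, 300)
            nc = effective_number_of_codons(table_from_codons(codons))
            assert nc == pytest.approx(wright_nc_oracle(codons), abs=1e-9)

    def test_codon_order_invariance(self):
        rng = np.random.default_rng(3)
        codons = random_gene_codons(rng, 240)
        before = effective_number_of_codons(table_from_codons(codons))
        rng.shuffle(codons)
        after = effective_number_of_codons(table_from_codons(codons))
        assert before == pytest.approx(after, abs=1e-12)

    def test_monotone_decrease_under_family_skew(self):
        # progressively concentrate the Ala family on GCC; all else uniform
        base = {c: 60 for c in SENSE_CODONS}
        values = []
        for skew in range(0, 60, 10):
            counts = dict(base)
            counts["GCC"] += 3 * skew
            for c in ("GCT", "GCA", "GCG"):
                counts[c] -= skew
            values.append(
                effective_number_of_codons(CodonCountTable.from_mapping(counts))
            )
        # non-increasing throughout (the 61 cap can plateau at the start),
        # strictly decreasing once below the cap
        assert all(a >= b for a, b in zip(values, values[1:]))
        below = [v for v in values if v < 61.0]
        assert all(a > b for a, b in zip(below, below[1:]))
        assert values[-1] < values[0]

    def test_ile_zero_homozygosity_interpolated(self):
        # two Ile codons of different synonyms: F(Ile)=0, interpolation kicks in
        counts = {c: 30 for c in SENSE_CODONS if c not in ("ATT", "ATC", "ATA")}
        counts.update({"ATT": 1, "ATC": 1})
        nc = effective_number_of_codons(CodonCountTable.from_mapping(counts))
        assert not math.isnan(nc)

    def test_undefined_when_class_empty(self):
        # only a 2-fold family present: 4- and 6-fold classes unusable
        t = CodonCountTable.from_mapping({"TTT": 5, "TTC": 5})
        assert math.isnan(effective_number_of_codons(t))


class TestBaseComposition:
    def test_all_c_ending(self):
        gene = GeneRecord("g", "", "ATG" + "GCC" * 30 + "TGA")
        comp = base_composition(CodonCountTable.from_gene(gene))
        assert comp["c3s"] == 1.0
        assert comp["gc3s"] == 1.0

    def test_third_position_fractions_partition(self):
        rng = np.random.default_rng(11)
        comp = base_composition(table_from_codons(random_gene_codons(rng, 150)))
        assert comp["a3s"] + comp["t3s"] + comp["g3s"] + comp["c3s"] == pytest.approx(1.0)
        assert comp["gc3s"] == pytest.approx(comp["g3s"] + comp["c3s"])

    def test_hand_enumerated_toy_gene(self):
        # ATG TTT TTC GGA TGG TAA: synonymous codons TTT TTC GGA
        # (ATG/TGG single-codon, TAA stop); third bases T, C, A -> gc3s = 1/3
        gene = GeneRecord("g", "", "ATGTTTTTCGGATGGTAA")
        comp = base_composition(CodonCountTable.from_gene(gene))
        assert comp["gc3s"] == pytest.approx(1 / 3)
        assert comp["c3s"] == pytest.approx(1 / 3)
        # gc1: sense codons ATG TTT TTC GGA TGG, first bases A,T,T,G,T -> 1/5
        assert comp["gc1"] == pytest.approx(1 / 5)

    def test_empty_is_nan(self):
        comp = base_composition(CodonCountTable())
        assert math.isnan(comp["gc3s"]) and math.isnan(comp["gc"])


class TestGravyAromaticity:
    def test_poly_ile(self):
        t = CodonCountTable.from_mapping({"ATC": 40})
        gravy, arom = gravy_and_aromaticity(t)
        assert gravy == pytest.approx(4.5)  # Kyte-Doolittle Ile
        assert arom == 0.0

    def test_poly_phe(self):
        gravy, arom = gravy_and_aromaticity(CodonCountTable.from_mapping({"TTC": 10}))
        assert arom == 1.0
        assert gravy == pytest.approx(2.8)

    def test_mixed_hand_sum(self):
        # 5 Ile (4.5) + 5 Arg (-4.5) -> 0.0; stops excluded from residues
        t = CodonCountTable.from_mapping({"ATC": 5, "CGC": 5, "TAA": 1})
        gravy, arom = gravy_and_aromaticity(t)
        assert gravy == pytest.approx(0.0)
        assert arom == 0.0

    def test_empty_is_nan(self):
        gravy, arom = gravy_and_aromaticity(CodonCountTable())
        assert math.isnan(gravy) and math.isnan(arom)


def test_pooled_rscu_table_layout():
    t = CodonCountTable.from_mapping({"TTT": 1795, "TTC": 15765})
    df = pooled_rscu_table(t).set_index("codon")
    assert df.loc["UUC", "rscu"] == 1.80
    assert df.loc["UUC", "aa"] == "Phe"
    assert len(df) == 64
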