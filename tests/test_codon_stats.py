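"""Codon counting, RSCU and classification behaviour."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from codonpause.codon_stats import (
    CodonUsageTable,
    classify_codons,
    compute_rscu,
    count_codons,
    load_rscu_table,
    synonymous_substitution,
    write_usage_table,
)
from codonpause.genetic_code import standard_code

from oracles import brute_force_rscu


def make_heg_map(code, **overrides):
    """All sense codons at RSCU 1.0 except explicit overrides."""
    base = {c: 1.0 for c in code.sense_codons}
    base.update({k.upper(): v for k, v in overrides.items()})
    return base


class TestCountCodons:
    def test_direct_enumeration(self):
        table = count_codons(["ATGGGTGGTGGGTAA"])
        assert table.counts == {"ATG": 1, "GGT": 2, "GGG": 1, "TAA": 1}

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError, match="empty gene set"):
            count_codons([])

    def test_duplication_doubles_counts(self):
        table = count_codons(["ATGTAA", "ATGTAA"])
        assert table.counts == {"ATG": 2, "TAA": 2}
        assert table.n_genes == 2

    def test_invalid_sequence_names_record(self):
        with pytest.raises(ValueError, match="record_1"):
            count_codons(["ATGCA"])


class TestComputeRscu:
    def test_glycine_family_by_hand(self, code):
        table = CodonUsageTable(counts={"GGT": 2, "GGG": 1}, code=code)
        rscu = compute_rscu(table).rscu
        assert rscu["GGT"] == pytest.approx(8 / 3)
        assert rscu["GGG"] == pytest.approx(4 / 3)
        assert rscu["GGA"] == 0.0
        assert rscu["GGC"] == 0.0

    def test_uniform_counts_give_unit_rscu(self, code):
        counts = {c: 5 for c in code.families["L"]}
        rscu = compute_rscu(CodonUsageTable(counts=counts, code=code)).rscu
        assert all(rscu[c] == pytest.approx(1.0) for c in code.families["L"])

    def test_zero_count_family_undefined(self, code):
        rscu = compute_rscu(CodonUsageTable(counts={"GGT": 3}, code=code)).rscu
        assert rscu["CAA"] is None and rscu["CAG"] is None

    def test_pseudocount_defines_empty_families(self, code):
        rscu = compute_rscu(CodonUsageTable(counts={}, code=code), pseudocount=1.0).rscu
        assert rscu["CAA"] == pytest.approx(1.0)

    def test_single_codon_family_rscu_is_one_when_observed(self, code):
        rscu = compute_rscu(CodonUsageTable(counts={"ATG": 7}, code=code)).rscu
        assert rscu["ATG"] == pytest.approx(1.0)

    @given(
        st.dictionaries(
            st.sampled_from(standard_code().sense_codons),
            st.integers(min_value=0, max_value=50),
            max_size=40,
        )
    )
    def test_family_normalization_invariant(self, counts):
        """For every multi-codon family with nonzero total, sum RSCU = family size."""
        code = standard_code()
        rscu = compute_rscu(CodonUsageTable(counts=counts, code=code)).rscu
        for aa, fam in code.families.items():
            total = sum(counts.get(c, 0) for c in fam)
            if total > 0:
                assert sum(rscu[c] for c in fam) == pytest.approx(len(fam))
            else:
                assert all(rscu[c] is None for c in fam)

    def test_scale_invariance_under_gene_duplication(self, usage_model):
        from codonpause.synthetic_data import generate_heg_set

        genes = [c.sequence + "TAA" for c in generate_heg_set(usage_model, 5, 60, seed=3)]
        once = compute_rscu(count_codons(genes)).rscu
        twice = compute_rscu(count_codons(genes * 2)).rscu
        for c, v in once.items():
            if v is None:
                assert twice[c] is None
            else:
                assert twice[c] == pytest.approx(v)

    def test_matches_brute_force_oracle(self, usage_model, code):
        from codonpause.synthetic_data import generate_heg_set

        for seed in range(10):
            genes = [
                c.sequence for c in generate_heg_set(usage_model, 3, 50, seed=seed)
            ]
            _, expected = brute_force_rscu(genes, code.families)
            got = compute_rscu(count_codons(genes)).rscu
            for codon, v in expected.items():
                if v is None:
                    assert got[codon] is None
                else:
                    assert got[codon] == pytest.approx(v)


class TestClassification:
    def test_rare_nonoptimal_codon(self, code):
        cls = classify_codons(make_heg_map(code, CAA=0.47, CAG=1.53))
        assert cls.is_non_optimal("CAA") and cls.is_rare("CAA")
        assert not cls.is_non_optimal("CAG")

    def test_unique_optimal_codon(self, code):
        cls = classify_codons(
            make_heg_map(code, GGT=1.83, GGG=0.18, GGA=0.99, GGC=1.00)
        )
        assert cls.is_optimal("GGT")
        assert not any(cls.is_optimal(c) for c in ("GGA", "GGC", "GGG"))
        assert cls.is_rare("GGG")

    def test_all_unit_rscu_yields_no_classes(self, code):
        cls = classify_codons(make_heg_map(code))
        assert not any(cls.non_optimal.values())
        assert not any(cls.optimal.values())

    def test_tied_maximum_means_no_optimal(self, code):
        cls = classify_codons(make_heg_map(code, GGT=1.5, GGA=1.5, GGC=0.5, GGG=0.5))
        assert not cls.is_optimal("GGT") and not cls.is_optimal("GGA")

    def test_single_codon_families_excluded(self, code):
        cls = classify_codons(make_heg_map(code))
        for c in ("ATG", "TGG"):
            assert not cls.is_non_optimal(c)
            assert not cls.is_optimal(c)
            assert cls.rscu_heg[c] == 1.0

    def test_undefined_rscu_suggests_pseudocount(self, code):
        partial = {c: 1.0 for c in code.sense_codons if not c.startswith("GG")}
        with pytest.raises(ValueError, match="pseudocount"):
            classify_codons(partial)

    def test_rare_implies_non_optimal(self, code):
        cls = classify_codons(make_heg_map(code, GGT=2.0, GGA=0.5, GGC=1.0, GGG=0.5))
        for codon, is_rare in cls.rare.items():
            if is_rare:
                assert cls.non_optimal[codon]


class TestSynonymousSubstitution:
    @pytest.mark.parametrize(
        "src,tgt,aa", [("CAA", "CAG", "Q"), ("GGG", "GGT", "G")]
    )
    def test_accepted_pairs(self, src, tgt, aa):
        rec = synonymous_substitution(src, tgt)
        assert rec.amino_acid == aa

    def test_non_synonymous_rejected(self):
        with pytest.raises(ValueError, match="not synonymous"):
            synonymous_substitution("CAA", "GGG")

    def test_direction_against_classification(self, code):
        cls = classify_codons(make_heg_map(code, CAA=0.47, CAG=1.53))
        assert synonymous_substitution("CAA", "CAG", classification=cls).direction == "optimizing"
        assert synonymous_substitution("CAG", "CAA", classification=cls).direction == "deoptimizing"

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            synonymous_substitution("TAA", "TAG")


class TestRscuTableIO:
    def test_load_and_normalize(self, tmp_path):
        p = tmp_path / "rscu.tsv"
        p.write_text("codon\trscu\nCAA\t0.47\ngga\t1.0\nGGu\t1.83\n")
        table = load_rscu_table(p)
        assert table == {"CAA": 0.47, "GGA": 1.0, "GGT": 1.83}

    def test_headerless_two_columns(self, tmp_path):
        p = tmp_path / "rscu.tsv"
        p.write_text("CAA\t0.47\nGGG\t0.18\n")
        assert load_rscu_table(p) == {"CAA": 0.47, "GGG": 0.18}

    def test_duplicate_codon_rejected(self, tmp_path):
        p = tmp_path / "rscu.tsv"
        p.write_text("codon\trscu\nCAA\t0.5\nCAA\t0.6\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_rscu_table(p)

    def test_negative_rscu_rejected(self, tmp_path):
        p = tmp_path / "rscu.tsv"
        p.write_text("codon\trscu\nCAA\t-0.1\n")
        with pytest.raises(ValueError, match="negative"):
            load_rscu_table(p)

    def test_write_usage_table_is_stable(self, tmp_path, code):
        table = compute_rscu(count_codons(["ATGGGTGGTGGGTAA"]))
        cls = classify_codons(make_heg_map(code, GGT=1.83, GGG=0.18, GGA=0.99, GGC=1.0))
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_usage_table(p1, table, cls)
        write_usage_table(p2, table, cls)
        assert p1.read_bytes() == p2.read_bytes()
        body = p1.read_text()
        assert body.splitlines()[1].startswith("codon\taa\tcount")
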