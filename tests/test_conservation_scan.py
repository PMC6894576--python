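"""Cross-species profiles, conserved-site detection and the batch scan."""

import numpy as np
import pytest

from codonpause.codon_alignment import (
    CodonMSA,
    backtranslate_alignment,
)
from codonpause.codon_stats import classify_codons
from codonpause.conservation_scan import (
    GeneFamily,
    SiteProfile,
    annotate_with_topology,
    codon_pair_gg_junction,
    detect_conserved_nonoptimal,
    group_adjacent,
    make_report,
    rscu_profile,
    scan_family,
    scan_gene_families,
)
from codonpause.genetic_code import standard_code
from codonpause.synthetic_data import FamilyConfig, generate_family
from codonpause.topology import TMSegment, TopologyAnnotation

from test_codon_stats import make_heg_map


def single_column_cmsa(cells: dict[str, str], reference: str) -> CodonMSA:
    ids = tuple(cells)
    return CodonMSA(ids=ids, rows=tuple((cells[i],) for i in ids), reference_species=reference)


class TestRscuProfile:
    def test_identical_rare_codons_across_species(self, code):
        cls = classify_codons(make_heg_map(code, CAA=0.47, CAG=1.53))
        cmsa = single_column_cmsa({f"sp{i}": "CAA" for i in range(8)}, "sp0")
        (profile,) = rscu_profile(cmsa, cls)
        assert profile.mean_rscu == pytest.approx(0.47)
        assert profile.sd_rscu == pytest.approx(0.0)
        assert profile.reference_position == 1

    def test_population_sd_over_two_species(self, code):
        cls = classify_codons(make_heg_map(code, GGA=0.2, GGC=0.6, GGT=2.2, GGG=1.0))
        cmsa = single_column_cmsa({"a": "GGA", "b": "GGC"}, "a")
        (profile,) = rscu_profile(cmsa, cls)
        assert profile.mean_rscu == pytest.approx(0.4)
        assert profile.sd_rscu == pytest.approx(0.2)

    def test_all_gap_column(self, code):
        cls = classify_codons(make_heg_map(code))
        cmsa = single_column_cmsa({"a": "---", "b": "---"}, "a")
        (profile,) = rscu_profile(cmsa, cls)
        assert profile.mean_rscu is None and profile.sd_rscu is None
        assert profile.reference_position is None

    def test_missing_per_species_classification_rejected(self, code):
        cls = classify_codons(make_heg_map(code))
        cmsa = single_column_cmsa({"a": "CAA", "b": "CAA"}, "a")
        with pytest.raises(KeyError, match="b"):
            rscu_profile(cmsa, {"a": cls})


def profile_of(column, rscus, reference_position=None):
    per = {f"sp{i}": (None if r is None else "NNN", r) for i, r in enumerate(rscus)}
    # codon string is irrelevant to detection; None marks a gap
    per = {
        sp: ((None, None) if r is None else (c, r)) for sp, (c, r) in per.items()
    }
    vals = [r for r in rscus if r is not None]
    mean = sum(vals) / len(vals) if vals else None
    return SiteProfile(
        column=column,
        per_species=per,
        mean_rscu=mean,
        sd_rscu=0.0 if vals else None,
        reference_position=reference_position or column,
    )


class TestDetect:
    def test_hundred_percent_rule(self):
        all_low = profile_of(1, [0.4] * 8)
        one_high = profile_of(2, [0.4] * 7 + [1.8])
        sites = detect_conserved_nonoptimal([all_low, one_high])
        assert [s.column for s in sites] == [1]
        assert sites[0].all_rare

    def test_empty_profiles(self):
        assert detect_conserved_nonoptimal([]) == []

    def test_gap_policy(self):
        gapped = profile_of(1, [0.4] * 7 + [None])
        assert detect_conserved_nonoptimal([gapped]) == []
        sites = detect_conserved_nonoptimal([gapped], require_gap_free=False)
        assert [s.column for s in sites] == [1]

    def test_require_rare_and_monotonicity(self):
        profiles = [
            profile_of(1, [0.4, 0.4]),
            profile_of(2, [0.4, 0.9]),
            profile_of(3, [0.9, 0.9]),
        ]
        strict = detect_conserved_nonoptimal(profiles, require_rare=True)
        relaxed = detect_conserved_nonoptimal(profiles, require_rare=False)
        assert {s.column for s in strict} <= {s.column for s in relaxed}
        assert [s.column for s in strict] == [1]
        assert [s.column for s in relaxed] == [1, 2, 3]

    def test_min_fraction_relaxation(self):
        seven_of_eight = profile_of(1, [0.4] * 7 + [1.8])
        assert detect_conserved_nonoptimal([seven_of_eight], min_fraction=0.8)


class TestGroupAdjacent:
    def test_adjacent_pair_forms_one_run(self):
        sites = [profile_to_site(c) for c in (24, 25)]
        (run,) = group_adjacent(sites)
        assert (run.start_column, run.end_column, run.length) == (24, 25, 2)

    def test_separate_columns_form_separate_runs(self):
        runs = group_adjacent([profile_to_site(c) for c in (5, 9)])
        assert [(r.start_column, r.length) for r in runs] == [(5, 1), (9, 1)]

    def test_empty(self):
        assert group_adjacent([]) == []

    def test_idempotent_under_resorting(self):
        sites = [profile_to_site(c) for c in (9, 5, 6, 24)]
        a = group_adjacent(sites)
        b = group_adjacent(reversed(sites))
        assert [(r.start_column, r.end_column) for r in a] == [
            (r.start_column, r.end_column) for r in b
        ]


def profile_to_site(column):
    (site,) = detect_conserved_nonoptimal([profile_of(column, [0.4, 0.4])])
    return site


class TestAnnotate:
    def test_offsets_from_reference_first_tms(self):
        report = make_report("fam", [profile_to_site(24), profile_to_site(11)])
        anns = {"ref": TopologyAnnotation("ref", (TMSegment(26, 46),))}
        out = annotate_with_topology(report, anns, "ref")
        offsets = {s.column: s.tms_offset for s in out.sites}
        assert offsets == {24: -2, 11: -15}

    def test_zero_offset_at_tms_start(self):
        report = make_report("fam", [profile_to_site(11)])
        out = annotate_with_topology(
            report, {"ref": TopologyAnnotation("ref", (TMSegment(11, 30),))}, "ref"
        )
        assert out.sites[0].tms_offset == 0

    def test_missing_annotation_keeps_none(self, caplog):
        report = make_report("fam", [profile_to_site(24)])
        out = annotate_with_topology(report, {}, "ref")
        assert out.sites[0].tms_offset is None


class TestCodonPairJunction:
    @pytest.mark.parametrize("second", ["GGA", "GGC", "GGG", "GGT"])
    def test_cag_before_gly_is_flagged(self, second):
        assert codon_pair_gg_junction("CAG", second)

    @pytest.mark.parametrize("second", ["GGA", "GGC", "GGG", "GGT"])
    def test_caa_before_gly_is_not_flagged(self, second):
        assert not codon_pair_gg_junction("CAA", second)

    def test_gg_gg(self):
        assert codon_pair_gg_junction("GGG", "GGG")

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            codon_pair_gg_junction("TAA", "GGG")


class TestScanFamily:
    def test_planted_sites_found_with_offsets(self, default_bundle, classification):
        family = GeneFamily("ureA_like", default_bundle.cds_by_id,
                            default_bundle.protein_msa, "sp01")
        report, profiles, ann = scan_family(family, classification)
        assert [s.column for s in report.sites] == [24, 25]
        assert [s.tms_offset for s in report.sites] == [-2, -1]
        assert len(profiles) == default_bundle.config.protein_length
        assert (ann.first_tms.start, ann.first_tms.end) == (26, 46)

    def test_divergence_survivors_match_direct_truth(self, usage_model, classification):
        """Detected planted columns = columns where the plant survived everywhere."""
        for seed in range(5):
            config = FamilyConfig(
                planted_codons={24: "CAA", 25: "GGG"},
                divergence=0.3,
                divergence_redraw="optimal",
                seed=100 + seed,
            )
            bundle = generate_family(config, usage_model)
            expected = set()
            for col in (24, 25):
                codons = {c.codons()[col - 1] for c in bundle.cds_by_id.values()}
                if all(classification.is_non_optimal(c) for c in codons):
                    expected.add(col)
            family = GeneFamily(f"f{seed}", bundle.cds_by_id, bundle.protein_msa, "sp01")
            report, _, _ = scan_family(family, classification)
            assert {s.column for s in report.sites if s.column in (24, 25)} == expected


class TestBatchScan:
    def test_planted_families_flagged(self, usage_model, classification):
        families = []
        planted_ids = set()
        for i in range(10):
            if i < 3:
                config = FamilyConfig(planted_codons={24: "CAA", 25: "GGG"}, seed=200 + i)
                planted_ids.add(f"fam{i}")
            else:
                config = FamilyConfig(seed=200 + i)
            bundle = generate_family(config, usage_model)
            families.append(
                GeneFamily(f"fam{i}", bundle.cds_by_id, bundle.protein_msa, "sp01")
            )
        result = scan_gene_families(families, classification, window=(-10, 5))
        assert {c.family_id for c in result.candidates} == planted_ids
        for cand in result.candidates:
            assert all(-10 <= s.tms_offset <= 5 for s in cand.report.sites)

    def test_family_without_tms_skipped(self, usage_model, classification):
        # hydrophobic stretch too short to be called a TMS
        config = FamilyConfig(tm_start=26, tm_end=33, seed=400)
        bundle = generate_family(config, usage_model)
        family = GeneFamily("noTM", bundle.cds_by_id, bundle.protein_msa, "sp01")
        result = scan_gene_families([family], classification)
        assert result.candidates == ()
        assert result.skipped == {"noTM": "no TMS"}

    def test_empty_batch(self, classification):
        result = scan_gene_families([], classification)
        assert result.candidates == () and result.skipped == {}
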