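"""Catalog fixture, HGVS parsing, domain classification, frameshift annotation."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dastrack.catalog import (
    CatalogError,
    DomainRanges,
    HgvsParseError,
    annotate_frameshift,
    classify_region,
    infer_variant_class,
    load_catalog,
    parse_hgvs_c,
    protein_position,
    summarize_catalog,
    synthetic_fas_cds,
)


@pytest.fixture(scope="module")
def catalog():
    return load_catalog()


class TestLoadCatalog:
    def test_forty_validated_records(self, catalog):
        assert len(catalog) == 40

    def test_novel_insertion_row(self, catalog):
        row = next(v for v in catalog if v.cdna_change == "c.718_719insGTCG")
        assert row.exon == 9
        assert row.region_label == "Intracellular (DD)"
        assert row.genomic_position == "chr10:89014161"
        assert row.protein_change == "p.M240SfsX8"
        assert row.variant_class == "frameshift"

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.raises(CatalogError):
            load_catalog(p)

    def test_malformed_row_names_row_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text(
            "exon\tregion\tgenomic_position_hg38\tcdna_change\tprotein_change\tvariant_class\treference\n"
            "9\tIntracellular (DD)\tNA\tNA\tp.M240SfsX8\tmissense\tX\n"
        )
        with pytest.raises(CatalogError, match="row 2"):
            load_catalog(p)

    def test_hgvs_round_trip_on_all_full_cdna_rows(self, catalog):
        with_cdna = [v for v in catalog if v.cdna_change is not None]
        assert len(with_cdna) == 33
        for v in with_cdna:
            assert parse_hgvs_c(v.cdna_change).render() == v.cdna_change


class TestParseHgvsC:
    @pytest.mark.parametrize(
        "text,start,end,kind,seq",
        [
            ("c.718_719insGTCG", 718, 719, "INS", "GTCG"),
            ("c.100G>T", 100, 100, "SUB", "T"),
            ("c.812_814del", 812, 814, "DEL", ""),
            ("c.657_658delAG", 657, 658, "DEL", "AG"),
            ("c.679delG", 679, 679, "DEL", "G"),
        ],
    )
    def test_supported_grammar(self, text, start, end, kind, seq):
        v = parse_hgvs_c(text)
        assert (v.start, v.end, v.kind, v.sequence) == (start, end, kind, seq)

    def test_intronic_offsets(self):
        v = parse_hgvs_c("c.652-1G>T")
        assert (v.start, v.start_offset, v.ref, v.sequence) == (652, -1, "G", "T")
        assert v.is_intronic
        d = parse_hgvs_c("c.652-9_653del")
        assert (d.start, d.start_offset, d.end, d.end_offset) == (652, -9, 653, 0)

    def test_unsupported_token_rejected(self):
        with pytest.raises(HgvsParseError, match="dup"):
            parse_hgvs_c("c.100dupA")

    @given(
        start=st.integers(1, 5000),
        kind=st.sampled_from(["SUB", "INS", "DEL"]),
        seq=st.text(alphabet="ACGT", min_size=1, max_size=6),
        ref=st.sampled_from(list("ACGT")),
        span=st.integers(0, 8),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_parse_render_round_trip(self, start, kind, seq, ref, span):
        if kind == "SUB":
            alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
            text = f"c.{start}{ref}>{alt}"
        elif kind == "INS":
            text = f"c.{start}_{start + 1}ins{seq}"
        else:
            text = f"c.{start}_{start + span}del" if span else f"c.{start}del"
        assert parse_hgvs_c(text).render() == text


class TestClassifyRegion:
    @pytest.mark.parametrize(
        "aa,label",
        [
            (34, "Extracellular"),
            (189, "Transmembrane"),
            (211, "Intracellular"),
            (229, "Intracellular"),
            (230, "Intracellular (DD)"),
            (240, "Intracellular (DD)"),
            (314, "Intracellular (DD)"),
            (315, "Intracellular"),
            (335, "Intracellular"),
        ],
    )
    def test_default_domain_map(self, aa, label):
        assert classify_region(aa) == label

    def test_total_and_deterministic_over_protein(self):
        labels = [classify_region(aa) for aa in range(1, 336)]
        assert set(labels) <= {"Extracellular", "Transmembrane", "Intracellular", "Intracellular (DD)"}
        assert labels == [classify_region(aa) for aa in range(1, 336)]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_region(0)
        with pytest.raises(ValueError):
            classify_region(336)

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            DomainRanges(extracellular=(1, 200), transmembrane=(174, 190))


class TestSummarizeCatalog:
    def test_class_counts_match_review(self, catalog):
        summary = summarize_catalog(catalog)
        assert summary["total"] == 40
        assert summary["by_class"] == {
            "frameshift": 18,
            "missense": 12,
            "nonsense": 7,
            "inframe_deletion": 1,
            "splice": 2,
        }

    def test_region_counts_match_review(self, catalog):
        summary = summarize_catalog(catalog)
        assert summary["dd_count"] == 15
        assert summary["dd_percent"] == 37.5
        assert summary["intracellular_total"] == 34
        assert summary["intracellular_percent"] == 85.0
        assert summary["by_region"]["Extracellular"] == 4
        assert summary["by_region"]["Transmembrane"] == 2

    def test_missense_concentrate_in_death_domain(self, catalog):
        summary = summarize_catalog(catalog)
        assert summary["missense_count"] == 12
        assert summary["missense_in_dd"] == 9

    def test_totals_conserved(self, catalog):
        summary = summarize_catalog(catalog)
        assert sum(summary["by_class"].values()) == 40
        assert sum(summary["by_region"].values()) == 40
        assert summary["crosstab"].to_numpy().sum() == 40

    def test_empty_catalog_all_zero(self):
        summary = summarize_catalog([])
        assert summary["total"] == 0
        assert all(v == 0 for v in summary["by_class"].values())


class TestInferVariantClass:
    @pytest.mark.parametrize(
        "p,cls",
        [
            ("p.G34X", "nonsense"),
            ("p.M240SfsX8", "frameshift"),
            ("p.W189fs (stop at 225)", "frameshift"),
            ("p.A271del", "inframe_deletion"),
            ("Splice", "splice"),
            ("p.E272G", "missense"),
        ],
    )
    def test_grammar(self, p, cls):
        assert infer_variant_class(p) == cls

    def test_protein_position(self):
        assert protein_position("p.Met240SerfsX8") == 240
        assert protein_position("p.G34X") == 34
        assert protein_position("Splice") is None


class TestAnnotateFrameshift:
    def test_study_insertion_on_synthetic_transcript(self):
        """insGTCG after c.718: codon 240 ATG -> AGT (Ser), stop 8 codons on."""
        res = annotate_frameshift(synthetic_fas_cds(), parse_hgvs_c("c.718_719insGTCG"))
        assert res.first_altered_position == 240
        assert res.first_altered_residue == "S"
        assert res.stop_offset == 8
        assert res.is_frameshift
        assert res.hgvs_p == "p.M240SfsX8"

    def test_three_letter_rendering(self):
        res = annotate_frameshift(
            synthetic_fas_cds(), parse_hgvs_c("c.718_719insGTCG"), style="triple"
        )
        assert res.hgvs_p == "p.Met240SerfsX8"

    def test_in_frame_insertion_not_frameshift(self):
        res = annotate_frameshift(synthetic_fas_cds(), parse_hgvs_c("c.718_719insGTC"))
        assert not res.is_frameshift

    def test_toy_stop_gain_rendered_as_ter_substitution(self):
        # inserting A after base 5 of ATG GGT AAA TAG leaves Gly2 intact and
        # turns codon 3 into TAA: first difference is a stop, not an fs call
        res = annotate_frameshift("ATGGGTAAATAG", parse_hgvs_c("c.5_6insA"))
        assert res.first_altered_position == 3
        assert res.first_altered_residue == "*"
        assert res.hgvs_p == "p.K3X"

    @given(n_codons=st.integers(1, 5), after=st.integers(3, 9))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_multiple_of_three_insertions_never_frameshift(self, n_codons, after):
        cds = "ATGGCTGCAGCCGCTTAA"
        seq = "GCA" * n_codons
        res = annotate_frameshift(cds, parse_hgvs_c(f"c.{after}_{after + 1}ins{seq}"))
        assert not res.is_frameshift

    def test_no_stop_before_cds_end_flagged_not_raised(self):
        # shift a frame whose remainder never contains a stop
        res = annotate_frameshift("ATGGCTGCAGCC", parse_hgvs_c("c.4_5insA"))
        assert res.is_frameshift
        assert res.stop_offset is None
        assert res.hgvs_p.endswith("fsX?")

    def test_substitution_reference_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            annotate_frameshift("ATGGCTTAA", parse_hgvs_c("c.4A>T"))

    def test_intronic_variant_rejected(self):
        with pytest.raises(ValueError, match="intronic"):
            annotate_frameshift(synthetic_fas_cds(), parse_hgvs_c("c.652-1G>T"))

    def test_synthetic_cds_shape(self):
        cds = synthetic_fas_cds()
        assert len(cds) == 336 * 3
        assert cds.startswith("ATG") and cds.endswith("TAA")
        assert cds[717:720] == "ATG"  # codon 240
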