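"""Clonal-mixture model, read simulator, and SAM/FASTQ round trips."""

from __future__ import annotations

import numpy as np
import pytest

from dastrack.pileup import FilterPolicy, count_alleles, filter_reads, vaf
from dastrack.samio import read_sam, write_fastq, write_sam, write_truth_table
from dastrack.simulate import (
    AlignedRead,
    ClonalMixture,
    SimParams,
    SimulationDomainError,
    SpikeVariant,
    cigar_query_length,
    expected_allele_fraction,
    parse_cigar,
    simulate_reads,
)


def ins_target(position: int) -> SpikeVariant:
    return SpikeVariant(position=position, ref_allele="", alt_allele="GTCG", kind="INS")


class TestExpectedAlleleFraction:
    @pytest.mark.parametrize(
        "dnt,other,zyg,expected",
        [
            (0.0, 0.0, "het", 0.0),
            (1.0, 0.0, "hom", 1.0),
            (0.074, 0.012, "het", 0.043),  # the initial whole-blood VAF of 4.3%
            (0.5, 0.0, "hom", 0.5),
        ],
    )
    def test_value(self, dnt, other, zyg, expected):
        f = expected_allele_fraction(
            ClonalMixture(carrier_fraction_dnt=dnt, carrier_fraction_other=other, zygosity=zyg)
        )
        assert f == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "dnt,other",
        [(-0.1, 0.0), (1.1, 0.0), (0.6, 0.5)],
    )
    def test_domain_errors(self, dnt, other):
        with pytest.raises(SimulationDomainError):
            ClonalMixture(carrier_fraction_dnt=dnt, carrier_fraction_other=other)


class TestSimulateReads:
    def test_no_carriers_no_errors_reproduce_reference(self, small_ref):
        params = SimParams(mean_coverage=50, seed=3, sub_error_rate=0.0, indel_error_rate=0.0)
        reads = simulate_reads(
            small_ref, ClonalMixture(0.0), [ins_target(130)], params
        )
        assert reads
        for r in reads:
            assert r.cigar == f"{len(r.bases)}M"
            start = r.ref_start - 1
            assert r.bases == small_ref.sequence[start : start + len(r.bases)]
            assert not r.carries_variant

    def test_full_hom_carriage_all_spanning_reads_carry_insertion(self, small_ref):
        params = SimParams(mean_coverage=50, seed=4, sub_error_rate=0.0, indel_error_rate=0.0)
        mixture = ClonalMixture(carrier_fraction_dnt=1.0, zygosity="hom")
        reads = simulate_reads(small_ref, mixture, [ins_target(130)], params)
        def ref_end(r):
            return r.ref_start + sum(n for op, n in parse_cigar(r.cigar) if op in "MD") - 1

        spanning = [r for r in reads if r.ref_start <= 130 <= ref_end(r)]
        assert spanning
        assert all("I" in r.cigar for r in spanning)

    def test_variant_read_fraction_within_binomial_error(self, small_ref):
        f = 0.05
        params = SimParams(mean_coverage=10000, seed=11, sub_error_rate=0.0, indel_error_rate=0.0)
        mixture = ClonalMixture(carrier_fraction_dnt=0.1, zygosity="het")
        reads = simulate_reads(small_ref, mixture, [ins_target(130)], params)
        carriers = sum(r.carries_variant for r in reads)
        n = len(reads)
        se = np.sqrt(f * (1 - f) / n)
        assert abs(carriers / n - f) < 4 * se

    def test_variant_outside_reference_rejected(self, small_ref):
        params = SimParams(mean_coverage=10, seed=1)
        with pytest.raises(SimulationDomainError):
            simulate_reads(small_ref, ClonalMixture(0.1), [ins_target(9999)], params)

    def test_zero_coverage_warns_and_returns_empty(self, small_ref):
        params = SimParams(mean_coverage=0, seed=1)
        with pytest.warns(UserWarning):
            assert simulate_reads(small_ref, ClonalMixture(0.0), [], params) == []

    def test_cigar_conservation(self, small_ref):
        params = SimParams(
            mean_coverage=300, seed=5, sub_error_rate=0.01, indel_error_rate=0.005
        )
        reads = simulate_reads(
            small_ref, ClonalMixture(0.3), [ins_target(130)], params
        )
        for r in reads:
            assert cigar_query_length(r.cigar) == len(r.bases)

    def test_determinism_same_seed_byte_identical_sam(self, small_ref, tmp_path):
        params = SimParams(mean_coverage=200, seed=99, duplicate_rate=0.05)
        paths = []
        for tag in ("a", "b"):
            reads = simulate_reads(small_ref, ClonalMixture(0.05), [ins_target(130)], params)
            p = tmp_path / f"{tag}.sam"
            write_sam(reads, small_ref, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_error_calibration(self, small_ref):
        e = 0.005
        params = SimParams(
            mean_coverage=2000, seed=21, sub_error_rate=e, indel_error_rate=0.0
        )
        reads = simulate_reads(small_ref, ClonalMixture(0.0), [], params)
        columns = count_alleles(reads, small_ref)
        nonref = sum(
            c.counts[b] for c in columns for b in "ACGT" if b != c.ref_base
        )
        total = sum(c.depth for c in columns)
        se = np.sqrt(e * (1 - e) / total)
        assert abs(nonref / total - e) < 3 * se

    def test_mapq_distribution_and_duplicates(self, small_ref):
        params = SimParams(mean_coverage=2000, seed=8, duplicate_rate=0.1)
        reads = simulate_reads(small_ref, ClonalMixture(0.0), [], params)
        frac_low = np.mean([r.mapq < 30 for r in reads])
        frac_dup = np.mean([r.is_duplicate for r in reads])
        assert 0.01 < frac_low < 0.03
        assert 0.08 < frac_dup < 0.12

    def test_paired_mode_mates_share_truth_status(self, small_ref):
        params = SimParams(mean_coverage=100, seed=13, paired=True)
        reads = simulate_reads(small_ref, ClonalMixture(0.5), [ins_target(130)], params)
        by_frag: dict[str, list] = {}
        for r in reads:
            by_frag.setdefault(r.read_name.rsplit("/", 1)[0], []).append(r)
        assert all(len(v) == 2 for v in by_frag.values())
        for mates in by_frag.values():
            assert mates[0].carries_variant == mates[1].carries_variant


class TestSamRoundTrip:
    def test_single_read_sam_fields(self, tiny_ref, tmp_path):
        read = AlignedRead("r1", 1, "4M", "ACGT", bytes([30]) * 4, 60)
        p = tmp_path / "one.sam"
        write_sam([read], tiny_ref, p)
        body = [l for l in p.read_text().splitlines() if not l.startswith("@")]
        fields = body[0].split("\t")
        assert fields[3] == "1" and fields[5] == "4M"

    def test_secondary_flag_bit(self, tiny_ref, tmp_path):
        read = AlignedRead("r1", 1, "4M", "ACGT", bytes([30]) * 4, 60, is_secondary=True)
        p = tmp_path / "sec.sam"
        write_sam([read], tiny_ref, p)
        body = [l for l in p.read_text().splitlines() if not l.startswith("@")]
        assert int(body[0].split("\t")[1]) & 0x100

    def test_round_trip_field_identical(self, small_ref, tmp_path):
        params = SimParams(
            mean_coverage=1000, seed=17, sub_error_rate=0.01,
            indel_error_rate=0.002, duplicate_rate=0.03,
        )
        reads = simulate_reads(small_ref, ClonalMixture(0.1), [ins_target(130)], params)
        assert len(reads) >= 1000
        p = tmp_path / "rt.sam"
        write_sam(reads, small_ref, p)
        back = read_sam(p)
        assert back == reads

    def test_truth_table_round_trip(self, small_ref, tmp_path):
        from dastrack.samio import read_truth_table

        params = SimParams(mean_coverage=50, seed=2)
        reads = simulate_reads(small_ref, ClonalMixture(0.5), [ins_target(130)], params)
        p = tmp_path / "truth.tsv"
        write_truth_table(reads, p)
        truth = read_truth_table(p)
        assert truth == {r.read_name: r.carries_variant for r in reads}

    def test_fastq_output(self, small_ref, tmp_path):
        params = SimParams(mean_coverage=20, seed=2)
        reads = simulate_reads(small_ref, ClonalMixture(0.0), [], params)
        p = tmp_path / "reads.fastq"
        write_fastq(reads, p)
        lines = p.read_text().splitlines()
        assert len(lines) == 4 * len(reads)
        assert lines[0].startswith("@sim_")
        assert set(lines[3]) == {chr(30 + 33)}
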