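"""SAM / FASTQ / truth-table serialization for simulated reads.

SAM text is written and read through pysam so headers, flags and CIGARs
follow the SAM 1.6 conventions exactly; the simulation-truth flag travels as
the custom ``XV`` integer tag so round trips preserve every field of
:class:`~dastrack.simulate.AlignedRead`.
"""

from __future__ import annotations

from pathlib import Path

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .reference import AmpliconReference
from .simulate import AlignedRead

FLAG_SECONDARY = 0x100
FLAG_DUPLICATE = 0x400


def sam_header(ref: AmpliconReference) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": ref.name, "LN": len(ref)}],
    }


def write_sam(reads: list[AlignedRead], ref: AmpliconReference, path) -> None:
    """Write reads as SAM text with @HD/@SQ headers consistent with *ref*."""
    header = pysam.AlignmentHeader.from_dict(sam_header(ref))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in reads:
            seg = pysam.AlignedSegment(header)
            seg.query_name = r.read_name
            seg.reference_id = 0
            seg.reference_start = r.ref_start - 1  # pysam is 0-based
            seg.mapping_quality = r.mapq
            seg.cigarstring = r.cigar
            seg.query_sequence = r.bases
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in r.quals)
            )
            flag = 0
            if r.is_secondary:
                flag |= FLAG_SECONDARY
            if r.is_duplicate:
                flag |= FLAG_DUPLICATE
            seg.flag = flag
            seg.set_tag("XV", int(r.carries_variant))
            out.write(seg)


def read_sam(path) -> list[AlignedRead]:
    """Read a SAM file back into :class:`AlignedRead` records."""
    reads: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for seg in fh.fetch(until_eof=True):
            quals = seg.query_qualities
            reads.append(
                AlignedRead(
                    read_name=seg.query_name,
                    ref_start=seg.reference_start + 1,
                    cigar=seg.cigarstring or "",
                    bases=seg.query_sequence or "",
                    quals=bytes(quals) if quals is not None else b"",
                    mapq=seg.mapping_quality,
                    is_secondary=bool(seg.flag & FLAG_SECONDARY),
                    is_duplicate=bool(seg.flag & FLAG_DUPLICATE),
                    carries_variant=bool(seg.get_tag("XV")) if seg.has_tag("XV") else False,
                )
            )
    return reads


def write_fastq(reads: list[AlignedRead], path) -> None:
    """Write reads as FASTQ with Phred+33 qualities."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.read_name, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_truth_table(reads: list[AlignedRead], path) -> None:
    """Per-read variant-carriage truth TSV enabling oracle-based tests."""
    with open(path, "w") as out:
        out.write("read_name\tref_start\tcarries_variant\n")
        for r in reads:
            out.write(f"{r.read_name}\t{r.ref_start}\t{int(r.carries_variant)}\n")


def read_truth_table(path) -> dict[str, bool]:
    truth: dict[str, bool] = {}
    with open(path) as fh:
        next(fh)
        for line in fh:
            name, _start, flag = line.rstrip("\n").split("\t")
            truth[name] = bool(int(flag))
    return truth
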