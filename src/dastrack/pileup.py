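"""Filtered per-position allele counting with anchored insertion alleles.

The counting walks each read's CIGAR: M operations assert the observed base
at each reference position, D operations assert a deleted allele, and I
operations assert an insertion allele keyed ``INS:<sequence>`` at the
reference base immediately 5' of the inserted bases (the HGVS anchor).
Soft clips consume query only.  Depth at a column is the number of filtered
reads whose alignment consumes that reference position (A+C+G+T+DEL), which
is also the VAF denominator for insertion alleles at their anchor.

Filters follow the study's processing: reads with mapping quality < 30,
secondary alignments and marked duplicates are discarded before counting,
and columns with fewer than 500 total counts are excluded afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .reference import AmpliconReference
from .simulate import AlignedRead, parse_cigar

BASE_KEYS = ("A", "C", "G", "T", "DEL")


class MalformedReadError(ValueError):
    """A read whose CIGAR does not match its sequence length."""


class UndefinedVAFError(ZeroDivisionError):
    """VAF requested at a column with zero depth."""


@dataclass(frozen=True)
class FilterPolicy:
    """Read- and column-level quality filters."""

    min_mapq: int = 30
    drop_secondary: bool = True
    drop_duplicates: bool = True
    min_depth: int = 500

    def __post_init__(self) -> None:
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")


@dataclass
class PileupColumn:
    """Allele counts at one reference position.

    ``counts`` always contains the five base-level keys (A, C, G, T, DEL)
    plus one ``INS:<sequence>`` key per observed insertion allele anchored
    here.  ``depth`` is the base-level total, i.e. the number of spanning
    reads.
    """

    position: int
    ref_base: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k in BASE_KEYS:
            self.counts.setdefault(k, 0)

    @property
    def depth(self) -> int:
        return sum(self.counts[k] for k in BASE_KEYS)

    def insertion_keys(self) -> list[str]:
        return sorted(k for k in self.counts if k.startswith("INS:"))


def filter_reads(reads: list[AlignedRead], policy: FilterPolicy) -> list[AlignedRead]:
    """Apply MAPQ / secondary / duplicate filters, preserving input order."""
    out = []
    for r in reads:
        if r.mapq < policy.min_mapq:
            continue
        if policy.drop_secondary and r.is_secondary:
            continue
        if policy.drop_duplicates and r.is_duplicate:
            continue
        out.append(r)
    return out


def filter_tally(reads: list[AlignedRead], policy: FilterPolicy) -> dict[str, int]:
    """Counts of reads dropped per filter (for audit logging)."""
    tally = {"input": len(reads), "low_mapq": 0, "secondary": 0, "duplicate": 0, "kept": 0}
    for r in reads:
        if r.mapq < policy.min_mapq:
            tally["low_mapq"] += 1
        elif policy.drop_secondary and r.is_secondary:
            tally["secondary"] += 1
        elif policy.drop_duplicates and r.is_duplicate:
            tally["duplicate"] += 1
        else:
            tally["kept"] += 1
    return tally


_BASE_INDEX = {65: 0, 67: 1, 71: 2, 84: 3}  # ASCII A C G T


def count_alleles(
    reads: list[AlignedRead], ref: AmpliconReference
) -> list[PileupColumn]:
    """Walk CIGARs and build per-position allele counts.

    Reads (or read parts) outside the amplicon window are ignored; columns
    are emitted only for positions covered by at least one read.  Reads
    whose CIGAR-implied query length disagrees with their sequence raise
    :class:`MalformedReadError` naming the read.

    The implementation separates a fast path (spanning-match coverage,
    accumulated as range increments) from explicit per-event bookkeeping for
    mismatches, deletions and insertions, so counting stays linear in reads
    plus events rather than reads times read length.
    """
    L = len(ref)
    ref_bytes = np.frombuffer(ref.sequence.encode(), dtype=np.uint8)
    ref_idx = np.empty(L, dtype=np.int64)
    for ascii_code, j in _BASE_INDEX.items():
        ref_idx[ref_bytes == ascii_code] = j

    match_diff = np.zeros(L + 1, dtype=np.int64)
    del_diff = np.zeros(L + 1, dtype=np.int64)
    # mismatch adjustments: at position p, one read asserted base b != ref
    sub_pos: list[list[int]] = [[], [], [], []]
    sub_from: list[int] = []
    ins_counts: dict[tuple[int, str], int] = {}

    for read in reads:
        ops = parse_cigar(read.cigar)
        qlen = sum(n for op, n in ops if op in "MIS")
        if qlen != len(read.bases):
            raise MalformedReadError(
                f"read {read.read_name!r}: CIGAR {read.cigar} implies query length "
                f"{qlen} but sequence has {len(read.bases)} bases"
            )
        qpos = 0
        rpos = read.ref_start  # 1-based
        read_bytes: np.ndarray | None = None
        for op, n in ops:
            if op == "S":
                qpos += n
            elif op == "M":
                seg_lo = max(rpos, 1)
                seg_hi = min(rpos + n - 1, L)  # inclusive
                if seg_lo <= seg_hi:
                    match_diff[seg_lo - 1] += 1
                    match_diff[seg_hi] -= 1
                    q_off = qpos + (seg_lo - rpos)
                    seg = read.bases[q_off : q_off + (seg_hi - seg_lo + 1)]
                    ref_seg = ref.sequence[seg_lo - 1 : seg_hi]
                    if seg != ref_seg:
                        if read_bytes is None:
                            read_bytes = np.frombuffer(read.bases.encode(), dtype=np.uint8)
                        a = read_bytes[q_off : q_off + (seg_hi - seg_lo + 1)]
                        b = ref_bytes[seg_lo - 1 : seg_hi]
                        for off in np.nonzero(a != b)[0]:
                            p = seg_lo + int(off)
                            code = int(a[off])
                            j = _BASE_INDEX.get(code)
                            if j is not None:
                                sub_pos[j].append(p - 1)
                                sub_from.append(p - 1)
                            else:  # non-ACGT observation: drop from match cov
                                sub_from.append(p - 1)
                qpos += n
                rpos += n
            elif op == "D":
                seg_lo = max(rpos, 1)
                seg_hi = min(rpos + n - 1, L)
                if seg_lo <= seg_hi:
                    del_diff[seg_lo - 1] += 1
                    del_diff[seg_hi] -= 1
                rpos += n
            elif op == "I":
                anchor = rpos - 1  # reference base immediately 5' of the insert
                if read.ref_start <= anchor <= L and anchor >= 1:
                    key = (anchor, read.bases[qpos : qpos + n])
                    ins_counts[key] = ins_counts.get(key, 0) + 1
                qpos += n

    match_cov = np.cumsum(match_diff[:-1])
    del_cov = np.cumsum(del_diff[:-1])
    counts = np.zeros((L, 5), dtype=np.int64)
    covered = match_cov > 0
    counts[covered, ref_idx[covered]] = match_cov[covered]
    if sub_from:
        np.subtract.at(counts, (np.array(sub_from), ref_idx[np.array(sub_from)]), 1)
    for j in range(4):
        if sub_pos[j]:
            np.add.at(counts[:, j], np.array(sub_pos[j]), 1)
    counts[:, 4] = del_cov

    ins_by_pos: dict[int, dict[str, int]] = {}
    for (pos, seq), k in ins_counts.items():
        ins_by_pos.setdefault(pos, {})[f"INS:{seq}"] = k

    columns: list[PileupColumn] = []
    any_cov = (counts.sum(axis=1) > 0)
    for pos0 in np.nonzero(any_cov)[0]:
        pos = int(pos0) + 1
        col_counts = {k: int(counts[pos0, i]) for i, k in enumerate(BASE_KEYS)}
        col_counts.update(ins_by_pos.get(pos, {}))
        columns.append(
            PileupColumn(position=pos, ref_base=ref.sequence[pos0], counts=col_counts)
        )
    return columns


def apply_depth_filter(
    columns: list[PileupColumn], policy: FilterPolicy
) -> list[PileupColumn]:
    """Drop low-coverage columns (depth strictly below ``min_depth``)."""
    kept = [c for c in columns if c.depth >= policy.min_depth]
    if columns and not kept:
        warnings.warn(
            f"all {len(columns)} columns fall below min_depth={policy.min_depth}",
            stacklevel=2,
        )
    return kept


def vaf(column: PileupColumn, allele_key: str) -> float:
    """Variant allele frequency of *allele_key* at a column.

    For insertion keys the denominator is the same base-level depth as for
    substitutions: the number of reads spanning the anchor position.
    """
    depth = column.depth
    if depth == 0:
        raise UndefinedVAFError(f"column {column.position} has zero depth")
    return column.counts.get(allele_key, 0) / depth


def write_pileup_tsv(columns: list[PileupColumn], path) -> None:
    """Pileup TSV: position, ref, depth, A, C, G, T, DEL, then INS keys."""
    ins_keys = sorted({k for c in columns for k in c.insertion_keys()})
    with open(path, "w") as out:
        out.write("\t".join(["position", "ref", "depth", *BASE_KEYS, *ins_keys]) + "\n")
        for c in columns:
            row = [str(c.position), c.ref_base, str(c.depth)]
            row += [str(c.counts.get(k, 0)) for k in BASE_KEYS]
            row += [str(c.counts.get(k, 0)) for k in ins_keys]
            out.write("\t".join(row) + "\n")


def read_pileup_tsv(path) -> list[PileupColumn]:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["position", "ref", "depth"]:
            raise ValueError(f"unexpected pileup header in {path}: {header[:3]}")
        allele_cols = header[3:]
        columns = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            counts = {k: int(v) for k, v in zip(allele_cols, parts[3:]) if int(v) or k in BASE_KEYS}
            columns.append(
                PileupColumn(position=int(parts[0]), ref_base=parts[1], counts=counts)
            )
    return columns
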