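"""Seeded amplicon read simulation under a clonal-mixture + error model.

The generator emulates deep amplicon sequencing of a blood sample in which a
somatic variant is carried by a cell subpopulation (in ALPS, chiefly the
double-negative T cells).  Each simulated fragment is drawn from a mutant
cell with probability equal to the expected allele fraction of the mixture,
then passed through an Illumina-like per-base substitution/indel error
process.  Everything is deterministic given ``SimParams.seed``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

from .reference import AmpliconReference

_CIGAR_RE = re.compile(r"(\d+)([MIDS])")

_BASES = "ACGT"


class SimulationDomainError(ValueError):
    """A mixture fraction or spike variant outside its valid domain."""


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    """Parse a CIGAR string over {M, I, D, S} into (op, length) pairs."""
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"malformed CIGAR string: {cigar!r}")
    return ops


def cigar_query_length(cigar: str) -> int:
    """Number of query bases implied by a CIGAR (M + I + S)."""
    return sum(n for op, n in parse_cigar(cigar) if op in "MIS")


@dataclass(frozen=True)
class SpikeVariant:
    """A variant to spike into mutant-cell fragments.

    Insertions are anchored at the reference base immediately 5' of the
    inserted bases, matching HGVS ``718_719ins`` anchoring at position 718.
    """

    position: int
    ref_allele: str
    alt_allele: str
    kind: str  # "SNV" | "INS" | "DEL"

    def __post_init__(self) -> None:
        if self.kind not in ("SNV", "INS", "DEL"):
            raise SimulationDomainError(f"unknown variant kind {self.kind!r}")
        if self.position < 1:
            raise SimulationDomainError("position must be >= 1")
        if self.kind == "SNV":
            if len(self.ref_allele) != 1 or len(self.alt_allele) != 1:
                raise SimulationDomainError("SNV alleles must be single bases")
            if self.ref_allele == self.alt_allele:
                raise SimulationDomainError("SNV ref and alt must differ")
        if self.kind == "INS" and len(self.alt_allele) < 1:
            raise SimulationDomainError("insertion alt_allele must be non-empty")
        if self.kind == "DEL" and len(self.ref_allele) < 1:
            raise SimulationDomainError("deletion ref_allele must be non-empty")

    def ref_span(self) -> tuple[int, int]:
        """Reference interval (1-based, inclusive) this variant touches."""
        if self.kind == "DEL":
            return self.position, self.position + len(self.ref_allele) - 1
        return self.position, self.position


@dataclass(frozen=True)
class ClonalMixture:
    """Fractions of variant-carrying cells inside and outside the DNT pool.

    ``carrier_fraction_dnt`` is the fraction of all nucleated cells that are
    variant-carrying DNTs; ``carrier_fraction_other`` the variant-carrying
    fraction outside DNTs.  The expected allele fraction is the mutant-cell
    fraction times 0.5 for a heterozygous variant (one of two alleles) or
    1.0 for homozygous.
    """

    carrier_fraction_dnt: float
    carrier_fraction_other: float = 0.0
    zygosity: str = "het"

    def __post_init__(self) -> None:
        for name in ("carrier_fraction_dnt", "carrier_fraction_other"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise SimulationDomainError(f"{name}={value} outside [0, 1]")
        if self.carrier_fraction_dnt + self.carrier_fraction_other > 1.0 + 1e-12:
            raise SimulationDomainError("carrier fractions sum to more than 1")
        if self.zygosity not in ("het", "hom"):
            raise SimulationDomainError(f"zygosity must be het or hom, got {self.zygosity!r}")

    @property
    def mutant_cell_fraction(self) -> float:
        return self.carrier_fraction_dnt + self.carrier_fraction_other


def expected_allele_fraction(mixture: ClonalMixture) -> float:
    """Expected variant allele fraction f of a clonal mixture.

    f = (carrier_fraction_dnt + carrier_fraction_other) * (0.5 if het else 1).
    Pure function; the worked study example is dnt=0.074, other=0.012, het
    -> f = 0.043, the initial whole-blood VAF of the tracked insertion.
    """
    zf = 0.5 if mixture.zygosity == "het" else 1.0
    return mixture.mutant_cell_fraction * zf


@dataclass
class SimParams:
    """Sequencing-run parameters for the simulator.

    Defaults mirror the study design: a MiSeq 2x250-bp run over ~200-bp
    fragments at very high coverage, with a per-base substitution error on
    the order of 1e-3 and rare indel errors.  ``seed`` is mandatory: every
    stochastic call must be reproducible.
    """

    mean_coverage: int
    seed: int
    read_length: int = 250
    fragment_length_mean: float = 200.0
    fragment_length_sd: float = 20.0
    paired: bool = False
    sub_error_rate: float = 0.001
    indel_error_rate: float = 0.0001
    mapq_high_prob: float = 0.98
    mapq_high: int = 60
    mapq_low: int = 20
    duplicate_rate: float = 0.0
    base_quality: int = 30

    def __post_init__(self) -> None:
        if self.mean_coverage < 0:
            raise SimulationDomainError("mean_coverage must be >= 0")
        if self.read_length < 1:
            raise SimulationDomainError("read_length must be positive")
        if self.fragment_length_mean <= 0 or self.fragment_length_sd < 0:
            raise SimulationDomainError("fragment length parameters must be positive")
        if not 0.0 <= self.sub_error_rate <= 0.05:
            raise SimulationDomainError("sub_error_rate outside [0, 0.05]")
        if not 0.0 <= self.indel_error_rate <= 0.01:
            raise SimulationDomainError("indel_error_rate outside [0, 0.01]")
        if not 0.0 <= self.mapq_high_prob <= 1.0:
            raise SimulationDomainError("mapq_high_prob outside [0, 1]")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise SimulationDomainError("duplicate_rate outside [0, 1]")
        if self.seed is None:
            raise SimulationDomainError("seed is required")


@dataclass
class AlignedRead:
    """One aligned read: the unit consumed by the pileup.

    ``quals`` is stored compactly as bytes of Phred values.  The
    ``carries_variant`` flag is simulation truth (clone membership of the
    originating fragment) used only by oracle tests and truth tables; it is
    round-tripped through SAM as the ``XV`` tag.
    """

    read_name: str
    ref_start: int  # 1-based inclusive
    cigar: str
    bases: str
    quals: bytes
    mapq: int
    is_secondary: bool = False
    is_duplicate: bool = False
    carries_variant: bool = False

    def query_length(self) -> int:
        return cigar_query_length(self.cigar)


def _compile_read(
    entries: list[str], ins_after: dict[int, str], start: int
) -> tuple[str, str, int]:
    """Compile per-reference-slot strings into (bases, cigar, ref_start).

    ``entries[i]`` holds the read base emitted at reference offset i ('' if
    deleted); ``ins_after[i]`` holds bases inserted after that slot.
    Leading/trailing deletions are stripped (an aligner would simply start or
    end the alignment elsewhere), adjusting ref_start as needed.
    """
    lo = 0
    hi = len(entries)
    while lo < hi and entries[lo] == "" and lo not in ins_after:
        lo += 1
    while hi > lo and entries[hi - 1] == "" and (hi - 1) not in ins_after:
        hi -= 1
    seq_parts: list[str] = []
    ops: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n == 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    for i in range(lo, hi):
        e = entries[i]
        if e:
            seq_parts.append(e)
            push("M", len(e))
        else:
            push("D", 1)
        ins = ins_after.get(i)
        if ins:
            seq_parts.append(ins)
            push("I", len(ins))
    cigar = "".join(f"{n}{op}" for op, n in ops)
    return "".join(seq_parts), cigar, start + lo


def simulate_reads(
    ref: AmpliconReference,
    mixture: ClonalMixture,
    variants: list[SpikeVariant],
    params: SimParams,
) -> list[AlignedRead]:
    """Simulate aligned reads over an amplicon.

    Each fragment independently belongs to the mutant clone with probability
    f = :func:`expected_allele_fraction`; mutant fragments carry every spiked
    variant that their span covers, with CIGARs reflecting true placement
    (insertions appear as I operations at the anchor).  Substitution and
    indel errors are then applied per base.  Reads are returned sorted by
    reference start; output is deterministic given ``params.seed``.
    """
    L = len(ref)
    for v in variants:
        lo, hi = v.ref_span()
        if lo < 1 or hi > L:
            raise SimulationDomainError(
                f"variant at {v.position} ({v.kind}) lies outside the 1..{L} reference"
            )
    f = expected_allele_fraction(mixture)
    rng = np.random.default_rng(params.seed)

    yield_per_read = min(params.read_length, params.fragment_length_mean)
    n = int(round(params.mean_coverage * L / yield_per_read))
    if params.paired:
        n = (n + 1) // 2  # each fragment emits two mates
    if n == 0:
        warnings.warn("zero coverage requested: returning no reads", stacklevel=2)
        return []

    frag_len = np.clip(
        np.rint(rng.normal(params.fragment_length_mean, params.fragment_length_sd, n)),
        20,
        min(params.read_length, L),
    ).astype(np.int64)
    starts = rng.integers(1, L - frag_len + 2)
    carrier = rng.random(n) < f
    n_sub = rng.binomial(frag_len, params.sub_error_rate)
    n_ind = rng.binomial(frag_len, params.indel_error_rate)
    high_mapq = rng.random(n) < params.mapq_high_prob
    duplicate = rng.random(n) < params.duplicate_rate

    refseq = ref.sequence
    reads: list[AlignedRead] = []
    for i in range(n):
        s = int(starts[i])
        length = int(frag_len[i])
        end = s + length - 1
        overlapped = [
            v
            for v in variants
            if carrier[i] and v.ref_span()[0] <= end and v.ref_span()[1] >= s
        ]
        if not overlapped and n_sub[i] == 0 and n_ind[i] == 0:
            bases = refseq[s - 1 : s - 1 + length]
            cigar = f"{length}M"
            ref_start = s
        else:
            entries = list(refseq[s - 1 : s - 1 + length])
            ins_after: dict[int, str] = {}
            for v in overlapped:
                if v.kind == "SNV":
                    entries[v.position - s] = v.alt_allele
                elif v.kind == "INS":
                    off = v.position - s
                    ins_after[off] = v.alt_allele + ins_after.get(off, "")
                else:  # DEL
                    for p in range(max(v.position, s), min(end, v.ref_span()[1]) + 1):
                        entries[p - s] = ""
            for _ in range(int(n_sub[i])):
                off = int(rng.integers(0, length))
                cur = entries[off]
                if len(cur) != 1:
                    continue  # slot deleted or already multi-base; skip error
                # uniform among the 3 non-current bases
                choices = _BASES.replace(cur, "") if cur in _BASES else _BASES[:3]
                entries[off] = choices[int(rng.integers(0, 3))]
            for _ in range(int(n_ind[i])):
                off = int(rng.integers(0, length))
                if rng.random() < 0.5:
                    ins_after[off] = ins_after.get(off, "") + _BASES[int(rng.integers(0, 4))]
                elif len(entries[off]) == 1:
                    entries[off] = ""
            bases, cigar, ref_start = _compile_read(entries, ins_after, s)
            if not bases:
                continue  # fully deleted fragment (vanishingly rare)
        mapq = params.mapq_high if high_mapq[i] else params.mapq_low
        quals = bytes([params.base_quality]) * len(bases)
        base = AlignedRead(
            read_name=f"sim_{i:07d}",
            ref_start=ref_start,
            cigar=cigar,
            bases=bases,
            quals=quals,
            mapq=mapq,
            is_duplicate=bool(duplicate[i]),
            carries_variant=bool(carrier[i]),
        )
        if params.paired:
            # Mates of a ~200-bp fragment read at 250 bp fully overlap; both
            # carry the same truth status.  Kept out of default workflows so
            # mate double-counting never affects allele counts.
            for mate in ("/1", "/2"):
                reads.append(
                    AlignedRead(
                        read_name=base.read_name + mate,
                        ref_start=base.ref_start,
                        cigar=base.cigar,
                        bases=base.bases,
                        quals=base.quals,
                        mapq=base.mapq,
                        is_duplicate=base.is_duplicate,
                        carries_variant=base.carries_variant,
                    )
                )
        else:
            reads.append(base)
    reads.sort(key=lambda r: (r.ref_start, r.read_name))
    return reads
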