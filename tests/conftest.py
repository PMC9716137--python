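"""Shared fixtures: tiny references, a deterministic random-read generator."""

from __future__ import annotations

import numpy as np
import pytest

from dastrack.reference import AmpliconReference
from dastrack.simulate import AlignedRead


@pytest.fixture
def tiny_ref() -> AmpliconReference:
    return AmpliconReference(name="tiny", sequence="ACGTACGTAC", contig="chr1", genomic_start=1)


@pytest.fixture
def small_ref() -> AmpliconReference:
    """A 260-bp seeded amplicon for simulation tests (fragments are 200 bp)."""
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=260))
    return AmpliconReference(name="amp260", sequence=seq, contig="chr10", genomic_start=1000)


def make_random_reads(
    rng: np.random.Generator, ref: AmpliconReference, max_reads: int = 8
) -> list[AlignedRead]:
    """Random but valid reads (M/I/D/S CIGARs) fully inside the amplicon."""
    L = len(ref)
    reads = []
    for i in range(int(rng.integers(1, max_reads + 1))):
        start = int(rng.integers(1, L))
        ops: list[tuple[str, int]] = []
        rpos = start
        bases: list[str] = []
        if rng.random() < 0.3:
            n = int(rng.integers(1, 4))
            ops.append(("S", n))
            bases.extend(rng.choice(list("ACGT"), size=n))
        n_segments = int(rng.integers(1, 4))
        for j in range(n_segments):
            remaining = L - rpos + 1
            if remaining <= 0:
                break
            op = "M" if j == 0 else str(rng.choice(["M", "D", "I"]))
            n = int(rng.integers(1, min(6, remaining) + 1))
            if op == "M":
                seg = list(ref.sequence[rpos - 1 : rpos - 1 + n])
                for k in range(n):  # sprinkle mismatches
                    if rng.random() < 0.2:
                        seg[k] = str(rng.choice([b for b in "ACGT" if b != seg[k]]))
                bases.extend(seg)
                rpos += n
            elif op == "D":
                rpos += n
            else:
                bases.extend(rng.choice(list("ACGT"), size=n))
            if ops and ops[-1][0] == op:
                ops[-1] = (op, ops[-1][1] + n)
            else:
                ops.append((op, n))
        # CIGAR must end having consumed >= 1 reference base via M
        if not any(op == "M" for op, _ in ops):
            continue
        if ops[-1][0] == "D":
            ops.pop()
        cigar = "".join(f"{n}{op}" for op, n in ops)
        seq = "".join(bases)
        reads.append(
            AlignedRead(
                read_name=f"r{i}",
                ref_start=start,
                cigar=cigar,
                bases=seq,
                quals=bytes([30]) * len(seq),
                mapq=60,
            )
        )
    return reads
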