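"""Amplicon reference sequences and coordinate conventions.

All amplicon coordinates in this package are 1-based and inclusive, matching
SAM POS and HGVS usage.  Genomic coordinates are derived by offsetting with
``genomic_start`` (the genomic position of amplicon base 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO

_ALPHABET = set("ACGT")


@dataclass(frozen=True)
class AmpliconReference:
    """A PCR amplicon target with genomic anchoring.

    Parameters
    ----------
    name:
        Sequence label, used as the SAM @SQ name.
    sequence:
        Upper-case DNA over {A, C, G, T}; amplimers in deep amplicon
        sequencing designs run a few hundred bases to ~1 kb.
    contig:
        Genomic contig the amplicon maps to (e.g. ``"chr10"``).
    genomic_start:
        1-based genomic position of ``sequence[0]``.
    """

    name: str
    sequence: str
    contig: str = "chrUn"
    genomic_start: int = 1

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("reference sequence must be non-empty")
        if set(self.sequence) - _ALPHABET:
            bad = sorted(set(self.sequence) - _ALPHABET)
            raise ValueError(f"reference contains non-ACGT symbols: {bad}")
        if self.genomic_start < 1:
            raise ValueError("genomic_start must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)

    def genomic_position(self, position: int) -> int:
        """Map a 1-based amplicon position to its genomic coordinate."""
        if not 1 <= position <= len(self):
            raise ValueError(f"position {position} outside amplicon 1..{len(self)}")
        return self.genomic_start + position - 1


#: Amplicon position of the anchor base for the c.718_719insGTCG spike used
#: throughout the synthetic study design (chosen so it maps to chr10:89014161).
SYNTHETIC_ANCHOR_POSITION = 350

#: The 4-bp inserted sequence of the tracked somatic FAS variant.
INSERTED_SEQUENCE = "GTCG"


def synthetic_fas_exon9_amplicon() -> AmpliconReference:
    """Synthetic stand-in for the FAS exon 9 amplimer.

    This is *not* the real genomic sequence: it is a fixed, seeded random
    695-bp sequence (the size of the study's second amplimer) anchored so
    that amplicon position :data:`SYNTHETIC_ANCHOR_POSITION` maps to
    chr10:89014161, the genomic anchor of c.718_719insGTCG.  Every pipeline
    stage here depends only on coordinates and allele identities, never on
    the true exon sequence, so a synthetic carrier is sufficient.
    """
    rng = np.random.default_rng(89014161)
    seq = "".join(rng.choice(list("ACGT"), size=695))
    return AmpliconReference(
        name="FAS_exon9_amplicon",
        sequence=seq,
        contig="chr10",
        genomic_start=89014161 - SYNTHETIC_ANCHOR_POSITION + 1,
    )


def load_fasta_reference(
    path, contig: str = "chrUn", genomic_start: int = 1
) -> AmpliconReference:
    """Read a single-record FASTA file as an :class:`AmpliconReference`."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"expected exactly one FASTA record, found {len(records)}")
    rec = records[0]
    return AmpliconReference(
        name=rec.id,
        sequence=str(rec.seq).upper(),
        contig=contig,
        genomic_start=genomic_start,
    )
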