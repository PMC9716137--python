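"""Curated catalog of reported somatic FAS variants in ALPS.

The packaged TSV fixture transcribes the published catalog of 40 somatic
FAS variants (exon, protein region, hg38 position, HGVS c. and p. notation,
class, citation key).  This module parses it, validates every row against
the HGVS-derived class grammar and the protein domain map, computes the
review summary statistics (class and region counts, missense-in-death-
domain enrichment), and annotates frameshift consequences of coding edits.

FAS domain layout used by default (mature-protein numbering, 335 aa):
extracellular through aa 173, transmembrane 174-190, intracellular 191-335
with the death domain at 230-314.  The ranges are overridable; each fixture
row's printed region label is the source of truth for validation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import pandas as pd
from Bio.Seq import Seq
from Bio.SeqUtils import seq1, seq3

VARIANT_CLASSES = ("frameshift", "missense", "nonsense", "inframe_deletion", "splice")
REGION_LABELS = ("Extracellular", "Transmembrane", "Intracellular", "Intracellular (DD)")

FAS_PROTEIN_LENGTH = 335


class HgvsParseError(ValueError):
    """Unsupported or malformed HGVS c. token."""


class CatalogError(ValueError):
    """A malformed or inconsistent catalog row."""


@dataclass(frozen=True)
class DomainRanges:
    """Amino-acid intervals of the FAS protein regions (1-based, inclusive)."""

    extracellular: tuple[int, int] = (1, 173)
    transmembrane: tuple[int, int] = (174, 190)
    intracellular: tuple[int, int] = (191, 335)
    death_domain: tuple[int, int] = (230, 314)

    def __post_init__(self) -> None:
        e, t, i, d = self.extracellular, self.transmembrane, self.intracellular, self.death_domain
        if not (e[0] <= e[1] < t[0] <= t[1] < i[0] <= i[1]):
            raise ValueError("domain intervals must be ordered and non-overlapping")
        if not (i[0] <= d[0] <= d[1] <= i[1]):
            raise ValueError("death domain must lie within the intracellular region")


def classify_region(aa_position: int, ranges: DomainRanges | None = None) -> str:
    """Region label of an amino-acid position; the DD takes precedence."""
    ranges = ranges or DomainRanges()
    if aa_position < 1 or aa_position > ranges.intracellular[1]:
        raise ValueError(
            f"aa position {aa_position} outside protein 1..{ranges.intracellular[1]}"
        )
    if ranges.death_domain[0] <= aa_position <= ranges.death_domain[1]:
        return "Intracellular (DD)"
    if aa_position >= ranges.intracellular[0]:
        return "Intracellular"
    if aa_position >= ranges.transmembrane[0]:
        return "Transmembrane"
    return "Extracellular"


# --- HGVS c. parsing (substitutions, deletions, insertions; intronic offsets) ---

_SUB_RE = re.compile(r"^c\.(\d+)([+-]\d+)?([ACGT])>([ACGT])$")
_DEL_RE = re.compile(r"^c\.(\d+)([+-]\d+)?(?:_(\d+)([+-]\d+)?)?del([ACGT]*)$")
_INS_RE = re.compile(r"^c\.(\d+)_(\d+)ins([ACGT]+)$")


@dataclass(frozen=True)
class HgvsC:
    """A parsed coding-DNA change (supported subset of the HGVS grammar)."""

    start: int
    end: int
    kind: str  # "SUB" | "INS" | "DEL"
    sequence: str = ""  # alt base(s) for SUB/INS; deleted bases for DEL if stated
    ref: str = ""  # SUB reference base
    start_offset: int = 0  # intronic offset (e.g. c.652-1G>T -> -1)
    end_offset: int = 0

    @property
    def is_intronic(self) -> bool:
        return self.start_offset != 0 or self.end_offset != 0

    def render(self) -> str:
        """Render back to HGVS text; the identity on every parsed input."""

        def pos(p: int, off: int) -> str:
            return f"{p}{off:+d}" if off else str(p)

        if self.kind == "SUB":
            return f"c.{pos(self.start, self.start_offset)}{self.ref}>{self.sequence}"
        if self.kind == "INS":
            return f"c.{self.start}_{self.end}ins{self.sequence}"
        span = pos(self.start, self.start_offset)
        if (self.end, self.end_offset) != (self.start, self.start_offset):
            span += f"_{pos(self.end, self.end_offset)}"
        return f"c.{span}del{self.sequence}"


def parse_hgvs_c(text: str) -> HgvsC:
    """Parse a supported HGVS c. string (SUB, INS, DEL, intronic offsets)."""
    m = _SUB_RE.match(text)
    if m:
        pos, off, ref, alt = m.groups()
        return HgvsC(
            start=int(pos),
            end=int(pos),
            kind="SUB",
            sequence=alt,
            ref=ref,
            start_offset=int(off) if off else 0,
            end_offset=int(off) if off else 0,
        )
    m = _INS_RE.match(text)
    if m:
        start, end, seq = m.groups()
        if int(end) != int(start) + 1:
            raise HgvsParseError(f"insertion interval must be adjacent: {text!r}")
        return HgvsC(start=int(start), end=int(end), kind="INS", sequence=seq)
    m = _DEL_RE.match(text)
    if m:
        s, soff, e, eoff, seq = m.groups()
        start = int(s)
        end = int(e) if e else start
        return HgvsC(
            start=start,
            end=end,
            kind="DEL",
            sequence=seq or "",
            start_offset=int(soff) if soff else 0,
            end_offset=int(eoff) if eoff else 0,
        )
    raise HgvsParseError(f"unsupported HGVS c. token: {text!r}")


# --- catalog fixture ---

_AA_POS_RE = re.compile(r"^p\.(?:[A-Z][a-z]{2}|[A-Z])(\d+)")

_MISSENSE_RE = re.compile(r"^p\.(?:[A-Z][a-z]{2}|[A-Z])\d+(?:[A-Z][a-z]{2}|[A-Z])$")
_NONSENSE_RE = re.compile(r"^p\.(?:[A-Z][a-z]{2}|[A-Z])\d+(?:X|Ter|\*)$")


def infer_variant_class(protein_change: str) -> str:
    """Derive the variant class from the HGVS p. grammar."""
    p = protein_change.strip()
    if p.lower() == "splice":
        return "splice"
    if "fs" in p:
        return "frameshift"
    if _NONSENSE_RE.match(p):
        return "nonsense"
    if "del" in p:
        return "inframe_deletion"
    if _MISSENSE_RE.match(p):
        return "missense"
    raise CatalogError(f"cannot classify protein change {protein_change!r}")


def protein_position(protein_change: str) -> int | None:
    """First amino-acid position named in a p. string, if any."""
    m = _AA_POS_RE.match(protein_change.strip())
    return int(m.group(1)) if m else None


@dataclass(frozen=True)
class CatalogVariant:
    """One curated catalog row."""

    exon: int
    region_label: str
    genomic_position: str | None
    cdna_change: str | None
    protein_change: str
    variant_class: str
    reference: str

    def __post_init__(self) -> None:
        if not 2 <= self.exon <= 9:
            raise CatalogError(f"exon {self.exon} outside 2..9")
        if self.region_label not in REGION_LABELS:
            raise CatalogError(f"unknown region label {self.region_label!r}")
        if self.variant_class not in VARIANT_CLASSES:
            raise CatalogError(f"unknown variant class {self.variant_class!r}")


def _catalog_path():
    return resources.files("dastrack.data") / "fas_somatic_variants.tsv"


def load_catalog(path=None, ranges: DomainRanges | None = None) -> list[CatalogVariant]:
    """Load and validate the somatic FAS variant catalog.

    Every row's class must match the grammar of its p. notation, and its
    region label must agree with the domain map whenever an amino-acid
    position is parseable.  Rows with NA genomic/cDNA fields are retained
    (they still carry class and region for the summaries).
    """
    path = path if path is not None else _catalog_path()
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CatalogError(f"catalog file {path} is empty") from None
    if df.empty:
        raise CatalogError(f"catalog file {path} has no rows")
    expected = [
        "exon",
        "region",
        "genomic_position_hg38",
        "cdna_change",
        "protein_change",
        "variant_class",
        "reference",
    ]
    if list(df.columns) != expected:
        raise CatalogError(f"catalog columns {list(df.columns)} != {expected}")
    ranges = ranges or DomainRanges()
    variants: list[CatalogVariant] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        try:
            v = CatalogVariant(
                exon=int(row.exon),
                region_label=row.region,
                genomic_position=None if row.genomic_position_hg38 == "NA" else row.genomic_position_hg38,
                cdna_change=None if row.cdna_change == "NA" else row.cdna_change,
                protein_change=row.protein_change,
                variant_class=row.variant_class,
                reference=row.reference,
            )
            inferred = infer_variant_class(v.protein_change)
            if inferred != v.variant_class:
                raise CatalogError(
                    f"class {v.variant_class!r} does not match grammar-derived {inferred!r}"
                )
            aa = protein_position(v.protein_change)
            if aa is not None and classify_region(aa, ranges) != v.region_label:
                raise CatalogError(
                    f"region {v.region_label!r} inconsistent with aa {aa} "
                    f"({classify_region(aa, ranges)})"
                )
            if v.cdna_change is not None:
                parse_hgvs_c(v.cdna_change)
        except (CatalogError, HgvsParseError, ValueError) as exc:
            raise CatalogError(f"catalog row {i}: {exc}") from exc
        variants.append(v)
    return variants


def summarize_catalog(catalog: list[CatalogVariant]) -> dict:
    """Review summary: counts by class, by region, and the class x region cross-tab.

    The death domain is reported both separately and inside the intracellular
    total; fractions are rendered to one decimal (percent of catalog size).
    """
    total = len(catalog)
    by_class = {cls: 0 for cls in VARIANT_CLASSES}
    by_region = {reg: 0 for reg in REGION_LABELS}
    cross: dict[tuple[str, str], int] = {}
    for v in catalog:
        by_class[v.variant_class] += 1
        by_region[v.region_label] += 1
        cross[(v.variant_class, v.region_label)] = cross.get((v.variant_class, v.region_label), 0) + 1
    dd = by_region["Intracellular (DD)"]
    intracellular_total = by_region["Intracellular"] + dd
    missense_in_dd = cross.get(("missense", "Intracellular (DD)"), 0)

    def pct(k: int) -> float:
        return round(100.0 * k / total, 1) if total else 0.0

    crosstab = pd.DataFrame(0, index=list(VARIANT_CLASSES), columns=list(REGION_LABELS))
    for (cls, reg), k in cross.items():
        crosstab.loc[cls, reg] = k
    return {
        "total": total,
        "by_class": by_class,
        "by_region": by_region,
        "dd_count": dd,
        "dd_percent": pct(dd),
        "intracellular_total": intracellular_total,
        "intracellular_percent": pct(intracellular_total),
        "missense_count": by_class["missense"],
        "missense_in_dd": missense_in_dd,
        "crosstab": crosstab,
    }


# --- frameshift consequence annotation ---


@dataclass(frozen=True)
class ConsequenceResult:
    """Protein consequence of a coding edit.

    ``stop_offset`` counts the first altered codon as 1 (the fsX convention:
    p.Met240SerfsX8 means the shifted frame stops at its 8th codon); None
    when no stop appears before the end of the mutated sequence.
    """

    first_altered_position: int
    first_altered_residue: str  # one-letter
    stop_offset: int | None
    is_frameshift: bool
    hgvs_p: str


def _aa(res: str, style: str) -> str:
    if style == "single":
        return "*" if res == "*" else res
    return "Ter" if res == "*" else seq3(res)


def annotate_frameshift(
    cds: str, variant: HgvsC, style: str = "single"
) -> ConsequenceResult:
    """Apply a coding edit and derive its protein consequence.

    Translates the mutated sequence from the first affected codon, locates
    the first residue differing from the reference protein (the HGVS
    first-difference rule), and for frame-disrupting edits scans for the
    first stop.  ``style`` selects one-letter (p.M240SfsX8) or three-letter
    (p.Met240SerfsX8) rendering.  A shifted frame that never reaches a stop
    before the sequence ends is reported with ``stop_offset=None``, not an
    exception.
    """
    cds = cds.upper()
    if not cds.startswith("ATG"):
        raise ValueError("CDS must start with ATG")
    if variant.is_intronic:
        raise ValueError("intronic variants cannot be annotated against a CDS")
    if variant.end > len(cds):
        raise ValueError(f"variant end {variant.end} beyond CDS length {len(cds)}")

    if variant.kind == "SUB":
        if cds[variant.start - 1] != variant.ref:
            raise ValueError(
                f"reference base mismatch at c.{variant.start}: "
                f"CDS has {cds[variant.start - 1]}, variant states {variant.ref}"
            )
        mutated = cds[: variant.start - 1] + variant.sequence + cds[variant.start :]
        net = 0
        first_codon = (variant.start - 1) // 3 + 1
    elif variant.kind == "INS":
        mutated = cds[: variant.start] + variant.sequence + cds[variant.start :]
        net = len(variant.sequence)
        first_codon = (variant.start - 1) // 3 + 1
    else:  # DEL
        if variant.sequence:
            stated = variant.sequence
            actual = cds[variant.start - 1 : variant.end]
            if stated != actual:
                raise ValueError(
                    f"deleted bases mismatch at c.{variant.start}_{variant.end}: "
                    f"CDS has {actual}, variant states {stated}"
                )
        mutated = cds[: variant.start - 1] + cds[variant.end :]
        net = -(variant.end - variant.start + 1)
        first_codon = (variant.start - 1) // 3 + 1

    is_fs = net % 3 != 0
    ref_protein = str(Seq(cds[: len(cds) - len(cds) % 3]).translate())
    mut_protein = str(Seq(mutated[: len(mutated) - len(mutated) % 3]).translate())

    # HGVS first-difference rule: scan forward from the first affected codon
    # until the residues disagree.
    idx = first_codon - 1
    while (
        idx < len(ref_protein)
        and idx < len(mut_protein)
        and ref_protein[idx] == mut_protein[idx]
    ):
        idx += 1
    if idx >= len(mut_protein):
        # edit silent at the protein level up to the end of the mutant frame
        return ConsequenceResult(
            first_altered_position=idx + 1,
            first_altered_residue="",
            stop_offset=None,
            is_frameshift=is_fs,
            hgvs_p="p.(=)",
        )
    pos = idx + 1
    ref_res = ref_protein[idx] if idx < len(ref_protein) else ""
    mut_res = mut_protein[idx]

    if mut_res == "*":
        # first changed residue is already a stop: a nonsense-style rendering
        hgvs = f"p.{_aa(ref_res, style)}{pos}{'X' if style == 'single' else 'Ter'}"
        return ConsequenceResult(
            first_altered_position=pos,
            first_altered_residue="*",
            stop_offset=1 if is_fs else None,
            is_frameshift=is_fs,
            hgvs_p=hgvs,
        )

    if is_fs:
        stop_rel = mut_protein.find("*", idx)
        stop_offset = (stop_rel - idx + 1) if stop_rel != -1 else None
        hgvs = f"p.{_aa(ref_res, style)}{pos}{_aa(mut_res, style)}fs"
        hgvs += f"X{stop_offset}" if stop_offset is not None else "X?"
        return ConsequenceResult(
            first_altered_position=pos,
            first_altered_residue=mut_res,
            stop_offset=stop_offset,
            is_frameshift=True,
            hgvs_p=hgvs,
        )

    # in-frame consequence
    if variant.kind == "SUB":
        hgvs = f"p.{_aa(ref_res, style)}{pos}{_aa(mut_res, style)}"
    elif variant.kind == "INS":
        hgvs = f"p.{_aa(ref_res, style)}{pos}ins"
    else:
        hgvs = f"p.{_aa(ref_res, style)}{pos}del"
    return ConsequenceResult(
        first_altered_position=pos,
        first_altered_residue=mut_res,
        stop_offset=None,
        is_frameshift=False,
        hgvs_p=hgvs,
    )


def synthetic_fas_cds() -> str:
    """Synthetic stand-in for the FAS coding sequence (NM_000043.6).

    Not the real transcript.  It is engineered only from constraints the
    tracked variant imposes: 335 codons plus a stop, codon 240 = ATG (Met),
    and downstream bases chosen so that inserting GTCG after c.718 yields a
    Ser at codon 240 and a premature stop at the 8th shifted codon
    (p.M240SfsX8), with the unmutated frame free of internal stops.  All
    other codons are inert filler; nothing in the pipeline depends on them.
    """
    filler = "GCT"  # Ala
    codons = [filler] * FAS_PROTEIN_LENGTH
    codons[0] = "ATG"
    codons[239] = "ATG"  # codon 240 = Met, c.718-720
    engineered = ["CTG", "CAT", "CCA", "ACC", "CAT", "GAT"]  # codons 241-246
    codons[240:246] = engineered
    codons.append("TAA")
    return "".join(codons)
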