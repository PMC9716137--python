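"""Noise-aware somatic allele calling and ranking.

Each non-reference allele observed in a depth-passing column is tested
against a background error model with a one-sided upper-tail binomial test:
``p = P(X >= k)`` for ``X ~ Binomial(n, e)``, where ``e`` is the per-allele-
class error rate.  Candidates are ranked by VAF (descending), ties broken by
p-value then position, and pass when they clear both the VAF noise floor and
the p-value threshold.  In deep amplicon data the error floor sits around a
few tenths of a percent VAF, so a genuine clonal variant at >=0.4-1% VAF
separates cleanly from the noise cloud.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .pileup import BASE_KEYS, PileupColumn, vaf as column_vaf

#: Smallest representable positive double; stands in for an exact-zero
#: p-value (which only arises under an error rate of exactly 0).
P_MIN = sys.float_info.min * sys.float_info.epsilon  # 5e-324, subnormal

ALLELE_CLASSES = ("SNV", "INS", "DEL")


class InsufficientDataError(ValueError):
    """Too few columns to estimate an empirical error rate."""


def allele_class(allele_key: str) -> str:
    if allele_key in "ACGT":
        return "SNV"
    if allele_key == "DEL":
        return "DEL"
    if allele_key.startswith("INS:"):
        return "INS"
    raise ValueError(f"unknown allele key {allele_key!r}")


@dataclass(frozen=True)
class ErrorModel:
    """Per-allele-class background error rates.

    ``empirical`` rates are medians over depth-passing columns, computed
    with candidate alleles excluded so a true variant cannot inflate its own
    background.
    """

    per_allele_rate: dict[str, float]
    estimation_method: str = "fixed"

    def __post_init__(self) -> None:
        for cls, e in self.per_allele_rate.items():
            if cls not in ALLELE_CLASSES:
                raise ValueError(f"unknown allele class {cls!r}")
            if not 0.0 <= e <= 0.05:
                raise ValueError(f"error rate {e} for {cls} outside [0, 0.05]")

    def rate(self, allele_key: str) -> float:
        return self.per_allele_rate[allele_class(allele_key)]


@dataclass
class NoiseProfile:
    """Thresholds separating background noise from credible variants.

    ``vaf_floor`` defaults to the 95th percentile of background VAFs (the
    study's observed noise ceiling was ~0.4% VAF); ``p_threshold`` to 1e-4.
    ``direction`` selects whether credible variants fall *below* the p
    threshold (default reading: lowest p = most credible) or above it.
    """

    vaf_floor: float = 0.004
    p_threshold: float = 1e-4
    direction: str = "below"

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf_floor <= 1.0:
            raise ValueError("vaf_floor outside [0, 1]")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold outside (0, 1)")
        if self.direction not in ("below", "above"):
            raise ValueError("direction must be 'below' or 'above'")

    def p_passes(self, p: float) -> bool:
        return p < self.p_threshold if self.direction == "below" else p > self.p_threshold


@dataclass
class AlleleCall:
    """One candidate somatic allele with its evidence."""

    position: int
    ref_base: str
    allele_key: str
    alt_count: int
    depth: int
    vaf: float
    p_value: float
    p_underflow: bool = False
    passes: bool = False
    rank: int = 0


def estimate_error_rate(
    columns: list[PileupColumn],
    exclude: set[tuple[int, str]] = frozenset(),
    method: str = "empirical",
    fixed_rates: dict[str, float] | None = None,
) -> ErrorModel:
    """Estimate per-class background error rates from pileup columns.

    The empirical rate of a class is the median across columns of that
    class's pooled non-reference count divided by depth; alleles listed in
    *exclude* (as ``(position, allele_key)``) do not contribute.
    """
    if method == "fixed":
        if fixed_rates is None:
            raise ValueError("fixed_rates required when method='fixed'")
        return ErrorModel(per_allele_rate=dict(fixed_rates), estimation_method="fixed")
    if method != "empirical":
        raise ValueError(f"unknown estimation method {method!r}")
    if len(columns) < 10:
        raise InsufficientDataError(
            f"empirical error estimation needs >= 10 columns, got {len(columns)}"
        )
    per_class: dict[str, list[float]] = {cls: [] for cls in ALLELE_CLASSES}
    for col in columns:
        depth = col.depth
        if depth == 0:
            continue
        snv = sum(
            col.counts[b]
            for b in "ACGT"
            if b != col.ref_base and (col.position, b) not in exclude
        )
        dele = 0 if (col.position, "DEL") in exclude else col.counts["DEL"]
        ins = sum(
            c
            for k, c in col.counts.items()
            if k.startswith("INS:") and (col.position, k) not in exclude
        )
        per_class["SNV"].append(snv / depth)
        per_class["DEL"].append(dele / depth)
        per_class["INS"].append(ins / depth)
    rates = {cls: float(np.median(vals)) if vals else 0.0 for cls, vals in per_class.items()}
    return ErrorModel(per_allele_rate=rates, estimation_method="empirical")


def test_allele(k: int, n: int, e: float) -> float:
    """Upper-tail binomial p-value: P(X >= k), X ~ Binomial(n, e).

    Exact via the regularized incomplete beta (scipy's binomial survival
    function); returns 1.0 for k = 0.  When e = 0 and k > 0 the true tail
    probability is 0; the smallest representable positive double is returned
    instead (callers flag this via :data:`P_MIN`), never a silent zero.
    """
    if not 0 <= k <= n:
        raise ValueError(f"require 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 <= e <= 1.0:
        raise ValueError(f"error rate {e} outside [0, 1]")
    if k == 0:
        return 1.0
    if e == 0.0:
        warnings.warn("k > 0 with error rate 0: clamping p-value to P_MIN", stacklevel=2)
        return P_MIN
    p = float(stats.binom.sf(k - 1, n, e))
    return p if p > 0.0 else P_MIN


def call_variants(
    columns: list[PileupColumn],
    error_model: ErrorModel,
    noise: NoiseProfile,
) -> list[AlleleCall]:
    """Score every observed non-reference allele and rank the candidates.

    Ranks are a permutation of 1..N over *all* calls (passing or not),
    ordered by VAF descending, then p ascending, then position ascending.
    """
    calls: list[AlleleCall] = []
    for col in columns:
        depth = col.depth
        if depth == 0:
            continue
        for key, count in col.counts.items():
            if count < 1 or key == col.ref_base:
                continue
            if key in BASE_KEYS or key.startswith("INS:"):
                e = error_model.rate(key)
                p = test_allele(count, depth, e)
                v = column_vaf(col, key)
                calls.append(
                    AlleleCall(
                        position=col.position,
                        ref_base=col.ref_base,
                        allele_key=key,
                        alt_count=count,
                        depth=depth,
                        vaf=v,
                        p_value=p,
                        p_underflow=(p == P_MIN),
                        passes=(v > noise.vaf_floor) and noise.p_passes(p),
                    )
                )
    calls.sort(key=lambda c: (-c.vaf, c.p_value, c.position))
    for i, c in enumerate(calls, start=1):
        c.rank = i
    return calls


def estimate_noise_floor(
    background_vafs: list[float],
    p_threshold: float = 1e-4,
    fallback_floor: float = 0.004,
    percentile: float = 95.0,
) -> NoiseProfile:
    """Noise floor = 95th percentile (linear interpolation) of background VAFs.

    With fewer than 20 background observations the configured fallback floor
    is used instead (with a warning): a percentile of a handful of points is
    not a stable noise estimate.
    """
    if len(background_vafs) < 20:
        warnings.warn(
            f"only {len(background_vafs)} background VAFs; falling back to "
            f"configured floor {fallback_floor}",
            stacklevel=2,
        )
        return NoiseProfile(vaf_floor=fallback_floor, p_threshold=p_threshold)
    floor = float(np.percentile(np.asarray(background_vafs, dtype=float), percentile))
    return NoiseProfile(vaf_floor=floor, p_threshold=p_threshold)


def background_vafs_from_calls(
    calls: list[AlleleCall], exclude: set[tuple[int, str]] = frozenset()
) -> list[float]:
    """VAFs of calls not listed in *exclude* — the background noise cloud."""
    return [c.vaf for c in calls if (c.position, c.allele_key) not in exclude]


def write_calls_tsv(calls: list[AlleleCall], path) -> None:
    """Calls TSV mirroring AlleleCall, plus a Bonferroni-adjusted column."""
    m = len(calls)
    with open(path, "w") as out:
        out.write(
            "rank\tposition\tref\tallele\talt_count\tdepth\tvaf\tp_value\t"
            "p_bonferroni\tp_underflow\tpasses\n"
        )
        for c in calls:
            out.write(
                f"{c.rank}\t{c.position}\t{c.ref_base}\t{c.allele_key}\t"
                f"{c.alt_count}\t{c.depth}\t{c.vaf:.6g}\t{c.p_value:.6g}\t"
                f"{min(1.0, c.p_value * m):.6g}\t{int(c.p_underflow)}\t{int(c.passes)}\n"
            )


def write_vcf(calls: list[AlleleCall], ref, path) -> None:
    """Minimal VCF 4.2 with DP/AD/AF/PV INFO fields.

    Insertions are emitted in VCF left-anchored style: REF is the anchor
    base, ALT the anchor base followed by the inserted sequence; POS is the
    genomic coordinate of the anchor.  *ref* is an
    :class:`~dastrack.reference.AmpliconReference` providing the contig and
    genomic offset.
    """
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={ref.contig}>",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##INFO=<ID=AD,Number=1,Type=Integer,Description="Alt allele depth">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Alt allele fraction">',
        '##INFO=<ID=PV,Number=1,Type=Float,Description="Binomial upper-tail p-value">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in sorted(calls, key=lambda c: (c.position, c.allele_key)):
        pos = ref.genomic_position(c.position)
        anchor = ref.sequence[c.position - 1]
        if c.allele_key.startswith("INS:"):
            vref, valt = anchor, anchor + c.allele_key[4:]
        elif c.allele_key == "DEL":
            # single-base deletion, anchored one base 5'
            if c.position == 1:
                continue  # cannot left-anchor a deletion at amplicon start
            pos -= 1
            prev = ref.sequence[c.position - 2]
            vref, valt = prev + anchor, prev
        else:
            vref, valt = anchor, c.allele_key
        filt = "PASS" if c.passes else "noise"
        info = f"DP={c.depth};AD={c.alt_count};AF={c.vaf:.6g};PV={c.p_value:.6g}"
        lines.append(f"{ref.contig}\t{pos}\t.\t{vref}\t{valt}\t.\t{filt}\t{info}")
    with open(path, "w") as out:
        out.write("\n".join(lines) + "\n")
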