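"""End-to-end study workflows shared by the CLI, analysis scripts and tests.

These functions wire the pipeline stages together for the study design this
package emulates: six longitudinal whole-blood samples from one ALPS
patient, each deep-amplicon-sequenced at ~20,000x, carrying a heterozygous
4-bp FAS insertion confined to a DNT-sized cell fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .calling import (
    AlleleCall,
    NoiseProfile,
    background_vafs_from_calls,
    call_variants,
    estimate_error_rate,
    estimate_noise_floor,
)
from .pileup import FilterPolicy, PileupColumn, apply_depth_filter, count_alleles, filter_reads
from .reference import (
    INSERTED_SEQUENCE,
    SYNTHETIC_ANCHOR_POSITION,
    AmpliconReference,
    synthetic_fas_exon9_amplicon,
)
from .simulate import ClonalMixture, SimParams, SpikeVariant, simulate_reads
from .tracking import CorrelationResult, SamplePoint, build_timeseries, pearson


def default_target(ref: AmpliconReference | None = None) -> SpikeVariant:
    """The tracked 4-bp insertion, anchored on the synthetic amplicon.

    On references too short to contain the canonical anchor the insertion
    is placed at the amplicon midpoint instead.
    """
    ref = ref or synthetic_fas_exon9_amplicon()
    pos = SYNTHETIC_ANCHOR_POSITION if len(ref) >= SYNTHETIC_ANCHOR_POSITION else max(1, len(ref) // 2)
    return SpikeVariant(
        position=pos, ref_allele="", alt_allele=INSERTED_SEQUENCE, kind="INS"
    )


def sample_seeds(seed: int, n: int) -> list[int]:
    """Derive n independent per-sample seeds (< 2**31) from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


@dataclass
class SampleResult:
    """Pileup and calls for one simulated sample."""

    label: str
    columns: list[PileupColumn]
    calls: list[AlleleCall]
    noise: NoiseProfile
    target_call: AlleleCall | None


def process_sample(
    label: str,
    ref: AmpliconReference,
    mixture: ClonalMixture,
    target: SpikeVariant,
    params: SimParams,
    policy: FilterPolicy | None = None,
    p_threshold: float = 1e-4,
) -> SampleResult:
    """Simulate one sample and run the full counting + calling stack on it."""
    policy = policy or FilterPolicy()
    reads = simulate_reads(ref, mixture, [target], params)
    kept = filter_reads(reads, policy)
    columns = apply_depth_filter(count_alleles(kept, ref), policy)
    target_key = f"INS:{target.alt_allele}" if target.kind == "INS" else target.alt_allele
    exclude = {(target.position, target_key)}
    error_model = estimate_error_rate(columns, exclude=exclude)
    provisional = call_variants(columns, error_model, NoiseProfile(p_threshold=p_threshold))
    noise = estimate_noise_floor(
        background_vafs_from_calls(provisional, exclude=exclude),
        p_threshold=p_threshold,
    )
    calls = call_variants(columns, error_model, noise)
    target_call = next(
        (c for c in calls if (c.position, c.allele_key) == (target.position, target_key)),
        None,
    )
    return SampleResult(
        label=label, columns=columns, calls=calls, noise=noise, target_call=target_call
    )


def simulate_longitudinal_cohort(
    dnt_table: pd.DataFrame,
    seed: int,
    ref: AmpliconReference | None = None,
    mean_coverage: int = 20000,
    sub_error_rate: float = 0.001,
    policy: FilterPolicy | None = None,
) -> tuple[list[SampleResult], list[SamplePoint], CorrelationResult]:
    """Simulate and analyse the six-sample longitudinal design.

    Each sample's mutant-cell fraction equals its DNT percentage
    (heterozygous, confined to DNTs: expected VAF = DNT/2).  Returns the
    per-sample results, the recovered VAF time series, and the Pearson
    correlation between DNT% and recovered VAF%.
    """
    ref = ref or synthetic_fas_exon9_amplicon()
    target = default_target(ref)
    seeds = sample_seeds(seed, len(dnt_table))
    results: list[SampleResult] = []
    for (row, s) in zip(dnt_table.itertuples(index=False), seeds):
        mixture = ClonalMixture(carrier_fraction_dnt=row.dnt_percent / 100.0)
        params = SimParams(
            mean_coverage=mean_coverage, seed=s, sub_error_rate=sub_error_rate
        )
        results.append(process_sample(row.label, ref, mixture, target, params))
    columns_by_label = {r.label: r.columns for r in results}
    series = build_timeseries(columns_by_label, target, dnt_table)
    corr = pearson([p.dnt_percent for p in series], [p.vaf_percent for p in series])
    return results, series, corr
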