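#!/usr/bin/env python
"""Count alleles and call somatic candidates for every cohort sample.

Applies the study's filters (MAPQ >= 30, no secondary alignments or
duplicates, columns >= 500 counts), estimates the background error model
with the tracked insertion excluded, and scores every non-reference allele
against it.  Also runs the discovery-setting comparison: the last
follow-up sample as whole blood versus CD3+-enriched material, where the
enrichment step roughly doubles the clone's VAF.
Inputs: scratch/sim (from 01); outputs: results/pileups, results/calls.
"""

import argparse
from pathlib import Path

from dastrack.calling import (
    NoiseProfile,
    background_vafs_from_calls,
    call_variants,
    estimate_error_rate,
    estimate_noise_floor,
    write_calls_tsv,
    write_vcf,
)
from dastrack.pileup import FilterPolicy, apply_depth_filter, count_alleles, filter_reads, filter_tally, write_pileup_tsv
from dastrack.reference import synthetic_fas_exon9_amplicon
from dastrack.samio import read_sam
from dastrack.simulate import ClonalMixture, SimParams
from dastrack.tracking import enrichment_fold_change, load_dnt_table
from dastrack.workflows import default_target, process_sample


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--sim-dir", type=Path, default=Path("scratch/sim"))
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    ref = synthetic_fas_exon9_amplicon()
    target = default_target(ref)
    target_key = f"INS:{target.alt_allele}"
    policy = FilterPolicy()
    table = load_dnt_table(args.sim_dir / "dnt_table.tsv")
    pile_dir = args.out_dir / "pileups"
    call_dir = args.out_dir / "calls"
    pile_dir.mkdir(parents=True, exist_ok=True)
    call_dir.mkdir(parents=True, exist_ok=True)

    for row in table.itertuples(index=False):
        reads = read_sam(args.sim_dir / f"{row.label}.sam")
        tally = filter_tally(reads, policy)
        kept = filter_reads(reads, policy)
        columns = apply_depth_filter(count_alleles(kept, ref), policy)
        write_pileup_tsv(columns, pile_dir / f"{row.label}.pileup.tsv")
        exclude = {(target.position, target_key)}
        model = estimate_error_rate(columns, exclude=exclude)
        provisional = call_variants(columns, model, NoiseProfile())
        noise = estimate_noise_floor(background_vafs_from_calls(provisional, exclude=exclude))
        calls = call_variants(columns, model, noise)
        write_calls_tsv(calls, call_dir / f"{row.label}.calls.tsv")
        write_vcf(calls, ref, call_dir / f"{row.label}.calls.vcf")
        top = calls[0]
        print(f"  {row.label}: {tally['kept']}/{tally['input']} reads kept "
              f"({tally['low_mapq']} low-MAPQ dropped); noise floor "
              f"{100 * noise.vaf_floor:.3f}% VAF; top call {top.allele_key} at "
              f"position {top.position}, VAF {100 * top.vaf:.3f}%, p {top.p_value:.3g}")

    # Discovery setting: last follow-up, whole blood vs CD3+ cells.  The
    # printed VAFs (0.67% blood, 1.58% CD3+) define the two mixtures.
    print("discovery comparison (last follow-up):")
    fold_printed = enrichment_fold_change(1.58, 0.67)
    results = {}
    for label, vaf_pct, seed_off in (("whole_blood", 0.67, 101), ("cd3_enriched", 1.58, 102)):
        mixture = ClonalMixture(carrier_fraction_dnt=2 * vaf_pct / 100.0)
        params = SimParams(mean_coverage=20000, seed=args.seed + seed_off, sub_error_rate=0.001)
        res = process_sample(label, ref, mixture, target, params)
        tc = res.target_call
        results[label] = 100 * tc.vaf
        print(f"  {label}: insertion rank {tc.rank}, VAF {100 * tc.vaf:.3f}%, "
              f"passes {tc.passes}")
    fold_recovered = enrichment_fold_change(results["cd3_enriched"], results["whole_blood"])
    print(f"  VAF fold change from CD3+ enrichment: recovered {fold_recovered:.2f}x "
          f"(printed values give {fold_printed:.2f}x; both exceed 2-fold)")


if __name__ == "__main__":
    main()
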