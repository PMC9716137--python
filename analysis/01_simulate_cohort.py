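#!/usr/bin/env python
"""Simulate the six-sample longitudinal cohort as SAM + truth tables.

One deep-amplicon run per clinic visit: the mutant-cell fraction of each
sample equals its measured DNT percentage (heterozygous, DNT-confined), at
20,000x mean coverage with an Illumina-like 1e-3 substitution error.
Outputs land in scratch/sim/.
"""

import argparse
from importlib import resources
from pathlib import Path

from dastrack.reference import synthetic_fas_exon9_amplicon
from dastrack.samio import write_sam, write_truth_table
from dastrack.simulate import ClonalMixture, SimParams, simulate_reads
from dastrack.tracking import load_dnt_table
from dastrack.workflows import default_target, sample_seeds


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--coverage", type=int, default=20000)
    parser.add_argument("--out-dir", type=Path, default=Path("scratch/sim"))
    args = parser.parse_args()

    ref = synthetic_fas_exon9_amplicon()
    target = default_target(ref)
    table = load_dnt_table(resources.files("dastrack.data") / "dnt_longitudinal.tsv")
    args.out_dir.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out_dir / "dnt_table.tsv", sep="\t", index=False)

    seeds = sample_seeds(args.seed, len(table))
    print(f"amplicon {ref.name}: {len(ref)} bp, insertion anchor at "
          f"position {target.position} ({ref.contig}:{ref.genomic_position(target.position)})")
    for row, seed in zip(table.itertuples(index=False), seeds):
        mixture = ClonalMixture(carrier_fraction_dnt=row.dnt_percent / 100.0)
        params = SimParams(mean_coverage=args.coverage, seed=seed, sub_error_rate=0.001)
        reads = simulate_reads(ref, mixture, [target], params)
        write_sam(reads, ref, args.out_dir / f"{row.label}.sam")
        write_truth_table(reads, args.out_dir / f"{row.label}.truth.tsv")
        carriers = sum(r.carries_variant for r in reads)
        print(f"  {row.label}: DNT {row.dnt_percent}% -> expected VAF "
              f"{row.dnt_percent / 2:.3f}%; {len(reads)} reads "
              f"({carriers} from the mutant clone), seed {seed}")
    print(f"wrote {len(table)} samples to {args.out_dir}")


if __name__ == "__main__":
    main()
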