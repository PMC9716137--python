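# Methods

## The problem being modelled

A somatic *FAS* variant in ALPS lives in a clone of hematopoietic origin
that is strongly enriched among double-negative T cells (DNTs). In whole
blood, the fraction of variant-carrying cells is therefore roughly the
DNT fraction; a heterozygous variant contributes one of two alleles, so
its expected variant allele frequency (VAF) is

    f = (m_DNT + m_other) · z,   z = ½ (het) or 1 (hom)

where `m_DNT` and `m_other` are the variant-carrying fractions inside and
outside the DNT compartment. The pipeline's job is to recover `f` from
amplicon reads when `f` is below 1%, i.e. within an order of magnitude of
the sequencing error rate, and to follow it across clinical visits.

`m_other` deserves a note: the observed initial whole-blood VAF of 4.3% at
7.4% DNTs is only consistent with the heterozygous model if ~1.2% of
non-DNT cells also carry the variant (4.3% = (7.4% + 1.2%)/2), which is
biologically expected for a progenitor-derived clone. The longitudinal
generator nevertheless defaults to `m_other = 0` (variant strictly
DNT-confined) because that is the cleanest statement of the design being
tested: VAF = DNT/2. The residual carriage is exercised in the worked
examples instead.

## Read simulation

Fragments of length ~N(200, 20²) bp (clipped to the 250-bp read length and
the amplicon) are placed uniformly on a 695-bp synthetic amplicon at a
mean coverage of 20,000× (≈ 69,500 single-end reads; interior positions
see ~28,000× because fragment placement is uniform over starts, matching
the 20,000–30,000× regime of the emulated instrument). Each fragment is a
mutant-clone draw with probability `f`; mutant fragments carry every
spiked variant their span covers, with truthful CIGARs (`I` operations at
the insertion anchor). Errors are applied after variant placement:

- substitutions at 10⁻³/base by default (uniform over the three other
  bases), the dominant error mode of the emulated chemistry after quality
  filtering;
- 1-bp insertion/deletion errors at 10⁻⁴/base, giving rare spurious
  `INS`/`DEL` alleles so the indel error channel is not trivially empty;
- MAPQ 60 with probability 0.98, else 20, so the MAPQ < 30 filter has
  work to do; base qualities are a flat Phred-30 profile (recalibration is
  treated as already done and base quality is not used downstream);
- optional duplicate flagging (`duplicate_rate`) to exercise the
  duplicate filter; no PCR-cycle duplication model.

Everything is driven by one integer seed through `numpy`'s Generator;
identical seed and parameters give byte-identical SAM output. Paired mode
exists (both mates share the fragment's truth status) but single-fragment
simulation is the default so mate-overlap double counting never arises.

What the generator does **not** emulate: PCR chimeras and primer
artefacts, cycle-dependent and context-dependent error rates, strand
bias, alignment ambiguity around homopolymers (reads are emitted with
their true placement, so left-alignment of indels is never in question),
and real mapping errors beyond the binary MAPQ classes. Passing tests
therefore demonstrate the statistical behaviour of the counting and
calling stack under a clean error model, not robustness to every MiSeq
artefact; on real data the noise floor would be higher and
position-dependent.

## Synthetic stand-ins

Two fixed sequences ship with the package, both labelled synthetic:

- the amplicon (`synthetic_fas_exon9_amplicon`) is a seeded random 695-bp
  sequence — the size of the study's second amplimer — anchored so that
  amplicon position 350 maps to chr10:89014161, the genomic anchor of
  c.718_719insGTCG. No pipeline stage depends on the true exon sequence.
- the coding sequence (`synthetic_fas_cds`) is 335 codons + stop with
  codon 240 = ATG and the 18 bases after c.720 chosen so that inserting
  GTCG after c.718 reproduces the published consequence exactly
  (p.Met240SerfsX8: Ser at the first altered codon, stop at shifted codon
  8) while the unmutated frame is stop-free. The Ser-at-240 part follows
  from the variant definition alone (A + GT → AGT); only the stop offset
  relies on the engineered bases. Supplying the real NM_000043.6 FASTA via
  `catalog annotate --cds` overrides the stand-in.

## Counting

`count_alleles` walks each CIGAR: `M` asserts the observed base per
reference position, `D` asserts a `DEL` allele at each deleted position,
`I` asserts an `INS:<sequence>` allele at the base immediately 5′ of the
insert, `S` consumes query only. Column depth is the number of filtered
reads whose alignment consumes the position (A+C+G+T+DEL), and that same
depth is the VAF denominator for insertion alleles at their anchor —
chosen over fragment-spanning denominators for simplicity and because it
matches how per-allele read counts are reported at a single position.
Deletions contribute to depth (a spanning read asserts an allele); this is
exposed through the counting semantics rather than a flag, and keeps the
invariant depth = spanning reads exact. Base quality is not a counting
filter; mapping quality is.

Filters use strict inequalities exactly as stated by their thresholds:
MAPQ 29 is discarded and 30 kept; a 499-count column is excluded and a
500-count column kept.

## Calling statistics

The somatic test is a one-sided exact binomial: p = P(X ≥ k) with
X ~ Binomial(n, e), where `e` is the error rate of the allele's class
(SNV / INS / DEL). `e` is the median across depth-passing columns of the
class's pooled non-reference fraction, with declared candidate alleles
excluded so a real variant cannot inflate its own background. A
Fisher-style tumor/normal statistic was deliberately not imitated: the
upstream caller it replaces has unstated parameters, so the statistic is
defined here in full and verified against brute-force pmf enumeration to
10⁻¹² for all n ≤ 50.

The noise floor is the 95th percentile (linear interpolation) of
background VAFs rather than a fixed 0.4%: the fixed number is one run's
observation, the percentile is its generalisation. Under the default
simulation conditions the estimated floor lands near 0.06% VAF,
comfortably below the ~0.4% ceiling it generalises, and a fixed floor can
be configured to reproduce the letter of that rule. The p-value threshold
(10⁻⁴) is read as "credible variants fall below it"; the direction is
configurable because the opposite reading exists, but the lowest-p-most-
credible interpretation is the only one under which the tracked variant
(p ≈ 10⁻⁷–10⁻²⁰ at its depths, often below double-precision underflow,
reported as the smallest positive double with an underflow flag, never a
silent zero) is separable from noise. No multiple-testing correction is
applied in the decision rule; a Bonferroni column is included in the calls
table for transparency. Ties rank deterministically (VAF desc, p asc,
position asc).

## Correlation and clone size

Pearson's r is computed from the covariance formula and its p-value from
Student's t with n−2 degrees of freedom, t = r√(n−2)/√(1−r²) (the
regularized incomplete beta underneath). Both sidednesses are reported;
the headline column is one-sided because at the published r = 0.98, n = 6
the one-sided tail (2.97×10⁻⁴) reproduces the published 3×10⁻⁴, while the
two-sided value is 6×10⁻⁴. VAF in percent against DNT in percent is used
throughout (r is scale-invariant, so this only matters for plots).
Mutant-cell fraction is recovered as m = 2·VAF (het) or VAF (hom); a
heterozygous VAF above 0.5 is flagged as inconsistent rather than
silently clamped. Missing time points are excluded pairwise, never
imputed.

## Catalog

The packaged TSV transcribes the curated 40-variant catalog. The variant
class is re-derived from the protein-notation grammar on load (`fs` →
frameshift; terminal X/Ter → nonsense; `del` without `fs` → in-frame
deletion; "Splice" → splice; single substitution → missense) and any
mismatch with the stored class is a load error, as is a region label
inconsistent with the domain map. Default domain ranges (extracellular
≤173, transmembrane 174–190, intracellular 191–335, death domain 230–314)
are config-overridable; the fixture's printed region labels, not the
ranges, are the source of truth in tests. Rows whose original reports gave
no usable cDNA string (7 of 40) keep NA fields but still count in the
summaries; the HGVS parse/render round trip covers the other 33.

## Problem sizes and numerical choices

Test and acceptance runs use the study's depth (20,000×) and error
(10⁻³) throughout. The six-sample acceptance run uses the full 695-bp
amplicon; replicate-heavy property checks (200-replicate VAF calibration,
50-replicate separation power, 20-replicate cohort recovery) use a 260-bp
amplicon so a replicate is ~26,000 reads — the anchor-position depth, which
is what the statistics see, is the same. Binomial and Pearson oracles are
exact enumerations/double-loop sums compared at 10⁻¹²; percentiles use
numpy's linear interpolation; random seeds are derived from the master
seed via `numpy.random.SeedSequence` and kept below 2³¹.

## Known limitations

No tumor/normal paired calling, strand-bias or positional artefact
modelling, mate-overlap merging, or indel realignment; the HGVS subset
covers the grammars present in the catalog (no dup/inv/delins); VCF output
is a minimal single-sample emitter (DP/AD/AF/PV INFO fields). The
simulator's clean error model means absolute false-positive rates on real
instruments will exceed those measured here.
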