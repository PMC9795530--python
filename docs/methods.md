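# Methods

## Problem and approach

Meiotic crossovers reshuffle parental haplotypes; mapping where they occur
normally needs pedigrees or large genotyped populations. Sequencing a pool
of gametes (in practice sperm) from a single individual offers a shortcut:
every long read derives from one haploid gamete, so a read whose alleles
switch from one parental haplotype to the other partway along its length is
direct physical evidence of a crossover in that gamete. `gametecross`
detects such reads in ONT-style long-read data and aggregates them into a
genome-wide recombination landscape.

Nanopore reads are accurate enough to phase but make most of their errors
in homopolymer runs, whose lengths the pore resolves poorly. The pipeline
therefore works throughout in **homopolymer-compressed space**: every
maximal run of identical bases in both the reads and the reference is
collapsed to a single base before alignment and variant calling, removing
the dominant error mode at the cost of a shrunken coordinate system. An
exact run-length map (one row per compressed position, storing its original
interval `[run_start, run_start + run_length)`) makes the transformation
invertible, so reported crossover intervals are lifted back to original
coordinates for the landscape.

## Detection model

For one read and the phased heterozygous SNVs it spans (positions
`n = 1..N`, haplotype alleles `H_ref(n)`, `H_alt(n)`, read base `G(n)` from
a CIGAR walk):

1. **Haplotype score** per site:
   `H(n) = +1` if `G(n) = H_ref(n)`, `−1` if `G(n) = H_alt(n)`, `0`
   otherwise (sequencing error, deletion, site not resolved).

2. **Sliding-window phase**: for every position `n` from the 4th to the
   4th-from-last site, the window is the 7 sites `n−3 … n+3` (step one).
   With `L(n)` the number of non-zero scores in the window, the call is

   - `HapA` if `Σ H / L(n) ≥ 4/6`,
   - `HapB` if `Σ H / L(n) ≤ −4/6`,
   - `NA` otherwise, or whenever `L(n) < 5`.

   Inequalities are inclusive and evaluated in exact integer arithmetic
   (`den·Σ ≥ num·L`), so threshold cases can never be lost to floating
   point. The minimum-representation rule is stated in the literature as
   "each haplotype must be represented by at least 5 variants within a
   window", which a 7-site window cannot satisfy for both haplotypes at
   once; we read it as requiring at least 5 *informative* (non-zero) sites
   per window, the only interpretation consistent with the NA rule's
   purpose. It is configurable (`min_represented`).

3. **Switch calling**: NA calls are dropped; if both `HapA` and `HapB`
   remain, the read is a recombinant molecule. Each transition yields a
   call whose switch interval runs (half-open, compressed coordinates)
   from the last supporting site of the outgoing phase to the first
   supporting site of the incoming phase, then lifted to original
   coordinates. Reads with ≥ 2 switches are emitted but flagged
   `multi_switch`: two genuine crossovers on one molecule are rare, so
   these are usually artifacts, and downstream users can drop them.

Phase is only meaningful within a phase set, so scoring and window
traversal never cross a block boundary (PS tag); a crossover can only be
called inside a block. "Haplotype A" is the allele left of the `|`
separator — an arbitrary convention; a global label swap exchanges
HapA/HapB calls without changing which reads are recombinant (tested as an
invariant).

Reads spanning fewer than 7 sites yield no phase calls and can never be
called recombinant; this bounds detection at low SNV density and is the
main driver of the sensitivity/density relationship below.

## Upstream filters

- **Alignments**: secondary and supplementary records and MAPQ < 60 are
  removed. Alignment, variant calling and phasing themselves are external
  (minimap2/Clair/Whatshap-class tools, consumed as BAM and phased VCF;
  when phasing gamete pools, capping Whatshap's maximum coverage at 20
  keeps its runtime reasonable without hurting block quality).
- **Variant quality**: long-read variant-quality distributions are
  bimodal (error mode low, real variants high). The cutoff is the valley
  between the two modes plus 50, located on a Gaussian-KDE density
  (Scott bandwidth, 512-point grid, peaks required to have ≥ 5% of the
  maximum density as prominence so tail wiggles do not count as modes).
  If fewer than two modes are found the rule's premise fails and the 5th
  percentile is used instead, with a warning — conservative in that it
  keeps nearly everything. A record exactly at the threshold is kept
  ("below" is strict).
- **Variant type**: only biallelic SNVs; indels, multiallelic and
  symbolic/structural records are dropped (misalignment around them
  produces spurious genotypes).
- **Clustered variants**: any 10-base window (both ends inclusive)
  holding more than 3 variants is an error cluster and all of its members
  are removed, not just the excess. The filter is idempotent.
- **Coverage**: a candidate whose read span has mean depth outside
  0.25–2.0× the genome-median depth (median over covered positions) is
  excluded — symmetric on a log scale, guarding against dropout on one
  side and collapsed-repeat pileups on the other. Both multipliers are
  configurable; `(0, ∞)` disables the filter.

## Landscape

Filtered events are binned into 1 Mb windows on original coordinates by
the midpoint of their switch interval (an overlap-weighted alternative is
available); the final partial window is kept with its true length. Sex
chromosomes are excluded by default (X/Y recombine only in the
pseudoautosomal region, so genome-wide counts are not comparable with
autosomes).

## Synthetic gamete pools

The simulator generates the entire input stack so that detection accuracy
can be measured against known truth:

- **Reference**: a homopolymer-free random skeleton expanded with
  geometric run lengths (`P(len = k) ∝ p^(k−1)`, `p = 0.25`, mean run
  ≈ 1.33), giving compression statistics resembling real genomes.
- **Haplotypes**: heterozygous SNVs at exponential spacing (means 100,
  200 or 300 original bases in the validation conditions), each alternate
  allele chosen to differ from both compressed neighbours so the two
  haplotypes share one compressed coordinate system; alleles are assigned
  to haplotype A or B at random. The phased VCF reproduces the pair
  exactly and adds ~8% low-quality decoy records drawn from a low quality
  mode (N(100, 30) vs N(700, 50) for real sites), which the QC stage is
  expected to remove via the valley rule.
- **Reads**: lengths N(20 kb, 5 kb) floored at 2 kb, uniform starts,
  counts set by mean depth over original bases. A fraction (default 10%)
  are recombinant templates switching haplotype at a uniform internal
  breakpoint (an option can require ≥ k sites per flank, used for the
  noiseless validation). Reads are emitted natively in compressed space
  with truthful CIGARs against the compressed reference, so no aligner is
  needed; the configured error rates are therefore *effective
  post-compression* rates: 2% substitution, 2% insertion, 3% deletion,
  indel probabilities ×3 at positions whose original run length exceeds
  one base (the nanopore error mode that survives compression).

What this emulates — and what it does not: the simulator reproduces the
geometry of the detection problem (site density, read length, breakpoint
position, post-compression error load) but not basecaller signal
artifacts, reference bias, alignment ambiguity in repeats, structural
variation, or phasing errors in the input VCF (the simulated phasing is
perfect within its single block). Passing validation therefore shows the
sliding-window detector behaves correctly under its stated error model,
not that any particular real dataset will reach the same numbers.

## Validation harness

Sensitivity (accuracy) is the fraction of truly recombinant molecules with
at least one surviving call; the error rate is the fraction of truly
non-recombinant molecules called recombinant. `run_grid` sweeps SNV
spacing × depth, simulating one genome per (spacing, replicate) and
running the complete pipeline — alignment filter, quality-valley cutoff,
variant filters, haplotype loading, detection, coverage filter — per depth
cell, all randomness derived from a single seed (per-cell seeds via
`SeedSequence`). Problem sizes used throughout the validation: 5 Mb
genomes, depths 20–70×, three replicates per cell (≥ 300 recombinant and
≥ 4500 non-recombinant reads per cell at 20×), chosen to give binomial
standard errors below one percentage point on sensitivity while keeping a
desk-scale footprint.

Two behaviours of the harness are worth knowing when interpreting results.
Sensitivity falls with sparser variants mainly through reads whose
breakpoint leaves < 7 sites on one flank, and is nearly flat in depth:
with a perfect phased VCF supplied, per-read detection does not depend on
how many other reads were sequenced, whereas in a real experiment depth
acts through variant-calling and phasing quality upstream. And under this
parametric error model the false-positive rate is essentially zero — a
spurious opposite-phase window call needs ≥ 5 of 7 informative sites to be
miscalled *as the other haplotype* (per-site probability ≈ sub_rate/3), so
the measured error rate sits far below the worst-case bound it is checked
against.

## Numerical and degenerate-input choices

- Coordinates are 0-based half-open internally; converted at VCF/BAM
  boundaries (1-based per their specifications).
- FASTQ compression keeps the maximum quality within each collapsed run
  (strongest evidence for the retained base).
- `N` runs compress like any other base.
- Empty inputs: an empty sequence compresses to an empty sequence; a VCF
  with no usable phased sites yields an empty table with a warning, not an
  error; an empty BAM yields an empty depth profile with a warning.
- A read whose CIGAR does not account for its sequence length is rejected
  with a logged warning, never a pipeline failure.
- Ties: a window ratio exactly at ±4/6 is a phase call (inclusive, as
  printed); a landscape midpoint exactly on a window edge belongs to the
  right window (floor division).

## Known limitations

- Gene conversion (double switches within short tracts) is not
  distinguished from artifacts; both surface as `multi_switch`.
- The coverage filter uses fixed multiplicative bounds, not a fitted depth
  distribution; at very low depth (< ~5×) Poisson noise alone can push
  read spans outside the band.
- Sensitivity estimates count every simulated recombinant read in the
  denominator, including reads whose breakpoint is too close to an end to
  be detectable by any window method; they are bounded away from 1 at
  finite site density.
- The landscape is a raw event count per window, not a genetic map
  (no cM/Mb scaling, no hotspot testing).
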