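# gametecross

Detection of meiotic crossovers from **gamete-pool long-read sequencing**.

Every long read from a pooled sperm sample derives from a single haploid
gamete. Along its length it should carry the alleles of exactly one
parental haplotype — unless a meiotic crossover fell inside the molecule,
in which case the allele pattern switches haplotype partway through.
`gametecross` finds those reads in ONT-style data and aggregates them into
an individual genome-wide recombination landscape, without pedigrees or
population genotyping.

It is intended for researchers building individualized recombination maps
from nanopore gamete pools, and for method developers who need a
ground-truth simulator for phase-switch detection.

## Method

ONT reads concentrate their errors in homopolymer runs, so reads and
reference are first **homopolymer-compressed** (`AGTTTCG → AGTCG`) and
the whole analysis runs in compressed coordinates; an exact run-length map
lifts results back to original coordinates. After alignment filtering
(primary records, MAPQ ≥ 60) and variant QC (quality valley + 50 cutoff,
biallelic SNVs only, clusters of > 3 variants per 10 bp removed), each
read is scored at every phased heterozygous site n it covers:

    H(n) = +1  if read base = haplotype-A allele
           −1  if read base = haplotype-B allele
            0  otherwise

A 7-site window slides from the 4th to the 4th-from-last site; with L(n)
the number of non-zero scores in the window,

    phase(n) = HapA  if Σ H / L(n) ≥  4/6
               HapB  if Σ H / L(n) ≤ −4/6
               NA    otherwise, or if L(n) < 5

After dropping NA calls, a read whose phase sequence contains both HapA
and HapB is a **recombinant molecule**; the switch interval spans from the
last site of the outgoing phase to the first site of the incoming one.
Candidates in regions of anomalous depth (outside 0.25–2× the genome
median over the read span) are excluded, and surviving events are binned
into 1 Mb windows (autosomes only) to form the landscape.

A built-in simulator generates the full input stack — reference with
realistic homopolymer runs, phased haplotype pair, noisy pre-aligned
gamete-pool reads with known breakpoints — so sensitivity and
false-positive rate are measurable against truth. See `docs/methods.md`
for assumptions, parameters and limitations.

## Worked example

Simulate a 1 Mb pool at 10× with one heterozygous SNV per 100 bp, detect
crossovers, and score against the truth set:

```sh
$ gametecross simulate pool --genome-length 1000000 --depth 10 \
      --snv-spacing 100 --recomb-fraction 0.2 --seed 42
500 reads (112 recombinant) -> pool

$ gametecross detect pool/reads.bam pool/phased.vcf calls.tsv \
      --position-map pool/position_map.tsv.gz
105 switch calls on 105 reads

$ gametecross evaluate calls.tsv pool/truth.tsv
{
  "accuracy": 0.9375,
  "error_rate": 0.0,
  "n_true_recombinant": 112,
  "n_true_nonrecombinant": 388,
  "n_called_recombinant": 105,
  "n_true_positive": 105,
  "n_false_positive": 0,
  "mean_breakpoint_error": 0.7714285714285715
}
```

105 of the 112 truly recombinant reads are recovered (93.8% sensitivity;
the misses are breakpoints too close to a read end to leave seven
informative sites on each flank), no non-recombinant read is miscalled,
and the reported switch intervals land on average within a base of the
true breakpoint. The call table carries both coordinate systems:

```
read_id     chrom  comp_start  comp_end  orig_start  orig_end  n_switches  ...
chr1_read3  chr1   23865       24750     31860       33069     1
chr1_read6  chr1   28870       29164     38543       38921     1
```

On real data the equivalent run is `gametecross run --reference ref.fa
--bam aligned.bam --phased-vcf phased.vcf --out-dir out/`, where the BAM
comes from aligning compressed reads (`compress-reads`) to the compressed
reference (`compress-ref`) and the VCF from any caller/phaser operating on
those alignments; `out/` then contains the event table/BED, the 1 Mb
landscape TSV and plot, and a resolved-config snapshot.

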