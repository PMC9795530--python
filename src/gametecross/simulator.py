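"""Synthetic gamete-pool generator and validation harness.

Validating a crossover caller needs reads whose recombination status is
known.  This module simulates, at desk scale, the whole input stack the
pipeline consumes: a reference with realistic homopolymer runs, a pair of
parental haplotypes differing at heterozygous SNVs with a chosen mean
spacing, a phased VCF, and a pool of noisy long reads drawn from haplotype
A, haplotype B, and recombinant templates that switch haplotype at a
uniform-random internal breakpoint.

Reads are emitted natively in homopolymer-compressed space, pre-aligned
with truthful CIGARs against the compressed reference (the alignment step
the real pipeline delegates to an external aligner is bypassed by
construction).  The substitution/insertion/deletion rates are therefore
*effective post-compression* error rates; deletions and insertions are made
more likely (a configurable multiplier) at positions whose original
homopolymer run is longer than one base, mimicking the dominant nanopore
error mode that survives compression.

``evaluate`` scores detection output against the truth set — sensitivity
(fraction of truly recombinant molecules detected) and error rate
(fraction of non-recombinant molecules miscalled) — and ``run_grid`` sweeps
variant density x sequencing depth over the full pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from gametecross import coverage as cov
from gametecross import variant_qc
from gametecross.crossover import DetectOptions, detect_all
from gametecross.haplotypes import load_haplotypes
from gametecross.hpc import CompressedSequence, PositionMap, compress_sequence

__all__ = [
    "SimConfig",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_reads",
    "evaluate",
    "EvalMetrics",
    "haplotype_tables_from_genome",
    "run_cell",
    "run_grid",
    "summarize_grid",
    "plot_grid",
]

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated gamete pool.

    Defaults follow the validation design: a 5 Mb genome, heterozygous
    SNVs every 100 bp on average (alternatives 200/300 bp), mean depth
    20-70x, ONT-like read lengths (20 +- 5 kb) and a parametric
    post-compression error model (2% substitution, 2% insertion, 3%
    deletion, x3 indels inside homopolymer runs).
    """

    genome_length: int = 5_000_000
    n_chromosomes: int = 1
    snv_spacing: float = 100.0          # mean original bases per het SNV
    depth: float = 20.0                 # mean coverage in original bases
    read_length_mean: float = 20_000.0
    read_length_sd: float = 5_000.0
    read_length_min: int = 2_000
    recomb_fraction: float = 0.1        # fraction of reads with one crossover
    sub_rate: float = 0.02
    ins_rate: float = 0.02
    del_rate: float = 0.03
    homopolymer_indel_mult: float = 3.0
    homopolymer_geom_p: float = 0.25    # run length 1 + Geom; mean 1/(1-p)
    decoy_variant_fraction: float = 0.08  # low-quality false VCF records
    qual_true: tuple[float, float] = (700.0, 50.0)   # (mean, sd)
    qual_decoy: tuple[float, float] = (100.0, 30.0)
    breakpoint_min_flank_sites: int = 0  # force >=k sites per flank (0 = uniform)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("recomb_fraction", "sub_rate", "ins_rate", "del_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.snv_spacing <= 0:
            raise ValueError("snv_spacing must be positive")
        if self.snv_spacing >= self.genome_length:
            raise ValueError("snv_spacing must be smaller than the genome")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0.0 <= self.homopolymer_geom_p < 1.0:
            raise ValueError("homopolymer_geom_p must be in [0, 1)")


@dataclass
class SimulatedGenome:
    """Reference, haplotype pair and phased variants of one simulation."""

    config: SimConfig
    references: dict[str, str]                      # original sequences
    compressed: dict[str, CompressedSequence]
    position_map: PositionMap
    # per chromosome: compressed site positions and the two phased alleles
    site_positions: dict[str, np.ndarray]
    hap_a_allele: dict[str, np.ndarray]
    hap_b_allele: dict[str, np.ndarray]
    hap_a_is_ref: dict[str, np.ndarray]
    # haplotype sequences in compressed space
    hap_a_seq: dict[str, np.ndarray] = field(default_factory=dict)  # uint8
    hap_b_seq: dict[str, np.ndarray] = field(default_factory=dict)
    decoys: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )  # positions, ref uint8, alt uint8

    def chrom_sizes_original(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.references.items()}

    def write_reference(self, path: str) -> None:
        _write_fasta(path, {c: s for c, s in self.references.items()})

    def write_compressed_reference(self, path: str) -> None:
        _write_fasta(path, {c: cs.seq for c, cs in self.compressed.items()})

    def write_phased_vcf(self, path: str, rng: Optional[np.random.Generator] = None) -> None:
        """Phased VCF on the compressed reference, true sites plus decoys.

        True heterozygous sites draw their quality from the high mode of
        the bimodal quality distribution, decoy (error) records from the
        low mode; the QC stage is expected to recover the valley cutoff
        and discard the decoys.
        """
        if rng is None:
            rng = np.random.default_rng(self.config.seed + 7)
        header = pysam.VariantHeader()
        header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">')
        for chrom, cs in self.compressed.items():
            header.contigs.add(chrom, length=len(cs))
        header.add_sample("gametes")
        mu_t, sd_t = self.config.qual_true
        mu_d, sd_d = self.config.qual_decoy
        with pysam.VariantFile(path, "w", header=header) as out:
            for chrom, cs in self.compressed.items():
                pos = self.site_positions[chrom]
                ref = np.frombuffer(cs.seq.encode(), dtype=np.uint8)[pos]
                a_is_ref = self.hap_a_is_ref[chrom]
                alt = np.where(a_is_ref, self.hap_b_seq[chrom][pos], self.hap_a_seq[chrom][pos])
                qual_t = np.maximum(rng.normal(mu_t, sd_t, len(pos)), 1.0)
                dpos, dref, dalt = self.decoys.get(
                    chrom, (np.empty(0, np.int64), np.empty(0, np.uint8), np.empty(0, np.uint8))
                )
                qual_d = np.maximum(rng.normal(mu_d, sd_d, len(dpos)), 1.0)
                records = sorted(
                    [(int(p), chr(r), chr(al), float(q), bool(ar), True)
                     for p, r, al, q, ar in zip(pos, ref, alt, qual_t, a_is_ref)]
                    + [(int(p), chr(r), chr(al), float(q), bool(rng.random() < 0.5), False)
                       for p, r, al, q in zip(dpos, dref, dalt, qual_d)]
                )
                for p, r, al, q, a_ref, _true in records:
                    rec = out.new_record(
                        contig=chrom, start=p, stop=p + 1, alleles=(r, al), qual=q
                    )
                    rec.samples["gametes"]["GT"] = (0, 1) if a_ref else (1, 0)
                    rec.samples["gametes"].phased = True
                    rec.samples["gametes"]["PS"] = 1
                    out.write(rec)


def haplotype_tables_from_genome(genome: "SimulatedGenome"):
    """True haplotype tables straight from the simulated phasing.

    Bypasses the VCF/QC round trip; used to study the detection step in
    isolation (e.g. the noiseless limit).
    """
    from gametecross.haplotypes import HaplotypeTable

    tables = {}
    for chrom, pos in genome.site_positions.items():
        tables[chrom] = HaplotypeTable(
            chrom,
            pos,
            np.array([chr(b) for b in genome.hap_a_allele[chrom]], dtype="U1"),
            np.array([chr(b) for b in genome.hap_b_allele[chrom]], dtype="U1"),
            np.zeros(len(pos), dtype=np.int64),
        )
    return tables


def _write_fasta(path: str, seqs: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as out:
        for name, seq in seqs.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def _random_compressed_skeleton(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random base indices 0-3 with no two adjacent equal."""
    first = rng.integers(0, 4, 1)
    steps = rng.integers(1, 4, n - 1)
    return np.concatenate([first, steps]).cumsum() % 4


def simulate_genome(config: SimConfig, rng: Optional[np.random.Generator] = None) -> SimulatedGenome:
    """Generate reference, haplotype pair and phased heterozygous SNVs.

    The reference is built from a homopolymer-free skeleton expanded with
    geometric run lengths, so compression statistics resemble a real
    genome.  SNV sites are placed with exponential spacing (mean
    ``snv_spacing`` original bases), mapped to compressed coordinates, and
    given an alternate allele that differs from both compressed neighbours
    so both haplotypes compress to the same coordinate system.  Alleles
    alternate randomly between haplotypes; the phased VCF reproduces the
    haplotype pair exactly, plus low-quality decoy records for the QC
    stage to remove.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cfg = config
    references: dict[str, str] = {}
    compressed: dict[str, CompressedSequence] = {}
    site_positions: dict[str, np.ndarray] = {}
    hap_a_allele: dict[str, np.ndarray] = {}
    hap_b_allele: dict[str, np.ndarray] = {}
    hap_a_is_ref: dict[str, np.ndarray] = {}
    hap_a_seq: dict[str, np.ndarray] = {}
    hap_b_seq: dict[str, np.ndarray] = {}
    decoys: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    chrom_len = cfg.genome_length // cfg.n_chromosomes
    mean_run = 1.0 / (1.0 - cfg.homopolymer_geom_p)
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n_comp_guess = int(chrom_len / mean_run * 1.1) + 100
        skel = _random_compressed_skeleton(rng, n_comp_guess)
        runs = rng.geometric(1.0 - cfg.homopolymer_geom_p, n_comp_guess)
        ends = runs.cumsum()
        cut = int(np.searchsorted(ends, chrom_len, side="left"))
        runs = runs[: cut + 1].copy()
        skel = skel[: cut + 1]
        runs[-1] -= int(ends[cut] - chrom_len)
        if runs[-1] <= 0:  # defensive; searchsorted('left') should prevent this
            runs, skel = runs[:-1], skel[:-1]
        seq_u8 = np.repeat(_BASES[skel], runs)
        ref = seq_u8.tobytes().decode("ascii")
        cs = compress_sequence(ref, name=chrom)
        assert len(cs) == len(skel)

        # SNV sites: exponential spacing in original coordinates
        n_guess = int(chrom_len / cfg.snv_spacing * 1.5) + 50
        gaps = rng.exponential(cfg.snv_spacing, n_guess)
        orig_pos = np.unique(np.floor(gaps.cumsum()).astype(np.int64))
        orig_pos = orig_pos[orig_pos < chrom_len - 1]
        cpos = np.searchsorted(cs.run_starts, orig_pos, side="right") - 1
        cpos = np.unique(cpos)
        cpos = cpos[(cpos > 0) & (cpos < len(cs) - 1)]
        # keep sites non-adjacent in compressed space so each alternate
        # allele sits between untouched reference bases on both haplotypes
        if len(cpos) > 1:
            cpos = cpos[np.diff(cpos, prepend=cpos[0] - 2) >= 2]

        comp_u8 = np.frombuffer(cs.seq.encode(), dtype=np.uint8)
        ref_b = comp_u8[cpos]
        left_b = comp_u8[cpos - 1]
        right_b = comp_u8[cpos + 1]
        # alternate allele differing from ref and both compressed neighbours
        scores = rng.random((len(cpos), 4))
        cand = np.broadcast_to(_BASES, (len(cpos), 4))
        invalid = (
            (cand == ref_b[:, None])
            | (cand == left_b[:, None])
            | (cand == right_b[:, None])
        )
        scores = np.where(invalid, np.inf, scores)
        alt_b = _BASES[np.argmin(scores, axis=1)]

        a_is_ref = rng.random(len(cpos)) < 0.5
        a_alleles = np.where(a_is_ref, ref_b, alt_b)
        b_alleles = np.where(a_is_ref, alt_b, ref_b)
        hap_a = comp_u8.copy()
        hap_b = comp_u8.copy()
        hap_a[cpos] = a_alleles
        hap_b[cpos] = b_alleles

        # decoy (error) records at non-site positions, low quality
        n_decoy = int(len(cpos) * cfg.decoy_variant_fraction)
        pool = rng.integers(1, len(cs) - 1, n_decoy * 2)
        pool = np.unique(pool)
        pool = pool[~np.isin(pool, cpos)][:n_decoy]
        dref = comp_u8[pool]
        shift = rng.integers(1, 4, len(pool))
        dalt = _BASES[(np.searchsorted(_BASES, dref) + shift) % 4]

        references[chrom] = ref
        compressed[chrom] = cs
        site_positions[chrom] = cpos
        hap_a_allele[chrom] = a_alleles
        hap_b_allele[chrom] = b_alleles
        hap_a_is_ref[chrom] = a_is_ref
        hap_a_seq[chrom] = hap_a
        hap_b_seq[chrom] = hap_b
        decoys[chrom] = (pool, dref, dalt)

    pmap = PositionMap.from_genome(compressed)
    return SimulatedGenome(
        cfg, references, compressed, pmap, site_positions,
        hap_a_allele, hap_b_allele, hap_a_is_ref, hap_a_seq, hap_b_seq, decoys,
    )


def _choose_breakpoint(
    rng: np.random.Generator,
    cstart: int,
    cend: int,
    sites: np.ndarray,
    min_flank: int,
) -> int:
    """Compressed breakpoint for a recombinant template.

    The template carries the source haplotype on ``[cstart, bp)`` and the
    other haplotype on ``[bp, cend)``.  With ``min_flank`` > 0 the
    breakpoint is drawn between two sites leaving at least that many sites
    on each side; otherwise it is uniform over the interior.  Returns -1
    when no valid breakpoint exists.
    """
    if cend - cstart < 3:
        return -1
    if min_flank <= 0:
        return int(rng.integers(cstart + 1, cend - 1))
    lo = np.searchsorted(sites, cstart, side="left")
    hi = np.searchsorted(sites, cend, side="left")
    inside = sites[lo:hi]
    if len(inside) < 2 * min_flank:
        return -1
    j = int(rng.integers(min_flank - 1, len(inside) - min_flank))
    # midpoint of the inter-site gap, strictly right of site j so the left
    # flank keeps its min_flank sites
    return max(int((inside[j] + inside[j + 1]) // 2), int(inside[j]) + 1)


def simulate_reads(
    config: SimConfig,
    genome: SimulatedGenome,
    bam_out: str,
    fastq_out: Optional[str] = None,
    truth_out: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
    bam_compression: Optional[int] = None,
) -> pd.DataFrame:
    """Draw the read pool and write a coordinate-sorted BAM plus truth set.

    Read original-coordinate lengths are normal (``read_length_mean`` +-
    sd, floored at ``read_length_min``); starts are uniform.  Each read is
    taken from haplotype A, haplotype B, or — with probability
    ``recomb_fraction`` — a recombinant template switching haplotype at an
    internal breakpoint.  Errors are injected in compressed space with the
    configured rates (indel probability multiplied inside homopolymer
    runs) and the CIGAR records the truthful alignment, so no external
    aligner is needed.  Returns the truth table (one row per read).
    """
    cfg = config
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [
                {"SN": chrom, "LN": len(cs)} for chrom, cs in genome.compressed.items()
            ],
        }
    )
    truth_rows = []
    fastq_fh = open(fastq_out, "w") if fastq_out else None
    n_total = 0
    mode = "wb" if bam_compression is None else f"wb{bam_compression}"
    with pysam.AlignmentFile(bam_out, mode, header=header) as out:
        for tid, (chrom, cs) in enumerate(genome.compressed.items()):
            ref_len_orig = genome.chrom_sizes_original()[chrom]
            n_reads = int(round(cfg.depth * ref_len_orig / cfg.read_length_mean))
            lengths = np.maximum(
                rng.normal(cfg.read_length_mean, cfg.read_length_sd, n_reads),
                cfg.read_length_min,
            ).astype(np.int64)
            lengths = np.minimum(lengths, ref_len_orig)
            starts = rng.integers(0, ref_len_orig - lengths + 1)
            order = np.argsort(starts, kind="stable")
            starts, lengths = starts[order], lengths[order]
            is_rec = rng.random(n_reads) < cfg.recomb_fraction
            src_a = rng.random(n_reads) < 0.5
            run_starts = cs.run_starts
            run_lengths = cs.run_lengths
            hap = {True: genome.hap_a_seq[chrom], False: genome.hap_b_seq[chrom]}
            sites = genome.site_positions[chrom]
            in_homopolymer = run_lengths > 1
            for i in range(n_reads):
                cstart = int(np.searchsorted(run_starts, starts[i], side="right") - 1)
                cend = int(
                    np.searchsorted(run_starts, starts[i] + lengths[i] - 1, side="right")
                )
                rec = bool(is_rec[i])
                bp = -1
                if rec:
                    bp = _choose_breakpoint(
                        rng, cstart, cend, sites, cfg.breakpoint_min_flank_sites
                    )
                    rec = bp >= 0
                if rec:
                    template = np.concatenate(
                        [hap[bool(src_a[i])][cstart:bp], hap[not src_a[i]][bp:cend]]
                    )
                    source = "AB" if src_a[i] else "BA"
                else:
                    template = hap[bool(src_a[i])][cstart:cend].copy()
                    source = "A" if src_a[i] else "B"
                read_id = f"{chrom}_read{n_total}"
                aln = _noisy_alignment(
                    rng, cfg, template, cstart, in_homopolymer[cstart:cend]
                )
                if aln is None:
                    rec, bp, source = False, -1, source  # degenerate, still recorded
                    seq = None
                else:
                    seq, quals, cigar, pos_shift = aln
                    a = pysam.AlignedSegment(header=header)
                    a.query_name = read_id
                    a.query_sequence = seq
                    a.query_qualities = pysam.qualitystring_to_array(quals)
                    a.flag = 0
                    a.reference_id = tid
                    a.reference_start = cstart + pos_shift
                    a.mapping_quality = 60
                    a.cigartuples = cigar
                    out.write(a)
                    if fastq_fh is not None:
                        fastq_fh.write(f"@{read_id}\n{seq}\n+\n{quals}\n")
                truth_rows.append(
                    {
                        "read_id": read_id,
                        "chrom": chrom,
                        "source": source,
                        "recombinant": rec,
                        "breakpoint_comp": bp,
                        "breakpoint_orig": int(run_starts[bp]) if bp >= 0 else -1,
                        "comp_start": cstart,
                        "comp_end": cend,
                        "aligned": seq is not None,
                    }
                )
                n_total += 1
    if fastq_fh is not None:
        fastq_fh.close()
    truth = pd.DataFrame(truth_rows)
    if truth_out:
        truth.to_csv(truth_out, sep="\t", index=False)
    logger.info(
        "simulated %d reads (%d recombinant)", len(truth), int(truth["recombinant"].sum())
    )
    return truth


def _noisy_alignment(
    rng: np.random.Generator,
    cfg: SimConfig,
    template: np.ndarray,
    cstart: int,
    in_homopolymer: np.ndarray,
):
    """Inject substitution/indel errors; return (seq, quals, cigar, pos_shift).

    Operates on the compressed-space template (uint8).  Deletion and
    insertion probabilities are multiplied by ``homopolymer_indel_mult`` at
    positions whose original run length exceeds one.  The CIGAR is the
    truthful alignment of the noisy read to ``[cstart, cstart+len)`` on the
    compressed reference; leading/trailing deletions are converted into a
    start shift / span reduction.  Returns None if every base is deleted.
    """
    m = len(template)
    if m == 0:
        return None
    mult = np.where(in_homopolymer, cfg.homopolymer_indel_mult, 1.0)
    p_del = np.minimum(cfg.del_rate * mult, 0.9)
    p_ins = np.minimum(cfg.ins_rate * mult, 0.9)
    deleted = rng.random(m) < p_del
    if deleted.all():
        return None
    bases = template.copy()
    sub = (~deleted) & (rng.random(m) < cfg.sub_rate)
    if sub.any():
        shift = rng.integers(1, 4, int(sub.sum()))
        idx = np.searchsorted(_BASES, bases[sub])
        bases[sub] = _BASES[(idx + shift) % 4]
    ops = np.where(deleted, 2, 0).astype(np.int8)  # 2=D, 0=M
    ins_after = rng.random(m) < p_ins
    ins_idx = np.flatnonzero(ins_after)
    if len(ins_idx):
        ins_bases = _BASES[rng.integers(0, 4, len(ins_idx))]
        ops = np.insert(ops, ins_idx + 1, np.int8(1))  # 1=I
        bases = np.insert(bases, ins_idx + 1, ins_bases)
    # trim leading/trailing deletions (alignments cannot start/end with D)
    non_del = np.flatnonzero(ops != 2)
    first, last = int(non_del[0]), int(non_del[-1])
    pos_shift = int((ops[:first] == 2).sum())
    ops = ops[first : last + 1]
    bases = bases[first : last + 1]
    # a leading insertion has nothing to anchor to; make it a soft clip
    if ops[0] == 1:
        lead = int(np.argmax(ops != 1)) if (ops != 1).any() else len(ops)
        ops[:lead] = 4  # S
    if ops[-1] == 1:
        tail = int(np.argmax(ops[::-1] != 1))
        ops[len(ops) - tail :] = 4
    seq = bases[ops != 2].tobytes().decode("ascii")
    # run-length encode the op string into CIGAR tuples
    change = np.flatnonzero(np.diff(ops)) + 1
    bounds = np.concatenate(([0], change, [len(ops)]))
    cigar = list(
        zip(
            ops[bounds[:-1]].tolist(),
            np.diff(bounds).tolist(),
        )
    )
    quals = (rng.integers(12, 31, len(seq)) + 33).astype(np.uint8).tobytes().decode("ascii")
    return seq, quals, cigar, pos_shift


@dataclass
class EvalMetrics:
    """Detection performance against the simulated truth."""

    accuracy: float                # sensitivity over truly recombinant reads
    error_rate: float              # false calls over truly non-recombinant reads
    n_true_recombinant: int
    n_true_nonrecombinant: int
    n_called_recombinant: int
    n_true_positive: int
    n_false_positive: int
    mean_breakpoint_error: float   # original bases, true positives only

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def evaluate(calls: pd.DataFrame, truth: pd.DataFrame) -> EvalMetrics:
    """Score a crossover-call table against the truth set.

    ``accuracy`` (sensitivity) is the fraction of truly recombinant
    molecules among which at least one call survives; ``error_rate`` is
    the fraction of truly non-recombinant molecules that received a call.
    The mean breakpoint localisation error is the distance (original
    bases) from the true breakpoint to the reported switch interval, zero
    when the interval contains it.
    """
    called = set(calls["read_id"]) if len(calls) else set()
    known = set(truth["read_id"])
    stray = called - known
    if stray:
        raise ValueError(
            f"calls contain read ids absent from the truth set, e.g. {sorted(stray)[:3]}"
        )
    is_rec = truth.set_index("read_id")["recombinant"]
    rec_ids = set(is_rec[is_rec].index)
    nonrec_ids = known - rec_ids
    tp = called & rec_ids
    fp = called & nonrec_ids
    accuracy = len(tp) / len(rec_ids) if rec_ids else float("nan")
    error_rate = len(fp) / len(nonrec_ids) if nonrec_ids else float("nan")

    bp_err = float("nan")
    if len(calls) and tp:
        merged = calls.merge(
            truth[["read_id", "breakpoint_orig", "recombinant"]], on="read_id"
        )
        merged = merged[merged["recombinant"]]
        lo = merged["orig_start"].to_numpy(float)
        hi = merged["orig_end"].to_numpy(float)
        b = merged["breakpoint_orig"].to_numpy(float)
        dist = np.maximum.reduce([lo - b, b - hi, np.zeros(len(merged))])
        # one distance per read: the best-localised call
        per_read = pd.Series(dist).groupby(merged["read_id"].to_numpy()).min()
        bp_err = float(per_read.mean())
    return EvalMetrics(
        accuracy=accuracy,
        error_rate=error_rate,
        n_true_recombinant=len(rec_ids),
        n_true_nonrecombinant=len(nonrec_ids),
        n_called_recombinant=len(called),
        n_true_positive=len(tp),
        n_false_positive=len(fp),
        mean_breakpoint_error=bp_err,
    )


def _derived_seed(*entropy: int) -> int:
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31))


def run_cell(
    config: SimConfig,
    workdir: Path,
    genome: Optional[SimulatedGenome] = None,
    options: DetectOptions = DetectOptions(),
    low_mult: float = 0.25,
    high_mult: float = 2.0,
) -> tuple[EvalMetrics, pd.DataFrame]:
    """Full pipeline on one simulated condition; returns metrics and kept calls.

    Stages: simulate genome and reads -> alignment filter -> variant-quality
    cutoff and filters -> haplotype loading -> sliding-window detection ->
    coverage filter -> evaluation against truth.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if genome is None:
        genome = simulate_genome(config, np.random.default_rng(config.seed))
    raw_bam = str(workdir / "reads.bam")
    truth = simulate_reads(
        config, genome, raw_bam,
        rng=np.random.default_rng(config.seed + 1),
        bam_compression=0,  # temp intermediates: skip BGZF compression
    )
    filt_bam = str(workdir / "reads.filtered.bam")
    variant_qc.filter_alignments(raw_bam, filt_bam, min_mapq=60, bam_compression=0)

    vcf_raw = str(workdir / "variants.vcf")
    genome.write_phased_vcf(vcf_raw, rng=np.random.default_rng(config.seed + 2))
    with pysam.VariantFile(vcf_raw) as vf:
        quals = [rec.qual for rec in vf if rec.qual is not None]
    cutoff = variant_qc.find_quality_cutoff(quals)
    vcf_filtered = str(workdir / "variants.filtered.vcf")
    variant_qc.filter_variants(vcf_raw, vcf_filtered, cutoff)

    tables = load_haplotypes(vcf_filtered)
    calls, _summary = detect_all(
        filt_bam, tables, options=options, position_map=genome.position_map
    )
    profile = cov.compute_depth(filt_bam)
    kept, _removed = cov.filter_by_coverage(calls, profile, low_mult, high_mult)
    return evaluate(kept, truth), kept


def run_grid(
    spacings: Sequence[float] = (100.0, 200.0, 300.0),
    depths: Sequence[float] = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0),
    reps: int = 3,
    seed: int = 0,
    base_config: Optional[SimConfig] = None,
    workdir: Optional[str] = None,
    figure_out: Optional[str] = None,
) -> pd.DataFrame:
    """Sweep variant density x depth over the full pipeline.

    For each (spacing, replicate) one genome is simulated and reused
    across depths; every cell runs the complete pipeline and is scored
    against its truth set.  Returns one row per (spacing, depth, rep) with
    accuracy, error rate and counts; all randomness derives from ``seed``.
    """
    import tempfile

    if base_config is None:
        base_config = SimConfig()
    rows = []
    with tempfile.TemporaryDirectory(dir=workdir) as tmp:
        tmp = Path(tmp)
        for si, spacing in enumerate(spacings):
            for rep in range(reps):
                gseed = _derived_seed(seed, si, rep)
                genome_cfg = replace(base_config, snv_spacing=float(spacing), seed=gseed)
                genome = simulate_genome(genome_cfg, np.random.default_rng(gseed))
                for di, depth in enumerate(depths):
                    cseed = _derived_seed(seed, si, rep, di + 100)
                    cfg = replace(genome_cfg, depth=float(depth), seed=cseed)
                    cell_dir = tmp / f"s{si}_r{rep}_d{di}"
                    metrics, _ = run_cell(cfg, cell_dir, genome=genome)
                    rows.append(
                        {
                            "snv_spacing": float(spacing),
                            "depth": float(depth),
                            "rep": rep,
                            **metrics.as_dict(),
                        }
                    )
                    logger.info(
                        "grid cell spacing=%g depth=%g rep=%d: acc=%.4f err=%.5f",
                        spacing, depth, rep, metrics.accuracy, metrics.error_rate,
                    )
    results = pd.DataFrame(rows)
    if figure_out:
        plot_grid(results, figure_out)
    return results


def summarize_grid(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate replicates: mean and binomial SE per (spacing, depth) cell."""
    def agg(sub: pd.DataFrame) -> pd.Series:
        n_rec = sub["n_true_recombinant"].sum()
        n_non = sub["n_true_nonrecombinant"].sum()
        tp = sub["n_true_positive"].sum()
        fp = sub["n_false_positive"].sum()
        acc = tp / n_rec if n_rec else np.nan
        err = fp / n_non if n_non else np.nan
        return pd.Series(
            {
                "accuracy": acc,
                "accuracy_se": np.sqrt(max(acc * (1 - acc), 1e-12) / n_rec) if n_rec else np.nan,
                "error_rate": err,
                "error_rate_se": np.sqrt(max(err * (1 - err), 1e-12) / n_non) if n_non else np.nan,
                "n_true_recombinant": n_rec,
                "n_true_nonrecombinant": n_non,
            }
        )

    return (
        results.groupby(["snv_spacing", "depth"])
        .apply(agg, include_groups=False)
        .reset_index()
    )


def plot_grid(results: pd.DataFrame, out_image: str) -> None:
    """Accuracy (top) and error-rate (bottom) panels versus depth."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    summary = summarize_grid(results)
    fig, (ax_acc, ax_err) = plt.subplots(2, 1, figsize=(7, 7), sharex=True)
    for spacing, sub in summary.groupby("snv_spacing"):
        label = f"1 SNV / {spacing:g} bp"
        ax_acc.errorbar(
            sub["depth"], sub["accuracy"], yerr=1.96 * sub["accuracy_se"],
            marker="o", capsize=3, label=label,
        )
        ax_err.errorbar(
            sub["depth"], sub["error_rate"], yerr=1.96 * sub["error_rate_se"],
            marker="o", capsize=3, label=label,
        )
    ax_acc.set_ylabel("accuracy (sensitivity)")
    ax_err.set_ylabel("error rate")
    ax_err.set_xlabel("mean sequencing depth (x)")
    ax_acc.legend(frameon=False, fontsize=9)
    fig.tight_layout()
    Path(out_image).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_image, dpi=120)
    plt.close(fig)
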