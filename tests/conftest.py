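"""Shared fixtures: tiny simulated gamete pools and hand-built file fixtures."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam
import pytest

from gametecross import simulator as sim


@pytest.fixture(scope="session")
def small_pool(tmp_path_factory):
    """A small noisy gamete pool with files on disk (shared, read-only)."""
    out = tmp_path_factory.mktemp("small_pool")
    cfg = sim.SimConfig(
        genome_length=400_000, depth=8.0, snv_spacing=100.0,
        recomb_fraction=0.3, seed=7,
    )
    genome = sim.simulate_genome(cfg, np.random.default_rng(cfg.seed))
    bam = out / "reads.bam"
    truth = sim.simulate_reads(
        cfg, genome, str(bam), rng=np.random.default_rng(cfg.seed + 1)
    )
    vcf = out / "phased.vcf"
    genome.write_phased_vcf(str(vcf), rng=np.random.default_rng(cfg.seed + 2))
    return {
        "config": cfg, "genome": genome, "bam": str(bam),
        "vcf": str(vcf), "truth": truth, "dir": out,
    }


def make_sam(path: str | Path, records: list[dict], chrom_lengths: dict[str, int]):
    """Write a coordinate-sorted BAM/SAM from simple record dicts."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths.items()],
        }
    )
    mode = "wb" if str(path).endswith(".bam") else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for rec in records:
            a = pysam.AlignedSegment(header=header)
            a.query_name = rec["name"]
            a.query_sequence = rec.get("seq", "A" * rec.get("length", 10))
            a.flag = rec.get("flag", 0)
            a.reference_id = list(chrom_lengths).index(rec.get("chrom", "chr1"))
            a.reference_start = rec["pos"]
            a.mapping_quality = rec.get("mapq", 60)
            a.cigartuples = rec.get("cigar", [(0, len(a.query_sequence))])
            a.query_qualities = pysam.qualitystring_to_array("I" * len(a.query_sequence))
            out.write(a)
    return str(path)


def make_vcf(path: str | Path, rows: list[tuple], contigs: dict[str, int]):
    """Write a single-sample VCF.

    Row format: (chrom, pos0, ref, alt, qual, gt, phased) where gt is a
    tuple like (0, 1).
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">')
    for c, ln in contigs.items():
        header.contigs.add(c, length=ln)
    header.add_sample("s1")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for chrom, pos0, ref, alt, qual, gt, phased in rows:
            rec = out.new_record(
                contig=chrom, start=pos0, stop=pos0 + len(ref),
                alleles=(ref, alt), qual=qual,
            )
            rec.samples["s1"]["GT"] = gt
            rec.samples["s1"].phased = phased
            out.write(rec)
    return str(path)
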