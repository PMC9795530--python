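"""End-to-end pipeline orchestration.

Runs the stages in order on real inputs (reference FASTA, gamete-pool
reads/alignments, phased VCF): build the compressed-coordinate map, filter
alignments, QC variants, load haplotypes, detect phase switches, filter by
coverage, lift to original coordinates and bin the landscape.  Every stage
logs its input/output counts and the resolved configuration is written next
to the outputs for provenance.

Upstream steps that belong to external tools — alignment (e.g. minimap2
against the compressed reference), variant calling, and phasing (for which
a maximum-coverage setting of 20 keeps runtime reasonable on gamete pools)
— are consumed as files, not reimplemented.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pysam

from gametecross import coverage as cov
from gametecross import landscape as lsc
from gametecross import variant_qc
from gametecross.crossover import DetectOptions, detect_all
from gametecross.haplotypes import load_haplotypes
from gametecross.hpc import build_position_map

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and parameters of one pipeline run.

    Defaults are the published operating point of the method: MAPQ >= 60,
    cluster filter 10 bp span / max 3, 7-site windows (flank 3) with at
    least 5 informative sites and +-4/6 thresholds, 0.25-2x coverage band,
    1 Mb landscape windows, sex chromosomes excluded.
    """

    reference_fasta: str = ""
    bam: str = ""
    phased_vcf: str = ""
    out_dir: str = "gametecross_out"

    min_mapq: int = 60
    qual_cutoff: Optional[float] = None  # None = derive from the VCF qualities
    cluster_span: int = 10
    cluster_max: int = 3
    window_flank: int = 3
    min_represented: int = 5
    threshold_num: int = 4
    threshold_den: int = 6
    low_mult: float = 0.25
    high_mult: float = 2.0
    window_size: int = 1_000_000
    exclude_chroms: tuple[str, ...] = tuple(sorted(lsc.DEFAULT_EXCLUDE))
    seed: int = 0

    def validate(self) -> None:
        for name in ("reference_fasta", "bam", "phased_vcf"):
            path = getattr(self, name)
            if not path or not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path!r} does not exist")
        if not 0 < self.threshold_num <= self.threshold_den:
            raise ValueError("phase threshold must be a fraction in (0, 1]")
        if self.min_mapq < 0 or self.cluster_span <= 0 or self.window_size <= 0:
            raise ValueError("min_mapq, cluster_span and window_size must be positive")
        if not 0 <= self.low_mult <= self.high_mult:
            raise ValueError("need 0 <= low_mult <= high_mult")

    def detect_options(self) -> DetectOptions:
        return DetectOptions(
            window_flank=self.window_flank,
            min_represented=self.min_represented,
            threshold_num=self.threshold_num,
            threshold_den=self.threshold_den,
        )


def _stage(name: str):
    logger.info("stage %s: start", name)
    return time.perf_counter()


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory.

    Outputs: ``events.tsv``/``events.bed`` (kept crossover calls, original
    coordinates), ``events.removed.tsv``, ``landscape.tsv`` and
    ``landscape.png``, ``position_map.tsv.gz`` and ``config.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=2, default=str) + "\n"
    )

    t = _stage("compress-map")
    pmap = build_position_map(config.reference_fasta, out / "position_map.tsv.gz")
    logger.info(
        "stage compress-map: %d chromosomes mapped (%.1fs)",
        len(pmap.chroms), time.perf_counter() - t,
    )

    t = _stage("filter-alignments")
    filt_bam = str(out / "filtered.bam")
    kept, removed = variant_qc.filter_alignments(config.bam, filt_bam, config.min_mapq)
    logger.info(
        "stage filter-alignments: kept %d, removed %d (%.1fs)",
        kept, removed, time.perf_counter() - t,
    )

    t = _stage("filter-variants")
    cutoff = config.qual_cutoff
    if cutoff is None:
        with pysam.VariantFile(config.phased_vcf) as vf:
            quals = [r.qual for r in vf if r.qual is not None]
        cutoff = variant_qc.find_quality_cutoff(quals)
    filt_vcf = str(out / "filtered.vcf")
    vkept, vremoved = variant_qc.filter_variants(
        config.phased_vcf, filt_vcf, cutoff, config.cluster_span, config.cluster_max
    )
    logger.info(
        "stage filter-variants: cutoff %.1f, kept %d, removed %d (%.1fs)",
        cutoff, vkept, vremoved, time.perf_counter() - t,
    )

    t = _stage("load-haplotypes")
    tables = load_haplotypes(filt_vcf)
    logger.info(
        "stage load-haplotypes: %d chromosomes, %d sites (%.1fs)",
        len(tables), sum(len(t_) for t_ in tables.values()), time.perf_counter() - t,
    )

    t = _stage("detect")
    calls, summary = detect_all(
        filt_bam, tables, options=config.detect_options(), position_map=pmap
    )
    summary.to_csv(out / "read_summary.tsv", sep="\t", index=False)
    logger.info(
        "stage detect: %d candidate switches on %d reads (%.1fs)",
        len(calls), int(summary["recombinant"].sum()) if len(summary) else 0,
        time.perf_counter() - t,
    )

    t = _stage("filter-coverage")
    profile = cov.compute_depth(filt_bam)
    kept_calls, removed_calls = cov.filter_by_coverage(
        calls, profile, config.low_mult, config.high_mult
    )
    kept_calls.to_csv(out / "events.tsv", sep="\t", index=False)
    removed_calls.to_csv(out / "events.removed.tsv", sep="\t", index=False)
    with open(out / "events.bed", "w") as bed:
        for row in kept_calls.itertuples(index=False):
            bed.write(f"{row.chrom}\t{row.orig_start}\t{row.orig_end}\t{row.read_id}\n")
    logger.info(
        "stage filter-coverage: kept %d, removed %d (median depth %.1f) (%.1fs)",
        len(kept_calls), len(removed_calls), profile.genome_median,
        time.perf_counter() - t,
    )

    t = _stage("landscape")
    sizes = {c: pmap.original_length(c) for c in pmap.chroms}
    table = lsc.build_landscape(
        kept_calls, sizes, config.window_size, exclude=config.exclude_chroms
    )
    table.to_csv(out / "landscape.tsv", sep="\t", index=False)
    if len(table):
        lsc.plot_landscape(table, str(out / "landscape.png"))
    logger.info(
        "stage landscape: %d windows, %s events binned (%.1fs)",
        len(table), table["crossover_count"].sum() if len(table) else 0,
        time.perf_counter() - t,
    )
    return out
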