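"""Alignment and variant quality control.

Long-read alignments against the compressed reference carry multiple and
low-quality placements, and the variant caller emits a characteristically
bimodal quality distribution: a low mode of error-driven calls and a high
mode of real heterozygous sites.  The filters here reduce both inputs to the
high-confidence set the crossover caller assumes:

* alignments: drop secondary/supplementary records and mapping quality
  below 60;
* variants: drop quality below an automatically chosen cutoff (the valley
  between the two quality modes plus 50), non-SNV and multiallelic records,
  and clustered variants (any window of 10 bases holding more than 3
  variants is removed wholesale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pysam
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde

__all__ = [
    "VariantRecord",
    "filter_alignments",
    "find_quality_cutoff",
    "filter_clustered",
    "filter_variants",
]

SECONDARY = 0x100
SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNV candidate in compressed-genome coordinates (0-based)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    qual: float
    genotype: tuple[int, int] = (0, 1)
    phased: bool = False

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if self.qual < 0:
            raise ValueError(f"negative quality at {self.chrom}:{self.pos}")


def filter_alignments(
    bam_in: str,
    bam_out: str,
    min_mapq: int = 60,
    bam_compression: int | None = None,
) -> tuple[int, int]:
    """Remove multiple alignments and low mapping quality records.

    Secondary (0x100) and supplementary (0x800) records are dropped, as is
    any record with ``MAPQ < min_mapq``.  Surviving records are written
    unchanged, in input (coordinate-sorted) order.  Returns
    ``(kept, removed)``.
    """
    with pysam.AlignmentFile(bam_in, check_sq=False) as fin:
        order = (fin.header.get("HD") or {}).get("SO", "unknown")
        if order != "coordinate":
            raise ValueError(
                f"{bam_in}: expected a coordinate-sorted input (HD SO tag is {order!r})"
            )
        if str(bam_out).endswith(".bam"):
            mode = "wb" if bam_compression is None else f"wb{bam_compression}"
        else:
            mode = "w"
        kept = removed = 0
        with pysam.AlignmentFile(bam_out, mode, template=fin) as fout:
            for rec in fin:
                if (
                    rec.is_secondary
                    or rec.is_supplementary
                    or rec.is_unmapped
                    or rec.mapping_quality < min_mapq
                ):
                    removed += 1
                else:
                    fout.write(rec)
                    kept += 1
    return kept, removed


def find_quality_cutoff(qual_values: Sequence[float], offset: float = 50.0) -> float:
    """Locate the valley between the two variant-quality modes, plus an offset.

    The quality distribution of long-read variant calls is typically
    bimodal: error-driven calls form a low mode, real variants a high one.
    The density is estimated with a Gaussian kernel (Scott bandwidth); the
    two highest local maxima are taken as the modes and the density minimum
    between them as the valley.  Returned threshold is ``valley + offset``.

    If fewer than two modes are found (unimodal or degenerate input), falls
    back to the 5th percentile of the qualities with a warning; the caller
    then keeps essentially everything, which is the conservative choice when
    the bimodal structure the rule assumes is absent.
    """
    q = np.asarray(qual_values, dtype=float)
    if q.size == 0:
        raise ValueError("cannot choose a quality cutoff from an empty list")
    if q.size < 2 or np.ptp(q) == 0:
        warnings.warn("quality distribution degenerate; falling back to 5th percentile")
        return float(np.percentile(q, 5.0))
    kde = gaussian_kde(q)
    grid = np.linspace(q.min(), q.max(), 512)
    dens = kde(grid)
    # pad with -inf so modes at the grid edges are detected too; demand a
    # minimum prominence so tail wiggles of a unimodal density do not count
    padded = np.concatenate(([-np.inf], dens, [-np.inf]))
    peaks, _ = find_peaks(padded, prominence=0.05 * dens.max())
    peaks -= 1
    if len(peaks) < 2:
        warnings.warn("quality distribution unimodal; falling back to 5th percentile")
        return float(np.percentile(q, 5.0))
    top2 = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = int(top2.min()), int(top2.max())
    valley = grid[lo + int(np.argmin(dens[lo : hi + 1]))]
    return float(valley) + offset


def filter_clustered(
    variants: Sequence[VariantRecord], span: int = 10, max_in_span: int = 3
) -> list[VariantRecord]:
    """Drop every variant in any dense same-chromosome window.

    A window of ``span`` bases (both ends inclusive: positions ``p`` and
    ``p + span - 1`` are within the window) containing more than
    ``max_in_span`` variants is an error cluster; all of its members are
    removed, not just the excess.  Input must be sorted by (chrom, pos);
    output stays sorted.  Idempotent.
    """
    keys = [(v.chrom, v.pos) for v in variants]
    if keys != sorted(keys):
        raise ValueError("variants must be sorted by (chrom, pos)")
    doomed = np.zeros(len(variants), dtype=bool)
    i = 0
    n = len(variants)
    while i < n:
        j = i
        while (
            j < n
            and variants[j].chrom == variants[i].chrom
            and variants[j].pos <= variants[i].pos + span - 1
        ):
            j += 1
        if j - i > max_in_span:
            doomed[i:j] = True
        i += 1
    return [v for v, d in zip(variants, doomed) if not d]


def filter_variants(
    vcf_in: str,
    vcf_out: str,
    threshold: float,
    span: int = 10,
    max_in_span: int = 3,
) -> tuple[int, int]:
    """Write the high-quality biallelic SNV subset of a VCF.

    Removes records with quality strictly below ``threshold`` (a record at
    exactly the threshold is kept), indels, multiallelic and symbolic
    records, then applies the clustered-variant filter.  Returns
    ``(kept, removed)`` over all input records.
    """
    with pysam.VariantFile(vcf_in) as fin:
        header = fin.header
        records = list(fin)
    total = len(records)

    survivors = []
    for rec in records:
        alts = rec.alts or ()
        if len(alts) != 1:
            continue
        ref, alt = rec.ref, alts[0]
        if len(ref) != 1 or len(alt) != 1 or alt.startswith("<"):
            continue
        if rec.qual is None or rec.qual < threshold:
            continue
        survivors.append(rec)

    order = [(r.chrom, r.pos) for r in survivors]
    if order != sorted(order):
        raise ValueError(f"{vcf_in}: records not sorted by position")
    slim = [
        VariantRecord(r.chrom, r.pos - 1, r.ref, r.alts[0], float(r.qual))
        for r in survivors
    ]
    kept_keys = {(v.chrom, v.pos) for v in filter_clustered(slim, span, max_in_span)}

    kept = 0
    with pysam.VariantFile(vcf_out, "w", header=header) as fout:
        for rec in survivors:
            if (rec.chrom, rec.pos - 1) in kept_keys:
                fout.write(rec)
                kept += 1
    return kept, total - kept
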