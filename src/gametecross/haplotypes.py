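"""Ingest phased heterozygous variants into per-chromosome haplotype tables.

The crossover caller compares each read base against the two parental
alleles at every phased heterozygous SNV.  This module turns a phased VCF
(on the compressed reference) into that lookup: per chromosome, the ordered
site positions with the allele carried by haplotype A and by haplotype B.

Haplotype A is defined as the allele left of the ``|`` phase separator —
an arbitrary but fixed convention; relabeling the haplotypes swaps the
phase calls downstream without changing which reads are recombinant.

Real phasers emit phase *blocks* (PS tag): phase is only comparable within
a block, so sites keep their block identifier and scoring never mixes
blocks.  Structural and non-SNV variants are excluded: misaligned reads
around them produce spurious genotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pysam

__all__ = ["HaplotypeTable", "load_haplotypes"]


@dataclass
class HaplotypeTable:
    """Phased heterozygous SNV sites of one chromosome.

    ``positions`` are 0-based compressed-reference coordinates, strictly
    increasing.  ``hap_a[i]`` / ``hap_b[i]`` are the single-nucleotide
    alleles of the two haplotypes at site ``i`` (always different —
    heterozygous sites only).  ``block_id[i]`` is the phase-set the site
    belongs to.
    """

    chrom: str
    positions: np.ndarray
    hap_a: np.ndarray
    hap_b: np.ndarray
    block_id: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.hap_a = np.asarray(self.hap_a, dtype="U1")
        self.hap_b = np.asarray(self.hap_b, dtype="U1")
        self.block_id = np.asarray(self.block_id)
        if len(self.positions) != len(self.hap_a) or len(self.hap_a) != len(self.hap_b):
            raise ValueError("positions and allele arrays must have equal length")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ValueError(f"{self.chrom}: site positions not strictly increasing")
        if (self.hap_a == self.hap_b).any():
            i = int(np.flatnonzero(self.hap_a == self.hap_b)[0])
            raise ValueError(
                f"{self.chrom}:{self.positions[i]}: identical alleles on both haplotypes"
            )

    def __len__(self) -> int:
        return len(self.positions)

    def swap_labels(self) -> "HaplotypeTable":
        """Exchange haplotype A and B (label symmetry)."""
        return HaplotypeTable(
            self.chrom, self.positions, self.hap_b.copy(), self.hap_a.copy(), self.block_id
        )

    def slice_span(self, start: int, end: int) -> "HaplotypeTable":
        """Sites within the half-open compressed interval [start, end)."""
        lo = int(np.searchsorted(self.positions, start, side="left"))
        hi = int(np.searchsorted(self.positions, end, side="left"))
        return HaplotypeTable(
            self.chrom,
            self.positions[lo:hi],
            self.hap_a[lo:hi],
            self.hap_b[lo:hi],
            self.block_id[lo:hi],
        )

    def span_arrays(self, start: int, end: int):
        """(positions, hap_a, hap_b, block_id) views for [start, end).

        Validation-free fast path for per-read scoring loops.
        """
        lo = int(np.searchsorted(self.positions, start, side="left"))
        hi = int(np.searchsorted(self.positions, end, side="left"))
        return (
            self.positions[lo:hi],
            self.hap_a[lo:hi],
            self.hap_b[lo:hi],
            self.block_id[lo:hi],
        )

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.positions,
                "hap_a": self.hap_a,
                "hap_b": self.hap_b,
                "block_id": self.block_id,
            }
        )


def load_haplotypes(phased_vcf: str) -> dict[str, HaplotypeTable]:
    """Build per-chromosome haplotype tables from a phased VCF.

    Keeps only phased (``|`` separator) heterozygous biallelic SNVs;
    indels, symbolic/structural records, unphased and homozygous genotypes
    are skipped.  Sites are grouped by phase set (PS tag; sites without one
    share a single per-chromosome default block).  A chromosome with no
    usable sites yields no table; an entirely empty result warns rather
    than errors.
    """
    per_chrom: dict[str, dict[str, list]] = {}
    with pysam.VariantFile(phased_vcf) as vf:
        if len(vf.header.samples) != 1:
            warnings.warn(
                f"{phased_vcf}: {len(vf.header.samples)} samples; using the first"
            )
        for rec in vf:
            alts = rec.alts or ()
            if len(alts) != 1:
                continue
            ref, alt = rec.ref, alts[0]
            if len(ref) != 1 or len(alt) != 1 or alt.startswith("<"):
                continue
            sample = rec.samples[0]
            gt = sample.get("GT")
            if gt is None or len(gt) != 2 or None in gt:
                continue
            if not sample.phased:
                continue
            a, b = gt
            if a == b:  # homozygous carries no phase information
                continue
            alleles = (ref, alt)
            ps = sample.get("PS")
            block = int(ps) if ps is not None else 0
            cols = per_chrom.setdefault(
                rec.chrom, {"pos": [], "a": [], "b": [], "block": []}
            )
            cols["pos"].append(rec.pos - 1)
            cols["a"].append(alleles[a])
            cols["b"].append(alleles[b])
            cols["block"].append(block)
    tables = {
        chrom: HaplotypeTable(
            chrom,
            np.array(cols["pos"], dtype=np.int64),
            np.array(cols["a"], dtype="U1"),
            np.array(cols["b"], dtype="U1"),
            np.array(cols["block"], dtype=np.int64),
        )
        for chrom, cols in per_chrom.items()
    }
    if not tables:
        warnings.warn(f"{phased_vcf}: no phased heterozygous SNVs found")
    return tables
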