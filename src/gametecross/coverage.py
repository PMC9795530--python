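"""Depth-based filtering of candidate recombinant molecules.

Crossover calls in regions of anomalous alignment depth are suspect:
collapsed repeats pile up reads from several loci (inflated depth) and
near-dropout regions phase poorly.  A read whose mean depth over its
aligned span falls outside a multiplicative band around the genome-median
depth is therefore excluded from the recombination map.  The default band
is 0.25x to 2.0x the median — symmetric on a log scale, guarding equally
against dropout and pileup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam

__all__ = ["DepthProfile", "compute_depth", "filter_by_coverage"]


@dataclass
class DepthProfile:
    """Per-position alignment depth over the compressed genome.

    ``depths[chrom][p]`` is the number of primary aligned reads whose
    reference span covers position ``p``; ``genome_median`` is the median
    depth over covered (depth > 0) positions genome-wide.
    """

    depths: dict[str, np.ndarray] = field(default_factory=dict)
    genome_median: float = 0.0

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        d = self.depths[chrom]
        start = max(0, start)
        end = min(len(d), end)
        if end <= start:
            return 0.0
        return float(d[start:end].mean())

    def to_dataframe(self) -> pd.DataFrame:
        """samtools-depth-compatible table (chrom, 1-based pos, depth)."""
        frames = [
            pd.DataFrame(
                {"chrom": chrom, "pos": np.arange(1, len(d) + 1), "depth": d}
            )
            for chrom, d in self.depths.items()
        ]
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "DepthProfile":
        depths = {}
        for chrom, sub in df.groupby("chrom", sort=False):
            size = int(sub["pos"].max())
            arr = np.zeros(size, dtype=np.int64)
            arr[sub["pos"].to_numpy() - 1] = sub["depth"].to_numpy()
            depths[str(chrom)] = arr
        return cls(depths, _median_covered(depths))


def _median_covered(depths: dict[str, np.ndarray]) -> float:
    covered = [d[d > 0] for d in depths.values() if (d > 0).any()]
    if not covered:
        return 0.0
    return float(np.median(np.concatenate(covered)))


def compute_depth(bam: str) -> DepthProfile:
    """Span depth of primary alignments, per reference position.

    Each primary aligned read contributes +1 over its full reference span
    (equivalent to stabbing every position with the read intervals).
    Deterministic; an empty BAM yields an empty profile with a warning.
    """
    diffs: dict[str, np.ndarray] = {}
    with pysam.AlignmentFile(bam, check_sq=False) as fin:
        lengths = dict(zip(fin.references, fin.lengths))
        for chrom, size in lengths.items():
            diffs[chrom] = np.zeros(size + 1, dtype=np.int64)
        n = 0
        for read in fin:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            d = diffs[read.reference_name]
            d[read.reference_start] += 1
            d[read.reference_end] -= 1
            n += 1
    if n == 0:
        warnings.warn(f"{bam}: no primary alignments; depth profile is empty")
        return DepthProfile({c: np.zeros(s, dtype=np.int64) for c, s in lengths.items()}, 0.0)
    depths = {chrom: np.cumsum(d[:-1]) for chrom, d in diffs.items()}
    return DepthProfile(depths, _median_covered(depths))


def filter_by_coverage(
    calls: pd.DataFrame,
    profile: DepthProfile,
    low_mult: float = 0.25,
    high_mult: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split crossover calls into (kept, removed) by span depth.

    For each call the mean depth over the read's aligned span (columns
    ``span_start``/``span_end``; the switch interval is used as a fallback
    when the span is unavailable) is compared against
    ``[low_mult, high_mult] x genome_median``; calls outside the band are
    removed.  Removed calls carry their mean depth and a reason column
    (``low_coverage``, ``high_coverage`` or ``no_depth`` for contigs absent
    from the profile).  Monotone: widening the band never removes a
    previously kept call.
    """
    if not 0 <= low_mult <= high_mult:
        raise ValueError("need 0 <= low_mult <= high_mult")
    if len(calls) == 0:
        empty = calls.assign(span_depth=pd.Series(dtype=float), reason=pd.Series(dtype=str))
        return empty, empty.copy()
    med = profile.genome_median
    mean_depth = np.full(len(calls), np.nan)
    reason = np.full(len(calls), "", dtype=object)
    for i, row in enumerate(calls.itertuples(index=False)):
        if row.chrom not in profile.depths:
            reason[i] = "no_depth"
            continue
        start, end = row.span_start, row.span_end
        if start < 0 or end <= start:
            start, end = row.comp_start, row.comp_end
        mean_depth[i] = profile.mean_over(row.chrom, int(start), int(end))
        if mean_depth[i] < low_mult * med:
            reason[i] = "low_coverage"
        elif mean_depth[i] > high_mult * med:
            reason[i] = "high_coverage"
    out = calls.copy()
    out["span_depth"] = mean_depth
    out["reason"] = reason
    keep = out["reason"] == ""
    return (
        out[keep].drop(columns="reason").reset_index(drop=True),
        out[~keep].reset_index(drop=True),
    )
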