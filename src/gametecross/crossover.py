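"""Per-read haplotype scoring, sliding-window phasing and crossover calling.

Each read from a gamete pool derives from a single haploid gamete, so along
its length it should carry the alleles of exactly one parental haplotype —
unless a meiotic crossover fell inside the molecule, in which case the
allele pattern switches from one haplotype to the other partway through.

The detection proceeds in three steps per read:

1. **Score** (``score_read``): at every phased heterozygous site the read
   covers, compare the read base ``Gn`` with the two haplotype alleles and
   assign ``Hk = +1`` (matches haplotype A), ``-1`` (matches haplotype B)
   or ``0`` (matches neither: sequencing error, deletion, unknown).

2. **Phase** (``phase_windows``): slide a 7-site window (position ``n``
   plus three sites either side, step one) from the 4th site to the 4th
   from last.  With ``Ln`` the number of non-zero scores in the window, the
   position is called HapA when ``(sum of window scores)/Ln >= 4/6``, HapB
   when ``<= -4/6``, and NA otherwise or when fewer than 5 informative
   sites are present (inclusive inequalities).

3. **Call** (``call_crossover``): discard NA positions; if both HapA and
   HapB survive, the read is a recombinant molecule and each phase
   transition yields a crossover call whose switch interval runs from the
   last site of the outgoing phase to the first site of the incoming one.

Scoring and phasing never mix phase sets: within a read, each block of
jointly phased sites is processed independently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from gametecross.haplotypes import HaplotypeTable
from gametecross.hpc import PositionMap

__all__ = [
    "HAP_A",
    "HAP_B",
    "NA",
    "DetectOptions",
    "ScoreVector",
    "PhaseVector",
    "CrossoverCall",
    "extract_genotypes",
    "score_read",
    "phase_windows",
    "call_crossover",
    "detect_all",
    "detect_segments",
]

logger = logging.getLogger(__name__)

# phase-call encoding
HAP_A: int = 1
HAP_B: int = -1
NA: int = 0
UNKNOWN_BASE = "."

_CALL_NAMES = {HAP_A: "HapA", HAP_B: "HapB", NA: "NA"}

# CIGAR op codes (pysam numbering)
_REF_OPS = frozenset({0, 2, 3, 7, 8})   # M, D, N, =, X consume reference
_READ_OPS = frozenset({0, 1, 4, 7, 8})  # M, I, S, =, X consume read
_MATCH_OPS = (0, 7, 8)


@dataclass(frozen=True)
class DetectOptions:
    """Tunable parameters of the sliding-window caller.

    ``window_flank`` sites either side of the evaluated position (window
    size ``2*flank + 1`` = 7 by default); ``min_represented`` informative
    (non-zero) sites required per window; phase thresholds
    ``±threshold_num/threshold_den`` (4/6 by default, inclusive).
    """

    window_flank: int = 3
    min_represented: int = 5
    threshold_num: int = 4
    threshold_den: int = 6

    def __post_init__(self) -> None:
        if self.window_flank < 1:
            raise ValueError("window_flank must be >= 1")
        if not (0 < self.threshold_num <= self.threshold_den):
            raise ValueError("threshold must be a fraction in (0, 1]")


@dataclass
class ScoreVector:
    """Haplotype scores of one read over the sites it spans."""

    read_id: str
    chrom: str
    site_positions: np.ndarray
    scores: np.ndarray          # values in {+1, -1, 0}
    read_genotypes: np.ndarray  # observed base per site ('.' = unknown)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass
class PhaseVector:
    """Sliding-window phase calls of one read.

    ``calls`` holds one entry per evaluated position (the 4th to the 4th
    from last site of the score vector), encoded HapA=+1, HapB=-1, NA=0;
    ``window_ln`` is the informative-site count of each window.
    """

    read_id: str
    chrom: str
    site_positions: np.ndarray
    calls: np.ndarray
    window_ln: np.ndarray

    def __len__(self) -> int:
        return len(self.calls)

    def call_names(self) -> list[str]:
        return [_CALL_NAMES[int(c)] for c in self.calls]


@dataclass
class CrossoverCall:
    """One phase switch on one read.

    The switch interval is half-open in compressed coordinates, running
    from the last supporting site of the outgoing phase to the first
    supporting site of the incoming phase; ``switch_interval_original`` is
    the same interval after liftover.  ``flank_a``/``flank_b`` count the
    consecutive supporting phase calls on the HapA and HapB side of the
    transition.  Reads with more than one switch are flagged
    ``multi_switch`` (single molecules with several crossovers are rare and
    usually artifactual).
    """

    read_id: str
    chrom: str
    switch_interval_compressed: tuple[int, int]
    switch_interval_original: Optional[tuple[int, int]] = None
    n_switches: int = 1
    flank_a: int = 0
    flank_b: int = 0
    multi_switch: bool = False
    read_span_compressed: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        s, e = self.switch_interval_compressed
        if not s < e:
            raise ValueError(f"{self.read_id}: empty switch interval [{s}, {e})")
        if self.n_switches < 1:
            raise ValueError("a crossover call implies at least one switch")


_REF_LOOKUP = np.zeros(16, dtype=bool)
_REF_LOOKUP[list(_REF_OPS)] = True
_READ_LOOKUP = np.zeros(16, dtype=bool)
_READ_LOOKUP[list(_READ_OPS)] = True


def _cigar_arrays(cigartuples: Sequence[tuple[int, int]]):
    arr = np.asarray(cigartuples, dtype=np.int64).reshape(-1, 2)
    ops, lens = arr[:, 0], arr[:, 1]
    ref_len = np.where(_REF_LOOKUP[ops], lens, 0)
    read_len = np.where(_READ_LOOKUP[ops], lens, 0)
    ref_start = np.concatenate(([0], np.cumsum(ref_len)[:-1]))
    read_start = np.concatenate(([0], np.cumsum(read_len)[:-1]))
    return ops, lens, ref_len, read_len, ref_start, read_start


_MATCH_LOOKUP = np.zeros(16, dtype=bool)
_MATCH_LOOKUP[list(_MATCH_OPS)] = True


def _bases_at_sites(
    read_name: str,
    cigartuples: Sequence[tuple[int, int]],
    seq: str,
    span_start: int,
    positions: np.ndarray,
) -> np.ndarray:
    """uint8 read base per site position; 0 marks unknown (deletion/skip)."""
    ops, lens, ref_len, read_len, ref_starts, read_starts = _cigar_arrays(cigartuples)
    expected = int(read_len.sum())
    if expected != len(seq):
        raise ValueError(
            f"{read_name}: CIGAR consumes {expected} read bases "
            f"but sequence has {len(seq)}"
        )
    if len(positions) == 0:
        return np.empty(0, dtype=np.uint8)
    offsets = positions - span_start
    # op covering each site: first op whose ref end is > offset
    ref_end = ref_starts + ref_len
    idx = np.searchsorted(ref_end, offsets, side="right")
    seq_arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    seq_arr = np.where(seq_arr >= 97, seq_arr - 32, seq_arr)  # uppercase
    is_match = _MATCH_LOOKUP[ops[idx]]
    read_pos = read_starts[idx] + (offsets - ref_starts[idx])
    bases = np.zeros(len(positions), dtype=np.uint8)
    if is_match.any():
        bases[is_match] = seq_arr[read_pos[is_match]]
    return bases


def extract_genotypes(
    read: pysam.AlignedSegment, table: HaplotypeTable
) -> tuple[np.ndarray, np.ndarray]:
    """Read base aligned to each haplotype site within the read's span.

    Walks the CIGAR to locate, for every site of ``table`` inside
    ``[reference_start, reference_end)``, the read base aligned to it.
    Sites under deletions/skips yield the unknown marker ``'.'``;
    insertions consume read bases without creating sites.  Returns
    ``(site_positions, bases)``.

    A read whose CIGAR does not account for its sequence length is
    rejected with ``ValueError`` (callers log and skip it).
    """
    cig = read.cigartuples
    seq = read.query_sequence
    if cig is None or seq is None:
        raise ValueError(f"{read.query_name}: missing CIGAR or sequence")
    span_start = read.reference_start
    span_end = read.reference_end
    positions, _, _, _ = table.span_arrays(span_start, span_end)
    raw = _bases_at_sites(read.query_name, cig, seq, span_start, positions)
    bases = np.full(len(positions), UNKNOWN_BASE, dtype="U1")
    known = raw != 0
    bases[known] = [chr(b) for b in raw[known]]
    return positions, bases


def score_read(
    read_id: str,
    chrom: str,
    site_positions: np.ndarray,
    bases: np.ndarray,
    table: HaplotypeTable,
) -> ScoreVector:
    """Compare observed bases with the two haplotype alleles at each site.

    Score ``+1`` where the base equals the haplotype-A allele, ``-1`` where
    it equals the haplotype-B allele, ``0`` otherwise (error, deletion,
    unknown).
    """
    sub = table.slice_span(
        int(site_positions[0]), int(site_positions[-1]) + 1
    ) if len(site_positions) else table.slice_span(0, 0)
    if len(sub) != len(site_positions) or not np.array_equal(sub.positions, site_positions):
        # fall back to explicit lookup for non-contiguous site selections
        index = {int(p): i for i, p in enumerate(table.positions)}
        rows = np.array([index[int(p)] for p in site_positions], dtype=np.int64)
        hap_a, hap_b = table.hap_a[rows], table.hap_b[rows]
    else:
        hap_a, hap_b = sub.hap_a, sub.hap_b
    scores = np.zeros(len(site_positions), dtype=np.int8)
    scores[bases == hap_a] = 1
    scores[bases == hap_b] = -1
    return ScoreVector(read_id, chrom, np.asarray(site_positions), scores, bases)


def phase_windows(
    sv: ScoreVector, options: DetectOptions = DetectOptions()
) -> PhaseVector:
    """Sliding-window phase estimation over a read's score vector.

    Every position from the ``(flank+1)``-th site to the ``(flank+1)``-th
    from last gets a window of the ``2*flank + 1`` surrounding sites.  With
    ``Ln`` informative (non-zero) scores in the window, the call is NA when
    ``Ln < min_represented``, otherwise HapA when ``sum/Ln >= 4/6`` and
    HapB when ``sum/Ln <= -4/6`` (inclusive); all comparisons are exact
    integer arithmetic.  Score vectors shorter than the window yield an
    empty phase vector.
    """
    calls, ln = _phase_calls(sv.scores, options)
    f = options.window_flank
    n = len(sv)
    positions = sv.site_positions[f : n - f] if n >= 2 * f + 1 else np.empty(0, np.int64)
    return PhaseVector(sv.read_id, sv.chrom, positions, calls, ln)


def _phase_calls(
    scores: np.ndarray, options: DetectOptions
) -> tuple[np.ndarray, np.ndarray]:
    """Array core of :func:`phase_windows`: (calls, Ln) per evaluated position."""
    f = options.window_flank
    w = 2 * f + 1
    n = len(scores)
    if n < w:
        return np.empty(0, dtype=np.int8), np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(scores.astype(np.int64), w)
    winsum = windows.sum(axis=1)
    ln = (windows != 0).sum(axis=1)
    calls = np.zeros(len(winsum), dtype=np.int8)
    valid = ln >= max(options.min_represented, 1)
    num, den = options.threshold_num, options.threshold_den
    calls[valid & (den * winsum >= num * ln)] = HAP_A
    calls[valid & (den * winsum <= -num * ln)] = HAP_B
    return calls, ln


def call_crossover(
    pv: PhaseVector,
    position_map: Optional[PositionMap] = None,
    read_span: Optional[tuple[int, int]] = None,
) -> list[CrossoverCall]:
    """Detect phase switches in a read's phase vector.

    NA calls are dropped; if the surviving sequence still contains both
    HapA and HapB, the read is a recombinant molecule and one call is
    emitted per transition.  The switch interval spans (half-open,
    compressed coordinates) from the last site of the outgoing phase to
    the first site of the incoming phase; when a position map is supplied
    the interval is also lifted to original coordinates.
    """
    informative = pv.calls != NA
    calls = pv.calls[informative]
    positions = pv.site_positions[informative]
    if len(calls) == 0:
        return []
    trans = np.flatnonzero(calls[1:] != calls[:-1])
    if len(trans) == 0:
        return []
    n_switches = len(trans)
    # run lengths of consecutive equal calls, for flank support counts
    boundaries = np.concatenate(([0], trans + 1, [len(calls)]))
    run_lengths = np.diff(boundaries)
    out = []
    for k, t in enumerate(trans):
        start = int(positions[t])
        end = int(positions[t + 1])
        outgoing, incoming = int(calls[t]), int(calls[t + 1])
        support = {outgoing: int(run_lengths[k]), incoming: int(run_lengths[k + 1])}
        orig = None
        if position_map is not None:
            orig = position_map.lift_to_original(pv.chrom, (start, end))
        out.append(
            CrossoverCall(
                read_id=pv.read_id,
                chrom=pv.chrom,
                switch_interval_compressed=(start, end),
                switch_interval_original=orig,
                n_switches=n_switches,
                flank_a=support.get(HAP_A, 0),
                flank_b=support.get(HAP_B, 0),
                multi_switch=n_switches >= 2,
                read_span_compressed=read_span,
            )
        )
    return out


@dataclass
class ReadPhaseSummary:
    """Per-read accounting of the detection pass."""

    read_id: str
    chrom: str
    n_sites: int = 0
    n_informative_calls: int = 0
    n_switches: int = 0
    recombinant: bool = False


def detect_segments(
    reads: Iterable[pysam.AlignedSegment],
    haplotype_tables: dict[str, HaplotypeTable],
    options: DetectOptions = DetectOptions(),
    position_map: Optional[PositionMap] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run extract → score → phase → call over an alignment stream.

    Secondary, supplementary and unmapped records are skipped (the
    alignment filter has normally removed them already).  Contigs absent
    from the haplotype tables are skipped with a warning.  Returns the
    crossover-call table and a per-read summary, both deterministically
    ordered by (chrom, position, read id).
    """
    calls: list[CrossoverCall] = []
    summaries: list[ReadPhaseSummary] = []
    missing: set[str] = set()
    # uint8 allele caches per chromosome for the hot comparison
    hap_u8: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    f = options.window_flank
    for read in reads:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        chrom = read.reference_name
        table = haplotype_tables.get(chrom)
        if table is None:
            if chrom not in missing:
                logger.warning("contig %s has no haplotype table; skipping its reads", chrom)
                missing.add(chrom)
            continue
        if chrom not in hap_u8:
            hap_u8[chrom] = (
                table.hap_a.astype("S1").view(np.uint8),
                table.hap_b.astype("S1").view(np.uint8),
            )
        span = (read.reference_start, read.reference_end)
        positions, _, _, block_id = table.span_arrays(*span)
        lo = int(np.searchsorted(table.positions, span[0], side="left"))
        a_u8 = hap_u8[chrom][0][lo : lo + len(positions)]
        b_u8 = hap_u8[chrom][1][lo : lo + len(positions)]
        try:
            bases = _bases_at_sites(
                read.query_name, read.cigartuples, read.query_sequence, span[0], positions
            )
        except (ValueError, TypeError) as exc:
            logger.warning("rejecting read %s: %s", read.query_name, exc)
            continue
        scores = np.zeros(len(positions), dtype=np.int8)
        scores[bases == a_u8] = 1
        scores[bases == b_u8] = -1
        summary = ReadPhaseSummary(read.query_name, chrom, n_sites=len(positions))
        read_calls: list[CrossoverCall] = []
        # never phase across phase-set boundaries
        single_block = len(block_id) == 0 or block_id[0] == block_id[-1]
        blocks = (
            [slice(None)]
            if single_block
            else [block_id == b for b in dict.fromkeys(block_id.tolist())]
        )
        for sel in blocks:
            sub_scores = scores[sel]
            sub_pos = positions[sel]
            pcalls, ln = _phase_calls(sub_scores, options)
            if len(pcalls) == 0:
                continue
            pv = PhaseVector(
                read.query_name, chrom, sub_pos[f : len(sub_pos) - f], pcalls, ln
            )
            summary.n_informative_calls += int((pcalls != NA).sum())
            read_calls.extend(call_crossover(pv, position_map, read_span=span))
        summary.n_switches = len(read_calls)
        summary.recombinant = bool(read_calls)
        calls.extend(read_calls)
        summaries.append(summary)

    call_df = calls_to_dataframe(calls)
    summary_df = pd.DataFrame(
        [s.__dict__ for s in summaries],
        columns=[
            "read_id", "chrom", "n_sites", "n_informative_calls",
            "n_switches", "recombinant",
        ],
    )
    summary_df = summary_df.sort_values(["chrom", "read_id"], ignore_index=True)
    n_rec = int(summary_df["recombinant"].sum()) if len(summary_df) else 0
    logger.info(
        "detection: %d reads scored, %d recombinant molecules, %d switch calls",
        len(summary_df), n_rec, len(call_df),
    )
    return call_df, summary_df


def calls_to_dataframe(calls: Sequence[CrossoverCall]) -> pd.DataFrame:
    """Flatten crossover calls into the canonical output table."""
    rows = []
    for c in calls:
        os_, oe = c.switch_interval_original or (-1, -1)
        rows.append(
            {
                "read_id": c.read_id,
                "chrom": c.chrom,
                "comp_start": c.switch_interval_compressed[0],
                "comp_end": c.switch_interval_compressed[1],
                "orig_start": os_,
                "orig_end": oe,
                "n_switches": c.n_switches,
                "flank_A": c.flank_a,
                "flank_B": c.flank_b,
                "multi_switch": c.multi_switch,
                "span_start": (c.read_span_compressed or (-1, -1))[0],
                "span_end": (c.read_span_compressed or (-1, -1))[1],
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "read_id", "chrom", "comp_start", "comp_end", "orig_start",
            "orig_end", "n_switches", "flank_A", "flank_B", "multi_switch",
            "span_start", "span_end",
        ],
    )
    return df.sort_values(
        ["chrom", "comp_start", "comp_end", "read_id"], ignore_index=True
    )


def detect_all(
    bam: str,
    haplotype_tables: dict[str, HaplotypeTable],
    options: DetectOptions = DetectOptions(),
    position_map: Optional[PositionMap] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """File-based front end of :func:`detect_segments`."""
    with pysam.AlignmentFile(bam, check_sq=False) as fin:
        return detect_segments(fin, haplotype_tables, options, position_map)
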