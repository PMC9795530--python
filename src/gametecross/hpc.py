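"""Homopolymer compression with exact coordinate correspondence.

ONT-style nanopore reads make most of their errors inside homopolymer runs
(stretches of identical nucleotides), because run length is poorly resolved
by the pore signal.  Collapsing every maximal run to a single base removes
that error mode before alignment and variant calling, at the price of working
in a shrunken coordinate system.  This module performs the compression for
sequences, FASTQ read sets and FASTA references, and maintains the exact
run-length map needed to lift intervals from compressed back to original
coordinates (e.g. to place a crossover interval on the uncompressed genome).

All coordinates are 0-based, half-open.  Example: ``AGTTTCG`` compresses to
``AGTCG`` with run lengths ``[1, 1, 3, 1, 1]``; compressed position 2 (the
collapsed ``TTT``) lifts back to the original interval ``[2, 5)``.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CompressedSequence",
    "PositionMap",
    "compress_sequence",
    "decompress",
    "compress_reads",
    "compress_fasta",
    "build_position_map",
    "load_position_map",
]

_VALID = frozenset(b"ACGTNacgtn")
PathLike = Union[str, Path]


@dataclass
class CompressedSequence:
    """A homopolymer-compressed sequence plus its run-length coordinate map.

    Attributes
    ----------
    name
        Chromosome or read identifier.
    seq
        Compressed nucleotide string; no two adjacent characters are equal.
    run_lengths
        For each compressed position, the length of the original run.
    run_starts
        For each compressed position, the 0-based original start coordinate
        of its run.  ``run_starts[i + 1] == run_starts[i] + run_lengths[i]``.
    """

    name: str
    seq: str
    run_lengths: np.ndarray
    run_starts: np.ndarray

    def __post_init__(self) -> None:
        self.run_lengths = np.asarray(self.run_lengths, dtype=np.int64)
        self.run_starts = np.asarray(self.run_starts, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def original_length(self) -> int:
        return int(self.run_lengths.sum())

    def lift_interval(self, start: int, end: int) -> tuple[int, int]:
        """Map a compressed half-open interval to original coordinates.

        Returns the smallest original half-open interval covering every
        original base of the runs in ``[start, end)``.
        """
        if not (0 <= start < end <= len(self.seq)):
            raise ValueError(
                f"interval [{start}, {end}) out of range for {self.name!r} "
                f"(compressed length {len(self.seq)})"
            )
        orig_start = int(self.run_starts[start])
        orig_end = int(self.run_starts[end - 1] + self.run_lengths[end - 1])
        return orig_start, orig_end


def compress_sequence(seq: str, name: str = "") -> CompressedSequence:
    """Collapse every maximal homopolymer run to a single base.

    Case is preserved; runs are detected case-insensitively so ``"Aa"`` is a
    single run.  Characters outside ``{A, C, G, T, N}`` are rejected with the
    offending position named.
    """
    if not seq:
        return CompressedSequence(name, "", np.empty(0, np.int64), np.empty(0, np.int64))
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    bad = ~np.isin(raw, np.frombuffer(bytes(_VALID), dtype=np.uint8))
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"invalid nucleotide {seq[pos]!r} at position {pos}"
            + (f" in {name!r}" if name else "")
        )
    upper = np.where((raw >= 97) & (raw <= 122), raw - 32, raw)
    keep = np.empty(len(raw), dtype=bool)
    keep[0] = True
    np.not_equal(upper[1:], upper[:-1], out=keep[1:])
    run_starts = np.flatnonzero(keep).astype(np.int64)
    run_lengths = np.diff(run_starts, append=len(raw))
    comp = raw[keep].tobytes().decode("ascii")
    return CompressedSequence(name, comp, run_lengths, run_starts)


def decompress(cs: CompressedSequence) -> str:
    """Reconstruct the original sequence by expanding each run."""
    if not cs.seq:
        return ""
    raw = np.frombuffer(cs.seq.encode("ascii"), dtype=np.uint8)
    return np.repeat(raw, cs.run_lengths).tobytes().decode("ascii")


def _open_text(path: PathLike, mode: str) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def compress_reads(fastq_in: PathLike, fastq_out: PathLike) -> int:
    """Homopolymer-compress every read in a FASTQ file.

    Read IDs are preserved.  The per-base quality of each retained base is
    the maximum quality within its collapsed run, keeping the strongest
    evidence for the base that survives.  Returns the number of reads
    written.  Truncated records are rejected with the record named.
    """
    n = 0
    with _open_text(fastq_in, "r") as fin, _open_text(fastq_out, "w") as fout:
        last_id = "<start of file>"
        try:
            for rec in SeqIO.parse(fin, "fastq"):
                last_id = rec.id
                cs = compress_sequence(str(rec.seq), name=rec.id)
                quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int64)
                if len(cs) == 0:
                    new_quals: list[int] = []
                else:
                    new_quals = np.maximum.reduceat(quals, cs.run_starts).tolist()
                out = SeqRecord(Seq(cs.seq), id=rec.id, description=rec.description)
                out.letter_annotations["phred_quality"] = new_quals
                SeqIO.write(out, fout, "fastq")
                n += 1
        except ValueError as exc:
            if "invalid nucleotide" in str(exc):
                raise
            raise ValueError(
                f"malformed FASTQ record after read {last_id!r} in {fastq_in}: {exc}"
            ) from exc
    return n


def compress_fasta(fasta_in: PathLike, fasta_out: PathLike) -> dict[str, CompressedSequence]:
    """Compress every chromosome of a FASTA file; returns the compressed set."""
    genome = compress_genome(fasta_in)
    with _open_text(fasta_out, "w") as fout:
        for name, cs in genome.items():
            SeqIO.write(SeqRecord(Seq(cs.seq), id=name, description=""), fout, "fasta")
    return genome


def compress_genome(fasta_in: PathLike) -> dict[str, CompressedSequence]:
    """Read a FASTA reference and compress each chromosome in memory."""
    genome: dict[str, CompressedSequence] = {}
    with _open_text(fasta_in, "r") as fin:
        for rec in SeqIO.parse(fin, "fasta"):
            if rec.id in genome:
                raise ValueError(f"duplicate chromosome name {rec.id!r} in {fasta_in}")
            genome[rec.id] = compress_sequence(str(rec.seq), name=rec.id)
    if not genome:
        raise ValueError(f"no sequences found in {fasta_in}")
    return genome


@dataclass
class PositionMap:
    """Per-chromosome correspondence between compressed and original coordinates.

    Thin container over the ``run_starts``/``run_lengths`` arrays of each
    chromosome; serializable to a TSV with one row per compressed position.
    """

    chroms: dict[str, CompressedSequence] = field(default_factory=dict)

    @classmethod
    def from_genome(cls, genome: Mapping[str, CompressedSequence]) -> "PositionMap":
        return cls(dict(genome))

    def lift_to_original(self, chrom: str, interval: tuple[int, int]) -> tuple[int, int]:
        """Lift a compressed half-open interval to original coordinates.

        Monotone: nested compressed intervals map to nested original
        intervals, and adjacent intervals map to adjacent original intervals.
        """
        if chrom not in self.chroms:
            raise KeyError(f"chromosome {chrom!r} not in position map")
        return self.chroms[chrom].lift_interval(*interval)

    def compressed_length(self, chrom: str) -> int:
        return len(self.chroms[chrom])

    def original_length(self, chrom: str) -> int:
        return self.chroms[chrom].original_length

    def write(self, path: PathLike) -> None:
        import pandas as pd

        frames = []
        for name, cs in self.chroms.items():
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": name,
                        "compressed_pos": np.arange(len(cs), dtype=np.int64),
                        "orig_start": cs.run_starts,
                        "orig_end": cs.run_starts + cs.run_lengths,
                    }
                )
            )
        table = pd.concat(frames, ignore_index=True)
        table.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: PathLike) -> "PositionMap":
        import pandas as pd

        table = pd.read_csv(path, sep="\t")
        expected = ["chrom", "compressed_pos", "orig_start", "orig_end"]
        if list(table.columns) != expected:
            raise ValueError(f"{path}: not a position-map TSV (columns {list(table.columns)})")
        out: dict[str, CompressedSequence] = {}
        for name, sub in table.groupby("chrom", sort=False):
            starts = sub["orig_start"].to_numpy(np.int64)
            lengths = (sub["orig_end"] - sub["orig_start"]).to_numpy(np.int64)
            # seq is not stored in the map file; substitute a placeholder of
            # the right length so interval arithmetic works.
            out[str(name)] = CompressedSequence(str(name), "?" * len(sub), lengths, starts)
        return cls(out)


def build_position_map(reference_fasta: PathLike, map_out: PathLike) -> PositionMap:
    """Build and write the compressed-to-original coordinate map of a reference.

    The map has one TSV row per compressed position: ``chrom,
    compressed_pos, orig_start, orig_end`` with the original run interval
    ``[orig_start, orig_end)``.  Gzip-compressed when ``map_out`` ends in
    ``.gz``.
    """
    pmap = PositionMap.from_genome(compress_genome(reference_fasta))
    pmap.write(map_out)
    return pmap


def load_position_map(path: PathLike) -> PositionMap:
    return PositionMap.read(path)


def iter_fastq_compressed(records: Iterable[SeqRecord]) -> Iterator[SeqRecord]:
    """Lazily compress an iterable of FASTQ records (utility for pipelines)."""
    for rec in records:
        cs = compress_sequence(str(rec.seq), name=rec.id)
        quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int64)
        out = SeqRecord(Seq(cs.seq), id=rec.id, description=rec.description)
        out.letter_annotations["phred_quality"] = (
            np.maximum.reduceat(quals, cs.run_starts).tolist() if len(cs) else []
        )
        yield out
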