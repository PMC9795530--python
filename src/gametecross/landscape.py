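"""Genome-wide recombination landscape in fixed windows.

After filtering, crossover events are binned into fixed-size windows
(1 Mb by default) on original (uncompressed) coordinates, one count per
window, tiling each autosome.  Sex chromosomes are excluded: X and Y only
pair and recombine in the pseudoautosomal region, so genome-wide counts
there are not comparable with autosomes.

Each event is assigned to the window containing the midpoint of its switch
interval; wide intervals spanning a window edge are thereby counted once.
An overlap-weighted alternative spreads each event across the windows its
interval touches, proportionally to the overlap.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_EXCLUDE",
    "read_chrom_sizes",
    "build_landscape",
    "plot_landscape",
]

DEFAULT_EXCLUDE = frozenset({"X", "Y", "chrX", "chrY"})


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Two-column chrom.sizes file -> {chrom: length}."""
    sizes: dict[str, int] = {}
    with open(path) as fin:
        for line in fin:
            if not line.strip():
                continue
            chrom, size = line.split()[:2]
            sizes[chrom] = int(size)
    return sizes


def build_landscape(
    calls: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    window_size: int = 1_000_000,
    exclude: Iterable[str] = DEFAULT_EXCLUDE,
    method: str = "midpoint",
) -> pd.DataFrame:
    """Count crossover events per fixed genomic window.

    ``calls`` must carry original-coordinate switch intervals
    (``orig_start``/``orig_end``).  Windows tile each chromosome of
    ``chrom_sizes`` (minus the excluded set) without overlap; the final
    partial window is retained with its true end.  ``method='midpoint'``
    assigns each event to the window containing its interval midpoint;
    ``method='overlap'`` distributes fractional counts by interval overlap.
    Events beyond the chromosome end are rejected — they indicate a
    liftover bug upstream.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if method not in ("midpoint", "overlap"):
        raise ValueError(f"unknown binning method {method!r}")
    exclude = set(exclude)
    chroms = {c: s for c, s in chrom_sizes.items() if c not in exclude}

    rows = []
    for chrom, size in chroms.items():
        starts = np.arange(0, size, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, size)
        counts = np.zeros(len(starts), dtype=float)
        sub = calls[calls["chrom"] == chrom] if len(calls) else calls
        if len(sub):
            s = sub["orig_start"].to_numpy(np.int64)
            e = sub["orig_end"].to_numpy(np.int64)
            if (s < 0).any() or (e > size).any():
                bad = sub[(s < 0) | (e > size)].iloc[0]
                raise ValueError(
                    f"event [{bad.orig_start}, {bad.orig_end}) beyond {chrom} "
                    f"length {size}: liftover bug?"
                )
            if method == "midpoint":
                mid = (s + e) // 2
                np.add.at(counts, np.minimum(mid // window_size, len(starts) - 1), 1.0)
            else:
                for a, b in zip(s, e):
                    lo, hi = a // window_size, (b - 1) // window_size
                    for w in range(lo, hi + 1):
                        ov = min(b, (w + 1) * window_size) - max(a, w * window_size)
                        counts[w] += ov / (b - a)
        for ws, we, c in zip(starts, ends, counts):
            rows.append((chrom, int(ws), int(we), c))
    table = pd.DataFrame(
        rows, columns=["chrom", "window_start", "window_end", "crossover_count"]
    )
    if method == "midpoint":
        table["crossover_count"] = table["crossover_count"].astype(np.int64)
    return table.sort_values(["chrom", "window_start"], ignore_index=True)


def plot_landscape(table: pd.DataFrame, out_image: str) -> None:
    """Per-chromosome histogram panels of crossover counts per window."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if len(table) == 0:
        raise ValueError("cannot plot an empty landscape table")
    chroms = list(dict.fromkeys(table["chrom"]))
    fig, axes = plt.subplots(
        len(chroms), 1, figsize=(10, 2.2 * len(chroms)), squeeze=False, sharex=False
    )
    for ax, chrom in zip(axes[:, 0], chroms):
        sub = table[table["chrom"] == chrom]
        width = (sub["window_end"] - sub["window_start"]).to_numpy()
        ax.bar(
            sub["window_start"].to_numpy() / 1e6,
            sub["crossover_count"].to_numpy(),
            width=width / 1e6,
            align="edge",
            color="#3b6ea5",
            edgecolor="none",
        )
        ax.set_ylabel("crossovers")
        ax.set_title(str(chrom), loc="left", fontsize=10)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.tight_layout()
    Path(out_image).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(out_image, dpi=120)
    plt.close(fig)
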