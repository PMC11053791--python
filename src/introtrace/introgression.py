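"""Windowed SNP-density tracks and donor-introgression block calling.

Donor-derived chromosome segments in an improved line show up as runs of
windows dense in donor-specific SNPs. Windows are fixed-size, fixed-step
(overlapping when step < window) and tile each chromosome; a block is a
maximal run of consecutive qualifying windows (category fraction and
category count both above thresholds), merged on genomic extent across the
step overlaps and clipped to the outermost qualifying SNPs. The same
machinery detects clusters of "unknown"-origin SNPs, which flag an
intermediate breeding parent that was never sequenced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io_formats import GenomeIndex, write_bed, write_bedgraph
from .trio_origin import CATEGORIES, TrioOriginTable

DEFAULT_WINDOW = 500_000
DEFAULT_STEP = 250_000
DEFAULT_MIN_FRACTION = 0.5
DEFAULT_MIN_SNPS = 10
DEFAULT_MIN_WINDOWS = 2

#: Window/step defaults above assume rice-scale chromosomes (~30 Mb).
_REFERENCE_CHROM_LENGTH = 30_000_000


def scaled_window_params(genome: GenomeIndex) -> tuple[int, int]:
    """Scale the default window/step to the genome's mean chromosome length.

    Keeps roughly 60 windows per chromosome regardless of whether the input
    is a real rice genome or a megabase-scale synthetic one.
    """
    mean_len = genome.total_length / len(genome.names)
    factor = mean_len / _REFERENCE_CHROM_LENGTH
    window = max(1_000, int(round(DEFAULT_WINDOW * factor)))
    return window, max(500, window // 2)


@dataclass
class IntrogressionBlock:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    n_snps: int
    mean_fraction: float
    source_category: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"degenerate block {self.chrom}:{self.start}-{self.end}")
        if self.source_category not in CATEGORIES:
            raise ValueError(f"unknown category {self.source_category}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def windowed_density(
    table: TrioOriginTable,
    genome: GenomeIndex,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> pd.DataFrame:
    """Count origin categories in sliding windows tiling every chromosome.

    Windows are [start, start+window-1] in 1-based coordinates, starting at
    1, step apart; the last window is truncated at the chromosome end.
    Columns: chrom, start, end, n_total, n_<category>..., donor_fraction,
    unknown_fraction (NaN where n_total == 0).
    """
    if not (window >= step > 0):
        raise ValueError("require window >= step > 0")
    by_chrom = {
        chrom: grp.sort_values("pos")
        for chrom, grp in table.sites.groupby("chrom")
    }
    rows = []
    for chrom, length in genome:
        if window > length:
            warnings.warn(f"window {window} exceeds {chrom} length {length}; truncating")
        starts = list(range(1, length + 1, step))
        grp = by_chrom.get(chrom)
        pos = grp["pos"].to_numpy() if grp is not None else np.empty(0, dtype=int)
        cat_pos = {
            c: grp.loc[grp["category"] == c, "pos"].to_numpy()
            if grp is not None
            else np.empty(0, dtype=int)
            for c in CATEGORIES
        }
        for start in starts:
            end = min(start + window - 1, length)
            n_total = int(
                np.searchsorted(pos, end, side="right") - np.searchsorted(pos, start)
            )
            row = {"chrom": chrom, "start": start, "end": end, "n_total": n_total}
            for c in CATEGORIES:
                cp = cat_pos[c]
                row[f"n_{c}"] = int(
                    np.searchsorted(cp, end, side="right") - np.searchsorted(cp, start)
                )
            rows.append(row)
    track = pd.DataFrame(rows)
    with np.errstate(invalid="ignore", divide="ignore"):
        track["donor_fraction"] = np.where(
            track["n_total"] > 0, track["n_donor"] / track["n_total"], np.nan
        )
        track["unknown_fraction"] = np.where(
            track["n_total"] > 0, track["n_unknown"] / track["n_total"], np.nan
        )
    return track


def call_blocks(
    track: pd.DataFrame,
    min_fraction: float = DEFAULT_MIN_FRACTION,
    min_snps: int = DEFAULT_MIN_SNPS,
    min_windows: int = DEFAULT_MIN_WINDOWS,
    category: str = "donor",
    table: TrioOriginTable | None = None,
) -> list[IntrogressionBlock]:
    """Call introgression blocks from a window track.

    A window qualifies when its ``category`` fraction is >= ``min_fraction``
    and it contains >= ``min_snps`` SNPs of that category. Maximal runs of
    >= ``min_windows`` consecutive qualifying windows become blocks; runs
    whose genomic extents overlap (step overlap) are merged. When the site
    ``table`` is provided, block bounds are clipped to the outermost
    category SNPs inside the extent and ``n_snps`` is recounted from sites.
    """
    if min_fraction <= 0 or min_snps <= 0 or min_windows <= 0:
        raise ValueError("thresholds must be positive")
    if category not in CATEGORIES:
        raise ValueError(f"unknown category {category!r}")
    ncat = track[f"n_{category}"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(track["n_total"] > 0, ncat / track["n_total"], np.nan)
    qual = (ncat >= min_snps) & (frac >= min_fraction) & ~np.isnan(frac)

    blocks: list[IntrogressionBlock] = []
    for chrom, grp_idx in track.groupby("chrom", sort=False).groups.items():
        idx = np.asarray(grp_idx)
        q = qual[idx]
        # maximal runs of consecutive qualifying windows
        runs: list[tuple[int, int]] = []
        i = 0
        while i < len(q):
            if q[i]:
                j = i
                while j + 1 < len(q) and q[j + 1]:
                    j += 1
                if j - i + 1 >= min_windows:
                    runs.append((i, j))
                i = j + 1
            else:
                i += 1
        # genomic extents, merged across overlaps
        extents: list[list] = []
        for i, j in runs:
            start = int(track["start"].iloc[idx[i]])
            end = int(track["end"].iloc[idx[j]])
            fr = float(np.nanmean(frac[idx[i : j + 1]]))
            nw = j - i + 1
            if extents and start <= extents[-1][1] + 1:
                prev = extents[-1]
                prev[1] = max(prev[1], end)
                prev[2] = (prev[2] * prev[3] + fr * nw) / (prev[3] + nw)
                prev[3] += nw
            else:
                extents.append([start, end, fr, nw])
        for start, end, fr, _ in extents:
            if table is not None:
                sites = table.sites
                mask = (
                    (sites["chrom"] == chrom)
                    & (sites["category"] == category)
                    & (sites["pos"] >= start)
                    & (sites["pos"] <= end)
                )
                pos = sites.loc[mask, "pos"]
                if pos.empty:
                    continue
                start, end = int(pos.min()), int(pos.max())
                n = int(mask.sum())
            else:
                sub = track.iloc[idx]
                inwin = sub[(sub["start"] >= start) & (sub["end"] <= end)]
                n = int(inwin[f"n_{category}"].max()) if len(inwin) else 0
            if end > start:
                blocks.append(
                    IntrogressionBlock(
                        chrom=str(chrom), start=start, end=end, n_snps=n,
                        mean_fraction=fr, source_category=category,
                    )
                )
    return blocks


def export_tracks(
    track: pd.DataFrame,
    blocks: Iterable[IntrogressionBlock],
    bedgraph_path,
    bed_path,
    fraction_column: str = "donor_fraction",
) -> None:
    """Write the window fraction track as bedGraph and blocks as BED."""
    rows = [
        (r.chrom, r.start, r.end, getattr(r, fraction_column))
        for r in track.itertuples()
        if r.n_total > 0
    ]
    write_bedgraph(rows, bedgraph_path, name=fraction_column)
    write_bed(
        [
            (b.chrom, b.start, b.end, f"{b.source_category}_block_{i + 1}")
            for i, b in enumerate(blocks)
        ],
        bed_path,
        header="introgression blocks (0-based half-open)",
    )


def plot_chromosome_paint(track: pd.DataFrame, blocks, genome: GenomeIndex, path) -> None:
    """Per-chromosome donor-fraction paint plot with called blocks shaded."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = genome.names
    fig, axes = plt.subplots(len(chroms), 1, figsize=(8, 1.1 * len(chroms)), sharex=True)
    if len(chroms) == 1:
        axes = [axes]
    for ax, chrom in zip(axes, chroms):
        sub = track[track["chrom"] == chrom]
        ax.plot(sub["start"], sub["donor_fraction"], lw=0.8, color="tab:blue")
        for b in blocks:
            if b.chrom == chrom:
                ax.axvspan(b.start, b.end, color="tab:green", alpha=0.3)
        ax.set_ylabel(chrom, rotation=0, ha="right", fontsize=7)
        ax.set_ylim(0, 1)
    axes[-1].set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
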