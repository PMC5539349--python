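"""Per-site, per-region, per-tile and global WCG/GCH level computation.

Levels are proportions in [0, 1].  Aggregation over sites is the
unweighted mean of qualifying site levels; pooled-count aggregation is
available behind a flag (the NDR caller works on pooled counts).
Undefined values are NaN, never silently 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from coolsuite.intervals import GenomicInterval


@dataclass(frozen=True)
class DepthPolicy:
    """Minimum per-site read depth by analysis regime."""

    single_cell_min: int = 1
    bulk_min: int = 3
    cross_cell_min: int = 2

    def __post_init__(self) -> None:
        for v in (self.single_cell_min, self.bulk_min, self.cross_cell_min):
            if v < 1:
                raise ValueError("depth thresholds must be positive")


DEFAULT_POLICY = DepthPolicy()


def site_levels(channel_table: pd.DataFrame, min_depth: int = 1) -> pd.DataFrame:
    """Per-site methylation levels, dropping sites below ``min_depth``.

    Returns columns chrom, pos, strand, level, depth.
    """
    depth = channel_table["meth"] + channel_table["unmeth"]
    keep = depth >= min_depth
    out = channel_table.loc[keep, ["chrom", "pos", "strand"]].copy()
    out["depth"] = depth[keep]
    out["level"] = channel_table.loc[keep, "meth"] / depth[keep]
    return out.reset_index(drop=True)


def global_level(channel_table: pd.DataFrame, min_depth: int = 1) -> float:
    """Unweighted mean level over qualifying sites; NaN if none qualify."""
    lv = site_levels(channel_table, min_depth=min_depth)
    if lv.empty:
        return float("nan")
    return float(lv["level"].mean())


def region_level(
    region: GenomicInterval,
    levels: pd.DataFrame,
    min_sites: int = 1,
    pooled: bool = False,
    counts: pd.DataFrame | None = None,
) -> float:
    """Mean site level inside ``[start, end)``; NaN below ``min_sites``.

    With ``pooled=True`` (requires a count table with meth/unmeth columns)
    returns sum(meth)/sum(meth+unmeth) instead of the mean of site levels.
    """
    inside = (
        (levels["chrom"] == region.chrom)
        & (levels["pos"] >= region.start)
        & (levels["pos"] < region.end)
    )
    n = int(inside.sum())
    if n < min_sites or n == 0:
        return float("nan")
    if pooled:
        if counts is None:
            raise ValueError("pooled mode needs the count table")
        sel = (
            (counts["chrom"] == region.chrom)
            & (counts["pos"] >= region.start)
            & (counts["pos"] < region.end)
        )
        m = counts.loc[sel, "meth"].sum()
        u = counts.loc[sel, "unmeth"].sum()
        return float(m / (m + u)) if (m + u) > 0 else float("nan")
    return float(levels.loc[inside, "level"].mean())


def region_levels(
    regions: Sequence[GenomicInterval],
    levels: pd.DataFrame,
    min_sites: int = 1,
) -> np.ndarray:
    """Vector of region_level over many regions (NaN where undefined)."""
    out = np.full(len(regions), np.nan)
    by_chrom = {c: g.sort_values("pos") for c, g in levels.groupby("chrom")}
    for i, region in enumerate(regions):
        g = by_chrom.get(region.chrom)
        if g is None:
            continue
        pos = g["pos"].to_numpy()
        lo = np.searchsorted(pos, region.start, side="left")
        hi = np.searchsorted(pos, region.end, side="left")
        if hi - lo >= min_sites and hi > lo:
            out[i] = g["level"].to_numpy()[lo:hi].mean()
    return out


def tile_levels(
    cell_levels: Mapping[str, pd.DataFrame],
    chrom_sizes: Mapping[str, int],
    tile_size: int = 5000,
    min_sites: int = 5,
) -> pd.DataFrame:
    """Tiles x cells matrix of mean site levels under the >= min_sites rule.

    The genome is partitioned into consecutive ``tile_size`` tiles (the
    final partial tile included).  Index is (chrom, start, end); one
    column per cell; NaN where fewer than ``min_sites`` sites are covered.
    """
    tiles: list[GenomicInterval] = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, tile_size):
            tiles.append(GenomicInterval(chrom, start, min(start + tile_size, size)))
    data = {
        cell: region_levels(tiles, lv, min_sites=min_sites)
        for cell, lv in cell_levels.items()
    }
    index = pd.MultiIndex.from_tuples(
        [(t.chrom, t.start, t.end) for t in tiles], names=["chrom", "start", "end"]
    )
    return pd.DataFrame(data, index=index)


def meta_profile(
    tss_table: pd.DataFrame,
    levels: pd.DataFrame,
    flank: int = 2000,
    n_bins: int = 40,
    mode: str = "tss",
    gene_length: Mapping[str, int] | None = None,
) -> np.ndarray:
    """Strand-aware averaged profile around TSSs (or along scaled bodies).

    ``mode='tss'``: bins span [TSS - flank, TSS + flank) in 5'->3'
    orientation.  ``mode='body'``: each gene body (length from
    ``gene_length``) is scaled into ``n_bins``; genes shorter than 2 bins
    are excluded.  Returns per-bin unweighted mean over all sites mapped
    into that bin across regions (NaN for empty bins).
    """
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    by_chrom = {c: g.sort_values("pos") for c, g in levels.groupby("chrom")}
    for row in tss_table.itertuples(index=False):
        g = by_chrom.get(row.chrom)
        if g is None:
            continue
        pos = g["pos"].to_numpy()
        lvl = g["level"].to_numpy()
        if mode == "tss":
            start, end = row.tss - flank, row.tss + flank
            span = end - start
        elif mode == "body":
            if gene_length is None:
                raise ValueError("body mode needs gene_length")
            span = gene_length[row.gene]
            # genes too short to populate at least 2 distinct bins are excluded
            if span < 2 * math.ceil(span / n_bins) or span < 2:
                continue
            if row.strand == "+":
                start, end = row.tss, row.tss + span
            else:
                start, end = row.tss - span + 1, row.tss + 1
        else:
            raise ValueError(f"unknown mode {mode!r}")
        lo = np.searchsorted(pos, max(start, 0), side="left")
        hi = np.searchsorted(pos, end, side="left")
        if hi <= lo:
            continue
        p = pos[lo:hi]
        offset = p - start
        if row.strand == "-":
            offset = (span - 1) - offset
        bins = np.minimum((offset * n_bins) // span, n_bins - 1).astype(int)
        np.add.at(sums, bins, lvl[lo:hi])
        np.add.at(counts, bins, 1)
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def region_coverage_fraction(
    levels: pd.DataFrame,
    regions: Sequence[GenomicInterval],
    min_sites: int = 5,
) -> float:
    """Fraction of regions with >= min_sites covered sites in this cell."""
    if not regions:
        return float("nan")
    vals = region_levels(regions, levels, min_sites=min_sites)
    return float(np.count_nonzero(~np.isnan(vals)) / len(regions))


def pooled_counts(tables: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-cell call tables by summing counts at identical sites."""
    frames = [t for t in tables if len(t)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "meth", "unmeth"])
    cat = pd.concat(frames, ignore_index=True)
    out = (
        cat.groupby(["chrom", "pos", "strand"], as_index=False)[["meth", "unmeth"]]
        .sum()
        .sort_values(["chrom", "pos", "strand"], ignore_index=True)
    )
    return out
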