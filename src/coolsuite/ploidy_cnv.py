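"""Spike-in ploidy estimation, CNV binning, replication timing and sex.

Ploidy: the ratio of genomic to lambda spike-in reads, normalized so the
mean ratio of the reference (known-diploid) cells maps to exactly 2N.

CNV: the genome is tiled into consecutive 1-Mb bins; per-bin counts are
GC-corrected by local regression, divided by the across-cell median of
the bin, and reported as log2 ratios.  A chromosome is flagged
gained/lost when most of its bins shift with one sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from coolsuite.intervals import GenomicInterval

PLOIDY_CLASSES = ("1N", "1N-2N", "2N", "2N-4N", "4N", "outlier")

# class boundaries on the normalized (2N-reference) scale
_BOUNDS = {
    "1N": (0.75, 1.25),
    "1N-2N": (1.25, 1.75),
    "2N": (1.75, 2.25),
    "2N-4N": (2.25, 3.5),
    "4N": (3.5, 4.5),
}


@dataclass(frozen=True)
class PloidyEstimate:
    cell: str
    genomic_reads: int
    lambda_reads: int
    raw_ratio: float
    ploidy: float
    ploidy_class: str


def classify_ploidy(value: float) -> str:
    for cls, (lo, hi) in _BOUNDS.items():
        anchored = cls in ("1N", "2N", "4N")
        hit = (lo <= value <= hi) if anchored else (lo < value < hi)
        if hit:
            return cls
    return "outlier"


def estimate_ploidy(
    read_counts: Mapping[str, tuple[int, int]],
    reference_cells: Sequence[str],
) -> list[PloidyEstimate]:
    """Normalized ploidy per cell from (genomic_reads, lambda_reads).

    ``reference_cells`` are assumed diploid; the mean of their ratios
    defines 2N.  Cells with zero lambda reads are flagged outliers
    without dividing.
    """
    if not reference_cells:
        raise ValueError("need at least one reference (2N) cell")
    ref_ratios = []
    for cell in reference_cells:
        g, l = read_counts[cell]
        if l <= 0:
            raise ValueError(f"reference cell {cell} has no lambda reads")
        ref_ratios.append(g / l)
    ref_mean = float(np.mean(ref_ratios))

    out = []
    for cell, (g, l) in read_counts.items():
        if l <= 0:
            out.append(PloidyEstimate(cell, g, l, float("nan"), float("nan"), "outlier"))
            continue
        ratio = g / l
        ploidy = 2.0 * ratio / ref_mean
        out.append(PloidyEstimate(cell, g, l, ratio, ploidy, classify_ploidy(ploidy)))
    return out


def make_bins(
    chrom_sizes: Mapping[str, int], bin_size: int = 1_000_000
) -> list[GenomicInterval]:
    """Consecutive fixed-size bins tiling every chromosome (gap/overlap free)."""
    bins = []
    for chrom, size in chrom_sizes.items():
        for start in range(0, size, bin_size):
            bins.append(GenomicInterval(chrom, start, min(start + bin_size, size)))
    return bins


def bin_read_positions(
    read_positions: Mapping[str, pd.DataFrame],
    chrom_sizes: Mapping[str, int],
    bin_size: int = 1_000_000,
) -> pd.DataFrame:
    """Bins x cells raw count matrix from per-cell read positions."""
    bins = make_bins(chrom_sizes, bin_size)
    index = pd.MultiIndex.from_tuples(
        [(b.chrom, b.start, b.end) for b in bins], names=["chrom", "start", "end"]
    )
    data = {}
    for cell, df in read_positions.items():
        counts = np.zeros(len(bins), dtype=int)
        for i, b in enumerate(bins):
            sel = (df["chrom"] == b.chrom) & (df["pos"] >= b.start) & (df["pos"] < b.end)
            counts[i] = int(sel.sum())
        data[cell] = counts
    return pd.DataFrame(data, index=index)


def gc_fraction_per_bin(
    genome: Mapping[str, str], chrom_sizes: Mapping[str, int], bin_size: int = 1_000_000
) -> pd.Series:
    bins = make_bins(chrom_sizes, bin_size)
    vals, keys = [], []
    for b in bins:
        seq = genome[b.chrom][b.start : b.end].upper()
        acgt = sum(seq.count(x) for x in "ACGT")
        gc = seq.count("G") + seq.count("C")
        vals.append(gc / acgt if acgt else np.nan)
        keys.append((b.chrom, b.start, b.end))
    return pd.Series(
        vals, index=pd.MultiIndex.from_tuples(keys, names=["chrom", "start", "end"])
    )


def bin_and_normalize(
    raw_counts: pd.DataFrame,
    gc_per_bin: pd.Series | None = None,
    min_cells: int = 3,
) -> pd.DataFrame:
    """GC-correct and median-normalize a bins x cells count matrix.

    Per cell, counts are divided by a lowess fit of count on GC fraction
    (median-anchored) when ``gc_per_bin`` is given; each bin is then
    divided by its across-cell median.  Returns log2 ratios with bins of
    zero median masked (NaN).
    """
    if raw_counts.shape[1] < min_cells:
        raise ValueError(f"median normalization needs >= {min_cells} cells")
    corrected = raw_counts.astype(float).copy()
    if gc_per_bin is not None:
        gc = gc_per_bin.reindex(raw_counts.index).to_numpy()
        for cell in corrected.columns:
            y = corrected[cell].to_numpy()
            ok = ~np.isnan(gc) & (y > 0)
            if ok.sum() >= 10:
                fit = lowess(y[ok], gc[ok], frac=0.5, return_sorted=False)
                fit = np.maximum(fit, 1e-9)
                ratio = np.ones_like(y)
                ratio[ok] = y[ok] / fit
                corrected[cell] = ratio * np.median(y[ok])
    med = corrected.median(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = corrected.div(med, axis=0)
        norm[med <= 0] = np.nan
        logratio = np.log2(norm)
    logratio[norm <= 0] = np.nan
    return logratio


def per_cell_cv(logratio: pd.DataFrame) -> pd.Series:
    """sd/mean per cell over linear-scale normalized bin values."""
    linear = np.power(2.0, logratio)
    mean = linear.mean(axis=0)
    sd = linear.std(axis=0, ddof=1)
    return sd / mean


def flag_chromosome_cnv(
    logratio: pd.DataFrame,
    min_abs_log2: float = 0.4,
    min_fraction_of_chrom: float = 0.8,
    min_bins: int = 3,
) -> pd.DataFrame:
    """Chromosome-level gain/loss flags per cell.

    A chromosome is flagged when >= ``min_fraction_of_chrom`` of its
    unmasked bins exceed ``min_abs_log2`` with a single sign.  Rows are
    chromosomes, columns cells, values in {gain, loss, neutral, untested}.
    """
    chroms = logratio.index.get_level_values("chrom")
    out = {}
    for cell in logratio.columns:
        col = {}
        for chrom in chroms.unique():
            vals = logratio.loc[chroms == chrom, cell].dropna().to_numpy()
            if len(vals) < min_bins:
                col[chrom] = "untested"
                continue
            gain = np.mean(vals > min_abs_log2)
            loss = np.mean(vals < -min_abs_log2)
            if gain >= min_fraction_of_chrom:
                col[chrom] = "gain"
            elif loss >= min_fraction_of_chrom:
                col[chrom] = "loss"
            else:
                col[chrom] = "neutral"
        out[cell] = col
    return pd.DataFrame(out)


def replication_lead_lag(
    tile_counts: pd.Series,
    domain_labels: Sequence[tuple[GenomicInterval, str]],
) -> tuple[float, float, float]:
    """Mean normalized counts in leading vs lagging domains + t-test p.

    ``tile_counts`` is indexed by (chrom, start, end) 100-kb tiles for one
    cell; ``domain_labels`` pairs intervals with 'leading'/'lagging'.
    Returns (mean_leading, mean_lagging, p) with NaNs when a class is
    missing.
    """
    leading, lagging = [], []
    for (chrom, start, end), v in tile_counts.items():
        if np.isnan(v):
            continue
        mid = (start + end) // 2
        for iv, label in domain_labels:
            if iv.contains_point(chrom, mid):
                (leading if label == "leading" else lagging).append(v)
                break
    if not leading or not lagging:
        return (float("nan"), float("nan"), float("nan"))
    t = stats.ttest_ind(leading, lagging)
    return (float(np.mean(leading)), float(np.mean(lagging)), float(t.pvalue))


def infer_sex(
    bin_counts: pd.Series,
    chrom_sizes: Mapping[str, int],
    x_chrom: str = "chrX",
    autosome: str = "chr1",
) -> str:
    """male/female from the X : autosome read ratio, length-normalized.

    Expected ratios are len(X)/len(chr1) for two X copies and half that
    for one; the midpoint is the decision threshold.
    """
    chroms = bin_counts.index.get_level_values("chrom")
    x_reads = float(bin_counts[chroms == x_chrom].sum())
    a_reads = float(bin_counts[chroms == autosome].sum())
    if a_reads <= 0:
        raise ValueError(f"no reads on {autosome}")
    ratio = x_reads / a_reads
    expected_2x = chrom_sizes[x_chrom] / chrom_sizes[autosome]
    threshold = 0.75 * expected_2x  # midpoint of 1-X and 2-X expectations
    return "female" if ratio > threshold else "male"
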