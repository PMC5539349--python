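"""NDR and nucleosome-occupied-region calling by windowed chi-square tests.

Pooled C (methylated) and T (unmethylated) counts at GCH sites are summed
in sliding windows and each window is tested against the genomic
background with a 2x2 chi-square (1 df, no continuity correction) on

    [[window_C, window_T], [genome_C - window_C, genome_T - window_T]]

Retained windows must pass the p cutoff AND lie on the requested side of
the background rate (enriched for NDRs, depleted for nucleosomes).
Overlapping retained windows are merged; merged regions are kept if wide
enough and covering enough GCH sites.  NDRs are classified promoter
(contain a TSS), proximal (within 2 kb of one) or distal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from coolsuite.intervals import GenomicInterval


@dataclass(frozen=True)
class WindowTestParams:
    window_bp: int
    step_bp: int
    p_cutoff: float
    min_region_bp: int
    min_gch_sites: int
    direction: str  # "enriched" | "depleted"

    def __post_init__(self) -> None:
        if self.step_bp > self.window_bp:
            raise ValueError("step must be <= window")
        if not (0.0 < self.p_cutoff < 1.0):
            raise ValueError("p_cutoff must be in (0, 1)")
        if self.direction not in ("enriched", "depleted"):
            raise ValueError(f"bad direction {self.direction!r}")


#: NDR calling preset: 120-bp windows / 20-bp step, p <= 1e-15,
#: >= 140 bp merged width, >= 5 GCH sites, GCH-methylation enriched.
NDR_PRESET = WindowTestParams(120, 20, 1e-15, 140, 5, "enriched")

#: nucleosome preset: 40-bp windows / 20-bp step, p <= 1e-3,
#: >= 60 bp merged width, >= 3 GCH sites, GCH-methylation depleted.
NUCLEOSOME_PRESET = WindowTestParams(40, 20, 1e-3, 60, 3, "depleted")


def window_test(
    window_c: int, window_t: int, genome_c: int, genome_t: int
) -> tuple[float, float]:
    """Chi-square (1 df, no Yates) of a window against the genome complement.

    Degenerate tables (any margin zero) return (0.0, 1.0).
    """
    a = float(window_c)
    b = float(window_t)
    c = float(genome_c - window_c)
    d = float(genome_t - window_t)
    if min(c, d) < 0:
        raise ValueError("genome totals must dominate window counts")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if r1 == 0 or r2 == 0 or c1 == 0 or c2 == 0:
        return 0.0, 1.0
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(stat), float(stats.chi2.sf(stat, df=1))


@dataclass(frozen=True)
class NdrRecord:
    interval: GenomicInterval
    n_gch_sites: int
    pooled_c: int
    pooled_t: int
    min_p: float
    ndr_class: str  # promoter | proximal | distal | "."

    @property
    def width(self) -> int:
        return self.interval.width

    @property
    def level(self) -> float:
        tot = self.pooled_c + self.pooled_t
        return self.pooled_c / tot if tot else float("nan")


def scan_and_call(
    gch_counts: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    params: WindowTestParams,
    tss_table: pd.DataFrame | None = None,
    background: tuple[int, int] | None = None,
    trim: bool = False,
) -> list[NdrRecord]:
    """Call NDRs (or nucleosome-occupied regions) from pooled GCH counts.

    ``gch_counts`` carries pooled per-site meth/unmeth read counts from
    merged cells.  The genomic background defaults to the totals over all
    covered GCH sites in the table.  Windows tile each chromosome from
    position 0 at ``params.step_bp``; the final partial window is tested
    as-is.

    By default the merged region is the union span of its retained
    windows.  ``trim=True`` refines boundaries to the outermost GCH site
    supporting the call (site rate beyond the midpoint of the background
    and region rates); the width and site filters then apply to the
    trimmed span.
    """
    if gch_counts.empty:
        return []
    if background is None:
        genome_c = int(gch_counts["meth"].sum())
        genome_t = int(gch_counts["unmeth"].sum())
    else:
        genome_c, genome_t = background
    bg_total = genome_c + genome_t
    bg_rate = genome_c / bg_total if bg_total else float("nan")

    records: list[NdrRecord] = []
    for chrom, size in chrom_sizes.items():
        sub = gch_counts[gch_counts["chrom"] == chrom].sort_values("pos")
        if sub.empty:
            continue
        pos = sub["pos"].to_numpy()
        meth = sub["meth"].to_numpy(dtype=np.int64)
        unmeth = sub["unmeth"].to_numpy(dtype=np.int64)
        cum_m = np.concatenate([[0], np.cumsum(meth)])
        cum_u = np.concatenate([[0], np.cumsum(unmeth)])

        starts = np.arange(0, size, params.step_bp, dtype=np.int64)
        ends = np.minimum(starts + params.window_bp, size)
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        wc = cum_m[hi] - cum_m[lo]
        wt = cum_u[hi] - cum_u[lo]
        wtot = wc + wt

        # vectorised 2x2 chi-square against the genome complement
        a, b = wc.astype(float), wt.astype(float)
        c, d = genome_c - a, genome_t - b
        ntot = a + b + c + d
        r1, r2 = a + b, c + d
        c1, c2 = a + c, b + d
        denom = r1 * r2 * c1 * c2
        ok = denom > 0
        stat = np.zeros_like(a)
        stat[ok] = ntot[ok] * (a[ok] * d[ok] - b[ok] * c[ok]) ** 2 / denom[ok]
        pvals = np.ones_like(a)
        pvals[ok] = stats.chi2.sf(stat[ok], df=1)

        rate = wc / np.maximum(wtot, 1)
        if params.direction == "enriched":
            side = rate > bg_rate
        else:
            side = rate < bg_rate
        keep = (pvals <= params.p_cutoff) & side & (wtot > 0)

        # merge overlapping retained windows (union span)
        idx = np.flatnonzero(keep)
        i = 0
        while i < len(idx):
            j = i
            reg_start = starts[idx[i]]
            reg_end = ends[idx[i]]
            min_p = pvals[idx[i]]
            while j + 1 < len(idx) and starts[idx[j + 1]] < reg_end:
                j += 1
                reg_end = max(reg_end, ends[idx[j]])
                min_p = min(min_p, pvals[idx[j]])
            rlo = np.searchsorted(pos, reg_start, side="left")
            rhi = np.searchsorted(pos, reg_end, side="left")
            if trim and rhi > rlo:
                site_m = meth[rlo:rhi].astype(float)
                site_u = unmeth[rlo:rhi].astype(float)
                site_tot = site_m + site_u
                reg_tot = site_m.sum() + site_u.sum()
                reg_rate = site_m.sum() / reg_tot if reg_tot else bg_rate
                thr = 0.5 * (bg_rate + reg_rate)
                with np.errstate(invalid="ignore"):
                    site_rate = np.where(site_tot > 0, site_m / np.maximum(site_tot, 1), np.nan)
                if params.direction == "enriched":
                    support = site_rate > thr
                else:
                    support = site_rate < thr
                support &= site_tot > 0
                if not support.any():
                    i = j + 1
                    continue
                first = int(np.flatnonzero(support)[0])
                last = int(np.flatnonzero(support)[-1])
                reg_start = int(pos[rlo + first])
                reg_end = int(pos[rlo + last]) + 1
                rlo, rhi = rlo + first, rlo + last + 1
            n_sites = int(rhi - rlo)
            width = int(reg_end - reg_start)
            if width >= params.min_region_bp and n_sites >= params.min_gch_sites:
                records.append(
                    NdrRecord(
                        GenomicInterval(chrom, int(reg_start), int(reg_end)),
                        n_sites,
                        int(cum_m[rhi] - cum_m[rlo]),
                        int(cum_u[rhi] - cum_u[rlo]),
                        float(min_p),
                        ".",
                    )
                )
            i = j + 1

    if tss_table is not None:
        records = [
            replace(r, ndr_class=classify_ndr(r.interval, tss_table))
            for r in records
        ]
    return records


def classify_ndr(
    interval: GenomicInterval, tss_table: pd.DataFrame, proximal_bp: int = 2000
) -> str:
    """promoter (contains a TSS) > proximal (within 2 kb) > distal."""
    sub = tss_table[tss_table["chrom"] == interval.chrom]
    if sub.empty:
        return "distal"
    tss = sub["tss"].to_numpy()
    if np.any((tss >= interval.start) & (tss < interval.end)):
        return "promoter"
    dist = np.minimum(
        np.abs(tss - interval.start), np.abs(tss - (interval.end - 1))
    )
    return "proximal" if dist.min() <= proximal_bp else "distal"


def wide_ndr_fraction(ndrs: Sequence[NdrRecord], width_cutoff: int = 300) -> float:
    """Fraction of NDRs wider than ``width_cutoff`` bp; NaN if empty."""
    if not ndrs:
        return float("nan")
    wide = sum(1 for r in ndrs if r.width > width_cutoff)
    return wide / len(ndrs)


def differential_ndrs(
    ndrs: Sequence[NdrRecord | GenomicInterval],
    group_a_counts: pd.DataFrame,
    group_b_counts: pd.DataFrame,
    fdr: float = 0.05,
    min_delta: float = 0.2,
) -> pd.DataFrame:
    """Per-NDR 2x2 chi-square between two cell groups with BH control.

    Returns one row per NDR with pooled levels, p, q, the tested flag and
    the direction ('A' or 'B' = more accessible group) for differential
    calls.  NDRs uncovered in either group are reported untested.
    """
    intervals = [r.interval if isinstance(r, NdrRecord) else r for r in ndrs]
    rows = []
    for iv in intervals:
        ca, ta = _region_counts(group_a_counts, iv)
        cb, tb = _region_counts(group_b_counts, iv)
        tested = (ca + ta) > 0 and (cb + tb) > 0
        if tested:
            stat, p = window_test(ca, ta, ca + cb, ta + tb)
            level_a = ca / (ca + ta)
            level_b = cb / (cb + tb)
        else:
            p, level_a, level_b = np.nan, np.nan, np.nan
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "level_a": level_a,
                "level_b": level_b,
                "p": p,
                "tested": tested,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    mask = out["tested"].to_numpy()
    if mask.any():
        out.loc[mask, "q"] = stats.false_discovery_control(
            out.loc[mask, "p"].to_numpy(), method="bh"
        )
    delta = out["level_a"] - out["level_b"]
    out["differential"] = mask & (out["q"] < fdr) & (delta.abs() >= min_delta)
    out["direction"] = np.where(
        out["differential"], np.where(delta > 0, "A", "B"), "."
    )
    return out


def _region_counts(counts: pd.DataFrame, iv: GenomicInterval) -> tuple[int, int]:
    sel = (
        (counts["chrom"] == iv.chrom)
        & (counts["pos"] >= iv.start)
        & (counts["pos"] < iv.end)
    )
    return int(counts.loc[sel, "meth"].sum()), int(counts.loc[sel, "unmeth"].sum())
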