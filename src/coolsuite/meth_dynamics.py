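"""Stage-transition methylation calling and cross-cell variability.

De novo / demethylated WCG sites between consecutive stages:

* a site enters a stage only if covered in >= 3 single cells of it;
* stage means are the unweighted mean of per-cell site levels;
* de novo: mean(from) < 0.25 and mean(to) - mean(from) >= 0.3;
* demethylated: mean(from) > 0.75 and mean(from) - mean(to) >= 0.3;
* significance from a two-sided Fisher exact test on stage-pooled
  (meth, unmeth) counts, Benjamini-Hochberg controlled at the given FDR
  across all sites tested for the transition (chi-square available
  behind ``test='chi2'``).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from coolsuite.intervals import GenomicInterval

MIN_CELLS_PER_STAGE = 3
DE_NOVO_BASE_MAX = 0.25
DEMETH_BASE_MIN = 0.75
MIN_DELTA = 0.3

SITE_KEY = ["chrom", "pos", "strand"]


def stage_site_table(
    cell_tables: Sequence[pd.DataFrame], min_depth: int = 1
) -> pd.DataFrame:
    """Per-site stage summary over a stage's cells.

    Columns: chrom, pos, strand, n_cells, mean_level (mean of per-cell
    levels), meth, unmeth (stage-pooled counts).
    """
    frames = []
    for t in cell_tables:
        depth = t["meth"] + t["unmeth"]
        keep = depth >= min_depth
        sub = t.loc[keep, SITE_KEY + ["meth", "unmeth"]].copy()
        sub["level"] = sub["meth"] / (sub["meth"] + sub["unmeth"])
        frames.append(sub)
    if not frames:
        return pd.DataFrame(
            columns=SITE_KEY + ["n_cells", "mean_level", "meth", "unmeth"]
        )
    cat = pd.concat(frames, ignore_index=True)
    g = cat.groupby(SITE_KEY, as_index=False)
    out = g.agg(
        n_cells=("level", "size"),
        mean_level=("level", "mean"),
        meth=("meth", "sum"),
        unmeth=("unmeth", "sum"),
    )
    return out


def call_transition_sites(
    from_cells: Sequence[pd.DataFrame],
    to_cells: Sequence[pd.DataFrame],
    mode: str = "de_novo",
    fdr: float = 0.05,
    min_cells: int = MIN_CELLS_PER_STAGE,
    min_depth: int = 1,
    test: str = "fisher",
) -> pd.DataFrame:
    """Call de novo (or demethylated) WCG sites between two stages.

    Returns every site meeting the coverage rule in both stages, with
    stage means, delta, p, q and the ``called`` flag.
    """
    if mode not in ("de_novo", "demethylated"):
        raise ValueError(f"bad mode {mode!r}")
    a = stage_site_table(from_cells, min_depth=min_depth)
    b = stage_site_table(to_cells, min_depth=min_depth)
    a = a[a["n_cells"] >= min_cells]
    b = b[b["n_cells"] >= min_cells]
    merged = a.merge(b, on=SITE_KEY, suffixes=("_from", "_to"))
    if merged.empty:
        import logging

        logging.getLogger(__name__).warning("no sites meet the coverage rule")
        merged["delta"] = merged["p"] = merged["q"] = merged["called"] = []
        return merged

    p = np.empty(len(merged))
    if test == "fisher":
        for i, row in enumerate(merged.itertuples(index=False)):
            table = [
                [row.meth_from, row.unmeth_from],
                [row.meth_to, row.unmeth_to],
            ]
            p[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    elif test == "chi2":
        from coolsuite.chromatin import window_test

        for i, row in enumerate(merged.itertuples(index=False)):
            p[i] = window_test(
                row.meth_from,
                row.unmeth_from,
                row.meth_from + row.meth_to,
                row.unmeth_from + row.unmeth_to,
            )[1]
    else:
        raise ValueError(f"unknown test {test!r}")
    merged["p"] = p
    merged["q"] = stats.false_discovery_control(p, method="bh")
    merged["delta"] = merged["mean_level_to"] - merged["mean_level_from"]
    if mode == "de_novo":
        merged["called"] = (
            (merged["mean_level_from"] < DE_NOVO_BASE_MAX)
            & (merged["delta"] >= MIN_DELTA)
            & (merged["q"] < fdr)
        )
    else:
        merged["called"] = (
            (merged["mean_level_from"] > DEMETH_BASE_MIN)
            & (-merged["delta"] >= MIN_DELTA)
            & (merged["q"] < fdr)
        )
    return merged.reset_index(drop=True)


def call_de_novo_cgis(
    cgis: Sequence[GenomicInterval],
    stage_cells: Mapping[str, Sequence[pd.DataFrame]],
    stage_order: Sequence[str],
    min_sites_per_cell: int = 3,
    min_cells: int = MIN_CELLS_PER_STAGE,
) -> pd.DataFrame:
    """De novo methylated CGIs across an ordered stage series.

    A CGI contributes a per-cell level only with >= 3 detected WCG sites
    in that cell, enters a stage only with >= 3 qualifying cells, and is
    de novo at a transition when the earlier stage mean is < 0.25 and the
    next stage gains >= 0.3.
    """
    stage_means: dict[str, np.ndarray] = {}
    for stage in stage_order:
        per_cell = []
        for t in stage_cells[stage]:
            depth = t["meth"] + t["unmeth"]
            sub = t[depth >= 1].copy()
            sub["level"] = sub["meth"] / (sub["meth"] + sub["unmeth"])
            vals = np.full(len(cgis), np.nan)
            for i, cgi in enumerate(cgis):
                inside = (
                    (sub["chrom"] == cgi.chrom)
                    & (sub["pos"] >= cgi.start)
                    & (sub["pos"] < cgi.end)
                )
                if int(inside.sum()) >= min_sites_per_cell:
                    vals[i] = sub.loc[inside, "level"].mean()
            per_cell.append(vals)
        mat = np.vstack(per_cell) if per_cell else np.empty((0, len(cgis)))
        n_ok = np.count_nonzero(~np.isnan(mat), axis=0)
        means = np.where(
            n_ok > 0, np.nansum(np.nan_to_num(mat), axis=0) / np.maximum(n_ok, 1), np.nan
        )
        means[n_ok < min_cells] = np.nan
        stage_means[stage] = means

    rows = []
    for i, cgi in enumerate(cgis):
        called = False
        at = None
        for s_from, s_to in zip(stage_order, stage_order[1:]):
            m0, m1 = stage_means[s_from][i], stage_means[s_to][i]
            if np.isnan(m0) or np.isnan(m1):
                continue
            if m0 < DE_NOVO_BASE_MAX and (m1 - m0) >= MIN_DELTA:
                called, at = True, f"{s_from}->{s_to}"
                break
        row = {"chrom": cgi.chrom, "start": cgi.start, "end": cgi.end}
        for s in stage_order:
            row[f"mean_{s}"] = stage_means[s][i]
        row["de_novo"] = called
        row["transition"] = at
        rows.append(row)
    return pd.DataFrame(rows)


def methylation_cv(per_cell_levels: pd.DataFrame) -> pd.Series:
    """Coefficient of variation (sd/mean, ddof=1) per feature across cells.

    ``per_cell_levels``: features x cells, NaN = undefined in that cell.
    Features with < 2 defined cells or zero mean return NaN.
    """
    mean = per_cell_levels.mean(axis=1)
    sd = per_cell_levels.std(axis=1, ddof=1)
    n = per_cell_levels.notna().sum(axis=1)
    cv = sd / mean
    cv[(n < 2) | (mean == 0)] = np.nan
    return cv


def correlate_omics(
    promoter_meth: pd.Series,
    promoter_access: pd.Series,
    expression: pd.Series,
    method: str = "spearman",
) -> pd.DataFrame:
    """Pairwise correlations among methylation, accessibility, expression.

    Vectors are aligned on their shared index; missing values are dropped
    pairwise.  Pairs with < 3 shared genes are NaN.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    series = {
        "meth": promoter_meth,
        "access": promoter_access,
        "expression": expression,
    }
    names = list(series)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            x, y = series[names[i]].align(series[names[j]], join="inner")
            ok = x.notna() & y.notna()
            n = int(ok.sum())
            if n < 3:
                r = float("nan")
            elif method == "spearman":
                r = float(stats.spearmanr(x[ok], y[ok]).statistic)
            else:
                r = float(stats.pearsonr(x[ok], y[ok]).statistic)
            rows.append({"pair": f"{names[i]}~{names[j]}", "r": r, "n": n})
    return pd.DataFrame(rows)
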