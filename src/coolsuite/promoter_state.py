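"""Promoter chromatin-state calling per cell and across the population.

Per cell, a promoter's assessment region (its merged-cell promoter NDR,
or a fixed window around the TSS when none exists) is called:

* ``open``        >= 5 covered GCH sites and mean level > 0.5
* ``closed``      >= 5 covered GCH sites and mean level < 0.3
* ``undefined``   >= 5 covered GCH sites and mean level in [0.3, 0.5]
* ``not_covered`` fewer than 5 covered GCH sites

Across cells, promoters covered in at least half of all sequenced cells
are labelled from the fraction f of definitive calls that are open:
homogeneously open (f > 0.7), homogeneously closed (f < 0.3), divergent
(0.3 <= f <= 0.7), or unclassified when no definitive call exists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from coolsuite.intervals import GenomicInterval

OPEN_LEVEL = 0.5
CLOSED_LEVEL = 0.3
MIN_SITES = 5
POP_OPEN_FRACTION = 0.7
POP_CLOSED_FRACTION = 0.3

UPSTREAM_BP = 200
DOWNSTREAM_BP = 100


@dataclass(frozen=True)
class CellPromoterCall:
    promoter: str
    cell: str
    level: float
    n_sites: int
    call: str  # open | closed | undefined | not_covered


def assessment_region(
    tss: int,
    strand: str,
    chrom: str,
    merged_ndrs: Sequence[GenomicInterval] = (),
) -> GenomicInterval:
    """The promoter NDR containing the TSS, else [TSS-200, TSS+100) strand-aware."""
    hits = [iv for iv in merged_ndrs if iv.contains_point(chrom, tss)]
    if hits:
        if len(hits) > 1:
            # should be impossible after merging; take the widest
            logging.getLogger(__name__).warning(
                "TSS %s:%d inside %d NDRs; using widest", chrom, tss, len(hits)
            )
        return max(hits, key=lambda iv: iv.width)
    if strand == "+":
        start, end = tss - UPSTREAM_BP, tss + DOWNSTREAM_BP
    else:
        start, end = tss - DOWNSTREAM_BP + 1, tss + UPSTREAM_BP + 1
    return GenomicInterval(chrom, max(start, 0), end)


def call_cell_state(
    promoter: str,
    cell: str,
    region: GenomicInterval,
    gch_levels: pd.DataFrame,
    min_sites: int = MIN_SITES,
) -> CellPromoterCall:
    """Call one promoter in one cell from that cell's GCH site levels.

    ``gch_levels`` should already honour the cross-cell depth policy
    (sites with >= 2x depth).
    """
    inside = (
        (gch_levels["chrom"] == region.chrom)
        & (gch_levels["pos"] >= region.start)
        & (gch_levels["pos"] < region.end)
    )
    n = int(inside.sum())
    if n < min_sites:
        return CellPromoterCall(promoter, cell, float("nan"), n, "not_covered")
    level = float(gch_levels.loc[inside, "level"].mean())
    return CellPromoterCall(promoter, cell, level, n, call_from_level(level))


def call_from_level(level: float) -> str:
    """open/closed/undefined from a mean GCH level (strict inequalities)."""
    if level > OPEN_LEVEL:
        return "open"
    if level < CLOSED_LEVEL:
        return "closed"
    return "undefined"


def classify_population(
    n_open: int, n_closed: int, n_covered: int, n_total_cells: int
) -> str:
    """Population label for one promoter.

    Coverage rule: labelled only if covered (any call but not_covered) in
    at least half of all sequenced cells.  f = open / (open + closed) over
    definitive calls; boundary f of exactly 0.3 or 0.7 is divergent.
    """
    if 2 * n_covered < n_total_cells:
        return "unclassified"
    definitive = n_open + n_closed
    if definitive == 0:
        return "unclassified"
    f = n_open / definitive
    if f > POP_OPEN_FRACTION:
        return "homogeneously_open"
    if f < POP_CLOSED_FRACTION:
        return "homogeneously_closed"
    return "divergent"


def build_state_matrix(
    tss_table: pd.DataFrame,
    cell_gch_levels: Mapping[str, pd.DataFrame],
    merged_ndrs: Sequence[GenomicInterval] = (),
    min_sites: int = MIN_SITES,
) -> pd.DataFrame:
    """Promoters x cells call matrix plus per-promoter population label.

    Rows are promoters (indexed by gene), columns one per cell holding the
    per-cell call, plus ``label`` with the population classification.
    """
    cells = list(cell_gch_levels)
    records: dict[str, dict[str, str]] = {}
    labels: dict[str, str] = {}
    for row in tss_table.itertuples(index=False):
        region = assessment_region(row.tss, row.strand, row.chrom, merged_ndrs)
        calls = {}
        for cell in cells:
            c = call_cell_state(row.gene, cell, region, cell_gch_levels[cell], min_sites)
            calls[cell] = c.call
        n_open = sum(1 for v in calls.values() if v == "open")
        n_closed = sum(1 for v in calls.values() if v == "closed")
        n_covered = sum(1 for v in calls.values() if v != "not_covered")
        labels[row.gene] = classify_population(n_open, n_closed, n_covered, len(cells))
        records[row.gene] = calls
    out = pd.DataFrame.from_dict(records, orient="index", columns=cells)
    out["label"] = pd.Series(labels)
    return out


# ---------------------------------------------------------------------------
# sensitivity worked example: what a sparse single-cell method can resolve
# ---------------------------------------------------------------------------

def sensitivity_fractions(
    p_open: float = 0.5, p_detect: float = 0.2, discriminating: bool = True
) -> dict[str, float]:
    """Analytic call fractions for a locus truly open in ``p_open`` of cells
    assayed at per-cell detection probability ``p_detect``.

    A discriminating method resolves every detected cell as open or
    closed; a non-discriminating one cannot tell closed from undetected,
    so only detected-and-open cells escape the undetermined pool.
    Returns fractions (not %) of open, closed and undetermined calls plus
    the open:closed ratio estimate where defined.
    """
    open_frac = p_detect * p_open
    if discriminating:
        closed_frac = p_detect * (1.0 - p_open)
        undetermined = 1.0 - p_detect
    else:
        closed_frac = 0.0
        undetermined = 1.0 - open_frac
    ratio = open_frac / closed_frac if closed_frac > 0 else float("nan")
    return {
        "open": open_frac,
        "closed": closed_frac,
        "undetermined": undetermined,
        "open_closed_ratio": ratio,
    }


def simulate_sensitivity(
    n_cells: int,
    p_open: float = 0.5,
    p_detect: float = 0.2,
    discriminating: bool = True,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Monte-Carlo version of :func:`sensitivity_fractions`."""
    rng = np.random.default_rng() if rng is None else rng
    truly_open = rng.random(n_cells) < p_open
    detected = rng.random(n_cells) < p_detect
    open_calls = detected & truly_open
    if discriminating:
        closed_calls = detected & ~truly_open
    else:
        closed_calls = np.zeros(n_cells, dtype=bool)
    undetermined = ~(open_calls | closed_calls)
    n_closed = int(closed_calls.sum())
    return {
        "open": open_calls.sum() / n_cells,
        "closed": n_closed / n_cells,
        "undetermined": undetermined.sum() / n_cells,
        "open_closed_ratio": (
            open_calls.sum() / n_closed if n_closed else float("nan")
        ),
    }
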