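"""Parental-allele partitioning of reads via heterozygous SNPs.

Bisulfite conversion makes some allele pairs unreadable on one strand:
on top-strand reads an unmethylated C is reported as T (so C/T pairs are
uninformative there), and on bottom-strand reads a G is reported as A
(G/A pairs uninformative).  Informative SNPs are therefore
strand-restricted, and base matching is conversion-aware on the usable
strand.  Reads are assigned by majority vote over informative SNPs.

Read records are simplified alignment stand-ins: one row per read with
its span, strand, SNP base observations and methylation observations.
"""

from __future__ import annotations

from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from coolsuite.intervals import GenomicInterval

ASSIGNMENTS = ("maternal", "paternal", "unassigned", "conflict")


def filter_informative_snps(snps: pd.DataFrame) -> pd.DataFrame:
    """Annotate SNPs with per-strand usability; drop fully unusable ones.

    Adds boolean ``usable_top`` / ``usable_bottom`` columns.  A C/T pair
    is unusable on the top strand, a G/A pair on the bottom strand; with
    two distinct alleles a SNP is never unusable on both, but the drop
    rule is applied for safety.
    """
    bad = snps["maternal"] == snps["paternal"]
    if bad.any():
        lines = (snps.index[bad] + 1).tolist()
        raise ValueError(f"homozygous SNP rows (1-based): {lines}")
    pair = snps.apply(lambda r: frozenset((r["maternal"], r["paternal"])), axis=1)
    out = snps.copy()
    out["usable_top"] = pair != frozenset("CT")
    out["usable_bottom"] = pair != frozenset("GA")
    out = out[out["usable_top"] | out["usable_bottom"]]
    return out.reset_index(drop=True)


def _matches(observed: str, allele: str, strand: str) -> bool:
    """Conversion-aware base match on the read's strand."""
    if observed == allele:
        return True
    if strand == "+" and allele == "C" and observed == "T":
        return True
    if strand == "-" and allele == "G" and observed == "A":
        return True
    return False


def assign_reads(reads: pd.DataFrame, usable_snps: pd.DataFrame) -> pd.DataFrame:
    """Assign each read maternal/paternal/unassigned/conflict.

    ``reads`` columns: read_id, cell, chrom, start, end, strand, snp_obs
    (list of (pos, base)), meth_obs (list of (pos, context, meth01)).
    Majority vote over SNPs usable on the read's strand; no informative
    SNP -> unassigned; tied non-zero evidence -> conflict.
    """
    lut: dict[tuple[str, int], tuple[str, str, bool, bool]] = {}
    for r in usable_snps.itertuples(index=False):
        lut[(r.chrom, r.pos)] = (r.maternal, r.paternal, r.usable_top, r.usable_bottom)

    assignments = []
    n_informative = []
    for read in reads.itertuples(index=False):
        mat = pat = 0
        for pos, base in read.snp_obs or []:
            snp = lut.get((read.chrom, pos))
            if snp is None:
                continue
            m_allele, p_allele, top_ok, bottom_ok = snp
            if read.strand == "+" and not top_ok:
                continue
            if read.strand == "-" and not bottom_ok:
                continue
            m_hit = _matches(base, m_allele, read.strand)
            p_hit = _matches(base, p_allele, read.strand)
            if m_hit and not p_hit:
                mat += 1
            elif p_hit and not m_hit:
                pat += 1
        if mat == 0 and pat == 0:
            call = "unassigned"
        elif mat > pat:
            call = "maternal"
        elif pat > mat:
            call = "paternal"
        else:
            call = "conflict"
        assignments.append(call)
        n_informative.append(mat + pat)
    out = reads.copy()
    out["assignment"] = assignments
    out["n_informative"] = n_informative
    return out


def _site_level_table(assigned: pd.DataFrame, which: str) -> pd.DataFrame:
    """Aggregate one allele's methylation observations to site levels."""
    rows = []
    for read in assigned[assigned["assignment"] == which].itertuples(index=False):
        for pos, context, m in read.meth_obs or []:
            rows.append((read.chrom, pos, context, int(m)))
    if not rows:
        return pd.DataFrame(columns=["chrom", "pos", "context", "meth", "total", "level"])
    df = pd.DataFrame(rows, columns=["chrom", "pos", "context", "m"])
    g = df.groupby(["chrom", "pos", "context"], as_index=False).agg(
        meth=("m", "sum"), total=("m", "size")
    )
    g["level"] = g["meth"] / g["total"]
    return g


def allelic_summary(
    assigned: pd.DataFrame,
    classify_site: Callable[[str, int], str],
    cells: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-cell, per-element-class, per-allele WCG and GCH levels.

    ``classify_site(chrom, pos)`` maps a site to its element class
    (e.g. intragenic / intergenic / CGI).  Levels are unweighted means of
    per-site levels from reads of that allele; ``difference`` columns are
    paternal - maternal.  Classes with no assigned sites are NaN.
    """
    cells = sorted(assigned["cell"].unique()) if cells is None else list(cells)
    rows = []
    for cell in cells:
        sub = assigned[assigned["cell"] == cell]
        per_allele = {
            al: _site_level_table(sub, al) for al in ("maternal", "paternal")
        }
        classes = set()
        for tab in per_allele.values():
            if len(tab):
                tab["element"] = [
                    classify_site(c, p) for c, p in zip(tab["chrom"], tab["pos"])
                ]
                classes.update(tab["element"].unique())
        for element in sorted(classes):
            row: dict = {"cell": cell, "element": element}
            for channel in ("WCG", "GCH"):
                for al in ("maternal", "paternal"):
                    tab = per_allele[al]
                    if len(tab):
                        sel = (tab["element"] == element) & (tab["context"] == channel)
                        row[f"{channel.lower()}_{al}"] = (
                            float(tab.loc[sel, "level"].mean()) if sel.any() else np.nan
                        )
                    else:
                        row[f"{channel.lower()}_{al}"] = np.nan
                row[f"{channel.lower()}_diff"] = (
                    row[f"{channel.lower()}_paternal"] - row[f"{channel.lower()}_maternal"]
                )
            rows.append(row)
    return pd.DataFrame(rows)


def icr_region_check(
    regions: Sequence[GenomicInterval], assigned: pd.DataFrame
) -> pd.DataFrame:
    """Per-region, per-allele WCG levels (imprinting-control-style check).

    Regions covered only by unassigned reads come back NaN on both
    alleles.
    """
    per_allele = {al: _site_level_table(assigned, al) for al in ("maternal", "paternal")}
    rows = []
    for iv in regions:
        row = {"chrom": iv.chrom, "start": iv.start, "end": iv.end}
        for al, tab in per_allele.items():
            if len(tab):
                sel = (
                    (tab["chrom"] == iv.chrom)
                    & (tab["pos"] >= iv.start)
                    & (tab["pos"] < iv.end)
                    & (tab["context"] == "WCG")
                )
                row[al] = float(tab.loc[sel, "level"].mean()) if sel.any() else np.nan
            else:
                row[al] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def assignment_counts(assigned: pd.DataFrame) -> dict[str, int]:
    """Read counts by assignment class (sums to the total read count)."""
    counts = assigned["assignment"].value_counts().to_dict()
    return {k: int(counts.get(k, 0)) for k in ASSIGNMENTS}


def make_element_classifier(
    intragenic: Sequence[GenomicInterval],
    cgis: Sequence[GenomicInterval],
) -> Callable[[str, int], str]:
    """Site -> element class; CGI takes precedence over intragenic."""

    def classify(chrom: str, pos: int) -> str:
        for iv in cgis:
            if iv.contains_point(chrom, pos):
                return "CGI"
        for iv in intragenic:
            if iv.contains_point(chrom, pos):
                return "intragenic"
        return "intergenic"

    return classify
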