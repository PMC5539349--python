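"""Trinucleotide context classification and channel routing.

Every cytosine (on either strand) is classified by the trinucleotide read
on its own strand:

* ``WCG`` (W = A/T): endogenous CpG methylation channel
* ``GCH`` (H = A/C/T): enzyme-deposited accessibility channel
* ``GCG`` and ``CCG``: excluded from both channels (enzyme on-target
  ambiguity and off-target activity respectively)
* ``OTHER``: everything else, including any 3-mer touching an N or a
  chromosome edge

The five classes partition all middle-C 3-mers.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

_W = frozenset("AT")
_H = frozenset("ACT")


def classify_trinucleotide(tri: str) -> str:
    """Classify a 3-mer whose middle base is C (on the C's own strand)."""
    if len(tri) != 3 or tri[1] != "C":
        raise ValueError(f"not a middle-C trinucleotide: {tri!r}")
    prev, nxt = tri[0], tri[2]
    if prev == "G":
        if nxt == "G":
            return "GCG"
        if nxt in _H:
            return "GCH"
        return "OTHER"
    if nxt == "G":
        if prev == "C":
            return "CCG"
        if prev in _W:
            return "WCG"
        return "OTHER"
    return "OTHER"


def reverse_complement(seq: str) -> str:
    return "".join(COMPLEMENT.get(b, "N") for b in reversed(seq))


def classify_cytosines(genome: dict[str, str]) -> pd.DataFrame:
    """Classify every cytosine on both strands of every chromosome.

    Returns a table with columns chrom, pos (0-based), strand, tri, context.
    A minus-strand row at position i corresponds to a G in the forward
    sequence; its trinucleotide is read on the minus strand.
    """
    frames = []
    for chrom, seq in genome.items():
        frames.append(_classify_one(chrom, seq.upper()))
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "tri", "context"])
    return pd.concat(frames, ignore_index=True)


def _classify_one(chrom: str, seq: str) -> pd.DataFrame:
    arr = np.frombuffer(seq.encode("ascii"), dtype="S1")
    n = len(arr)
    rows: dict[str, list] = {"pos": [], "strand": [], "tri": [], "context": []}

    plus_pos = np.flatnonzero(arr == b"C")
    for i in plus_pos:
        if i == 0 or i == n - 1:
            tri, ctx = _edge_tri(seq, i), "OTHER"
        else:
            tri = seq[i - 1 : i + 2]
            ctx = "OTHER" if "N" in tri else classify_trinucleotide(tri)
        rows["pos"].append(int(i))
        rows["strand"].append("+")
        rows["tri"].append(tri)
        rows["context"].append(ctx)

    minus_pos = np.flatnonzero(arr == b"G")
    for i in minus_pos:
        if i == 0 or i == n - 1:
            tri, ctx = "NCN", "OTHER"
        else:
            tri = reverse_complement(seq[i - 1 : i + 2])
            ctx = "OTHER" if "N" in tri else classify_trinucleotide(tri)
        rows["pos"].append(int(i))
        rows["strand"].append("-")
        rows["tri"].append(tri)
        rows["context"].append(ctx)

    df = pd.DataFrame(rows)
    df.insert(0, "chrom", chrom)
    return df.sort_values(["pos", "strand"], ignore_index=True)


def _edge_tri(seq: str, i: int) -> str:
    left = seq[i - 1] if i > 0 else "N"
    right = seq[i + 1] if i < len(seq) - 1 else "N"
    return left + "C" + right


def annotate_calls(
    calls: pd.DataFrame, context_map: pd.DataFrame, strict: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Route calls into (wcg_table, gch_table) by genome context.

    GCG/CCG/OTHER rows are dropped from both channels.  With ``strict``,
    a call at a position where the genome has no C on the stated strand
    raises a consistency error.
    """
    ctx = context_map.set_index(["chrom", "pos", "strand"])
    keyed = calls.set_index(["chrom", "pos", "strand"])
    missing = keyed.index.difference(ctx.index)
    if len(missing) and strict:
        chrom, pos, strand = missing[0]
        raise ValueError(
            f"call at {chrom}:{pos}({strand}) has no cytosine on that strand "
            f"({len(missing)} such calls)"
        )
    merged = calls.merge(
        context_map[["chrom", "pos", "strand", "context", "tri"]],
        on=["chrom", "pos", "strand"],
        how="inner",
        suffixes=("_call", ""),
    )
    keep = ["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]
    wcg = merged.loc[merged["context"] == "WCG", keep].reset_index(drop=True)
    gch = merged.loc[merged["context"] == "GCH", keep].reset_index(drop=True)
    return wcg, gch


def split_channels(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a call table that already carries a context column."""
    wcg = calls.loc[calls["context"] == "WCG"].reset_index(drop=True)
    gch = calls.loc[calls["context"] == "GCH"].reset_index(drop=True)
    return wcg, gch
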