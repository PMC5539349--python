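"""Readers and writers for the on-disk formats.

Internal convention: 0-based half-open coordinates.  Cytosine reports and
SNP tables are 1-based on disk (Bismark-style) and converted here, at the
boundary.  All tables are tab-separated plain text.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from coolsuite.intervals import GenomicInterval

logger = logging.getLogger(__name__)

VALID_CONTEXTS = frozenset({"WCG", "GCH", "GCG", "CCG", "OTHER"})
VALID_BASES = frozenset("ACGT")

#: columns of an in-memory cytosine call table (pos is 0-based internally)
CALL_COLUMNS = ["chrom", "pos", "strand", "meth", "unmeth", "context", "tri"]


class ParseError(ValueError):
    """Malformed input line; message carries the file and line number."""


# ---------------------------------------------------------------------------
# cytosine report (Bismark CX-style dialect + explicit context class column)
# ---------------------------------------------------------------------------

def read_cytosine_report(path: str | Path) -> pd.DataFrame:
    """Read a 7-column cytosine report into a call table.

    File columns: chrom, pos (1-based), strand, meth_count, unmeth_count,
    context_class, trinucleotide.  Returns a DataFrame with 0-based ``pos``.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ParseError(
                    f"{path}:{lineno}: expected 7 tab-separated fields, got {len(fields)}"
                )
            chrom, pos_s, strand, meth_s, unmeth_s, context, tri = fields
            try:
                pos = int(pos_s)
                meth = int(meth_s)
                unmeth = int(unmeth_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field ({exc})") from None
            if pos < 1:
                raise ParseError(f"{path}:{lineno}: position must be >= 1, got {pos}")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            if meth < 0 or unmeth < 0:
                raise ParseError(f"{path}:{lineno}: negative count")
            if context not in VALID_CONTEXTS:
                raise ParseError(f"{path}:{lineno}: unknown context class {context!r}")
            if len(tri) != 3 or tri[1] != "C":
                raise ParseError(
                    f"{path}:{lineno}: trinucleotide {tri!r} is not a 3-mer with middle C"
                )
            rows.append((chrom, pos - 1, strand, meth, unmeth, context, tri))
    df = pd.DataFrame(rows, columns=CALL_COLUMNS)
    logger.info("read %d cytosine calls from %s", len(df), path)
    return df


def write_cytosine_report(calls: pd.DataFrame, path: str | Path) -> None:
    """Write a call table (0-based internally) as a 1-based 7-column report."""
    out = calls.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out[CALL_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def empty_call_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=int),
            "strand": pd.Series(dtype=str),
            "meth": pd.Series(dtype=int),
            "unmeth": pd.Series(dtype=int),
            "context": pd.Series(dtype=str),
            "tri": pd.Series(dtype=str),
        }
    )


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def write_bed(
    intervals: Sequence[GenomicInterval],
    path: str | Path,
    extra_columns: Sequence[Sequence] | None = None,
) -> None:
    """Write intervals as BED (0-based half-open, like the internal model).

    With ``extra_columns`` (one row of extras per interval) emits
    chrom/start/end/name/score/strand followed by the extras.
    """
    if extra_columns is not None and len(extra_columns) != len(intervals):
        raise ValueError("extra_columns length must match intervals")
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.strand is not None or extra_columns is not None:
                fields.append(iv.name if iv.name is not None else ".")
                fields.append("0")
                fields.append(iv.strand if iv.strand is not None else ".")
            if extra_columns is not None:
                fields.extend(str(x) for x in extra_columns[i])
            fh.write("\t".join(fields) + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+; name and strand are picked up from columns 4 and 6."""
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
            if start >= end:
                raise ParseError(f"{path}:{lineno}: start >= end")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else None
            intervals.append(GenomicInterval(chrom, start, end, strand=strand, name=name))
    return intervals


# ---------------------------------------------------------------------------
# SNP table
# ---------------------------------------------------------------------------

def read_snp_table(path: str | Path) -> pd.DataFrame:
    """Read a heterozygous SNP TSV: chrom, pos (1-based), maternal, paternal."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields")
            chrom, pos_s, mat, pat = fields
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer position") from None
            if mat not in VALID_BASES or pat not in VALID_BASES:
                raise ParseError(f"{path}:{lineno}: bases must be A/C/G/T")
            if mat == pat:
                raise ParseError(f"{path}:{lineno}: homozygous SNP ({mat}/{pat})")
            rows.append((chrom, pos - 1, mat, pat))
    return pd.DataFrame(rows, columns=["chrom", "pos", "maternal", "paternal"])


def write_snp_table(snps: pd.DataFrame, path: str | Path) -> None:
    out = snps.copy()
    out["pos"] = out["pos"].astype(int) + 1
    out[["chrom", "pos", "maternal", "paternal"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# TSS / gene annotation
# ---------------------------------------------------------------------------

def read_tss_table(path: str | Path) -> pd.DataFrame:
    """Read a TSS annotation as TSV (gene, chrom, tss, strand) or BED6.

    BED6 rows are normalized to the TSV model with TSS = strand-aware 5' end.
    Returned ``tss`` is a 0-based position.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 4:
                gene, chrom, tss_s, strand = fields
                try:
                    tss = int(tss_s)
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-integer TSS") from None
            elif len(fields) >= 6:
                chrom, start_s, end_s, gene, _score, strand = fields[:6]
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-integer coordinates") from None
                tss = start if strand == "+" else end - 1
            else:
                raise ParseError(f"{path}:{lineno}: need 4 (TSV) or >= 6 (BED6) fields")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: bad strand {strand!r}")
            rows.append((gene, chrom, tss, strand))
    return pd.DataFrame(rows, columns=["gene", "chrom", "tss", "strand"])


def write_tss_table(tss: pd.DataFrame, path: str | Path) -> None:
    tss[["gene", "chrom", "tss", "strand"]].to_csv(
        path, sep="\t", header=False, index=False
    )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    genome: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    genome[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        genome[name] = "".join(chunks)
    return genome


# ---------------------------------------------------------------------------
# config / JSON helpers
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load a nested key/value config (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def _json_default(o):
    if hasattr(o, "item"):  # numpy scalars
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def dump_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def load_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def read_call_tables(directory: str | Path, pattern: str = "*.tsv") -> dict[str, pd.DataFrame]:
    """Read every per-cell cytosine report in a directory, keyed by stem."""
    directory = Path(directory)
    tables = {}
    for p in sorted(directory.glob(pattern)):
        tables[p.stem] = read_cytosine_report(p)
    return tables
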