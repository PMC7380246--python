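"""Per-cytosine methylation calls, gene models and region-level summaries.

The on-disk dialect is the Bismark-style cytosine report: one tab-separated
line per cytosine with chromosome, 1-based position, strand, methylated and
unmethylated read counts and sequence context (``CG``/``CHG``/``CHH``).  In
memory a collection of calls is a :class:`pandas.DataFrame` with the columns
in :data:`CALL_COLUMNS`; a single call is a :class:`MethylationCall`.

All coordinates in this package are 1-based inclusive; BED input is converted
at the boundary.  Calls on both strands are pooled for all region/window
statistics.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CONTEXTS",
    "CALL_COLUMNS",
    "MethylationCall",
    "GeneModel",
    "RegionMethylSummary",
    "ParseError",
    "read_cytosine_report",
    "write_cytosine_report",
    "read_gene_models",
    "write_gene_models",
    "region_methylation_summary",
    "write_region_summary",
]

#: Cytosine sequence contexts (H = A, C or T).
CONTEXTS = ("CpG", "CHG", "CHH")

#: Canonical column order for a call collection.
CALL_COLUMNS = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context"]

_CONTEXT_ALIASES = {
    "CG": "CpG",
    "CPG": "CpG",
    "CpG": "CpG",
    "CHG": "CHG",
    "CHH": "CHH",
}


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass(frozen=True)
class MethylationCall:
    """One cytosine in one sample."""

    chrom: str
    pos: int          # 1-based
    strand: str       # '+' or '-'
    n_meth: int
    n_unmeth: int
    context: str      # 'CpG', 'CHG' or 'CHH'

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.n_meth < 0 or self.n_unmeth < 0:
            raise ValueError("read counts must be non-negative")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")

    @property
    def coverage(self) -> int:
        return self.n_meth + self.n_unmeth


@dataclass(frozen=True)
class GeneModel:
    """A gene span; coordinates 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id}: end {self.end} < start {self.start}"
            )


GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]


def _normalize_context(tokens: pd.Series) -> pd.Series:
    return tokens.map(_CONTEXT_ALIASES)


def read_cytosine_report(
    path: str | Path | _io.IOBase, min_coverage: int = 5
) -> pd.DataFrame:
    """Read a cytosine report, keeping calls with coverage >= *min_coverage*.

    Parameters
    ----------
    path
        Tab-separated file: chrom, pos (1-based), strand, count_methylated,
        count_unmethylated, context (``CG``/``CHG``/``CHH``); an optional
        seventh trinucleotide column is ignored.
    min_coverage
        Minimum total reads (methylated + unmethylated) for a call to be
        retained.  The default of 5 reads matches the coverage floor used
        throughout the DMR analysis.

    Returns
    -------
    pandas.DataFrame with :data:`CALL_COLUMNS`, input order preserved.
    """
    if min_coverage < 0:
        raise ValueError("min_coverage must be >= 0")
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, dtype=str, comment=None,
            skip_blank_lines=False,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=CALL_COLUMNS).astype(
            {"pos": int, "n_meth": int, "n_unmeth": int}
        )
    except pd.errors.ParserError as exc:
        raise ParseError(f"malformed cytosine report: {exc}") from exc

    if df.shape[1] not in (6, 7):
        raise ParseError(
            f"cytosine report must have 6 or 7 columns, found {df.shape[1]}"
        )
    df = df.iloc[:, :6]
    df.columns = CALL_COLUMNS

    def _bad_line(mask: pd.Series, why: str) -> None:
        if mask.any():
            lineno = int(mask.idxmax()) + 1
            raise ParseError(f"line {lineno}: {why}")

    _bad_line(df.isna().any(axis=1), "wrong column count")
    for col in ("pos", "n_meth", "n_unmeth"):
        _bad_line(~df[col].str.fullmatch(r"\d+"), f"non-integer {col}")
        df[col] = df[col].astype(np.int64)
    _bad_line(df["pos"] < 1, "position must be >= 1")
    _bad_line(~df["strand"].isin(["+", "-"]), "strand must be + or -")
    ctx = _normalize_context(df["context"])
    _bad_line(ctx.isna(), "unknown context")
    df["context"] = ctx

    keep = (df["n_meth"] + df["n_unmeth"]) >= min_coverage
    return df.loc[keep].reset_index(drop=True)


def write_cytosine_report(calls: pd.DataFrame, path: str | Path) -> None:
    """Write calls in the cytosine-report dialect (6 columns, CpG -> CG)."""
    out = calls[CALL_COLUMNS].copy()
    out["context"] = out["context"].replace({"CpG": "CG"})
    out.to_csv(path, sep="\t", header=False, index=False)


def _read_bed_genes(df: pd.DataFrame) -> pd.DataFrame:
    if df.shape[1] < 4:
        raise ParseError("BED gene file needs at least 4 columns")
    out = pd.DataFrame(
        {
            "gene_id": df.iloc[:, 3].astype(str),
            "chrom": df.iloc[:, 0].astype(str),
            "start": df.iloc[:, 1].astype(np.int64) + 1,  # 0-based half-open
            "end": df.iloc[:, 2].astype(np.int64),
            "strand": df.iloc[:, 5].astype(str) if df.shape[1] >= 6 else "+",
        }
    )
    return out


_GFF_COLS = [
    "chrom", "source", "type", "start", "end",
    "score", "strand", "phase", "attributes",
]


def _gff_gene_id(attrs: str) -> str:
    for field in attrs.split(";"):
        field = field.strip()
        for key in ("ID=", "Name=", "gene_id="):
            if field.startswith(key):
                return field[len(key):].strip('"')
    return attrs


def _read_gff_genes(df: pd.DataFrame) -> pd.DataFrame:
    df.columns = _GFF_COLS
    genes = df[df["type"].str.lower() == "gene"]
    if genes.empty:  # annotations without explicit gene features
        genes = df
    return pd.DataFrame(
        {
            "gene_id": genes["attributes"].map(_gff_gene_id),
            "chrom": genes["chrom"].astype(str),
            "start": genes["start"].astype(np.int64),
            "end": genes["end"].astype(np.int64),
            "strand": genes["strand"].astype(str),
        }
    )


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Read gene models from GFF3 or BED into 1-based inclusive coordinates.

    Dialect is sniffed: 9 columns (or a ``##gff`` header) means GFF3, in which
    case rows of type ``gene`` are kept; otherwise 4-6 column BED is assumed
    and the half-open 0-based start is shifted by +1.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=GENE_COLUMNS).astype({"start": int, "end": int})
    if df.shape[1] == 9:
        out = _read_gff_genes(df)
    else:
        out = _read_bed_genes(df)
    bad = out["end"] < out["start"]
    if bad.any():
        raise ParseError(
            f"gene {out.loc[bad.idxmax(), 'gene_id']}: end < start"
        )
    if out["gene_id"].duplicated().any():
        dup = out.loc[out["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ParseError(f"duplicate gene_id {dup!r}")
    return out.reset_index(drop=True)


def write_gene_models(genes: pd.DataFrame, path: str | Path) -> None:
    """Write gene models as 6-column BED (converting back to 0-based starts)."""
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"] - 1,
            "end": genes["end"],
            "name": genes["gene_id"],
            "score": ".",
            "strand": genes["strand"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class RegionMethylSummary:
    """Per-context percent methylation over a genomic region.

    ``table`` is indexed by context with columns ``n_cytosines``,
    ``n_meth_calls``, ``n_total_calls`` and ``percent``.  The percent is
    read-weighted: 100 * sum(n_meth) / sum(n_meth + n_unmeth) over qualifying
    cytosines of that context; contexts with no qualifying cytosine have
    percent NaN (undefined, not zero).
    """

    chrom: str
    start: int
    end: int
    table: pd.DataFrame

    def percent(self, context: str) -> float:
        return float(self.table.loc[context, "percent"])


def region_methylation_summary(
    calls: pd.DataFrame,
    chrom: str,
    start: int,
    end: int,
    min_coverage: int = 5,
) -> RegionMethylSummary:
    """Summarize percent methylation per context over ``chrom:start-end``.

    Both strands are pooled.  Cytosines with coverage below *min_coverage*
    are ignored.
    """
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    sel = calls[
        (calls["chrom"] == chrom)
        & (calls["pos"] >= start)
        & (calls["pos"] <= end)
        & ((calls["n_meth"] + calls["n_unmeth"]) >= min_coverage)
    ]
    rows = []
    for ctx in CONTEXTS:
        sub = sel[sel["context"] == ctx]
        n_meth = int(sub["n_meth"].sum())
        n_total = int((sub["n_meth"] + sub["n_unmeth"]).sum())
        pct = 100.0 * n_meth / n_total if n_total > 0 else np.nan
        rows.append((ctx, len(sub), n_meth, n_total, pct))
    table = pd.DataFrame(
        rows, columns=["context", "n_cytosines", "n_meth_calls",
                       "n_total_calls", "percent"]
    ).set_index("context")
    return RegionMethylSummary(chrom, start, end, table)


def write_region_summary(
    summaries: Iterable[RegionMethylSummary], path: str | Path
) -> None:
    """Emit region summaries as TSV (one row per region x context)."""
    frames = []
    for s in summaries:
        t = s.table.reset_index()
        t.insert(0, "chrom", s.chrom)
        t.insert(1, "start", s.start)
        t.insert(2, "end", s.end)
        frames.append(t)
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["chrom", "start", "end", "context", "n_cytosines",
                 "n_meth_calls", "n_total_calls", "percent"]
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def calls_to_records(calls: pd.DataFrame) -> list[MethylationCall]:
    """Convert a call DataFrame to a list of :class:`MethylationCall`."""
    return [MethylationCall(**row) for row in calls[CALL_COLUMNS].to_dict("records")]


def records_to_calls(records: Iterable[MethylationCall]) -> pd.DataFrame:
    """Convert :class:`MethylationCall` records to the canonical DataFrame."""
    rows = [
        (r.chrom, r.pos, r.strand, r.n_meth, r.n_unmeth, r.context)
        for r in records
    ]
    return pd.DataFrame(rows, columns=CALL_COLUMNS)
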