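"""Readers and writers for the text formats the pipeline touches.

Supported formats: BED3/BED6, ENCODE narrowPeak (BED6+4), refFlat gene
models, bedGraph signal tracks, DESeq2-shaped expression TSVs, and TSV/JSON
result tables. All on-disk coordinates follow each format's own convention;
in memory everything is 0-based half-open.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import GeneModel, GenomicInterval


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line."""


_SKIP_PREFIXES = ("track", "browser", "#")


def _data_lines(path: str | Path):
    """Yield (lineno, stripped line), skipping track/browser/comment/blank."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


def _int_coord(text: str, path, lineno: int, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-integer {what} {text!r}") from None


def read_intervals(path: str | Path, format: str = "bed6") -> list[GenomicInterval]:
    """Read a BED3, BED6 or narrowPeak file into intervals, in file order.

    narrowPeak columns 7-10 (signalValue, pValue, qValue, peak) are kept as
    attributes; a summit offset of ``-1`` becomes ``None``. Strand is ``.``
    when the format carries none.
    """
    ncols = {"bed3": 3, "bed6": 6, "narrowpeak": 10}.get(format)
    if ncols is None:
        raise ValueError(f"unknown interval format {format!r}")
    out: list[GenomicInterval] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < ncols:
            raise ParseError(
                f"{path}:{lineno}: expected {ncols} columns, got {len(fields)}"
            )
        chrom = fields[0]
        start = _int_coord(fields[1], path, lineno, "start")
        end = _int_coord(fields[2], path, lineno, "end")
        if start >= end or start < 0:
            raise ParseError(f"{path}:{lineno}: invalid span {start}-{end}")
        kwargs: dict = {}
        if ncols >= 6:
            kwargs["name"] = fields[3] if fields[3] != "." else None
            kwargs["score"] = float(fields[4]) if fields[4] != "." else None
            kwargs["strand"] = fields[5] if fields[5] in ("+", "-") else "."
        if ncols == 10:
            kwargs["signal_value"] = float(fields[6])
            kwargs["peak_pvalue"] = float(fields[7])
            kwargs["peak_qvalue"] = float(fields[8])
            summit = _int_coord(fields[9], path, lineno, "summit")
            kwargs["summit"] = None if summit < 0 else summit
        out.append(GenomicInterval(chrom, start, end, **kwargs))
    return out


def write_intervals(
    intervals: Iterable[GenomicInterval], path: str | Path, format: str = "bed6"
) -> None:
    """Write intervals in the given dialect; inverse of :func:`read_intervals`."""
    if format not in ("bed3", "bed6", "narrowpeak"):
        raise ValueError(f"unknown interval format {format!r}")
    with open(path, "w") as fh:
        for iv in intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if format in ("bed6", "narrowpeak"):
                cols += [
                    iv.name if iv.name is not None else ".",
                    _num(iv.score, "0"),
                    iv.strand,
                ]
            if format == "narrowpeak":
                cols += [
                    _num(iv.signal_value, "0"),
                    _num(iv.peak_pvalue, "-1"),
                    _num(iv.peak_qvalue, "-1"),
                    str(iv.summit) if iv.summit is not None else "-1",
                ]
            fh.write("\t".join(cols) + "\n")


def _num(value: float | None, default: str) -> str:
    if value is None:
        return default
    return format(value, "g")


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read a refFlat file (11 tab-separated columns) into gene models.

    Columns: geneName, name, chrom, strand, txStart, txEnd, cdsStart,
    cdsEnd, exonCount, exonStarts, exonEnds. Coordinates are already
    0-based half-open. exonCount must match the comma-terminated lists.
    """
    genes: list[GeneModel] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 11:
            raise ParseError(f"{path}:{lineno}: expected 11 columns, got {len(fields)}")
        strand = fields[3]
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
        n_exons = _int_coord(fields[8], path, lineno, "exonCount")
        try:
            exon_starts = tuple(int(x) for x in fields[9].split(",") if x)
            exon_ends = tuple(int(x) for x in fields[10].split(",") if x)
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: malformed exon list in column 10/11"
            ) from None
        if len(exon_starts) != n_exons or len(exon_ends) != n_exons:
            raise ParseError(
                f"{path}:{lineno}: exonCount {n_exons} does not match exon lists"
            )
        try:
            genes.append(
                GeneModel(
                    gene_id=fields[0],
                    transcript_id=fields[1],
                    chrom=fields[2],
                    strand=strand,
                    tx_start=int(fields[4]),
                    tx_end=int(fields[5]),
                    cds_start=int(fields[6]),
                    cds_end=int(fields[7]),
                    exon_starts=exon_starts,
                    exon_ends=exon_ends,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                "\t".join(
                    [
                        g.gene_id,
                        g.transcript_id or g.gene_id,
                        g.chrom,
                        g.strand,
                        str(g.tx_start),
                        str(g.tx_end),
                        str(g.cds_start),
                        str(g.cds_end),
                        str(len(g.exon_starts)),
                        "".join(f"{s}," for s in g.exon_starts),
                        "".join(f"{e}," for e in g.exon_ends),
                    ]
                )
                + "\n"
            )


class SignalTrack:
    """A piecewise-constant genomic signal (the bedGraph model).

    Per chromosome: sorted, non-overlapping half-open steps with float
    values; bases not covered by any step have implicit value 0. Windowed
    integrals and means are exact (base-pair weighted), computed from a
    cumulative-integral index.
    """

    def __init__(self, steps: dict[str, Sequence[tuple[int, int, float]]] | None = None):
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        if steps:
            for chrom, triples in steps.items():
                self._set_chrom(chrom, triples)

    def _set_chrom(self, chrom: str, triples: Sequence[tuple[int, int, float]]) -> None:
        triples = sorted(triples)
        starts = np.array([t[0] for t in triples], dtype=np.int64)
        ends = np.array([t[1] for t in triples], dtype=np.int64)
        values = np.array([t[2] for t in triples], dtype=float)
        if np.any(starts >= ends):
            raise ValueError(f"{chrom}: step with non-positive span")
        if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"{chrom}: overlapping steps")
        cumint = np.concatenate([[0.0], np.cumsum(values * (ends - starts))])
        self._chrom[chrom] = (starts, ends, values, cumint)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chrom)

    def steps(self, chrom: str) -> list[tuple[int, int, float]]:
        if chrom not in self._chrom:
            return []
        starts, ends, values, _ = self._chrom[chrom]
        return [(int(s), int(e), float(v)) for s, e, v in zip(starts, ends, values)]

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Exact integral of the signal over ``[start, end)`` (0 off-track)."""
        return float(self.integrals(chrom, np.array([start]), np.array([end]))[0])

    def integrals(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorized exact integrals over many windows on one chromosome."""
        starts = np.asarray(starts, dtype=np.int64)
        ends = np.asarray(ends, dtype=np.int64)
        if chrom not in self._chrom:
            return np.zeros(len(starts))
        s, e, v, cum = self._chrom[chrom]
        i0 = np.searchsorted(e, starts, side="right")
        i1 = np.searchsorted(s, ends, side="left")
        total = cum[i1] - cum[i0]
        has = i0 < i1
        if np.any(has):
            head = np.clip(starts[has] - s[i0[has]], 0, None) * v[i0[has]]
            tail = np.clip(e[i1[has] - 1] - ends[has], 0, None) * v[i1[has] - 1]
            total[has] -= head + tail
        total[~has] = 0.0
        return total

    def mean(self, chrom: str, start: int, end: int) -> float:
        """Base-pair-weighted mean over ``[start, end)``, implicit zeros."""
        if end <= start:
            raise ValueError("window must have positive width")
        return self.integral(chrom, start, end) / (end - start)


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Line order is irrelevant; overlapping steps or non-positive spans are
    rejected as an ill-formed track.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        start = _int_coord(fields[1], path, lineno, "start")
        end = _int_coord(fields[2], path, lineno, "end")
        if start >= end or start < 0:
            raise ParseError(f"{path}:{lineno}: negative or empty span {start}-{end}")
        try:
            value = float(fields[3])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric value {fields[3]!r}") from None
        per_chrom.setdefault(fields[0], []).append((start, end, value))
    try:
        return SignalTrack(per_chrom)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            for start, end, value in track.steps(chrom):
                fh.write(f"{chrom}\t{start}\t{end}\t{format(value, 'g')}\n")


@dataclass(frozen=True)
class ExpressionRecord:
    """One gene's differential-expression result (DESeq2-shaped)."""

    gene_id: str
    log2fc: float
    pvalue: float
    padj: float | None = None


def read_expression(
    path: str | Path,
    gene_col: str = "gene",
    lfc_col: str = "log2FoldChange",
    p_col: str = "pvalue",
    padj_col: str = "padj",
) -> list[ExpressionRecord]:
    """Read a differential-expression TSV with configurable column names.

    The defaults match a DESeq2 results table. ``padj`` may be absent or
    NA. Duplicate gene ids and non-numeric fold changes are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={gene_col: str})
    for col in (gene_col, lfc_col, p_col):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    dupes = df[gene_col][df[gene_col].duplicated()]
    if len(dupes):
        raise ParseError(f"{path}: duplicate gene_id {dupes.iloc[0]!r}")
    lfc = pd.to_numeric(df[lfc_col], errors="coerce")
    if lfc.isna().any():
        bad = df.loc[lfc.isna(), gene_col].iloc[0]
        raise ParseError(f"{path}: non-numeric log2 fold change for gene {bad!r}")
    pvals = pd.to_numeric(df[p_col], errors="coerce")
    if pvals.isna().any() or ((pvals < 0) | (pvals > 1)).any():
        raise ParseError(f"{path}: p-values must be numbers in [0, 1]")
    padj = (
        pd.to_numeric(df[padj_col], errors="coerce")
        if padj_col in df.columns
        else pd.Series(np.nan, index=df.index)
    )
    return [
        ExpressionRecord(
            gene_id=g,
            log2fc=float(l),
            pvalue=float(p),
            padj=None if pd.isna(q) else float(q),
        )
        for g, l, p, q in zip(df[gene_col], lfc, pvals, padj)
    ]


def expression_frame(records: Sequence[ExpressionRecord]) -> pd.DataFrame:
    """Expression records as a DataFrame indexed by gene_id."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "log2fc": [r.log2fc for r in records],
            "pvalue": [r.pvalue for r in records],
            "padj": [np.nan if r.padj is None else r.padj for r in records],
        }
    ).set_index("gene_id")


def write_expression(records: Sequence[ExpressionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tlog2FoldChange\tpvalue\tpadj\n")
        for r in records:
            padj = "NA" if r.padj is None else format(r.padj, ".6g")
            fh.write(
                f"{r.gene_id}\t{r.log2fc:.6g}\t{format(r.pvalue, '.6g')}\t{padj}\n"
            )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV with stable float formatting."""
    df.to_csv(path, sep="\t", index=index, float_format="%.6g", na_rep="NA")


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
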