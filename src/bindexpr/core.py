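"""Coordinate conventions and strand-aware interval/distance primitives.

All coordinates are 0-based half-open (BED native). A peak is represented
by its integer midpoint ``floor((start + end) / 2)``; distances to a gene
are measured from that midpoint to the strand-aware transcription start
site (TSS). Signed distances follow the transcript's reading direction:
positive means the peak lies downstream of the TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class ChromosomeMismatchError(ValueError):
    """Raised when a distance is requested across different chromosomes."""


@dataclass(frozen=True)
class GenomicInterval:
    """A located span on a chromosome, half-open ``[start, end)``.

    The atom of peaks, gene features and signal steps. ``strand`` is one of
    ``+``, ``-`` or ``.`` (unstranded). narrowPeak extras (signal value,
    -log10 p/q, summit offset) ride along when present; a summit of ``-1``
    on disk is stored as ``None``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None
    score: float | None = None
    signal_value: float | None = None
    peak_pvalue: float | None = None
    peak_qvalue: float | None = None
    summit: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        """Integer midpoint, guaranteed inside ``[start, end)``."""
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    """A transcript model with a strand-aware TSS.

    ``tss`` is ``tx_start`` on the + strand and ``tx_end - 1`` on the
    - strand, so the TSS is always a covered genomic base of the
    transcript. ``gene_id`` is the gene symbol; ``transcript_id`` keeps the
    per-transcript accession when the source format provides one.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...] = field(default=())
    exon_ends: tuple[int, ...] = field(default=())
    transcript_id: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"gene {self.gene_id}: tx_start must be < tx_end")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError(f"gene {self.gene_id}: exon list length mismatch")
        prev_end = self.tx_start
        for s, e in zip(self.exon_starts, self.exon_ends):
            if s >= e or s < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons must be sorted, "
                    "non-overlapping and within the transcript"
                )
            prev_end = e
        if self.exon_ends and self.exon_ends[-1] > self.tx_end:
            raise ValueError(f"gene {self.gene_id}: exon beyond tx_end")

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share >= 1 bp on one chromosome."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def distance_to_tss(peak: GenomicInterval, gene: GeneModel) -> int:
    """Signed midpoint-to-TSS distance in the gene's reading direction.

    Positive means the peak midpoint lies downstream of the TSS (into the
    gene body), negative upstream. The absolute value is the distance used
    by the regulatory-potential decay.

    Raises
    ------
    ChromosomeMismatchError
        If peak and gene sit on different chromosomes (no distance
        defined; callers treat this as beyond any window).
    """
    if peak.chrom != gene.chrom:
        raise ChromosomeMismatchError(
            f"{peak.chrom} vs {gene.chrom}: no distance defined"
        )
    signed = peak.midpoint - gene.tss
    return signed if gene.strand == "+" else -signed


def nearest_gene(
    peak: GenomicInterval, genes: list[GeneModel]
) -> tuple[GeneModel, int] | None:
    """Gene whose TSS is closest to the peak midpoint, with |distance|.

    Ties are broken by lexicographic ``gene_id``. Returns ``None`` when no
    gene lies on the peak's chromosome (the peak is unassigned).
    """
    if not genes:
        raise ValueError("genes must be non-empty")
    best: tuple[int, str, GeneModel] | None = None
    for g in genes:
        if g.chrom != peak.chrom:
            continue
        d = abs(peak.midpoint - g.tss)
        key = (d, g.gene_id)
        if best is None or key < (best[0], best[1]):
            best = (d, g.gene_id, g)
    if best is None:
        return None
    return best[2], best[0]
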