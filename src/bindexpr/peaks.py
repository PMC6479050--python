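"""Peak co-occupancy classes, genomic-distribution annotation, width stats.

The three-class scheme for a focal factor against a partner factor:
Class I = focal peaks overlapping at least one partner peak (co-occupied),
Class II = focal peaks with no partner overlap, Class III = partner peaks
with no focal overlap. Overlap means >= ``min_overlap`` shared bases under
half-open coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .core import GeneModel, GenomicInterval

CATEGORIES = ("promoter", "5utr", "3utr", "coding_exon", "intron", "distal_intergenic")


@dataclass
class PeakClassification:
    """Class labels for a focal/partner peak pair of lists.

    ``focal_classes[i]`` is "I" or "II"; ``partner_classes[j]`` is
    "I-partner" or "III". ``partners[i]`` lists the partner indices
    overlapping Class I focal peak i (empty for Class II).
    """

    focal_classes: list[str]
    partner_classes: list[str]
    partners: list[list[int]]

    def focal_indices(self, label: str) -> list[int]:
        return [i for i, c in enumerate(self.focal_classes) if c == label]

    def counts(self) -> dict[str, int]:
        return {
            "I": self.focal_classes.count("I"),
            "II": self.focal_classes.count("II"),
            "III": self.partner_classes.count("III"),
        }


def _tree_index(peaks: list[GenomicInterval], min_overlap: int) -> dict[str, IntervalTree]:
    """Per-chromosome interval trees encoding the >= min_overlap rule.

    Both the stored spans and the queries have their right edge pulled in
    by ``min_overlap - 1``; together with the width guards, a tree hit is
    then exactly an overlap of at least ``min_overlap`` bases.
    """
    trees: dict[str, IntervalTree] = {}
    shrink = min_overlap - 1
    for j, p in enumerate(peaks):
        if p.width < min_overlap:
            continue
        trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end - shrink, j)
    return trees


def classify_peaks(
    focal: list[GenomicInterval],
    partner: list[GenomicInterval],
    min_overlap: int = 1,
) -> PeakClassification:
    """Partition both peak lists by mutual overlap.

    A focal peak is Class I iff it shares >= ``min_overlap`` bases with any
    partner peak, else Class II; a partner peak with no such focal overlap
    is Class III. Input order is irrelevant to the labels.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    shrink = min_overlap - 1
    partner_trees = _tree_index(partner, min_overlap)
    focal_classes: list[str] = []
    partners: list[list[int]] = []
    partner_hit = [False] * len(partner)
    for p in focal:
        tree = partner_trees.get(p.chrom)
        hits = (
            sorted(iv.data for iv in tree.overlap(p.start, p.end - shrink))
            if tree is not None and p.width >= min_overlap
            else []
        )
        if hits:
            focal_classes.append("I")
            partners.append(hits)
            for j in hits:
                partner_hit[j] = True
        else:
            focal_classes.append("II")
            partners.append([])
    partner_classes = ["I-partner" if h else "III" for h in partner_hit]
    return PeakClassification(focal_classes, partner_classes, partners)


@dataclass
class GenomicDistribution:
    """Per-peak annotation category and the aggregate fractions."""

    categories: list[str]

    @property
    def fractions(self) -> dict[str, float]:
        n = max(1, len(self.categories))
        return {c: self.categories.count(c) / n for c in CATEGORIES}


def _feature_trees(
    genes: list[GeneModel], promoter_halfwidth: int
) -> dict[str, dict[str, IntervalTree]]:
    """Interval trees per category per chromosome, built once per gene set."""
    trees: dict[str, dict[str, IntervalTree]] = {c: {} for c in CATEGORIES[:-1]}

    def add(cat: str, chrom: str, start: int, end: int) -> None:
        if start < end:
            trees[cat].setdefault(chrom, IntervalTree()).addi(start, end)

    for g in genes:
        add("promoter", g.chrom, max(0, g.tss - promoter_halfwidth), g.tss + promoter_halfwidth + 1)
        if g.strand == "+":
            add("5utr", g.chrom, g.tx_start, g.cds_start)
            add("3utr", g.chrom, g.cds_end, g.tx_end)
        else:
            add("5utr", g.chrom, g.cds_end, g.tx_end)
            add("3utr", g.chrom, g.tx_start, g.cds_start)
        for es, ee in zip(g.exon_starts, g.exon_ends):
            add("coding_exon", g.chrom, max(es, g.cds_start), min(ee, g.cds_end))
        prev = g.tx_start
        for es, ee in zip(g.exon_starts, g.exon_ends):
            add("intron", g.chrom, prev, es)
            prev = ee
        add("intron", g.chrom, prev, g.tx_end)
    return trees


def annotate_distribution(
    peaks: list[GenomicInterval],
    genes: list[GeneModel],
    promoter_halfwidth: int = 1000,
) -> GenomicDistribution:
    """Assign each peak midpoint to a single genomic category.

    Precedence promoter > 5'UTR > 3'UTR > coding exon > intron >
    distal intergenic, applied jointly across all genes: if the midpoint
    hits features of several genes, the highest-precedence category wins.
    The promoter is TSS +/- ``promoter_halfwidth``. Fractions sum to 1 by
    construction.
    """
    trees = _feature_trees(genes, promoter_halfwidth)
    categories: list[str] = []
    for p in peaks:
        m = p.midpoint
        for cat in CATEGORIES[:-1]:
            tree = trees[cat].get(p.chrom)
            if tree is not None and tree.overlaps_point(m):
                categories.append(cat)
                break
        else:
            categories.append("distal_intergenic")
    return GenomicDistribution(categories)


def width_stats(
    classification: PeakClassification,
    focal: list[GenomicInterval],
    partner: list[GenomicInterval],
) -> pd.DataFrame:
    """Per-class peak-width summaries plus a Class I vs II width test.

    Returns one row per class (I, II, III) with n, mean, median and
    quartiles of peak width, and on the Class I row the two-sided
    Mann-Whitney U p-value for Class I vs Class II widths (NaN when either
    class has fewer than two peaks).
    """
    widths = {
        "I": np.array([focal[i].width for i in classification.focal_indices("I")]),
        "II": np.array([focal[i].width for i in classification.focal_indices("II")]),
        "III": np.array(
            [partner[j].width for j, c in enumerate(classification.partner_classes) if c == "III"]
        ),
    }
    rows = []
    if len(widths["I"]) >= 2 and len(widths["II"]) >= 2:
        mwu_p = float(stats.mannwhitneyu(widths["I"], widths["II"], alternative="two-sided").pvalue)
    else:
        mwu_p = np.nan
    for cls, w in widths.items():
        if len(w):
            q1, med, q3 = np.percentile(w, [25, 50, 75])
            rows.append(
                {
                    "class": cls,
                    "n": len(w),
                    "mean": float(w.mean()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "mwu_p_I_vs_II": mwu_p if cls == "I" else np.nan,
                }
            )
        else:
            rows.append(
                {
                    "class": cls,
                    "n": 0,
                    "mean": np.nan,
                    "q1": np.nan,
                    "median": np.nan,
                    "q3": np.nan,
                    "mwu_p_I_vs_II": np.nan,
                }
            )
    return pd.DataFrame(rows)


def classification_frame(
    classification: PeakClassification,
    focal: list[GenomicInterval],
    partner: list[GenomicInterval],
) -> pd.DataFrame:
    """Long-form table of every peak with its role, class and partners."""
    rows = []
    for i, p in enumerate(focal):
        rows.append(
            {
                "peak": p.name or f"focal_{i + 1}",
                "role": "focal",
                "chrom": p.chrom,
                "start": p.start,
                "end": p.end,
                "class": classification.focal_classes[i],
                "partners": ",".join(
                    partner[j].name or f"partner_{j + 1}" for j in classification.partners[i]
                ),
            }
        )
    for j, q in enumerate(partner):
        rows.append(
            {
                "peak": q.name or f"partner_{j + 1}",
                "role": "partner",
                "chrom": q.chrom,
                "start": q.start,
                "end": q.end,
                "class": classification.partner_classes[j],
                "partners": "",
            }
        )
    return pd.DataFrame(rows)
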