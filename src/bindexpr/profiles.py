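"""Binned signal matrices around peaks and differential-signal analyses.

The metagene machinery: a row per peak, fixed-width bins spanning the peak
midpoint +/- a flank, every bin the exact base-pair-weighted mean of the
piecewise-constant track (uncovered bases count as zero, as do bases
beyond the chromosome start). Per-site condition comparisons use the mean
signal in a window around each site and a pseudocounted log2 ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneModel, GenomicInterval
from .io import ExpressionRecord, SignalTrack, expression_frame


@dataclass
class ProfileMatrix:
    """Peaks x bins signal matrix around peak midpoints."""

    values: np.ndarray  # (n_peaks, n_bins)
    peak_names: list[str]
    flank: int
    bin_size: int
    track_id: str = ""
    row_labels: list[str] = field(default_factory=list)  # optional class labels

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def bin_starts(self) -> np.ndarray:
        """Offsets of bin left edges relative to the peak midpoint."""
        return np.arange(-self.flank, self.flank, self.bin_size)


def binned_matrix(
    track: SignalTrack,
    peaks: list[GenomicInterval],
    flank: int = 5000,
    bin_size: int = 50,
    track_id: str = "",
) -> ProfileMatrix:
    """Exact binned signal around each peak midpoint.

    Window = [midpoint - flank, midpoint + flank), split into
    ``2 * flank / bin_size`` bins; each bin holds the base-pair-weighted
    mean of the track over the bin (implicit zeros off-track and beyond the
    chromosome start, where coordinates would go negative).
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin_size")
    n_bins = 2 * flank // bin_size
    values = np.zeros((len(peaks), n_bins))
    offsets = np.arange(n_bins, dtype=np.int64) * bin_size - flank
    for i, p in enumerate(peaks):
        starts = p.midpoint + offsets
        ends = starts + bin_size
        # clip negative coordinates; clipped bases contribute zero signal
        cs = np.clip(starts, 0, None)
        ce = np.maximum(np.clip(ends, 0, None), cs)
        ints = track.integrals(p.chrom, cs, ce)
        values[i] = ints / bin_size
    return ProfileMatrix(
        values=values,
        peak_names=[p.name or f"peak_{i + 1}" for i, p in enumerate(peaks)],
        flank=flank,
        bin_size=bin_size,
        track_id=track_id,
    )


def average_profile(
    matrix: ProfileMatrix, labels: list[str] | None = None
) -> dict[str, np.ndarray]:
    """Column means within each row class; empty classes give NaN vectors."""
    labels = labels if labels is not None else matrix.row_labels
    if not labels:
        labels = ["all"] * len(matrix.peak_names)
    if len(labels) != matrix.values.shape[0]:
        raise ValueError("one label per matrix row required")
    out: dict[str, np.ndarray] = {}
    for cls in sorted(set(labels)):
        mask = np.array([l == cls for l in labels])
        out[cls] = (
            matrix.values[mask].mean(axis=0)
            if mask.any()
            else np.full(matrix.n_bins, np.nan)
        )
    return out


def site_signal_change(
    track_a: SignalTrack,
    track_b: SignalTrack,
    sites: list[GenomicInterval],
    window: int = 1000,
    pseudocount: float = 1.0,
    genes: list[GeneModel] | None = None,
) -> pd.DataFrame:
    """Per-site mean signal in two conditions and the pseudocounted ratio.

    Means are taken over [midpoint - window, midpoint + window) in each
    track; change = log2((mean_b + pc) / (mean_a + pc)), finite by
    construction. When ``genes`` is given, each site also gets its
    nearest-TSS gene and absolute distance (NaN / empty when no gene
    shares the chromosome).
    """
    mids = np.array([s.midpoint for s in sites], dtype=np.int64)
    chroms = [s.chrom for s in sites]
    mean_a = np.empty(len(sites))
    mean_b = np.empty(len(sites))
    for chrom in set(chroms):
        idx = np.array([i for i, c in enumerate(chroms) if c == chrom])
        ws = np.clip(mids[idx] - window, 0, None)
        we = mids[idx] + window
        span = 2.0 * window
        mean_a[idx] = track_a.integrals(chrom, ws, we) / span
        mean_b[idx] = track_b.integrals(chrom, ws, we) / span
    change = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    df = pd.DataFrame(
        {
            "site": [s.name or f"site_{i + 1}" for i, s in enumerate(sites)],
            "chrom": chroms,
            "midpoint": mids,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2_change": change,
        }
    )
    if genes is not None:
        tss_by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
        for chrom in set(g.chrom for g in genes):
            sub = sorted(
                (g.tss, g.gene_id) for g in genes if g.chrom == chrom
            )
            tss_by_chrom[chrom] = (np.array([t for t, _ in sub]), [g for _, g in sub])
        nearest = []
        dist = []
        for chrom, m in zip(chroms, mids):
            if chrom not in tss_by_chrom:
                nearest.append("")
                dist.append(np.nan)
                continue
            tss, ids = tss_by_chrom[chrom]
            j = np.searchsorted(tss, m)
            # candidates flanking the insertion point; ties -> smaller gene_id
            best = None
            for k in (j - 1, j, j + 1):
                if 0 <= k < len(tss):
                    key = (abs(int(tss[k]) - int(m)), ids[k])
                    if best is None or key < best:
                        best = key
            nearest.append(best[1])
            dist.append(best[0])
        df["nearest_gene"] = nearest
        df["tss_distance"] = dist
    return df


def proximal_distal_correlation(
    table: pd.DataFrame,
    expression: list[ExpressionRecord] | pd.DataFrame,
    proximal_cutoff: int = 2000,
    method: str = "spearman",
) -> dict:
    """Rank correlation of site signal change vs nearest-gene fold change,
    stratified into TSS-proximal (|distance| <= cutoff) and TSS-distal sites.

    Sites whose nearest gene is missing from the expression table are
    dropped (the count is reported). Strata with fewer than 3 sites are
    marked not applicable (NaN statistics).
    """
    if not isinstance(expression, pd.DataFrame):
        expression = expression_frame(expression)
    if "nearest_gene" not in table.columns:
        raise ValueError("site table lacks nearest-gene assignments")
    merged = table.merge(
        expression[["log2fc"]], left_on="nearest_gene", right_index=True, how="left"
    )
    usable = merged.dropna(subset=["log2fc", "tss_distance"])
    dropped = len(merged) - len(usable)
    corr = stats.spearmanr if method == "spearman" else stats.pearsonr
    result: dict = {"dropped_sites": int(dropped), "method": method, "per_site": usable}
    for name, stratum in (
        ("proximal", usable[usable["tss_distance"] <= proximal_cutoff]),
        ("distal", usable[usable["tss_distance"] > proximal_cutoff]),
    ):
        if len(stratum) < 3:
            result[name] = {"n": int(len(stratum)), "rho": np.nan, "p": np.nan}
        else:
            r = corr(stratum["log2_change"], stratum["log2fc"])
            result[name] = {
                "n": int(len(stratum)),
                "rho": float(r.statistic),
                "p": float(r.pvalue),
            }
    return result


def matrix_frame(matrix: ProfileMatrix) -> pd.DataFrame:
    """ProfileMatrix as a TSV-ready DataFrame (one row per peak)."""
    cols = [f"bin_{int(s)}" for s in matrix.bin_starts()]
    df = pd.DataFrame(matrix.values, columns=cols)
    df.insert(0, "peak", matrix.peak_names)
    if matrix.row_labels:
        df.insert(1, "class", matrix.row_labels)
    return df
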