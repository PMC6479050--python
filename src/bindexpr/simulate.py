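"""Seeded generator of paired cistrome + transcriptome studies.

Emulates the statistical structure of a two-factor ChIP-seq experiment with
matched knockout RNA-seq: two peak sets with partial co-occupancy (a focal
factor and a partner factor), focal peaks planted near the TSSs of a chosen
subset of "direct target" genes with exponentially distributed distances,
piecewise-constant signal tracks with localized enrichment in two
conditions, and a differential-expression table where planted targets carry
directional log2 fold changes and everything else is static.

Every stage draws from its own RNG stream derived from the master seed and
the stage name, so changing the peak count never perturbs the expression
draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .core import GeneModel, GenomicInterval
from .io import (
    ExpressionRecord,
    SignalTrack,
    write_bedgraph,
    write_expression,
    write_gene_models,
    write_intervals,
    write_json,
    write_table,
)

RP_WINDOW = 100_000  # planted peaks are guaranteed within this radius of their TSS


class ConfigurationError(ValueError):
    """An infeasible or inconsistent simulation configuration."""


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the standard conditions.

    The default geometry (2,000 genes, 200 up + 200 down planted targets,
    peak-to-TSS distance scale 5 kb, effect size 2.0 log2 units) is the
    planted scenario every downstream inference stage is exercised on.
    """

    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 20_000_000
    n_genes: int = 2000
    n_target_genes_up: int = 200
    n_target_genes_down: int = 200
    n_focal_peaks: int = 1000
    n_partner_peaks: int = 1000
    frac_cooccupied: float = 0.5
    target_distance_scale: float = 5000.0
    peak_width_mean: float = 400.0
    peak_width_sigma: float = 0.25  # lognormal sigma, log scale
    cooccupied_width_factor: float = 2.0  # co-occupied peaks are wider
    effect_size_log2fc: float = 2.0
    static_sd_log2fc: float = 0.25
    signal_height: float = 5.0
    signal_noise_sd: float = 0.5
    frac_signal_up: float = 0.5
    frac_signal_down: float = 0.5
    signal_up_factor: float = 2.0
    signal_down_factor: float = 0.5
    baseline_step: int = 1000
    mark: str = "H3K27ac"

    def validate(self) -> None:
        if min(
            self.n_chroms,
            self.chrom_length,
            self.n_genes,
            self.n_focal_peaks,
            self.n_partner_peaks,
        ) <= 0:
            raise ConfigurationError("counts and lengths must be positive")
        if self.n_target_genes_up < 0 or self.n_target_genes_down < 0:
            raise ConfigurationError("target counts must be non-negative")
        if self.n_target_genes_up + self.n_target_genes_down > self.n_genes:
            raise ConfigurationError("more planted targets than genes")
        if not 0.0 <= self.frac_cooccupied <= 1.0:
            raise ConfigurationError("frac_cooccupied must be in [0, 1]")
        n_planted = self.n_target_genes_up + self.n_target_genes_down
        if n_planted > self.n_focal_peaks:
            raise ConfigurationError("need at least one focal peak per planted gene")
        slot = self.chrom_length / -(-self.n_genes // self.n_chroms)
        if slot < 20 * self.peak_width_mean:
            raise ConfigurationError(
                "gene spacing infeasible: chrom_length per gene must be "
                ">= 20 x peak_width_mean"
            )


def _rng(seed: int, stage: str) -> np.random.Generator:
    """Independent stream per stage: master seed + CRC32 of the stage name."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(stage.encode())]))


@dataclass
class StudyTruth:
    """Ground truth of a simulated study: planted gene and peak labels."""

    gene_labels: dict[str, str]  # gene_id -> planted_up / planted_down / static
    focal_peak_labels: list[str]  # per focal peak: target-linked / background
    planted_peak_gene: dict[int, str] = field(default_factory=dict)  # focal idx -> gene

    @property
    def planted_up(self) -> list[str]:
        return sorted(g for g, l in self.gene_labels.items() if l == "planted_up")

    @property
    def planted_down(self) -> list[str]:
        return sorted(g for g, l in self.gene_labels.items() if l == "planted_down")

    def focal_peak_directions(self) -> list[str]:
        """Per focal peak: the expression direction of its planted gene
        (up/down), or none for background peaks."""
        out = []
        for i in range(len(self.focal_peak_labels)):
            gene = self.planted_peak_gene.get(i)
            if gene is None:
                out.append("none")
            else:
                out.append("up" if self.gene_labels[gene] == "planted_up" else "down")
        return out


def simulate_genes(config: SimulationConfig) -> list[GeneModel]:
    """Place two-exon gene models with UTRs on evenly spaced TSS slots.

    Chromosomes are named chr1..chrN; each gene occupies its own slot so
    TSS spacing never drops below 30% of the slot width. Strands are drawn
    50/50 and each model has a 5'UTR, two coding exons, one intron and a
    3'UTR so every annotation category is populated.
    """
    config.validate()
    rng = _rng(config.seed, "genes")
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    width = len(str(max(config.n_genes, 1000)))
    genes: list[GeneModel] = []
    gid = 0
    for ci, n_here in enumerate(per_chrom):
        if n_here == 0:
            continue
        chrom = f"chr{ci + 1}"
        slot = config.chrom_length / n_here
        for j in range(n_here):
            gid += 1
            tss = int(j * slot + rng.uniform(0.35, 0.65) * slot)
            strand = "+" if rng.random() < 0.5 else "-"
            e1 = int(rng.uniform(300, 1600))
            e2 = int(rng.uniform(300, 800))
            intron = int(rng.uniform(500, 4000))
            edge = tss if strand == "-" else config.chrom_length - 1 - tss
            intron = max(200, min(intron, edge - e1 - e2 - 50))
            tx_len = e1 + intron + e2
            # 5'UTRs may run past a +/-1 kb promoter so the category shows up
            utr5 = int(rng.uniform(100, min(1400, e1 - 50)))
            utr3 = int(rng.uniform(100, min(250, e2 - 50)))
            if strand == "+":
                tx_start, tx_end = tss, tss + tx_len
                cds_start, cds_end = tx_start + utr5, tx_end - utr3
            else:
                tx_end = tss + 1
                tx_start = tx_end - tx_len
                cds_start, cds_end = tx_start + utr3, tx_end - utr5
            exon_starts = (tx_start, tx_end - (e2 if strand == "+" else e1))
            exon_ends = (tx_start + (e1 if strand == "+" else e2), tx_end)
            genes.append(
                GeneModel(
                    gene_id=f"g{gid:0{width}d}",
                    transcript_id=f"tx{gid:0{width}d}",
                    chrom=chrom,
                    strand=strand,
                    tx_start=tx_start,
                    tx_end=tx_end,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    exon_starts=exon_starts,
                    exon_ends=exon_ends,
                )
            )
    return genes


def _peak(chrom: str, midpoint: int, width: int, name: str, chrom_length: int) -> GenomicInterval:
    width = max(2, width)
    start = max(0, midpoint - width // 2)
    end = min(chrom_length, start + width)
    if end - start < 2:  # peak fell off the chromosome edge
        start, end = max(0, end - 2), min(chrom_length, start + 2)
    return GenomicInterval(chrom, start, end, name=name)


def simulate_peaks(
    config: SimulationConfig, genes: list[GeneModel]
) -> tuple[list[GenomicInterval], list[GenomicInterval], StudyTruth]:
    """Plant focal peaks near target TSSs and partner peaks over a subset.

    Each planted target gene receives one focal peak at a signed distance
    drawn from +/-Exponential(target_distance_scale), truncated at 100 kb
    so every planted gene has binding inside the scoring window. Remaining
    focal peaks fall uniformly over the genome. A fraction
    ``frac_cooccupied`` of focal peaks receives an overlapping partner peak
    (the partner midpoint lands inside the focal span); remaining partner
    peaks are placed uniformly but never overlapping any focal peak.
    Co-occupied focal peaks draw wider widths (lognormal around
    ``peak_width_mean * cooccupied_width_factor``).
    """
    config.validate()
    rng = _rng(config.seed, "peaks")
    n_up, n_down = config.n_target_genes_up, config.n_target_genes_down
    planted_idx = rng.choice(len(genes), size=n_up + n_down, replace=False)
    gene_labels = {g.gene_id: "static" for g in genes}
    for i in planted_idx[:n_up]:
        gene_labels[genes[i].gene_id] = "planted_up"
    for i in planted_idx[n_up:]:
        gene_labels[genes[i].gene_id] = "planted_down"

    n_focal = config.n_focal_peaks
    n_planted = n_up + n_down
    # decide co-occupancy before widths: co-occupied peaks are wider
    n_co = int(round(config.frac_cooccupied * n_focal))
    co_idx = set(rng.choice(n_focal, size=n_co, replace=False).tolist())

    def draw_width(i: int) -> int:
        center = config.peak_width_mean * (
            config.cooccupied_width_factor if i in co_idx else 1.0
        )
        return int(rng.lognormal(np.log(center), config.peak_width_sigma))

    focal: list[GenomicInterval] = []
    focal_labels: list[str] = []
    planted_peak_gene: dict[int, str] = {}
    for k, gi in enumerate(planted_idx):
        gene = genes[gi]
        while True:
            dist = rng.exponential(config.target_distance_scale)
            if dist > RP_WINDOW:
                continue
            sign = -1 if rng.random() < 0.5 else 1
            midpoint = gene.tss + sign * int(round(dist))
            if 0 <= midpoint < config.chrom_length:
                break
        focal.append(
            _peak(gene.chrom, midpoint, draw_width(k), f"focal_{k + 1:05d}", config.chrom_length)
        )
        focal_labels.append("target-linked")
        planted_peak_gene[k] = gene.gene_id
    for k in range(n_planted, n_focal):
        chrom = f"chr{rng.integers(1, config.n_chroms + 1)}"
        midpoint = int(rng.integers(0, config.chrom_length))
        focal.append(_peak(chrom, midpoint, draw_width(k), f"focal_{k + 1:05d}", config.chrom_length))
        focal_labels.append("background")

    # partner peaks: overlapping partners first, then free-standing ones
    partner: list[GenomicInterval] = []
    for j, fi in enumerate(sorted(co_idx)):
        fp = focal[fi]
        half = max(1, fp.width // 2 - 1)
        offset = int(rng.integers(-half, half + 1))
        partner.append(
            _peak(
                fp.chrom,
                fp.midpoint + offset,
                int(rng.lognormal(np.log(config.peak_width_mean), config.peak_width_sigma)),
                f"partner_{j + 1:05d}",
                config.chrom_length,
            )
        )
    focal_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for fp in focal:
        focal_by_chrom.setdefault(fp.chrom, []).append((fp.start, fp.end))
    for spans in focal_by_chrom.values():
        spans.sort()

    def hits_focal(chrom: str, start: int, end: int) -> bool:
        spans = focal_by_chrom.get(chrom, [])
        import bisect

        i = bisect.bisect_left(spans, (end, -1))
        # check the few spans that could reach into [start, end)
        for s, e in spans[max(0, i - 8): i + 1]:
            if s < end and start < e:
                return True
        return False

    j = len(partner)
    while j < config.n_partner_peaks:
        chrom = f"chr{rng.integers(1, config.n_chroms + 1)}"
        midpoint = int(rng.integers(0, config.chrom_length))
        w = int(rng.lognormal(np.log(config.peak_width_mean), config.peak_width_sigma))
        cand = _peak(chrom, midpoint, w, f"partner_{j + 1:05d}", config.chrom_length)
        if hits_focal(cand.chrom, cand.start, cand.end):
            continue
        partner.append(cand)
        j += 1

    truth = StudyTruth(
        gene_labels=gene_labels,
        focal_peak_labels=focal_labels,
        planted_peak_gene=planted_peak_gene,
    )
    return focal, partner, truth


def _flatten_additive(
    segments: list[tuple[int, int, float]], drop_zero: bool = True
) -> list[tuple[int, int, float]]:
    """Sum overlapping additive (start, end, value) segments into disjoint steps."""
    if not segments:
        return []
    bounds = np.unique(
        np.concatenate([[s for s, _, _ in segments], [e for _, e, _ in segments]])
    )
    diff = np.zeros(len(bounds), dtype=float)
    starts = np.array([s for s, _, _ in segments])
    ends = np.array([e for _, e, _ in segments])
    vals = np.array([v for _, _, v in segments])
    i0 = np.searchsorted(bounds, starts)
    i1 = np.searchsorted(bounds, ends)
    np.add.at(diff, i0, vals)
    np.subtract.at(diff, i1, vals)
    level = np.cumsum(diff)[:-1]
    out: list[tuple[int, int, float]] = []
    for s, e, v in zip(bounds[:-1], bounds[1:], level):
        if drop_zero and v == 0.0:
            continue
        if out and out[-1][1] == s and out[-1][2] == v:
            out[-1] = (out[-1][0], int(e), float(v))
        else:
            out.append((int(s), int(e), float(v)))
    return out


def _trapezoid(peak: GenomicInterval, height: float) -> list[tuple[int, int, float]]:
    """Triangular-plateau enrichment: quarter ramps, half-width plateau."""
    q = max(1, peak.width // 4)
    segs: list[tuple[int, int, float]] = []
    n_ramp = min(4, q)
    ramp_step = q / n_ramp
    for r in range(n_ramp):
        frac = (r + 1) / (n_ramp + 1)
        a = peak.start + int(r * ramp_step)
        b = peak.start + int((r + 1) * ramp_step)
        if a < b:
            segs.append((a, b, height * frac))
        a2 = peak.end - int((r + 1) * ramp_step)
        b2 = peak.end - int(r * ramp_step)
        if a2 < b2:
            segs.append((a2, b2, height * frac))
    lo, hi = peak.start + q, peak.end - q
    if lo < hi:
        segs.append((lo, hi, height))
    return segs


def simulate_signal(
    config: SimulationConfig,
    peaks: list[GenomicInterval],
    peak_labels: list[str] | None = None,
    peak_directions: list[str] | None = None,
) -> tuple[SignalTrack, SignalTrack, list[str]]:
    """Piecewise-constant tracks for two conditions with planted changes.

    Both conditions carry a trapezoidal enrichment of ``signal_height``
    over every peak on a baseline of half-normal noise steps (sd
    ``signal_noise_sd``, independent per condition). In the second
    condition (ko) a fraction ``frac_signal_up`` of target-linked peaks is
    scaled by ``signal_up_factor`` and ``frac_signal_down`` by
    ``signal_down_factor`` — the bidirectional change a factor knockout
    induces on active histone marks. When ``peak_directions`` (up / down /
    none per peak) is given, the scaled subset follows it: a fraction
    ``frac_signal_up`` of the up-directed peaks gains signal and
    ``frac_signal_down`` of the down-directed peaks loses it, coupling
    chromatin change to the linked gene's expression change. Returns
    (wt, ko, per-peak change label in {up, down, none}).
    """
    config.validate()
    rng = _rng(config.seed, "signal")
    if peak_labels is None:
        peak_labels = ["target-linked"] * len(peaks)
    linked = [i for i, l in enumerate(peak_labels) if l == "target-linked"]
    change = ["none"] * len(peaks)
    if peak_directions is not None:
        for direction, frac in (("up", config.frac_signal_up), ("down", config.frac_signal_down)):
            pool = [i for i in linked if peak_directions[i] == direction]
            chosen = rng.choice(len(pool), size=int(round(frac * len(pool))), replace=False) \
                if pool else []
            for k in chosen:
                change[pool[k]] = direction
    else:
        perm = rng.permutation(len(linked))
        n_up = int(round(config.frac_signal_up * len(linked)))
        n_down = int(round(config.frac_signal_down * len(linked)))
        for k in perm[:n_up]:
            change[linked[k]] = "up"
        for k in perm[n_up: n_up + n_down]:
            change[linked[k]] = "down"

    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    tracks = []
    for cond in ("wt", "ko"):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom in chroms:
            n_steps = -(-config.chrom_length // config.baseline_step)
            noise = np.abs(rng.normal(0.0, config.signal_noise_sd, size=n_steps))
            segs = [
                (
                    i * config.baseline_step,
                    min((i + 1) * config.baseline_step, config.chrom_length),
                    float(v),
                )
                for i, v in enumerate(noise)
                if v != 0.0
            ]
            per_chrom[chrom] = segs
        for i, peak in enumerate(peaks):
            h = config.signal_height
            if cond == "ko":
                if change[i] == "up":
                    h *= config.signal_up_factor
                elif change[i] == "down":
                    h *= config.signal_down_factor
            per_chrom.setdefault(peak.chrom, []).extend(_trapezoid(peak, h))
        flat = {c: _flatten_additive(segs) for c, segs in per_chrom.items() if segs}
        tracks.append(SignalTrack(flat))
    return tracks[0], tracks[1], change


def simulate_expression(
    config: SimulationConfig, truth: StudyTruth
) -> list[ExpressionRecord]:
    """Differential-expression table with planted directional fold changes.

    planted_up genes draw log2fc ~ N(+effect, sd), planted_down ~
    N(-effect, sd), static ~ N(0, sd). P-values are the two-sided normal
    tail of |log2fc| / sd — a monotone map that makes the p-ranking
    coherent with effect sizes and exactly Uniform(0,1) for static genes.
    Adjusted p-values are Benjamini-Hochberg over the whole table.
    """
    config.validate()
    rng = _rng(config.seed, "expression")
    gene_ids = sorted(truth.gene_labels)
    labels = np.array([truth.gene_labels[g] for g in gene_ids])
    mu = np.where(
        labels == "planted_up",
        config.effect_size_log2fc,
        np.where(labels == "planted_down", -config.effect_size_log2fc, 0.0),
    )
    lfc = mu + rng.normal(0.0, config.static_sd_log2fc, size=len(gene_ids))
    if config.static_sd_log2fc > 0:
        z = np.abs(lfc) / config.static_sd_log2fc
    else:
        z = np.where(lfc == 0.0, 0.0, np.inf)
    pvals = np.clip(2.0 * stats.norm.sf(z), np.nextafter(0, 1), 1.0)
    padj = stats.false_discovery_control(pvals, method="bh")
    return [
        ExpressionRecord(g, float(l), float(p), float(q))
        for g, l, p, q in zip(gene_ids, lfc, pvals, padj)
    ]


@dataclass
class SyntheticStudy:
    """One simulated study: gene models, peaks, tracks, expression, truth."""

    config: SimulationConfig
    genes: list[GeneModel]
    focal_peaks: list[GenomicInterval]
    partner_peaks: list[GenomicInterval]
    expression: list[ExpressionRecord]
    truth: StudyTruth
    signal_wt: SignalTrack | None = None
    signal_ko: SignalTrack | None = None
    signal_change: list[str] | None = None


def simulate_study(config: SimulationConfig, include_signal: bool = True) -> SyntheticStudy:
    """Run every generator stage on one config; fully seed-deterministic."""
    genes = simulate_genes(config)
    focal, partner, truth = simulate_peaks(config, genes)
    expression = simulate_expression(config, truth)
    wt = ko = change = None
    if include_signal:
        wt, ko, change = simulate_signal(
            config, focal, truth.focal_peak_labels, truth.focal_peak_directions()
        )
    return SyntheticStudy(
        config=config,
        genes=genes,
        focal_peaks=focal,
        partner_peaks=partner,
        expression=expression,
        truth=truth,
        signal_wt=wt,
        signal_ko=ko,
        signal_change=change,
    )


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write the study to disk in the pipeline's input formats."""
    from pathlib import Path
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_gene_models(study.genes, outdir / "genes.refflat")
    write_intervals(study.focal_peaks, outdir / "focal.narrowPeak", "narrowpeak")
    write_intervals(study.partner_peaks, outdir / "partner.narrowPeak", "narrowpeak")
    write_expression(study.expression, outdir / "expression.tsv")
    mark = study.config.mark
    if study.signal_wt is not None:
        write_bedgraph(study.signal_wt, outdir / f"{mark}.wt.bedGraph")
    if study.signal_ko is not None:
        write_bedgraph(study.signal_ko, outdir / f"{mark}.ko.bedGraph")
    write_table(
        pd.DataFrame(
            {
                "gene_id": sorted(study.truth.gene_labels),
                "label": [study.truth.gene_labels[g] for g in sorted(study.truth.gene_labels)],
            }
        ),
        outdir / "truth.tsv",
    )
    write_table(
        pd.DataFrame(
            {
                "peak": [p.name for p in study.focal_peaks],
                "label": study.truth.focal_peak_labels,
                "signal_change": study.signal_change or ["none"] * len(study.focal_peaks),
            }
        ),
        outdir / "truth_peaks.tsv",
    )
    write_json(asdict(study.config), outdir / "config.json")
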