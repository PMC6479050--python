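# Methods

## The model

The package treats a gene's exposure to a chromatin factor as the sum of
exponentially distance-decayed contributions of the factor's binding
sites. With the TSS as the gene's anchor point and peak midpoints as the
sites' representative points, the regulatory potential of gene *g* is

    S_g = Σ_{i=1..k} exp(−(offset + scale · Δ_i)),   Δ_i = |d_i| / window

where the sum runs over the k peaks whose midpoint lies within `window`
of the TSS and d_i is the signed midpoint-to-TSS distance. Defaults are
`window` = 100 kb, `offset` = 0.5, `scale` = 4: a peak at the TSS weighs
e^−0.5 ≈ 0.6065, a peak at 10 kb (Δ = 0.1) weighs e^−0.9, and the weight
falls e-fold every 25 kb. The window boundary is closed — a peak at
exactly 100 kb enters with Δ = 1 and the negligible weight e^−4.5.

Inference of activating/repressive function asks whether the S_g
distribution of regulated genes stochastically dominates that of static
genes. Groups are formed from a differential-expression table: `up` is
the `da` = 500 most significant genes with log2FC > 0 (ordered by
ascending p, ties by descending |log2FC|, then gene id), `down`
symmetric, `static` every remaining gene with p ≥ 0.1 (the floor keeps
near-significant genes out of the background). Each group is compared to
static by a two-sample Kolmogorov–Smirnov test; the headline p-value is
one-sided (group stochastically greater in S_g), with the two-sided p
co-reported. Direct targets are the group genes with S_g > 0, ranked by
the product of their binding rank and their differential-expression rank.

## Conventions and numerical choices

- All coordinates are 0-based half-open (BED native); refFlat is already
  half-open, so no shifting occurs at I/O boundaries.
- A peak's representative point is its integer midpoint
  ⌊(start+end)/2⌋. Summits are parsed from narrowPeak but not used for
  distances: summits may be absent (−1), and a single convention keeps
  every stage consistent.
- The TSS of a − strand transcript is `tx_end − 1`, the last covered
  base, so the TSS is always a genomic position inside the transcript.
- Signed distances follow the reading direction: positive = downstream of
  the TSS. Only |d| enters the decay.
- Genes with several transcripts score as the maximum over their
  transcripts' TSSs (the best-scoring TSS gets the credit).
- Peak overlap means ≥ `min_overlap` (default 1) shared bases under
  half-open arithmetic; classification is by interval index and is
  order-independent. Ranking ties anywhere break by gene id, making every
  table deterministic.
- Binned profile matrices are exact base-pair-weighted means of the
  piecewise-constant track, computed from a cumulative-integral index;
  bases off the track or before base 0 contribute zero. Bin width
  default 50 bp with 5 kb flanks (200 columns).
- Per-site condition comparisons use the mean signal in a ±1 kb window
  and log2((mean_b + 1)/(mean_a + 1)); the pseudocount bounds the ratio
  at empty sites.
- The signal-change versus expression-change correlation is Spearman by
  default (robust to the long-tailed signal scale; Pearson available),
  stratified at a 2 kb nearest-TSS cutoff into proximal (promoter-like)
  and distal (enhancer-like) sites.
- Promoter = TSS ± 1 kb (configurable). Annotation precedence is
  promoter > 5'UTR > 3'UTR > coding exon > intron > distal intergenic,
  applied jointly across genes, so each peak receives exactly one
  category and fractions sum to 1.
- KS p-values use the asymptotic two-sample formula: regulatory
  potentials are heavily tied at zero, which invalidates the exact
  small-sample path. Groups smaller than 3 are marked not applicable
  rather than tested.

## The synthetic-data generator

`bindexpr.simulate` produces a complete in-silico study: gene models,
two peak sets, two-condition signal tracks, an expression table, and the
ground truth. It emulates the statistical structure the pipeline is meant
to detect, not sequencing itself:

- **Genes**: one two-exon model per slot on equal-length chromosomes,
  strands 50/50, with 5'UTR/intron/3'UTR so every annotation category
  exists. TSS spacing is guarded (slot ≥ 20 × mean peak width).
- **Peaks**: each planted target gene receives one focal peak at a signed
  ±Exponential(5 kb) distance, truncated at 100 kb so planted targets are
  always scorable; remaining focal peaks are uniform. A configurable
  fraction (default 0.5) of focal peaks gets an overlapping partner peak;
  remaining partner peaks avoid focal spans entirely, so co-occupancy is
  exactly the planted Bernoulli structure. Widths are lognormal (σ = 0.25)
  around 400 bp, with co-occupied peaks drawn around 800 bp — shared sites
  are wider, as joint binding tends to produce broader enrichment.
- **Signal**: trapezoidal enrichment (quarter ramps, half-width plateau,
  height 5) over every peak on a half-normal noise baseline (sd 0.5,
  independent per condition, 1 kb steps). In the knockout condition, half
  of the peaks linked to up-regulated genes gain signal (×2) and half of
  those linked to down-regulated genes lose it (×0.5), coupling chromatin
  change to expression change the way an active mark tracks transcription.
- **Expression**: planted-up genes draw log2FC ~ N(+2, 0.25), planted-down
  N(−2, 0.25), static N(0, 0.25). P-values are the two-sided normal tail
  of |log2FC|/sd — a monotone map that keeps the significance ranking
  coherent with effect sizes and is exactly Uniform(0,1) for static genes,
  which is what makes the KS null calibration meaningful. BH adjustment is
  applied across the table.

Each stage draws from its own RNG stream (master seed + stage-name hash),
so changing the peak count cannot perturb the expression draws, and the
whole study is byte-reproducible from one seed.

Default problem sizes (2,000 genes on 4 × 20 Mb, 1,000 + 1,000 peaks, 500
null replicates at 400 genes for calibration) were chosen as the smallest
study at which the planted effects are unambiguous while whole-pipeline
runs complete in seconds.

What the generator does **not** model: read-level noise, fragment-length
and GC effects, replicate structure, peak-calling artifacts, copy-number
variation, overlapping genes and nested transcripts, and correlated
binding of the two factors beyond planted co-occupancy. Passing tests
therefore demonstrate that the inference machinery is correct and
calibrated on its own model assumptions — not that those assumptions hold
in any particular real dataset.

## Open design points, resolved

- The `da` parameter is read as "top 500 per direction"; it is exposed as
  a flag, so either reading is reachable.
- Per-class inference (`--select class:I` / `class:II`) recomputes gene
  ranking from the selected subset alone, mirroring per-class display
  panels; pooled ranking is `--select all`.
- The two compared signal conditions are generic "A/B" throughout — the
  machinery does not care which is wild type.
- Run provenance (`run_metadata.json`) records version, parameters and
  input SHA-256 hashes but deliberately no timestamps, so repeated runs
  are byte-identical.

## Limitations

Midpoint-based annotation assigns exactly one category per peak; a wide
peak straddling a promoter and an enhancer is counted once. The
regulatory-potential model ignores insulation, contact domains, and
strand asymmetry of regulation. The KS comparison treats genes as
exchangeable; correlated genes (clusters sharing a peak within 100 kb)
mildly overstate effective sample size. The rank-product target score is
a heuristic conjunction; it is deterministic and monotone in both
evidence ranks but carries no calibrated error rate.
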