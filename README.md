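# bindexpr

Integration of transcription-factor binding (ChIP-seq peaks and signal
tracks) with differential expression (RNA-seq), for asking whether a
chromatin factor's binding *directly* activates or represses its nearby
genes — and which genes those are.

The package implements the analysis chain used to characterize a factor
that binds partly with and partly without a partner factor (for example a
SWI/SNF-family subunit against the complex's ATPase):

1. **Peak classes** — focal peaks that overlap a partner peak (Class I),
   focal-only peaks (Class II), and partner-only peaks (Class III).
2. **Genomic distribution** — each peak's midpoint is assigned to
   promoter / 5'UTR / 3'UTR / coding exon / intron / distal intergenic,
   with promoter-first precedence.
3. **Signal profiles** — exact base-pair-weighted binned matrices of a
   bedGraph track ±5 kb around peaks, per-class average profiles, and
   per-site log2 signal changes between two conditions.
4. **Regulatory potential** — each gene *g* is scored over the peaks
   within 100 kb of its TSS:

   S_g = Σ_{i=1..k} exp(−(0.5 + 4·Δ_i)),  Δ_i = |d_i| / 100 kb

   so a peak at the TSS contributes e^−0.5 ≈ 0.607 and the weight decays
   e-fold every 25 kb.
5. **Activating/repressive inference** — the S_g distributions of the up-
   and down-regulated gene groups (top `da` = 500 genes per direction) are
   compared against static (non-differential) genes with a one-sided
   two-sample Kolmogorov–Smirnov test; cumulative rank curves visualize the
   enrichment.
6. **Direct targets** — genes that are both bound (S_g > 0) and regulated,
   ranked by the rank-product of binding and differential-expression
   evidence; plus a nearest-peak distance comparison of regulated versus
   static genes (Mann–Whitney).

Because the real datasets such analyses consume are large downloads, the
package ships a seeded synthetic-study generator (`bindexpr.simulate`)
that plants known direct targets — genes with directional fold changes and
a peak at an exponentially distributed distance from their TSS — so every
stage can be exercised and validated against ground truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
planted conditions (2,000 genes, 200 up + 200 down targets, peaks planted
at 5 kb scale, effect size 2.0 log2 units, 50% peak co-occupancy):

```sh
python analysis/01_simulate_study.py --seed 1
python analysis/02_classify_peaks.py
python analysis/03_signal_profiles.py
python analysis/04_beta_targets.py
python analysis/05_distance_to_targets.py
```

which prints (seed 1):

```
Class I 501 (50% of focal), Class II 499, Class III 500
median width: Class I 796 bp vs Class II 399 bp (Mann-Whitney p = 7.5e-150)
proximal: Spearman rho = 0.421 (n = 189, p = 1.6e-09)
distal: Spearman rho = 0.291 (n = 811, p = 2.6e-17)
[all] KS one-sided p: up 1.59e-25, down 7.35e-24; recall of planted targets: up 100%, down 100%
up: median 14.3 kb vs static 36.5 kb (one-sided Mann-Whitney p = 1.63e-29)
```

Reading this: half the focal peaks are co-occupied (Class I) and those are
about twice as wide; the wt→ko signal change at bound sites correlates
positively with the nearest gene's expression change in both TSS-proximal
and distal strata; binding is strongly enriched at both up- and
down-regulated genes relative to the static background (the factor has
both activating and repressive direct function); every planted target is
recovered in the direct-target lists; and regulated genes sit roughly
2.5× closer to their nearest peak than unchanged genes.

The same chain is available as a CLI:

```sh
bindexpr all --config demo.yaml --seed 7 --out run/
```

with per-stage subcommands (`simulate`, `classify`, `profile`, `beta`,
`distance`) for real data; see `bindexpr <cmd> --help` and the demo config
in `demo.yaml`. Inputs are BED3/BED6/narrowPeak peaks, refFlat gene
models, bedGraph signal, and a DESeq2-shaped expression TSV.

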