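# cisconn

Promoter–enhancer (P–E) connectivity analysis for high-resolution chromatin
contact maps, built around the question of how cis-regulatory connectivity
is lost during early colorectal carcinogenesis (normal mucosa → polyp →
adenocarcinoma) and what that loss does to gene expression.

The package implements, as a tested pipeline exercisable end-to-end on
synthetic cohorts with planted ground truth:

* **Mappability-normalized stripe calling.** Architectural stripes are loci
  whose long-range (>1.5 kb) contact coverage exceeds what read mappability
  predicts. Short-range self-ligation pairs (<1 kb, inward orientation) are
  a distal-interaction-independent mappability proxy, so the expected
  long-range count per 100-bp bin is

  ```
  expected = (long_bg / short_bg) × short_local
  ```

  with a 2-kb local and a 50-kb background window. Bins are tested with an
  upper-tail Poisson test (BH-corrected per sample); stripe strength is
  `log10((obs + 1) / (expected + 1))`. Consensus anchors are bins with
  q < 0.01 in ≥ 3 samples, merged, ≥ 500 bp, blacklist-free, autosomal.

* **Per-gene P–E connectivity.** For each gene, accessible peaks within
  200 kb of the TSS (promoter zone −1.5 kb/+0.5 kb, strand-oriented) are
  paired as distal partners, and

  ```
  C_g = Σ_peaks raw(promoter, peak ± 500 bp; 1 kb bins) / M / D
  ```

  where `M` is the promoter's self-ligation read density relative to its
  50-kb neighborhood (mappability) and `D` is the long-range background
  contact density in the 5–50-kb donut around the TSS in contacts per
  1 kb² (between-sample coverage normalization). `C_g` is invariant to
  planted mappability bias and to sequencing depth.

* **Loop quantification and APA.** Loop strength
  `log10((obs + 1)/(donut expected + 1))`, priority merging of multi-source
  loop lists, 1.2-fold stage-positive calls, and aggregate peak analysis
  (center 10 × 10 block vs bottom-left background corner; per-diagonal
  normalization in stripe mode).

* **Methylation and CRE annotation.** Region methylation states
  (demethylated < 25%, methylated > 40%), stage changes (>15 points at
  FDR < 0.1, two-proportion test), multi-sample ATAC consensus peaks
  (≥ 3 hits, ≥ 300 bp), and priority-ordered CRE annotation
  (promoter > enhancer > CTCF > open chromatin).

* **The two-phase model.** Expression follows a saturating function of
  connectivity, `E = β·min(C, C_sat) + ε`: above saturation connectivity is
  redundant ("stabilization phase"), below it rate-limiting ("activation
  phase"). Global connectivity loss therefore *raises* the
  connectivity–expression correlation among active genes (TPM > 0.5), and a
  dense regressor (2048/512/128 units, 20% dropout, best-epoch selection on
  2,800 held-out genes) trained on baseline features predicts stage fold
  changes. Feature importances come from seeded permutation attribution
  (validated against exact Shapley values on small models), and direction
  predictions are scored against the mean of coded up/down calls across
  cohorts (directionality score).

* **Synthetic cohorts with planted truth** (`cisconn.synthetic`):
  distance-decay background, promoter stripe anchors with triangular reach
  taper, focal loops, self-ligation pairs, locus-level mappability bias,
  stage attenuation, accessibility peaks, CpG methylation and two-phase
  expression — everything the benchmarks in `cisconn.benchmarks` score
  recovery against.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/04_pe_connectivity.py` simulates a one-sample-per-stage
cohort of 60 genes and prints:

```
mucosa           mean C_g    878.7   Spearman vs planted truth 0.94
polyp            mean C_g    626.4   Spearman vs planted truth 0.93
adenocarcinoma   mean C_g    514.1   Spearman vs planted truth 0.93

example record: gene g0000, C_g=546.3 from 6 paired peaks (raw=102, M=1.04, D=0.179)
```

Mean connectivity falls with stage because planted stripe/loop intensity is
attenuated (×0.8 in polyp, ×0.6 in adenocarcinoma), while the Spearman
correlation against planted truth stays ≈ 0.93: the normalization removes
mappability and coverage effects but preserves between-gene ordering.

A full orchestrated run (simulate → stripes → loops → connectivity →
methylation → two-phase, with a JSON manifest) is available as a library
call (`cisconn.pipeline.run_pipeline`) or from the shell:

```bash
cisconn all --out demo_run --seed 1
```

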