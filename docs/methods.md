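# Methods

This note documents the models, estimators and simulation assumptions
behind cisconn, the defaults that matter, and the choices made where the
design was genuinely open.

## The measurement problem

High-resolution (multi-cutter) chromatin contact maps resolve architectural
stripes and focal loops at active regulatory elements, but read mappability
is itself elevated at open chromatin, so raw long-range coverage conflates
interaction activity with mappability. The package's central normalization
assumption is that mappability inflates long-range and short-range coverage
*proportionally at a locus*, while short-range self-ligation pairs (<1 kb,
inward `+/-` orientation) carry no distal-interaction signal. Self-ligation
coverage is therefore used as the mappability reference everywhere:

* **Stripe calling.** Per 100-bp bin, `expected = (long_bg/short_bg) ×
  short_local` with a 2-kb local and 50-kb background window; the observed
  local long-range count is tested with an upper-tail Poisson test,
  Benjamini–Hochberg corrected in one family per sample (all chromosomes
  jointly — the more conservative reading, since the family definition is a
  free choice). Stripe strength is `log10((obs+1)/(exp+1))`; log10 is used
  for every strength-type quantity in the package.
* **Connectivity.** Raw 1-kb promoter–peak contacts are divided by the
  promoter mappability `M` (self-ligation density in the promoter zone
  relative to its 50-kb neighborhood) and by the background density `D`.

Two estimator details matter and are deliberate:

* **Centered background windows.** Both coverage tracks are forward-anchored
  at the bin start (`values[i]` covers `[i·step, i·step+window)`); the
  caller index-shifts the background track so the 50-kb window is centered
  on the 2-kb local window. Without this, the 24-kb offset between window
  centers turns any locally sloped signal (e.g. the flank of a strong
  stripe) into a systematic excess over expectation, which measurably
  floods the caller with false anchors along stripe flanks.
* **A gap around the promoter zone in `M`.** The 50-kb neighborhood
  excludes the promoter zone plus a 2-kb margin on each side, because
  self-ligation mates of reads inside the zone land within one pair length
  of it. With the margin, `M` recovers planted promoter bias essentially
  exactly (0.5/1/2/3 on the benchmark grid); without it, the estimate is
  diluted ~8–10% and the bias-invariance of `C_g` degrades.

## The background density D

`D` normalizes coverage between samples and localizes the distance-decay
background. It is computed as the density (contacts per 1 kb² pixel) of
long-range contacts whose endpoints **both** lie at a ring distance
(5–50 kb, either side) from the TSS. Anchoring `D` entirely off the
promoter row is essential: a variant that counts promoter-anchored contacts
into the ring would itself scale with promoter mappability, and
`C = (raw/M)/D` would then scale as `1/b` instead of being bias-free. The
implemented reading is the one under which the package's measured bias
slopes vanish (|slope| < 1% of the mean across the b ∈ {0.5,1,2,3} grid)
and matches the donut-background idea: a local 2-D background that excludes
the focal row and column.

## Degenerate-input rules

* `short_bg = 0`: the bin has no mappability estimate → marked unmappable
  (NaN) and excluded from testing, rather than assigned a floor.
* Empty background ring: `D` floored at 1e-6 and the gene flagged.
* Zero neighborhood self-ligation coverage: `M` undefined (NaN), gene
  flagged; a tiny pseudo-rate keeps `M > 0` otherwise.
* Pseudo-count 1 is applied unconditionally in every log-ratio
  (stripe/loop strengths, stage-positive ratios, fold changes of
  connectivity and methylation) for determinism.
* Records in the distance dead zone between the self-ligation cutoff
  (1 kb) and the long-range threshold (1.5 kb) belong to neither class.
* Boundary conventions are strict as stated everywhere: methylation
  categories `<25`, `>40`, changes `>15` points, stage-positive `>1.2`.
  All intervals are 0-based half-open; merge ties resolve by half-open
  arithmetic.

## APA

Loop-mode APA sums windows around anchor pairs and scores the 10×10 center
block against the 100×100 bottom-left corner; the corner is additionally
clamped to `(window − center)/2` so that on desk-scale windows it can never
reach the center block (at the conventional 500-pixel window the 100×100
corner is unchanged). Stripe-mode APA first divides every pixel by the
chromosome-average intensity at its diagonal distance, then averages
windows and reports the center-block mean. Matrices are log-transformed
only for visualization output.

## The two-phase layer

Expression is modeled as `E = β·min(C, C_sat) + ε` with per-sample TPM
renormalization. Renormalization is what lets saturated high-connectivity
genes *gain* relative expression under global attenuation while
low-connectivity genes lose it — without it, a uniform attenuation could
only downregulate. Two consequences are checked: the Spearman correlation
between connectivity and active-gene (TPM > 0.5) expression rises strictly
with attenuation, and baseline features predict stage fold changes.

The regressor is a dense feed-forward network written in numpy (ReLU,
inverted dropout 0.2, Adam, MSE), with the published 2048/512/128 widths as
the default and width-scaling for desk-scale runs; training runs ≤ 50
epochs and the returned weights are those of the epoch with the lowest
held-out MSE on the seeded 2,800-gene held-out split. Everything is
deterministic for a fixed seed.

Feature attribution is seeded permutation attribution: per gene and
feature, the mean prediction change when that feature's column is permuted
(5 repetitions). Importance is the absolute mean across genes. For
directionality, note that the *plain* mean of permutation attributions
vanishes by construction (permutation preserves the marginal), so the
package reports the attribution mean oriented by whether the gene's feature
value lies above the feature median — positive when high values push
predictions up. Sign agreement is validated against an exact brute-force
Shapley oracle (subset enumeration with mean-baseline value function) on
small models, and the Shapley implementation itself is validated against
the closed form `φ_ij = β_j(x_ij − mean_j)` for linear models.

Rank transforms are ascending average ranks (ties averaged). Whether the
held-out gene set is shared between the initial and differential models is
unspecified in principle; a shared seeded split is used. Fold changes in
differential mode use `log2((a+1)/(b+1))` for positive-scale features
(connectivity, methylation, TPM) and plain differences for features already
on a log scale.

## The synthetic generator

`simulate_contacts` emits four contact classes per sample, with nominal
fractions background 0.35, stripe 0.20 (× stage attenuation), loop 0.05
(× attenuation), self-ligation 0.40 — self-ligation artifacts are the most
abundant class in multi-cutter libraries, and a well-populated short track
is what makes the Poisson model's expectation stable at 100-bp resolution.

* Background distances follow `P(d) ∝ d^(−α)` (α = 1 by default; the true
  decay exponent of this assay class is not established, so α is a free
  simulation parameter), truncated at 2 Mb to bound memory.
* Stripe contacts join a uniformly drawn position inside the anchor to a
  far end whose offset has a **triangular taper** to the 200-kb reach. A
  uniform reach window was tried first and rejected: its hard density cliff
  at the reach boundary is a genuine edge in the simulated data that the
  caller correctly flags, but it is an artifact of the truncation, not of
  stripe biology — real stripes fade with distance. The taper removed
  essentially all boundary false positives (precision 0.74 → 0.97).
* Mappability bias `b(x) ∈ [0.3, 3]` acts as one-shot thinning: candidate
  budgets are pre-scaled by `b_max²` (`b_max` for self-ligation) and each
  pair is kept with probability `b(end1)·b(end2)/b_max²` (self-ligation:
  `b(x)/b_max`), with lost pairs *not* re-drawn. This reproduces what
  mappability does to a sequencing library — reads at low-mappability loci
  are lost, and coverage at a biased locus scales multiplicatively with
  `b` — and keeps the long/short coverage ratio at a locus independent of
  `b`, the property the stripe caller exploits. (A budget-conserving
  rejection sampler was tried and rejected: it redistributes rather than
  thins, so uniform bias cancels out of the planted classes.)
* Stage attenuation defaults to mucosa 1.0, polyp 0.8, adenocarcinoma 0.6,
  matching a ~40% connectivity/stripe loss at the cancer stage with polyps
  intermediate. Accessibility attenuates much more mildly (×0.877 at the
  cancer stage).
* Planted connectivity is `C_true(g, stage) = strength_g × attenuation ×
  taper-weighted enhancer span / norm`, with log-normal anchor strengths
  (σ = 0.5 dex) and `norm` fixing the cohort median mucosa `C_true` at
  `2·C_sat` so that, as in normal tissue, most genes are saturated.
* Expression: `β = 50` (TPM scale), `C_sat = 1`, Gaussian noise σ = 5,
  per-sample TPM renormalization on by default.
* Tracks: peaks at promoters and planted enhancers with log-normal fold
  enrichments plus shared and sample-private decoys (5% per-sample
  dropout); ~20 CpGs per promoter drawn around per-stage category means
  (demethylated 10%, intermediate 32%, methylated 60%, with a hypermethyl
  subset in adenocarcinoma); coverage Poisson(30).

What the generator does **not** emulate: TADs and compartments, structural
variants, fragment-level digestion patterns and read-level artifacts beyond
self-ligation, trans contacts, replication-timing or copy-number effects,
sequence context, and any coupling between methylation change and contact
loss beyond the planted category means. Passing benchmarks therefore show
that the estimators recover the signals they are built for under the
stated noise model — not that real tissue data contain no other confounders.

## Benchmark problem sizes

The standard benchmarks use: stripe recovery — 60 genes on 2×10 Mb, six
samples (2/2/2), 0.8 M contacts each, 50% subsampling; bias invariance —
40 genes on 12 Mb, one sample per bias level at 3 M contacts, paired maps
sharing the truth layout (neutral-locus bumps and promoter bumps simulated
separately so each readout's partner loci stay unbiased); connectivity
recovery — 220 genes on 3×10 Mb, six samples at 1.5 M; APA — 25 loops at
1-kb pixels, 2 M contacts per stage; two-phase — 10,000 genes, 2,800 held
out, scaled widths (256/64/16). These sizes make the full validation run
in minutes on one CPU while keeping every threshold at its standard value.

## Known limitations

* The proportionality assumption behind the expected-count formula is
  asserted, not adjudicated; the package exposes the raw long/short fold
  enrichment track as a diagnostic but cannot validate the assumption on
  real data by itself.
* Loop *detection* is out of scope; anchors come from planted truth or
  external callers, and the donut geometry (inner 2, outer 10 bins) is the
  standard convention rather than a fitted choice.
* KR/ICE balancing is not implemented; the self-ligation normalization is
  the normative path (an IPF balancer exists behind
  `ContactMatrix.balance_ipf` for parity experiments only).
* The promoter-accessibility summary ("mean of the two highest quartile
  means of per-bp fold enrichment, log10") is one reading of an ambiguous
  convention and is configurable at the call site.
* TF-binding indicator features are synthetic binary columns; ingesting a
  real ChIP-seq catalog is a documented extension, so the feature count
  depends on the inputs provided.
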