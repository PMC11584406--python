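"""Call consensus stripe anchors on a six-sample synthetic cohort.

Per sample, long-range coverage is tested against the mappability-
normalized expectation (long_bg / short_bg) x short_local per 100-bp bin;
bins significant (q < 0.01) in >= 3 samples are merged into anchors
(>= 500 bp).  Recovery is scored against the planted anchors.
"""
from cisconn import stripes, synthetic

truth = synthetic.build_truth(
    n_genes=40, chrom_sizes={"chr1": 9_000_000, "chr2": 9_000_000},
    samples=synthetic.default_cohort(2, 2, 2), seed=1)
per_sample = {}
for sample in truth.samples:
    pairs = synthetic.simulate_contacts(truth, sample, depth=600_000, seed=1)
    per_sample[sample] = stripes.call_sample_stripes(pairs, truth.chrom_sizes)

anchors = stripes.consensus_anchors(per_sample, autosomes=set(truth.chrom_sizes))
planted = [(a.chrom, a.start, a.end) for a in truth.stripe_anchors]
hit = sum(1 for (c, s, e) in planted
          if any(a.chrom == c and a.start < e and s < a.end for a in anchors))
true_calls = sum(1 for a in anchors
                 if any(a.chrom == c and a.start < e and s < a.end
                        for (c, s, e) in planted))
print(f"called {len(anchors)} consensus anchors; {len(planted)} planted")
print(f"recall {hit / len(planted):.2f}, precision {true_calls / len(anchors):.2f}")
a = anchors[0]
print(f"example anchor: {a.chrom}:{a.start}-{a.end}, "
      f"supported by {a.n_supporting_samples}/6 samples")
print("A recall/precision near 1 means the caller finds promoter stripe "
      "anchors without mistaking mappability hotspots for stripes.")
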