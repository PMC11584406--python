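"""Quantify planted loops and aggregate them with APA across stages.

Loop strength is log10((observed + 1) / (donut expected + 1)) at the anchor
pixel block; APA piles up windows around all loop anchor pairs and scores
the 10x10 center against the bottom-left background corner.
"""
import pandas as pd

from cisconn import loops, synthetic
from cisconn.contacts import bin_matrix

samples = {f"{st}_1": st for st in synthetic.STAGES}
truth = synthetic.build_truth(
    n_genes=30, chrom_sizes={"chr1": 9_000_000, "chr2": 9_000_000},
    samples=samples, seed=2, n_loops=20)
loop_frame = pd.DataFrame([{"chrom": lp.chrom, "start1": lp.start1,
                            "end1": lp.end1, "start2": lp.start2,
                            "end2": lp.end2} for lp in truth.loop_pairs])

for sample, stage in samples.items():
    pairs = synthetic.simulate_contacts(truth, sample, depth=1_200_000, seed=2)
    mats = {c: bin_matrix(pairs, c, truth.chrom_sizes[c], 1000)
            for c in truth.chrom_sizes}
    q = pd.concat([loops.quantify_loops(loop_frame[loop_frame.chrom == c],
                                        mats[c]) for c in mats])
    positive = loops.stage_positive({sample: q}, [sample])
    apa = loops.apa(list(mats.values()), loop_frame, half_width=25)
    print(f"{stage:16s} mean loop strength {q['strength'].mean():.3f}  "
          f"positive loops {int(positive.sum())}/{len(q)}  "
          f"APA score {apa.score:.0f}")
print("\nLoop strength and the APA score shrink from mucosa to "
      "adenocarcinoma because planted loop intensity is attenuated with "
      "stage, mirroring the global loss of focal contacts.")
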