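"""Per-gene promoter-enhancer connectivity across a staged cohort.

C_g sums raw 1-kb promoter-peak contacts over all accessible peaks within
200 kb, divided by the promoter's self-ligation mappability M and the local
long-range background density D (contacts per kb^2 in the 5-50 kb ring).
"""
import numpy as np
from scipy import stats

from cisconn import connectivity as cn
from cisconn import synthetic

truth = synthetic.build_truth(
    n_genes=60, chrom_sizes={"chr1": 10_000_000, "chr2": 10_000_000},
    samples=synthetic.default_cohort(1, 1, 1), seed=3)
peaks, _, _ = synthetic.simulate_tracks(truth, seed=3)
genes = cn.genes_from_frame(synthetic.gene_models(truth))
contacts = {s: cn.SampleContacts(
    synthetic.simulate_contacts(truth, s, depth=1_200_000, seed=3))
    for s in truth.samples}

table = cn.connectivity_table(contacts, genes,
                              peaks[peaks["kind"] != "promoter"],
                              sample_stage=truth.samples)
truth_c = {g.gene_id: g.c_true for g in truth.genes}
for stage in synthetic.STAGES:
    sub = table[table["stage"] == stage]
    rho = stats.spearmanr(sub["connectivity"],
                          [truth_c[g][stage] for g in sub["gene_id"]]).statistic
    print(f"{stage:16s} mean C_g {sub['connectivity'].mean():8.1f}   "
          f"Spearman vs planted truth {rho:.2f}")

mucosa = table[table["stage"] == "mucosa"].iloc[0]
print(f"\nexample record: gene {mucosa['gene_id']}, "
      f"C_g={mucosa['connectivity']:.1f} from {mucosa['n_pairs']} paired peaks "
      f"(raw={mucosa['raw_contacts']:.0f}, M={mucosa['mappability']:.2f}, "
      f"D={mucosa['background_density']:.3f})")
print("Mean C_g drops with stage (planted attenuation) while the rank "
      "correlation with truth stays high: the normalization preserves "
      "between-gene ordering.")
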