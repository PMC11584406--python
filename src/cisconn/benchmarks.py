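"""Planted-truth benchmarks: standard synthetic-cohort evaluations.

Each function builds a seeded synthetic dataset, runs the corresponding
analysis path and measures recovery of the planted ground truth.  They are
the package's validation surface: the test suite asserts on their outputs
and the reproduction script reports them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import connectivity as conn
from . import loops as loops_mod
from . import stripes as stripes_mod
from . import synthetic, twophase
from .contacts import bin_matrix, endpoint_positions, split_by_range, subsample


def _overlap_prf(called, planted) -> tuple[float, float, float]:
    """Precision/recall/F1 of called anchors vs planted intervals by any-bp
    overlap."""
    tp_p = sum(1 for (c, s, e) in planted
               if any(a.chrom == c and a.start < e and s < a.end for a in called))
    tp_c = sum(1 for a in called
               if any(a.chrom == c and a.start < e and s < a.end
                      for (c, s, e) in planted))
    prec = tp_c / len(called) if called else 0.0
    rec = tp_p / len(planted) if planted else 0.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
    return prec, rec, f1


def _anchor_bins(anchors) -> set:
    out = set()
    for a in anchors:
        out.update((a.chrom, i) for i in range(a.start // 100, a.end // 100))
    return out


def stripe_recovery(seed: int = 1, n_genes: int = 60, depth: int = 800_000,
                    cohort: tuple[int, int, int] = (2, 2, 2),
                    chrom_sizes: dict[str, int] | None = None,
                    subsample_fraction: float = 0.5) -> dict:
    """Consensus-anchor recovery on a multi-sample cohort.

    Returns precision/recall/F1 against planted anchors and the bin-level
    Jaccard overlap between anchors called at full depth and at
    *subsample_fraction* depth.
    """
    chrom_sizes = chrom_sizes or {"chr1": 10_000_000, "chr2": 10_000_000}
    truth = synthetic.build_truth(
        n_genes=n_genes, chrom_sizes=chrom_sizes,
        samples=synthetic.default_cohort(*cohort), seed=seed)
    pairs = {s: synthetic.simulate_contacts(truth, s, depth, seed=seed)
             for s in truth.samples}
    per_sample = {s: stripes_mod.call_sample_stripes(df, chrom_sizes)
                  for s, df in pairs.items()}
    anchors = stripes_mod.consensus_anchors(per_sample,
                                            autosomes=set(chrom_sizes))
    planted = [(a.chrom, a.start, a.end) for a in truth.stripe_anchors]
    prec, rec, f1 = _overlap_prf(anchors, planted)
    per_half = {s: stripes_mod.call_sample_stripes(
        subsample(df, subsample_fraction, seed=seed + 11), chrom_sizes)
        for s, df in pairs.items()}
    anchors_half = stripes_mod.consensus_anchors(per_half,
                                                 autosomes=set(chrom_sizes))
    sA, sB = _anchor_bins(anchors), _anchor_bins(anchors_half)
    jac = len(sA & sB) / len(sA | sB) if sA | sB else 0.0
    return {"precision": prec, "recall": rec, "f1": f1,
            "subsample_jaccard": jac, "n_anchors": len(anchors),
            "n_planted": len(planted)}


def bias_invariance(seed: int = 2, n_genes: int = 40,
                    depth: int = 3_000_000,
                    bias_grid: tuple[float, ...] = (0.5, 1.0, 2.0, 3.0),
                    n_neutral: int = 16) -> dict:
    """Mappability-bias neutrality of stripe enrichment and connectivity.

    Paired design: one contact map is simulated per bias level, identical
    except that bias bumps of that level sit at every gene promoter and at
    a fixed panel of neutral loci (midway between anchors).  Each readout is
    normalized against the b = 1 map at the same locus, cancelling locus-
    and gene-specific structure so only counting noise remains.  Under
    correct normalization the stripe enrichment ratio and connectivity have
    slope ~ 0 versus b while raw long-range coverage has slope ~ 1.
    """
    chrom_sizes = {"chr1": 12_000_000}
    base = synthetic.build_truth(n_genes=n_genes, chrom_sizes=chrom_sizes,
                                 samples={"s1": "mucosa"}, seed=seed)
    anch = sorted((a.start, a.end) for a in base.stripe_anchors)
    mids = [(anch[i][1] + anch[i + 1][0]) // 2 for i in range(len(anch) - 1)]
    mids = [m for m in mids if min(abs(m - s) for s, e in anch) > 80_000]
    if len(mids) < n_neutral:
        raise ValueError("not enough anchor-free midpoints")
    # neutral bumps narrower than the minimum long-range distance, so no
    # long-range pair has both ends inside one bump (coverage stays prop. b);
    # bump edges aligned to the 100-bp binning grid
    neutral = [((m // 100) * 100 - 500, (m // 100) * 100 + 500)
               for m in mids[:n_neutral]]
    # promoter bumps extend one pair length beyond the zone, so the zone's
    # self-ligation coverage is uniformly scaled by b
    promoter_bumps = []
    for g in base.genes:
        zs, ze = conn.GeneModel(g.gene_id, g.chrom, g.tss,
                                g.strand).promoter_zone
        promoter_bumps.append((zs - 1000, ze + 1000))

    per_level: dict[float, dict] = {}
    for b in bias_grid:
        # two maps per level: neutral-locus bumps for the stripe/coverage
        # readout and promoter bumps for the connectivity readout, so the
        # partner loci of each readout stay unbiased
        truth = synthetic.build_truth(
            n_genes=n_genes, chrom_sizes=chrom_sizes, samples={"s1": "mucosa"},
            seed=seed, bias_bumps=[("chr1", s, e, b) for s, e in neutral])
        df = synthetic.simulate_contacts(truth, "s1", depth, seed=seed + 1)
        if b == 1.0:
            df_p = df
        else:
            truth_p = synthetic.build_truth(
                n_genes=n_genes, chrom_sizes=chrom_sizes,
                samples={"s1": "mucosa"}, seed=seed,
                bias_bumps=[("chr1", zs, ze, b) for zs, ze in promoter_bumps])
            df_p = synthetic.simulate_contacts(truth_p, "s1", depth,
                                               seed=seed + 1)
        st = stripes_mod.call_sample_stripes(df, chrom_sizes)["chr1"]
        long_df, _ = split_by_range(df)
        lpos = np.sort(endpoint_positions(long_df, "chr1"))
        fe, cov = [], []
        for (s, e) in neutral:
            # the single 2-kb window [s, s+2000) covers the bump plus the
            # full downstream reach of self-ligation mates, so its long and
            # short contents mix the biased and flanking densities
            # identically and their ratio is exactly bias-free
            i = s // 100
            obs = st.long_local[i]
            exp = float(np.nan_to_num(st.expected[i]))
            fe.append(float((obs + 1) / (exp + 1)))
            cov.append(float(np.searchsorted(lpos, e) - np.searchsorted(lpos, s)))
        sc = conn.SampleContacts(df_p)
        peaks, _, _ = synthetic.simulate_tracks(truth, seed=seed + 1)
        enh = peaks[(peaks["sample"] == "s1") & (peaks["kind"] != "promoter")]
        genes = conn.genes_from_frame(synthetic.gene_models(truth))
        cg, mp = [], []
        for g in genes:
            paired = conn.pair_promoter_enhancers(g, enh)
            rec = conn.connectivity(sc, g, paired)
            cg.append(rec["connectivity"])
            mp.append(rec["mappability"])
        per_level[b] = {"fe": np.array(fe), "cov": np.array(cov),
                        "cg": np.array(cg), "mp": np.array(mp)}

    bs = np.asarray(bias_grid)
    ref = per_level[1.0]
    fe_means = np.array([per_level[b]["fe"].mean() for b in bias_grid])
    cov_ratio = np.array([np.mean(per_level[b]["cov"] / ref["cov"])
                          for b in bias_grid])
    cg_ratio = np.array([np.mean(per_level[b]["cg"] / ref["cg"])
                         for b in bias_grid])
    fe_slope = float(np.polyfit(bs, fe_means, 1)[0] / fe_means.mean())
    cov_slope = float(np.polyfit(bs, cov_ratio, 1)[0])
    conn_slope = float(np.polyfit(bs, cg_ratio, 1)[0] / cg_ratio.mean())
    mapp = {b: float(per_level[b]["mp"].mean()) for b in bias_grid}
    return {"fe_slope_frac": fe_slope, "coverage_slope": cov_slope,
            "connectivity_slope_frac": conn_slope,
            "mappability_by_bias": mapp,
            "fe_by_bias": {b: float(v) for b, v in zip(bias_grid, fe_means)},
            "coverage_by_bias": {b: float(v) for b, v in zip(bias_grid, cov_ratio)},
            "connectivity_by_bias": {b: float(v) for b, v in zip(bias_grid, cg_ratio)}}


def connectivity_recovery(seed: int = 3, n_genes: int = 220,
                          depth: int = 1_500_000,
                          cohort: tuple[int, int, int] = (2, 2, 2),
                          chrom_sizes: dict[str, int] | None = None) -> dict:
    """Recovery of planted per-gene connectivity across a staged cohort.

    Returns the Spearman correlation between measured C_g and planted
    C_true (pooled over samples, per-stage values) and the stage means.
    """
    chrom_sizes = chrom_sizes or {"chr1": 10_000_000, "chr2": 10_000_000,
                                  "chr3": 10_000_000}
    truth = synthetic.build_truth(
        n_genes=n_genes, chrom_sizes=chrom_sizes,
        samples=synthetic.default_cohort(*cohort), seed=seed)
    peaks, _, _ = synthetic.simulate_tracks(truth, seed=seed)
    genes = conn.genes_from_frame(synthetic.gene_models(truth))
    truth_by_id = {g.gene_id: g for g in truth.genes}
    contacts_by_sample = {}
    for s in truth.samples:
        df = synthetic.simulate_contacts(truth, s, depth, seed=seed)
        contacts_by_sample[s] = conn.SampleContacts(df)
    enh = peaks[peaks["kind"] != "promoter"]
    table = conn.connectivity_table(contacts_by_sample, genes, enh,
                                    sample_stage=truth.samples)
    gene_stage = (table.groupby(["gene_id", "stage"])["connectivity"]
                  .mean().reset_index())
    gene_stage["c_true"] = [truth_by_id[g].c_true[s]
                            for g, s in zip(gene_stage["gene_id"],
                                            gene_stage["stage"])]
    rho = float(sps.spearmanr(gene_stage["connectivity"],
                              gene_stage["c_true"]).statistic)
    mucosa = gene_stage[gene_stage["stage"] == "mucosa"]
    rho_mucosa = float(sps.spearmanr(mucosa["connectivity"],
                                     mucosa["c_true"]).statistic)
    stage_means = {s: float(gene_stage.loc[gene_stage["stage"] == s,
                                           "connectivity"].mean())
                   for s in synthetic.STAGES}
    return {"spearman_pooled": rho, "spearman_mucosa": rho_mucosa,
            "stage_means": stage_means, "n_genes": len(mucosa),
            "table": table}


def apa_attenuation(seed: int = 4, n_genes: int = 40,
                    depth: int = 2_000_000, resolution: int = 1000,
                    half_width: int = 25) -> dict:
    """Loop APA scores per stage on a one-sample-per-stage cohort; planted
    loop attenuation should order the scores mucosa > adenocarcinoma."""
    chrom_sizes = {"chr1": 10_000_000, "chr2": 10_000_000}
    samples = {f"{st}_1": st for st in synthetic.STAGES}
    truth = synthetic.build_truth(n_genes=n_genes, chrom_sizes=chrom_sizes,
                                  samples=samples, seed=seed, n_loops=25)
    loop_frame = pd.DataFrame([{"chrom": lp.chrom, "start1": lp.start1,
                                "end1": lp.end1, "start2": lp.start2,
                                "end2": lp.end2}
                               for lp in truth.loop_pairs])
    scores = {}
    for sample, stage in samples.items():
        df = synthetic.simulate_contacts(truth, sample, depth, seed=seed)
        mats = [bin_matrix(df, c, chrom_sizes[c], resolution)
                for c in chrom_sizes]
        scores[stage] = loops_mod.apa(mats, loop_frame,
                                      half_width=half_width, mode="loop").score
    return {"apa_by_stage": scores}


def twophase_behavior(seed: int = 5, n_genes: int = 10_000,
                      test_n: int = 2800, epochs: int = 40,
                      hidden: tuple[int, ...] = (256, 64, 16),
                      n_cohorts: int = 8) -> dict:
    """Two-phase cohort behavior: correlation shift, initial-model skill
    against a target-permutation null, and direction-prediction accuracy
    stratified by directionality score."""
    feats, stage_tables, _ = synthetic.simulate_feature_cohort(
        n_genes=n_genes, seed=seed)
    tf_cols = [c for c in feats if c.startswith("tf_")]
    extra = feats.set_index("gene_id")[tf_cols]
    target = feats.set_index("gene_id")["log2fc_polyp"]
    ft = twophase.build_features(stage_tables, "initial", target=target,
                                 extra=extra)
    model = twophase.train_model(ft, test_n=test_n, epochs=epochs,
                                 seed=seed, hidden=hidden)
    p_perm = twophase.heldout_permutation_pvalue(model, ft, seed=seed)
    # control: same pipeline with the target permuted before training
    rng = np.random.default_rng([seed, 888])
    y_perm = pd.Series(rng.permutation(target.to_numpy()), index=target.index)
    ft_null = twophase.build_features(stage_tables, "initial", target=y_perm,
                                      extra=extra)
    null_model = twophase.train_model(ft_null, test_n=test_n,
                                      epochs=max(10, epochs // 3),
                                      seed=seed, hidden=hidden)
    connd = {s: stage_tables[s]["connectivity"].to_numpy()
             for s in synthetic.STAGES}
    exprd = {s: stage_tables[s]["tpm"].to_numpy() for s in synthetic.STAGES}
    shift = twophase.correlation_shift(connd, exprd)
    calls = synthetic.simulate_multicancer_calls(feats, n_cohorts=n_cohorts,
                                                 seed=seed)
    pred = model.predict(ft.X)
    auc, accs = twophase.direction_prediction_eval(pred, calls)
    return {"heldout_r": model.heldout_r,
            "permutation_p": p_perm,
            "null_model_r": null_model.heldout_r,
            "selected_epoch": model.selected_epoch,
            "rho_by_stage": dict(zip(shift["stage"], shift["rho"])),
            "auc": auc,
            "accuracy_by_bin": accs["accuracy"].tolist(),
            "bin_n": accs["n"].tolist()}
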