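import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from cisconn import annotate, synthetic
from cisconn.contacts import distances, is_inward, split_by_range
from cisconn.synthetic import (STAGES, SyntheticTruth, build_truth,
                               two_phase_expression)


def background_only_truth(alpha=1.0):
    return SyntheticTruth(
        chrom_sizes={"chr1": 10_000_000}, stripe_anchors=[], loop_pairs=[],
        genes=[], samples={"s": "mucosa"}, decay_exponent=alpha,
        fractions={"background": 1.0, "stripe": 0.0, "loop": 0.0,
                   "selflig": 0.0})


class TestTruthValidation:
    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError, match="stage"):
            build_truth(n_genes=5, samples={"s": "tumour"})

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            SyntheticTruth(chrom_sizes={"chr1": 0}, stripe_anchors=[],
                           loop_pairs=[], genes=[], samples={})

    def test_bias_outside_declared_range_rejected(self):
        with pytest.raises(ValueError, match="bias"):
            build_truth(n_genes=5, bias_bumps=[("chr1", 0, 100, 5.0)])

    def test_nonunit_mucosa_attenuation_rejected(self):
        with pytest.raises(ValueError, match="mucosa"):
            build_truth(n_genes=5, stage_attenuation={
                "mucosa": 0.9, "polyp": 0.8, "adenocarcinoma": 0.6})

    def test_unknown_sample_rejected(self):
        truth = build_truth(n_genes=5)
        with pytest.raises(ValueError, match="unknown sample"):
            synthetic.simulate_contacts(truth, "nope", 1000, seed=0)

    def test_json_round_trip(self, tmp_path):
        truth = build_truth(n_genes=5, seed=3)
        truth.to_json(tmp_path / "t.json")
        back = SyntheticTruth.from_json(tmp_path / "t.json")
        assert back.chrom_sizes == truth.chrom_sizes
        assert back.genes[0] == truth.genes[0]
        assert back.stripe_anchors == truth.stripe_anchors


class TestSimulateContacts:
    def test_determinism_byte_identical(self, small_truth):
        a = synthetic.simulate_contacts(small_truth, "polyp_1", 50_000, seed=5)
        b = synthetic.simulate_contacts(small_truth, "polyp_1", 50_000, seed=5)
        assert_frame_equal(a, b)
        c = synthetic.simulate_contacts(small_truth, "polyp_1", 50_000, seed=6)
        assert not a.equals(c)

    def test_background_decay_slope(self):
        truth = background_only_truth(alpha=1.0)
        df = synthetic.simulate_contacts(truth, "s", 400_000, seed=1)
        d = distances(df)
        bins = np.geomspace(10_000, 1_000_000, 15)
        hist, edges = np.histogram(d, bins=bins)
        centers = np.sqrt(edges[:-1] * edges[1:])
        dens = hist / np.diff(edges)
        slope = np.polyfit(np.log10(centers), np.log10(dens), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_depth_proportionality(self, small_truth):
        d1 = synthetic.simulate_contacts(small_truth, "mucosa_1", 100_000, seed=2)
        d2 = synthetic.simulate_contacts(small_truth, "mucosa_1", 200_000, seed=3)
        n1 = int((d1["chrom1"] == "chr1").sum())
        n2 = int((d2["chrom1"] == "chr1").sum())
        assert abs(n2 - 2 * n1) < 3 * np.sqrt(2 * n1) + 3 * np.sqrt(n2)

    def test_self_ligation_inward_short(self, small_sample_pairs):
        _, short = split_by_range(small_sample_pairs)
        assert len(short) > 0
        assert np.all(is_inward(short))
        assert np.all(distances(short) < 1000)

    def test_planted_loop_exceeds_donut_median(self, small_truth):
        from cisconn.contacts import bin_matrix
        from cisconn.loops import donut_expected
        df = synthetic.simulate_contacts(small_truth, "mucosa_1", 400_000, seed=8)
        lp = small_truth.loop_pairs[0]
        m = bin_matrix(df, lp.chrom, small_truth.chrom_sizes[lp.chrom], 1000)
        i = (lp.start1 + lp.end1) // 2 // 1000
        j = (lp.start2 + lp.end2) // 2 // 1000
        obs = m.symmetric()[i, j]
        assert obs > donut_expected(m, i, j)

    def test_zero_depth_rejected(self, small_truth):
        with pytest.raises(ValueError):
            synthetic.simulate_contacts(small_truth, "mucosa_1", 0, seed=1)

    def test_stage_attenuation_orders_anchor_coverage(self, small_truth):
        counts = {}
        for stage in STAGES:
            df = synthetic.simulate_contacts(small_truth, f"{stage}_1",
                                             200_000, seed=4)
            long_df, _ = split_by_range(df)
            total = 0
            for a in small_truth.stripe_anchors:
                sel = ((long_df["chrom1"] == a.chrom)
                       & (long_df["pos1"] >= a.start) & (long_df["pos1"] < a.end))
                total += int(sel.sum())
            counts[stage] = total
        assert counts["mucosa"] > counts["polyp"] > counts["adenocarcinoma"]


class TestTwoPhaseRule:
    def test_saturation_ratio(self):
        c_sat, beta = 1.0, 50.0
        e_mucosa = two_phase_expression(2.0 * c_sat, beta, c_sat)
        e_polyp = two_phase_expression(0.5 * c_sat, beta, c_sat)
        assert e_polyp / e_mucosa == pytest.approx(0.5)

    def test_saturated_genes_insensitive(self):
        assert (two_phase_expression(3.0, 50.0, 1.0)
                == two_phase_expression(8.0, 50.0, 1.0))


class TestSimulateTracks:
    def test_demethylated_round_trip(self, small_truth):
        _, meth, _ = synthetic.simulate_tracks(small_truth, seed=1)
        g = next(g for g in small_truth.genes if g.meth_mean["mucosa"] == 10.0)
        sub = meth[(meth["sample"] == "mucosa_1") & (meth["gene_id"] == g.gene_id)]
        mean = annotate.region_methylation(sub, g.chrom, g.tss - 1600,
                                           g.tss + 1600)
        assert annotate.classify_state(mean) == "demethylated"

    def test_two_seeds_same_truth_columns_different_noise(self, small_truth):
        p1, m1, e1 = synthetic.simulate_tracks(small_truth, seed=1)
        p2, m2, e2 = synthetic.simulate_tracks(small_truth, seed=2)
        assert list(e1["gene_id"]) == list(e2["gene_id"])
        assert not np.allclose(e1["tpm"], e2["tpm"])
        shared1 = p1[p1["kind"] == "enhancer"][["chrom", "start", "end"]]
        shared2 = p2[p2["kind"] == "enhancer"][["chrom", "start", "end"]]
        assert set(map(tuple, shared1.values)) == set(map(tuple, shared2.values))

    def test_empty_gene_truth_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_tracks(background_only_truth(), seed=0)

    def test_stage_monotone_planted_connectivity(self, small_truth):
        means = {s: np.mean([g.c_true[s] for g in small_truth.genes])
                 for s in STAGES}
        assert means["mucosa"] > means["polyp"] > means["adenocarcinoma"]


class TestFeatureCohort:
    def test_shapes_and_determinism(self):
        f1, t1, _ = synthetic.simulate_feature_cohort(n_genes=500, seed=9)
        f2, t2, _ = synthetic.simulate_feature_cohort(n_genes=500, seed=9)
        assert_frame_equal(f1, f2)
        assert set(t1) == set(STAGES)
        assert len(f1) == 500

    def test_saturated_majority_in_mucosa(self):
        _, _, truth = synthetic.simulate_feature_cohort(n_genes=2000, seed=1)
        assert (truth["c_mucosa"] > 1.0).mean() > 0.6

    def test_multicancer_calls_coding(self):
        feats, _, _ = synthetic.simulate_feature_cohort(n_genes=300, seed=2)
        calls = synthetic.simulate_multicancer_calls(feats, n_cohorts=4, seed=2)
        assert calls.shape == (300, 4)
        assert set(np.unique(calls)) <= {-1, 0, 1}
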