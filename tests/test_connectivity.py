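import numpy as np
import pandas as pd
import pytest

from cisconn import connectivity as cn
from cisconn.contacts import subsample
from conftest import make_pairs


GENE = cn.GeneModel("g1", "chr1", 500_000, "+")


def peaks_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                       "fold_enrichment"])


class TestGeneModel:
    def test_plus_strand_zone(self):
        assert GENE.promoter_zone == (498_500, 500_500)

    def test_minus_strand_zone_mirrored(self):
        g = cn.GeneModel("g2", "chr1", 500_000, "-")
        assert g.promoter_zone == (499_500, 501_500)

    def test_zone_length_2kb(self):
        for strand in "+-":
            zs, ze = cn.GeneModel("g", "chr1", 10_000, strand).promoter_zone
            assert ze - zs == 2000


class TestPairing:
    def test_distance_window(self):
        peaks = peaks_frame([
            ("chr1", 650_000, 650_600, 5.0),   # TSS + 150 kb -> paired
            ("chr1", 750_000, 750_600, 5.0),   # TSS + 250 kb -> not paired
            ("chr1", 499_000, 499_400, 5.0),   # inside promoter zone -> excluded
            ("chr2", 650_000, 650_600, 5.0),   # other chromosome
        ])
        paired = cn.pair_promoter_enhancers(GENE, peaks)
        assert list(paired["start"]) == [650_000]

    def test_promoter_peaks_excludable(self):
        peaks = peaks_frame([("chr1", 650_000, 650_600, 5.0)])
        peaks["kind"] = "promoter"
        assert len(cn.pair_promoter_enhancers(GENE, peaks)) == 1
        assert len(cn.pair_promoter_enhancers(GENE, peaks,
                                              exclude_promoters=True)) == 0


def uniform_short_pairs(chrom="chr1", start=400_000, end=600_000, step=50):
    """Inward self-ligation pairs tiling [start, end) uniformly."""
    rows = [(chrom, p, "+", chrom, p + 400, "-")
            for p in range(start, end, step)]
    return make_pairs(rows)


class TestPromoterMappability:
    def test_uniform_coverage_is_one(self):
        sc = cn.SampleContacts(uniform_short_pairs())
        assert cn.promoter_mappability(sc, GENE) == pytest.approx(1.0, abs=0.02)

    def test_doubled_promoter_coverage_is_two(self):
        extra = make_pairs([("chr1", p, "+", "chr1", p + 100, "-")
                            for p in range(498_500, 500_400, 50)])
        sc = cn.SampleContacts(pd.concat([uniform_short_pairs(), extra],
                                         ignore_index=True))
        assert cn.promoter_mappability(sc, GENE) == pytest.approx(2.0, abs=0.08)

    def test_no_neighborhood_coverage_flagged(self):
        sc = cn.SampleContacts(make_pairs([("chr1", 0, "+", "chr1", 400, "-")]))
        assert np.isnan(cn.promoter_mappability(sc, GENE))


class TestBackgroundDensity:
    def test_count_over_area_division(self):
        # 90 contacts fully inside the downstream ring, each spanning 10 kb
        rows = [("chr1", 510_000 + 200 * k, "+", "chr1", 520_000 + 200 * k, "-")
                for k in range(90)]
        sc = cn.SampleContacts(make_pairs(rows))
        d = cn.background_density(sc, GENE)
        area = cn._ring_area_kb2(5000, 50_000, 1500, 1000)
        assert d == pytest.approx(90 / area)

    def test_depth_linearity(self):
        rows = [("chr1", 510_000 + 200 * k, "+", "chr1", 520_000 + 200 * k, "-")
                for k in range(90)]
        sc1 = cn.SampleContacts(make_pairs(rows))
        sc2 = cn.SampleContacts(make_pairs(rows + rows))
        assert (cn.background_density(sc2, GENE)
                == pytest.approx(2 * cn.background_density(sc1, GENE)))

    def test_empty_ring_floored(self):
        sc = cn.SampleContacts(make_pairs([("chr1", 0, "+", "chr1", 5000, "-")]))
        assert cn.background_density(sc, GENE) == pytest.approx(1e-6)


class TestConnectivity:
    def test_normalization_arithmetic(self):
        # 10 raw promoter-peak contacts, M = 2, D = 0.5 -> C = 10
        rows = [("chr1", 499_000 + 10 * k, "+", "chr1", 650_100, "-")
                for k in range(10)]
        sc = cn.SampleContacts(make_pairs(rows))
        peaks = peaks_frame([("chr1", 650_000, 650_600, 5.0)])
        rec = cn.connectivity(sc, GENE, peaks, mappability=2.0, density=0.5)
        assert rec["raw_contacts"] == 10
        assert rec["connectivity"] == pytest.approx(10.0)
        assert rec["n_pairs"] == 1
        assert rec["enhancer_accessibility"] == pytest.approx(np.log10(6.0))

    def test_no_paired_peaks(self):
        sc = cn.SampleContacts(uniform_short_pairs())
        rec = cn.connectivity(sc, GENE, peaks_frame([]), mappability=1.0,
                              density=1.0)
        assert rec["connectivity"] == 0.0 and rec["n_pairs"] == 0

    def test_depth_invariance_on_synthetic_cohort(self, small_truth):
        from cisconn import synthetic
        pairs = synthetic.simulate_contacts(small_truth, "mucosa_1",
                                            600_000, seed=21)
        half = subsample(pairs, 0.5, seed=22)
        peaks, _, _ = synthetic.simulate_tracks(small_truth, seed=21)
        enh = peaks[(peaks["sample"] == "mucosa_1") & (peaks["kind"] != "promoter")]
        genes = cn.genes_from_frame(synthetic.gene_models(small_truth))
        sc_full = cn.SampleContacts(pairs)
        sc_half = cn.SampleContacts(half)
        ratios = []
        for g in genes:
            paired = cn.pair_promoter_enhancers(g, enh)
            if len(paired) < 3:
                continue
            c_full = cn.connectivity(sc_full, g, paired)["connectivity"]
            c_half = cn.connectivity(sc_half, g, paired)["connectivity"]
            ratios.append(c_half / c_full)
        assert len(ratios) >= 10
        assert np.median(ratios) == pytest.approx(1.0, abs=0.15)
        assert np.mean([(0.8 <= r <= 1.25) for r in ratios]) >= 0.8


class TestPromoterAccessibility:
    def test_constant_track(self):
        fe = np.full(2000, 4.0)
        assert cn.promoter_accessibility(fe) == pytest.approx(np.log10(4.0))

    def test_top_two_quartiles(self):
        fe = np.concatenate([np.full(1000, 1.0), np.full(500, 4.0),
                             np.full(500, 8.0)])
        # quartile means sorted: 1, 1, 4, 8 -> mean of top two = 6
        assert cn.promoter_accessibility(fe) == pytest.approx(np.log10(6.0))

    def test_zero_track_undefined(self):
        assert np.isnan(cn.promoter_accessibility(np.zeros(100)))


class TestFilterGeneSet:
    def make_table(self):
        cols = {}
        for stage, v in zip(("mucosa", "polyp", "adenocarcinoma"),
                            ([-1.0, 2.0, 1.0], [0.0, -3.0, 2.0], [0.0, 4.0, 3.0])):
            cols[f"connectivity_{stage}"] = v
            cols[f"promoter_accessibility_{stage}"] = [1.0, 1.0, 1.0]
            cols[f"promoter_stripe_strength_{stage}"] = [0.5, 0.5, 0.5]
        return pd.DataFrame(cols, index=["gA", "gB", "gC"])

    def test_all_nonpositive_removed(self):
        out = cn.filter_gene_set(self.make_table())
        assert "gA" not in out.index  # connectivity <= 0 in all stages
        assert list(out.index) == ["gB", "gC"]

    def test_negative_values_zeroed(self):
        out = cn.filter_gene_set(self.make_table())
        assert out.loc["gB", "connectivity_polyp"] == 0.0
        assert out.loc["gB", "connectivity_mucosa"] == 2.0

    def test_all_positive_unchanged(self):
        out = cn.filter_gene_set(self.make_table())
        assert out.loc["gC", "connectivity_adenocarcinoma"] == 3.0
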