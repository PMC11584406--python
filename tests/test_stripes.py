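import math

import numpy as np
import pytest

from cisconn import stripes as sm
from cisconn import synthetic
from cisconn.contacts import empty_pairs


def brute_poisson_sf(observed: int, lam: float) -> float:
    """Independent oracle: upper-tail P(X >= observed) by direct pmf
    summation (log-space terms, fsum accumulation)."""
    if observed <= 0:
        return 1.0
    if lam == 0:
        return 0.0
    terms = [math.exp(k * math.log(lam) - lam - math.lgamma(k + 1))
             for k in range(0, observed)]
    return max(0.0, 1.0 - math.fsum(terms))


class TestExpectedCount:
    def test_direct_formula(self):
        assert sm.expected_count(1000, 500, 40) == pytest.approx(80.0)

    def test_zero_long_background(self):
        assert sm.expected_count(0, 500, 40) == pytest.approx(0.0)

    def test_zero_short_background_is_unmappable(self):
        assert np.isnan(sm.expected_count(1000, 0, 40))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            sm.expected_count(-1, 500, 40)


class TestPoisson:
    def test_zero_observed_gives_one(self):
        assert sm.poisson_p(0, 5.0) == pytest.approx(1.0)

    def test_matches_brute_force_summation(self):
        # frozen from the oracle: P(X >= 10 | lam = 1)
        assert brute_poisson_sf(10, 1.0) == pytest.approx(1.1142547829e-07, rel=1e-8)
        assert sm.poisson_p(10, 1.0) == pytest.approx(brute_poisson_sf(10, 1.0),
                                                      abs=1e-10)

    def test_single_test_q_equals_p(self):
        q = sm.poisson_q(np.array([10]), np.array([1.0]))
        assert q[0] == pytest.approx(sm.poisson_p(10, 1.0))

    def test_bh_is_monotone_and_bounded(self):
        p = np.array([0.001, 0.01, 0.5, 0.9])
        q = sm.bh_qvalues(p)
        assert np.all(np.diff(q[np.argsort(p)]) >= -1e-12)
        assert np.all((q >= p - 1e-12) & (q <= 1.0))


class TestStripeStrength:
    @pytest.mark.parametrize("obs,exp,val", [
        (99, 9, 1.0),          # log10(100/10)
        (7, 7, 0.0),
        (0, 0, 0.0),           # pseudo-count limit
    ])
    def test_values(self, obs, exp, val):
        assert sm.stripe_strength(obs, exp) == pytest.approx(val)


class TestCallSampleStripes:
    def test_empty_stream_gives_empty_result(self):
        assert sm.call_sample_stripes(empty_pairs(), {"chr1": 1_000_000}) == {}

    def test_short_chromosome_skipped(self, small_sample_pairs):
        out = sm.call_sample_stripes(small_sample_pairs,
                                     {"chr1": 6_000_000, "chrTiny": 10_000})
        assert "chrTiny" not in out and "chr1" in out

    def test_planted_anchor_attains_minimum_q(self):
        truth = synthetic.build_truth(n_genes=4,
                                      chrom_sizes={"chr1": 4_000_000},
                                      samples={"s": "mucosa"}, seed=7)
        pairs = synthetic.simulate_contacts(truth, "s", 400_000, seed=7)
        st = sm.call_sample_stripes(pairs, truth.chrom_sizes)["chr1"]
        q = np.nan_to_num(st.q_value, nan=1.0)
        best_bin = int(np.argmin(q)) * st.step
        anchors = [(a.start, a.end) for a in truth.stripe_anchors]
        assert any(s - 2000 <= best_bin < e for s, e in anchors)


def _fake_stats(q_rows, step=100):
    """StripeBinStats with fabricated q-values (one chromosome)."""
    n = len(q_rows)
    z = np.zeros(n)
    return sm.StripeBinStats(chrom="chr1", step=step, long_local=z,
                             long_bg=z, short_local=z, short_bg=z,
                             expected=z, q_value=np.array(q_rows, dtype=float),
                             strength=z)


class TestConsensusAnchors:
    def test_min_sample_threshold(self):
        # six bins significant in 5,4,3,2,1,0 of 5 samples
        sig = [[1, 1, 1, 1, 1, 0],
               [1, 1, 1, 1, 0, 0],
               [1, 1, 1, 0, 0, 0],
               [1, 1, 0, 0, 0, 0],
               [1, 0, 0, 0, 0, 0]]
        per_sample = {f"s{k}": {"chr1": _fake_stats(
            [0.001 if v else 0.5 for v in row])} for k, row in enumerate(sig)}
        anchors = sm.consensus_anchors(per_sample, min_samples=3, min_size=100)
        assert len(anchors) == 1
        assert (anchors[0].start, anchors[0].end) == (0, 300)

    def test_min_size_drops_short_windows(self):
        row = [0.001] * 4 + [0.5] * 6  # 400 bp run
        per_sample = {f"s{k}": {"chr1": _fake_stats(row)} for k in range(3)}
        assert sm.consensus_anchors(per_sample, min_samples=3, min_size=500) == []

    def test_blacklist_removal(self):
        # three 600-bp runs; the middle one overlaps the blacklist
        row = ([0.001] * 6 + [0.5] * 4) * 3
        per_sample = {f"s{k}": {"chr1": _fake_stats(row)} for k in range(3)}
        import pandas as pd
        bl = pd.DataFrame({"chrom": ["chr1"], "start": [1100], "end": [1300]})
        anchors = sm.consensus_anchors(per_sample, min_samples=3, min_size=500,
                                       blacklist=bl)
        assert [(a.start, a.end) for a in anchors] == [(0, 600), (2000, 2600)]

    def test_autosome_filter(self):
        row = [0.001] * 6
        per_sample = {f"s{k}": {"chr1": _fake_stats(row)} for k in range(3)}
        assert sm.consensus_anchors(per_sample, min_size=100,
                                    autosomes={"chr2"}) == []

    def test_too_few_samples_error(self):
        per_sample = {"s0": {"chr1": _fake_stats([0.001])}}
        with pytest.raises(ValueError):
            sm.consensus_anchors(per_sample, min_samples=3)


class TestInteractionFETrack:
    def test_ratio_with_pseudo(self):
        from conftest import make_pairs
        rows = [("chr1", 500, "+", "chr1", 3500, "-")] * 20     # long (>2 kb)
        rows += [("chr1", 500, "+", "chr1", 900, "-")] * 10     # short (<1.5 kb)
        track = sm.interaction_fe_track(make_pairs(rows), "chr1", 10_000)
        assert track.values[5] == pytest.approx(21 / 11)

    def test_empty_bin_is_one(self):
        from conftest import make_pairs
        track = sm.interaction_fe_track(
            make_pairs([("chr1", 500, "+", "chr1", 3500, "-")]), "chr1", 10_000)
        assert track.values[70] == pytest.approx(1.0)

    def test_planted_anchor_exceeds_random_locus(self, small_truth,
                                                 small_sample_pairs):
        track = sm.interaction_fe_track(small_sample_pairs, "chr1", 6_000_000)
        a = next(a for a in small_truth.stripe_anchors if a.chrom == "chr1")
        anchor_fe = track.values[a.start // 100: a.end // 100].mean()
        random_fe = track.values[1000:1020].mean()
        assert anchor_fe > random_fe
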