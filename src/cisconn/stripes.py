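"""Architectural stripe calling with mappability normalization.

A stripe anchor is a locus whose long-range contact coverage exceeds what its
short-range self-ligation coverage predicts.  Because read mappability
inflates long- and short-range coverage proportionally, the expected
long-range count for a 100-bp bin is

    expected = (long_bg / short_bg) * short_local

where *local* uses a 2-kb window and *bg* a 50-kb window, both sliding at
100 bp.  Observed long-range counts are tested against this expectation with
an upper-tail Poisson test, Benjamini-Hochberg corrected per sample, and the
log10 fold enrichment (pseudo-count 1) is reported as stripe strength.
Consensus anchors are bins significant (q < 0.01) in >= 3 samples, merged,
>= 500 bp, blacklist-free and autosomal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .contacts import (BinnedTrack, coverage_track, endpoint_positions,
                       interval_overlaps, merge_intervals, split_by_range)


@dataclass
class StripeParams:
    """Thresholds of the stripe caller (defaults as published)."""

    long_min: int = 1500        # bp, long-range distance threshold
    short_max: int = 1000       # bp, self-ligation distance threshold
    local_window: int = 2000    # bp
    background_window: int = 50000  # bp
    step: int = 100             # bp
    pseudo: float = 1.0
    fdr: float = 0.01
    min_samples: int = 3
    min_size: int = 500         # bp


def expected_count(long_bg, short_bg, short_local) -> np.ndarray:
    """Expected long-range count: (long_bg / short_bg) * short_local.

    Bins with ``short_bg == 0`` carry no mappability estimate and are
    returned as NaN (unmappable; excluded from testing downstream).
    Negative inputs are rejected.
    """
    long_bg = np.asarray(long_bg, dtype=float)
    short_bg = np.asarray(short_bg, dtype=float)
    short_local = np.asarray(short_local, dtype=float)
    if (long_bg < 0).any() or (short_bg < 0).any() or (short_local < 0).any():
        raise ValueError("counts must be nonnegative")
    with np.errstate(divide="ignore", invalid="ignore"):
        exp = long_bg / short_bg * short_local
    exp = np.where(short_bg == 0, np.nan, exp)
    return exp


def poisson_p(observed, expected) -> np.ndarray:
    """Upper-tail Poisson probability P(X >= observed | lambda = expected)."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    p = stats.poisson.sf(observed - 1, expected)
    # lambda = 0: P(X >= 0) = 1, P(X >= k>0) = 0 (sf handles, but be explicit
    # about observed == 0 for any lambda)
    p = np.where(observed <= 0, 1.0, p)
    return p


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values; NaNs are passed through."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def poisson_q(observed, expected, n_tests: int | None = None) -> np.ndarray:
    """Upper-tail Poisson p-values BH-corrected over the tested bins.

    The BH family is the set of bins passed in one call (one family per
    sample).  *n_tests* pads the family size when only a subset of the
    tested bins is supplied.
    """
    p = poisson_p(observed, expected)
    if n_tests is not None and n_tests > np.isfinite(p).sum():
        # pad with p=1 placeholders so ranks reflect the full family
        pad = np.ones(n_tests - int(np.isfinite(p).sum()))
        full = np.concatenate([p[np.isfinite(p)], pad])
        qfull = multipletests(full, method="fdr_bh")[1]
        q = np.full_like(np.asarray(p, dtype=float), np.nan)
        q[np.isfinite(p)] = qfull[: int(np.isfinite(p).sum())]
        return q
    return bh_qvalues(p)


def stripe_strength(observed, expected, pseudo: float = 1.0) -> np.ndarray:
    """log10((observed + pseudo) / (expected + pseudo)); NaN expected -> NaN."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    return np.log10((observed + pseudo) / (expected + pseudo))


@dataclass
class StripeBinStats:
    """Per-bin stripe statistics of one sample on one chromosome."""

    chrom: str
    step: int
    long_local: np.ndarray = field(repr=False)
    long_bg: np.ndarray = field(repr=False)
    short_local: np.ndarray = field(repr=False)
    short_bg: np.ndarray = field(repr=False)
    expected: np.ndarray = field(repr=False)
    q_value: np.ndarray = field(repr=False)
    strength: np.ndarray = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.expected)

    def to_frame(self) -> pd.DataFrame:
        starts = np.arange(self.n_bins, dtype=np.int64) * self.step
        return pd.DataFrame({
            "chrom": self.chrom, "start": starts, "end": starts + self.step,
            "long_local": self.long_local, "long_bg": self.long_bg,
            "short_local": self.short_local, "short_bg": self.short_bg,
            "expected": self.expected, "q_value": self.q_value,
            "strength": self.strength,
        })


def call_sample_stripes(pairs: pd.DataFrame, chrom_sizes: dict[str, int],
                        params: StripeParams | None = None) -> dict[str, StripeBinStats]:
    """Per-100-bp-bin stripe statistics for one sample.

    Computes the four coverages (local/background x long/short), the
    mappability-normalized expected count, BH-corrected Poisson q-values
    (one BH family per sample across all chromosomes) and the log10 fold
    enrichment.  Chromosomes shorter than the background window are skipped.
    """
    params = params or StripeParams()
    if len(pairs) == 0:
        return {}
    long_df, short_df = split_by_range(pairs, params.long_min, params.short_max)
    per_chrom: dict[str, dict] = {}
    all_p: list[np.ndarray] = []
    for chrom, size in chrom_sizes.items():
        if size < params.background_window:
            continue
        lpos = endpoint_positions(long_df, chrom)
        spos = endpoint_positions(short_df, chrom)
        tracks = {
            "long_local": coverage_track(lpos, chrom, size, params.local_window, params.step),
            "long_bg": coverage_track(lpos, chrom, size, params.background_window, params.step),
            "short_local": coverage_track(spos, chrom, size, params.local_window, params.step),
            "short_bg": coverage_track(spos, chrom, size, params.background_window, params.step),
        }
        # align background-window centers with the local window center so a
        # locally sloped signal does not bias the expectation (windows are
        # forward-anchored at the bin start; clamped at chromosome edges)
        shift = (params.background_window - params.local_window) // (2 * params.step)
        n_bins = tracks["long_local"].n_bins
        src = np.clip(np.arange(n_bins) - shift, 0, n_bins - 1)
        long_bg = tracks["long_bg"].values[src]
        short_bg = tracks["short_bg"].values[src]
        tracks["long_bg"].values = long_bg
        tracks["short_bg"].values = short_bg
        exp = expected_count(long_bg, short_bg, tracks["short_local"].values)
        p = np.where(np.isnan(exp), np.nan,
                     poisson_p(tracks["long_local"].values, np.nan_to_num(exp)))
        per_chrom[chrom] = {"tracks": tracks, "expected": exp, "p": p}
        all_p.append(p)
    if not per_chrom:
        return {}
    # one BH family per sample, jointly over chromosomes
    concat_p = np.concatenate(all_p)
    concat_q = bh_qvalues(concat_p)
    out: dict[str, StripeBinStats] = {}
    offset = 0
    for chrom, d in per_chrom.items():
        n = len(d["expected"])
        q = concat_q[offset: offset + n]
        offset += n
        t = d["tracks"]
        out[chrom] = StripeBinStats(
            chrom=chrom, step=params.step,
            long_local=t["long_local"].values, long_bg=t["long_bg"].values,
            short_local=t["short_local"].values, short_bg=t["short_bg"].values,
            expected=d["expected"], q_value=q,
            strength=stripe_strength(t["long_local"].values,
                                     np.nan_to_num(d["expected"]),
                                     params.pseudo),
        )
    return out


@dataclass
class StripeAnchor:
    """Consensus stripe anchor interval with cross-sample support."""

    chrom: str
    start: int
    end: int
    n_supporting_samples: int
    mean_strength: dict[str, float] = field(default_factory=dict)

    @property
    def width(self) -> int:
        return self.end - self.start


def consensus_anchors(per_sample: dict[str, dict[str, StripeBinStats]],
                      fdr: float = 0.01, min_samples: int = 3,
                      min_size: int = 500,
                      blacklist: pd.DataFrame | None = None,
                      autosomes: set[str] | None = None) -> list[StripeAnchor]:
    """Merge per-sample significant bins into consensus stripe anchors.

    A 100-bp bin is a hit in a sample if its q-value < *fdr*; bins with hits
    in >= *min_samples* samples are kept, adjacent kept bins merged, merged
    windows < *min_size* dropped, blacklist overlaps removed and only
    *autosomes* retained (all chromosomes if None).
    """
    if len(per_sample) < min_samples:
        raise ValueError("need at least min_samples input samples")
    chroms: set[str] = set()
    for stats_by_chrom in per_sample.values():
        chroms.update(stats_by_chrom)
    anchors: list[StripeAnchor] = []
    for chrom in sorted(chroms):
        if autosomes is not None and chrom not in autosomes:
            continue
        bl = []
        if blacklist is not None:
            sub = blacklist[blacklist["chrom"] == chrom]
            bl = list(zip(sub["start"], sub["end"]))
        hit_count = None
        step = None
        for sample, stats_by_chrom in per_sample.items():
            st = stats_by_chrom.get(chrom)
            if st is None:
                continue
            step = st.step
            hits = (np.nan_to_num(st.q_value, nan=1.0) < fdr).astype(int)
            hit_count = hits if hit_count is None else hit_count + hits
        if hit_count is None:
            continue
        kept = np.flatnonzero(hit_count >= min_samples)
        if kept.size == 0:
            continue
        starts = kept * step
        ends = starts + step
        for s, e in merge_intervals(starts, ends):
            if e - s < min_size:
                continue
            if interval_overlaps(s, e, bl):
                continue
            n_support = 0
            mean_strength = {}
            for sample, stats_by_chrom in per_sample.items():
                st = stats_by_chrom.get(chrom)
                if st is None:
                    continue
                b0, b1 = s // st.step, e // st.step
                qs = np.nan_to_num(st.q_value[b0:b1], nan=1.0)
                if (qs < fdr).any():
                    n_support += 1
                mean_strength[sample] = float(np.nanmean(st.strength[b0:b1]))
            anchors.append(StripeAnchor(chrom, int(s), int(e), n_support,
                                        mean_strength))
    return anchors


def anchors_to_frame(anchors: list[StripeAnchor]) -> pd.DataFrame:
    return pd.DataFrame([{"chrom": a.chrom, "start": a.start, "end": a.end,
                          "name": f"anchor_{i}", "score": a.n_supporting_samples}
                         for i, a in enumerate(anchors)])


def interaction_fe_track(pairs: pd.DataFrame, chrom: str, chrom_size: int,
                         long_min: int = 2000, short_max: int = 1500,
                         step: int = 100, pseudo: float = 1.0) -> BinnedTrack:
    """Raw interaction fold enrichment: per-100-bp ratio of long-range to
    short-range self-ligation coverage, (long + pseudo) / (short + pseudo).

    This is the raw stripe strength before local-background normalization;
    note the distance thresholds here (>2.0 kb long, <1.5 kb short) differ
    from the stripe caller's and both are exposed as parameters.
    """
    if long_min <= short_max:
        raise ValueError("long_min must exceed short_max")
    long_df, short_df = split_by_range(pairs, long_min, short_max)
    lt = coverage_track(endpoint_positions(long_df, chrom), chrom, chrom_size,
                        window=step, step=step)
    st = coverage_track(endpoint_positions(short_df, chrom), chrom, chrom_size,
                        window=step, step=step)
    fe = (lt.values + pseudo) / (st.values + pseudo)
    return BinnedTrack(chrom=chrom, step=step, window=step, values=fe,
                       chrom_size=chrom_size)
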