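"""Methylation state classification, ATAC consensus peaks and CRE annotation.

CpG tables are DataFrames with columns (chrom, pos, meth_pct, coverage), one
row per CpG per sample (a ``sample`` column when multi-sample).  Regional
methylation is the unweighted mean percentage over valid (covered) CpGs.
States: demethylated < 25%, methylated > 40%, intermediate otherwise
(boundaries strict).  Stage changes require both a > 15 percentage-point
difference and BH FDR < 0.1 from a two-proportion z-test on aggregated
methylated/unmethylated read counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportions_ztest

from .contacts import interval_overlaps, merge_intervals
from .stripes import bh_qvalues

DEMETHYLATED_MAX = 25.0   # % ; strict <
METHYLATED_MIN = 40.0     # % ; strict >


def region_methylation(cpg_table: pd.DataFrame, chrom: str, start: int,
                       end: int) -> float:
    """Unweighted mean methylation % over valid CpGs in [start, end).

    CpGs with zero coverage are invalid and excluded; a region with no valid
    CpG is undefined (NaN) and should be excluded downstream.
    """
    sel = ((cpg_table["chrom"] == chrom)
           & (cpg_table["pos"] >= start) & (cpg_table["pos"] < end)
           & (cpg_table["coverage"] > 0))
    if not sel.any():
        return float("nan")
    return float(cpg_table.loc[sel, "meth_pct"].mean())


def classify_state(mean_pct: float) -> str:
    """Map a mean methylation % to demethylated / intermediate / methylated."""
    if np.isnan(mean_pct):
        raise ValueError("mean methylation is undefined")
    if mean_pct < DEMETHYLATED_MAX:
        return "demethylated"
    if mean_pct > METHYLATED_MIN:
        return "methylated"
    return "intermediate"


def differential_methylation(counts_a: pd.DataFrame, counts_b: pd.DataFrame,
                             min_diff: float = 15.0,
                             fdr: float = 0.1) -> pd.DataFrame:
    """Per-region hyper/hypo/NC calls between two sample groups.

    Inputs are per-region aggregated CpG read counts with columns
    (region, meth_reads, total_reads), aligned on ``region``.  A region is
    hyper-/hypomethylated in B relative to A when the percentage-point
    difference exceeds *min_diff* AND the BH-corrected two-proportion z-test
    q-value is below *fdr*; direction follows the sign of the difference.
    Degenerate counts (zero totals) give NC.
    """
    a = counts_a.set_index("region")
    b = counts_b.set_index("region")
    regions = a.index.intersection(b.index)
    pvals = np.ones(len(regions))
    delta = np.zeros(len(regions))
    ok = np.zeros(len(regions), dtype=bool)
    for k, r in enumerate(regions):
        ma, ta = int(a.loc[r, "meth_reads"]), int(a.loc[r, "total_reads"])
        mb, tb = int(b.loc[r, "meth_reads"]), int(b.loc[r, "total_reads"])
        if ta == 0 or tb == 0:
            continue
        delta[k] = 100.0 * (mb / tb - ma / ta)
        if (ma == 0 and mb == 0) or (ma == ta and mb == tb):
            pvals[k] = 1.0
        else:
            _, pvals[k] = proportions_ztest([ma, mb], [ta, tb])
        ok[k] = True
    qvals = np.ones(len(regions))
    if ok.any():
        qvals[ok] = bh_qvalues(pvals[ok])
    change = np.where(ok & (np.abs(delta) > min_diff) & (qvals < fdr),
                      np.where(delta > 0, "hyper", "hypo"), "NC")
    return pd.DataFrame({"region": regions, "delta_pct": delta,
                         "p_value": pvals, "q_value": qvals, "change": change})


def atac_consensus(per_sample_peaks: list[pd.DataFrame], chrom_sizes: dict[str, int],
                   min_hits: int = 3, min_size: int = 300,
                   bin_size: int = 100) -> pd.DataFrame:
    """Multi-sample consensus peaks.

    A 100-bp bin is hit by a sample when any of its peaks overlaps it; bins
    with >= *min_hits* hits are merged and merged intervals < *min_size*
    dropped.  Peaks are BED-like frames (chrom, start, end).
    """
    if len(per_sample_peaks) < min_hits:
        raise ValueError("need at least min_hits samples")
    out = []
    for chrom, size in chrom_sizes.items():
        n_bins = int(np.ceil(size / bin_size))
        counts = np.zeros(n_bins, dtype=int)
        for peaks in per_sample_peaks:
            sub = peaks[peaks["chrom"] == chrom]
            hit = np.zeros(n_bins, dtype=bool)
            for s, e in zip(sub["start"], sub["end"]):
                hit[max(0, int(s) // bin_size): -(-int(e) // bin_size)] = True
            counts += hit
        kept = np.flatnonzero(counts >= min_hits)
        if kept.size == 0:
            continue
        for s, e in merge_intervals(kept * bin_size, kept * bin_size + bin_size):
            if e - s >= min_size:
                out.append({"chrom": chrom, "start": int(s), "end": int(e)})
    return pd.DataFrame(out, columns=["chrom", "start", "end"])


#: CRE annotation priority, highest first
ANNOTATION_PRIORITY = ["promoter", "enhancer", "ctcf", "open_chromatin"]


def annotate_feature(chrom: str, start: int, end: int,
                     references: dict[str, pd.DataFrame]) -> str:
    """First matching CRE class in priority order
    (promoter > enhancer > CTCF > open chromatin); 'unannotated' otherwise.

    *references* maps class name to a BED-like frame of reference intervals.
    """
    for cls in ANNOTATION_PRIORITY:
        ref = references.get(cls)
        if ref is None:
            continue
        sub = ref[ref["chrom"] == chrom]
        if interval_overlaps(start, end, zip(sub["start"], sub["end"])):
            return cls
    return "unannotated"
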