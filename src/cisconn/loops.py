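"""Loop strength quantification, list merging, stage calls and APA.

Loops are anchor pairs (chrom, start1, end1, start2, end2) held in pandas
DataFrames with anchor1 upstream of anchor2.  Strength is the log10 ratio of
observed counts at the loop pixel block to the mean of a surrounding donut
ring, with a pseudo-count of 1 applied unconditionally to numerator and
denominator.  Aggregate peak analysis (APA) piles up submatrices around many
anchor pairs; the loop-mode score compares the 10x10 center block with the
100x100 bottom-left corner, while the stripe mode first normalizes every
diagonal by the genome-average intensity at that distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactMatrix

LOOP_COLUMNS = ["chrom", "start1", "end1", "start2", "end2"]


def loop_strength(observed, donut_expected, pseudo: float = 1.0) -> np.ndarray:
    """log10((observed + pseudo) / (donut_expected + pseudo)).

    NaN donut expectations (donut out of matrix bounds) propagate so the
    loop stays flagged.
    """
    observed = np.asarray(observed, dtype=float)
    donut_expected = np.asarray(donut_expected, dtype=float)
    return np.log10((observed + pseudo) / (donut_expected + pseudo))


def donut_expected(matrix: ContactMatrix, i0: int, j0: int,
                   inner: int = 2, outer: int = 10) -> float:
    """Mean count in the square donut ring around pixel (i0, j0).

    Ring pixels satisfy ``inner < max(|di|, |dj|) <= outer`` (Chebyshev
    annulus).  Returns NaN when the ring extends past the matrix bounds.
    """
    n = matrix.n_bins
    if i0 - outer < 0 or j0 - outer < 0 or i0 + outer >= n or j0 + outer >= n:
        return float("nan")
    win = matrix.dense_window(i0, j0, outer)
    d = np.arange(-outer, outer + 1)
    cheb = np.maximum(np.abs(d)[:, None], np.abs(d)[None, :])
    ring = (cheb > inner) & (cheb <= outer)
    return float(win[ring].mean())


def quantify_loops(loops: pd.DataFrame, matrix: ContactMatrix,
                   inner: int = 2, outer: int = 10,
                   pseudo: float = 1.0) -> pd.DataFrame:
    """Observed counts, donut expectation and strength for each loop.

    Observed is the summed count over the anchor1 x anchor2 bin rectangle;
    the donut is centered on the rectangle center.  Returns the input frame
    with ``observed``, ``expected`` and ``strength`` columns appended.
    """
    res = matrix.resolution
    m = matrix.symmetric()
    obs = np.zeros(len(loops))
    exp = np.zeros(len(loops))
    rows = loops.reset_index(drop=True)
    for k, row in rows.iterrows():
        i_lo, i_hi = int(row.start1) // res, max(int(row.start1) // res + 1,
                                                 -(-int(row.end1) // res))
        j_lo, j_hi = int(row.start2) // res, max(int(row.start2) // res + 1,
                                                 -(-int(row.end2) // res))
        obs[k] = m[i_lo:i_hi, j_lo:j_hi].sum()
        # per-pixel observed for comparison against the per-pixel donut mean
        obs[k] /= (i_hi - i_lo) * (j_hi - j_lo)
        exp[k] = donut_expected(matrix, (i_lo + i_hi - 1) // 2,
                                (j_lo + j_hi - 1) // 2, inner, outer)
    out = rows.copy()
    out["observed"] = obs
    out["expected"] = exp
    out["strength"] = loop_strength(obs, exp, pseudo)
    return out


def _anchors_overlap(s1, e1, s2, e2) -> bool:
    return s1 < e2 and s2 < e1


def merge_loop_lists(lists: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge loop lists ordered by decreasing priority.

    Iterating in priority order, a candidate is dropped iff BOTH of its
    anchors overlap (any bp) both anchors of an already-accepted loop on the
    same chromosome; sharing a single anchor is not a conflict.  The output
    carries a ``priority`` column with the source list rank (0 = highest).
    """
    accepted: list[dict] = []
    for rank, frame in enumerate(lists):
        for _, row in frame.iterrows():
            conflict = False
            for acc in accepted:
                if acc["chrom"] != row["chrom"]:
                    continue
                if (_anchors_overlap(row["start1"], row["end1"],
                                     acc["start1"], acc["end1"])
                        and _anchors_overlap(row["start2"], row["end2"],
                                             acc["start2"], acc["end2"])):
                    conflict = True
                    break
            if not conflict:
                rec = {c: row[c] for c in LOOP_COLUMNS}
                rec["priority"] = rank
                accepted.append(rec)
    return pd.DataFrame(accepted, columns=LOOP_COLUMNS + ["priority"])


def stage_positive(quantified: dict[str, pd.DataFrame],
                   samples_of_stage: list[str],
                   fold: float = 1.2, pseudo: float = 1.0) -> np.ndarray:
    """Boolean mask of loops positive in a stage.

    A loop is positive when its stage-averaged enrichment ratio
    ``(observed + pseudo) / (expected + pseudo)`` exceeds *fold* (strict >).
    *quantified* maps sample id to the frame from :func:`quantify_loops`.
    """
    if not samples_of_stage:
        raise ValueError("stage has no samples")
    ratios = []
    for s in samples_of_stage:
        q = quantified[s]
        ratios.append((q["observed"].to_numpy() + pseudo)
                      / (q["expected"].to_numpy() + pseudo))
    return np.nanmean(np.vstack(ratios), axis=0) > fold


@dataclass
class ApaResult:
    """Aggregated submatrix pile-up and its enrichment score."""

    matrix: np.ndarray = field(repr=False)
    score: float = 0.0
    n_pairs: int = 0
    mode: str = "loop"

    def log_matrix(self, pseudo: float = 1.0) -> np.ndarray:
        """log-transformed pile-up for visualization only."""
        return np.log10(self.matrix + pseudo)


def apa(matrices: list[ContactMatrix], anchor_pairs: pd.DataFrame,
        half_width: int = 25, mode: str = "loop",
        center: int = 10, background: int = 100) -> ApaResult:
    """Aggregate peak analysis over anchor pairs.

    loop mode: submatrices around each anchor-pair midpoint are summed; the
    score is mean(center x center block) / mean(background x background
    bottom-left corner).  stripe mode: each pixel is first divided by the
    genome-average intensity at its diagonal distance, submatrices averaged,
    and the score is the mean of the center block.  *center* is clamped to
    the window size and *background* additionally to ``(size - center)//2``
    so the corner block never reaches the center block on small windows.
    Anchor pairs whose window leaves the matrix are skipped; no valid pair
    is an error.
    """
    if mode not in ("loop", "stripe"):
        raise ValueError("mode must be 'loop' or 'stripe'")
    h = half_width
    size = 2 * h + 1
    c = min(center, size)
    bgn = min(background, max(1, (size - c) // 2))
    agg = np.zeros((size, size))
    n_valid = 0
    for matrix in matrices:
        res = matrix.resolution
        sub = anchor_pairs[anchor_pairs["chrom"] == matrix.chrom]
        if len(sub) == 0:
            continue
        sym = matrix.symmetric()
        if mode == "stripe":
            expd = matrix.expected_by_distance()
            expd = np.where(expd > 0, expd, np.nan)
        for _, row in sub.iterrows():
            i0 = (int(row.start1) + int(row.end1)) // 2 // res
            j0 = (int(row.start2) + int(row.end2)) // 2 // res
            if i0 - h < 0 or j0 - h < 0 or i0 + h >= matrix.n_bins or j0 + h >= matrix.n_bins:
                continue
            win = np.asarray(sym[i0 - h:i0 + h + 1, j0 - h:j0 + h + 1].todense(),
                             dtype=float)
            if mode == "stripe":
                ii = np.arange(i0 - h, i0 + h + 1)[:, None]
                jj = np.arange(j0 - h, j0 + h + 1)[None, :]
                d = np.abs(jj - ii)
                win = win / expd[d]
            agg += np.nan_to_num(win)
            n_valid += 1
    if n_valid == 0:
        raise ValueError("no valid anchor pairs for APA")
    if mode == "stripe":
        agg /= n_valid
    lo = (size - c) // 2
    center_block = agg[lo:lo + c, lo:lo + c]
    if mode == "loop":
        bg_block = agg[size - bgn:, :bgn]
        bg_mean = float(bg_block.mean())
        score = float(center_block.mean() / bg_mean) if bg_mean > 0 else float("nan")
    else:
        score = float(center_block.mean())
    return ApaResult(matrix=agg, score=score, n_pairs=n_valid, mode=mode)
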