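"""Contact-record parsing, filtering, binning and coverage primitives.

Pair-level chromatin contacts are held in pandas DataFrames with the columns
``chrom1, pos1, strand1, chrom2, pos2, strand2`` (0-based bp, canonical order
``pos1 <= pos2`` for intra-chromosomal records).  Text interchange uses the
4DN ``.pairs`` dialect, BED/bedGraph for intervals and tracks, and a sparse
COO TSV for binned matrices.  All intervals are 0-based half-open.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: canonical column order of the in-memory pair table
PAIR_COLUMNS = ["chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]


# ---------------------------------------------------------------------------
# .pairs I/O
# ---------------------------------------------------------------------------

def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_pairs(path, chrom_sizes: dict[str, int] | None = None,
               intra_only: bool = False) -> pd.DataFrame:
    """Read a 4DN-style ``.pairs`` file into a pair table.

    The ``#columns:`` header is required and must name at least
    chrom1/pos1/chrom2/pos2/strand1/strand2 (readID and pair_type are
    ignored if present).  Malformed lines are counted and logged; records on
    chromosomes absent from *chrom_sizes* (when given) are skipped with a
    warning.  Intra-chromosomal records are returned in canonical order
    (``pos1 <= pos2``).

    Returns a DataFrame with :data:`PAIR_COLUMNS`; the counters are attached
    under ``df.attrs['n_malformed']`` and ``df.attrs['n_skipped']``.
    """
    needed = ["chrom1", "pos1", "chrom2", "pos2", "strand1", "strand2"]
    columns: list[str] | None = None
    rows: list[tuple] = []
    n_malformed = 0
    n_skipped = 0
    with _open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#columns:"):
                    columns = line.split(":", 1)[1].split()
                continue
            if columns is None:
                raise ValueError(f"{path}: missing #columns header")
            parts = line.split("\t")
            if len(parts) < len(columns):
                n_malformed += 1
                continue
            rec = dict(zip(columns, parts))
            try:
                row = (rec["chrom1"], int(rec["pos1"]), rec["strand1"],
                       rec["chrom2"], int(rec["pos2"]), rec["strand2"])
            except (KeyError, ValueError):
                n_malformed += 1
                continue
            if chrom_sizes is not None and (
                    row[0] not in chrom_sizes or row[3] not in chrom_sizes):
                n_skipped += 1
                continue
            if row[1] < 0 or row[4] < 0:
                n_malformed += 1
                continue
            rows.append(row)
    if columns is None:
        raise ValueError(f"{path}: missing #columns header")
    missing = [c for c in needed if c not in columns]
    if missing:
        raise ValueError(f"{path}: #columns header lacks {missing}")
    df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    if len(df) == 0:
        df = empty_pairs()
    df = canonicalize(df)
    if intra_only:
        inter = df["chrom1"] != df["chrom2"]
        n_skipped += int(inter.sum())
        df = df.loc[~inter].reset_index(drop=True)
    if n_malformed:
        logger.warning("%s: %d malformed lines dropped", path, n_malformed)
    if n_skipped:
        logger.warning("%s: %d records skipped", path, n_skipped)
    df.attrs["n_malformed"] = n_malformed
    df.attrs["n_skipped"] = n_skipped
    return df


def write_pairs(df: pd.DataFrame, path, chrom_sizes: dict[str, int] | None = None) -> None:
    """Write a pair table as 4DN ``.pairs`` text (round-trips with read_pairs)."""
    with _open(path, "wt") as fh:
        fh.write("## pairs format v1.0\n")
        if chrom_sizes:
            for chrom, size in chrom_sizes.items():
                fh.write(f"#chromsize: {chrom} {size}\n")
        fh.write("#columns: readID chrom1 pos1 chrom2 pos2 strand1 strand2\n")
        arr = df[PAIR_COLUMNS].to_numpy()
        for i, (c1, p1, s1, c2, p2, s2) in enumerate(arr):
            fh.write(f"r{i}\t{c1}\t{p1}\t{c2}\t{p2}\t{s1}\t{s2}\n")


def empty_pairs() -> pd.DataFrame:
    return pd.DataFrame({"chrom1": pd.Series(dtype=str),
                         "pos1": pd.Series(dtype=np.int64),
                         "strand1": pd.Series(dtype=str),
                         "chrom2": pd.Series(dtype=str),
                         "pos2": pd.Series(dtype=np.int64),
                         "strand2": pd.Series(dtype=str)})


def canonicalize(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce ``pos1 <= pos2`` on intra-chromosomal records (strands follow)."""
    df = df.copy()
    flip = (df["chrom1"] == df["chrom2"]) & (df["pos1"] > df["pos2"])
    if flip.any():
        for a, b in (("pos1", "pos2"), ("strand1", "strand2")):
            tmp = df.loc[flip, a].copy()
            df.loc[flip, a] = df.loc[flip, b]
            df.loc[flip, b] = tmp
    return df


# ---------------------------------------------------------------------------
# range / orientation splitting
# ---------------------------------------------------------------------------

def distances(df: pd.DataFrame) -> np.ndarray:
    """|pos2 - pos1| on pair positions; inter-chromosomal records get -1."""
    d = np.abs(df["pos2"].to_numpy() - df["pos1"].to_numpy())
    d = np.where(df["chrom1"].to_numpy() == df["chrom2"].to_numpy(), d, -1)
    return d


def is_inward(df: pd.DataFrame) -> np.ndarray:
    """Inward (+/-) orientation on canonically ordered records."""
    return (df["strand1"].to_numpy() == "+") & (df["strand2"].to_numpy() == "-")


def split_by_range(df: pd.DataFrame, long_min: int = 1500, short_max: int = 1000,
                   orientation_filter: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split intra-chromosomal pairs into long-range and short-range classes.

    long: distance > *long_min*.  short: distance < *short_max* and, when
    *orientation_filter* is set, inward (+/-) orientation — the self-ligation
    class used as a mappability proxy.  Records in the dead zone
    ``[short_max, long_min]`` belong to neither class and are discarded.
    """
    if long_min <= short_max:
        raise ValueError("long_min must exceed short_max")
    d = distances(df)
    intra = d >= 0
    long_mask = intra & (d > long_min)
    short_mask = intra & (d < short_max)
    if orientation_filter:
        short_mask &= is_inward(df)
    return (df.loc[long_mask].reset_index(drop=True),
            df.loc[short_mask].reset_index(drop=True))


# ---------------------------------------------------------------------------
# binned tracks
# ---------------------------------------------------------------------------

@dataclass
class BinnedTrack:
    """Sliding-window count track on one chromosome.

    ``values[i]`` covers the window ``[i*step, i*step + window)``.  With
    ``window == step`` this degenerates to a plain histogram.
    """

    chrom: str
    step: int
    window: int
    values: np.ndarray
    chrom_size: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values)

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def starts(self) -> np.ndarray:
        return np.arange(self.n_bins, dtype=np.int64) * self.step

    def to_bedgraph(self, path, mode: str = "wt") -> None:
        starts = self.starts()
        with _open(path, mode) as fh:
            for s, v in zip(starts, self.values):
                fh.write(f"{self.chrom}\t{s}\t{s + self.step}\t{v:g}\n")


def endpoint_positions(df: pd.DataFrame, chrom: str) -> np.ndarray:
    """All endpoints of intra-chromosomal records on *chrom* (both mates)."""
    intra = (df["chrom1"] == chrom) & (df["chrom2"] == chrom)
    sub = df.loc[intra]
    return np.concatenate([sub["pos1"].to_numpy(), sub["pos2"].to_numpy()])


def coverage_track(positions: np.ndarray, chrom: str, chrom_size: int,
                   window: int, step: int = 100) -> BinnedTrack:
    """Sliding-window endpoint counts: bin i counts positions in
    ``[i*step, i*step + window)``.

    *positions* are bp coordinates on *chrom* (both mates of a pair should be
    passed to count each at its own locus; see :func:`endpoint_positions`).
    """
    if window < step:
        raise ValueError("window must be >= step")
    if window % step != 0:
        raise ValueError("step must divide window")
    n_hist = int(np.ceil(chrom_size / step))
    positions = np.asarray(positions, dtype=np.int64)
    positions = positions[(positions >= 0) & (positions < chrom_size)]
    hist = np.bincount(positions // step, minlength=n_hist)[:n_hist]
    w = window // step
    # forward rolling sum: value[i] = hist[i] + ... + hist[i+w-1]
    cum = np.concatenate([[0], np.cumsum(hist)])
    upper = np.minimum(np.arange(n_hist) + w, n_hist)
    values = cum[upper] - cum[: n_hist]
    return BinnedTrack(chrom=chrom, step=step, window=window,
                       values=values, chrom_size=chrom_size)


# ---------------------------------------------------------------------------
# binned contact matrices
# ---------------------------------------------------------------------------

@dataclass
class ContactMatrix:
    """Upper-triangular sparse binned contact matrix for one chromosome."""

    chrom: str
    resolution: int
    n_bins: int
    counts: sp.coo_matrix = field(repr=False)

    @property
    def matrix(self) -> sp.csr_matrix:
        return self.counts.tocsr()

    def symmetric(self) -> sp.csr_matrix:
        m = self.counts.tocsr()
        upper = sp.triu(m, k=1)
        return m + upper.T

    def dense_window(self, i0: int, j0: int, half_width: int) -> np.ndarray:
        """Dense (2h+1)x(2h+1) symmetric submatrix centered on bin (i0, j0)."""
        h = half_width
        m = self.symmetric()
        i_lo, i_hi = i0 - h, i0 + h + 1
        j_lo, j_hi = j0 - h, j0 + h + 1
        if i_lo < 0 or j_lo < 0 or i_hi > self.n_bins or j_hi > self.n_bins:
            raise IndexError("window outside matrix bounds")
        return np.asarray(m[i_lo:i_hi, j_lo:j_hi].todense(), dtype=float)

    def expected_by_distance(self) -> np.ndarray:
        """Mean count per diagonal (distance-decay profile), length n_bins."""
        coo = self.counts.tocoo()
        d = np.abs(coo.col - coo.row)
        sums = np.bincount(d, weights=coo.data, minlength=self.n_bins)
        n_per = self.n_bins - np.arange(self.n_bins)
        return sums / n_per

    def scaled(self, factor: float) -> "ContactMatrix":
        c = self.counts.tocoo()
        return ContactMatrix(self.chrom, self.resolution, self.n_bins,
                             sp.coo_matrix((c.data * factor, (c.row, c.col)),
                                           shape=c.shape))

    def balance_ipf(self, n_iter: int = 50, tol: float = 1e-5) -> np.ndarray:
        """Iterative proportional fitting weights (optional parity tool;
        the normative normalization path is self-ligation based and does not
        use balancing)."""
        m = self.symmetric().astype(float)
        w = np.ones(self.n_bins)
        for _ in range(n_iter):
            s = m.multiply(w).T.multiply(w).sum(axis=1).A1
            nz = s > 0
            corr = np.ones_like(w)
            corr[nz] = np.sqrt(s[nz] / s[nz].mean())
            w[nz] /= corr[nz]
            if np.abs(corr[nz] - 1).max() < tol:
                break
        return w

    def to_tsv(self, path) -> None:
        coo = self.counts.tocoo()
        with _open(path, "wt") as fh:
            fh.write(f"#chrom={self.chrom}\tresolution={self.resolution}\t"
                     f"n_bins={self.n_bins}\n")
            for i, j, v in zip(coo.row, coo.col, coo.data):
                fh.write(f"{self.chrom}\t{i}\t{j}\t{v:g}\n")

    @classmethod
    def from_tsv(cls, path) -> "ContactMatrix":
        with _open(path) as fh:
            header = fh.readline().strip().lstrip("#")
            meta = dict(kv.split("=") for kv in header.split("\t"))
            rows, cols, vals = [], [], []
            for line in fh:
                _, i, j, v = line.split("\t")
                rows.append(int(i)); cols.append(int(j)); vals.append(float(v))
        n = int(meta["n_bins"])
        return cls(meta["chrom"], int(meta["resolution"]), n,
                   sp.coo_matrix((vals, (rows, cols)), shape=(n, n)))


def bin_matrix(df: pd.DataFrame, chrom: str, chrom_size: int,
               resolution: int) -> ContactMatrix:
    """Aggregate intra-chromosomal pairs on *chrom* into an upper-triangular
    sparse matrix at *resolution* bp."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    intra = (df["chrom1"] == chrom) & (df["chrom2"] == chrom)
    sub = df.loc[intra]
    n = int(np.ceil(chrom_size / resolution))
    b1 = sub["pos1"].to_numpy() // resolution
    b2 = sub["pos2"].to_numpy() // resolution
    lo = np.minimum(b1, b2)
    hi = np.maximum(b1, b2)
    ok = (lo >= 0) & (hi < n)
    counts = sp.coo_matrix((np.ones(ok.sum()), (lo[ok], hi[ok])), shape=(n, n))
    counts.sum_duplicates()
    return ContactMatrix(chrom=chrom, resolution=resolution, n_bins=n, counts=counts)


def subsample(df: pd.DataFrame, fraction: float, seed: int) -> pd.DataFrame:
    """Keep each record independently with probability *fraction* (seeded)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if fraction == 1:
        return df.copy()
    rng = np.random.default_rng(seed)
    keep = rng.random(len(df)) < fraction
    return df.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# BED / bedGraph helpers
# ---------------------------------------------------------------------------

def read_bed(path) -> pd.DataFrame:
    """Read BED3+ into (chrom, start, end[, name, score, strand])."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    cols = [c for c in ["chrom", "start", "end", "name", "score", "strand"]
            if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    return df


def merge_intervals(starts: Sequence[int], ends: Sequence[int]) -> list[tuple[int, int]]:
    """Merge overlapping or touching half-open intervals."""
    order = np.argsort(starts)
    merged: list[list[int]] = []
    for k in order:
        s, e = int(starts[k]), int(ends[k])
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def interval_overlaps(start: int, end: int, others: Iterable[tuple[int, int]]) -> bool:
    """True if [start, end) overlaps any half-open interval in *others*."""
    return any(s < end and start < e for s, e in others)
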