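"""Per-gene promoter-enhancer connectivity with self-ligation normalization.

For each gene, accessible peaks within 200 kb of the TSS (excluding the
promoter zone itself) are paired as distal partners.  Raw promoter-peak
contacts are extracted at 1-kb resolution, divided by the promoter's
mappability M (short-range self-ligation read density at the promoter zone
relative to its 50-kb neighborhood) and by the local long-range background
density D (contacts per 1 kb^2 among loci in the 5-50 kb ring around the
TSS, which normalizes sequencing coverage between samples without inheriting
the promoter's own mappability bias).  The sum over paired peaks is the
gene's total P-E connectivity C_g.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .contacts import split_by_range

PROMOTER_UP = 1500    # bp upstream of TSS (transcription direction)
PROMOTER_DOWN = 500   # bp downstream


@dataclass(frozen=True)
class GeneModel:
    """Gene with a strand-oriented 2-kb promoter zone."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    @property
    def promoter_zone(self) -> tuple[int, int]:
        """[TSS-1.5 kb, TSS+0.5 kb) oriented by transcription direction."""
        if self.strand == "-":
            return (self.tss - PROMOTER_DOWN, self.tss + PROMOTER_UP)
        return (self.tss - PROMOTER_UP, self.tss + PROMOTER_DOWN)


def genes_from_frame(frame: pd.DataFrame) -> list[GeneModel]:
    return [GeneModel(r.gene_id, r.chrom, int(r.tss), r.strand)
            for r in frame.itertuples()]


def pair_promoter_enhancers(gene: GeneModel, peaks: pd.DataFrame,
                            max_dist: int = 200_000,
                            exclude_promoters: bool = False) -> pd.DataFrame:
    """Peaks paired to *gene* as distal partners.

    A peak qualifies when its whole interval lies within *max_dist* of the
    TSS on the same chromosome and it does not overlap the promoter zone.
    Other genes' promoter peaks count as partners (P-P contacts) unless
    *exclude_promoters* is set and the peak table carries a ``kind`` column.
    """
    zs, ze = gene.promoter_zone
    sub = peaks[peaks["chrom"] == gene.chrom]
    within = ((sub["start"] >= gene.tss - max_dist)
              & (sub["end"] <= gene.tss + max_dist))
    distal = (sub["end"] <= zs) | (sub["start"] >= ze)
    sel = within & distal
    if exclude_promoters and "kind" in sub.columns:
        sel &= sub["kind"] != "promoter"
    return sub.loc[sel].reset_index(drop=True)


class SampleContacts:
    """Pre-indexed per-chromosome contact arrays of one sample.

    Long-range pairs are indexed by each endpoint for promoter-anchored
    queries; short-range self-ligation endpoints support mappability
    queries.
    """

    def __init__(self, pairs: pd.DataFrame, long_min: int = 1500,
                 short_max: int = 1000):
        self.long_min = long_min
        long_df, short_df = split_by_range(pairs, long_min, short_max)
        self.n_long = len(long_df)
        self.n_short = len(short_df)
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom in pd.unique(pairs["chrom1"]):
            lsub = long_df[long_df["chrom1"] == chrom]
            ssub = short_df[short_df["chrom1"] == chrom]
            p1 = lsub["pos1"].to_numpy()
            p2 = lsub["pos2"].to_numpy()
            o1 = np.argsort(p1, kind="stable")
            o2 = np.argsort(p2, kind="stable")
            spos = np.sort(np.concatenate([ssub["pos1"].to_numpy(),
                                           ssub["pos2"].to_numpy()]))
            self._by_chrom[chrom] = {
                "p1": p1[o1], "p1_partner": p2[o1],
                "p2": p2[o2], "p2_partner": p1[o2],
                "short": spos,
            }

    def _c(self, chrom):
        return self._by_chrom.get(chrom)

    def short_count(self, chrom: str, start: int, end: int) -> int:
        c = self._c(chrom)
        if c is None:
            return 0
        s = c["short"]
        return int(np.searchsorted(s, end) - np.searchsorted(s, start))

    def partners_of(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Partner positions of long-range contacts with one end in
        [start, end)."""
        c = self._c(chrom)
        if c is None:
            return np.array([], dtype=np.int64)
        out = []
        for key, pkey in (("p1", "p1_partner"), ("p2", "p2_partner")):
            lo = np.searchsorted(c[key], start)
            hi = np.searchsorted(c[key], end)
            out.append(c[pkey][lo:hi])
        return np.concatenate(out)

    def long_in_window(self, chrom: str, start: int, end: int):
        """(pos1, pos2) of long-range contacts with pos1 in [start, end)."""
        c = self._c(chrom)
        if c is None:
            return (np.array([], dtype=np.int64),) * 2
        lo = np.searchsorted(c["p1"], start)
        hi = np.searchsorted(c["p1"], end)
        return c["p1"][lo:hi], c["p1_partner"][lo:hi]


def promoter_mappability(contacts: SampleContacts, gene: GeneModel,
                         neighborhood: int = 50_000,
                         exclude_margin: int = 2000,
                         pseudo_rate: float = 1e-9) -> float:
    """Mappability M: short-range self-ligation read density (per kb) in the
    promoter zone relative to the 50-kb neighborhood centered on the TSS.

    The neighborhood excludes the promoter zone plus an *exclude_margin*
    gap on both sides (local-background convention: self-ligation mates of
    reads inside the zone fall within one pair length of it, so the gap
    keeps the background estimate free of the zone's own signal).
    Per-million factors cancel in the ratio.  Returns NaN (gene flagged)
    when the neighborhood has no coverage.
    """
    zs, ze = gene.promoter_zone
    half = neighborhood // 2
    ns, ne = gene.tss - half, gene.tss + half
    xs, xe = zs - exclude_margin, ze + exclude_margin
    cnt_p = contacts.short_count(gene.chrom, zs, ze)
    cnt_n = (contacts.short_count(gene.chrom, ns, ne)
             - contacts.short_count(gene.chrom, max(ns, xs), min(ne, xe)))
    len_p = (ze - zs) / 1000.0
    len_n = (ne - ns) / 1000.0 - (min(ne, xe) - max(ns, xs)) / 1000.0
    if cnt_n <= 0 or len_n <= 0:
        return float("nan")
    rate_p = cnt_p / len_p
    rate_n = cnt_n / len_n
    return (rate_p + pseudo_rate) / (rate_n + pseudo_rate)


@lru_cache(maxsize=None)
def _ring_area_kb2(inner: int, outer: int, long_min: int, resolution: int) -> int:
    """Number of 1-kb^2 pixel pairs with both loci in the ring and
    separation above the long-range threshold."""
    offs = [k for k in range(-outer // resolution, outer // resolution + 1)
            if inner <= abs(k * resolution) < outer]
    offs = np.array(offs)
    n = 0
    for a in offs:
        n += int(np.sum((offs > a) & ((offs - a) * resolution > long_min)))
    return n


def background_density(contacts: SampleContacts, gene: GeneModel,
                       ring: tuple[int, int] = (5000, 50_000),
                       long_min: int = 1500, resolution: int = 1000,
                       pseudo: float = 1e-6) -> float:
    """Local long-range background density D, in contacts per 1 kb^2.

    Counts long-range contacts (> *long_min*) whose endpoints BOTH lie at a
    ring distance (inner-outer, either side) from the TSS, divided by the
    ring's pixel-pair area.  Anchored entirely off the promoter, D is free
    of the promoter's own mappability bias and serves as the coverage
    normalizer between samples.  An empty ring is floored at *pseudo* and
    flagged by the caller.
    """
    inner, outer = ring
    tss = gene.tss
    p1, p2 = contacts.long_in_window(gene.chrom, tss - outer, tss + outer)
    d1 = np.abs(p1 - tss)
    d2 = np.abs(p2 - tss)
    ok = ((d1 >= inner) & (d1 < outer) & (d2 >= inner) & (d2 < outer)
          & ((p2 - p1) > long_min))
    count = int(ok.sum())
    area = _ring_area_kb2(inner, outer, long_min, resolution)
    d = count / area
    return max(d, pseudo)


def raw_promoter_peak_contacts(contacts: SampleContacts, gene: GeneModel,
                               peaks: pd.DataFrame, resolution: int = 1000,
                               peak_flank: int = 500) -> tuple[float, np.ndarray]:
    """Summed raw contacts between the promoter zone and each paired peak,
    both extended to intersecting 1-kb bins (peak windows get a 500-bp
    flank).  Returns (total, per-peak counts)."""
    zs, ze = gene.promoter_zone
    pz_lo = (zs // resolution) * resolution
    pz_hi = -(-ze // resolution) * resolution
    partners = np.sort(contacts.partners_of(gene.chrom, pz_lo, pz_hi))
    per_peak = np.zeros(len(peaks))
    for k, (s, e) in enumerate(zip(peaks["start"], peaks["end"])):
        w_lo = ((int(s) - peak_flank) // resolution) * resolution
        w_hi = -(-(int(e) + peak_flank) // resolution) * resolution
        per_peak[k] = (np.searchsorted(partners, w_hi)
                       - np.searchsorted(partners, w_lo))
    return float(per_peak.sum()), per_peak


def promoter_accessibility(fe_per_bp: np.ndarray) -> float:
    """Promoter accessibility summary: mean of the two highest quartile-bin
    means of per-bp fold enrichment within the promoter zone, log10 of
    (value + 1)."""
    fe = np.asarray(fe_per_bp, dtype=float)
    if fe.size == 0:
        return float("nan")
    quarts = np.array_split(np.sort(fe), 4)
    means = sorted(q.mean() for q in quarts if q.size)
    top2 = np.mean(means[-2:])
    if top2 <= 0:
        return float("nan")
    return float(np.log10(top2))


def connectivity(contacts: SampleContacts, gene: GeneModel,
                 paired_peaks: pd.DataFrame, resolution: int = 1000,
                 ring: tuple[int, int] = (5000, 50_000),
                 mappability: float | None = None,
                 density: float | None = None) -> dict:
    """ConnectivityRecord for one gene in one sample.

    ``C_g = sum_peaks raw(promoter, peak +/- 500 bp) / M / D`` with M the
    promoter mappability and D the background density (both computed here
    when not supplied).  Companion summaries: number of paired peaks,
    enhancer accessibility (log10 of summed peak fold enrichment) and, when
    the peak table carries promoter annotations, promoter accessibility.
    """
    m = promoter_mappability(contacts, gene) if mappability is None else mappability
    d = background_density(contacts, gene, ring=ring) if density is None else density
    n_pairs = len(paired_peaks)
    if n_pairs == 0:
        raw = 0.0
        c_g = 0.0
    else:
        raw, _ = raw_promoter_peak_contacts(contacts, gene, paired_peaks,
                                            resolution=resolution)
        c_g = raw / m / d if np.isfinite(m) and m > 0 else float("nan")
    if "fold_enrichment" in paired_peaks.columns and n_pairs:
        enh_acc = float(np.log10(paired_peaks["fold_enrichment"].sum() + 1))
    else:
        enh_acc = float("nan")
    return {"gene_id": gene.gene_id, "connectivity": c_g, "n_pairs": n_pairs,
            "raw_contacts": raw, "mappability": m, "background_density": d,
            "enhancer_accessibility": enh_acc}


def connectivity_table(contacts_by_sample: dict[str, SampleContacts],
                       genes: list[GeneModel], peaks: pd.DataFrame,
                       sample_stage: dict[str, str] | None = None,
                       max_dist: int = 200_000, resolution: int = 1000,
                       promoter_fe: dict[str, float] | None = None,
                       promoter_meth: dict[str, float] | None = None,
                       stripe_strength: dict[str, dict[str, float]] | None = None,
                       ) -> pd.DataFrame:
    """Per-sample, per-gene connectivity records as a tidy DataFrame.

    *peaks* may be a multi-sample table with a ``sample`` column; pairing
    then uses each sample's own peaks.  Optional per-gene annotations
    (promoter fold enrichment, methylation %, per-sample stripe strength)
    are attached when provided.
    """
    rows = []
    per_sample_peaks = ("sample" in peaks.columns)
    for sample, contacts in contacts_by_sample.items():
        pk = peaks[peaks["sample"] == sample] if per_sample_peaks else peaks
        for gene in genes:
            paired = pair_promoter_enhancers(gene, pk, max_dist=max_dist)
            rec = connectivity(contacts, gene, paired, resolution=resolution)
            rec["sample"] = sample
            if sample_stage:
                rec["stage"] = sample_stage[sample]
            if promoter_fe is not None:
                rec["promoter_accessibility"] = promoter_fe.get(gene.gene_id, np.nan)
            if promoter_meth is not None:
                rec["promoter_methylation"] = promoter_meth.get(gene.gene_id, np.nan)
            if stripe_strength is not None:
                rec["promoter_stripe_strength"] = (
                    stripe_strength.get(sample, {}).get(gene.gene_id, np.nan))
            rows.append(rec)
    return pd.DataFrame(rows)


def filter_gene_set(stage_table: pd.DataFrame,
                    feature_cols: tuple[str, ...] = (
                        "connectivity", "promoter_accessibility",
                        "promoter_stripe_strength")) -> pd.DataFrame:
    """Gene filtering and zero imputation across the three stages.

    *stage_table* is indexed by gene with columns ``<feature>_<stage>``.
    A gene is removed when any of the listed features is nonpositive (or
    missing) in ALL three stages; for retained genes, missing or negative
    values are replaced with zero.
    """
    present = [f for f in feature_cols
               if any(c.startswith(f + "_") for c in stage_table.columns)]
    keep = pd.Series(True, index=stage_table.index)
    for f in present:
        cols = [c for c in stage_table.columns if c.startswith(f + "_")]
        vals = stage_table[cols].to_numpy(dtype=float)
        all_nonpos = np.all(np.nan_to_num(vals, nan=0.0) <= 0, axis=1)
        keep &= ~all_nonpos
    out = stage_table.loc[keep].copy()
    num = out.select_dtypes(include=[np.number]).columns
    out[num] = out[num].fillna(0.0).clip(lower=0.0)
    return out
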