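"""Synthetic multi-sample cohorts with planted ground truth.

Emulates the statistical structure the analysis assumes in a three-stage
colon cohort (mucosa, polyp, adenocarcinoma): distance-decay background
contacts, architectural stripes at gene promoters, focal loops, short-range
self-ligation pairs, locus-level mappability bias, accessibility peaks,
CpG methylation and expression following the saturating two-phase rule

    E = beta * min(C_true, C_sat) + eps

optionally renormalized per sample to a fixed TPM budget, which lets
saturated high-connectivity genes rise in *relative* expression when global
connectivity is attenuated.

Bias semantics: long-range, stripe and loop pairs are accepted with
probability proportional to b(end1) * b(end2); self-ligation pairs are
emitted at a rate proportional to b(x) at their single locus.  Under this
scheme the long/short coverage ratio at a locus is independent of b in
expectation — the property the stripe caller exploits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .contacts import PAIR_COLUMNS

STAGES = ("mucosa", "polyp", "adenocarcinoma")

#: default per-stage multiplier on stripe/loop intensity, anchored to the
#: reported ~40% connectivity/stripe loss in adenocarcinoma
DEFAULT_ATTENUATION = {"mucosa": 1.0, "polyp": 0.8, "adenocarcinoma": 0.6}

#: milder stage attenuation of promoter accessibility
DEFAULT_ACC_ATTENUATION = {"mucosa": 1.0, "polyp": 0.95, "adenocarcinoma": 0.877}

BIAS_RANGE = (0.3, 3.0)


def two_phase_expression(c_true, beta: float, c_sat: float, eps=0.0):
    """Saturating two-phase expression rule: beta * min(C, C_sat) + eps."""
    return beta * np.minimum(np.asarray(c_true, dtype=float), c_sat) + eps


@dataclass
class AnchorTruth:
    """Planted stripe anchor; stage strength = base_strength * attenuation."""
    chrom: str
    start: int
    end: int
    base_strength: float


@dataclass
class LoopTruth:
    chrom: str
    start1: int
    end1: int
    start2: int
    end2: int
    enrichment: float


@dataclass
class GeneTruth:
    gene_id: str
    chrom: str
    tss: int
    strand: str
    anchor_index: int                       # promoter stripe anchor
    enhancers: list[tuple[int, int]]        # distal peak intervals
    c_true: dict[str, float]                # per-stage planted connectivity
    meth_mean: dict[str, float]             # promoter methylation % per stage


@dataclass
class SyntheticTruth:
    """Ground truth of one synthetic cohort."""

    chrom_sizes: dict[str, int]
    stripe_anchors: list[AnchorTruth]
    loop_pairs: list[LoopTruth]
    genes: list[GeneTruth]
    samples: dict[str, str]                 # sample id -> stage
    bias_bumps: list[tuple[str, int, int, float]] = field(default_factory=list)
    decay_exponent: float = 1.0
    stage_attenuation: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ATTENUATION))
    acc_attenuation: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACC_ATTENUATION))
    beta: float = 50.0
    c_sat: float = 1.0
    expr_noise_sd: float = 5.0
    max_distance: int = 2_000_000           # background decay truncation
    min_distance: int = 1000
    stripe_reach: int = 200_000
    stripe_min_offset: int = 2000
    fractions: dict[str, float] = field(default_factory=lambda: {
        "background": 0.35, "stripe": 0.20, "loop": 0.05, "selflig": 0.40})
    decoy_peaks: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if abs(self.stage_attenuation["mucosa"] - 1.0) > 1e-12:
            raise ValueError("mucosa attenuation must be 1")
        for a in self.stripe_anchors:
            if not (0 <= a.start < a.end <= self.chrom_sizes[a.chrom]):
                raise ValueError(f"anchor outside chromosome: {a}")
        for c, s, e, b in self.bias_bumps:
            if not BIAS_RANGE[0] <= b <= BIAS_RANGE[1]:
                raise ValueError(f"bias {b} outside declared range {BIAS_RANGE}")
            if not (0 <= s < e <= self.chrom_sizes[c]):
                raise ValueError("bias bump outside chromosome")
        for c, size in self.chrom_sizes.items():
            if size <= 0:
                raise ValueError(f"zero-length chromosome {c}")
        for s, stage in self.samples.items():
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage} for sample {s}")

    # -- bias ---------------------------------------------------------------
    def bias_array(self, chrom: str, bin_size: int = 100) -> np.ndarray:
        n = int(np.ceil(self.chrom_sizes[chrom] / bin_size))
        b = np.ones(n)
        for c, s, e, v in self.bias_bumps:
            if c == chrom:
                b[s // bin_size: -(-e // bin_size)] = v
        return b

    def bias_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        arr = self.bias_array(chrom)
        idx = np.clip(np.asarray(pos) // 100, 0, len(arr) - 1)
        return arr[idx]

    def stage_of(self, sample: str) -> str:
        if sample not in self.samples:
            raise ValueError(f"unknown sample {sample}")
        return self.samples[sample]

    # -- (de)serialization --------------------------------------------------
    def to_json(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["stripe_anchors"] = [AnchorTruth(**a) for a in d["stripe_anchors"]]
        d["loop_pairs"] = [LoopTruth(**a) for a in d["loop_pairs"]]
        d["genes"] = [GeneTruth(**{**g, "enhancers":
                                   [tuple(e) for e in g["enhancers"]]})
                      for g in d["genes"]]
        d["bias_bumps"] = [tuple(b) for b in d["bias_bumps"]]
        d["decoy_peaks"] = [tuple(p) for p in d["decoy_peaks"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# cohort builder
# ---------------------------------------------------------------------------

def default_cohort(n_mucosa: int = 7, n_polyp: int = 19,
                   n_adenocarcinoma: int = 7) -> dict[str, str]:
    """Sample manifest mirroring the study cohort shape (7/19/7)."""
    samples = {}
    for stage, n in zip(STAGES, (n_mucosa, n_polyp, n_adenocarcinoma)):
        for k in range(n):
            samples[f"{stage}_{k + 1}"] = stage
    return samples


def build_truth(n_genes: int = 60,
                chrom_sizes: dict[str, int] | None = None,
                samples: dict[str, str] | None = None,
                seed: int = 0,
                gene_spacing: int | None = None,
                n_enhancers: tuple[int, int] = (2, 6),
                enhancer_width: int = 600,
                n_decoys_per_chrom: int = 20,
                n_loops: int = 20,
                bias_bumps: list[tuple[str, int, int, float]] | None = None,
                **overrides) -> SyntheticTruth:
    """Build a reproducible synthetic truth.

    Genes are laid out on a regular grid (plus jitter); each gene's promoter
    is a planted stripe anchor whose base strength is log-normal across
    genes.  Planted connectivity is

        C_true(g, stage) = strength_g * attenuation(stage) * span_kb(g) / norm

    where span is the total enhancer interaction span of the gene, and norm
    sets the cohort median mucosa C_true to 2 * C_sat so that, as in normal
    tissue, most genes sit in the saturated phase.
    """
    rng = np.random.default_rng([seed, 101])
    if chrom_sizes is None:
        chrom_sizes = {"chr1": 10_000_000, "chr2": 10_000_000, "chr3": 10_000_000}
    samples = samples or default_cohort()
    atten = overrides.get("stage_attenuation", dict(DEFAULT_ATTENUATION))
    c_sat = overrides.get("c_sat", 1.0)

    chroms = list(chrom_sizes)
    total = sum(chrom_sizes.values())
    per_chrom = {c: max(1, round(n_genes * chrom_sizes[c] / total)) for c in chroms}
    # trim/extend to exactly n_genes
    while sum(per_chrom.values()) > n_genes:
        per_chrom[chroms[-1]] -= 1
    while sum(per_chrom.values()) < n_genes:
        per_chrom[chroms[0]] += 1

    anchors: list[AnchorTruth] = []
    genes: list[GeneTruth] = []
    strengths = 10 ** rng.normal(0.0, 0.5, size=n_genes)
    spans = np.zeros(n_genes)
    gi = 0
    margin = 300_000
    for chrom in chroms:
        n_c = per_chrom[chrom]
        size = chrom_sizes[chrom]
        spacing = gene_spacing or (size - 2 * margin) // max(n_c, 1)
        for k in range(n_c):
            tss = margin + k * spacing + int(rng.integers(-spacing // 8, spacing // 8 + 1))
            tss = int(np.clip(tss, margin, size - margin))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                pstart, pend = tss - 1500, tss + 500
            else:
                pstart, pend = tss - 500, tss + 1500
            anchors.append(AnchorTruth(chrom, pstart, pend, float(strengths[gi])))
            n_enh = int(rng.integers(n_enhancers[0], n_enhancers[1] + 1))
            enhancers = []
            for _ in range(n_enh):
                off = int(rng.integers(10_000, 180_000))
                side = 1 if rng.random() < 0.5 else -1
                es = tss + side * off
                es = int(np.clip(es, 1000, size - enhancer_width - 1000))
                enhancers.append((es, es + enhancer_width))
            # taper-weighted interaction span: each peak window (peak +/-
            # 500 bp, kb units) weighted by the triangular stripe offset
            # density at its distance from the TSS
            reach = overrides.get("stripe_reach", 200_000)
            spans[gi] = sum(((e - s + 1000) / 1000.0)
                            * max(reach - abs((s + e) // 2 - tss), 0) / reach
                            for s, e in enhancers)
            genes.append(GeneTruth(
                gene_id=f"g{gi:04d}", chrom=chrom, tss=tss, strand=strand,
                anchor_index=len(anchors) - 1, enhancers=enhancers,
                c_true={}, meth_mean={}))
            gi += 1
    n_genes = gi
    strengths = strengths[:n_genes]
    spans = spans[:n_genes]

    norm = float(np.median(strengths * spans)) / (2.0 * c_sat)
    demeth_rank = pd.Series(strengths).rank(pct=True).to_numpy()
    hyper_subset = rng.random(n_genes) < 0.10
    for g, s, span, dr, hyp in zip(genes, strengths, spans, demeth_rank, hyper_subset):
        g.c_true = {stage: float(s * atten[stage] * span / norm) for stage in STAGES}
        if dr > 0.4:
            base_meth = 10.0
        elif dr > 0.2:
            base_meth = 32.0
        else:
            base_meth = 60.0
        g.meth_mean = {stage: base_meth for stage in STAGES}
        if hyp and base_meth == 10.0:
            g.meth_mean["adenocarcinoma"] = base_meth + 25.0

    # loops between nearby anchor pairs
    loop_pairs: list[LoopTruth] = []
    anchor_by_chrom: dict[str, list[int]] = {}
    for idx, a in enumerate(anchors):
        anchor_by_chrom.setdefault(a.chrom, []).append(idx)
    candidates = []
    for chrom, idxs in anchor_by_chrom.items():
        for i, j in zip(idxs[:-1], idxs[1:]):
            a1, a2 = anchors[i], anchors[j]
            if 20_000 < a2.start - a1.end < 1_000_000:
                candidates.append((a1, a2))
    take = min(n_loops, len(candidates))
    chosen = rng.choice(len(candidates), size=take, replace=False) if candidates else []
    for k in chosen:
        a1, a2 = candidates[int(k)]
        loop_pairs.append(LoopTruth(a1.chrom, a1.start, a1.end, a2.start, a2.end,
                                    float(10 ** rng.normal(0.8, 0.2))))

    decoys = []
    for chrom in chroms:
        for _ in range(n_decoys_per_chrom):
            s = int(rng.integers(50_000, chrom_sizes[chrom] - 50_000))
            decoys.append((chrom, s, s + enhancer_width))

    return SyntheticTruth(
        chrom_sizes=dict(chrom_sizes), stripe_anchors=anchors,
        loop_pairs=loop_pairs, genes=genes, samples=dict(samples),
        bias_bumps=list(bias_bumps or []), decoy_peaks=decoys, **overrides)


# ---------------------------------------------------------------------------
# contact simulation
# ---------------------------------------------------------------------------

def _sample_seed(truth: SyntheticTruth, sample: str, seed: int) -> list[int]:
    idx = list(truth.samples).index(sample)
    return [seed, 7919, idx]


def _power_law_distances(rng, n, d_min, d_max, alpha) -> np.ndarray:
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        d = d_min * (d_max / d_min) ** u
    else:
        a = 1.0 - alpha
        d = (d_min ** a + u * (d_max ** a - d_min ** a)) ** (1.0 / a)
    return d.astype(np.int64)


def _rand_strands(rng, n) -> tuple[np.ndarray, np.ndarray]:
    s1 = np.where(rng.random(n) < 0.5, "+", "-")
    s2 = np.where(rng.random(n) < 0.5, "+", "-")
    return s1, s2


def simulate_contacts(truth: SyntheticTruth, sample: str, depth: int,
                      seed: int) -> pd.DataFrame:
    """Emit *depth* intra-chromosomal contact records for one sample.

    Components: (a) distance-decay background (density ~ d^-alpha, truncated
    at ``max_distance``); (b) stripe contacts between a planted anchor and a
    sliding position within the stripe reach (triangular taper, see below);
    (c) focal loop contacts; (d) inward-oriented self-ligation pairs < 1 kb.
    Stripe and loop budgets scale with the sample's stage attenuation.

    Mappability bias acts as a one-shot thinning: every candidate pair is
    kept with probability b(end1)*b(end2)/b_max^2 (self-ligation pairs with
    b(x)/b_max at their single locus) and lost pairs are NOT re-drawn, so
    coverage at a biased locus scales multiplicatively with b as lost reads
    do in sequencing.  Candidate budgets are pre-scaled by b_max^2 (b_max
    for self-ligation) so loci at b = 1 receive the nominal class budget.
    *depth* is the nominal depth at unit bias.
    Deterministic for fixed (truth, sample, depth, seed).
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    stage = truth.stage_of(sample)
    atten = truth.stage_attenuation[stage]
    rng = np.random.default_rng(_sample_seed(truth, sample, seed))
    f = truth.fractions
    pair_mult = BIAS_RANGE[1] ** 2 if truth.bias_bumps else 1.0
    self_mult = BIAS_RANGE[1] if truth.bias_bumps else 1.0
    n_bg = int(depth * f["background"] * pair_mult)
    n_stripe = int(depth * f["stripe"] * atten * pair_mult)
    n_loop = int(depth * f["loop"] * atten * pair_mult)
    n_self = int(depth * f["selflig"] * self_mult)

    chroms = list(truth.chrom_sizes)
    chrom_arr = np.array(chroms)
    sizes = np.array([truth.chrom_sizes[c] for c in chroms], dtype=np.int64)
    p_chrom = sizes / sizes.sum()
    b_max = BIAS_RANGE[1] if truth.bias_bumps else 1.0
    bias_arrays = {c: truth.bias_array(c) for c in chroms} if truth.bias_bumps else None

    def bias_at(chrom_idx, pos):
        b = np.ones(len(pos))
        if bias_arrays is not None:
            for ci, c in enumerate(chroms):
                m = chrom_idx == ci
                if m.any():
                    arr = bias_arrays[c]
                    b[m] = arr[np.clip(pos[m] // 100, 0, len(arr) - 1)]
        return b

    def thin(chrom_idx, pos1, pos2=None):
        """One-shot bias thinning mask; never refilled."""
        if bias_arrays is None:
            return np.ones(len(pos1), dtype=bool)
        p = bias_at(chrom_idx, pos1) / b_max
        if pos2 is not None:
            p = p * bias_at(chrom_idx, pos2) / b_max
        return rng.random(len(pos1)) < p

    parts = []

    # (a) background: draw exactly n_bg in-bounds candidates, then thin
    ci = rng.choice(len(chroms), size=n_bg, p=p_chrom)
    d = _power_law_distances(rng, n_bg, truth.min_distance,
                             truth.max_distance, truth.decay_exponent)
    # resample out-of-range distances per chromosome rather than clipping
    too_big = d >= sizes[ci]
    d[too_big] = (sizes[ci][too_big] * 0.45).astype(np.int64)
    p1 = (rng.random(n_bg) * (sizes[ci] - d)).astype(np.int64)
    keep = thin(ci, p1, p1 + d)
    s1, s2 = _rand_strands(rng, int(keep.sum()))
    parts.append(pd.DataFrame({
        "chrom1": chrom_arr[ci[keep]], "pos1": p1[keep], "strand1": s1,
        "chrom2": chrom_arr[ci[keep]], "pos2": (p1 + d)[keep], "strand2": s2}))

    # (b) stripes: anchored end in the anchor interval, far end with a
    # triangular taper (stripes fade linearly toward their reach rather
    # than ending in a hard cliff, which would register as an edge anchor)
    if n_stripe > 0 and truth.stripe_anchors:
        w = np.array([a.base_strength for a in truth.stripe_anchors])
        p_anchor = w / w.sum()
        a_chrom = np.array([chroms.index(a.chrom) for a in truth.stripe_anchors])
        a_start = np.array([a.start for a in truth.stripe_anchors])
        a_end = np.array([a.end for a in truth.stripe_anchors])
        ai = rng.choice(len(w), size=n_stripe, p=p_anchor)
        ci = a_chrom[ai]
        apos = a_start[ai] + (rng.random(n_stripe)
                              * (a_end[ai] - a_start[ai])).astype(np.int64)
        span = truth.stripe_reach - truth.stripe_min_offset
        off = (truth.stripe_reach
               - (span * np.sqrt(1.0 - rng.random(n_stripe))).astype(np.int64))
        side = np.where(rng.random(n_stripe) < 0.5, 1, -1)
        opos = apos + side * off
        # reflect far ends that fall off the chromosome
        opos = np.where(opos < 0, apos + off, opos)
        opos = np.where(opos >= sizes[ci], apos - off, opos)
        ok = (opos >= 0) & (opos < sizes[ci])
        keep = ok & thin(ci, apos, opos)
        lo = np.minimum(apos, opos)[keep]
        hi = np.maximum(apos, opos)[keep]
        s1, s2 = _rand_strands(rng, int(keep.sum()))
        parts.append(pd.DataFrame({
            "chrom1": chrom_arr[ci[keep]], "pos1": lo, "strand1": s1,
            "chrom2": chrom_arr[ci[keep]], "pos2": hi, "strand2": s2}))

    # (c) loops
    if n_loop > 0 and truth.loop_pairs:
        w = np.array([lp.enrichment for lp in truth.loop_pairs])
        p_loop = w / w.sum()
        li = rng.choice(len(w), size=n_loop, p=p_loop)
        ci = np.array([chroms.index(truth.loop_pairs[k].chrom) for k in li])
        s1a = np.array([truth.loop_pairs[k].start1 for k in li])
        e1a = np.array([truth.loop_pairs[k].end1 for k in li])
        s2a = np.array([truth.loop_pairs[k].start2 for k in li])
        e2a = np.array([truth.loop_pairs[k].end2 for k in li])
        p1 = s1a + (rng.random(n_loop) * (e1a - s1a)).astype(np.int64)
        p2 = s2a + (rng.random(n_loop) * (e2a - s2a)).astype(np.int64)
        keep = thin(ci, p1, p2)
        s1, s2 = _rand_strands(rng, int(keep.sum()))
        parts.append(pd.DataFrame({
            "chrom1": chrom_arr[ci[keep]], "pos1": p1[keep], "strand1": s1,
            "chrom2": chrom_arr[ci[keep]], "pos2": p2[keep], "strand2": s2}))

    # (d) self-ligation, inward orientation, < 1 kb, rate prop. to b(x)
    ci = rng.choice(len(chroms), size=n_self, p=p_chrom)
    p1 = (rng.random(n_self) * (sizes[ci] - 1000)).astype(np.int64)
    d = rng.integers(100, 1000, size=n_self)
    keep = thin(ci, p1)
    parts.append(pd.DataFrame({
        "chrom1": chrom_arr[ci[keep]], "pos1": p1[keep], "strand1": "+",
        "chrom2": chrom_arr[ci[keep]], "pos2": (p1 + d)[keep], "strand2": "-"}))

    df = pd.concat(parts, ignore_index=True)[PAIR_COLUMNS]
    df["pos1"] = df["pos1"].astype(np.int64)
    df["pos2"] = df["pos2"].astype(np.int64)
    return df


# ---------------------------------------------------------------------------
# track simulation (peaks, methylation, expression)
# ---------------------------------------------------------------------------

def simulate_tracks(truth: SyntheticTruth, seed: int,
                    normalize_tpm: bool = True,
                    peak_dropout: float = 0.05,
                    n_private_decoys: int = 5,
                    cpg_per_promoter: int = 20):
    """Per-sample accessibility peaks, CpG methylation and expression.

    Returns ``(peaks, methylation, expression)`` DataFrames.  Peaks sit at
    promoter anchors and planted enhancers (shared across samples, with a
    small per-sample dropout) plus shared and sample-private decoys, each
    carrying a fold-enrichment signal.  CpG methylation is drawn around the
    gene's declared per-stage category mean.  Expression follows the
    two-phase rule per stage; with *normalize_tpm* each sample's TPM vector
    is rescaled to a fixed budget so relative fold changes can be positive
    for saturated genes under global attenuation.
    """
    if not truth.genes:
        raise ValueError("truth has no genes")
    rng = np.random.default_rng([seed, 424242])
    peak_rows, meth_rows, expr_rows = [], [], []

    # shared peak catalogue: promoters + enhancers + shared decoys
    catalogue = []
    for g in truth.genes:
        a = truth.stripe_anchors[g.anchor_index]
        catalogue.append(("promoter", g.gene_id, g.chrom, a.start, a.end))
        for s, e in g.enhancers:
            catalogue.append(("enhancer", g.gene_id, g.chrom, s, e))
    for c, s, e in truth.decoy_peaks:
        catalogue.append(("decoy", "", c, s, e))
    base_fe = 10 ** rng.normal(0.7, 0.25, size=len(catalogue))

    cpg_offsets = {g.gene_id: np.sort(rng.integers(-1500, 500, size=cpg_per_promoter))
                   for g in truth.genes}

    for sample, stage in truth.samples.items():
        srng = np.random.default_rng([seed, 515151, list(truth.samples).index(sample)])
        acc = truth.acc_attenuation[stage]
        # peaks
        drop = srng.random(len(catalogue)) < peak_dropout
        for k, (kind, gid, chrom, s, e) in enumerate(catalogue):
            if drop[k]:
                continue
            fe = base_fe[k] * (acc if kind != "decoy" else 1.0)
            fe *= 10 ** srng.normal(0, 0.05)
            peak_rows.append({"sample": sample, "stage": stage, "kind": kind,
                              "gene_id": gid, "chrom": chrom, "start": s,
                              "end": e, "fold_enrichment": fe})
        for _ in range(n_private_decoys):
            chrom = list(truth.chrom_sizes)[int(srng.integers(len(truth.chrom_sizes)))]
            s = int(srng.integers(50_000, truth.chrom_sizes[chrom] - 50_000))
            peak_rows.append({"sample": sample, "stage": stage, "kind": "private",
                              "gene_id": "", "chrom": chrom, "start": s,
                              "end": s + 400,
                              "fold_enrichment": float(10 ** srng.normal(0.5, 0.2))})
        # methylation
        for g in truth.genes:
            mu = g.meth_mean[stage]
            pct = np.clip(srng.normal(mu, 5.0, size=cpg_per_promoter), 0, 100)
            cov = srng.poisson(30, size=cpg_per_promoter)
            for off, p, c in zip(cpg_offsets[g.gene_id], pct, cov):
                meth_rows.append({"sample": sample, "stage": stage,
                                  "gene_id": g.gene_id, "chrom": g.chrom,
                                  "pos": g.tss + int(off),
                                  "meth_pct": float(p), "coverage": int(c)})
        # expression
        c_vec = np.array([g.c_true[stage] for g in truth.genes])
        eps = srng.normal(0, truth.expr_noise_sd, size=len(c_vec))
        raw = np.clip(two_phase_expression(c_vec, truth.beta, truth.c_sat, eps), 0, None)
        if normalize_tpm and raw.sum() > 0:
            tpm = raw / raw.sum() * (truth.beta * 0.8 * len(raw))
        else:
            tpm = raw
        for g, t in zip(truth.genes, tpm):
            expr_rows.append({"sample": sample, "stage": stage,
                              "gene_id": g.gene_id, "tpm": float(t)})

    peaks = pd.DataFrame(peak_rows)
    methylation = pd.DataFrame(meth_rows)
    expression = pd.DataFrame(expr_rows)
    return peaks, methylation, expression


def gene_models(truth: SyntheticTruth) -> pd.DataFrame:
    """BED-like gene model table (gene_id, chrom, tss, strand)."""
    return pd.DataFrame([{"gene_id": g.gene_id, "chrom": g.chrom,
                          "tss": g.tss, "strand": g.strand}
                         for g in truth.genes])


# ---------------------------------------------------------------------------
# gene-level feature cohorts for predictive modeling
# ---------------------------------------------------------------------------

def simulate_feature_cohort(n_genes: int = 10_000, seed: int = 0,
                            beta: float = 50.0, c_sat: float = 1.0,
                            feature_noise: float = 0.15,
                            target_noise_frac: float = 0.5,
                            n_tf: int = 10,
                            attenuation: dict[str, float] | None = None):
    """Gene-level feature tables at model scale, without contact simulation.

    Planted mucosa connectivity is log-normal (median 2 * C_sat, so most
    genes are saturated); stage expression follows the two-phase rule with
    per-sample TPM renormalization; measured features are noisy monotone
    readouts of the planted quantities.  The target column
    ``log2fc_<stage>`` has Gaussian noise with s.d. equal to
    *target_noise_frac* times the clean signal s.d.

    Returns ``(features, stage_tables, truth_frame)``: *features* holds
    per-gene mucosa feature readouts, TF indicator columns and the fold-
    change targets; *stage_tables* maps each stage to the per-stage measured
    feature table (indexed by gene id) used by the differential model.
    """
    rng = np.random.default_rng([seed, 606060])
    attenuation = attenuation or dict(DEFAULT_ATTENUATION)
    c_mucosa = 10 ** rng.normal(np.log10(2.0 * c_sat), 0.4, size=n_genes)
    gene_ids = [f"g{k:05d}" for k in range(n_genes)]
    enh_acc_base = rng.normal(1.0, 0.4, n_genes)

    expr = {}
    c_stage = {}
    stage_tables: dict[str, pd.DataFrame] = {}
    for stage in STAGES:
        c_stage[stage] = c_mucosa * attenuation[stage] * 10 ** rng.normal(0, 0.05, n_genes)
        eps = rng.normal(0, 0.05 * beta, size=n_genes)
        raw = np.clip(two_phase_expression(c_stage[stage], beta, c_sat, eps), 0, None)
        expr[stage] = raw / raw.sum() * (beta * 0.8 * n_genes)
        c_meas = c_stage[stage] * 10 ** rng.normal(0, feature_noise, n_genes)
        t = pd.DataFrame({
            "connectivity": c_meas,
            "promoter_stripe": np.log10(c_stage[stage]) + rng.normal(0, feature_noise, n_genes),
            "promoter_accessibility": (np.log10(c_stage[stage]) * 0.6
                                       + rng.normal(0, feature_noise, n_genes)),
            "promoter_methylation": np.clip(
                35 - 20 * np.log10(c_mucosa) + rng.normal(0, 8, n_genes), 0, 100),
            "enhancer_accessibility": enh_acc_base + rng.normal(0, 0.05, n_genes),
            "tpm": expr[stage],
        }, index=pd.Index(gene_ids, name="gene_id"))
        stage_tables[stage] = t

    feats = stage_tables["mucosa"].reset_index().rename(
        columns={"tpm": "expression_mucosa"})
    for k in range(n_tf):
        feats[f"tf_{k}"] = (rng.random(n_genes) < 0.3).astype(float)

    truth_rows = {"c_mucosa": c_mucosa}
    for stage in ("polyp", "adenocarcinoma"):
        clean = np.log2((expr[stage] + 1) / (expr["mucosa"] + 1))
        noise = rng.normal(0, target_noise_frac * clean.std(), n_genes)
        feats[f"log2fc_{stage}"] = clean + noise
        truth_rows[f"clean_log2fc_{stage}"] = clean
        truth_rows[f"c_{stage}"] = c_stage[stage]
    truth_frame = pd.DataFrame(truth_rows)
    return feats, stage_tables, truth_frame


def simulate_multicancer_calls(features: pd.DataFrame, n_cohorts: int = 8,
                               seed: int = 0, beta: float = 50.0,
                               c_sat: float = 1.0,
                               fold_threshold: float = 1.3):
    """Per-cohort up/down/unchanged calls from the two-phase rule.

    Each cohort applies its own global attenuation (uniform in [0.5, 0.8])
    plus per-gene noise to the planted mucosa connectivity implied by the
    feature table, renormalizes expression, and calls a gene up/down when
    |fold change| exceeds *fold_threshold* (coded +1/-1, else 0).
    Returns an (n_genes, n_cohorts) integer array.
    """
    rng = np.random.default_rng([seed, 717171])
    c = features["connectivity"].to_numpy()
    n = len(c)
    calls = np.zeros((n, n_cohorts), dtype=int)
    base = np.clip(two_phase_expression(c, beta, c_sat), 1e-9, None)
    base_tpm = base / base.sum() * (beta * 0.8 * n)
    for t in range(n_cohorts):
        a = rng.uniform(0.5, 0.8)
        c_t = c * a * 10 ** rng.normal(0, 0.08, n)
        e = np.clip(two_phase_expression(c_t, beta, c_sat,
                                         rng.normal(0, 0.05 * beta, n)), 0, None)
        tpm = e / e.sum() * (beta * 0.8 * n)
        fc = (tpm + 1) / (base_tpm + 1)
        calls[:, t] = np.where(fc > fold_threshold, 1,
                               np.where(fc < 1 / fold_threshold, -1, 0))
    return calls
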