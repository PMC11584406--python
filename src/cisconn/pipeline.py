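"""End-to-end orchestration: simulate -> stripes -> loops -> connectivity ->
methylation -> two-phase, with a reproducibility manifest.

All thresholds default to the published values (stripe windows and distance
cuts, FDR 0.01 / >= 3 samples / >= 500 bp consensus, 200-kb pairing, 5-50 kb
donut, methylation 25/40/15% cuts, 1.2-fold stage-positive loops, up to 50
training epochs, 2,800 held-out genes); simulation sizes and model widths
are artifact defaults.  A run writes plain-text artifacts into a run
directory plus a JSON manifest recording the seed, thresholds and input
digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, connectivity as conn, loops as loops_mod
from . import stripes as stripes_mod, synthetic, twophase
from .contacts import bin_matrix, write_pairs

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline thresholds and sizes; round-trips via YAML."""

    out_dir: str = "cisconn_run"
    seed: int = 0
    # cohort / simulation (artifact defaults)
    n_mucosa: int = 2
    n_polyp: int = 2
    n_adenocarcinoma: int = 2
    n_genes: int = 60
    depth: int = 800_000
    chrom_size: int = 10_000_000
    n_chroms: int = 2
    # stripe calling
    long_min: int = 1500
    short_max: int = 1000
    local_window: int = 2000
    background_window: int = 50_000
    step: int = 100
    fdr: float = 0.01
    min_samples: int = 3
    min_size: int = 500
    # loops / APA
    loop_fold: float = 1.2
    apa_resolution: int = 200
    apa_half_width: int = 25
    # connectivity
    max_dist: int = 200_000
    resolution: int = 1000
    ring_inner: int = 5000
    ring_outer: int = 50_000
    # methylation
    demethylated_max: float = 25.0
    methylated_min: float = 40.0
    min_diff: float = 15.0
    meth_fdr: float = 0.1
    # two-phase model (widths are artifact defaults, scaled for desk runs)
    model_genes: int = 4000
    test_n: int = 1000
    epochs: int = 20
    hidden: tuple = (64, 32, 16)
    dropout: float = 0.2

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["hidden"] = list(self.hidden)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "hidden" in d:
            d["hidden"] = tuple(d["hidden"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def validate(self) -> None:
        if self.long_min <= self.short_max:
            raise ValueError("long_min must exceed short_max")
        if self.depth <= 0 or self.n_genes <= 0:
            raise ValueError("depth and n_genes must be positive")
        if self.model_genes <= self.test_n:
            raise ValueError("model_genes must exceed test_n")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage on a synthetic cohort; returns the run directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")

    chrom_sizes = {f"chr{k + 1}": config.chrom_size
                   for k in range(config.n_chroms)}
    samples = synthetic.default_cohort(config.n_mucosa, config.n_polyp,
                                       config.n_adenocarcinoma)
    truth = synthetic.build_truth(n_genes=config.n_genes,
                                  chrom_sizes=chrom_sizes, samples=samples,
                                  seed=config.seed)
    truth.to_json(out / "truth.json")

    # simulate
    pairs_dir = out / "pairs"
    pairs_dir.mkdir(exist_ok=True)
    pairs_by_sample = {}
    for sample in truth.samples:
        df = synthetic.simulate_contacts(truth, sample, config.depth, config.seed)
        pairs_by_sample[sample] = df
        write_pairs(df, pairs_dir / f"{sample}.pairs", chrom_sizes)
    peaks, methylation, expression = synthetic.simulate_tracks(truth, config.seed)
    peaks.to_csv(out / "peaks.tsv", sep="\t", index=False)
    methylation.to_csv(out / "methylation.tsv", sep="\t", index=False)
    expression.to_csv(out / "expression.tsv", sep="\t", index=False)

    # stripes
    params = stripes_mod.StripeParams(
        long_min=config.long_min, short_max=config.short_max,
        local_window=config.local_window,
        background_window=config.background_window, step=config.step,
        fdr=config.fdr, min_samples=config.min_samples,
        min_size=config.min_size)
    per_sample = {s: stripes_mod.call_sample_stripes(df, chrom_sizes, params)
                  for s, df in pairs_by_sample.items()}
    anchors = stripes_mod.consensus_anchors(
        per_sample, fdr=config.fdr, min_samples=config.min_samples,
        min_size=config.min_size, autosomes=set(chrom_sizes))
    stripes_mod.anchors_to_frame(anchors).to_csv(
        out / "stripe_anchors.bed", sep="\t", header=False, index=False)

    # loops + APA per stage
    loop_frame = pd.DataFrame([dataclasses.asdict(lp) for lp in truth.loop_pairs])
    apa_scores = {}
    if len(loop_frame):
        for stage in synthetic.STAGES:
            stage_samples = [s for s, st in truth.samples.items() if st == stage]
            mats = [bin_matrix(pairs_by_sample[s], c, chrom_sizes[c],
                               config.apa_resolution)
                    for s in stage_samples for c in chrom_sizes]
            try:
                res = loops_mod.apa(mats, loop_frame.rename(columns={
                    "start1": "start1", "end1": "end1"}),
                    half_width=config.apa_half_width, mode="loop")
                apa_scores[stage] = res.score
            except ValueError:
                apa_scores[stage] = float("nan")
    with open(out / "apa_scores.json", "w") as fh:
        json.dump(apa_scores, fh, indent=1)

    # connectivity
    genes = conn.genes_from_frame(synthetic.gene_models(truth))
    contacts_by_sample = {s: conn.SampleContacts(df, config.long_min,
                                                 config.short_max)
                          for s, df in pairs_by_sample.items()}
    enhancer_peaks = peaks[peaks["kind"] != "promoter"]
    table = conn.connectivity_table(
        contacts_by_sample, genes, enhancer_peaks,
        sample_stage=truth.samples, max_dist=config.max_dist,
        resolution=config.resolution)
    table.to_csv(out / "connectivity.tsv", sep="\t", index=False)

    # methylation classification per gene promoter, per stage
    meth_rows = []
    for stage in synthetic.STAGES:
        sub = methylation[methylation["stage"] == stage]
        for g in truth.genes:
            zs, ze = conn.GeneModel(g.gene_id, g.chrom, g.tss, g.strand).promoter_zone
            m = annotate.region_methylation(sub, g.chrom, zs, ze)
            meth_rows.append({"gene_id": g.gene_id, "stage": stage,
                              "mean_meth": m,
                              "state": annotate.classify_state(m)})
    pd.DataFrame(meth_rows).to_csv(out / "promoter_methylation.tsv",
                                   sep="\t", index=False)

    # two-phase: correlation shift on the cohort + initial model at scale
    stage_conn = {}
    stage_expr = {}
    expr_wide = expression.pivot_table(index="gene_id", columns="sample",
                                       values="tpm")
    for stage in synthetic.STAGES:
        stage_samples = [s for s, st in truth.samples.items() if st == stage]
        sub = table[table["stage"] == stage]
        stage_conn[stage] = sub.groupby("gene_id")["connectivity"].mean().reindex(
            expr_wide.index).to_numpy()
        stage_expr[stage] = expr_wide[stage_samples].mean(axis=1).to_numpy()
    shift = twophase.correlation_shift(stage_conn, stage_expr)
    shift.to_csv(out / "correlation_shift.tsv", sep="\t", index=False)

    feats, stage_tables, _ = synthetic.simulate_feature_cohort(
        n_genes=config.model_genes, seed=config.seed)
    ft = twophase.build_features(
        stage_tables, "initial",
        target=feats.set_index("gene_id")["log2fc_polyp"],
        extra=feats.set_index("gene_id")[[c for c in feats if c.startswith("tf_")]])
    model = twophase.train_model(ft, test_n=config.test_n,
                                 epochs=config.epochs, seed=config.seed,
                                 hidden=config.hidden, dropout=config.dropout)
    imp = twophase.feature_importance(model, ft, seed=config.seed)
    imp.to_csv(out / "feature_importance.tsv", sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "n_samples": len(truth.samples),
        "n_anchors_called": len(anchors),
        "n_genes": len(truth.genes),
        "apa_scores": apa_scores,
        "model_heldout_r": model.heldout_r,
        "model_selected_epoch": model.selected_epoch,
        "correlation_shift": shift.to_dict(orient="records"),
        "input_digests": {p.name: _digest(p) for p in sorted(out.glob("*.tsv"))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    logger.info("pipeline complete: %s", out)
    return out
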