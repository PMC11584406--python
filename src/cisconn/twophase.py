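"""Two-phase analysis layer: features, predictive models, attribution.

The two-phase view of promoter-enhancer (P-E) connectivity holds that in
normal tissue most genes sit in a saturated "stabilization" phase where
extra connectivity no longer raises expression, while global connectivity
loss in neoplasia pushes genes into an "activation" phase where connectivity
is rate-limiting.  Its operational consequences, implemented here:

* per-stage Spearman correlation between connectivity and expression of
  active genes rises as connectivity is attenuated (correlation shift);
* a predictive model trained on baseline (mucosa) features anticipates
  expression fold changes in later stages (the "initial" model), and one
  trained on stage fold changes is the "differential" model;
* attribution-based feature importances identify connectivity as the
  dominant predictor, and the mean of coded up/down calls across cancer
  cohorts (the directionality score) stratifies prediction accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .regressor import DropoutMLPRegressor


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

#: positive-scale features that take a pseudo-count of 1 in fold changes
PSEUDO_FEATURES = ("connectivity", "promoter_methylation", "tpm")


def rank_transform(values: np.ndarray) -> np.ndarray:
    """Ascending average ranks (ties averaged); a monotone map of the raw
    column, invariant under any monotone rescaling."""
    return stats.rankdata(np.asarray(values, dtype=float), method="average")


@dataclass
class FeatureTable:
    """Per-gene design matrix (raw + rank columns) and target."""

    X: pd.DataFrame
    y: pd.Series
    mode: str

    @property
    def gene_ids(self) -> pd.Index:
        return self.X.index

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def build_features(stage_tables: dict[str, pd.DataFrame], mode: str,
                   target: pd.Series, stage: str = "polyp",
                   baseline: str = "mucosa",
                   extra: pd.DataFrame | None = None) -> FeatureTable:
    """Assemble the design matrix for the initial or differential model.

    initial mode uses the baseline-stage feature values; differential mode
    uses stage-versus-baseline changes — ``log2((a+1)/(b+1))`` for
    positive-scale features (connectivity, methylation, TPM) and plain
    differences for features already on a log scale.  *extra* columns
    (e.g. TF-binding indicators) are appended as-is.  Every feature column
    is duplicated as its ascending rank transform.  Genes missing from any
    input are reported via ``X.attrs['n_dropped']`` and dropped.
    """
    if mode not in ("initial", "differential"):
        raise ValueError("mode must be 'initial' or 'differential'")
    base = stage_tables[baseline]
    if mode == "initial":
        raw = base.copy()
    else:
        cur = stage_tables[stage]
        idx = base.index.intersection(cur.index)
        raw = pd.DataFrame(index=idx)
        for col in base.columns:
            a = cur.loc[idx, col].to_numpy(dtype=float)
            b = base.loc[idx, col].to_numpy(dtype=float)
            if col in PSEUDO_FEATURES:
                raw[f"{col}_fc"] = np.log2((a + 1) / (b + 1))
            else:
                raw[f"{col}_diff"] = a - b
    if extra is not None:
        raw = raw.join(extra, how="inner")
    idx = raw.index.intersection(target.index)
    n_dropped = (len(raw) - len(idx)) + (len(target) - len(idx))
    raw = raw.loc[idx]
    y = target.loc[idx].astype(float)
    X = raw.astype(float).copy()
    for col in list(raw.columns):
        X[f"{col}_rank"] = rank_transform(raw[col].to_numpy())
    X = X.fillna(0.0)
    X.attrs["n_dropped"] = int(n_dropped)
    return FeatureTable(X=X, y=y, mode=mode)


# ---------------------------------------------------------------------------
# model training
# ---------------------------------------------------------------------------

@dataclass
class TwoPhaseModel:
    """Trained regressor with its held-out split and selection record."""

    regressor: DropoutMLPRegressor
    feature_names: list[str]
    train_idx: np.ndarray = field(repr=False)
    test_idx: np.ndarray = field(repr=False)
    selected_epoch: int = 0
    heldout_predictions: np.ndarray = field(repr=False, default=None)
    heldout_r: float = float("nan")

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.regressor.predict(X[self.feature_names].to_numpy())


def train_model(table: FeatureTable, test_n: int = 2800, epochs: int = 50,
                seed: int = 0, hidden: tuple[int, ...] = (2048, 512, 128),
                dropout: float = 0.2, batch_size: int = 128,
                lr: float = 1e-3) -> TwoPhaseModel:
    """Train the two-phase regressor with a seeded held-out split.

    *test_n* genes are excluded at random as the held-out set; the model is
    trained for up to *epochs* epochs and the returned weights are those of
    the epoch with the lowest held-out MSE.  Identical seeds give identical
    splits and selected epochs.
    """
    n = len(table.X)
    if n <= test_n:
        raise ValueError("table must have more rows than test_n")
    rng = np.random.default_rng([seed, 31337])
    perm = rng.permutation(n)
    test_idx = np.sort(perm[:test_n])
    train_idx = np.sort(perm[test_n:])
    X = table.X.to_numpy(dtype=float)
    y = table.y.to_numpy(dtype=float)
    reg = DropoutMLPRegressor(hidden=hidden, dropout=dropout, epochs=epochs,
                              batch_size=batch_size, lr=lr, seed=seed)
    reg.fit(X[train_idx], y[train_idx], X[test_idx], y[test_idx])
    pred = reg.predict(X[test_idx])
    r = float(np.corrcoef(pred, y[test_idx])[0, 1])
    return TwoPhaseModel(regressor=reg, feature_names=list(table.X.columns),
                         train_idx=train_idx, test_idx=test_idx,
                         selected_epoch=reg.selected_epoch_,
                         heldout_predictions=pred, heldout_r=r)


def heldout_permutation_pvalue(model: TwoPhaseModel, table: FeatureTable,
                               n_perm: int = 999, seed: int = 0) -> float:
    """Permutation p-value for the held-out correlation.

    Null: predicted and observed held-out values are unrelated; generated by
    re-pairing predictions with permuted observations.  One-sided (observed
    r at least as large as null r)."""
    y = table.y.to_numpy(dtype=float)[model.test_idx]
    pred = model.heldout_predictions
    obs = np.corrcoef(pred, y)[0, 1]
    rng = np.random.default_rng([seed, 55555])
    null = np.array([np.corrcoef(pred, rng.permutation(y))[0, 1]
                     for _ in range(n_perm)])
    return float((1 + np.sum(null >= obs)) / (1 + n_perm))


# ---------------------------------------------------------------------------
# attribution
# ---------------------------------------------------------------------------

def feature_importance(model: TwoPhaseModel, table: FeatureTable,
                       n_repeats: int = 5, seed: int = 0,
                       max_rows: int | None = 4000) -> pd.DataFrame:
    """Permutation-based attribution per feature.

    Per gene and feature, the attribution is the mean (over *n_repeats*
    seeded permutations) of ``f(x) - f(x with that feature's column
    permuted)``.  Average importance is the absolute mean of the
    attributions across genes; directionality is the attribution mean
    oriented by whether the gene's feature value lies above the feature
    median, positive when high values push predictions up.
    """
    rng = np.random.default_rng([seed, 77777])
    X = table.X.to_numpy(dtype=float)
    if max_rows is not None and len(X) > max_rows:
        rows = rng.choice(len(X), size=max_rows, replace=False)
        X = X[rows]
    base_pred = model.regressor.predict(X)
    records = []
    medians = np.median(X, axis=0)
    for j, name in enumerate(table.X.columns):
        attr = np.zeros(len(X))
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = X[rng.permutation(len(X)), j]
            attr += base_pred - model.regressor.predict(Xp)
        attr /= n_repeats
        orient = np.sign(X[:, j] - medians[j])
        records.append({"feature": name,
                        "importance": float(np.mean(np.abs(attr))),
                        "direction": float(np.mean(attr * orient))})
    return (pd.DataFrame(records)
            .sort_values("importance", ascending=False)
            .reset_index(drop=True))


def shapley_attribution(predict, X: np.ndarray,
                        baseline: np.ndarray | None = None) -> np.ndarray:
    """Exact Shapley values by subset enumeration (oracle for small models).

    The value of a coalition S is the model output with features outside S
    replaced by the column baseline (default: column means).  Complexity is
    O(2^d); intended for d <= ~12 feature toy models only.
    """
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if d > 14:
        raise ValueError("exact Shapley is exponential; use <= 14 features")
    if baseline is None:
        baseline = X.mean(axis=0)
    all_feats = list(range(d))
    # cache v(S) for all subsets
    values = {}
    for r in range(d + 1):
        for S in combinations(all_feats, r):
            Xs = np.tile(baseline, (n, 1))
            if S:
                Xs[:, list(S)] = X[:, list(S)]
            values[S] = predict(Xs)
    phi = np.zeros((n, d))
    for j in all_feats:
        rest = [f for f in all_feats if f != j]
        for r in range(d):
            for S in combinations(rest, r):
                w = factorial(len(S)) * factorial(d - len(S) - 1) / factorial(d)
                phi[:, j] += w * (values[tuple(sorted(S + (j,)))] - values[S])
    return phi


# ---------------------------------------------------------------------------
# directionality & evaluation
# ---------------------------------------------------------------------------

def directionality_score(calls) -> np.ndarray:
    """Mean of coded calls (-1 down, 0 unchanged, +1 up) per gene.

    *calls* is an (n_genes, n_cohorts) array-like; a 1-D input is treated
    as a single gene's calls.
    """
    arr = np.asarray(calls, dtype=float)
    if arr.ndim == 1:
        if arr.size == 0:
            raise ValueError("at least one call required")
        return float(arr.mean())
    if arr.shape[1] == 0:
        raise ValueError("at least one call required")
    return arr.mean(axis=1)


def direction_prediction_eval(predicted_fc: np.ndarray, calls: np.ndarray,
                              bins: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)
                              ) -> tuple[float, pd.DataFrame]:
    """ROC and score-stratified accuracy of direction prediction.

    Genes with a nonzero directionality score are labeled up (score > 0) or
    down; the AUC uses the predicted fold change as the ranking score.
    Accuracy (sign of predicted fold change matching the label) is reported
    per |directionality score| bin.
    """
    predicted_fc = np.asarray(predicted_fc, dtype=float)
    score = directionality_score(calls)
    nz = score != 0
    if not nz.any():
        raise ValueError("no genes with nonzero observed calls")
    label_up = score[nz] > 0
    auc = float(roc_auc_score(label_up, predicted_fc[nz]))
    correct = np.sign(predicted_fc[nz]) == np.where(label_up, 1, -1)
    mag = np.abs(score[nz])
    rows = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        m = (mag > lo) & (mag <= hi)
        rows.append({"bin_low": lo, "bin_high": hi, "n": int(m.sum()),
                     "accuracy": float(correct[m].mean()) if m.any() else np.nan})
    return auc, pd.DataFrame(rows)


def correlation_shift(connectivity: dict[str, np.ndarray],
                      expression: dict[str, np.ndarray],
                      tpm_min: float = 0.5) -> pd.DataFrame:
    """Per-stage Spearman rho between connectivity and expression of active
    genes (TPM > *tpm_min*), with the shift relative to the first stage."""
    rows = []
    stages = list(connectivity)
    rho0 = None
    for stage in stages:
        c = np.asarray(connectivity[stage], dtype=float)
        e = np.asarray(expression[stage], dtype=float)
        act = e > tpm_min
        rho = float(stats.spearmanr(c[act], e[act]).statistic) if act.sum() > 2 else np.nan
        if rho0 is None:
            rho0 = rho
        rows.append({"stage": stage, "n_active": int(act.sum()),
                     "rho": rho, "delta_rho": rho - rho0})
    return pd.DataFrame(rows)
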