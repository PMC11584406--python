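import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cisconn import synthetic, twophase as tp
from cisconn.regressor import DropoutMLPRegressor


class TestRankTransform:
    def test_ties_averaged_ascending(self):
        assert list(tp.rank_transform([3.0, 1.0, 1.0, 2.0])) == [4.0, 1.5, 1.5, 3.0]

    @given(st.lists(st.integers(min_value=-1000, max_value=1000),
                    min_size=3, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_monotone_rescaling(self, xs):
        xs = np.asarray(xs, dtype=float)
        assert np.allclose(tp.rank_transform(xs),
                           tp.rank_transform(np.exp(xs / 50.0)))


def toy_stage_tables(n=50, seed=0):
    rng = np.random.default_rng(seed)
    idx = pd.Index([f"g{k}" for k in range(n)], name="gene_id")
    tables = {}
    for stage, scale in zip(("mucosa", "polyp", "adenocarcinoma"), (1.0, 0.8, 0.6)):
        tables[stage] = pd.DataFrame({
            "connectivity": rng.lognormal(0.5, 0.5, n) * scale,
            "promoter_methylation": rng.uniform(0, 80, n),
            "promoter_stripe": rng.normal(0, 1, n),
            "tpm": rng.lognormal(2, 1, n) * scale,
        }, index=idx)
    return tables


class TestBuildFeatures:
    def test_rank_augmentation_doubles_columns(self):
        tables = toy_stage_tables()
        target = tables["mucosa"]["connectivity"] * 0 + 1.0
        ft = tp.build_features(tables, "initial", target=target)
        assert ft.n_features == 8  # 4 raw + 4 rank

    def test_fold_change_pseudocount_zero_to_zero(self):
        tables = toy_stage_tables()
        tables["mucosa"].loc["g0", "connectivity"] = 0.0
        tables["polyp"].loc["g0", "connectivity"] = 0.0
        ft = tp.build_features(tables, "differential",
                               target=tables["mucosa"]["tpm"], stage="polyp")
        assert ft.X.loc["g0", "connectivity_fc"] == pytest.approx(0.0)

    def test_log_scale_features_use_difference(self):
        tables = toy_stage_tables()
        ft = tp.build_features(tables, "differential",
                               target=tables["mucosa"]["tpm"], stage="polyp")
        g = "g3"
        expect = (tables["polyp"].loc[g, "promoter_stripe"]
                  - tables["mucosa"].loc[g, "promoter_stripe"])
        assert ft.X.loc[g, "promoter_stripe_diff"] == pytest.approx(expect)

    def test_row_content_invariant_to_gene_order(self):
        tables = toy_stage_tables()
        target = tables["mucosa"]["tpm"]
        ft1 = tp.build_features(tables, "initial", target=target)
        shuffled = {s: t.sample(frac=1, random_state=1)
                    for s, t in tables.items()}
        ft2 = tp.build_features(shuffled, "initial", target=target)
        g = "g7"
        assert np.allclose(ft1.X.loc[g], ft2.X.loc[g])

    def test_gene_mismatch_reported_and_dropped(self):
        tables = toy_stage_tables()
        target = tables["mucosa"]["tpm"].iloc[:40]
        ft = tp.build_features(tables, "initial", target=target)
        assert len(ft.X) == 40
        assert ft.X.attrs["n_dropped"] == 10

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            tp.build_features(toy_stage_tables(), "both", target=pd.Series())


def planted_table(n=2000, seed=0, noise_frac=0.5, n_noise_features=3,
                  include_ranks=True):
    """Target generated directly from the feature columns."""
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({f"x{k}": rng.normal(0, 1, n) for k in range(3 + n_noise_features)},
                     index=pd.Index([f"g{k}" for k in range(n)], name="gene_id"))
    signal = 1.0 * X["x0"] - 0.6 * X["x1"] + 0.5 * np.minimum(X["x2"], 0.5)
    y = signal + rng.normal(0, noise_frac * signal.std(), n)
    ft_X = X.copy()
    if include_ranks:
        for col in X.columns:
            ft_X[f"{col}_rank"] = tp.rank_transform(X[col])
    return tp.FeatureTable(X=ft_X, y=pd.Series(y, index=X.index), mode="initial")


class TestTrainModel:
    def test_recovery_under_known_generative_model(self):
        table = planted_table(n=10_000, seed=1)
        model = tp.train_model(table, test_n=2800, epochs=25, seed=1,
                               hidden=(64, 32, 16))
        assert model.heldout_r >= 0.7

    def test_pure_noise_target_has_no_skill(self):
        table = planted_table(n=4000, seed=2)
        rng = np.random.default_rng(0)
        null = tp.FeatureTable(X=table.X,
                               y=pd.Series(rng.normal(0, 1, len(table.X)),
                                           index=table.X.index),
                               mode="initial")
        model = tp.train_model(null, test_n=1000, epochs=10, seed=2,
                               hidden=(32, 16))
        assert abs(model.heldout_r) < 0.1

    def test_seed_reproducibility(self):
        table = planted_table(n=1200, seed=3)
        m1 = tp.train_model(table, test_n=300, epochs=6, seed=7, hidden=(16, 8))
        m2 = tp.train_model(table, test_n=300, epochs=6, seed=7, hidden=(16, 8))
        assert np.array_equal(m1.test_idx, m2.test_idx)
        assert m1.selected_epoch == m2.selected_epoch
        assert np.allclose(m1.heldout_predictions, m2.heldout_predictions)

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            tp.train_model(planted_table(n=100), test_n=2800)


class TestRegressor:
    def test_fit_learns_linear_map(self):
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, (2000, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0])
        reg = DropoutMLPRegressor(hidden=(32, 16), dropout=0.1, epochs=30,
                                  seed=0)
        reg.fit(X[:1500], y[:1500], X[1500:], y[1500:])
        r = np.corrcoef(reg.predict(X[1500:]), y[1500:])[0, 1]
        assert r > 0.97

    def test_selected_epoch_minimizes_validation_mse(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (600, 3))
        y = X[:, 0] + rng.normal(0, 0.5, 600)
        reg = DropoutMLPRegressor(hidden=(16,), epochs=12, seed=1)
        reg.fit(X[:400], y[:400], X[400:], y[400:])
        assert reg.selected_epoch_ == int(np.argmin(reg.val_mse_path_)) + 1


class TestAttribution:
    def _fitted(self, n=3000):
        # raw columns only: rank duplicates are near-copies of the raw
        # features and would split permutation importance between them
        table = planted_table(n=n, seed=4, n_noise_features=2,
                              include_ranks=False)
        model = tp.train_model(table, test_n=500, epochs=15, seed=4,
                               hidden=(32, 16))
        return table, model

    def test_planted_effects_recovered(self):
        table, model = self._fitted()
        imp = tp.feature_importance(model, table, seed=4).set_index("feature")
        # dominant positive-effect feature ranks highest among raw columns
        raw = imp.loc[[f"x{k}" for k in range(5)]]
        assert raw["importance"].idxmax() == "x0"
        assert imp.loc["x0", "direction"] > 0
        assert imp.loc["x1", "direction"] < 0
        # unused feature sits near the noise floor
        assert imp.loc["x3", "importance"] < 0.2 * imp.loc["x0", "importance"]

    def test_importance_invariant_to_column_order(self):
        table, model = self._fitted(n=1500)
        imp1 = tp.feature_importance(model, table, seed=9).set_index("feature")
        shuffled_cols = list(table.X.columns)[::-1]
        table2 = tp.FeatureTable(X=table.X[shuffled_cols], y=table.y,
                                 mode="initial")
        model2 = tp.TwoPhaseModel(
            regressor=_Reordered(model, list(table.X.columns), shuffled_cols),
            feature_names=shuffled_cols, train_idx=model.train_idx,
            test_idx=model.test_idx)
        imp2 = tp.feature_importance(model2, table2, seed=9).set_index("feature")
        assert np.allclose(imp1.loc["x0", "importance"],
                           imp2.loc["x0", "importance"], rtol=0.2)

    def test_exact_shapley_linear_closed_form(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 1, (40, 5))
        beta = np.array([2.0, -1.0, 0.5, 0.0, 1.5])

        def predict(A):
            return A @ beta

        phi = tp.shapley_attribution(predict, X)
        closed = (X - X.mean(axis=0)) * beta
        assert np.allclose(phi, closed, atol=1e-8)

    def test_direction_sign_agrees_with_shapley(self):
        table, model = self._fitted(n=1500)
        imp = tp.feature_importance(model, table, seed=4).set_index("feature")
        X = table.X.to_numpy()[:150]
        phi = tp.shapley_attribution(lambda A: model.regressor.predict(A), X)
        med = np.median(table.X.to_numpy(), axis=0)
        for j, name in enumerate(table.X.columns):
            if name not in ("x0", "x1"):
                continue
            oriented = float(np.mean(phi[:, j] * np.sign(X[:, j] - med[j])))
            assert np.sign(oriented) == np.sign(imp.loc[name, "direction"])


class _Reordered:
    """Adapter presenting a trained regressor under permuted columns."""

    def __init__(self, model, orig_cols, new_cols):
        self._model = model
        self._perm = [new_cols.index(c) for c in orig_cols]

    def predict(self, X):
        return self._model.regressor.predict(np.asarray(X)[:, self._perm])


class TestDirectionality:
    @pytest.mark.parametrize("calls,score", [
        ([1, 1, 1, -1], 0.5),
        ([0, 0, 0], 0.0),
        ([1, 1, 1, 1], 1.0),
    ])
    def test_examples(self, calls, score):
        assert tp.directionality_score(calls) == pytest.approx(score)

    def test_empty_calls_rejected(self):
        with pytest.raises(ValueError):
            tp.directionality_score([])


class TestDirectionPredictionEval:
    def test_perfect_ordering_auc_one(self):
        calls = np.array([[1, 1], [1, 1], [-1, -1], [-1, -1]])
        pred = np.array([2.0, 1.0, -1.0, -2.0])
        auc, accs = tp.direction_prediction_eval(pred, calls)
        assert auc == pytest.approx(1.0)
        assert accs.loc[accs["bin_high"] == 1.0, "accuracy"].iloc[0] == 1.0

    def test_random_predictions_auc_near_half(self):
        rng = np.random.default_rng(3)
        calls = rng.choice([-1, 1], size=(4000, 3))
        pred = rng.normal(0, 1, 4000)
        auc, _ = tp.direction_prediction_eval(pred, calls)
        assert abs(auc - 0.5) < 0.05

    def test_all_zero_calls_rejected(self):
        with pytest.raises(ValueError):
            tp.direction_prediction_eval(np.zeros(3), np.zeros((3, 2)))


class TestCorrelationShift:
    def test_exact_monotone_gives_rho_one(self):
        c = np.linspace(1, 10, 50)
        out = tp.correlation_shift({"mucosa": c}, {"mucosa": c ** 2})
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_independent_expression_near_zero(self):
        rng = np.random.default_rng(0)
        c = rng.lognormal(0, 1, 3000)
        e = rng.lognormal(1, 1, 3000)
        out = tp.correlation_shift({"mucosa": c}, {"mucosa": e})
        assert abs(out.loc[0, "rho"]) < 0.06

    def test_active_gene_filter(self):
        c = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([0.1, 0.2, 5.0, 6.0])  # two genes below TPM 0.5
        out = tp.correlation_shift({"mucosa": c}, {"mucosa": e})
        assert out.loc[0, "n_active"] == 2
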