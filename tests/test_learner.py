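"""Embeddings, stacked RF+GP model, acquisition, consensus, campaigns."""

import numpy as np
import pandas as pd
import pytest

from agglearn import learner
from agglearn.learner import (
    EmbeddingMatrix,
    TrainingSet,
    acquisition_rank,
    benchmark_models,
    consensus_select,
    embed_library,
    fit_stacked,
    make_initial_training_set,
    optimization_rate,
    predict_with_uncertainty,
    run_campaign,
)
from agglearn.kinetics import RateSummary


def toy_training(n=40, d=5, seed=0, target_fn=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, d))
    if target_fn is None:
        target_fn = lambda X: 2 + np.abs(X[:, 0]) + 0.5 * X[:, 1] ** 2
    y = target_fn(X)
    return TrainingSet(tuple(f"m{i:03d}" for i in range(n)), X, y)


class TestEmbedLibrary:
    def test_external_latents_passthrough(self, tiny_library):
        ids = [r.id for r in tiny_library]
        ext = pd.DataFrame(
            np.arange(len(ids) * 3, dtype=float).reshape(len(ids), 3),
            index=pd.Index(ids, name="id"),
        ).reset_index()
        emb = embed_library(tiny_library, external_latents=ext)
        assert emb.source == "external-latent"
        assert np.array_equal(emb.vectors, ext.set_index("id").to_numpy())

    def test_missing_external_id_raises(self, tiny_library):
        ext = pd.DataFrame({"id": ["m01"], "z0": [1.0]})
        with pytest.raises(KeyError):
            embed_library(tiny_library, external_latents=ext)

    def test_duplicate_molecules_identical_rows(self, tiny_library):
        from agglearn.chemspace import make_record

        lib = tiny_library + [make_record("m01b", tiny_library[0].smiles_std)]
        emb = embed_library(lib)
        i = emb.molecule_ids.index("m01")
        j = emb.molecule_ids.index("m01b")
        assert np.allclose(emb.vectors[i], emb.vectors[j])

    def test_fallback_matches_eigendecomposition_oracle(self, small_library):
        lib = list(small_library.molecules[:100])
        emb = embed_library(lib, target_dim=8)
        assert emb.source == "fingerprint-pca"
        X = np.stack([r.fingerprint for r in lib]).astype(float)
        Xc = X - X.mean(axis=0)
        # independent oracle: direct eigendecomposition of the covariance
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1][:8]
        proj = Xc @ evecs[:, order]
        for k in range(8):
            got, exp = emb.vectors[:, k], proj[:, k]
            assert np.allclose(got, exp, atol=1e-6) or np.allclose(got, -exp, atol=1e-6)

    def test_deterministic(self, tiny_library):
        a = embed_library(tiny_library)
        b = embed_library(tiny_library)
        assert np.array_equal(a.vectors, b.vectors)


class TestStackedModel:
    def test_constant_target_predicts_constant(self):
        ts = toy_training(target_fn=lambda X: np.full(len(X), 3.7))
        model = fit_stacked(ts, seed=0, n_trees=30)
        pred, _ = predict_with_uncertainty(
            model, EmbeddingMatrix(ts.molecule_ids, ts.features, "fingerprint-pca")
        )
        assert np.allclose(pred, 3.7, atol=1e-6)

    def test_refit_same_seed_identical(self):
        ts = toy_training()
        emb = EmbeddingMatrix(ts.molecule_ids, ts.features, "fingerprint-pca")
        p1, u1 = predict_with_uncertainty(fit_stacked(ts, seed=5, n_trees=30), emb)
        p2, u2 = predict_with_uncertainty(fit_stacked(ts, seed=5, n_trees=30), emb)
        assert np.array_equal(p1, p2) and np.array_equal(u1, u2)

    def test_degenerate_features_rejected(self):
        ts = toy_training()
        flat = TrainingSet(ts.molecule_ids, np.ones_like(ts.features), ts.target)
        with pytest.raises(ValueError, match="constant"):
            fit_stacked(flat, seed=0)

    def test_beats_linear_baseline_on_nonlinear_landscape(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(200, 6))
        y = 2 + np.sin(2 * X[:, 0]) + X[:, 1] ** 2 + rng.normal(0, 0.1, 200)
        ts = TrainingSet(tuple(f"m{i}" for i in range(150)), X[:150], y[:150])
        model = fit_stacked(ts, seed=0, n_trees=100)
        hold = X[150:]
        pred = model.predict(hold)
        from sklearn.linear_model import LinearRegression
        lin = LinearRegression().fit(X[:150], y[:150]).predict(hold)
        sse = lambda p: np.sum((y[150:] - p) ** 2)
        assert sse(pred) < sse(lin)

    def test_training_point_interpolation_sane(self):
        ts = toy_training()
        model = fit_stacked(ts, seed=0, n_trees=100)
        emb = EmbeddingMatrix(ts.molecule_ids, ts.features, "fingerprint-pca")
        pred, _ = predict_with_uncertainty(model, emb)
        rmse = np.sqrt(np.mean((pred - ts.target) ** 2))
        assert np.all(np.abs(pred - ts.target) <= max(3 * rmse, 0.5))

    def test_uncertainty_grows_away_from_data(self):
        # 1-D toy: training cluster at 0, probe 10 lengthscales away
        rng = np.random.default_rng(0)
        X = rng.normal(0, 1, size=(30, 1))
        ts = TrainingSet(tuple(f"m{i}" for i in range(30)), X, 2 + X[:, 0] ** 2)
        model = fit_stacked(ts, seed=0, n_trees=30)
        near = EmbeddingMatrix(("a",), X[:1], "fingerprint-pca")
        far = EmbeddingMatrix(("b",), np.array([[50.0]]), "fingerprint-pca")
        _, u_near = predict_with_uncertainty(model, near)
        _, u_far = predict_with_uncertainty(model, far)
        assert u_near[0] < u_far[0]

    def test_empty_candidates_empty_output(self):
        ts = toy_training()
        model = fit_stacked(ts, seed=0, n_trees=30)
        empty = EmbeddingMatrix((), np.empty((0, 5)), "fingerprint-pca")
        pred, unc = predict_with_uncertainty(model, empty)
        assert len(pred) == 0 and len(unc) == 0

    def test_dimension_mismatch_rejected(self):
        ts = toy_training(d=5)
        model = fit_stacked(ts, seed=0, n_trees=30)
        bad = EmbeddingMatrix(("a",), np.zeros((1, 7)), "fingerprint-pca")
        with pytest.raises(ValueError, match="dimension"):
            predict_with_uncertainty(model, bad)


class TestAcquisition:
    def test_beta_zero_orders_by_prediction(self):
        ids = ["a", "b", "c"]
        ranking = acquisition_rank(ids, np.array([1.0, 3.0, 2.0]),
                                   np.array([9.0, 9.0, 0.1]), beta=0.0)
        assert [r.molecule_id for r in ranking] == ["b", "c", "a"]

    def test_equal_predictions_order_by_uncertainty(self):
        ids = ["a", "b", "c"]
        ranking = acquisition_rank(ids, np.ones(3), np.array([0.3, 0.1, 0.2]), beta=1.0)
        assert [r.molecule_id for r in ranking] == ["b", "c", "a"]

    def test_hand_computed_five_candidates(self):
        ids = ["m1", "m2", "m3", "m4", "m5"]
        pred = np.array([4.0, 3.5, 3.0, 2.5, 2.0])
        unc = np.array([2.0, 0.5, 0.2, 0.1, 0.1])
        # scores: 2.0, 3.0, 2.8, 2.4, 1.9
        ranking = acquisition_rank(ids, pred, unc, beta=1.0)
        assert [r.molecule_id for r in ranking] == ["m2", "m3", "m4", "m1", "m5"]
        assert [r.rank for r in ranking] == [0, 1, 2, 3, 4]

    def test_score_strictly_decreasing_in_uncertainty(self):
        base = acquisition_rank(["x"], np.array([2.0]), np.array([0.5]), beta=1.5)[0]
        worse = acquisition_rank(["x"], np.array([2.0]), np.array([0.6]), beta=1.5)[0]
        assert worse.score < base.score

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            acquisition_rank(["a"], np.array([np.nan]), np.array([0.0]))

    def test_tie_broken_by_ascending_id(self):
        ranking = acquisition_rank(["z", "a"], np.ones(2), np.zeros(2))
        assert [r.molecule_id for r in ranking] == ["a", "z"]


class TestConsensus:
    def _setup(self, n_cand=80):
        ts = toy_training(n=40, d=4, seed=1)
        rng = np.random.default_rng(2)
        cand = EmbeddingMatrix(
            tuple(f"c{i:03d}" for i in range(n_cand)),
            rng.normal(size=(n_cand, 4)), "fingerprint-pca",
        )
        return ts, cand

    def test_frequencies_match_manual_re_run_tally(self):
        ts, cand = self._setup()
        kw = dict(n_runs=3, top_n=10, freq_threshold=0.0, beta=1.0, n_trees=20)
        got = consensus_select(ts, cand, seed=7, **kw)
        # independent tally: replay the three runs with the same derived seeds
        run_seeds = np.random.default_rng(7).integers(0, 2**31 - 1, size=3)
        counts = {}
        for rs in run_seeds:
            model = fit_stacked(ts, seed=int(rs), n_trees=20)
            pred, unc = predict_with_uncertainty(model, cand)
            for e in acquisition_rank(cand.molecule_ids, pred, unc, beta=1.0)[:10]:
                counts[e.molecule_id] = counts.get(e.molecule_id, 0) + 1
        expected = {m: c / 3 for m, c in counts.items()}
        assert got == dict(sorted(expected.items(), key=lambda kv: (-kv[1], kv[0])))

    def test_threshold_nesting(self):
        ts, cand = self._setup()
        kw = dict(n_runs=4, top_n=10, beta=1.0, n_trees=20)
        strict = consensus_select(ts, cand, seed=3, freq_threshold=0.8, **kw)
        loose = consensus_select(ts, cand, seed=3, freq_threshold=0.5, **kw)
        assert set(strict) <= set(loose)
        assert all(f == loose[m] for m, f in strict.items())

    def test_unanimous_threshold_requires_every_run(self):
        ts, cand = self._setup()
        sel = consensus_select(ts, cand, seed=3, n_runs=4, top_n=10,
                               freq_threshold=1.0 - 1e-9, beta=1.0, n_trees=20)
        assert all(f == 1.0 for f in sel.values())
        assert len(sel) <= 10

    def test_candidate_overlap_rejected(self):
        ts, _ = self._setup()
        cand = EmbeddingMatrix(ts.molecule_ids[:5], ts.features[:5], "fingerprint-pca")
        with pytest.raises(ValueError, match="overlap"):
            consensus_select(ts, cand, seed=0, n_runs=2)


class TestOptimizationRate:
    @pytest.mark.parametrize(
        "potent,total,expected",
        [(8, 64, 12.5), (11, 64, 17.1875), (12, 56, 21.428571), (0, 10, 0.0)],
    )
    def test_rates(self, potent, total, expected):
        flags = [True] * potent + [False] * (total - potent)
        assert optimization_rate(flags) == pytest.approx(expected)

    def test_accepts_rate_summaries(self):
        rs = [
            RateSummary("a", 10, 2.5, False, True),
            RateSummary("b", 10, 1.0, False, False),
        ]
        assert optimization_rate(rs) == 50.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            optimization_rate([])


@pytest.fixture(scope="module")
def mini_campaign_world():
    from agglearn import synthdata

    lib = synthdata.landscape_potency(
        synthdata.generate_library(250, seed=11), synthdata.LandscapeSpec(seed=11)
    )
    emb = embed_library(lib.molecules, target_dim=16)
    oracle = synthdata.campaign_oracle(lib)
    return lib, emb, oracle


class TestCampaign:
    KW = dict(n_runs=3, top_n=30, n_trees=20)

    def test_training_set_grows_by_batch(self, mini_campaign_world):
        _, emb, oracle = mini_campaign_world
        init = make_initial_training_set(emb, oracle, 30, seed=0)
        state = run_campaign(init, emb, oracle, n_iterations=2, batch_size=15,
                             seed=0, **self.KW)
        assert len(state.training_set.target) == 30 + 2 * 15
        assert state.iteration == 2
        assert len(state.optimization_rates) == 2

    def test_selections_disjoint_from_training(self, mini_campaign_world):
        _, emb, oracle = mini_campaign_world
        init = make_initial_training_set(emb, oracle, 30, seed=0)
        state = run_campaign(init, emb, oracle, n_iterations=2, batch_size=15,
                             seed=0, **self.KW)
        seen = set(init.molecule_ids)
        for sel in state.selections:
            assert not (set(sel) & seen)
            seen |= set(sel)

    def test_identical_seeds_identical_trajectories(self, mini_campaign_world):
        _, emb, oracle = mini_campaign_world
        init = make_initial_training_set(emb, oracle, 30, seed=4)
        a = run_campaign(init, emb, oracle, n_iterations=2, batch_size=10,
                         seed=9, **self.KW)
        b = run_campaign(init, emb, oracle, n_iterations=2, batch_size=10,
                         seed=9, **self.KW)
        assert a.selections == b.selections
        assert a.optimization_rates == b.optimization_rates


class TestBenchmarks:
    def test_perfect_predictor_scores_perfectly(self):
        # feature 0 IS the target, so a linear model predicts it exactly
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 3))
        y = 10.0 + X[:, 0]
        ts = TrainingSet(tuple(f"m{i}" for i in range(50)), X, y)
        from sklearn.linear_model import LinearRegression

        reports = benchmark_models(ts, {"oracle": LinearRegression()}, cv_folds=5)
        assert reports[0].r2 == pytest.approx(1.0, abs=1e-9)
        assert reports[0].mae == pytest.approx(0.0, abs=1e-9)

    def test_constant_predictor_nonpositive_r2(self):
        from sklearn.dummy import DummyRegressor

        ts = toy_training(n=50)
        reports = benchmark_models(ts, {"dummy": DummyRegressor()}, cv_folds=5)
        assert reports[0].r2 <= 0.0

    def test_rmse_at_least_mae_for_default_roster(self):
        ts = toy_training(n=60)
        reports = benchmark_models(ts, cv_folds=3, seed=1, n_trees=30)
        names = {r.model_name for r in reports}
        assert {"stacked-rf-gp", "rf", "gp", "linear"} <= names
        for r in reports:
            assert r.rmse >= r.mae >= 0

    def test_stacked_not_much_worse_than_rf_alone(self):
        ts = toy_training(n=80, seed=2)
        reports = {r.model_name: r for r in benchmark_models(ts, cv_folds=4, seed=0,
                                                             n_trees=60)}
        assert reports["stacked-rf-gp"].r2 >= reports["rf"].r2 - 0.05

    def test_excess_folds_rejected(self):
        ts = toy_training(n=12)
        with pytest.raises(ValueError):
            benchmark_models(ts, cv_folds=20)
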