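import numpy as np
import pytest

from flavodoe import (
    GroundTruth,
    TrainConfig,
    evaluate,
    latin_hypercube,
    quadratic_truth,
    simulate_responses,
    split_data,
    train,
)
from flavodoe.ann import _forward_residuals, select_hidden_size


def _lhs_data(seed, sigma):
    d = latin_hypercube(51, 3, seed=[seed, 101], factor_names=["ratio", "temperature", "ethanol"])
    y = simulate_responses(d, GroundTruth(sigma=sigma), seed=[seed, 102])
    return d.levels, y


class TestSplit:
    def test_sizes_with_remainder_to_training(self):
        tr, va, te = split_data(51, (0.70, 0.15, 0.15), seed=1)
        assert (len(tr), len(va), len(te)) == (36, 8, 7)

    def test_disjoint_exhaustive_reproducible(self):
        tr, va, te = split_data(40, seed=5)
        again = split_data(40, seed=5)
        assert all(np.array_equal(a, b) for a, b in zip((tr, va, te), again))
        union = np.concatenate([tr, va, te])
        assert sorted(union) == list(range(40))
        assert len(set(union)) == 40

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_data(3, (0.70, 0.15, 0.15), seed=0)
        with pytest.raises(ValueError):
            split_data(51, (0.5, 0.3, 0.3), seed=0)


class TestTraining:
    def test_linear_target_reaches_goal(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(-1, 1, (60, 3))
        y = 2.0 + X @ np.array([1.0, -0.5, 0.25])
        model, hist = train(X, y, hidden=4, config=TrainConfig(seed=0))
        assert hist.stop_reason in ("goal", "validation_failures", "damping_overflow")
        assert min(hist.train_mse) <= 1e-5  # representable function is crushed

    def test_noise_free_surrogate_capacity(self):
        """4 tanh units represent the quadratic surface: test R2 >= 0.99 in >= 8/10 seeds."""
        hits = 0
        for seed in range(10):
            X, y = _lhs_data(seed, sigma=0.0)
            model, _ = train(X, y, hidden=4, config=TrainConfig(seed=seed))
            _, _, te = split_data(51, seed=seed)
            hits += evaluate(model, X[te], y[te]).r_squared >= 0.99
        assert hits >= 8

    def test_deterministic_under_seed(self):
        X, y = _lhs_data(3, sigma=0.251)
        m1, h1 = train(X, y, hidden=4, config=TrainConfig(seed=7))
        m2, h2 = train(X, y, hidden=4, config=TrainConfig(seed=7))
        np.testing.assert_array_equal(m1.W1, m2.W1)
        assert h1.train_mse == h2.train_mse

    def test_loss_never_worse_than_initialization(self):
        for seed in range(5):
            X, y = _lhs_data(seed, sigma=0.251)
            conf = TrainConfig(seed=seed)
            model, hist = train(X, y, hidden=4, config=conf)
            tr, _, _ = split_data(51, conf.fractions, seed)
            from flavodoe.ann import _MinMax, _init_params

            Zx = _MinMax.fit(X).normalize(X)
            zy = _MinMax.fit(y[:, None]).normalize(y[:, None])[:, 0]
            r0, _ = _forward_residuals(_init_params(3, 4, seed), Zx[tr], zy[tr], 3, 4)
            init_mse = float(np.mean(r0**2))
            # loss at the returned (best-validation) weights
            r_ret = model.predict(X[tr]) - y[tr]
            zr = 2 * r_ret / (y.max() - y.min())
            assert float(np.mean(zr**2)) <= init_mse + 1e-12

    def test_early_stopping_contract(self):
        X, y = _lhs_data(2, sigma=0.4)
        model, hist = train(X, y, hidden=4, config=TrainConfig(seed=2))
        assert hist.best_epoch <= hist.n_epochs - 1
        assert min(hist.val_mse) == pytest.approx(hist.val_mse[hist.best_epoch])

    def test_normalization_roundtrip_and_range(self):
        X, y = _lhs_data(1, sigma=0.251)
        model, _ = train(X, y, hidden=4, config=TrainConfig(seed=1))
        z = model.y_norm.normalize(y[:, None])
        np.testing.assert_allclose(model.y_norm.denormalize(z), y[:, None], atol=1e-10)
        assert z.min() == pytest.approx(-1.0) and z.max() == pytest.approx(1.0)
        zx = model.x_norm.normalize(X)
        assert zx.min(axis=0) == pytest.approx(np.full(3, -1.0))
        assert zx.max(axis=0) == pytest.approx(np.full(3, 1.0))

    def test_serialization_roundtrip(self):
        X, y = _lhs_data(4, sigma=0.251)
        model, _ = train(X, y, hidden=4, config=TrainConfig(seed=4))
        from flavodoe.ann import MLPSurrogate

        clone = MLPSurrogate.from_dict(model.to_dict())
        np.testing.assert_allclose(clone.predict(X), model.predict(X), atol=1e-12)


class TestEvaluate:
    def test_perfect_and_mean_predictors(self):
        X, y = _lhs_data(0, sigma=0.251)
        model, _ = train(X, y, hidden=4, config=TrainConfig(seed=0))
        yhat = model.predict(X)
        m = evaluate(model, X, yhat)  # score against its own predictions
        assert m.mse == pytest.approx(0.0, abs=1e-20)
        assert m.r_squared == pytest.approx(1.0)
        assert m.pearson_r == pytest.approx(1.0)

    def test_metrics_match_brute_force(self):
        rng = np.random.default_rng(8)
        X, y = _lhs_data(8, sigma=0.251)
        model, _ = train(X, y, hidden=4, config=TrainConfig(seed=8))
        m = evaluate(model, X, y)
        yhat = model.predict(X)
        assert m.mse == pytest.approx(sum((a - b) ** 2 for a, b in zip(yhat, y)) / len(y), abs=1e-12)
        assert m.mae == pytest.approx(sum(abs(a - b) for a, b in zip(yhat, y)) / len(y), abs=1e-12)
        assert m.rmse == pytest.approx(np.sqrt(m.mse), rel=1e-12)
        ss_res = sum((a - b) ** 2 for a, b in zip(yhat, y))
        ss_tot = sum((v - np.mean(y)) ** 2 for v in y)
        assert m.r_squared == pytest.approx(1 - ss_res / ss_tot, rel=1e-10)

    def test_zero_variance_flagged(self):
        X, y = _lhs_data(0, sigma=0.251)
        model, _ = train(X, y, hidden=4, config=TrainConfig(seed=0))
        m = evaluate(model, X[:5], np.full(5, 19.0))
        assert np.isnan(m.r_squared) and np.isnan(m.pearson_r)


class TestHiddenSizeSelection:
    def test_contract_and_determinism(self):
        X, y = _lhs_data(5, sigma=0.251)
        sizes = [1, 2, 4, 6]
        h1, rows1 = select_hidden_size(X, y, sizes, TrainConfig(seed=5))
        h2, rows2 = select_hidden_size(X, y, sizes, TrainConfig(seed=5))
        assert h1 == h2
        assert len(rows1) == 4
        assert [r["val_mse"] for r in rows1] == [r["val_mse"] for r in rows2]
        best = min(r["val_mse"] for r in rows1)
        assert rows1[[r["hidden"] for r in rows1].index(h1)]["val_mse"] <= best + 1e-9

    def test_near_ties_prefer_smaller_network(self):
        X, y = _lhs_data(6, sigma=0.251)
        h, rows = select_hidden_size(X, y, [3, 3], TrainConfig(seed=6))
        assert h == 3  # identical losses -> smaller (equal) size wins deterministically
        assert rows[0]["val_mse"] == rows[1]["val_mse"]

    def test_empty_candidates_rejected(self):
        X, y = _lhs_data(0, sigma=0.251)
        with pytest.raises(ValueError):
            select_hidden_size(X, y, [])
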