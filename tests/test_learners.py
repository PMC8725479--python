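import numpy as np
import pandas as pd
import pytest

from lungrad import learners
from lungrad.learners import (
    BoostedEnsemble,
    SamplerSpec,
    WeakLearnerSpec,
    adasyn,
    ensemble_from_json,
    ensemble_to_json,
    predict_label,
    predict_score,
    random_undersample,
    smote,
    train_adaboost,
    train_margin_classifier,
    train_rusboost,
    train_smoteboost,
)


def _imbalanced(seed=0, n_maj=100, n_min=20, d=3, shift=1.0):
    rng = np.random.default_rng(seed)
    X = np.vstack([rng.normal(0, 1, (n_maj, d)), rng.normal(shift, 1, (n_min, d))])
    y = np.array([0] * n_maj + [1] * n_min)
    return X, y


# -- samplers ----------------------------------------------------------------


def test_adasyn_balance_count():
    X, y = _imbalanced()
    X2, y2 = adasyn(X, y, SamplerSpec(seed=0))
    assert (y2 == 1).sum() == 100 and (y2 == 0).sum() == 100
    assert len(X2) == 200


def test_adasyn_synthetics_in_minority_box():
    X, y = _imbalanced(seed=1)
    X2, y2 = adasyn(X, y, SamplerSpec(seed=1))
    X_min = X[y == 1]
    synth = X2[len(X):]
    assert (synth >= X_min.min(axis=0) - 1e-12).all()
    assert (synth <= X_min.max(axis=0) + 1e-12).all()


def test_adasyn_density_adaptive_allocation():
    # embedded minority points (inside the majority cloud) receive more
    # synthetics than an isolated far-away minority cluster
    rng = np.random.default_rng(0)
    X_maj = rng.normal(0, 0.5, (60, 2))
    X_embed = rng.normal(0, 0.5, (8, 2))  # aliased with the majority
    X_far = rng.normal(50, 0.5, (8, 2))  # pure minority region
    X = np.vstack([X_maj, X_embed, X_far])
    y = np.array([0] * 60 + [1] * 16)
    X2, y2 = adasyn(X, y, SamplerSpec(seed=0, k=5))
    synth = X2[len(X):]
    near_embed = (np.linalg.norm(synth, axis=1) < 25).sum()
    near_far = len(synth) - near_embed
    assert near_embed > 3 * near_far


def test_adasyn_uniform_fallback_warns():
    X_maj = np.random.default_rng(0).normal(0, 1, (30, 2)) + 100
    X_min = np.random.default_rng(1).normal(0, 1, (10, 2))
    X = np.vstack([X_maj, X_min])
    y = np.array([0] * 30 + [1] * 10)
    with pytest.warns(UserWarning, match="uniform"):
        adasyn(X, y, SamplerSpec(seed=0, k=3))


def test_smote_uniform_allocation_count():
    X, y = _imbalanced()
    X2, y2 = smote(X, y, SamplerSpec(seed=0))
    assert len(X2) - len(X) == 80  # 4 per minority point


def test_smote_k1_on_nearest_segments():
    X, y = _imbalanced(seed=2, n_maj=30, n_min=10)
    X2, _ = smote(X, y, SamplerSpec(seed=0, k=1))
    X_min = X[y == 1]
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=2).fit(X_min)
    pairs = nn.kneighbors(X_min, return_distance=False)
    for s in X2[len(X):]:
        on_segment = False
        for i, j in pairs:
            a, b = X_min[i], X_min[j]
            d = np.linalg.norm(a - b)
            if abs(np.linalg.norm(s - a) + np.linalg.norm(s - b) - d) < 1e-9:
                on_segment = True
                break
        assert on_segment


def test_smote_mean_preserved():
    X, y = _imbalanced(seed=3, n_maj=400, n_min=100)
    X2, y2 = smote(X, y, SamplerSpec(seed=0))
    X_min = X[y == 1]
    synth = X2[len(X):]
    se = X_min.std(axis=0) / np.sqrt(len(synth))
    assert (np.abs(synth.mean(axis=0) - X_min.mean(axis=0)) < 3 * se + 0.1).all()


def test_samplers_never_touch_minority_originals():
    X, y = _imbalanced(seed=4)
    for fn in (adasyn, smote):
        X2, y2 = fn(X, y, SamplerSpec(seed=0))
        np.testing.assert_array_equal(X2[: len(X)], X)
        np.testing.assert_array_equal(y2[: len(y)], y)
        assert (y2[len(y):] == 1).all()  # oversamplers add only minority points


def test_rus_published_counts():
    X, y = _imbalanced(seed=5, n_maj=127, n_min=40)
    X2, y2 = random_undersample(X, y, SamplerSpec(method="rus", seed=0))
    assert (y2 == 0).sum() == 40 and (y2 == 1).sum() == 40


def test_rus_identity_and_seed_variation():
    X, y = _imbalanced(seed=6, n_maj=40, n_min=20)
    X2, y2 = random_undersample(X, y, SamplerSpec(method="rus", ratio=0.5, seed=0))
    assert len(X2) == 60  # target majority = 40 = all of them
    a, _ = random_undersample(X, y, SamplerSpec(method="rus", seed=0))
    b, _ = random_undersample(X, y, SamplerSpec(method="rus", seed=1))
    assert len(a) == len(b)
    assert not np.array_equal(a, b)


def test_rus_infeasible_ratio():
    X, y = _imbalanced(n_maj=10, n_min=9)
    with pytest.raises(ValueError, match="infeasible"):
        random_undersample(X, y, SamplerSpec(method="rus", ratio=0.5, seed=0))


# -- boosting ----------------------------------------------------------------


def test_adaboost_alpha_closed_form():
    # stump errs on exactly 1 of 4 equally weighted points: eps=0.25
    X = np.array([[0.0], [1.0], [2.0], [3.0]])
    y = np.array([0, 0, 1, 0])
    model = train_adaboost(X, y, T=1, weak=WeakLearnerSpec(max_depth=1, min_leaf=1), seed=0)
    assert model.alphas[0] == pytest.approx(0.5 * np.log(3), abs=1e-9)


def test_adaboost_separable_training_error_zero():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(-3, 0.3, (30, 2)), rng.normal(3, 0.3, (30, 2))])
    y = np.array([0] * 30 + [1] * 30)
    model = train_adaboost(X, y, T=50, weak=WeakLearnerSpec(max_depth=1), seed=0)
    assert (model.predict(X) == y).all()


def test_adaboost_weight_normalization_each_round():
    X, y = _imbalanced(seed=7, shift=0.8)
    model = train_adaboost(X, y, T=30, seed=0)
    assert len(model.weight_sums) >= 1
    for s in model.weight_sums:
        assert s == pytest.approx(1.0, abs=1e-12)


def test_adaboost_cannot_beat_chance_single_member():
    # XOR with depth-1 stumps: weighted error is 0.5 -> single member + warning
    X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
    y = np.array([0, 1, 1, 0])
    with pytest.warns(UserWarning, match="chance"):
        model = train_adaboost(X, y, T=10, weak=WeakLearnerSpec(max_depth=1, min_leaf=1), seed=0)
    assert len(model.members) == 1
    assert model.alphas == [0.0]
    assert model.early_stop


def test_rusboost_round_subsets_balanced():
    sizes = []

    class Recording(WeakLearnerSpec):
        def build(self, random_state):
            tree = super().build(random_state)
            orig = tree.fit

            def fit(X, y, sample_weight=None):
                sizes.append((int((y == 1).sum()), int((y == 0).sum())))
                return orig(X, y, sample_weight=sample_weight)

            tree.fit = fit
            return tree

    X, y = _imbalanced(seed=8, n_maj=60, n_min=15, shift=1.5)
    train_rusboost(X, y, T=5, weak=Recording(), seed=0)
    for n_min, n_maj in sizes:
        assert n_min == 15 and n_maj == 15  # 1:1 every round


def test_rusboost_agrees_with_adaboost_on_balanced_data():
    agreements = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(-1, 1, (50, 2)), rng.normal(1, 1, (50, 2))])
        y = np.array([0] * 50 + [1] * 50)
        a = train_adaboost(X, y, T=30, seed=seed).predict(X)
        b = train_rusboost(X, y, T=30, seed=seed).predict(X)
        agreements.append((a == b).mean())
    assert np.mean(agreements) >= 0.9


def test_smoteboost_single_round():
    X, y = _imbalanced(seed=9)
    model = train_smoteboost(X, y, T=1, seed=0)
    assert len(model.members) == 1
    assert isinstance(model.score(X), np.ndarray)


def test_boosting_deterministic():
    X, y = _imbalanced(seed=10)
    for fn in (train_adaboost, train_rusboost, train_smoteboost):
        a = fn(X, y, T=10, seed=4)
        b = fn(X, y, T=10, seed=4)
        np.testing.assert_array_equal(a.score(X), b.score(X))


# -- margin classifiers ------------------------------------------------------


def test_margin_symmetric_boundary():
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(-2, 0.5, (50, 2)), rng.normal(2, 0.5, (50, 2))])
    y = np.array([0] * 50 + [1] * 50)
    model = train_margin_classifier(X, y, seed=0)
    assert abs(model.score(np.zeros((1, 2)))[0]) < 0.3


def test_cost_ratio_monotone_tradeoff():
    X, y = _imbalanced(seed=1, n_maj=120, n_min=30, shift=1.2)
    rng = np.random.default_rng(5)
    Xt = np.vstack([rng.normal(0, 1, (60, 3)), rng.normal(1.2, 1, (30, 3))])
    yt = np.array([0] * 60 + [1] * 30)
    sens, spec = [], []
    for ratio in (1.0, 3.0, 10.0):
        m = train_margin_classifier(X, y, cost_ratio=ratio, seed=0)
        pred = m.predict(Xt)
        sens.append(((pred == 1) & (yt == 1)).sum() / (yt == 1).sum())
        spec.append(((pred == 0) & (yt == 0)).sum() / (yt == 0).sum())
    assert sens == sorted(sens)
    assert spec == sorted(spec, reverse=True)


def test_cost_vs_duplication_equivalence():
    X, y = _imbalanced(seed=2, n_maj=80, n_min=20, shift=1.5)
    doubled = np.vstack([X, X[y == 1]])
    y_doubled = np.concatenate([y, np.ones((y == 1).sum(), dtype=int)])
    m_cost = train_margin_classifier(X, y, cost_ratio=2.0, seed=0)
    m_dup = train_margin_classifier(doubled, y_doubled, cost_ratio=1.0, seed=0)
    grid = np.random.default_rng(3).normal(0.5, 1.5, (200, 3))
    agreement = (m_cost.predict(grid) == m_dup.predict(grid)).mean()
    assert agreement >= 0.95


def test_margin_single_point_class_error():
    X = np.array([[0.0], [1.0], [2.0]])
    y = np.array([0, 0, 1])
    with pytest.raises(ValueError, match=">= 2"):
        train_margin_classifier(X, y)


# -- scoring / serialization -------------------------------------------------


def test_single_tree_score_is_sign():
    X, y = _imbalanced(seed=11, shift=3.0)
    model = train_adaboost(X, y, T=1, seed=0)
    model.alphas = [1.0]
    s = predict_score(model, X)
    assert set(np.unique(s)) <= {-1.0, 1.0}
    np.testing.assert_array_equal(predict_label(model, X), (s > 0).astype(int))


def test_feature_name_mismatch_rejected():
    X, y = _imbalanced(seed=12)
    df = pd.DataFrame(X, columns=["a", "b", "c"])
    model = train_adaboost(df, y, T=5, seed=0)
    wrong = df.rename(columns={"c": "z"})
    with pytest.raises(ValueError, match="feature names"):
        model.score(wrong)


def test_ensemble_json_roundtrip():
    X, y = _imbalanced(seed=13)
    model = train_adaboost(X, y, T=10, seed=0)
    back = ensemble_from_json(ensemble_to_json(model))
    np.testing.assert_allclose(back.score(X), model.score(X), rtol=1e-12)
    assert isinstance(back, BoostedEnsemble)
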