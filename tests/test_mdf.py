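"""Mass-defect featurization, resampling, the focal-loss MLP and its
explainability metrics."""

import math

import numpy as np
import pytest
from sklearn.metrics import precision_recall_fscore_support

from gsltracer._nn import MlpNetwork, _focal_grad_logits, focal_loss, softmax
from gsltracer.mdf import (
    MdfDataset,
    MdfModel,
    MdfModelConfig,
    build_training_dataset,
    evaluate,
    featurize,
    permutation_importance,
    predict_top2,
    smote_tomek_resample,
    train_mdf,
)


# ----------------------------------------------------------------- featurize
@pytest.mark.parametrize(
    "mz, expected",
    [
        (436.0416, (436, 0.0416, 119, 0.0535)),
        (316.9881, (316, 0.9881, 0, 0.0)),
        (422.0255, (422, 0.0255, 105, 0.0374)),
    ],
)
def test_featurize_examples(mz, expected):
    v = featurize(mz)
    assert v.M_integer == expected[0]
    assert v.M_decimal == pytest.approx(expected[1], abs=1e-6)
    assert v.m_integer == expected[2]
    assert v.m_decimal == pytest.approx(expected[3], abs=1e-6)


def test_featurize_consistency():
    """Recombining the splits recovers the precursor and its residual."""
    for mz in (436.0416, 521.1234, 317.0001):
        v = featurize(mz)
        assert v.M_integer + v.M_decimal == pytest.approx(mz, abs=1e-6)
        assert (v.m_integer + v.m_decimal) == pytest.approx(mz - 316.9881, abs=1e-6)


def test_featurize_below_core_stays_four_dim():
    v = featurize(100.0)
    assert (v.m_integer, v.m_decimal) == (0, 0.0)


# ------------------------------------------------------------------ dataset
def test_build_training_dataset_counts():
    library = [(400.0 + i, i % 2) for i in range(10)]
    ds = build_training_dataset(library, ppm_spread=10, n_augment=2, seed=0)
    assert len(ds) == 30
    assert sorted(set(ds.provenance)) == ["augmented", "theoretical"]


def test_augmentation_stays_within_spread_and_class():
    library = [(436.0416, 0), (448.1234, 1)]
    ds = build_training_dataset(library, ppm_spread=10, n_augment=50, seed=1)
    masses = ds.X[:, 0] + ds.X[:, 1]
    for mz, label in library:
        rows = np.isclose(masses, mz, atol=mz * 11e-6)
        assert np.all(ds.y[rows] == label)  # augmentation never crosses labels
        assert np.all(np.abs(masses[rows] - mz) / mz * 1e6 <= 10 + 1e-9)


def test_zero_spread_duplicates_base():
    ds = build_training_dataset([(400.0, 0), (500.0, 1)], ppm_spread=0, n_augment=3, seed=0)
    assert np.allclose(ds.X[:4], ds.X[0])  # first entry's rows all identical


def test_build_training_dataset_empty_library():
    with pytest.raises(ValueError):
        build_training_dataset([], 10, 5, 0)


# -------------------------------------------------------------- SMOTE+Tomek
def _toy_dataset(n0, n1, rng, separation=5.0):
    X0 = rng.normal(0.0, 0.5, size=(n0, 2))
    X1 = rng.normal(separation, 0.5, size=(n1, 2))
    X = np.vstack([X0, X1])
    y = np.array([0] * n0 + [1] * n1)
    prov = np.array(["theoretical"] * (n0 + n1), dtype=object)
    return MdfDataset(X, y, prov)


def test_smote_balanced_separable_input_unchanged(rng):
    ds = _toy_dataset(30, 30, rng)
    out = smote_tomek_resample(ds, seed=0)
    assert len(out) == len(ds)
    assert np.allclose(out.X, ds.X)


def test_smote_balances_counts(rng):
    ds = _toy_dataset(100, 20, rng)
    out = smote_tomek_resample(ds, seed=0)
    # classes are well separated, so no Tomek link forms and counts stay equal
    assert out.class_counts() == {0: 100, 1: 100}


def test_smote_synthetic_points_are_convex_combinations(rng):
    ds = _toy_dataset(40, 10, rng)
    out = smote_tomek_resample(ds, seed=0)
    minority = ds.X[ds.y == 1]
    synth = out.X[out.provenance == "synthetic"]
    assert len(synth) == 30
    for p in synth:
        on_segment = False
        for i in range(len(minority)):
            for j in range(len(minority)):
                if i == j:
                    continue
                a, b = minority[i], minority[j]
                ab = b - a
                denom = float(ab @ ab)
                if denom == 0:
                    continue
                t = float((p - a) @ ab) / denom
                if -1e-9 <= t <= 1 + 1e-9 and np.linalg.norm(a + t * ab - p) < 1e-9:
                    on_segment = True
                    break
            if on_segment:
                break
        assert on_segment


def test_smote_rejects_tiny_class(rng):
    ds = _toy_dataset(20, 3, rng)
    with pytest.raises(ValueError, match="k_neighbors"):
        smote_tomek_resample(ds, k_neighbors=5, seed=0)


def test_tomek_links_removed():
    # 0.0/0.1 are opposite-class mutual nearest neighbors (a Tomek link);
    # the tight 5.0/5.2 and 20.0/20.2 pairs are same-class, so they stay
    X = np.array([[0.0, 0.0], [5.0, 0.0], [5.2, 0.0],
                  [0.1, 0.0], [20.0, 0.0], [20.2, 0.0]])
    y = np.array([0, 0, 0, 1, 1, 1])
    ds = MdfDataset(X, y, np.array(["theoretical"] * 6, dtype=object))
    out = smote_tomek_resample(ds, k_neighbors=2, seed=0)
    assert len(out) == 4
    assert set(map(tuple, out.X)) == {(5.0, 0.0), (5.2, 0.0), (20.0, 0.0), (20.2, 0.0)}


# --------------------------------------------------------------- focal loss
def test_focal_loss_perfect_predictions():
    probs = np.array([[1.0, 0.0], [0.0, 1.0]])
    labels = np.array([0, 1])
    assert focal_loss(probs, labels) == pytest.approx(0.0, abs=1e-9)


def test_focal_loss_reduces_to_cross_entropy():
    rng = np.random.default_rng(0)
    probs = rng.dirichlet([1, 1], size=20)
    labels = rng.integers(0, 2, size=20)
    ce = -np.mean(np.log(probs[np.arange(20), labels]))
    assert focal_loss(probs, labels, alpha=1.0, gamma=0.0) == pytest.approx(ce, rel=1e-12)


def test_focal_loss_hand_value():
    # single sample, p_t = 0.5, alpha=1, gamma=2: 0.25 * ln 2
    probs = np.array([[0.5, 0.5]])
    labels = np.array([0])
    assert focal_loss(probs, labels, alpha=1.0, gamma=2.0) == pytest.approx(
        0.25 * math.log(2.0), rel=1e-12
    )


def test_focal_gradient_matches_finite_differences():
    rng = np.random.default_rng(1)
    logits = rng.normal(size=(6, 2))
    labels = rng.integers(0, 2, size=6)
    alpha, gamma = 0.25, 2.0
    grad = _focal_grad_logits(softmax(logits), labels, alpha, gamma)
    eps = 1e-6
    for i in range(6):
        for j in range(2):
            lp, lm = logits.copy(), logits.copy()
            lp[i, j] += eps
            lm[i, j] -= eps
            num = (
                focal_loss(softmax(lp), labels, alpha, gamma)
                - focal_loss(softmax(lm), labels, alpha, gamma)
            ) / (2 * eps)
            assert grad[i, j] == pytest.approx(num, abs=1e-6)


def test_network_backward_matches_finite_differences():
    """Full-stack gradient check through dense + batch-norm + ReLU layers."""
    rng = np.random.default_rng(2)
    net = MlpNetwork(input_dim=3, hidden=(5, 4), output_dim=2, dropout=0.0,
                     rng=rng, dtype=np.float64)
    X = rng.normal(size=(7, 3))
    y = rng.integers(0, 2, size=7)
    alpha, gamma = 0.25, 2.0

    def loss_fn():
        logits = net.forward(X, training=True, rng=rng)
        return focal_loss(softmax(logits), y, alpha, gamma)

    logits = net.forward(X, training=True, rng=rng)
    grads = net.backward(_focal_grad_logits(softmax(logits), y, alpha, gamma))
    params = net.parameters()
    eps = 1e-6
    rng_check = np.random.default_rng(3)
    for p, g in zip(params, grads):
        flat_idx = rng_check.choice(p.size, size=min(5, p.size), replace=False)
        for k in flat_idx:
            orig = p.flat[k]
            p.flat[k] = orig + eps
            up = loss_fn()
            p.flat[k] = orig - eps
            down = loss_fn()
            p.flat[k] = orig
            assert g.flat[k] == pytest.approx((up - down) / (2 * eps), abs=1e-5)


# ----------------------------------------------------------------- training
def _separable_datasets(rng, n=120):
    """GSL-like residual decimals on the CH2 band vs uniform decoys."""
    mz_gsl = 330.0 + rng.integers(0, 15, size=n // 2) * 14 + 0.9881 + rng.integers(0, 13, size=n // 2) * 0.01565
    # integer base + decimal in [0.3, 0.8] keeps decoy mass defects clear of
    # the glucosinolate band, so the toy is linearly separable on decimals
    mz_dec = rng.integers(320, 560, size=n // 2) + rng.uniform(0.3, 0.8, size=n // 2)
    lib = [(float(m), 0) for m in mz_gsl] + [(float(m), 1) for m in mz_dec]
    train = build_training_dataset(lib, ppm_spread=10, n_augment=3, seed=5)
    test = build_training_dataset(lib, ppm_spread=5, n_augment=1, seed=6)
    return train, test


SMALL_CONFIG = MdfModelConfig(hidden=(32, 16), epochs=50, batch_size=32,
                              learning_rate=3e-3, seed=9)


def test_train_on_separable_toy(rng):
    train, test = _separable_datasets(rng)
    model = train_mdf(train, test, SMALL_CONFIG)
    assert model.history[-1]["train_accuracy"] >= 0.99
    best = max(h["test_accuracy"] for h in model.history)
    ckpt = evaluate(model, test)["accuracy"]
    assert ckpt == pytest.approx(best, abs=1e-9)
    assert min(h["test_loss"] for h in model.history) <= model.history[0]["test_loss"]


def test_training_is_deterministic(rng):
    train, test = _separable_datasets(rng, n=60)
    cfg = MdfModelConfig(hidden=(16,), epochs=5, seed=4)
    h1 = train_mdf(train, test, cfg).history
    h2 = train_mdf(train, test, cfg).history
    assert h1 == h2


def test_train_rejects_single_class():
    X = np.random.default_rng(0).normal(size=(20, 4))
    ds = MdfDataset(X, np.zeros(20), np.array(["theoretical"] * 20, dtype=object))
    with pytest.raises(ValueError, match="both classes"):
        train_mdf(ds, ds, SMALL_CONFIG)


def test_predict_top2_contract(rng):
    train, test = _separable_datasets(rng, n=60)
    model = train_mdf(train, test, MdfModelConfig(hidden=(16,), epochs=5, seed=4))
    preds = predict_top2(model, test.X[:10])
    for p in preds:
        assert p.first[1] >= p.second[1]
        assert p.first[1] + p.second[1] == pytest.approx(1.0, abs=1e-9)
        assert {p.first[0], p.second[0]} == {0, 1}


def test_predict_requires_trained_model():
    net = MlpNetwork(4, (8,), 2, rng=np.random.default_rng(0))
    model = MdfModel(network=net, config=SMALL_CONFIG, trained=False)
    with pytest.raises(ValueError, match="trained"):
        predict_top2(model, np.zeros((1, 4)))


# --------------------------------------------------------------- evaluation
class _StubNetwork:
    """Fixed-prediction stand-in so the confusion matrix is known exactly."""

    def __init__(self, predictions):
        self.predictions = np.asarray(predictions)

    def predict_proba(self, X):
        probs = np.zeros((len(self.predictions), 2))
        probs[np.arange(len(self.predictions)), self.predictions] = 1.0
        return probs


def test_evaluate_against_hand_confusion_matrix():
    y_true = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1, 1])
    y_pred = np.array([0, 0, 0, 1, 1, 1, 1, 1, 0, 1])
    ds = MdfDataset(np.zeros((10, 4)), y_true, np.array(["theoretical"] * 10, dtype=object))
    model = MdfModel(network=_StubNetwork(y_pred), config=SMALL_CONFIG, trained=True)
    metrics = evaluate(model, ds)
    # hand arithmetic: class0 TP=3 FP=1 FN=2; class1 TP=4 FP=2 FN=1
    assert metrics["accuracy"] == pytest.approx(0.7)
    assert metrics["per_class"][0]["precision"] == pytest.approx(3 / 4)
    assert metrics["per_class"][0]["recall"] == pytest.approx(3 / 5)
    assert metrics["per_class"][1]["f1"] == pytest.approx(2 * (4 / 6) * (4 / 5) / (4 / 6 + 4 / 5))
    # independent cross-check via sklearn
    prec, rec, f1, _ = precision_recall_fscore_support(y_true, y_pred, labels=[0, 1])
    for cls in (0, 1):
        assert metrics["per_class"][cls]["precision"] == pytest.approx(prec[cls])
        assert metrics["per_class"][cls]["recall"] == pytest.approx(rec[cls])
        assert metrics["per_class"][cls]["f1"] == pytest.approx(f1[cls])


def test_evaluate_constant_predictor_zero_recall():
    y_true = np.array([0, 0, 1, 1])
    model = MdfModel(network=_StubNetwork([0, 0, 0, 0]), config=SMALL_CONFIG, trained=True)
    ds = MdfDataset(np.zeros((4, 4)), y_true, np.array(["theoretical"] * 4, dtype=object))
    metrics = evaluate(model, ds)
    assert metrics["per_class"][1]["recall"] == 0.0


# ------------------------------------------------------- feature importance
def test_permutation_importance_constant_and_planted(rng):
    # labels depend only on M_decimal; M_integer is constant
    n = 400
    M_dec = rng.uniform(0, 1, size=n)
    y = (M_dec > 0.5).astype(int)
    X = np.column_stack([np.full(n, 400.0), M_dec, rng.uniform(0, 80, n), rng.uniform(0, 1, n)])
    ds = MdfDataset(X, y, np.array(["theoretical"] * n, dtype=object))
    model = train_mdf(ds, ds, MdfModelConfig(hidden=(16, 8), epochs=30, seed=2))
    drops = permutation_importance(model, ds, n_repeats=5, seed=3)
    assert abs(drops["M_integer"]) < 0.02  # constant feature carries nothing
    assert max(drops, key=drops.get) == "M_decimal"
    drops2 = permutation_importance(model, ds, n_repeats=5, seed=3)
    assert drops == drops2  # seeded reproducibility


def test_permutation_importance_rejects_zero_repeats(rng):
    train, test = _separable_datasets(rng, n=60)
    model = train_mdf(train, test, MdfModelConfig(hidden=(16,), epochs=3, seed=4))
    with pytest.raises(ValueError):
        permutation_importance(model, test, n_repeats=0)


def test_config_validation():
    with pytest.raises(ValueError):
        MdfModelConfig(hidden=(0,))
    with pytest.raises(ValueError):
        MdfModelConfig(dropout=1.0)
    with pytest.raises(ValueError):
        MdfModelConfig(epochs=0)
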