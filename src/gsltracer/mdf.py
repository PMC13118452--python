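"""Deep-learning-assisted Mass Defect Filter (MDF).

Glucosinolate precursor ions share the deprotonated glucosyl-sulfated
core [C7H11O9NS2]- (m/z 316.9881); side chains are mostly CH2 runs plus a
few substituent classes, so both the accurate mass M-H and the residual
m-H = (M-H) - core carry class-specific mass-defect structure.  Each
precursor is represented by four features: the integer and decimal parts
of M-H and of m-H.  A five-layer MLP (4 -> 512 -> 256 -> 128 -> 64 -> 2,
batch-norm + ReLU + dropout 0.01) trained with focal loss on a
SMOTE+Tomek-balanced library classifies precursors as glucosinolate
(label 0) or other (label 1), and reports the top-two classes with their
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from ._nn import AdamOptimizer, MlpNetwork, focal_loss, softmax
from .chem import split_mass
from .constants import GSL_CORE_MZ

__all__ = [
    "MdfFeatureVector",
    "MdfDataset",
    "MdfModelConfig",
    "MdfModel",
    "TopTwoPrediction",
    "featurize",
    "build_training_dataset",
    "smote_tomek_resample",
    "train_mdf",
    "predict_top2",
    "evaluate",
    "permutation_importance",
]

FEATURE_NAMES = ("M_integer", "M_decimal", "m_integer", "m_decimal")


@dataclass(frozen=True)
class MdfFeatureVector:
    M_integer: int
    M_decimal: float
    m_integer: int
    m_decimal: float
    label: int | None = None  # 0 = GSL, 1 = other

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.M_integer, self.M_decimal, self.m_integer, self.m_decimal], dtype=np.float64
        )


def featurize(precursor_mz: float, core_mass: float = GSL_CORE_MZ,
              label: int | None = None) -> MdfFeatureVector:
    """Split precursor m/z and its core residual into integer/decimal parts.

    A precursor lighter than the core cannot be a glucosinolate; its
    residual features are the split of zero so the representation stays
    four-dimensional.
    """
    if precursor_mz <= 0:
        raise ValueError(f"precursor m/z must be positive, got {precursor_mz}")
    big = split_mass(precursor_mz)
    residual = precursor_mz - core_mass
    small = split_mass(residual) if residual >= 0 else split_mass(0.0)
    return MdfFeatureVector(
        M_integer=big.integer_part,
        M_decimal=big.decimal_part,
        m_integer=small.integer_part,
        m_decimal=small.decimal_part,
        label=label,
    )


@dataclass
class MdfDataset:
    """Feature matrix (n, 4) + labels + per-row provenance tag."""

    X: np.ndarray
    y: np.ndarray
    provenance: np.ndarray  # "theoretical" | "augmented" | "synthetic" | "experimental"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.provenance = np.asarray(self.provenance, dtype=object)
        if not (len(self.X) == len(self.y) == len(self.provenance)):
            raise ValueError("X, y and provenance must have equal length")

    def __len__(self) -> int:
        return len(self.y)

    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


def build_training_dataset(
    library: Sequence[tuple[float, int]],
    ppm_spread: float = 10.0,
    n_augment: int = 30,
    seed: int = 0,
    core_mass: float = GSL_CORE_MZ,
) -> MdfDataset:
    """Base rows (one per library entry) plus ppm-jittered augmentations.

    Each entry (theoretical anion m/z, label) contributes its exact-mass
    row plus ``n_augment`` rows with the mass perturbed uniformly within
    +-``ppm_spread`` ppm, emulating instrument mass error around the
    theoretical values.  Fully reproducible from ``seed``.
    """
    if not library:
        raise ValueError("library must be non-empty")
    if ppm_spread < 0:
        raise ValueError("ppm_spread must be non-negative")
    rng = np.random.default_rng(seed)
    rows, labels, prov = [], [], []
    for mz, label in library:
        rows.append(featurize(mz, core_mass).as_array())
        labels.append(label)
        prov.append("theoretical")
        if n_augment:
            offsets = rng.uniform(-ppm_spread, ppm_spread, size=n_augment)
            for off in offsets:
                rows.append(featurize(mz * (1.0 + off * 1e-6), core_mass).as_array())
                labels.append(label)
                prov.append("augmented")
    return MdfDataset(np.array(rows), np.array(labels), np.array(prov, dtype=object))


def smote_tomek_resample(
    ds: MdfDataset, k_neighbors: int = 5, seed: int = 0
) -> MdfDataset:
    """Balance classes by SMOTE oversampling, then drop Tomek-link pairs.

    SMOTE synthesizes minority points as convex combinations of a point
    and one of its k nearest minority neighbors until class counts are
    equal; Tomek links (opposite-class mutual nearest neighbors) are then
    removed, both members of each link, to clean the class boundary.
    """
    counts = ds.class_counts()
    if len(counts) != 2:
        raise ValueError(f"expected two classes, got {sorted(counts)}")
    for label, n in counts.items():
        if n < k_neighbors + 1:
            raise ValueError(
                f"class {label} has {n} member(s); needs at least k_neighbors+1={k_neighbors + 1}"
            )
    rng = np.random.default_rng(seed)
    (a, b) = sorted(counts)
    minority = a if counts[a] < counts[b] else b
    deficit = abs(counts[a] - counts[b])

    X, y, prov = ds.X, ds.y, ds.provenance
    if deficit > 0:
        Xm = X[y == minority]
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xm)
        _, idx = nn.kneighbors(Xm)
        base = rng.integers(0, len(Xm), size=deficit)
        pick = rng.integers(1, k_neighbors + 1, size=deficit)  # skip self at col 0
        lam = rng.random(deficit)
        neigh = Xm[idx[base, pick]]
        synth = Xm[base] + lam[:, None] * (neigh - Xm[base])
        X = np.vstack([X, synth])
        y = np.concatenate([y, np.full(deficit, minority, dtype=np.int64)])
        prov = np.concatenate([prov, np.full(deficit, "synthetic", dtype=object)])

    # Tomek links: opposite-class pairs that are each other's nearest neighbor
    nn_all = NearestNeighbors(n_neighbors=2).fit(X)
    _, idx_all = nn_all.kneighbors(X)
    nearest = idx_all[:, 1]
    drop = np.zeros(len(X), dtype=bool)
    for i, j in enumerate(nearest):
        if nearest[j] == i and y[i] != y[j]:
            drop[i] = drop[j] = True
    keep = ~drop
    return MdfDataset(X[keep], y[keep], prov[keep])


@dataclass(frozen=True)
class MdfModelConfig:
    hidden: tuple[int, ...] = (512, 256, 128, 64)
    dropout: float = 0.01
    batch_size: int = 64
    epochs: int = 100
    focal_alpha: float = 0.25
    focal_gamma: float = 2.0
    learning_rate: float = 1e-3
    l2: float = 1e-4
    seed: int = 0
    checkpoint: str = "best_test_accuracy"  # or "last"

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.hidden):
            raise ValueError("hidden widths must be positive")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class MdfModel:
    network: MlpNetwork
    config: MdfModelConfig
    history: list[dict[str, float]] = field(default_factory=list)
    best_state: dict | None = None
    trained: bool = False
    # input standardization fitted on the training set; the four raw
    # features differ in scale by orders of magnitude (integer parts span
    # hundreds of Da, decimals live in [0,1)), and z-scoring them keeps
    # the first layer well conditioned
    feature_mean: np.ndarray | None = None
    feature_scale: np.ndarray | None = None

    def use_best(self) -> None:
        if self.best_state is not None:
            self.network.set_state(self.best_state)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if self.feature_mean is None:
            return X
        return (X - self.feature_mean) / self.feature_scale

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(self.transform(X))


@dataclass(frozen=True)
class TopTwoPrediction:
    """The two most likely classes with their probabilities, descending."""

    first: tuple[int, float]
    second: tuple[int, float]


def _epoch_metrics(net: MlpNetwork, X: np.ndarray, y: np.ndarray,
                   alpha: float, gamma: float) -> tuple[float, float]:
    probs = net.predict_proba(X)
    loss = focal_loss(probs, y, alpha, gamma)
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return loss, acc


def train_mdf(ds: MdfDataset, test: MdfDataset, config: MdfModelConfig | None = None) -> MdfModel:
    """Train the focal-loss MLP, recording per-epoch train/test loss and
    accuracy and retaining the best-test-accuracy weights.

    Ties on test accuracy are broken toward the lower test loss, so the
    checkpointed model is never worse than the first epoch on either
    metric.  Entirely deterministic given ``config.seed``.
    """
    config = config or MdfModelConfig()
    if len(ds) == 0:
        raise ValueError("training dataset is empty")
    if len(np.unique(ds.y)) < 2:
        raise ValueError("training dataset must contain both classes")
    rng = np.random.default_rng(config.seed)
    net = MlpNetwork(
        input_dim=ds.X.shape[1],
        hidden=config.hidden,
        output_dim=2,
        dropout=config.dropout,
        rng=rng,
    )
    opt = AdamOptimizer(net, lr=config.learning_rate, l2=config.l2)
    grad_buffer = np.empty_like(net.flat_parameters)
    mean = ds.X.mean(axis=0).astype(np.float32)
    scale = ds.X.std(axis=0).astype(np.float32)
    scale[scale < 1e-9] = 1.0
    model = MdfModel(network=net, config=config, feature_mean=mean, feature_scale=scale)

    Xtr = model.transform(ds.X)
    ytr = ds.y
    best_key: tuple[float, float] | None = None
    from ._nn import _focal_grad_logits  # local import keeps the helper private

    for epoch in range(config.epochs):
        order = rng.permutation(len(Xtr))
        loss_sum = 0.0
        correct = 0
        seen = 0
        for start in range(0, len(Xtr), config.batch_size):
            batch = order[start : start + config.batch_size]
            if len(batch) < 2:
                continue  # batch-norm needs more than one row
            logits = net.forward(Xtr[batch], training=True, rng=rng)
            probs = softmax(logits.astype(np.float64))
            yb = ytr[batch]
            loss_sum += len(batch) * focal_loss(probs, yb, config.focal_alpha, config.focal_gamma)
            correct += int(np.sum(probs.argmax(axis=1) == yb))
            seen += len(batch)
            grad = _focal_grad_logits(probs, yb, config.focal_alpha, config.focal_gamma)
            opt.step(net.flat_gradients(grad, grad_buffer))
        # train metrics are the running averages over this epoch's batches
        train_loss = loss_sum / max(seen, 1)
        train_acc = correct / max(seen, 1)
        test_loss, test_acc = _epoch_metrics(
            net, model.transform(test.X), test.y, config.focal_alpha, config.focal_gamma
        )
        model.history.append(
            {
                "epoch": epoch,
                "train_loss": train_loss,
                "train_accuracy": train_acc,
                "test_loss": test_loss,
                "test_accuracy": test_acc,
            }
        )
        key = (-test_acc, test_loss)
        if best_key is None or key < best_key:
            best_key = key
            model.best_state = net.get_state()
    if config.checkpoint == "best_test_accuracy":
        model.use_best()
    model.trained = True
    return model


def predict_top2(model: MdfModel, vectors: Sequence[MdfFeatureVector] | np.ndarray) -> list[TopTwoPrediction]:
    """Dual-label prediction: both classes ordered by probability."""
    if not model.trained:
        raise ValueError("model has not been trained")
    X = _to_matrix(vectors)
    probs = model.predict_proba(X)
    out = []
    for p in probs:
        order = np.argsort(-p)
        out.append(
            TopTwoPrediction(
                first=(int(order[0]), float(p[order[0]])),
                second=(int(order[1]), float(p[order[1]])),
            )
        )
    return out


def _to_matrix(vectors) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        return vectors
    return np.vstack([v.as_array() for v in vectors])


def evaluate(model: MdfModel, testset: MdfDataset) -> dict[str, object]:
    """Confusion-matrix metrics: accuracy plus per-class precision/recall/F1."""
    if len(testset) == 0:
        raise ValueError("test set is empty")
    probs = model.predict_proba(testset.X)
    pred = probs.argmax(axis=1)
    y = testset.y
    metrics: dict[str, object] = {"accuracy": float(np.mean(pred == y))}
    per_class: dict[int, dict[str, float]] = {}
    for cls in (0, 1):
        tp = int(np.sum((pred == cls) & (y == cls)))
        fp = int(np.sum((pred == cls) & (y != cls)))
        fn = int(np.sum((pred != cls) & (y == cls)))
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
        per_class[cls] = {"precision": precision, "recall": recall, "f1": f1}
    metrics["per_class"] = per_class
    return metrics


def permutation_importance(
    model: MdfModel, ds: MdfDataset, n_repeats: int = 10, seed: int = 0
) -> dict[str, float]:
    """Mean accuracy drop when each feature column is shuffled.

    The standard model-agnostic importance: a feature the model relies on
    costs accuracy when its values are permuted across samples.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    X = np.asarray(ds.X, dtype=np.float32)
    y = ds.y
    base_acc = float(np.mean(model.predict_proba(X).argmax(axis=1) == y))
    drops: dict[str, float] = {}
    for j, name in enumerate(FEATURE_NAMES):
        vals = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, j] = Xp[rng.permutation(len(Xp)), j]
            acc = float(np.mean(model.predict_proba(Xp).argmax(axis=1) == y))
            vals.append(base_acc - acc)
        drops[name] = float(np.mean(vals))
    return drops
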