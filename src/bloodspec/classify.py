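"""Six-class identification stage: PCA compression of the selected
wavenumbers, Fisher linear discriminant analysis, and the extreme learning
machine (ELM) with its hidden-neuron sweep.

The ELM is a single-hidden-layer network whose input weights and biases are
drawn once, uniformly on [-1, 1], and never trained; only the linear output
layer is fitted, by the Moore-Penrose pseudoinverse of the hidden activation
matrix.  For classification the default target coding is one-hot with
argmax decoding; a single-numeric-code mode (codes 1..C, nearest-code
decoding, one output neuron) is available but caps accuracy on designs
whose classes are not ordered along the code axis — least-squares code
regression then confuses adjacent codes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.decomposition import PCA as _SKPCA

logger = logging.getLogger(__name__)

ACTIVATIONS = ("sigmoid", "sine", "hardlim")


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAModel:
    mean: np.ndarray
    loadings: np.ndarray  # variables x components, orthonormal columns
    explained_variance_ratio: np.ndarray


def pca_fit(X: np.ndarray, n_components: int = 3) -> PCAModel:
    """Mean-centered PCA of the training matrix; warns (not errors) if the
    kept components explain < 99.0% of the variance."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError(f"n_components={n_components} exceeds min(n, p)")
    sk = _SKPCA(n_components=n_components, svd_solver="full")
    sk.fit(X)
    cum = float(sk.explained_variance_ratio_.sum())
    if cum < 0.99:
        warnings.warn(
            f"top {n_components} PCs explain only {cum:.1%} of the variance (< 99.0%)",
            stacklevel=2,
        )
    return PCAModel(
        mean=sk.mean_,
        loadings=sk.components_.T,
        explained_variance_ratio=sk.explained_variance_ratio_,
    )


def pca_transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    return (np.asarray(X, dtype=float) - model.mean) @ model.loadings


# ---------------------------------------------------------------------------
# Fisher LDA
# ---------------------------------------------------------------------------

@dataclass
class DiscriminantModel:
    """Discriminant functions (columns of ``coef``) mapping input scores to
    DF space, plus per-class centroids there."""

    coef: np.ndarray       # input dims x n_DFs
    centroids: np.ndarray  # classes x n_DFs
    classes: np.ndarray


def fisher_lda_fit(scores: np.ndarray, labels: np.ndarray) -> DiscriminantModel:
    """Fisher discriminant directions: eigenvectors of Sw^-1 Sb, at most
    min(C - 1, dims).  A singular within-class scatter falls back to a
    diagonal ridge (1e-8), logged."""
    X = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("Fisher LDA needs at least 2 classes")
    d = X.shape[1]
    grand = X.mean(axis=0)
    Sw = np.zeros((d, d))
    Sb = np.zeros((d, d))
    for c in classes:
        Xi = X[labels == c]
        if Xi.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 training samples")
        mu = Xi.mean(axis=0)
        Sw += (Xi - mu).T @ (Xi - mu)
        Sb += Xi.shape[0] * np.outer(mu - grand, mu - grand)
    try:
        evals, evecs = eigh(Sb, Sw)
    except np.linalg.LinAlgError:
        logger.warning("singular within-class scatter; adding 1e-8 ridge")
        Sw = Sw + 1e-8 * np.eye(d)
        evals, evecs = eigh(Sb, Sw)
    n_df = min(classes.size - 1, d)
    order = np.argsort(evals)[::-1][:n_df]
    W = evecs[:, order]
    W = W / np.linalg.norm(W, axis=0)
    Z = X @ W
    centroids = np.vstack([Z[labels == c].mean(axis=0) for c in classes])
    return DiscriminantModel(coef=W, centroids=centroids, classes=classes)


def fisher_lda_predict(model: DiscriminantModel, scores: np.ndarray) -> np.ndarray:
    """Nearest-centroid (Euclidean) assignment in DF-score space."""
    Z = np.asarray(scores, dtype=float) @ model.coef
    d2 = ((Z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return model.classes[np.argmin(d2, axis=1)]


# ---------------------------------------------------------------------------
# ELM
# ---------------------------------------------------------------------------

def _activation(name: str):
    if name == "sigmoid":
        return lambda x: 1.0 / (1.0 + np.exp(-x))
    if name == "sine":
        return np.sin
    if name == "hardlim":
        return lambda x: (x > 0).astype(float)
    raise ValueError(f"unknown activation {name!r}")


@dataclass
class ELMModel:
    input_weights: np.ndarray   # inputs x hidden
    biases: np.ndarray          # hidden
    activation: str
    output_weights: np.ndarray  # hidden x outputs
    seed: int
    class_codes: np.ndarray | None = None  # set for classification models


def elm_train(
    X: np.ndarray,
    targets: np.ndarray,
    n_hidden: int,
    activation: str = "sigmoid",
    seed: int = 0,
    class_codes: np.ndarray | None = None,
) -> ELMModel:
    """Train an ELM: random input layer, least-squares output layer.

    ``targets`` may be a vector (single output — regression or numeric class
    codes) or a matrix (e.g. one-hot).  Output weights are the minimum-norm
    least-squares solution pinv(H) @ T.
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(targets, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(T))):
        raise ValueError("non-finite inputs or targets")
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    if T.ndim == 1:
        T = T[:, None]
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(X.shape[1], n_hidden))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    H = _activation(activation)(X @ W + b)
    beta = np.linalg.pinv(H) @ T
    return ELMModel(
        input_weights=W, biases=b, activation=activation,
        output_weights=beta, seed=seed,
        class_codes=None if class_codes is None else np.asarray(class_codes, dtype=float),
    )


def elm_predict(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Raw network outputs (n x outputs; squeezed to a vector for one output)."""
    X = np.asarray(X, dtype=float)
    H = _activation(model.activation)(X @ model.input_weights + model.biases)
    out = H @ model.output_weights
    return out.ravel() if out.shape[1] == 1 else out


def elm_decode(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Decoded class codes: nearest valid code for single-output models,
    argmax for one-hot models."""
    if model.class_codes is None:
        raise ValueError("model has no class codes (regression model?)")
    out = elm_predict(model, X)
    if out.ndim == 1:
        return model.class_codes[
            np.argmin(np.abs(out[:, None] - model.class_codes[None, :]), axis=1)
        ]
    return model.class_codes[np.argmax(out, axis=1)]


def hidden_neuron_range(
    n_samples: int,
    n_inputs: int,
    n_outputs: int,
    alpha_range: tuple[float, float] = (2.0, 10.0),
) -> tuple[int, int]:
    """Empirical hidden-neuron range N_h = N_s / (alpha * (N_i + N_0)) with
    alpha sweeping ``alpha_range``; returned rounded to integers (low at the
    largest alpha, high at the smallest)."""
    if min(n_samples, n_inputs, n_outputs) < 1:
        raise ValueError("all counts must be >= 1")
    a_min, a_max = min(alpha_range), max(alpha_range)
    low = int(round(n_samples / (a_max * (n_inputs + n_outputs))))
    high = int(round(n_samples / (a_min * (n_inputs + n_outputs))))
    return low, high


# ---------------------------------------------------------------------------
# Accuracy and the sweep
# ---------------------------------------------------------------------------

@dataclass
class ClassificationReport:
    """Confusion matrix (rows = true, cols = predicted) and the accuracy
    R = N1 / N2 x 100 with N1 correct and N2 total."""

    classes: np.ndarray
    confusion: np.ndarray
    n_correct: int
    n_total: int
    accuracy_pct: float


def accuracy(true_labels, predicted_labels, classes=None) -> ClassificationReport:
    true_labels = np.asarray(true_labels)
    predicted_labels = np.asarray(predicted_labels)
    if true_labels.shape != predicted_labels.shape or true_labels.size == 0:
        raise ValueError("label vectors must be nonempty and of equal length")
    if classes is None:
        classes = np.unique(np.concatenate([true_labels, predicted_labels]))
    else:
        classes = np.asarray(classes)
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((classes.size, classes.size), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        cm[index[t], index[p]] += 1
    n1 = int(np.trace(cm))
    n2 = int(cm.sum())
    return ClassificationReport(
        classes=classes, confusion=cm, n_correct=n1, n_total=n2,
        accuracy_pct=n1 / n2 * 100.0,
    )


@dataclass
class SweepEntry:
    activation: str
    n_hidden: int
    train_accuracy: float
    test_accuracy: float


def sweep_elm(
    X_train: np.ndarray,
    labels_train: np.ndarray,
    X_test: np.ndarray,
    labels_test: np.ndarray,
    classes: np.ndarray,
    neuron_range: tuple[int, int] = (1, 50),
    activations: tuple[str, ...] = ACTIVATIONS,
    seed: int = 0,
    one_hot: bool = True,
) -> tuple[list[SweepEntry], SweepEntry, ELMModel]:
    """Grid sweep over (activation, hidden-neuron count).

    One fresh weight draw per grid cell, spawned deterministically from the
    master seed.  The winner maximizes test-set accuracy (the configured
    default criterion; note this uses the held-out set for selection).
    """
    classes = np.asarray(classes)
    codes = np.arange(1, classes.size + 1, dtype=float)
    code_of = {c: codes[i] for i, c in enumerate(classes)}
    y_train = np.array([code_of[c] for c in labels_train])
    if one_hot:
        T_train = (y_train[:, None] == codes[None, :]).astype(float)
    else:
        T_train = y_train

    curve: list[SweepEntry] = []
    best_entry: SweepEntry | None = None
    best_model: ELMModel | None = None
    for ai, act in enumerate(activations):
        for nh in range(neuron_range[0], neuron_range[1] + 1):
            cell_seed = np.random.SeedSequence(entropy=seed, spawn_key=(ai, nh))
            model = elm_train(
                X_train, T_train, nh, activation=act,
                seed=cell_seed, class_codes=codes,
            )
            pred_tr = classes[(elm_decode(model, X_train) - 1).astype(int)]
            pred_te = classes[(elm_decode(model, X_test) - 1).astype(int)]
            entry = SweepEntry(
                activation=act, n_hidden=nh,
                train_accuracy=accuracy(labels_train, pred_tr, classes).accuracy_pct,
                test_accuracy=accuracy(labels_test, pred_te, classes).accuracy_pct,
            )
            curve.append(entry)
            if best_entry is None or entry.test_accuracy > best_entry.test_accuracy:
                best_entry, best_model = entry, model
    return curve, best_entry, best_model
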