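"""One-vs-one support-vector classification of instruments.

A binary soft-margin SVM is trained for every unordered pair of classes
with a Gaussian kernel ``K(x, y) = exp(-||x - y||^2 / (2 sigma^2))`` (or a
linear kernel); a test sample is voted on by every pairwise classifier and
assigned to the class with the maximum count, ties broken by summed signed
decision values then lexical order.  A single (sigma, C) pair is chosen by
grid search on a held-out subset of the training data and reused across all
pairwise classifiers and all cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)


@dataclass
class FeatureVector:
    """A tagged feature vector for one note."""

    values: np.ndarray
    tag: str = "full"  # full | separable | global | undersampled | physio | spectrum | fourier_spectrum
    label: str | None = None
    class_label: str | None = None

    _EXPECTED = {
        "full": 30976,
        "separable": 4224,
        "global": 33,
        "undersampled": 3840,
        "physio": 142080,
        "spectrum": 128,
    }

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def check_unreduced_length(self) -> None:
        expected = self._EXPECTED.get(self.tag)
        if expected is not None and self.values.size != expected:
            raise ValueError(
                f"variant {self.tag!r} expects {expected} dims, got {self.values.size}"
            )


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    names: list[str]

    def normalized(self) -> np.ndarray:
        """Row-normalized percentages; each row sums to 100."""
        c = self.counts.astype(float)
        sums = c.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        return 100.0 * c / sums

    def to_csv(self, path) -> None:
        pd.DataFrame(self.normalized(), index=self.names, columns=self.names).to_csv(path)


@dataclass
class SVMModel:
    """Pairwise classifiers over standardized features."""

    classifiers: dict
    pair_indices: dict
    X: np.ndarray
    labels: np.ndarray
    classes: list[str]
    kernel: str
    sigma: float | None
    C: float
    scaler_mean: np.ndarray | None = None
    scaler_std: np.ndarray | None = None

    def _prep(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.X.shape[1]:
            raise ValueError(
                f"feature dimension {x.shape[1]} does not match model {self.X.shape[1]}"
            )
        if self.scaler_mean is not None:
            x = (x - self.scaler_mean) / self.scaler_std
        return x


def _svc(kernel: str, sigma: float | None, C: float, tol: float = 1e-3) -> SVC:
    if kernel == "gaussian":
        return SVC(kernel="rbf", gamma=1.0 / (2.0 * sigma**2), C=C, tol=tol)
    if kernel == "linear":
        return SVC(kernel="linear", C=C, tol=tol)
    raise ValueError("kernel must be 'gaussian' or 'linear'")


def train(
    features,
    labels,
    kernel: str = "gaussian",
    sigma: float | None = None,
    C: float = 1.0,
    standardize: bool = False,
    tol: float = 1e-3,
) -> SVMModel:
    """Train one binary classifier per unordered class pair."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray([str(v) for v in labels])
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for c in classes:
        if np.sum(y == c) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    if kernel == "gaussian":
        if sigma is None or sigma <= 0:
            raise ValueError("gaussian kernel needs sigma > 0")
    if C <= 0:
        raise ValueError("C must be positive")
    mean = std = None
    if standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        X = (X - mean) / std
    classifiers, pair_indices = {}, {}
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            idx = np.where((y == a) | (y == b))[0]
            svc = _svc(kernel, sigma, C, tol)
            svc.fit(X[idx], y[idx])
            classifiers[(a, b)] = svc
            pair_indices[(a, b)] = idx
    return SVMModel(
        classifiers, pair_indices, X, y, classes, kernel, sigma, C, mean, std
    )


def predict(model: SVMModel, features) -> np.ndarray:
    """Majority vote over all pairwise classifiers."""
    x = model._prep(features)
    votes = {c: np.zeros(x.shape[0], dtype=int) for c in model.classes}
    scores = {c: np.zeros(x.shape[0]) for c in model.classes}
    for (a, b), svc in model.classifiers.items():
        dec = svc.decision_function(x)  # positive -> the lexically later class b
        votes[b] += dec > 0
        votes[a] += dec <= 0
        scores[b] += dec
        scores[a] -= dec
    out = []
    for i in range(x.shape[0]):
        best = max(
            model.classes,
            key=lambda c: (votes[c][i], scores[c][i], [-ord(ch) for ch in c]),
        )
        out.append(best)
    return np.asarray(out)


def extract_support_vectors(model: SVMModel, class_pair) -> dict:
    """Support-vector feature rows of one pairwise classifier, grouped by
    true class (rows are in the model's standardized feature space)."""
    pair = tuple(sorted(str(c) for c in class_pair))
    if pair not in model.classifiers:
        raise ValueError(f"unknown class pair {pair}")
    svc = model.classifiers[pair]
    idx = model.pair_indices[pair][svc.support_]
    out = {}
    for c in pair:
        rows = idx[model.labels[idx] == c]
        out[c] = model.X[rows]
    return out


@dataclass
class CVResult:
    fold_accuracies: np.ndarray
    mean: float
    sd: float
    confusion: ConfusionMatrix
    sigma: float | None
    C: float
    trace: dict = field(default_factory=dict)


def _sigma_grid(X: np.ndarray, n: int = 10, rng=None) -> np.ndarray:
    """Log-spaced sigma candidates spanning the 5th-95th percentile of
    pairwise Euclidean distances on (a subsample of) the data."""
    m = X.shape[0]
    if rng is not None and m > 400:
        X = X[rng.choice(m, 400, replace=False)]
    d2 = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    d = np.sqrt(d2[np.triu_indices(X.shape[0], k=1)])
    d = d[d > 0]
    lo, hi = np.percentile(d, [5, 95])
    lo = max(lo, 1e-12)
    return np.logspace(np.log10(lo), np.log10(max(hi, lo * 1.001)), n)


def _grid_search(
    X: np.ndarray, y: np.ndarray, kernel: str, seed: int, c_grid, max_subset: int = 600
) -> tuple[float | None, float]:
    """Pick a single (sigma, C) on a held-out split of a training subset."""
    rng = np.random.default_rng(seed)
    if X.shape[0] > max_subset:
        idx = []
        for c in sorted(set(y)):
            rows = np.where(y == c)[0]
            take = max(2, int(round(max_subset * rows.size / X.shape[0])))
            idx.append(rng.choice(rows, min(take, rows.size), replace=False))
        idx = np.concatenate(idx)
        X, y = X[idx], y[idx]
    Xtr, Xval, ytr, yval = train_test_split(
        X, y, test_size=0.25, stratify=y, random_state=seed % (2**32)
    )
    sigmas = _sigma_grid(Xtr, rng=rng) if kernel == "gaussian" else [None]
    best, best_acc = (None, 1.0), -1.0
    for sigma in sigmas:
        for C in c_grid:
            model = train(Xtr, ytr, kernel=kernel, sigma=sigma, C=C)
            acc = float(np.mean(predict(model, Xval) == yval))
            # ties go to the smoother kernel (larger sigma) at the smaller C
            if acc > best_acc or (
                acc == best_acc and sigma is not None and sigma != best[0]
            ):
                best, best_acc = (sigma, C), acc
    return best


def cross_validate(
    features,
    labels,
    kernel: str = "gaussian",
    k: int = 10,
    seed: int = 0,
    reducer=None,
    standardize: bool = True,
    c_grid=DEFAULT_C_GRID,
) -> CVResult:
    """Stratified k-fold cross-validation with a single grid-searched
    (sigma, C).

    ``reducer`` is an optional factory ``fit(train_X) -> transform`` (e.g.
    from :mod:`cortimbre.dimred`) applied per fold so that projections are
    estimated on training data only.  Features are standardized per
    dimension with training-fold statistics by default.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray([str(v) for v in labels])
    classes = sorted(set(y))
    counts = {c: int(np.sum(y == c)) for c in classes}
    bad = [c for c, n in counts.items() if n < k]
    if bad:
        raise ValueError(f"classes with fewer than {k} samples: {bad}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    folds = list(skf.split(X, y))

    # hyper-parameters from a subset of the first fold's training data
    tr0 = folds[0][0]
    X0 = X[tr0]
    if reducer is not None:
        X0 = reducer(X0)(X0)
    if standardize:
        mu, sd = X0.mean(axis=0), X0.std(axis=0)
        sd[sd == 0] = 1.0
        X0 = (X0 - mu) / sd
    sigma, C = _grid_search(X0, y[tr0], kernel, seed, c_grid)

    accs = []
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    cls_index = {c: i for i, c in enumerate(classes)}
    for tr, te in folds:
        Xtr, Xte = X[tr], X[te]
        if reducer is not None:
            transform = reducer(Xtr)
            Xtr, Xte = transform(Xtr), transform(Xte)
        model = train(
            Xtr, y[tr], kernel=kernel, sigma=sigma, C=C, standardize=standardize
        )
        pred = predict(model, Xte)
        accs.append(float(np.mean(pred == y[te])))
        for t, p in zip(y[te], pred):
            cm[cls_index[t], cls_index[p]] += 1
    accs = np.asarray(accs)
    return CVResult(
        fold_accuracies=accs,
        mean=float(accs.mean()),
        sd=float(accs.std(ddof=1)),
        confusion=ConfusionMatrix(cm, classes),
        sigma=sigma,
        C=C,
        trace={"class_counts": counts},
    )
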