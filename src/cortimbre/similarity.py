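"""Perceptual-similarity kernel learning.

Learns non-negative per-dimension weights ``beta_d`` of a weighted Gaussian
kernel ``K_beta(x, y) = exp(-sum_d beta_d (x_d - y_d)^2)`` so that the
kernel-induced distances between instrument profiles correlate maximally
(Pearson, over the strict upper triangle) with a human — or simulated —
dissimilarity matrix.  The induced distance is the canonical RKHS metric for
a normalized kernel, ``d_K = sqrt(2 - 2 K)``.

The optimizer is plain gradient ascent on the Pearson correlation, run on
log-parameters ``b_d`` with ``beta_d = exp(b_d)`` so positivity is automatic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# containers


@dataclass
class DissimilarityMatrix:
    """Instrument-by-instrument dissimilarities with upper-triangle semantics.

    ``values`` is square; ratings live in [0, 1], model distances are
    arbitrary non-negative.  The diagonal is conventionally zero and is never
    used in comparisons.
    """

    values: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names length must match matrix size")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("dissimilarity matrix must be finite")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def upper(self) -> np.ndarray:
        """Strict upper-triangle entries, row-major order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def symmetrized(self) -> "DissimilarityMatrix":
        """Average the two presentation orders (upper and lower halves)."""
        v = 0.5 * (self.values + self.values.T)
        np.fill_diagonal(v, 0.0)
        return DissimilarityMatrix(v, list(self.names))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.values, index=self.names, columns=self.names).to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DissimilarityMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(df.to_numpy(dtype=float), [str(c) for c in df.columns])


@dataclass
class InstrumentProfile:
    """Mean feature vector of one instrument across its notes."""

    name: str
    x: np.ndarray


@dataclass
class KernelWeights:
    """Learned kernel weights and the per-iteration objective trace.

    The backtracking optimizer produces a non-decreasing trace; the
    adaptive optimizer's trace may fluctuate locally while trending up.
    """

    beta: np.ndarray
    trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if np.any(self.beta < 0):
            raise ValueError("kernel weights must be non-negative")


# ---------------------------------------------------------------------------
# operations


def average_profiles(features: np.ndarray, labels) -> list[InstrumentProfile]:
    """Per-instrument mean feature vector (one profile per distinct label)."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    if X.shape[0] != labels.shape[0]:
        raise ValueError("features and labels must have equal length")
    profiles = []
    for name in sorted(set(labels.tolist())):
        rows = X[labels == name]
        if rows.size == 0:
            raise ValueError(f"empty group for instrument {name!r}")
        profiles.append(InstrumentProfile(str(name), rows.mean(axis=0)))
    return profiles


def weighted_kernel_distance(x: np.ndarray, y: np.ndarray, weights: KernelWeights) -> float:
    """Kernel-induced distance ``sqrt(2 - 2 K_beta(x, y))``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    beta = weights.beta
    if x.shape != y.shape or x.shape != beta.shape:
        raise ValueError("x, y and beta must have equal lengths")
    k = np.exp(-np.dot(beta, (x - y) ** 2))
    return float(np.sqrt(max(2.0 - 2.0 * k, 0.0)))


def _pair_matrix(profiles: list[InstrumentProfile]) -> tuple[np.ndarray, np.ndarray]:
    """Stack profiles and return (X, squared pairwise differences P x N)."""
    X = np.stack([p.x for p in profiles])
    n = X.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    d2 = (X[iu] - X[ju]) ** 2
    return X, d2


def _distances(d2: np.ndarray, beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    k = np.exp(-d2 @ beta)
    d = np.sqrt(np.maximum(2.0 - 2.0 * k, 0.0))
    return d, k


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    sa = np.sqrt((a * a).mean())
    sb = np.sqrt((b * b).mean())
    if sa == 0 or sb == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float((a * b).mean() / (sa * sb))


def correlation_objective(d2: np.ndarray, beta: np.ndarray, target: np.ndarray) -> float:
    """Pearson correlation between induced distances and target distances."""
    d, _ = _distances(d2, beta)
    return _pearson(d, target)


def correlation_gradient(d2: np.ndarray, beta: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Analytic gradient of the correlation objective w.r.t. beta.

    ``dd_p/dbeta_d = delta2_pd * K_p / d_p`` (from d = sqrt(2 - 2K)), chained
    with the gradient of the Pearson statistic through the distance vector.
    """
    d, k = _distances(d2, beta)
    P = d.size
    dc = d - d.mean()
    tc = target - target.mean()
    sd = np.sqrt((dc * dc).mean())
    st = np.sqrt((tc * tc).mean())
    if sd == 0 or st == 0:
        return np.zeros_like(beta)
    r = float((dc * tc).mean() / (sd * st))
    # dJ/dd_p for population-moment Pearson r
    dJ_dd = tc / (P * sd * st) - r * dc / (P * sd * sd)
    dd_db = d2 * (k / np.maximum(d, 1e-12))[:, None]
    return dd_db.T @ dJ_dd


def optimize_weights(
    profiles: list[InstrumentProfile],
    d_human: DissimilarityMatrix,
    seed: int = 0,
    max_iter: int = 2000,
    tol: float = 1e-6,
    step: float = 0.05,
    method: str = "adaptive",
) -> KernelWeights:
    """Fit kernel weights by gradient ascent on the Pearson objective.

    Ascent runs on log-weights, so positivity is automatic.  The default
    ``adaptive`` method takes per-coordinate moment-normalized steps
    (Adam-style), which both maximizes the correlation and lets weights on
    uninformative dimensions decay toward zero at a uniform rate — plain
    ascent stalls there because the log-space gradient of a vanishing
    weight vanishes with it.  ``backtracking`` selects monotone fixed-step
    ascent with step-halving, stopping when the accepted improvement drops
    below ``tol``.  ``seed`` is accepted for interface uniformity; both
    methods are deterministic given their initialization.
    """
    if len(profiles) < 4:
        raise ValueError("need at least 4 instruments to fit kernel weights")
    names = [p.name for p in profiles]
    if names != list(d_human.names):
        raise ValueError("profile and dissimilarity instrument names must match")
    _, d2 = _pair_matrix(profiles)
    target = d_human.symmetrized().upper()
    if np.allclose(target, target[0]):
        raise ValueError("constant dissimilarity matrix: correlation undefined")

    n_dim = d2.shape[1]
    med = float(np.median(d2[d2 > 0])) if np.any(d2 > 0) else 1.0
    b = np.full(n_dim, -np.log(n_dim * med))
    beta = np.exp(b)
    J = correlation_objective(d2, beta, target)
    trace = [J]

    if method == "adaptive":
        m = np.zeros(n_dim)
        v = np.zeros(n_dim)
        b1, b2, eps = 0.9, 0.999, 1e-8
        for it in range(1, max_iter + 1):
            g = correlation_gradient(d2, beta, target) * beta  # chain to log-params
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            b = b + step * (m / (1 - b1**it)) / (np.sqrt(v / (1 - b2**it)) + eps)
            beta = np.exp(np.clip(b, -700, 50))
            trace.append(correlation_objective(d2, beta, target))
        return KernelWeights(beta=beta, trace=trace)

    if method != "backtracking":
        raise ValueError("method must be 'adaptive' or 'backtracking'")
    eta = 1.0
    for _ in range(max_iter):
        g = correlation_gradient(d2, beta, target) * beta
        gnorm = float(np.max(np.abs(g)))
        if gnorm == 0:
            break
        accepted = False
        for _ in range(40):
            b_new = b + eta * g / gnorm
            beta_new = np.exp(np.clip(b_new, -700, 50))
            J_new = correlation_objective(d2, beta_new, target)
            if J_new >= J:
                accepted = True
                break
            eta *= 0.5
        if not accepted:
            break
        dJ = J_new - J
        b, beta, J = b_new, beta_new, J_new
        trace.append(J)
        eta = min(eta * 1.5, 10.0)
        if dJ < tol:
            break
    return KernelWeights(beta=beta, trace=trace)


def model_dissimilarity(
    profiles: list[InstrumentProfile], weights: KernelWeights, rescale: bool = True
) -> DissimilarityMatrix:
    """Matrix of induced distances between all instrument profiles.

    Min-max scaled to [0, 1] for display by default; Pearson comparisons are
    invariant to this scaling.
    """
    n = len(profiles)
    v = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = weighted_kernel_distance(
                profiles[i].x, profiles[j].x, weights
            )
    if rescale:
        off = v[np.triu_indices(n, k=1)]
        lo, hi = off.min(), off.max()
        if hi > lo:
            v = (v - lo) / (hi - lo)
            np.fill_diagonal(v, 0.0)
    return DissimilarityMatrix(v, [p.name for p in profiles])


def pearson_upper(a: DissimilarityMatrix, b: DissimilarityMatrix) -> float:
    """Pearson r over strict upper-triangle entries of two matrices."""
    if a.n != b.n:
        raise ValueError("matrices must have the same size")
    if list(a.names) != list(b.names):
        raise ValueError("matrices must describe the same instruments")
    ua, ub = a.upper(), b.upper()
    if ua.size < 3:
        raise ValueError("need at least 3 instrument pairs")
    return _pearson(ua, ub)
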