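"""Decision-space analysis: support-vector densities and symmetric KL.

For each cross-class instrument pair, the support vectors of the pairwise
classifier are treated as samples from two distributions in the reduced
(eigenfrequency x eigenrate x eigenscale) space.  Per-dimension densities
are estimated with 100-bin histograms over shared edges, compared with the
symmetric Kullback-Leibler divergence (zero-probability bins dropped), and
pooled by instrument class (winds, strings, percussions).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .classify import SVMModel, extract_support_vectors

N_BINS = 100


@dataclass
class DensityEstimate:
    """Per-dimension normalized histograms (D x 100) with their edges."""

    p: np.ndarray
    edges: np.ndarray  # (D, N_BINS + 1)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.edges = np.asarray(self.edges, dtype=float)
        if self.p.shape[1] != N_BINS or self.edges.shape[1] != N_BINS + 1:
            raise ValueError(f"histograms must have exactly {N_BINS} bins")
        if not np.allclose(self.p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each histogram must sum to 1")


def shared_edges(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-dimension bin edges spanning the pooled min-max of two sample sets."""
    pooled = np.vstack([np.atleast_2d(a), np.atleast_2d(b)])
    lo = pooled.min(axis=0)
    hi = pooled.max(axis=0)
    span = hi - lo
    flat = span == 0
    lo[flat] -= 0.5
    hi[flat] += 0.5
    edges = lo[:, None] + (hi - lo)[:, None] * np.linspace(0, 1, N_BINS + 1)[None, :]
    # guard the extreme bins against rounding so every pooled sample lands inside
    edges[:, 0] = np.nextafter(lo, -np.inf)
    edges[:, -1] = np.nextafter(hi, np.inf)
    return edges


def estimate_density(samples: np.ndarray, edges: np.ndarray) -> DensityEstimate:
    """100-bin histogram per dimension, normalized to unit mass."""
    X = np.atleast_2d(np.asarray(samples, dtype=float))
    if X.shape[0] < 1 or X.size == 0:
        raise ValueError("need at least one sample")
    D = X.shape[1]
    p = np.empty((D, N_BINS))
    for d in range(D):
        counts, _ = np.histogram(X[:, d], bins=edges[d])
        p[d] = counts / X.shape[0]
    return DensityEstimate(p, edges)


def smoothed(density: DensityEstimate, eps: float = 1e-6) -> DensityEstimate:
    """Add-epsilon smoothing over zero bins, renormalized."""
    p = density.p + eps
    p /= p.sum(axis=1, keepdims=True)
    return DensityEstimate(p, density.edges)


def symmetric_kl(
    p: DensityEstimate, q: DensityEstimate, dim: int, halved: bool = False
) -> float:
    """Symmetric KL divergence KL(p||q) + KL(q||p) on one dimension (nats).

    Bins where either distribution is zero are disregarded.  ``halved``
    selects the Jeffreys/2 variant.
    """
    if not np.array_equal(p.edges[dim], q.edges[dim]):
        raise ValueError("densities must share bin edges")
    pv, qv = p.p[dim], q.p[dim]
    mask = (pv > 0) & (qv > 0)
    if not np.any(mask):
        raise ValueError("no common non-zero bin")
    pv, qv = pv[mask], qv[mask]
    d = float(np.sum(pv * np.log(pv / qv)) + np.sum(qv * np.log(qv / pv)))
    return 0.5 * d if halved else d


def symmetric_kl_all(p: DensityEstimate, q: DensityEstimate, halved: bool = False) -> np.ndarray:
    """Symmetric KL on every dimension; dimensions with no common non-zero
    bin get NaN."""
    out = np.empty(p.p.shape[0])
    for d in range(p.p.shape[0]):
        try:
            out[d] = symmetric_kl(p, q, d, halved=halved)
        except ValueError:
            out[d] = np.nan
    return out


def class_pair_divergences(
    model: SVMModel,
    class_map: dict,
    dims: tuple[int, int, int] = (21, 4, 5),
    pool: str = "mean",
    classes=None,
) -> dict:
    """Pooled per-dimension divergences between instrument classes.

    For every instrument pair whose classes differ, the support vectors of
    the pairwise classifier are compared dimension by dimension; the
    resulting 420-vectors are reshaped to (eigenfrequency, eigenrate,
    eigenscale) and averaged (or median-pooled) within each unordered class
    pair.  Returns {(class_a, class_b): divergence tensor}.
    """
    n_f, n_r, n_s = dims
    classes = sorted(classes) if classes is not None else sorted(set(class_map.values()))
    members = {c: [i for i in model.classes if class_map.get(i) == c] for c in classes}
    for c, m in members.items():
        if not m:
            raise ValueError(f"class {c!r} has no instruments")
    out = {}
    for ca, cb in combinations(classes, 2):
        vals = []
        for ia in members[ca]:
            for ib in members[cb]:
                sv = extract_support_vectors(model, (ia, ib))
                a, b = sv[min(ia, ib)], sv[max(ia, ib)]
                if a.shape[0] == 0 or b.shape[0] == 0:
                    continue
                edges = shared_edges(a, b)
                da = estimate_density(a, edges)
                db = estimate_density(b, edges)
                vals.append(symmetric_kl_all(da, db))
        if not vals:
            raise ValueError(f"no support vectors for class pair ({ca}, {cb})")
        stacked = np.vstack(vals)
        pooled = (
            np.nanmean(stacked, axis=0) if pool == "mean" else np.nanmedian(stacked, axis=0)
        )
        out[(ca, cb)] = np.nan_to_num(pooled).reshape(n_f, n_r, n_s)
    return out


def eigenrate_profile(div_tensor: np.ndarray) -> np.ndarray:
    """Divergence mass per eigenrate (marginal over the other modes)."""
    return div_tensor.sum(axis=(0, 2))


def divergences_to_frame(div: dict) -> pd.DataFrame:
    """Long-format table: class_pair, eigenfrequency, eigenrate, eigenscale, value."""
    rows = []
    for (ca, cb), t in div.items():
        nf, nr, ns = t.shape
        for a in range(nf):
            for b in range(nr):
                for c in range(ns):
                    rows.append(
                        {
                            "class_pair": f"{ca}-{cb}",
                            "eigenfrequency": a,
                            "eigenrate": b,
                            "eigenscale": c,
                            "value": t[a, b, c],
                        }
                    )
    return pd.DataFrame(rows)


def ranksum(x, y):
    """Wilcoxon rank-sum test (thin wrapper; statistic, p-value)."""
    res = stats.ranksums(x, y)
    return float(res.statistic), float(res.pvalue)


def kruskal(*groups):
    """Kruskal-Wallis H test (thin wrapper; statistic, p-value)."""
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)
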