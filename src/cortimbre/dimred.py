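"""Dimensionality reduction: tensor SVD of cortical tensors and plain SVD.

The tensor route unfolds the stacked cortical tensors along each mode
(frequency, rate, scale), takes the singular value decomposition of each
unfolded matrix, and keeps the leading components per mode ("eigenfrequency
/ eigenrate / eigenscale" bases).  Projecting a tensor onto the three bases
and flattening yields the reduced feature vector; the canonical choice of
21 x 4 x 5 components gives 420 features.  The matrix route reduces stacked
response vectors (e.g. measured-STRF responses) with ordinary SVD.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """Make each basis vector's largest-magnitude entry positive
    (reproducibility across SVD backends)."""
    idx = np.argmax(np.abs(u), axis=0)
    signs = np.sign(u[idx, np.arange(u.shape[1])])
    signs[signs == 0] = 1.0
    return u * signs


@dataclass
class TensorProjection:
    """Per-mode orthonormal bases with singular values and variance accounting."""

    basis_f: np.ndarray
    basis_r: np.ndarray
    basis_s: np.ndarray
    sv_f: np.ndarray
    sv_r: np.ndarray
    sv_s: np.ndarray
    variance_retained: float
    mean: np.ndarray | None = None  # subtracted before projection when centered

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.basis_f.shape[1], self.basis_r.shape[1], self.basis_s.shape[1])

    @property
    def n_features(self) -> int:
        nf, nr, ns = self.counts
        return nf * nr * ns

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("basis_f", "basis_r", "basis_s", "sv_f", "sv_r", "sv_s"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["variance_retained"] = self.variance_retained
            if self.mean is not None:
                f.create_dataset("mean", data=self.mean)

    @classmethod
    def from_hdf5(cls, path) -> "TensorProjection":
        with h5py.File(path, "r") as f:
            kw = {
                name: f[name][()]
                for name in ("basis_f", "basis_r", "basis_s", "sv_f", "sv_r", "sv_s")
            }
            return cls(
                **kw,
                variance_retained=float(f.attrs["variance_retained"]),
                mean=f["mean"][()] if "mean" in f else None,
            )


def _mode_svd(data: np.ndarray, mode_axis: int, n: int) -> tuple[np.ndarray, np.ndarray]:
    """SVD of the data unfolded along one tensor mode (samples pooled)."""
    unfolded = np.moveaxis(data, mode_axis, 0).reshape(data.shape[mode_axis], -1)
    u, s, _ = np.linalg.svd(unfolded, full_matrices=False)
    return _fix_signs(u[:, :n]), s


def tensor_svd_fit(
    tensors, n_f: int, n_r: int, n_s: int, center: bool = False
) -> TensorProjection:
    """Fit per-mode bases from a collection of cortical tensors.

    ``tensors`` is a list of CorticalTensor or an array (n, F, R, S).
    ``variance_retained`` is the overall retained fraction: the energy of
    the multilinear projection over the total energy of the (optionally
    centered) data.
    """
    if hasattr(tensors[0], "r"):
        data = np.stack([t.r for t in tensors])
    else:
        data = np.asarray(tensors, dtype=float)
        if data.ndim == 3:
            data = data[None]
    n_samples, F, R, S = data.shape
    for n, size, name in ((n_f, F, "frequency"), (n_r, R, "rate"), (n_s, S, "scale")):
        if not 1 <= n <= size:
            raise ValueError(f"{name} component count {n} exceeds mode size {size}")
    mean = None
    if center:
        mean = data.mean(axis=0)
        data = data - mean
    uf, sf = _mode_svd(data, 1, n_f)
    ur, sr = _mode_svd(data, 2, n_r)
    us, ss = _mode_svd(data, 3, n_s)
    total = float(np.sum(data**2))
    core = np.einsum("nfrs,fa,rb,sc->nabc", data, uf, ur, us, optimize=True)
    retained = float(np.sum(core**2)) / total if total > 0 else 1.0
    return TensorProjection(uf, ur, us, sf, sr, ss, min(retained, 1.0), mean)


def tensor_svd_apply(tensor, projection: TensorProjection) -> np.ndarray:
    """Multilinear projection of one tensor, flattened (eigenfrequency-major
    C order: index = (a * n_r + b) * n_s + c)."""
    t = tensor.r if hasattr(tensor, "r") else np.asarray(tensor, dtype=float)
    F, R, S = projection.basis_f.shape[0], projection.basis_r.shape[0], projection.basis_s.shape[0]
    if t.shape != (F, R, S):
        raise ValueError(f"tensor shape {t.shape} does not match projection {(F, R, S)}")
    if projection.mean is not None:
        t = t - projection.mean
    core = np.einsum(
        "frs,fa,rb,sc->abc", t, projection.basis_f, projection.basis_r, projection.basis_s,
        optimize=True,
    )
    return core.ravel()


@dataclass
class MatrixProjection:
    """Top right-singular directions of a stacked data matrix."""

    components: np.ndarray  # (n, D)
    singular_values: np.ndarray
    variance_retained: float
    mean: np.ndarray | None = None

    def apply(self, vectors: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(vectors, dtype=float))
        if self.mean is not None:
            X = X - self.mean
        out = X @ self.components.T
        return out[0] if np.asarray(vectors).ndim == 1 else out


def matrix_svd_reduce(
    vectors, n: int, center: bool = False
) -> tuple[MatrixProjection, np.ndarray]:
    """SVD-reduce stacked vectors to their top-n singular directions."""
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 vectors")
    if n > min(X.shape):
        raise ValueError(f"n={n} exceeds min(dim, count)={min(X.shape)}")
    mean = None
    if center:
        mean = X.mean(axis=0)
        X = X - mean
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    comps = _fix_signs(vt[:n].T).T
    total = float(np.sum(s**2))
    retained = float(np.sum(s[:n] ** 2)) / total if total > 0 else 1.0
    proj = MatrixProjection(comps, s, min(retained, 1.0), mean)
    return proj, (X @ comps.T)


def tensor_reducer(n_f: int, n_r: int, n_s: int, shape=(128, 22, 11), center: bool = False):
    """Factory for cross-validation: fit a tensor projection on training-fold
    vectors (raveled tensors) and return the transform for any fold."""

    def fit(train_X: np.ndarray):
        data = train_X.reshape(-1, *shape)
        proj = tensor_svd_fit(data, n_f, n_r, n_s, center=center)

        def transform(X: np.ndarray) -> np.ndarray:
            data_x = X.reshape(-1, *shape)
            if proj.mean is not None:
                data_x = data_x - proj.mean
            return np.einsum(
                "nfrs,fa,rb,sc->nabc", data_x, proj.basis_f, proj.basis_r, proj.basis_s,
                optimize=True,
            ).reshape(X.shape[0], -1)

        return transform

    return fit


def matrix_reducer(n: int, center: bool = False):
    """Factory for cross-validation: plain SVD reduction fit on training folds."""

    def fit(train_X: np.ndarray):
        proj, _ = matrix_svd_reduce(train_X, n, center=center)
        return proj.apply

    return fit
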