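"""Phase-space reconstructions of R(t): Broomhead-King eigenfunction
embedding and recurrence plots.

The Broomhead-King (singular-spectrum) embedding projects lagged windows of
the mean-removed series onto the leading eigenvectors of the M x M window
autocovariance matrix C_M = X^T X / (n - M + 1), where X is the
(n - M + 1) x M trajectory matrix of M-lagged windows.  Projections onto
the top three eigenvectors form the eigenfunctions Psi_1..Psi_3, a
relatively denoised alternative to raw delay coordinates: variance in the
discarded trailing eigendirections is the "noise" floor.

A recurrence plot marks the pairs of times whose 3-dimensional
delay-embedded states (delay tau = 1) lie within a closeness threshold
epsilon of each other: RP[i, j] = Theta(eps - ||x_i - x_j||).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import SeriesTooShortError
from .measures import delay_embed_values, _values


def delay_embed(series, dim: int = 3, tau: int = 1) -> np.ndarray:
    """Time-delay embedding: point i = (x_i, x_{i+tau}, ..., x_{i+(dim-1)tau}).

    Returns an (n - (dim-1)*tau, dim) array.
    """
    return delay_embed_values(_values(series), dim, tau)


# ---------------------------------------------------------------------------
# Broomhead-King

@dataclass
class BKEmbedding:
    """Eigendecomposition of the lag-window covariance and the projected
    trajectories."""

    M: int
    eigenvalues: np.ndarray    # descending, length M
    eigenvectors: np.ndarray   # (M, M), columns orthonormal
    psi: np.ndarray            # (n - M + 1, 3): Psi_1..Psi_3

    @property
    def psi1(self) -> np.ndarray:
        return self.psi[:, 0]

    @property
    def psi2(self) -> np.ndarray:
        return self.psi[:, 1]

    @property
    def psi3(self) -> np.ndarray:
        return self.psi[:, 2]

    def bounding_box_volume(self) -> float:
        """Volume of the axis-aligned bounding box of the (Psi1,Psi2,Psi3)
        trajectory — a simple occupied-phase-volume summary."""
        ext = self.psi.max(0) - self.psi.min(0)
        return float(np.prod(ext))


class BroomheadKing(BaseEstimator, TransformerMixin):
    """sklearn-style Broomhead-King embedding estimator.

    Parameters
    ----------
    M : int
        Lag-window length (default 8, about one correlation decay interval
        of R(t) at 2 s sampling).
    n_components : int
        Number of leading eigenfunctions returned by ``transform``.

    Attributes (after ``fit``)
    --------------------------
    eigenvalues_ : (M,) descending eigenvalues of C_M.
    components_ : (M, M) eigenvector matrix, columns sorted to match,
        each flipped so its largest-magnitude entry is positive.
    mean_ : the series mean removed before windowing.
    """

    def __init__(self, M: int = 8, n_components: int = 3):
        self.M = M
        self.n_components = n_components

    def _trajectory_matrix(self, x: np.ndarray) -> np.ndarray:
        n = x.size
        if n < 10 * self.M:
            raise SeriesTooShortError(
                f"series of length {n} too short for M={self.M} (need 10M)")
        idx = np.arange(self.M)[None, :] + np.arange(n - self.M + 1)[:, None]
        return x[idx]

    def fit(self, series, y=None):
        x = _values(series)
        self.mean_ = float(x.mean())
        X = self._trajectory_matrix(x - self.mean_)
        C = X.T @ X / X.shape[0]
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        # sign convention: largest-magnitude entry of each vector positive
        flips = np.sign(V[np.abs(V).argmax(axis=0), np.arange(self.M)])
        flips[flips == 0] = 1.0
        self.eigenvalues_ = w
        self.components_ = V * flips
        self.covariance_ = C
        return self

    def transform(self, series) -> np.ndarray:
        x = _values(series)
        X = self._trajectory_matrix(x - self.mean_)
        return X @ self.components_[:, : self.n_components]

    def fit_transform(self, series, y=None):
        return self.fit(series).transform(series)


def bk_embed(series, M: int = 8) -> BKEmbedding:
    """Broomhead-King embedding with the top three eigenfunctions."""
    est = BroomheadKing(M=M, n_components=3)
    psi = est.fit_transform(series)
    return BKEmbedding(M=M, eigenvalues=est.eigenvalues_,
                       eigenvectors=est.components_, psi=psi)


# ---------------------------------------------------------------------------
# recurrence plots

@dataclass
class RecurrencePlot:
    """Binary recurrence matrix of an embedded series."""

    matrix: np.ndarray   # (n', n') bool, symmetric, diagonal True
    dim: int
    tau: int
    eps: float           # the threshold actually applied (absolute units)
    norm: str = "euclidean"

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def recurrence_plot(series, dim: int = 3, tau: int = 1, eps: float = 1.0,
                    mode: str = "absolute", q: float = 10.0,
                    norm: str = "euclidean") -> RecurrencePlot:
    """Recurrence plot RP[i, j] = 1 iff ||x_i - x_j|| <= eps.

    ``mode="absolute"`` applies ``eps`` directly (the figure-matching
    default, eps = 1).  Because R(t) scales differ across data sources,
    ``mode="quantile"`` instead sets the threshold to the q-th percentile of
    the off-diagonal pairwise distances, which makes cross-state comparisons
    scale-fair.  ``norm`` is "euclidean" or "max".
    """
    pts = delay_embed(series, dim, tau)
    if eps < 0:
        raise ValueError("eps must be nonnegative")
    diff = pts[:, None, :] - pts[None, :, :]
    if norm == "euclidean":
        dist = np.sqrt((diff ** 2).sum(-1))
    elif norm == "max":
        dist = np.abs(diff).max(-1)
    else:
        raise ValueError(f"unknown norm {norm!r}")
    if mode == "quantile":
        off = dist[~np.eye(len(pts), dtype=bool)]
        eps = float(np.percentile(off, q))
    elif mode != "absolute":
        raise ValueError(f"unknown mode {mode!r}")
    return RecurrencePlot(matrix=dist <= eps, dim=dim, tau=tau,
                          eps=float(eps), norm=norm)


def recurrence_rate(rp: RecurrencePlot):
    """Off-diagonal recurrence density and the per-diagonal profile.

    Returns (rate, profile): ``rate`` is the fraction of off-diagonal ones;
    ``profile[k-1]`` is the recurrence density of diagonal offset k (the
    fraction of time pairs separated by k samples that recur), used for
    band/clustering detection.  Idling cells give near-uniform profiles
    (homogeneous returns); treadmilling cells cluster their return times,
    raising the profile's coefficient of variation.
    """
    m = rp.matrix
    n = m.shape[0]
    off_mask = ~np.eye(n, dtype=bool)
    rate = float(m[off_mask].mean()) if n > 1 else 0.0
    profile = np.array([m.diagonal(k).mean() for k in range(1, n)])
    return rate, profile


def rp_to_image(rp: RecurrencePlot, path) -> None:
    """Export the RP as a PNG, black = recurrent."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(~rp.matrix, cmap="gray", origin="lower", interpolation="none")
    ax.set_xlabel("i")
    ax.set_ylabel("j")
    fig.savefig(path, dpi=150)
    plt.close(fig)
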