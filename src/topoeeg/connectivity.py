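"""Per-epoch connectivity: phase-locking (C) and standardized-distance (D).

Two channel-by-channel matrices feed the filtration:

* the C-matrix holds phase-locking values, ``C_pq = |mean_n exp(j(phi_p(n) -
  phi_q(n)))|`` with instantaneous phases from the analytic (Hilbert)
  signal, zero diagonal by convention;
* the D-matrix holds squared standardized Euclidean distances between
  channel time series, ``d(r, t) = sum_k ((r_k - t_k) / s_k)^2`` where
  ``s_k`` is the sample standard deviation across channels at sample ``k``.

``to_filtration`` converts either into a dissimilarity in [0, 1] for the
Vietoris-Rips sweep: strongly locked pairs (C near 1) get small weights and
connect early.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class PhaseMatrix:
    """Instantaneous phases per channel, radians in (-pi, pi]."""

    phases: np.ndarray
    fs: float
    edge_frac: float = 0.1

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=np.float64)
        if self.phases.ndim != 2:
            raise ValueError("phases must be channels x samples")
        if np.any(self.phases > np.pi + 1e-12) or np.any(self.phases <= -np.pi - 1e-12):
            raise ValueError("phases must lie in (-pi, pi]")

    @property
    def n_samples(self) -> int:
        return self.phases.shape[1]

    @property
    def edge_mask(self) -> np.ndarray:
        """True on the first and last ``edge_frac`` of samples, where the
        Hilbert transform is edge-affected."""
        n = self.n_samples
        k = int(np.floor(self.edge_frac * n))
        mask = np.zeros(n, dtype=bool)
        if k:
            mask[:k] = True
            mask[-k:] = True
        return mask


@dataclass
class ConnectivityMatrix:
    """Symmetric channels x channels matrix, C-kind or D-kind."""

    values: np.ndarray
    kind: str
    normalized: bool = False
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.kind not in ("C", "D"):
            raise ValueError("kind must be 'C' or 'D'")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.abs(np.diag(v)) > 1e-12):
            raise ValueError("connectivity matrix must have zero diagonal")
        if self.kind == "C" and not self.normalized:
            if v.min() < -1e-12 or v.max() > 1 + 1e-9:
                raise ValueError("phase-locking values must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def instantaneous_phase(epoch: np.ndarray, fs: float,
                        edge_frac: float = 0.1) -> PhaseMatrix:
    """Phase of the analytic signal of each channel.

    The caller is responsible for band-limiting the epoch first; a broadband
    signal has no meaningful single instantaneous phase.
    """
    epoch = np.asarray(epoch, dtype=np.float64)
    if epoch.ndim != 2:
        raise ValueError("epoch must be channels x samples")
    if epoch.shape[1] < 64:
        raise ValueError("need at least 64 samples for a stable phase estimate")
    power = np.abs(epoch).max(axis=1)
    dead = np.nonzero(power == 0)[0]
    if len(dead):
        raise ValueError(
            f"channel(s) {dead.tolist()} are identically zero; instantaneous "
            f"phase is undefined"
        )
    analytic = hilbert(epoch, axis=1)
    return PhaseMatrix(np.angle(analytic), fs, edge_frac=edge_frac)


def plv_matrix(phases: PhaseMatrix, trim_edges: bool = False,
               channel_labels: list[str] | None = None) -> ConnectivityMatrix:
    """Phase-locking value for every channel pair; diagonal fixed at 0.

    ``trim_edges=True`` excludes the edge-affected 10% of samples at either
    end from the time average.
    """
    phi = phases.phases
    if phi.shape[0] < 2:
        raise ValueError("need at least 2 channels")
    if trim_edges:
        phi = phi[:, ~phases.edge_mask]
    z = np.exp(1j * phi)
    n = z.shape[1]
    c = np.abs(z @ z.conj().T) / n
    np.fill_diagonal(c, 0.0)
    np.clip(c, 0.0, 1.0, out=c)
    c = 0.5 * (c + c.T)
    return ConnectivityMatrix(c, "C", normalized=False,
                              channel_labels=list(channel_labels or []))


def distance_matrix(epoch: np.ndarray, squared: bool = True,
                    channel_labels: list[str] | None = None,
                    ) -> ConnectivityMatrix:
    """Standardized Euclidean distance between channel time series.

    Standardization is per sample position: ``s_k`` is the sample standard
    deviation (ddof=1) of the values all channels take at sample ``k``. The
    squared form is the default; ``squared=False`` takes the square root
    (same simplex ordering after min-max normalization, different values).
    """
    x = np.asarray(epoch, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("epoch must be channels x samples with >= 2 channels")
    s = x.std(axis=0, ddof=1)
    degenerate = np.nonzero(s == 0)[0]
    if len(degenerate):
        raise ValueError(
            f"all channels are equal at sample position(s) "
            f"{degenerate[:5].tolist()}; standardized distance is undefined"
        )
    d = pdist(x, metric="seuclidean", V=s ** 2)
    if squared:
        d = d ** 2
    return ConnectivityMatrix(squareform(d), "D", normalized=False,
                              channel_labels=list(channel_labels or []))


def to_filtration(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Dissimilarity weights in [0, 1] for the Vietoris-Rips sweep.

    C-kind: ``w = 1 - C`` (perfectly locked pairs connect at eps = 0+).
    D-kind: min-max normalization of the off-diagonal entries.
    """
    v = matrix.values.copy()
    m = matrix.n_channels
    off = ~np.eye(m, dtype=bool)
    if matrix.kind == "C":
        v[off] = 1.0 - v[off]
    else:
        lo, hi = v[off].min(), v[off].max()
        if hi == lo:
            warnings.warn(
                "degenerate distance matrix (all off-diagonal entries equal); "
                "using uniform weights 0.5", stacklevel=2)
            v[off] = 0.5
        else:
            v[off] = (v[off] - lo) / (hi - lo)
    np.fill_diagonal(v, 0.0)
    return ConnectivityMatrix(v, matrix.kind, normalized=True,
                              channel_labels=list(matrix.channel_labels))


class PhaseLockingConnectivity(TransformerMixin, BaseEstimator):
    """Transform band-limited epochs into PLV filtration weights.

    Input ``X`` has shape (n_trials, n_channels, n_samples); output is
    (n_trials, n_channels, n_channels) of ``1 - PLV`` weights (or raw PLV
    with ``normalize=False``). Stateless; ``fit`` only validates.
    """

    def __init__(self, fs: float = 250.0, trim_edges: bool = False,
                 normalize: bool = True):
        self.fs = fs
        self.trim_edges = trim_edges
        self.normalize = normalize

    def fit(self, X, y=None):
        self._validate(X)
        return self

    def transform(self, X) -> np.ndarray:
        X = self._validate(X)
        out = np.empty((X.shape[0], X.shape[1], X.shape[1]))
        for i, epoch in enumerate(X):
            cm = plv_matrix(instantaneous_phase(epoch, self.fs),
                            trim_edges=self.trim_edges)
            if self.normalize:
                cm = to_filtration(cm)
            out[i] = cm.values
        return out

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3:
            raise ValueError("X must be (n_trials, n_channels, n_samples)")
        return X


class StandardizedDistanceConnectivity(TransformerMixin, BaseEstimator):
    """Transform epochs into standardized-distance filtration weights."""

    def __init__(self, squared: bool = True, normalize: bool = True):
        self.squared = squared
        self.normalize = normalize

    def fit(self, X, y=None):
        PhaseLockingConnectivity._validate(X)
        return self

    def transform(self, X) -> np.ndarray:
        X = PhaseLockingConnectivity._validate(X)
        out = np.empty((X.shape[0], X.shape[1], X.shape[1]))
        for i, epoch in enumerate(X):
            cm = distance_matrix(epoch, squared=self.squared)
            if self.normalize:
                cm = to_filtration(cm)
            out[i] = cm.values
        return out
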