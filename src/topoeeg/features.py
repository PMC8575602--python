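"""Persistent entropy of barcodes.

The persistent entropy of a barcode ``B = {(x_i, y_i)}`` is the Shannon
entropy of its normalized bar-length distribution,

    H = -sum_i p_i log p_i,    p_i = (y_i - x_i) / L,    L = sum_i (y_i - x_i),

and the rescaled form divides by the log of the longest bar,

    H_hat = H / log(l_max).

Essential bars are truncated at the maximal filtration scale before lengths
are taken (for a connected complex the essential component bar is the
largest-scale structure; dropping it would discard exactly that).

Caveat, documented rather than silently corrected: on a normalized
filtration every bar length is <= 1, so ``log(l_max) <= 0`` and the printed
rescaling flips the sign of H (and is undefined at ``l_max = 1``). The
alternative normalization ``H_hat_alt = H / log(n_bars)`` (entropy divided
by its maximum, in [0, 1]) is therefore computed alongside and is what the
condition classifier consumes by default; ``H_hat`` is reported exactly as
defined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .topology import BarcodeSet


@dataclass
class PEFeature:
    """Persistent-entropy summary of one barcode.

    ``H`` is in units of the configured ``log_base`` (nats by default);
    ``H_hat`` is H / log(l_max) as printed, ``H_hat_alt`` is H / log(n_bars).
    Optional metadata identifies where the barcode came from.
    """

    H: float
    H_hat: float
    H_hat_alt: float
    n_bars: int
    l_max: float
    dims_used: tuple[int, ...]
    log_base: float = math.e
    matrix_kind: str | None = None
    band: str | None = None
    trial_index: int | None = None
    condition: str | None = None


def _bar_lengths(barcode: BarcodeSet, dims) -> np.ndarray:
    lengths = np.asarray(
        [b.length(barcode.max_filtration) for b in barcode.in_dims(dims)])
    return lengths[lengths > 0]


def persistent_entropy(barcode: BarcodeSet, dims=(0, 1, 2),
                       log_base: float = math.e, **metadata) -> PEFeature:
    """Shannon entropy of the normalized bar-length distribution.

    Bars of the requested dimensions are pooled into one distribution;
    zero-length bars are dropped; essential bars get death = the barcode's
    maximal filtration scale.
    """
    lengths = _bar_lengths(barcode, dims)
    if len(lengths) == 0:
        raise ValueError(
            f"no bars of positive length in dimensions {tuple(dims)}"
        )
    h_nats = float(stats.entropy(lengths))  # normalizes internally
    h = h_nats / math.log(log_base)
    l_max = float(lengths.max())
    n = len(lengths)
    h_hat = rescaled_entropy(h, l_max, log_base=log_base, warn=False)
    h_hat_alt = 0.0 if n == 1 else h_nats / math.log(n)
    return PEFeature(h, h_hat, h_hat_alt, n, l_max, tuple(dims),
                     log_base=log_base, **metadata)


def rescaled_entropy(h: float, l_max: float, log_base: float = math.e,
                     warn: bool = True) -> float:
    """H / log(l_max), exactly as defined; NaN when l_max = 1.

    The ratio is independent of ``log_base`` (both logs change base
    together). Negative for l_max < 1; see the module caveat.
    """
    if l_max <= 0:
        raise ValueError("l_max must be positive")
    if l_max == 1.0:
        if warn:
            warnings.warn(
                "l_max = 1 makes H/log(l_max) undefined; use H_hat_alt",
                stacklevel=2)
        return float("nan")
    return h / (math.log(l_max) / math.log(log_base))


class PersistentEntropy(TransformerMixin, BaseEstimator):
    """Transform barcodes into entropy features.

    Input is a list of :class:`BarcodeSet`; output has shape (n_trials, 3)
    with columns ``[H, H_hat, H_hat_alt]``. Stateless.
    """

    FEATURE_NAMES = ("H", "H_hat", "H_hat_alt")

    def __init__(self, dims=(0, 1, 2), log_base: float = math.e):
        self.dims = dims
        self.log_base = log_base

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        out = np.empty((len(X), 3))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i, bc in enumerate(X):
                f = persistent_entropy(bc, dims=self.dims,
                                       log_base=self.log_base)
                out[i] = (f.H, f.H_hat, f.H_hat_alt)
        return out

    def get_feature_names_out(self, input_features=None):
        return np.asarray(self.FEATURE_NAMES, dtype=object)
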