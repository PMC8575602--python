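"""Vietoris-Rips filtrations, persistent homology, Euler curves.

The filtration is built on the channel set of a normalized connectivity
matrix: a simplex on a vertex subset enters at the maximum pairwise weight
among its vertices (clique/flag rule), swept over the scale ``epsilon``.
Simplices are kept up to dimension 3 so that voids (beta_2) are computable
and the Euler characteristic can be cross-checked against
beta_0 - beta_1 + beta_2 - beta_3.

Persistence is computed by column reduction of the boundary matrices over
GF(2), with the clearing optimization (a pivot found while reducing
dimension d identifies a creator column in dimension d-1 that need not be
reduced). Columns are processed in (filtration value, lexicographic vertex
tuple) order within each dimension; any face-respecting order yields the
same barcode, the fixed order makes internal pairings reproducible.

The Euler characteristic curve chi(epsilon) is the alternating sum of
simplex counts, the Euler entropy is S = ln|chi| (with a -inf sentinel at
chi = 0), and the phase-transition point eps* is the scale at which S
attains its negative peak, i.e. where chi first touches or crosses zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .connectivity import ConnectivityMatrix

_INF = float("inf")


# ---------------------------------------------------------------------------
# filtered complexes

@dataclass
class FilteredComplex:
    """A filtered simplicial complex of dimension <= 3.

    ``simplices[d]`` is an integer array of shape (n_d, d+1) with vertex
    tuples sorted ascending per row; ``values[d]`` holds the filtration value
    of each d-simplex. ``max_filtration`` is the scale at which essential
    features are truncated downstream (1.0 for normalized connectivity
    filtrations).
    """

    n_vertices: int
    simplices: dict[int, np.ndarray]
    values: dict[int, np.ndarray]
    max_filtration: float | None = None

    def __post_init__(self) -> None:
        if self.max_filtration is None:
            vmax = 0.0
            for v in self.values.values():
                if len(v):
                    vmax = max(vmax, float(v.max()))
            self.max_filtration = vmax

    @classmethod
    def from_simplices(cls, simplices: list[tuple[tuple[int, ...], float]],
                       n_vertices: int | None = None,
                       max_filtration: float | None = None,
                       ) -> "FilteredComplex":
        """Build from an explicit (vertex-tuple, value) list (test fixtures)."""
        by_dim: dict[int, list] = {}
        by_val: dict[int, list] = {}
        nv = 0
        for verts, val in simplices:
            verts = tuple(sorted(verts))
            d = len(verts) - 1
            by_dim.setdefault(d, []).append(verts)
            by_val.setdefault(d, []).append(float(val))
            nv = max(nv, verts[-1] + 1)
        if n_vertices is None:
            n_vertices = nv
        return cls(
            n_vertices,
            {d: np.asarray(v, dtype=np.int64).reshape(len(v), d + 1)
             for d, v in by_dim.items()},
            {d: np.asarray(v, dtype=np.float64) for d, v in by_val.items()},
            max_filtration=max_filtration,
        )

    @property
    def max_dim(self) -> int:
        return max((d for d, s in self.simplices.items() if len(s)), default=0)

    @property
    def n_simplices(self) -> int:
        return sum(len(s) for s in self.simplices.values())

    def simplex_list(self) -> list[tuple[tuple[int, ...], float]]:
        out = []
        for d in sorted(self.simplices):
            for row, val in zip(self.simplices[d], self.values[d]):
                out.append((tuple(int(v) for v in row), float(val)))
        return out

    def validate_faces(self) -> None:
        """Raise unless every face is present with value <= its coface's."""
        lookup: dict[int, dict[tuple, float]] = {}
        for d in self.simplices:
            lookup[d] = {tuple(row): float(val) for row, val
                         in zip(self.simplices[d], self.values[d])}
        for d in sorted(self.simplices):
            if d == 0:
                continue
            faces = lookup.get(d - 1, {})
            for row, val in zip(self.simplices[d], self.values[d]):
                verts = tuple(row)
                for j in range(d + 1):
                    face = verts[:j] + verts[j + 1:]
                    if face not in faces:
                        raise ValueError(
                            f"complex not face-closed: {verts} present but "
                            f"face {face} missing"
                        )
                    if faces[face] > val + 1e-12:
                        raise ValueError(
                            f"face {face} enters after its coface {verts}"
                        )


@lru_cache(maxsize=8)
def _combinations(n: int, k: int) -> np.ndarray:
    """All k-subsets of range(n) as an (C(n,k), k) int array (cached)."""
    return np.asarray(list(itertools.combinations(range(n), k)),
                      dtype=np.int64).reshape(-1, k)


def vietoris_rips(weights: ConnectivityMatrix | np.ndarray, max_dim: int = 3,
                  max_simplices: int = 2_000_000,
                  max_filtration: float | None = None) -> FilteredComplex:
    """Flag filtration of the complete weighted graph, up to ``max_dim``.

    ``weights`` must be a symmetric dissimilarity matrix with zero diagonal
    (a filtration-ready connectivity matrix). A d-simplex gets the maximum
    pairwise weight among its vertices; vertices enter at 0.
    """
    if isinstance(weights, ConnectivityMatrix):
        if not weights.normalized:
            raise ValueError(
                "connectivity matrix must be filtration-normalized first "
                "(see to_filtration)"
            )
        if max_filtration is None:
            max_filtration = 1.0
        w = weights.values
    else:
        w = np.asarray(weights, dtype=np.float64)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("weight matrix must be symmetric")
    if np.any(np.abs(np.diag(w)) > 1e-12):
        raise ValueError("weight matrix must have zero diagonal")

    m = w.shape[0]
    total = sum(math.comb(m, k + 1) for k in range(max_dim + 1))
    if total > max_simplices:
        raise ValueError(
            f"{total} simplices for {m} vertices at max_dim={max_dim} exceeds "
            f"the cap {max_simplices}; threshold the weights or use fewer "
            f"channels"
        )

    simplices = {0: _combinations(m, 1)}
    values = {0: np.zeros(m)}
    for d in range(1, max_dim + 1):
        if m < d + 1:
            break
        combos = _combinations(m, d + 1)
        val = w[combos[:, 0], combos[:, 1]]
        for a, b in itertools.combinations(range(d + 1), 2):
            if (a, b) == (0, 1):
                continue
            np.maximum(val, w[combos[:, a], combos[:, b]], out=val)
        simplices[d] = combos
        values[d] = val
    return FilteredComplex(m, simplices, values,
                           max_filtration=max_filtration)


# ---------------------------------------------------------------------------
# barcodes

@dataclass(frozen=True)
class Bar:
    """One persistence interval [birth, death) in a given dimension.

    ``death`` is ``inf`` for essential features (alive at the maximal scale).
    """

    dim: int
    birth: float
    death: float

    @property
    def essential(self) -> bool:
        return math.isinf(self.death)

    def length(self, max_filtration: float) -> float:
        return (max_filtration if self.essential else self.death) - self.birth


@dataclass
class BarcodeSet:
    """All persistence intervals of one filtration."""

    bars: list[Bar]
    max_filtration: float

    def in_dims(self, dims) -> list[Bar]:
        dims = set(dims)
        return [b for b in self.bars if b.dim in dims]

    def n_essential(self, dim: int) -> int:
        return sum(1 for b in self.bars if b.dim == dim and b.essential)


def _dim_order(complex_: FilteredComplex, d: int) -> np.ndarray:
    """Indices sorting d-simplices by (value, lexicographic vertex tuple)."""
    verts = complex_.simplices[d]
    keys = tuple(verts[:, j] for j in range(verts.shape[1] - 1, -1, -1))
    return np.lexsort(keys + (complex_.values[d],))


def persistence(complex_: FilteredComplex, check_faces: bool = True,
                ) -> BarcodeSet:
    """Barcode of a filtered complex by GF(2) boundary-matrix reduction.

    Returns bars in every dimension present (0 .. max_dim of the complex);
    dimension-3 bars exist only to support the Euler-Poincare cross-check.
    """
    if check_faces:
        complex_.validate_faces()

    dims = [d for d in sorted(complex_.simplices) if len(complex_.simplices[d])]
    if not dims or dims[0] != 0:
        raise ValueError("complex must contain vertices")
    top = dims[-1]

    order = {d: _dim_order(complex_, d) for d in dims}
    sorted_values = {d: complex_.values[d][order[d]] for d in dims}
    sorted_verts = {d: complex_.simplices[d][order[d]] for d in dims}
    # row index of each (d-1)-simplex in its sorted order
    row_index = {
        d: {tuple(row): i for i, row in enumerate(sorted_verts[d])}
        for d in dims
    }

    # reduce top dimension first so pivots clear creator columns below
    pairs: dict[int, list[tuple[int, int]]] = {}   # d -> [(row in d-1, col in d)]
    cleared: dict[int, set[int]] = {d: set() for d in dims}
    zero_cols: dict[int, set[int]] = {d: set() for d in dims}

    for d in reversed(dims):
        if d == 0:
            break
        rows = row_index[d - 1]
        verts = sorted_verts[d]
        n_cols = len(verts)
        pivot: dict[int, int] = {}      # row -> column bitset
        d_pairs: list[tuple[int, int]] = []
        skip = cleared[d]
        for j in range(n_cols):
            if j in skip:
                continue
            vj = tuple(verts[j])
            col = 0
            for k in range(d + 1):
                col |= 1 << rows[vj[:k] + vj[k + 1:]]
            while col:
                p = col.bit_length() - 1
                other = pivot.get(p)
                if other is None:
                    break
                col ^= other
            if col:
                pivot[p] = col
                d_pairs.append((p, j))
            else:
                zero_cols[d].add(j)
        pairs[d] = d_pairs
        cleared[d - 1] = {p for p, _ in d_pairs}

    # assemble bars: creators in dim d are zero/cleared columns (all vertices
    # in dim 0); deaths come from the pairs found one dimension up.
    bars: list[Bar] = []
    for d in dims:
        death_of = {p: sorted_values[d + 1][j]
                    for p, j in pairs.get(d + 1, [])} if d + 1 in dims else {}
        if d == 0:
            creators = range(complex_.n_vertices)
        else:
            creators = sorted(zero_cols[d] | cleared[d])
        for i in creators:
            birth = float(sorted_values[d][i])
            death = float(death_of.get(i, _INF))
            bars.append(Bar(d, birth, death))
    return BarcodeSet(bars, float(complex_.max_filtration))


def betti_curves(barcode: BarcodeSet, grid: np.ndarray,
                 dims=(0, 1, 2, 3)) -> dict[int, np.ndarray]:
    """beta_k(eps) = bars with birth <= eps < death (half-open convention).

    Essential bars count for every eps >= birth.
    """
    grid = np.asarray(grid, dtype=np.float64)
    out = {d: np.zeros(len(grid), dtype=np.int64) for d in dims}
    for b in barcode.bars:
        if b.dim not in out:
            continue
        alive = (grid >= b.birth) & (grid < b.death)
        out[b.dim] += alive
    return out


# ---------------------------------------------------------------------------
# Euler characteristic / entropy

@dataclass
class EulerCurve:
    """chi(eps) and the Euler entropy S(eps) = ln|chi| on a value grid.

    ``entropy`` carries ``-inf`` where chi = 0; ``transition_point`` is the
    scale of the negative peak of S (None when the curve never dips).
    """

    grid: np.ndarray
    chi: np.ndarray
    entropy: np.ndarray = field(init=False)
    transition_point: float | None = field(init=False, default=None)
    transition_rule: str = "global-min"

    def __post_init__(self) -> None:
        with np.errstate(divide="ignore"):
            self.entropy = np.where(
                self.chi == 0, -np.inf, np.log(np.abs(self.chi)))
        self.transition_point = phase_transition_point(
            self, rule=self.transition_rule)


def euler_curve(complex_: FilteredComplex, grid: np.ndarray | None = None,
                transition_rule: str = "global-min") -> EulerCurve:
    """Alternating simplex-count curve chi(eps) over the filtration.

    The default grid is the sorted unique filtration values (every event is
    a grid point); a uniform grid may be passed for plotting.
    """
    all_vals = np.concatenate([complex_.values[d]
                               for d in sorted(complex_.simplices)
                               if len(complex_.values[d])])
    if grid is None:
        grid = np.unique(all_vals)
    else:
        grid = np.asarray(grid, dtype=np.float64)

    chi = np.zeros(len(grid), dtype=np.int64)
    for d in sorted(complex_.simplices):
        vals = np.sort(complex_.values[d])
        counts = np.searchsorted(vals, grid, side="right")
        chi += (-1) ** d * counts
    return EulerCurve(grid, chi, transition_rule=transition_rule)


def phase_transition_point(curve: EulerCurve,
                           rule: str = "global-min") -> float | None:
    """Scale of the negative peak of the Euler entropy.

    The first grid value where chi touches zero or changes sign wins (S dives
    to -inf through a zero crossing there). If chi keeps its initial sign
    throughout, the ``global-min`` rule returns the earliest grid value at
    which S attains its minimum, or None when that minimum already sits at
    the first grid point (no dip at all); the ``first-zero`` rule returns
    None in that case.
    """
    chi, grid = curve.chi, curve.grid
    if len(grid) == 0:
        return None
    sign0 = np.sign(chi[0])
    crossed = np.nonzero((chi == 0) | (np.sign(chi) != sign0))[0]
    if len(crossed):
        return float(grid[crossed[0]])
    if rule == "first-zero":
        return None
    if rule != "global-min":
        raise ValueError(f"unknown transition rule {rule!r}")
    with np.errstate(divide="ignore"):
        s = np.where(chi == 0, -np.inf, np.log(np.abs(chi)))
    i = int(np.argmin(s))
    if i == 0:
        return None
    return float(grid[i])


class VietorisRipsPersistence(TransformerMixin, BaseEstimator):
    """Per-trial flag-filtration persistence from filtration weights.

    Input ``X`` has shape (n_trials, n_channels, n_channels) of normalized
    dissimilarity matrices; output is a list of :class:`BarcodeSet`.
    Stateless; ``fit`` only validates. Face-closure checking is skipped in
    the batch path (the flag construction guarantees it).
    """

    def __init__(self, max_dim: int = 3, max_filtration: float = 1.0,
                 max_simplices: int = 2_000_000):
        self.max_dim = max_dim
        self.max_filtration = max_filtration
        self.max_simplices = max_simplices

    def fit(self, X, y=None):
        self._validate(X)
        return self

    def transform(self, X) -> list[BarcodeSet]:
        X = self._validate(X)
        out = []
        for w in X:
            cx = vietoris_rips(w, max_dim=self.max_dim,
                               max_simplices=self.max_simplices,
                               max_filtration=self.max_filtration)
            out.append(persistence(cx, check_faces=False))
        return out

    @staticmethod
    def _validate(X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 3 or X.shape[1] != X.shape[2]:
            raise ValueError("X must be (n_trials, n_channels, n_channels)")
        return X
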