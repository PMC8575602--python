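"""Independent oracles for the topology tests.

The Betti oracle computes ranks of the boundary matrices of the sub-complex
at each scale directly by Gauss elimination over GF(2) — no persistence
pairing anywhere — so it is an independent check on the reduction algorithm.
"""

from __future__ import annotations

import numpy as np

from topoeeg.topology import FilteredComplex


def gf2_rank(a: np.ndarray) -> int:
    """Rank of a 0/1 matrix over the two-element field."""
    a = a.copy().astype(np.uint8)
    rank = 0
    rows, cols = a.shape
    for c in range(cols):
        piv = None
        for i in range(rank, rows):
            if a[i, c]:
                piv = i
                break
        if piv is None:
            continue
        a[[rank, piv]] = a[[piv, rank]]
        mask = a[:, c].astype(bool)
        mask[rank] = False
        a[mask] ^= a[rank]
        rank += 1
    return rank


def betti_bruteforce(cx: FilteredComplex, eps: float) -> dict[int, int]:
    """Betti numbers of the sub-complex at scale eps by rank-nullity.

    beta_d = n_d - rank(boundary_d) - rank(boundary_{d+1}).
    """
    present = {
        d: [tuple(v) for v, val in zip(cx.simplices[d], cx.values[d])
            if val <= eps + 1e-12]
        for d in sorted(cx.simplices)
    }

    def boundary_rank(k: int) -> int:
        cols = present.get(k, [])
        rows = present.get(k - 1, [])
        if not cols or not rows:
            return 0
        idx = {s: i for i, s in enumerate(rows)}
        mat = np.zeros((len(rows), len(cols)), dtype=np.uint8)
        for j, s in enumerate(cols):
            for m in range(len(s)):
                mat[idx[s[:m] + s[m + 1:]], j] = 1
        return gf2_rank(mat)

    return {d: len(present.get(d, [])) - boundary_rank(d) - boundary_rank(d + 1)
            for d in present}


def random_weight_matrix(m: int, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric dissimilarity matrix in [0, 1] with zero diagonal."""
    w = rng.uniform(0.0, 1.0, (m, m))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return w
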