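"""Binomial multiplicative cascade: the closed-form multifractal oracle.

The 1-D binomial cascade splits mass recursively with weights p and
1 - p; after k generations the 2^k cell masses are products of k
factors.  Its Renyi spectrum is known exactly:

    D_q = log2(p^q + (1-p)^q) / (1 - q)        (q != 1)
    D_1 = -(p log2 p + (1-p) log2 (1-p))

which makes it the reference object for validating generalized
dimension estimates.
"""

from __future__ import annotations

import numpy as np

__all__ = ["binomial_cascade", "cascade_count_grid", "renyi_closed_form"]


def binomial_cascade(p: float, depth: int) -> np.ndarray:
    """Cell masses of the depth-k cascade; 2^k values summing to 1."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    masses = np.array([1.0])
    for _ in range(depth):
        masses = np.concatenate([masses * p, masses * (1.0 - p)])
    return masses


def cascade_count_grid(p: float, depth: int, total: int = 2**24) -> np.ndarray:
    """The cascade rasterized as an integer count grid (1 row).

    Cell masses are scaled by ``total`` and rounded, giving a 1 x 2^k
    grid of pixel counts that the partition-moment machinery accepts in
    place of a binary image.  Rounding is the only approximation.
    """
    masses = binomial_cascade(p, depth)
    counts = np.round(masses * total).astype(np.int64)
    if np.any(counts == 0):
        raise ValueError("total too small: some cells round to zero mass")
    return counts[np.newaxis, :]


def renyi_closed_form(p: float, q: float) -> float:
    """Exact D_q of the binomial cascade with weight p."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must lie in (0, 1)")
    if np.isclose(q, 1.0):
        return float(-(p * np.log2(p) + (1 - p) * np.log2(1 - p)))
    return float(np.log2(p**q + (1 - p) ** q) / (1.0 - q))
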