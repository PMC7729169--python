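"""Order-2 (piecewise-linear) B-spline bases on [0, 1] and tensor products.

Order-2 B-splines on a clamped knot vector are triangular "hat" functions:
one basis function per knot site, peaking at its knot and falling linearly to
zero at the neighbouring knots.  They form a partition of unity, which is
what lets a fitted spline network be read out as fuzzy membership sets
(Low / Mid / High) later on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "initial_knots",
    "insert_node",
    "hat_basis",
    "one_hot",
    "tensor_basis",
]


def initial_knots(n_sets: int = 2) -> tuple[float, ...]:
    """Uniform clamped knot sites for ``n_sets`` basis functions on [0, 1]."""
    if n_sets < 2:
        raise ValueError("at least two basis functions are required")
    return tuple(np.linspace(0.0, 1.0, n_sets))


def insert_node(knots: tuple[float, ...]) -> tuple[float, ...]:
    """Insert one knot at the midpoint of the widest inter-knot interval.

    Ties are broken toward the lower interval, making refinement fully
    deterministic (refining [0, 1] yields 0.5, then 0.25, then 0.75, ...).
    """
    arr = np.asarray(knots)
    widths = np.diff(arr)
    i = int(np.argmax(widths))  # argmax takes the first (lowest) maximum
    mid = (arr[i] + arr[i + 1]) / 2.0
    return tuple(sorted(set(knots) | {float(mid)}))


def hat_basis(knots: tuple[float, ...], x: np.ndarray) -> np.ndarray:
    """Evaluate the hat-function basis at ``x`` (clamped to [0, 1]).

    Returns an array of shape ``(len(x), len(knots))`` whose rows sum to 1.
    """
    t = np.asarray(knots, dtype=float)
    x = np.clip(np.asarray(x, dtype=float), t[0], t[-1])
    n = len(t)
    out = np.zeros((x.size, n))
    # interval index j such that t[j] <= x < t[j+1]
    j = np.clip(np.searchsorted(t, x, side="right") - 1, 0, n - 2)
    left, right = t[j], t[j + 1]
    frac = (x - left) / (right - left)
    rows = np.arange(x.size)
    out[rows, j] = 1.0 - frac
    out[rows, j + 1] += frac
    return out


def one_hot(levels: tuple, values: np.ndarray) -> np.ndarray:
    """Indicator basis for a categorical input (one column per level)."""
    index = {level: k for k, level in enumerate(levels)}
    out = np.zeros((len(values), len(levels)))
    for i, v in enumerate(values):
        try:
            out[i, index[v]] = 1.0
        except KeyError:
            raise ValueError(f"unknown categorical level {v!r}; expected one of {levels}")
    return out


def tensor_basis(blocks: list[np.ndarray]) -> np.ndarray:
    """Row-wise Kronecker product of per-input basis matrices.

    Each block has shape ``(n, k_i)``; the result has shape ``(n, prod k_i)``
    and inherits the partition-of-unity property from its factors.
    """
    out = blocks[0]
    for block in blocks[1:]:
        out = np.einsum("ni,nj->nij", out, block).reshape(out.shape[0], -1)
    return out
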