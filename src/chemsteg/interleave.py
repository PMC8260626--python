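"""Seed-regenerable permutations shared by the codec and the framing layer.

A writer and a reader who share only one small integer must rebuild the
same permutation, so the shuffle is pinned to a fixed 64-bit linear
congruential generator and a Fisher-Yates pass over Python integers.
This keeps the permutation bit-identical across platforms and numpy
versions (no dependence on ``numpy.random`` stream details).
"""

from __future__ import annotations

import numpy as np

# Knuth/MMIX LCG constants, modulus 2**64.
_LCG_A = 6364136223846793005
_LCG_C = 1442695040888963407
_MASK = (1 << 64) - 1


def lcg_permutation(seed: int, n: int) -> np.ndarray:
    """Deterministic permutation of ``0..n-1`` driven by ``seed``.

    Fisher-Yates shuffle; the swap index at step ``i`` is drawn from the
    upper 32 bits of the LCG state, modulo ``i + 1``.

    Parameters
    ----------
    seed : int
        Any Python integer; reduced modulo 2**64.
    n : int
        Permutation length, at least 1.

    Returns
    -------
    numpy.ndarray of int64, shape ``(n,)``
        A permutation of ``0..n-1`` (0-based indices).
    """
    if n < 1:
        raise ValueError(f"permutation length must be >= 1, got {n}")
    state = int(seed) & _MASK
    idx = list(range(n))
    for i in range(n - 1, 0, -1):
        state = (_LCG_A * state + _LCG_C) & _MASK
        j = (state >> 32) % (i + 1)
        idx[i], idx[j] = idx[j], idx[i]
    return np.asarray(idx, dtype=np.int64)


def check_permutation(idx: np.ndarray) -> np.ndarray:
    """Validate that ``idx`` is a 0-based permutation; return it as int64."""
    idx = np.asarray(idx, dtype=np.int64)
    n = idx.size
    if n == 0 or not np.array_equal(np.sort(idx), np.arange(n)):
        raise ValueError("indices are not a permutation of 0..n-1")
    return idx
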