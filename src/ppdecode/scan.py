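"""Work-efficient tree-based inclusive prefix sum.

Cumulative weight sums inside the particle filter are computed with the
balanced-binary-tree (up-sweep / down-sweep) schedule rather than a library
cumulative sum: the two-phase schedule performs O(n) additions over
O(log2 n) levels and is the algorithm that parallelises on wide hardware.
The serial running sum is kept only as a cross-check oracle in the tests.
"""

from __future__ import annotations

import numpy as np

__all__ = ["inclusive_scan"]


def _next_pow2(n: int) -> int:
    return 1 << (n - 1).bit_length()


def inclusive_scan(values, *, return_level_adds: bool = False):
    """Inclusive prefix sum via the two-phase balanced-tree schedule.

    Parameters
    ----------
    values : 1-d array-like of finite numbers
        Input sequence. Non-power-of-two lengths are zero-padded to the
        next power of two internally and truncated back on output.
    return_level_adds : bool
        If True, also return the number of additions performed at each
        up-sweep level (level ``d`` uses stride ``2**d``); with a padded
        length ``m`` the count at level ``d`` is ``m / 2**(d+1)``.

    Returns
    -------
    out : ndarray, same length as ``values``
        ``out[k] == values[0] + ... + values[k]``. Integer inputs stay in
        exact integer arithmetic.
    level_adds : list of int, only if ``return_level_adds``
    """
    x = np.asarray(values)
    if x.ndim != 1:
        raise ValueError("inclusive_scan expects a 1-d vector")
    if x.size == 0:
        raise ValueError("inclusive_scan requires a non-empty vector")
    if np.issubdtype(x.dtype, np.integer):
        x = x.astype(np.int64)
    else:
        x = x.astype(np.float64)
        if not np.all(np.isfinite(x)):
            raise ValueError("inclusive_scan requires finite values")

    n = x.size
    m = _next_pow2(n)
    buf = np.zeros(m, dtype=x.dtype)
    buf[:n] = x

    # Up-sweep: at stride d each right child accumulates its left sibling,
    # leaving each subtree root holding the sum of its leaves.
    level_adds = []
    d = 1
    while d < m:
        buf[2 * d - 1 :: 2 * d] += buf[d - 1 :: 2 * d]
        level_adds.append(m // (2 * d))
        d *= 2

    # Down-sweep: root cleared, then each parent hands its value to the
    # left child and (value + old left subtree sum) to the right child,
    # producing the exclusive scan.
    buf[m - 1] = 0
    d = m // 2
    while d >= 1:
        left = buf[d - 1 :: 2 * d].copy()
        buf[d - 1 :: 2 * d] = buf[2 * d - 1 :: 2 * d]
        buf[2 * d - 1 :: 2 * d] += left
        d //= 2

    out = buf[:n] + x  # exclusive -> inclusive
    if return_level_adds:
        return out, level_adds
    return out
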