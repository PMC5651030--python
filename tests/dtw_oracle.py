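"""Independent brute-force DTW oracle shared by the test modules."""

import functools

import numpy as np


def brute_force_dtw(x, y, squared=False):
    """Plain unconstrained DTW by memoized recursion.

    Returns ``(distance, path_length)`` where the path length is the
    minimum among cost-optimal alignments. Written independently of the
    banded dynamic program it checks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)

    def cost(i, j):
        d = x[i] - y[j]
        return d * d if squared else abs(d)

    @functools.lru_cache(maxsize=None)
    def best(i, j):
        """(cost, min path length) of the best alignment of x[:i+1], y[:j+1]."""
        c = cost(i, j)
        if i == 0 and j == 0:
            return c, 1
        candidates = []
        if i > 0 and j > 0:
            candidates.append(best(i - 1, j - 1))
        if i > 0:
            candidates.append(best(i - 1, j))
        if j > 0:
            candidates.append(best(i, j - 1))
        opt = min(c for c, _ in candidates)
        length = min(l for c, l in candidates if c == opt)
        return c + opt, length + 1

    return best(len(x) - 1, len(y) - 1)
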