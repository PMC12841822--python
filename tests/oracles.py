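"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own implementations: the Jenks
oracle enumerates every partition of the sorted values, and the quarter
oracle scans all 12 wrap-around quarters directly.
"""

from itertools import combinations

import numpy as np


def exhaustive_jenks(values, k):
    """Globally optimal within-class SSE over all partitions of the sorted
    values into k contiguous classes, by full enumeration.

    Returns (min_sse, breaks) with breaks = the minimum of each upper class,
    choosing the lowest break values among ties.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    pref = np.concatenate([[0.0], np.cumsum(x)])
    pref2 = np.concatenate([[0.0], np.cumsum(x * x)])

    def sse(i, j):  # x[i:j]
        c = j - i
        s = pref[j] - pref[i]
        return pref2[j] - pref2[i] - s * s / c

    best = (np.inf, None)
    # split points are the start indices of classes 2..k
    for splits in combinations(range(1, n), k - 1):
        bounds = (0,) + splits + (n,)
        total = sum(sse(bounds[c], bounds[c + 1]) for c in range(k))
        brks = tuple(x[i] for i in splits)
        if total < best[0] - 1e-12 or (
            abs(total - best[0]) <= 1e-12 and (best[1] is None or brks < best[1])
        ):
            best = (total, brks)
    return best


def exhaustive_jenks_vectorized(values, k):
    """Same optimum as :func:`exhaustive_jenks` but vectorized so n = 60,
    k = 6 (about 5 million partitions) stays fast."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    pref = np.concatenate([[0.0], np.cumsum(x)])
    pref2 = np.concatenate([[0.0], np.cumsum(x * x)])
    combos = np.array(list(combinations(range(1, n), k - 1)), dtype=np.int64)
    bounds = np.hstack(
        [np.zeros((combos.shape[0], 1), np.int64), combos, np.full((combos.shape[0], 1), n)]
    )
    total = np.zeros(combos.shape[0])
    for c in range(k):
        i = bounds[:, c]
        j = bounds[:, c + 1]
        s = pref[j] - pref[i]
        total += pref2[j] - pref2[i] - s * s / (j - i)
    best = float(total.min())
    return best


def dp_sse(values, breaks):
    """Within-class SSE implied by a set of break values (half-open classes)."""
    x = np.asarray(values, dtype=float)
    codes = np.searchsorted(np.asarray(breaks, dtype=float), x, side="right")
    total = 0.0
    for c in np.unique(codes):
        seg = x[codes == c]
        total += float(((seg - seg.mean()) ** 2).sum())
    return total


def brute_force_quarter_min_precip(rain12):
    """Minimum 3-month wrap-around quarter precipitation, by direct scan."""
    r = np.asarray(rain12, dtype=float)
    return min(r[[q % 12, (q + 1) % 12, (q + 2) % 12]].sum() for q in range(12))
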