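"""Independent brute-force oracles used by the test suite only.

The excess-mass oracle enumerates every system of at most j disjoint
intervals with endpoints at data points (exhaustive recursion), represents
each as the line mass - lam*length, and maximises the piecewise-linear
difference of the two upper envelopes exactly: the maximiser lies at a
pairwise line intersection or at an endpoint of [0, lam_hi].
"""

from __future__ import annotations

import numpy as np


def _system_lines(x: np.ndarray, j_max: int) -> np.ndarray:
    """All (mass, total_length) pairs over systems of <= j_max index-disjoint
    intervals with endpoints at data points (plus the empty system)."""
    n = x.size
    intervals = [(i, j) for i in range(n) for j in range(i, n)]
    lines: set[tuple[int, float]] = {(0, 0.0)}

    def recurse(start: int, left: int, count: int, length: float) -> None:
        for (i, j) in intervals:
            if i < start:
                continue
            c, ln = count + (j - i + 1), length + (x[j] - x[i])
            lines.add((c, ln))
            if left > 1:
                recurse(j + 1, left - 1, c, ln)

    recurse(0, j_max, 0, 0.0)
    return np.array([[c / n, ln] for c, ln in lines], dtype=float)


def excess_mass_brute(data, k: int) -> float:
    """Exact D_{n,k} by exhaustive enumeration; practical for n <= 8."""
    x = np.sort(np.asarray(data, dtype=float))
    n = x.size
    if n <= 1:
        return 0.0
    span = x[-1] - x[0]
    if span <= 0:
        return 0.0
    x = (x - x[0]) / span
    gaps = np.diff(x)
    pos = gaps[gaps > 0]
    lam_hi = 1.000001 / pos.min()

    lines_k = _system_lines(x, k)
    lines_k1 = _system_lines(x, k + 1)
    both = np.vstack([lines_k, lines_k1])
    mass, length = both[:, 0], both[:, 1]
    cands = [0.0, lam_hi]
    for i in range(both.shape[0]):
        dm = mass[i] - mass
        dl = length[i] - length
        ok = np.abs(dl) > 1e-15
        lam = dm[ok] / dl[ok]
        cands.extend(lam[(lam > 0) & (lam < lam_hi)].tolist())
    lam = np.unique(np.asarray(cands))
    best = 0.0
    for chunk in np.array_split(lam, max(1, lam.size // 4000)):
        e_k = (lines_k[:, 0][None, :]
               - np.outer(chunk, lines_k[:, 1])).max(axis=1)
        e_k1 = (lines_k1[:, 0][None, :]
                - np.outer(chunk, lines_k1[:, 1])).max(axis=1)
        best = max(best, float((e_k1 - e_k).max()))
    return best
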