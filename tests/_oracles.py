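"""Independent reference implementations used only as test oracles.

These deliberately duplicate none of the package's code paths: the
fixation-index oracle is a plain scalar transcription of the general
r-population variance-component equations of Weir & Cockerham (1984),
the connectivity oracle is a double loop over gene pairs, and the
permutation oracle enumerates label arrangements exhaustively.
"""

from __future__ import annotations

from itertools import combinations
from math import sqrt

import numpy as np


def wc84_components(pop_counts):
    """Weir & Cockerham (1984) a, b, c for r populations, scalar arithmetic.

    Parameters
    ----------
    pop_counts : list of (nAA, nAa, naa) tuples, one per population.

    Returns
    -------
    (a, b, c) floats. theta-hat = a / (a + b + c) when the denominator is
    non-zero.
    """
    r = len(pop_counts)
    n = [sum(c) for c in pop_counts]
    p = [(2 * c[0] + c[1]) / (2 * ni) for c, ni in zip(pop_counts, n)]
    h = [c[1] / ni for c, ni in zip(pop_counts, n)]

    nbar = sum(n) / r
    nc = (r * nbar - sum(ni * ni for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)

    a = (nbar / nc) * (
        s2 - (1.0 / (nbar - 1)) * (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar)
        - ((r - 1) / r) * s2
        - ((2 * nbar - 1) / (4 * nbar)) * hbar
    )
    c = hbar / 2
    return a, b, c


def wc84_theta(pop_counts):
    a, b, c = wc84_components(pop_counts)
    denom = a + b + c
    return a / denom if denom != 0 else float("nan")


def brute_ktotal(values, beta):
    """kTotal by an explicit double loop with scalar Pearson correlation."""
    g, s = values.shape
    means = values.mean(axis=1)
    out = np.zeros(g)
    for i in range(g):
        for j in range(g):
            if i == j:
                continue
            xi = values[i] - means[i]
            xj = values[j] - means[j]
            r = float(xi @ xj) / (sqrt(float(xi @ xi)) * sqrt(float(xj @ xj)))
            out[i] += abs(r) ** beta
    return out


def exhaustive_permutation_p(values, labels, sided="two"):
    """Exact permutation p by enumerating every label arrangement.

    ``values`` must be free of missing entries; ``labels`` boolean. The
    observed arrangement counts as one of the enumerated ones.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    k = int(labels.sum())
    n = values.size
    obs = values[labels].mean() - values[~labels].mean()
    count = 0
    total = 0
    for idx in combinations(range(n), k):
        sel = np.zeros(n, dtype=bool)
        sel[list(idx)] = True
        d = values[sel].mean() - values[~sel].mean()
        if sided == "two":
            hit = abs(d) >= abs(obs) - 1e-12
        else:
            hit = d >= obs - 1e-12
        count += hit
        total += 1
    return count / total
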