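"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own code paths: assignment optima
are found by enumerating permutations, and rarefied richness by averaging
over every subset of sampling units.
"""

from itertools import combinations, permutations

import numpy as np


def kw_brute_force(d: np.ndarray) -> float:
    """Minimal mean cost over all fixed-point-free permutations."""
    n = d.shape[0]
    perms = np.array(
        [p for p in permutations(range(n)) if all(p[i] != i for i in range(n))]
    )
    costs = d[np.arange(n), perms].sum(axis=1)
    return float(costs.min() / n)


def kb_brute_force(block: np.ndarray) -> float:
    """Minimal mean cost over all injections of the smaller population into
    the larger."""
    na, nb = block.shape
    mat = block if na <= nb else block.T
    na, nb = mat.shape
    best = np.inf
    for p in permutations(range(nb), na):
        best = min(best, mat[np.arange(na), list(p)].sum())
    return float(best / na)


def rarefied_richness_brute_force(unit_incidence: np.ndarray, t: int) -> float:
    """Mean richness over every size-t subset of sampling units."""
    T = unit_incidence.shape[1]
    vals = [
        (unit_incidence[:, list(c)].sum(axis=1) > 0).sum()
        for c in combinations(range(T), t)
    ]
    return float(np.mean(vals))


def expected_spectrum_brute_force(unit_incidence: np.ndarray, t: int) -> np.ndarray:
    """Mean incidence-frequency spectrum E[Q_k(t)], k = 1..t, over every
    size-t subset of units."""
    T = unit_incidence.shape[1]
    acc = np.zeros(t)
    subsets = list(combinations(range(T), t))
    for c in subsets:
        y = unit_incidence[:, list(c)].sum(axis=1)
        for k in range(1, t + 1):
            acc[k - 1] += (y == k).sum()
    return acc / len(subsets)


def permanova_f_brute_force(d: np.ndarray, labels: np.ndarray) -> float:
    """Pseudo-F computed from first principles on the full matrix."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = (d**2).sum() / (2 * n)
    ss_within = 0.0
    for g in groups:
        ix = np.flatnonzero(labels == g)
        ss_within += (d[np.ix_(ix, ix)] ** 2).sum() / (2 * len(ix))
    ss_between = ss_total - ss_within
    k = len(groups)
    return (ss_between / (k - 1)) / (ss_within / (n - k))
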