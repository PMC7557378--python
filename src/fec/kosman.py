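"""Assignment-based dispersion and differentiation of plant populations.

Within-population variation is measured by the assignment-based dispersion
KW: the minimal average dissimilarity achieved by optimally matching each
plant to a *different* plant of the same population (a fixed-point-free
permutation; mutual 2-cycles are permitted).  Between-population distance
KB is the minimal average dissimilarity of a one-to-one matching of the
smaller population's plants to distinct plants of the larger one.

Differentiation D among the N populations of one host follows the additive
partition of average-based dispersion (total = within + among), tested by
permuting plants among populations while preserving sizes.  The effective
number of populations ¹D(TM) = 1 + (N−1)·M (M the mean pairwise KB), and
its normalized form ¹nD(TM) = (¹D(TM) − 1)/(N − 1) = M, translate the mean
between-population distance into "how many completely distinct populations
would look like this".

Both statistics are linear assignment problems solved exactly
(Jonker–Volgenant via scipy); the self-assignment ban is imposed by an
infinite diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .io import DistanceMatrix, FecError


def kw_dispersion(d: np.ndarray | DistanceMatrix) -> float:
    """Assignment-based dispersion of one population.

    KW = (1/n) × minimal total cost of a fixed-point-free assignment on the
    within-population distance matrix.
    """
    mat = d.d if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    n = mat.shape[0]
    if n < 2:
        raise FecError("KW dispersion requires at least 2 individuals")
    cost = mat.copy()
    np.fill_diagonal(cost, np.inf)
    rows, cols = linear_sum_assignment(cost)
    assert (rows != cols).all()  # derangement by construction
    return float(mat[rows, cols].sum() / n)


def kosman_distance(block: np.ndarray) -> float:
    """Between-population distance KB from a rectangular block of
    cross-population dissimilarities.

    Each member of the smaller population is matched to a distinct member
    of the larger; KB is the average cost over the min(n_a, n_b) matched
    pairs at the optimum.
    """
    block = np.asarray(block, dtype=float)
    if block.ndim != 2 or 0 in block.shape:
        raise FecError("between-population block must be non-empty 2-D")
    rows, cols = linear_sum_assignment(block)
    return float(block[rows, cols].sum() / min(block.shape))


def average_dispersion(d: np.ndarray | DistanceMatrix) -> float:
    """Average-based dispersion: mean pairwise distance (i < j)."""
    mat = d.d if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    n = mat.shape[0]
    if n < 2:
        raise FecError("average dispersion requires at least 2 individuals")
    iu = np.triu_indices(n, 1)
    return float(mat[iu].mean())


def effective_number(M: float, N: int) -> tuple[float, float]:
    """Effective number of populations from a mean distance M in [0, 1]:
    effective = 1 + (N−1)·M, normalized = (effective − 1)/(N − 1)."""
    if not 0.0 <= M <= 1.0:
        raise FecError(f"mean distance {M} outside [0, 1]")
    if N < 2:
        raise FecError("need at least 2 populations")
    eff = 1.0 + (N - 1) * M
    return eff, (eff - 1.0) / (N - 1)


@dataclass
class DispersionResult:
    population: str
    n: int
    kw: float
    m_avg: float
    normalized_effective_number: float  # ¹nD(T, KW)


@dataclass
class DifferentiationResult:
    group: str
    n_populations: int
    kb: pd.DataFrame            # pairwise Kosman distances between populations
    M: float                    # mean pairwise KB
    D: float                    # among-population differentiation
    p_value: float
    effective: float            # ¹D(TM)
    normalized: float           # ¹nD(TM)
    n_permutations: int
    seed: int | None
    variant: str


def within_population_variation(
    dm: DistanceMatrix,
    populations: dict[str, list[str]],
    pooled_label: str = "all",
) -> list[DispersionResult]:
    """KW dispersion and normalized effective number of plants, per
    population and for the pooled set of all listed plants.

    With M = KW and N = the population's plant count, the normalized
    effective number ¹nD(T, KW) equals KW itself.
    """
    out: list[DispersionResult] = []
    pooled_ids: list[str] = []
    for name, ids in populations.items():
        pooled_ids.extend(ids)
        if len(ids) < 2:
            warnings.warn(f"population {name!r} has fewer than 2 plants; skipped")
            continue
        sub = dm.submatrix(ids)
        kw = kw_dispersion(sub)
        _, norm = effective_number(kw, len(ids))
        out.append(DispersionResult(name, len(ids), kw, average_dispersion(sub), norm))
    if len(populations) > 1 and len(pooled_ids) >= 2:
        sub = dm.submatrix(pooled_ids)
        kw = kw_dispersion(sub)
        _, norm = effective_number(kw, len(pooled_ids))
        out.append(
            DispersionResult(pooled_label, len(pooled_ids), kw, average_dispersion(sub), norm)
        )
    return out


def _d_statistic(
    d: np.ndarray, idx: list[np.ndarray], variant: str
) -> float:
    """Differentiation D from a pooled distance matrix and population
    index lists."""
    sizes = np.array([len(ix) for ix in idx])
    if variant == "partition":
        n = d.shape[0]
        iu = np.triu_indices(n, 1)
        m_pooled = d[iu].mean()
        within = 0.0
        for ix in idx:
            sub = d[np.ix_(ix, ix)]
            within += len(ix) / sizes.sum() * sub[np.triu_indices(len(ix), 1)].mean()
        return float(m_pooled - within)
    if variant == "assignment":
        kbs = []
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                kbs.append(kosman_distance(d[np.ix_(idx[a], idx[b])]))
        kws = [kw_dispersion(d[np.ix_(ix, ix)]) for ix in idx]
        return float(np.mean(kbs) - np.mean(kws))
    raise FecError(f"unknown D variant {variant!r}")


def differentiation(
    dm: DistanceMatrix,
    populations: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int | None = None,
    variant: str = "partition",
    group: str = "",
) -> DifferentiationResult:
    """Differentiation among populations with permutation significance.

    The observed D follows ``variant`` ("partition": pooled average-based
    dispersion minus size-weighted within dispersion; "assignment": mean
    pairwise KB minus mean KW).  The permutation null reshuffles plants
    among populations preserving sizes; p = (1 + #{D_perm >= D_obs}) /
    (1 + n_perm).  Effective numbers always derive from M, the mean
    pairwise Kosman distance between populations.
    """
    if n_perm < 1:
        raise FecError("n_perm must be >= 1")
    names = list(populations)
    if len(names) < 2:
        raise FecError("need at least 2 populations")
    for name in names:
        if len(populations[name]) < 2:
            raise FecError(f"population {name!r} has fewer than 2 plants")

    all_ids = [i for name in names for i in populations[name]]
    sub = dm.submatrix(all_ids)
    pos = {s: i for i, s in enumerate(all_ids)}
    idx = [np.array([pos[i] for i in populations[name]]) for name in names]

    kb = np.zeros((len(names), len(names)))
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            kb[a, b] = kb[b, a] = kosman_distance(sub.d[np.ix_(idx[a], idx[b])])
    M = float(kb[np.triu_indices(len(names), 1)].mean())
    eff, norm = effective_number(M, len(names))

    d_obs = _d_statistic(sub.d, idx, variant)
    rng = np.random.default_rng(seed)
    n = len(all_ids)
    sizes = [len(ix) for ix in idx]
    bounds = np.cumsum([0] + sizes)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pidx = [perm[bounds[g] : bounds[g + 1]] for g in range(len(sizes))]
        if _d_statistic(sub.d, pidx, variant) >= d_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return DifferentiationResult(
        group=group,
        n_populations=len(names),
        kb=pd.DataFrame(kb, index=names, columns=names),
        M=M,
        D=float(d_obs),
        p_value=p,
        effective=eff,
        normalized=norm,
        n_permutations=n_perm,
        seed=seed,
        variant=variant,
    )
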