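"""Pairwise dissimilarities, principal coordinates, permutation group tests.

Community structure among plants is compared with Bray–Curtis
dissimilarity on (typically Hellinger-transformed) abundances and Dice
dissimilarity on incidence data, ordinated by classical PCoA, and tested
for host/site effects with one-factor PERMANOVA and ANOSIM under label
permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .io import AbundanceTable, DistanceMatrix, FecError, IncidenceMatrix


def _check_no_zero_pairs(mat: np.ndarray, ids: list[str]) -> None:
    zero = np.flatnonzero(mat.sum(axis=0) == 0)
    if len(zero) >= 2:
        pair = (ids[zero[0]], ids[zero[1]])
        raise FecError(f"dissimilarity undefined between empty samples, e.g. {pair}")


def bray_curtis(at: AbundanceTable) -> DistanceMatrix:
    """d(x, y) = Σ|x_i − y_i| / Σ(x_i + y_i) on sample columns."""
    _check_no_zero_pairs(at.values, at.sample_ids)
    d = squareform(pdist(at.values.T, metric="braycurtis"))
    return DistanceMatrix(list(at.sample_ids), d)


def dice(inc: IncidenceMatrix) -> DistanceMatrix:
    """d = 1 − 2a/(2a + b + c): shared presences a, unilateral b, c."""
    _check_no_zero_pairs(inc.incidence, inc.sample_ids)
    d = squareform(pdist(inc.incidence.T.astype(bool), metric="dice"))
    return DistanceMatrix(list(inc.sample_ids), d)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame      # items × axes
    eigenvalues: np.ndarray        # positive eigenvalues, decreasing
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> OrdinationResult:
    """Classical scaling: double-center −½ d², eigendecompose, scale
    eigenvectors by sqrt of positive eigenvalues.  Axes with non-positive
    eigenvalues are dropped (negative ones are reported)."""
    n = len(dm.ids)
    d2 = dm.d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(abs(evals[0]), 1.0) * 1e-12
    pos = evals > tol
    neg = evals[evals < -tol]
    lam = evals[pos]
    coords = evecs[:, pos] * np.sqrt(lam)
    if n_axes is not None:
        if n_axes > pos.sum():
            warnings.warn(
                f"requested {n_axes} axes but only {int(pos.sum())} positive "
                "eigenvalues; truncating"
            )
            n_axes = int(pos.sum())
        coords = coords[:, :n_axes]
        kept_lam = lam[:n_axes]
    else:
        kept_lam = lam
    prop = kept_lam / lam.sum() if lam.size else kept_lam
    frame = pd.DataFrame(
        coords[:, : len(kept_lam)],
        index=dm.ids,
        columns=[f"PCo{i + 1}" for i in range(len(kept_lam))],
    )
    return OrdinationResult(frame, kept_lam, prop, neg)


@dataclass
class GroupTestResult:
    method: str
    statistic: float               # pseudo-F (PERMANOVA) or R (ANOSIM)
    p_value: float
    n_permutations: int
    seed: int | None
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise FecError("permutation p-value must lie in (0, 1]")


def _group_indices(labels: np.ndarray) -> list[np.ndarray]:
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise FecError("need at least 2 groups")
    idx = [np.flatnonzero(labels == g) for g in groups]
    if any(len(i) == 0 for i in idx):
        raise FecError("empty group")
    return idx


def _permanova_f(d2: np.ndarray, idx: list[np.ndarray], n: int) -> tuple[float, float]:
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for ix in idx:
        sub = d2[np.ix_(ix, ix)]
        ss_within += sub.sum() / (2.0 * len(ix))
    ss_between = ss_total - ss_within
    k = len(idx)
    with np.errstate(divide="ignore"):  # zero within-group SS -> F = inf
        f = (ss_between / (k - 1)) / (ss_within / (n - k))
    return f, ss_between / ss_total


def permanova(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
) -> GroupTestResult:
    """One-factor PERMANOVA: pseudo-F from squared-distance partitions,
    p-value by label reshuffling, reported as (1 + b)/(1 + B)."""
    labels = np.asarray(pd.Series(labels, index=dm.ids).loc[dm.ids])
    n = len(dm.ids)
    d2 = dm.d**2
    idx = _group_indices(labels)
    f_obs, r2 = _permanova_f(d2, idx, n)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        pidx = [perm[ix] for ix in idx]
        f_perm, _ = _permanova_f(d2, pidx, n)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return GroupTestResult("permanova", float(f_obs), p, n_perm, seed, r_squared=float(r2))


def anosim(
    dm: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int | None = None,
) -> GroupTestResult:
    """ANOSIM R = (mean between-group rank − mean within-group rank) /
    (M/2), with M = n(n−1)/2 condensed distances, ties by midranks."""
    labels = np.asarray(pd.Series(labels, index=dm.ids).loc[dm.ids])
    n = len(dm.ids)
    _group_indices(labels)  # validation
    condensed = squareform(dm.d, checks=False)
    ranks = rankdata(condensed)  # midranks
    M = n * (n - 1) / 2.0
    total_sum = ranks.sum()
    iu = np.triu_indices(n, 1)

    def r_stat(lab: np.ndarray) -> float:
        within_mask = (lab[:, None] == lab[None, :])[iu]
        within_sum = ranks[within_mask].sum()
        n_within = within_mask.sum()
        n_between = M - n_within
        mean_w = within_sum / n_within
        mean_b = (total_sum - within_sum) / n_between
        return (mean_b - mean_w) / (M / 2.0)

    r_obs = r_stat(labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(labels)) >= r_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return GroupTestResult("anosim", float(r_obs), p, n_perm, seed)
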