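"""Incidence-based Hill-number diversity with rarefaction and extrapolation.

Diversity of a population of plants is measured on incidence data: each
plant is a sampling unit and a taxon's incidence frequency ``Y_i`` is the
number of units that contain it.  Hill numbers of order q (q = 0 richness,
q = 1 exponential Shannon entropy, q = 2 inverse Simpson concentration)
are interpolated to smaller numbers of sampling units and extrapolated
beyond the observed ``T``, with an asymptotic estimate attached.

Estimators
----------
* q = 0 interpolation is the exact expected richness in a random subset of
  ``t`` units: ``S(t) = S_obs − Σ_i C(T−Y_i, t)/C(T, t)``; extrapolation
  adds the Chao2 unseen-taxa term ``Q̂_0`` geometrically.
* q = 1 interpolation uses the exact expected incidence-frequency spectrum
  ``E[Q_k(t)]`` (hypergeometric): ``¹D(t) = exp(−Σ_k (k/U_t) ln(k/U_t)
  E[Q_k(t)])`` with ``U_t = tU/T``; extrapolated entropy interpolates
  between the observed value and a Chao–Jost-type asymptote in proportion
  to sampling effort.
* q = 2 has a single closed form valid for all ``t`` (the hypergeometric
  second factorial moment is linear in ``t(t−1)``), which reduces to the
  observed inverse Simpson at ``t = T``.

Confidence intervals are percentile bootstrap over sampling units
(plants) resampled with replacement — a deliberately simple, honest
interval rather than an estimated-assemblage bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln

from .io import CountTable, FecError, IncidenceMatrix, SampleMetadata


@dataclass
class IncidenceFrequencies:
    """Incidence summary of one population of sampling units."""

    T: int                       # number of sampling units (plants)
    Y: np.ndarray                # incidence frequency per detected taxon (1..T)
    unit_incidence: np.ndarray | None = None  # taxa × units, for bootstrapping

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=np.int64)
        self.Y = self.Y[self.Y > 0]
        if self.T < 1:
            raise FecError("population must have at least one sampling unit")
        if (self.Y > self.T).any():
            raise FecError("incidence frequency exceeds number of units")

    @property
    def S_obs(self) -> int:
        return int(len(self.Y))

    @property
    def U(self) -> int:
        return int(self.Y.sum())

    def Q(self, k: int) -> int:
        return int((self.Y == k).sum())


def sample_richness(
    ct: CountTable, meta: SampleMetadata | None = None
) -> tuple[pd.Series, pd.Series | None]:
    """Per-sample taxon counts, and mean richness per host if metadata given."""
    rich = pd.Series((ct.counts > 0).sum(axis=0), index=ct.sample_ids, name="richness")
    means = None
    if meta is not None:
        hosts = meta.table.loc[ct.sample_ids, "host"]
        means = rich.groupby(hosts).mean()
    return rich, means


def incidence_frequencies(
    inc: IncidenceMatrix, sample_ids: list[str] | None = None
) -> IncidenceFrequencies:
    """Collapse a population's incidence matrix to incidence frequencies."""
    if sample_ids is None:
        mat = inc.incidence
    else:
        if not sample_ids:
            raise FecError("population sample list is empty")
        pos = {s: j for j, s in enumerate(inc.sample_ids)}
        mat = inc.incidence[:, [pos[s] for s in sample_ids]]
    Y = mat.sum(axis=1)
    return IncidenceFrequencies(T=mat.shape[1], Y=Y, unit_incidence=mat[Y > 0, :])


def _lgamma_table(n: int) -> np.ndarray:
    """gammaln(0..n+1) lookup — all binomial arguments here are integers,
    so table indexing replaces repeated gammaln evaluation."""
    return gammaln(np.arange(n + 2, dtype=float))


def _lchoose_int(gl: np.ndarray, n, k):
    n = np.asarray(n, dtype=np.int64)
    k = np.asarray(k, dtype=np.int64)
    valid = (k >= 0) & (k <= n)
    kk = np.where(valid, k, 0)
    out = gl[n + 1] - gl[kk + 1] - gl[n - kk + 1]
    return np.where(valid, out, -np.inf)


def _q0_interpolated(f: IncidenceFrequencies, t: int) -> float:
    gl = _lgamma_table(f.T)
    ratio = np.exp(_lchoose_int(gl, f.T - f.Y, t) - _lchoose_int(gl, f.T, t))
    return float(f.S_obs - ratio.sum())


def _chao2_unseen(f: IncidenceFrequencies) -> float:
    Q1, Q2 = f.Q(1), f.Q(2)
    if Q2 > 0:
        return (f.T - 1) / f.T * Q1 * Q1 / (2.0 * Q2)
    return (f.T - 1) / f.T * Q1 * (Q1 - 1) / 2.0


def chao2(f: IncidenceFrequencies) -> float:
    """Chao2 lower-bound estimate of asymptotic richness."""
    return f.S_obs + _chao2_unseen(f)


def _expected_spectrum(f: IncidenceFrequencies, t: int) -> np.ndarray:
    """E[Q_k(t)] for k = 1..t under subsampling t of T units without
    replacement (hypergeometric)."""
    gl = _lgamma_table(f.T)
    k = np.arange(1, t + 1)
    lc = (
        _lchoose_int(gl, f.Y[:, None], k[None, :])
        + _lchoose_int(gl, f.T - f.Y[:, None], t - k[None, :])
        - _lchoose_int(gl, f.T, t)
    )
    return np.exp(lc).sum(axis=0)


def _observed_entropy(f: IncidenceFrequencies) -> float:
    p = f.Y / f.U
    return float(-(p * np.log(p)).sum())


def _asymptotic_entropy(f: IncidenceFrequencies) -> float:
    """Chao–Jost-type debiased Shannon entropy for incidence data,
    expressed for the normalized relative incidences."""
    T, U = f.T, f.U
    Y = f.Y
    Q1, Q2 = f.Q(1), f.Q(2)
    part = float((Y[Y < T] / T * (digamma(T) - digamma(Y[Y < T]))).sum())
    if Q2 > 0:
        A = 2.0 * Q2 / ((T - 1) * Q1 + 2.0 * Q2)
    elif Q1 > 1:
        A = 2.0 / ((T - 1) * (Q1 - 1) + 2.0)
    else:
        A = 1.0
    corr = 0.0
    if Q1 > 0 and A < 1.0:
        r = np.arange(1, T)
        corr = (
            Q1 / T * (1.0 - A) ** (1 - T)
            * (-np.log(A) - ((1.0 - A) ** r / r).sum())
        )
    h_raw = part + corr
    return T / U * h_raw + np.log(U / T)


def _q2_closed_form(f: IncidenceFrequencies, t: float) -> float:
    Ut = t * f.U / f.T
    s2 = float((f.Y * (f.Y - 1)).sum()) / (f.T * (f.T - 1)) if f.T > 1 else 0.0
    denom = Ut + t * (t - 1) * s2
    if denom <= 0:
        return float(f.S_obs)
    return Ut * Ut / denom


def asymptotic_diversity(f: IncidenceFrequencies, q: int) -> float:
    """Asymptotic (infinite-effort) Hill number of order q."""
    if q == 0:
        return chao2(f)
    if q == 1:
        h = _asymptotic_entropy(f)
        return float(np.exp(max(h, _observed_entropy(f))))
    if q == 2:
        s2 = float((f.Y * (f.Y - 1)).sum()) / (f.T * (f.T - 1)) if f.T > 1 else 0.0
        if s2 <= 0:
            return float(f.S_obs)  # every taxon a unique: no concentration signal
        return (f.U / f.T) ** 2 / s2
    raise FecError(f"q must be 0, 1 or 2; got {q}")


def observed_diversity(f: IncidenceFrequencies, q: int) -> float:
    """Hill number of the observed relative incidences."""
    p = f.Y / f.U
    if q == 0:
        return float(f.S_obs)
    if q == 1:
        return float(np.exp(-(p * np.log(p)).sum()))
    if q == 2:
        return float(1.0 / (p * p).sum())
    raise FecError(f"q must be 0, 1 or 2; got {q}")


def hill_estimate(f: IncidenceFrequencies, q: int, t: int) -> float:
    """Hill number of order q at ``t`` sampling units (rarefied or
    extrapolated)."""
    if q not in (0, 1, 2):
        raise FecError(f"q must be 0, 1 or 2; got {q}")
    if t < 1:
        raise FecError("t must be >= 1")
    T = f.T
    if q == 2:
        return _q2_closed_form(f, t)
    if t <= T:
        if q == 0:
            return _q0_interpolated(f, t)
        # q == 1: entropy of the exact expected frequency spectrum
        delta = _expected_spectrum(f, t)
        Ut = t * f.U / T
        k = np.arange(1, t + 1)
        w = k / Ut
        h = float(-(w * np.log(w) * delta).sum())
        return float(np.exp(h))
    # extrapolation
    tstar = t - T
    if q == 0:
        q0hat = _chao2_unseen(f)
        Q1 = f.Q(1)
        if q0hat <= 0 or Q1 == 0:
            return float(f.S_obs)
        return f.S_obs + q0hat * (1.0 - (1.0 - Q1 / (T * q0hat + Q1)) ** tstar)
    # q == 1: entropy moves from the observed value toward the asymptote
    h_obs = _observed_entropy(f)
    h_asy = max(_asymptotic_entropy(f), h_obs)
    h = (T / t) * h_obs + (tstar / t) * h_asy
    return float(np.exp(h))


@dataclass
class HillCurve:
    """Rarefaction/extrapolation curve for one population and order q."""

    q: int
    knots: pd.DataFrame  # columns t, estimate, lower, upper, regime
    asymptote: float

    def at(self, t: int) -> float:
        row = self.knots[self.knots["t"] == t]
        if row.empty:
            raise FecError(f"t={t} is not a knot of this curve")
        return float(row["estimate"].iloc[0])


def default_t_grid(T: int, extrapolation_factor: float = 2.0, n_knots: int = 20) -> list[int]:
    """Roughly even integer knots from 1 to ``extrapolation_factor * T``,
    always including 1 and T."""
    tmax = max(int(round(extrapolation_factor * T)), T)
    grid = np.unique(np.round(np.linspace(1, tmax, n_knots)).astype(int))
    grid = np.union1d(grid, [1, T])
    return [int(t) for t in grid]


def hill_curve(
    f: IncidenceFrequencies,
    q: int,
    t_grid: list[int] | None = None,
    bootstrap_reps: int = 200,
    seed: int | None = None,
    ci: float = 0.95,
) -> HillCurve:
    """Point estimates on a grid of sampling efforts with percentile
    bootstrap intervals (resampling plants with replacement)."""
    if bootstrap_reps < 1:
        raise FecError("bootstrap_reps must be >= 1")
    if t_grid is None:
        t_grid = default_t_grid(f.T)
    est = np.array([hill_estimate(f, q, t) for t in t_grid])

    if f.unit_incidence is None:
        raise FecError("bootstrap requires unit-level incidence data")
    rng = np.random.default_rng(seed)
    boot = np.empty((bootstrap_reps, len(t_grid)))
    n_units = f.unit_incidence.shape[1]
    for b in range(bootstrap_reps):
        cols = rng.integers(0, n_units, n_units)
        Yb = f.unit_incidence[:, cols].sum(axis=1)
        fb = IncidenceFrequencies(T=n_units, Y=Yb)
        boot[b] = [hill_estimate(fb, q, t) for t in t_grid]
    a = (1.0 - ci) / 2.0
    lower = np.quantile(boot, a, axis=0)
    upper = np.quantile(boot, 1.0 - a, axis=0)
    lower = np.minimum(lower, est)
    upper = np.maximum(upper, est)

    regime = ["interpolated" if t < f.T else "observed" if t == f.T else "extrapolated" for t in t_grid]
    knots = pd.DataFrame(
        {"t": t_grid, "estimate": est, "lower": lower, "upper": upper, "regime": regime}
    )
    return HillCurve(q=q, knots=knots, asymptote=asymptotic_diversity(f, q))


def population_hill_curves(
    inc: IncidenceMatrix,
    meta: SampleMetadata,
    qs: tuple[int, ...] = (0, 1, 2),
    bootstrap_reps: int = 200,
    seed: int | None = None,
) -> pd.DataFrame:
    """Tidy table of Hill curves for every (host, site) population: one row
    per (population, q, t) with estimate, bootstrap interval, regime, and
    the asymptotic estimate."""
    rows = []
    for i, ((h, s), ids) in enumerate(sorted(meta.populations(inc.sample_ids).items())):
        f = incidence_frequencies(inc, ids)
        for q in qs:
            sub_seed = None if seed is None else [seed, i, q]
            curve = hill_curve(f, q, bootstrap_reps=bootstrap_reps, seed=sub_seed)
            k = curve.knots.copy()
            k.insert(0, "host", h)
            k.insert(1, "site", s)
            k.insert(2, "q", q)
            k["asymptote"] = curve.asymptote
            k["observed"] = observed_diversity(f, q)
            k["T"] = f.T
            rows.append(k)
    return pd.concat(rows, ignore_index=True)
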