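"""Synthetic multi-host, multi-site endophyte community generator.

Emulates the post-denoising state of a stem-endophyte amplicon survey: a
few hundred core taxa shared across hosts (log-normal latent abundances
shifted by host and site effects), a long tail of sporadic low-abundance
taxa that occur independently at low probability, per-plant log-normal
noise, variable library sizes, and — optionally — pairs of taxa whose
within-population abundances co-vary with a target Spearman correlation
(injected through a Gaussian copula on the latent log-abundances).

Because every structural feature is planted explicitly, the generator
provides ground truth for parameter-recovery tests of each downstream
stage: Venn partitions, diversity ordering, differentiation, and
co-occurrence edge detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import RANKS, UNASSIGNED, CountTable, FecError, SampleMetadata, Taxonomy
from .study import SAMPLING_DESIGN


@dataclass
class CorrelatedPair:
    """A planted co-occurrence: two taxa with target within-population
    Spearman correlation ``rho``, active in ``sites`` (None = all sites)."""

    taxon_a: str
    taxon_b: str
    rho: float
    sites: list[str] | None = None

    def __post_init__(self) -> None:
        if abs(self.rho) > 0.99:
            raise FecError(f"target |rho| {self.rho} > 0.99 is infeasible")


@dataclass
class CorrelatedModule:
    """A planted densely associated set: all member taxa pairwise
    co-varying with target Spearman ``rho`` >= 0 (equicorrelated latent
    factor), active in ``sites`` (None = all sites)."""

    taxa: list[str]
    rho: float
    sites: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.taxa) < 2 or len(set(self.taxa)) != len(self.taxa):
            raise FecError("module needs >= 2 distinct taxa")
        if not 0.0 <= self.rho <= 0.99:
            raise FecError("module rho must lie in [0, 0.99]")


@dataclass
class SyntheticConfig:
    hosts: list[str]
    sites_per_host: dict[str, list[str]]
    seed: int
    plants_per_population: int | dict[tuple[str, str], int] = 40
    n_core_taxa: int = 400
    n_sporadic_taxa: int = 1300
    n_unique_per_host: int = 0
    core_log_abundance_mean: float = 0.0
    core_log_abundance_sd: float = 1.5
    host_effect_sd: float = 0.0
    site_effect_sd: float = 0.0
    plant_noise_sd: float = 0.8
    sporadic_log_abundance_mean: float = -3.5
    sporadic_occurrence_prob: float = 0.03
    library_size_log_mean: float = math.log(20_000)
    library_size_log_sd: float = 0.5
    overdispersion: float = 0.0  # >0: Dirichlet-multinomial concentration 1/overdispersion
    correlated_pairs: list[CorrelatedPair] = field(default_factory=list)
    correlated_modules: list[CorrelatedModule] = field(default_factory=list)
    #: Beta(a, b) parameters for per-core-taxon plant occupancy; None means
    #: every core taxon is latently present in every plant.  Heterogeneous
    #: occupancy reproduces the large gap between per-plant and per-site
    #: richness seen in real stem endophyte surveys.
    core_occupancy: tuple[float, float] | None = None
    n_classes: int = 12
    n_genera: int = 150

    def __post_init__(self) -> None:
        if not self.hosts:
            raise FecError("at least one host required")
        for h in self.hosts:
            if h not in self.sites_per_host or not self.sites_per_host[h]:
                raise FecError(f"host {h!r} has no sites")
        for p in (self.sporadic_occurrence_prob,):
            if not 0.0 <= p <= 1.0:
                raise FecError("probabilities must lie in [0, 1]")
        if self.n_core_taxa < 1:
            raise FecError("need at least one core taxon")

    def populations(self) -> list[tuple[str, str]]:
        return [(h, s) for h in self.hosts for s in self.sites_per_host[h]]

    def n_plants(self, host: str, site: str) -> int:
        if isinstance(self.plants_per_population, dict):
            return self.plants_per_population[(host, site)]
        return self.plants_per_population


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    role: dict[str, str]  # taxon -> core | sporadic | unique:<host>
    expected_relative_abundance: pd.DataFrame  # hosts × taxa
    correlated_pairs: list[CorrelatedPair]
    genus_of: dict[str, str]
    class_of: dict[str, str]
    correlated_modules: list[CorrelatedModule] = field(default_factory=list)


def _spearman_to_pearson(rho: float) -> float:
    """Bivariate-Gaussian Pearson correlation yielding Spearman ``rho``."""
    return 2.0 * math.sin(math.pi * rho / 6.0)


def _structure(cfg: SyntheticConfig):
    """Population-invariant structural draws: taxon ids, latent means and
    host/site effect shifts.  Independent of the correlated-pair list."""
    hosts = list(cfg.hosts)
    pops = cfg.populations()

    core_ids = [f"core{i:04d}" for i in range(cfg.n_core_taxa)]
    sporadic_ids = [f"spor{i:04d}" for i in range(cfg.n_sporadic_taxa)]
    unique_ids = {
        h: [f"uniq_{h}_{i:02d}" for i in range(cfg.n_unique_per_host)] for h in hosts
    }
    taxon_ids = core_ids + sporadic_ids + [t for h in hosts for t in unique_ids[h]]
    n_taxa = len(taxon_ids)
    tpos = {t: i for i, t in enumerate(taxon_ids)}

    rng_struct = np.random.default_rng([cfg.seed, 0])
    mu = np.full(n_taxa, cfg.sporadic_log_abundance_mean)
    mu[: cfg.n_core_taxa] = rng_struct.normal(
        cfg.core_log_abundance_mean, cfg.core_log_abundance_sd, cfg.n_core_taxa
    )
    # unique taxa get core-like means within their host, structural zero elsewhere
    for h in hosts:
        for t in unique_ids[h]:
            mu[tpos[t]] = rng_struct.normal(
                cfg.core_log_abundance_mean, cfg.core_log_abundance_sd
            )

    host_eff = {
        h: rng_struct.normal(0.0, cfg.host_effect_sd, n_taxa) if cfg.host_effect_sd > 0
        else np.zeros(n_taxa)
        for h in hosts
    }
    site_eff = {
        pop: rng_struct.normal(0.0, cfg.site_effect_sd, n_taxa) if cfg.site_effect_sd > 0
        else np.zeros(n_taxa)
        for pop in pops
    }
    # per-core-taxon plant occupancy (1 = latently present in every plant)
    occupancy = np.ones(n_taxa)
    if cfg.core_occupancy is not None:
        a, b = cfg.core_occupancy
        occupancy[: cfg.n_core_taxa] = rng_struct.beta(a, b, cfg.n_core_taxa)
        # host-specific taxa share the core occupancy model
        n_uni = sum(len(v) for v in unique_ids.values())
        if n_uni:
            occupancy[-n_uni:] = rng_struct.beta(a, b, n_uni)
        # taxa carrying planted correlations are kept prevalent, as the
        # hub/association candidates of real surveys are
        for t in _correlated_taxa(cfg):
            occupancy[tpos[t]] = max(occupancy[tpos[t]], 0.8)
    return (hosts, pops, core_ids, sporadic_ids, unique_ids, taxon_ids, tpos,
            mu, host_eff, site_eff, occupancy)


def _correlated_taxa(cfg: SyntheticConfig) -> list[str]:
    out = []
    for p in cfg.correlated_pairs:
        out.extend([p.taxon_a, p.taxon_b])
    for m in cfg.correlated_modules:
        out.extend(m.taxa)
    return out


def abundant_core_taxa(cfg: SyntheticConfig, k: int) -> list[str]:
    """The k core taxa with the highest latent mean abundance under this
    config/seed.  Useful for planting correlated pairs on taxa abundant
    enough to be detectable after count sampling; the structural stream
    does not depend on the pair list, so the ranking is stable."""
    res = _structure(cfg)
    core_ids, tpos, mu = res[2], res[6], res[7]
    order = sorted(core_ids, key=lambda t: -mu[tpos[t]])
    return order[:k]


def generate(cfg: SyntheticConfig) -> tuple[CountTable, SampleMetadata, Taxonomy, GroundTruth]:
    """Draw one synthetic survey. Deterministic under a fixed config/seed."""
    (hosts, pops, core_ids, sporadic_ids, unique_ids,
     taxon_ids, tpos, mu, host_eff, site_eff, occupancy) = _structure(cfg)
    n_taxa = len(taxon_ids)

    seen: set[str] = set()
    for t in _correlated_taxa(cfg):
        if t not in tpos:
            raise FecError(f"correlated pair/module names unknown taxon {t!r}")
        if t in seen:
            raise FecError(f"taxon {t!r} appears in more than one planted correlation")
        seen.add(t)
    groups: list[tuple[list[int], float, list[str] | None]] = [
        ([tpos[p.taxon_a], tpos[p.taxon_b]], p.rho, p.sites)
        for p in cfg.correlated_pairs
    ] + [([tpos[t] for t in m.taxa], m.rho, m.sites) for m in cfg.correlated_modules]

    sporadic_mask = np.zeros(n_taxa, dtype=bool)
    sporadic_mask[cfg.n_core_taxa : cfg.n_core_taxa + cfg.n_sporadic_taxa] = True

    # --- per-population sampling ----------------------------------------
    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    count_cols: list[np.ndarray] = []
    for k, (h, s) in enumerate(pops):
        rng = np.random.default_rng([cfg.seed, 1, k])
        n = cfg.n_plants(h, s)
        base = mu + host_eff[h] + site_eff[(h, s)]
        eps = rng.normal(0.0, cfg.plant_noise_sd, size=(n, n_taxa))
        # copula injection: replace the correlated group's noise columns
        # with equicorrelated Gaussians of the same marginal scale
        for idx, rho, active_sites in groups:
            if active_sites is not None and s not in active_sites:
                continue
            r = _spearman_to_pearson(rho)
            if r < 0:  # pairs only; modules validated non-negative
                z = rng.multivariate_normal([0.0, 0.0], [[1.0, r], [r, 1.0]], size=n)
            else:
                f_shared = rng.normal(0.0, 1.0, size=(n, 1))
                e = rng.normal(0.0, 1.0, size=(n, len(idx)))
                z = math.sqrt(r) * f_shared + math.sqrt(1.0 - r) * e
            eps[:, idx] = z * cfg.plant_noise_sd
        latent = np.exp(base + eps)
        # sporadic occurrence: independent presence draws at low probability
        occ = rng.random((n, cfg.n_sporadic_taxa)) < cfg.sporadic_occurrence_prob
        latent[:, sporadic_mask] *= occ
        # heterogeneous occupancy: core and host-specific taxa are latently
        # present in a given plant with their occupancy probability
        if cfg.core_occupancy is not None:
            occ_mask = ~sporadic_mask
            occ_draw = rng.random((n, int(occ_mask.sum()))) < occupancy[occ_mask]
            latent[:, occ_mask] *= occ_draw
        # unique-to-host taxa are structural zeros outside their host
        for h2 in hosts:
            if h2 != h:
                for t in unique_ids[h2]:
                    latent[:, tpos[t]] = 0.0

        libs = np.maximum(
            1,
            rng.lognormal(cfg.library_size_log_mean, cfg.library_size_log_sd, n).astype(int),
        )
        for j in range(n):
            tot = latent[j].sum()
            if tot <= 0:  # degenerate plant: give it one read of a core taxon
                probs = np.zeros(n_taxa)
                probs[0] = 1.0
            else:
                probs = latent[j] / tot
            if cfg.overdispersion > 0:
                alpha = probs / cfg.overdispersion
                probs = rng.dirichlet(np.where(alpha > 0, alpha, 1e-12))
                probs[latent[j] == 0] = 0.0
                probs = probs / probs.sum()
            count_cols.append(rng.multinomial(libs[j], probs))
            sid = f"{h}_{s}_p{j:03d}"
            sample_ids.append(sid)
            meta_rows.append({"sample_id": sid, "host": h, "site": s})

    counts = np.vstack(count_cols).T  # taxa × samples
    ct = CountTable(taxon_ids, sample_ids, counts)
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    tax = _make_taxonomy(cfg, taxon_ids)

    truth = GroundTruth(
        role=_roles(cfg, core_ids, sporadic_ids, unique_ids),
        expected_relative_abundance=_expected_relabund(
            cfg, hosts, pops, taxon_ids, mu, host_eff, site_eff, sporadic_mask,
            unique_ids, tpos, occupancy,
        ),
        correlated_pairs=list(cfg.correlated_pairs),
        correlated_modules=list(cfg.correlated_modules),
        genus_of={t: g for t, g in zip(taxon_ids, tax.table["genus"])},
        class_of={t: c for t, c in zip(taxon_ids, tax.table["class"])},
    )
    return ct, meta, tax, truth


def _roles(cfg, core_ids, sporadic_ids, unique_ids) -> dict[str, str]:
    role = {t: "core" for t in core_ids}
    role.update({t: "sporadic" for t in sporadic_ids})
    for h, ids in unique_ids.items():
        role.update({t: f"unique:{h}" for t in ids})
    return role


def _expected_relabund(
    cfg, hosts, pops, taxon_ids, mu, host_eff, site_eff, sporadic_mask,
    unique_ids, tpos, occupancy,
) -> pd.DataFrame:
    """Approximate expected relative abundance per host (ratio of latent
    means, averaged over the host's sites)."""
    rows = {}
    v = cfg.plant_noise_sd**2 / 2.0
    for h in hosts:
        acc = np.zeros(len(taxon_ids))
        sites = cfg.sites_per_host[h]
        for s in sites:
            lat = np.exp(mu + host_eff[h] + site_eff[(h, s)] + v) * occupancy
            lat[sporadic_mask] *= cfg.sporadic_occurrence_prob
            for h2 in hosts:
                if h2 != h:
                    for t in unique_ids[h2]:
                        lat[tpos[t]] = 0.0
            acc += lat / lat.sum()
        rows[h] = acc / len(sites)
    return pd.DataFrame(rows, index=taxon_ids).T


def _make_taxonomy(cfg: SyntheticConfig, taxon_ids: list[str]) -> Taxonomy:
    """Deterministic taxonomy: planted pair members get dedicated genera so
    genus-level aggregation preserves their signal; sporadic taxa are partly
    unassigned at genus/species rank, mimicking real surveys."""
    pair_taxa = set(_correlated_taxa(cfg))
    classes = [f"Class{c:02d}" for c in range(cfg.n_classes)]
    rows = []
    genus_counter = 0
    for i, t in enumerate(taxon_ids):
        cls = classes[i % cfg.n_classes]
        sporadic = t.startswith("spor")
        if t in pair_taxa:
            genus = f"PairGenus_{t}"
        elif sporadic and i % 3 == 0:
            genus = UNASSIGNED
        else:
            genus = f"Genus{genus_counter % cfg.n_genera:03d}"
            genus_counter += 1
        species = UNASSIGNED if (genus == UNASSIGNED or (sporadic and i % 2 == 0)) else f"{genus} sp{i:04d}"
        rows.append(
            {
                "taxon_id": t,
                "kingdom": "Fungi",
                "phylum": "Ascomycota" if i % 4 else "Basidiomycota",
                "class": cls,
                "order": f"Order{i % 30:02d}",
                "family": f"Family{i % 60:02d}",
                "genus": genus,
                "species": species,
            }
        )
    df = pd.DataFrame(rows).set_index("taxon_id")
    # enforce the rank-nesting invariant: below an UNASSIGNED rank all lower
    # ranks are UNASSIGNED (genus is the only rank we blank above species)
    return Taxonomy(df)


def preset_paper_shape(seed: int = 0, **overrides) -> SyntheticConfig:
    """Configuration mirroring the published survey's shape: 3 hosts at
    7/4/3 sites with paired site names, the survey's per-population retained
    sample counts (530 samples in total), ~1700 taxa of which a few hundred
    are shared core taxa with heterogeneous plant occupancy (so per-plant
    richness is far below per-site richness), a long sporadic tail, a few
    host-specific taxa, and a planted association module plus a handful of
    correlated pairs among abundant core taxa."""
    plants = {
        (h, s): retained
        for h, sites in SAMPLING_DESIGN.items()
        for s, (retained, _collected) in sites.items()
    }
    base = dict(
        hosts=["AS", "TA", "TD"],
        sites_per_host={h: list(s) for h, s in SAMPLING_DESIGN.items()},
        plants_per_population=plants,
        n_core_taxa=450,
        n_sporadic_taxa=1230,
        n_unique_per_host=20,
        core_occupancy=(0.45, 4.5),
        sporadic_occurrence_prob=0.004,
        sporadic_log_abundance_mean=-1.2,
        host_effect_sd=0.35,
        site_effect_sd=0.25,
        library_size_log_mean=math.log(10_000),
        seed=seed,
    )
    base.update(overrides)
    cfg = SyntheticConfig(**base)
    if cfg.correlated_pairs or cfg.correlated_modules:
        return cfg
    top = abundant_core_taxa(cfg, 20)
    cfg.correlated_modules = [CorrelatedModule(taxa=top[:6], rho=0.8)]
    cfg.correlated_pairs = [
        CorrelatedPair(top[6 + 2 * i], top[7 + 2 * i], 0.8) for i in range(6)
    ]
    cfg.correlated_pairs.append(CorrelatedPair(top[18], top[19], -0.7))
    return cfg
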