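"""Cross-site co-occurrence networks of fungal genera and hub detection.

Within each population (all plants of one host at one site), Spearman rank
correlations between genus-level abundances yield candidate edges at a raw
significance threshold (default p < 0.001, no multiple-testing correction).
Edges seen in only one of a host's sites are treated as noise and
discarded; the surviving edges form the host's combined network, carrying
the number of supporting sites and the accumulated rho (summed separately
over positive and negative site-level coefficients).  Hub (keystone)
candidates are genera with high degree and closeness but low betweenness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .io import UNASSIGNED, CountTable, FecError, Taxonomy, relative_abundance


def genus_table(ct: CountTable, tax: Taxonomy) -> CountTable:
    """Sum counts by genus; taxa without a genus assignment are removed."""
    missing = set(ct.taxon_ids) - set(tax.taxon_ids)
    if missing:
        raise FecError(f"taxonomy missing taxa: {sorted(missing)[:5]}")
    genera = tax.table.loc[ct.taxon_ids, "genus"]
    keep = genera != UNASSIGNED
    if not keep.any():
        raise FecError("no genus-assigned taxa remain")
    df = ct.to_frame().loc[keep.to_numpy()]
    grouped = df.groupby(genera[keep].to_numpy(), sort=True).sum()
    return CountTable(list(grouped.index), list(ct.sample_ids), grouped.to_numpy())


@dataclass(frozen=True)
class EdgeRecord:
    genus_a: str    # lexicographically first
    genus_b: str
    site: str
    rho: float
    p_value: float

    def __post_init__(self) -> None:
        if self.genus_a == self.genus_b:
            raise FecError("self-edges are not allowed")
        if self.genus_a > self.genus_b:
            raise FecError("genus pair must be lexicographically ordered")


def _spearman_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman rho (midranks) across rows of ``values`` plus
    two-sided p from the t-distribution approximation."""
    n = values.shape[1]
    ranks = np.apply_along_axis(rankdata, 1, values)
    ranks = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (ranks @ ranks.T) / np.outer(norm, norm)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    return rho, p


def spearman_edges(
    genus_ct: CountTable,
    site: str,
    alpha: float = 0.001,
    min_prevalence: int = 5,
    scale: str = "relative",
) -> list[EdgeRecord]:
    """Significant genus–genus Spearman associations within one population.

    ``scale`` selects the values correlated: per-sample relative abundance
    (default), raw counts, or Hellinger-transformed abundance — Spearman is
    invariant to per-genus monotone maps but not to per-sample
    renormalization, so the choice is explicit.  Genus pairs where either
    member is present in fewer than ``min_prevalence`` plants, or is
    constant across plants, are skipped.
    """
    n = len(genus_ct.sample_ids)
    if n < 5:
        raise FecError("population needs at least 5 plants for correlation")
    if scale == "relative":
        vals = relative_abundance(genus_ct).values
    elif scale == "raw":
        vals = genus_ct.counts.astype(float)
    elif scale == "hellinger":
        from .io import hellinger_transform

        vals = hellinger_transform(genus_ct).values
    else:
        raise FecError(f"unknown scale {scale!r}")

    prevalence = (genus_ct.counts > 0).sum(axis=1)
    variable = np.ptp(vals, axis=1) > 0
    ok = (prevalence >= min_prevalence) & variable
    idx = np.flatnonzero(ok)
    if len(idx) < 2:
        return []
    rho, p = _spearman_matrix(vals[idx])
    genera = [genus_ct.taxon_ids[i] for i in idx]
    out: list[EdgeRecord] = []
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            if np.isnan(rho[a, b]):
                continue
            if p[a, b] < alpha:
                ga, gb = sorted((genera[a], genera[b]))
                out.append(EdgeRecord(ga, gb, site, float(rho[a, b]), float(p[a, b])))
    return out


@dataclass
class CombinedNetwork:
    """Per-host genus co-occurrence graph after the multi-site filter.

    Edge attributes: ``site_count``, ``acc_rho_pos``, ``acc_rho_neg``,
    ``sites`` (comma-joined, sorted).
    """

    host: str
    graph: nx.Graph

    def edges_frame(self) -> pd.DataFrame:
        rows = [
            {
                "genus_a": a,
                "genus_b": b,
                "site_count": d["site_count"],
                "acc_rho_pos": d["acc_rho_pos"],
                "acc_rho_neg": d["acc_rho_neg"],
                "sites": d["sites"],
            }
            for a, b, d in sorted(self.graph.edges(data=True))
        ]
        return pd.DataFrame(
            rows, columns=["genus_a", "genus_b", "site_count", "acc_rho_pos", "acc_rho_neg", "sites"]
        )


def combine_networks(
    edges_by_site: dict[str, list[EdgeRecord]],
    min_sites: int = 2,
    host: str = "",
) -> CombinedNetwork:
    """Merge per-site edge sets: keep pairs significant in at least
    ``min_sites`` sites, accumulating positive and negative rho separately."""
    if len(edges_by_site) < 2:
        raise FecError("need edge sets from at least 2 sites")
    acc: dict[tuple[str, str], dict] = {}
    for site in sorted(edges_by_site):
        for e in edges_by_site[site]:
            key = (e.genus_a, e.genus_b)
            rec = acc.setdefault(
                key, {"sites": set(), "acc_rho_pos": 0.0, "acc_rho_neg": 0.0}
            )
            if e.site in rec["sites"]:
                raise FecError(f"duplicate edge record for {key} at site {e.site}")
            rec["sites"].add(e.site)
            if e.rho >= 0:
                rec["acc_rho_pos"] += e.rho
            else:
                rec["acc_rho_neg"] += e.rho

    g = nx.Graph()
    for (a, b), rec in sorted(acc.items()):
        if len(rec["sites"]) < min_sites:
            continue
        g.add_edge(
            a,
            b,
            site_count=len(rec["sites"]),
            acc_rho_pos=rec["acc_rho_pos"],
            acc_rho_neg=rec["acc_rho_neg"],
            sites=",".join(sorted(rec["sites"])),  # plain string: GraphML-safe
        )
    return CombinedNetwork(host=host, graph=g)


def centralities(net: CombinedNetwork) -> pd.DataFrame:
    """Per-genus degree, harmonic closeness, normalized betweenness, and
    per-component eigenvector centrality (scores scaled by the component's
    share of vertices).  Paths treat edges as unweighted."""
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        raise FecError("empty network")
    deg = dict(g.degree())
    closeness = {
        v: (c / (n - 1) if n > 1 else 0.0)
        for v, c in nx.harmonic_centrality(g).items()
    }
    betw = nx.betweenness_centrality(g, normalized=True)
    eig: dict[str, float] = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        share = len(comp) / n
        if len(comp) == 1:
            scores = {next(iter(comp)): 1.0}
        else:
            scores = nx.eigenvector_centrality(sub, max_iter=10_000, tol=1e-10)
        for v, s in scores.items():
            eig[v] = s * share
    out = pd.DataFrame(
        {
            "degree": pd.Series(deg),
            "closeness": pd.Series(closeness),
            "betweenness": pd.Series(betw),
            "eigenvector": pd.Series(eig),
        }
    ).sort_index()
    out.index.name = "genus"
    return out


def hub_candidates(net: CombinedNetwork, top_k: int = 10) -> pd.DataFrame:
    """Rank genera by the composite hub rule: competition ranks of
    descending degree + descending closeness + ascending betweenness;
    smaller sums rank higher, ties broken by genus id."""
    cent = centralities(net)
    r_deg = rankdata(-cent["degree"], method="min")
    r_clo = rankdata(-cent["closeness"], method="min")
    r_bet = rankdata(cent["betweenness"], method="min")
    cent = cent.assign(composite=r_deg + r_clo + r_bet)
    cent = cent.sort_index().sort_values("composite", kind="stable")
    return cent.head(top_k)


def network_summary(net: CombinedNetwork) -> dict:
    """Diameter and mean shortest-path distance of the largest connected
    component; edge density over the full vertex set."""
    g = net.graph
    n = g.number_of_nodes()
    if n == 0:
        raise FecError("empty network")
    comp = max(nx.connected_components(g), key=len)
    sub = g.subgraph(comp)
    if len(comp) > 1:
        diameter = nx.diameter(sub)
        mean_dist = nx.average_shortest_path_length(sub)
    else:
        diameter, mean_dist = 0, 0.0
    density = g.number_of_edges() / (n * (n - 1) / 2.0) if n > 1 else 0.0
    return {
        "n_vertices": n,
        "n_edges": g.number_of_edges(),
        "diameter": diameter,
        "mean_distance": float(mean_dist),
        "edge_density": float(density),
        "largest_component": len(comp),
    }


def host_network(
    ct: CountTable,
    tax: Taxonomy,
    populations: dict[str, list[str]],
    host: str = "",
    alpha: float = 0.001,
    min_sites: int = 2,
    min_prevalence: int = 5,
    scale: str = "relative",
    min_plants: int = 5,
) -> CombinedNetwork:
    """Convenience: per-site Spearman edges on the genus table, combined
    into one host network.  ``populations`` maps site -> sample ids."""
    gt = genus_table(ct, tax)
    edges_by_site: dict[str, list[EdgeRecord]] = {}
    for site, ids in sorted(populations.items()):
        if len(ids) < min_plants:
            continue
        sub = gt.select_samples(ids)
        edges_by_site[site] = spearman_edges(
            sub, site, alpha=alpha, min_prevalence=min_prevalence, scale=scale
        )
    if len(edges_by_site) < 2:
        raise FecError("need at least 2 usable sites for a combined network")
    return combine_networks(edges_by_site, min_sites=min_sites, host=host)
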