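"""Dataset-preparation bookkeeping: agglomeration, filters, summaries.

Reproduces the standard post-denoising curation steps of an amplicon
survey: agglomerating sequence variants that share a full species-level
assignment, dropping shallow samples, removing singleton/doubleton and
low-prevalence taxa, and partitioning the retained taxa by the host
species in which they occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    RANKS,
    UNASSIGNED,
    AbundanceTable,
    CountTable,
    FecError,
    SampleMetadata,
    Taxonomy,
)

#: Named threshold presets for :func:`filter_rare_taxa`:
#: (min_total_reads, min_incidence).
RARE_TAXA_PRESETS = {
    "singleton_doubleton": (3, 0),  # drop taxa with <= 2 reads overall
    "core": (0, 5),                 # drop taxa present in < 5 samples
    "beta": (3, 5),                 # both, for beta-diversity analyses
}


@dataclass
class FilterReport:
    """Bookkeeping for one filtering step."""

    step: str
    items_removed: int
    items_remaining: int
    fraction_of_reads_removed: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_of_reads_removed <= 1.0:
            raise FecError("fraction_of_reads_removed outside [0, 1]")


def agglomerate_species(ct: CountTable, tax: Taxonomy) -> tuple[CountTable, Taxonomy]:
    """Sum counts of taxa sharing an identical full species-level assignment.

    Taxa unassigned at species rank are kept as separate original taxa.  The
    agglomerated taxon takes the id of the first member (input order) and
    total reads are conserved.
    """
    missing = set(ct.taxon_ids) - set(tax.taxon_ids)
    if missing:
        raise FecError(f"taxonomy missing taxa: {sorted(missing)[:5]}")
    tab = tax.table.loc[ct.taxon_ids]
    keys: list[tuple] = []
    for tid, row in tab.iterrows():
        if row["species"] == UNASSIGNED:
            keys.append(("__asv__", tid))
        else:
            keys.append(tuple(row[list(RANKS)]))

    groups: dict[tuple, list[int]] = {}
    order: list[tuple] = []
    for i, k in enumerate(keys):
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(i)

    new_ids, rows, tax_rows = [], [], []
    for k in order:
        idx = groups[k]
        new_ids.append(ct.taxon_ids[idx[0]])
        rows.append(ct.counts[idx].sum(axis=0))
        tax_rows.append(tab.iloc[idx[0]])
    out_ct = CountTable(new_ids, list(ct.sample_ids), np.vstack(rows))
    out_tax = Taxonomy(pd.DataFrame(tax_rows, index=new_ids))
    return out_ct, out_tax


def filter_samples_min_reads(
    ct: CountTable, min_reads: int = 1000
) -> tuple[CountTable, FilterReport]:
    """Drop samples whose library is shallower than ``min_reads`` reads.

    The comparison is strict: a sample with exactly ``min_reads`` is kept.
    """
    if min_reads < 0:
        raise FecError("min_reads must be >= 0")
    totals = ct.sample_totals()
    keep = totals >= min_reads
    if not keep.any():
        raise FecError(f"all samples fall below {min_reads} reads")
    kept_ids = [s for s, k in zip(ct.sample_ids, keep) if k]
    out = ct.select_samples(kept_ids)
    total = ct.total_reads()
    removed_reads = int(totals[~keep].sum())
    rep = FilterReport(
        step=f"samples_min_reads_{min_reads}",
        items_removed=int((~keep).sum()),
        items_remaining=int(keep.sum()),
        fraction_of_reads_removed=removed_reads / total if total else 0.0,
    )
    return out, rep


def filter_rare_taxa(
    ct: CountTable,
    min_total_reads: int = 0,
    min_incidence: int = 0,
    preset: str | None = None,
) -> tuple[CountTable, FilterReport]:
    """Drop taxa with total reads < ``min_total_reads`` OR incidence
    (number of samples with at least one read) < ``min_incidence``.

    Named presets: ``singleton_doubleton`` (3, 0), ``core`` (0, 5),
    ``beta`` (3, 5).
    """
    if preset is not None:
        min_total_reads, min_incidence = RARE_TAXA_PRESETS[preset]
    if min_total_reads < 0 or min_incidence < 0:
        raise FecError("thresholds must be >= 0")
    totals = ct.taxon_totals()
    incidence = (ct.counts > 0).sum(axis=1)
    keep = (totals >= min_total_reads) & (incidence >= min_incidence)
    kept_ids = [t for t, k in zip(ct.taxon_ids, keep) if k]
    out = ct.select_taxa(kept_ids)
    total = ct.total_reads()
    removed_reads = int(totals[~keep].sum())
    rep = FilterReport(
        step=preset or f"rare_taxa_reads{min_total_reads}_inc{min_incidence}",
        items_removed=int((~keep).sum()),
        items_remaining=int(keep.sum()),
        fraction_of_reads_removed=removed_reads / total if total else 0.0,
    )
    return out, rep


@dataclass
class VennSummary:
    """Partition of taxa by the subset of groups in which they occur."""

    groups: list[str]
    #: frozenset of group names -> (taxon count, share of reference reads)
    subsets: dict[frozenset, tuple[int, float]]
    taxa_by_subset: dict[frozenset, list[str]]

    def count(self, *groups: str) -> int:
        return self.subsets.get(frozenset(groups), (0, 0.0))[0]

    def share(self, *groups: str) -> float:
        return self.subsets.get(frozenset(groups), (0, 0.0))[1]

    def total_taxa(self) -> int:
        return sum(c for c, _ in self.subsets.values())


def venn_partition(
    ct: CountTable,
    meta: SampleMetadata,
    by: str = "host",
    reference: CountTable | None = None,
) -> VennSummary:
    """Assign each taxon to the subset of groups where it has >= 1 read.

    Read shares are computed against ``reference`` (default: ``ct`` itself),
    so shares can be expressed against a larger pre-filter dataset.
    """
    if by not in ("host", "site"):
        raise FecError("venn_partition groups by 'host' or 'site'")
    labels = meta.table.loc[ct.sample_ids, by]
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise FecError("need at least 2 groups for a Venn partition")
    ref_total = (reference or ct).total_reads()

    masks = {g: (labels == g).to_numpy() for g in groups}
    subsets: dict[frozenset, tuple[int, float]] = {}
    taxa_by_subset: dict[frozenset, list[str]] = {}
    presence = {g: (ct.counts[:, m] > 0).any(axis=1) for g, m in masks.items()}
    taxon_reads = ct.taxon_totals()
    for i, tid in enumerate(ct.taxon_ids):
        key = frozenset(g for g in groups if presence[g][i])
        if not key:
            continue  # all-zero taxon: occurs nowhere
        c, r = subsets.get(key, (0, 0.0))
        subsets[key] = (c + 1, r + taxon_reads[i] / ref_total if ref_total else 0.0)
        taxa_by_subset.setdefault(key, []).append(tid)
    return VennSummary(groups, subsets, taxa_by_subset)


def rank_abundance_summary(
    at: AbundanceTable,
    meta: SampleMetadata,
    top_n: int = 18,
    rank_by: str = "median",
) -> pd.DataFrame:
    """Rank taxa by median transformed abundance across all samples.

    Returns the ``top_n`` taxa with per-host mean abundance, a one-way ANOVA
    p-value across hosts, and a significance star code
    (*** p<0.001, ** p<0.01, * p<0.05).  Median ties are broken by mean,
    then taxon id.
    """
    if top_n > len(at.taxon_ids):
        raise FecError("top_n exceeds number of taxa")
    if rank_by not in ("median", "mean"):
        raise FecError("rank_by must be 'median' or 'mean'")
    vals = at.values
    med = np.median(vals, axis=1)
    mean = vals.mean(axis=1)
    primary = med if rank_by == "median" else mean
    order = sorted(
        range(len(at.taxon_ids)),
        key=lambda i: (-primary[i], -mean[i], at.taxon_ids[i]),
    )[:top_n]

    hosts = meta.table.loc[at.sample_ids, "host"]
    host_names = sorted(hosts.unique())
    rows = []
    for i in order:
        groups = [vals[i, (hosts == h).to_numpy()] for h in host_names]
        groups = [g for g in groups if len(g) > 0]
        if len(groups) >= 2 and any(np.ptp(g) > 0 for g in groups):
            p = float(stats.f_oneway(*groups).pvalue)
            if np.isnan(p):
                p = 1.0
        else:
            p = 1.0
        stars = "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""
        row = {
            "taxon_id": at.taxon_ids[i],
            "median_abundance": med[i],
            "mean_abundance": mean[i],
            "anova_p": p,
            "significance": stars,
        }
        for h in host_names:
            row[f"mean_{h}"] = float(vals[i, (hosts == h).to_numpy()].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def class_composition(
    ct: CountTable,
    tax: Taxonomy,
    meta: SampleMetadata,
    top_k: int = 12,
) -> pd.DataFrame:
    """Relative read abundance summed by taxonomic class, per population
    and per host.

    Classes beyond the ``top_k`` most abundant overall are pooled into
    ``Other``; taxa unassigned at class rank are reported as their own
    category.
    """
    classes = tax.table.loc[ct.taxon_ids, "class"].to_numpy()
    overall = pd.Series(ct.taxon_totals(), index=ct.taxon_ids).groupby(classes).sum()
    ranked = overall.sort_values(ascending=False)
    top = [c for c in ranked.index if c != UNASSIGNED][:top_k]

    def bucket(c: str) -> str:
        if c == UNASSIGNED:
            return UNASSIGNED
        return c if c in top else "Other"

    buckets = np.array([bucket(c) for c in classes])
    labels = meta.table.loc[ct.sample_ids]
    rows = []
    group_iters = [
        ("population", [((h, s), (labels["host"] == h) & (labels["site"] == s))
                        for (h, s) in sorted(meta.populations(ct.sample_ids))]),
        ("host", [((h,), labels["host"] == h) for h in sorted(labels["host"].unique())]),
    ]
    for level, items in group_iters:
        for key, mask in items:
            sub = ct.counts[:, mask.to_numpy()]
            total = sub.sum()
            if total == 0:
                continue
            shares = pd.Series(sub.sum(axis=1), index=ct.taxon_ids).groupby(buckets).sum() / total
            for cls, share in shares.items():
                rows.append(
                    {
                        "level": level,
                        "group": "|".join(key),
                        "class": cls,
                        "share": float(share),
                    }
                )
    return pd.DataFrame(rows)
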