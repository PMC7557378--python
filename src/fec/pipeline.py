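"""End-to-end orchestration: ingest/simulate → filter → alpha → beta →
kosman → network → report.

A single :class:`PipelineConfig` (YAML-serializable) drives every stage
with explicit seeds; re-running the same config writes byte-identical
outputs.  Outputs are flat TSV tables plus a JSON manifest and a markdown
report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alpha import (
    incidence_frequencies,
    observed_diversity,
    population_hill_curves,
    asymptotic_diversity,
    sample_richness,
)
from .beta import anosim, bray_curtis, dice, pcoa, permanova
from .filters import (
    agglomerate_species,
    filter_rare_taxa,
    filter_samples_min_reads,
)
from .io import (
    CountTable,
    FecError,
    SampleMetadata,
    Taxonomy,
    hellinger_transform,
    read_count_table,
    read_metadata,
    read_taxonomy,
    to_incidence,
    write_count_table,
    write_metadata,
    write_taxonomy,
)
from .kosman import differentiation, within_population_variation
from .network import centralities, host_network, hub_candidates, network_summary
from .synth import SyntheticConfig, generate, preset_paper_shape


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    # input: either file paths ...
    counts_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    counts_format: str = "tsv"
    # ... or a synthetic config ("paper_shape" preset or explicit kwargs)
    synthetic: dict | str | None = None
    # filters
    min_reads_sample: int = 1000
    apply_agglomeration: bool = True
    core_min_incidence: int = 5
    # alpha
    alpha_qs: tuple[int, ...] = (0, 1, 2)
    alpha_bootstrap: int = 100
    # beta
    beta_permutations: int = 999
    # kosman
    kosman_permutations: int = 1000
    d_variant: str = "partition"
    # network
    network_alpha: float = 0.001
    network_min_sites: int = 2
    network_min_prevalence: int = 5
    network_scale: str = "relative"

    def stage_seed(self, offset: int) -> int:
        return int(self.seed) * 101 + offset

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["alpha_qs"] = list(self.alpha_qs)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FecError(f"unknown pipeline config keys: {sorted(unknown)}")
        if "alpha_qs" in d:
            d["alpha_qs"] = tuple(d["alpha_qs"])
        return cls(**d)


def _load_inputs(cfg: PipelineConfig) -> tuple[CountTable, SampleMetadata, Taxonomy]:
    if cfg.synthetic is not None:
        if cfg.synthetic == "paper_shape" or cfg.synthetic == {"preset": "paper_shape"}:
            scfg = preset_paper_shape(seed=cfg.stage_seed(1))
        elif isinstance(cfg.synthetic, dict):
            kw = dict(cfg.synthetic)
            if kw.pop("preset", None) == "paper_shape":
                scfg = preset_paper_shape(seed=cfg.stage_seed(1), **kw)
            else:
                kw.setdefault("seed", cfg.stage_seed(1))
                if "sites_per_host" in kw:
                    kw["sites_per_host"] = {h: list(v) for h, v in kw["sites_per_host"].items()}
                scfg = SyntheticConfig(**kw)
        else:
            raise FecError(f"unrecognized synthetic config {cfg.synthetic!r}")
        ct, meta, tax, _truth = generate(scfg)
        return ct, meta, tax
    if not (cfg.counts_path and cfg.metadata_path and cfg.taxonomy_path):
        raise FecError("either synthetic config or all three input paths required")
    ct = read_count_table(cfg.counts_path, format=cfg.counts_format)
    meta = read_metadata(cfg.metadata_path)
    tax = read_taxonomy(cfg.taxonomy_path)
    missing = set(ct.sample_ids) - set(meta.sample_ids)
    if missing:
        raise FecError(f"metadata missing samples: {sorted(missing)[:5]}")
    return ct, meta, tax


def _stage(name: str):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:  # noqa: BLE001 - re-raise with stage context
                raise PipelineError(f"stage {name!r} failed: {e}") from e

        return wrapper

    return deco


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages, writing TSV outputs plus manifest.json and report.md
    into ``cfg.out_dir``.  Returns a dict of the main in-memory results."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    ct, meta, tax = _stage("ingest")(_load_inputs)(cfg)

    # ---- filters -------------------------------------------------------
    @_stage("filters")
    def do_filters():
        reports = []
        table, taxonomy = ct, tax
        if cfg.apply_agglomeration:
            before = len(table.taxon_ids)
            table, taxonomy = agglomerate_species(table, taxonomy)
            reports.append(
                {
                    "step": "agglomerate_species",
                    "items_removed": before - len(table.taxon_ids),
                    "items_remaining": len(table.taxon_ids),
                    "fraction_of_reads_removed": 0.0,
                }
            )
        table, rep = filter_samples_min_reads(table, cfg.min_reads_sample)
        reports.append(dataclasses.asdict(rep))
        alpha_table = table  # singletons/doubletons retained for alpha diversity
        table, rep = filter_rare_taxa(table, preset="singleton_doubleton")
        reports.append(dataclasses.asdict(rep))
        full = table
        core, rep = filter_rare_taxa(table, min_incidence=cfg.core_min_incidence)
        reports.append(dataclasses.asdict(rep))
        taxonomy_full = taxonomy.subset(full.taxon_ids)
        pd.DataFrame(reports).to_csv(out / "filter_report.tsv", sep="\t", index=False)
        return alpha_table, full, core, taxonomy_full, reports

    alpha_table, full, core, tax_f, filter_reports = do_filters()
    meta_f = meta.subset(full.sample_ids)
    results["filter_reports"] = filter_reports

    write_count_table(full, out / "counts_filtered.tsv")
    write_metadata(meta_f, out / "metadata.tsv")
    write_taxonomy(tax_f, out / "taxonomy.tsv")

    # ---- alpha ---------------------------------------------------------
    @_stage("alpha")
    def do_alpha():
        inc = to_incidence(alpha_table)
        rich, rich_means = sample_richness(alpha_table, meta_f)
        rich.to_frame().to_csv(out / "richness_per_sample.tsv", sep="\t")
        curves = population_hill_curves(
            inc, meta_f, qs=cfg.alpha_qs,
            bootstrap_reps=cfg.alpha_bootstrap, seed=cfg.stage_seed(2),
        )
        curves.to_csv(out / "alpha_curves.tsv", sep="\t", index=False, float_format="%.6f")
        asy_rows = []
        for (h, s), ids in sorted(meta_f.populations(alpha_table.sample_ids).items()):
            f = incidence_frequencies(inc, ids)
            for q in cfg.alpha_qs:
                asy_rows.append(
                    {
                        "host": h,
                        "site": s,
                        "q": q,
                        "sample_size": f.T,
                        "observed_diversity": observed_diversity(f, q),
                        "asymptotic_estimator": asymptotic_diversity(f, q),
                    }
                )
        asy = pd.DataFrame(asy_rows)
        asy.to_csv(out / "alpha_asymptotes.tsv", sep="\t", index=False, float_format="%.3f")
        return curves, asy, rich_means

    results["alpha_curves"], results["alpha_asymptotes"], results["richness_means"] = do_alpha()

    # ---- beta ----------------------------------------------------------
    @_stage("beta")
    def do_beta():
        hel = hellinger_transform(core)
        dm_bray = bray_curtis(hel)
        dm_dice = dice(to_incidence(core))
        tests = []
        for metric, dm in (("bray", dm_bray), ("dice", dm_dice)):
            ord_res = pcoa(dm, n_axes=2)
            ord_res.coordinates.to_csv(out / f"pcoa_{metric}.tsv", sep="\t", float_format="%.6f")
            for factor in ("host", "site"):
                labels = meta_f.table.loc[dm.ids, factor]
                for test_fn, name in ((permanova, "permanova"), (anosim, "anosim")):
                    res = test_fn(dm, labels, n_perm=cfg.beta_permutations,
                                  seed=cfg.stage_seed(3))
                    tests.append(
                        {
                            "metric": metric,
                            "factor": factor,
                            "test": name,
                            "statistic": res.statistic,
                            "r_squared": res.r_squared,
                            "p_value": res.p_value,
                            "n_permutations": res.n_permutations,
                        }
                    )
        tests = pd.DataFrame(tests)
        tests.to_csv(out / "beta_tests.tsv", sep="\t", index=False, float_format="%.6f")
        return dm_bray, dm_dice, tests

    dm_bray, dm_dice, results["beta_tests"] = do_beta()

    # ---- kosman --------------------------------------------------------
    @_stage("kosman")
    def do_kosman():
        pops = meta_f.populations(core.sample_ids)
        within_rows = []
        diff_rows = []
        for metric, dm in (("dice", dm_dice), ("bray", dm_bray)):
            for host in meta_f.hosts():
                host_pops = {
                    s: ids for (h, s), ids in sorted(pops.items()) if h == host
                }
                disp = within_population_variation(
                    dm, {f"{host}|{s}": ids for s, ids in host_pops.items()},
                    pooled_label=f"{host}|all",
                )
                for r in disp:
                    within_rows.append(
                        {"metric": metric, "population": r.population, "n": r.n,
                         "kw": r.kw, "normalized_effective_number": r.normalized_effective_number}
                    )
                if len(host_pops) >= 2:
                    res = differentiation(
                        dm, host_pops, n_perm=cfg.kosman_permutations,
                        seed=cfg.stage_seed(4), variant=cfg.d_variant, group=host,
                    )
                    diff_rows.append(
                        {"metric": metric, "host": host, "n_populations": res.n_populations,
                         "D": res.D, "effective_1DTM": res.effective,
                         "normalized_1nDTM": res.normalized, "p_value": res.p_value}
                    )
        within = pd.DataFrame(within_rows)
        diff = pd.DataFrame(diff_rows)
        within.to_csv(out / "kosman_within.tsv", sep="\t", index=False, float_format="%.6f")
        diff.to_csv(out / "kosman_differentiation.tsv", sep="\t", index=False, float_format="%.6f")
        return within, diff

    results["kosman_within"], results["kosman_differentiation"] = do_kosman()

    # ---- network -------------------------------------------------------
    @_stage("network")
    def do_network():
        import networkx as nx

        pops = meta_f.populations(core.sample_ids)
        summaries = []
        hubs = {}
        for host in meta_f.hosts():
            site_pops = {s: ids for (h, s), ids in sorted(pops.items()) if h == host}
            if len(site_pops) < 2:
                continue
            try:
                net = host_network(
                    core, tax_f.subset(core.taxon_ids), site_pops, host=host,
                    alpha=cfg.network_alpha, min_sites=cfg.network_min_sites,
                    min_prevalence=cfg.network_min_prevalence, scale=cfg.network_scale,
                )
            except FecError:
                continue
            net.edges_frame().to_csv(out / f"network_edges_{host}.tsv", sep="\t",
                                     index=False, float_format="%.6f")
            if net.graph.number_of_nodes() > 0:
                centralities(net).to_csv(out / f"network_centralities_{host}.tsv",
                                         sep="\t", float_format="%.6f")
                hubs[host] = hub_candidates(net, top_k=10)
                hubs[host].to_csv(out / f"network_hubs_{host}.tsv", sep="\t",
                                  float_format="%.6f")
                nx.write_graphml(net.graph, out / f"network_{host}.graphml")
                summaries.append({"host": host, **network_summary(net)})
            else:
                summaries.append({"host": host, "n_vertices": 0, "n_edges": 0,
                                  "diameter": 0, "mean_distance": 0.0,
                                  "edge_density": 0.0, "largest_component": 0})
        summ = pd.DataFrame(summaries)
        summ.to_csv(out / "network_summary.tsv", sep="\t", index=False, float_format="%.6f")
        return summ, hubs

    results["network_summary"], results["network_hubs"] = do_network()

    cfg_dump = {**dataclasses.asdict(cfg), "alpha_qs": list(cfg.alpha_qs)}
    cfg_dump.pop("out_dir")  # manifests from reruns in different dirs must match
    manifest = {
        "version": __version__,
        "config": cfg_dump,
        "stage_seeds": {name: cfg.stage_seed(k) for k, name in
                        enumerate(["synth", "alpha", "beta", "kosman"], start=1)},
        "n_samples": len(full.sample_ids),
        "n_taxa_full": len(full.taxon_ids),
        "n_taxa_core": len(core.taxon_ids),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out / "report.md").write_text(report(out))
    return results


def report(out_dir: str | Path) -> str:
    """Human-readable markdown summary of a pipeline output directory."""
    out = Path(out_dir)
    lines = ["# Endophyte community analysis report", ""]

    fr = out / "filter_report.tsv"
    if fr.exists():
        df = pd.read_csv(fr, sep="\t")
        lines += ["## Filtering ledger", ""]
        for _, r in df.iterrows():
            lines.append(
                f"- {r['step']}: removed {r['items_removed']}, "
                f"remaining {r['items_remaining']} "
                f"({100 * r['fraction_of_reads_removed']:.2f}% of reads removed)"
            )
        lines.append("")

    asy = out / "alpha_asymptotes.tsv"
    if asy.exists():
        df = pd.read_csv(asy, sep="\t")
        lines += ["## Diversity (incidence-based Hill numbers)", ""]
        for host, sub in df[df["q"] == 0].groupby("host"):
            lines.append(
                f"- {host}: observed richness per site "
                f"{sub['observed_diversity'].min():.0f}–{sub['observed_diversity'].max():.0f}, "
                f"asymptotic {sub['asymptotic_estimator'].min():.0f}–"
                f"{sub['asymptotic_estimator'].max():.0f}"
            )
        lines.append("")

    bt = out / "beta_tests.tsv"
    if bt.exists():
        df = pd.read_csv(bt, sep="\t")
        lines += ["## Group tests", ""]
        for _, r in df.iterrows():
            stat = f"F = {r['statistic']:.2f}" if r["test"] == "permanova" else f"R = {r['statistic']:.3f}"
            r2 = f", R² = {r['r_squared']:.3f}" if pd.notna(r.get("r_squared")) else ""
            lines.append(
                f"- {r['test']} ({r['metric']}, {r['factor']}): {stat}{r2}, "
                f"p = {r['p_value']:.4g} (resolution 1/{int(r['n_permutations']) + 1})"
            )
        lines.append("")

    kd = out / "kosman_differentiation.tsv"
    if kd.exists():
        df = pd.read_csv(kd, sep="\t")
        lines += ["## Differentiation among populations", ""]
        for _, r in df.iterrows():
            lines.append(
                f"- {r['host']} ({r['metric']}): D = {r['D']:.3f}, "
                f"¹D(TM) = {r['effective_1DTM']:.3f}, "
                f"¹nD(TM) = {r['normalized_1nDTM']:.3f}, p = {r['p_value']:.4g}"
            )
        lines.append("")

    ns = out / "network_summary.tsv"
    lines += ["## Co-occurrence networks", ""]
    if ns.exists():
        df = pd.read_csv(ns, sep="\t")
        if df.empty:
            lines.append("No host network retained edges at the multi-site threshold.")
        else:
            for _, r in df.iterrows():
                lines.append(
                    f"- {r['host']}: {int(r['n_vertices'])} genera, "
                    f"{int(r['n_edges'])} edges, diameter {int(r['diameter'])}, "
                    f"mean distance {r['mean_distance']:.2f}, "
                    f"density {r['edge_density']:.3f}"
                )
                hub_path = out / f"network_hubs_{r['host']}.tsv"
                if hub_path.exists():
                    hubs = pd.read_csv(hub_path, sep="\t")
                    top = ", ".join(hubs["genus"].head(5))
                    lines.append(f"  top hub candidates: {top}")
    else:
        lines.append("No host network retained edges at the multi-site threshold.")
    lines.append("")
    return "\n".join(lines)
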