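import numpy as np
import pandas as pd
import pytest

from fec.filters import (
    RARE_TAXA_PRESETS,
    agglomerate_species,
    class_composition,
    filter_rare_taxa,
    filter_samples_min_reads,
    rank_abundance_summary,
    venn_partition,
)
from fec.io import CountTable, FecError, hellinger_transform
from fec.synth import SyntheticConfig, generate
from conftest import make_metadata, make_taxonomy


class TestAgglomeration:
    def test_identical_species_summed(self):
        ct = CountTable(
            ["asv1", "asv2"], ["s1", "s2"], np.array([[3, 5], [2, 0]])
        )
        tax = make_taxonomy(
            {
                "asv1": ("Fungi", "Asc", "Dot", "Pleo", "Pleos", "Alternaria", "Alternaria infectoria"),
                "asv2": ("Fungi", "Asc", "Dot", "Pleo", "Pleos", "Alternaria", "Alternaria infectoria"),
            }
        )
        out, out_tax = agglomerate_species(ct, tax)
        assert out.shape == (1, 2)
        assert out.counts[0].tolist() == [5, 5]
        assert out_tax.table.loc[out.taxon_ids[0], "species"] == "Alternaria infectoria"

    def test_species_unassigned_kept_separate(self):
        ct = CountTable(["asv1", "asv2"], ["s1"], np.array([[3], [2]]))
        tax = make_taxonomy(
            {"asv1": ("Fungi", "Asc"), "asv2": ("Fungi", "Asc")}
        )
        out, _ = agglomerate_species(ct, tax)
        assert out.shape[0] == 2

    def test_reads_conserved(self):
        rng = np.random.default_rng(1)
        ct = CountTable(
            [f"asv{i}" for i in range(6)], ["s1", "s2"], rng.integers(0, 20, (6, 2))
        )
        tax = make_taxonomy(
            {
                f"asv{i}": ("Fungi", "Asc", "C", "O", "F", "G", f"sp{i % 2}")
                for i in range(6)
            }
        )
        out, _ = agglomerate_species(ct, tax)
        assert out.total_reads() == ct.total_reads()
        assert out.shape[0] == 2


class TestSampleFilter:
    def test_strict_boundary(self):
        ct = CountTable(
            ["t"], ["a", "b", "c"], np.array([[999, 1000, 5000]])
        )
        out, rep = filter_samples_min_reads(ct, 1000)
        assert out.sample_ids == ["b", "c"]
        assert rep.items_removed == 1
        assert rep.fraction_of_reads_removed == pytest.approx(999 / 6999)

    def test_zero_threshold_identity(self, tiny_ct):
        out, rep = filter_samples_min_reads(tiny_ct, 0)
        assert out.sample_ids == tiny_ct.sample_ids
        assert rep.items_removed == 0

    def test_all_removed_errors(self, tiny_ct):
        with pytest.raises(FecError, match="all samples"):
            filter_samples_min_reads(tiny_ct, 10**9)


class TestRareTaxaFilter:
    def test_singleton_doubleton_preset(self):
        ct = CountTable(["a", "b"], ["s1", "s2"], np.array([[1, 1], [5, 5]]))
        out, rep = filter_rare_taxa(ct, preset="singleton_doubleton")
        assert out.taxon_ids == ["b"]
        assert rep.items_removed == 1

    def test_core_preset_incidence_boundary(self):
        counts = np.zeros((2, 6), dtype=int)
        counts[0, :4] = 1  # incidence 4: removed
        counts[1, :5] = 1  # incidence 5: kept
        ct = CountTable(["lo", "hi"], [f"s{i}" for i in range(6)], counts)
        out, _ = filter_rare_taxa(ct, preset="core")
        assert out.taxon_ids == ["hi"]

    def test_zero_thresholds_identity(self, tiny_ct):
        out, _ = filter_rare_taxa(tiny_ct, 0, 0)
        assert out.taxon_ids == tiny_ct.taxon_ids

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        ct = CountTable(
            [f"t{i}" for i in range(30)],
            [f"s{j}" for j in range(8)],
            rng.integers(0, 3, (30, 8)),
        )
        once, _ = filter_rare_taxa(ct, 3, 2)
        twice, rep = filter_rare_taxa(once, 3, 2)
        assert twice.taxon_ids == once.taxon_ids
        assert rep.items_removed == 0

    def test_preset_chain_monotone(self):
        """Applying the survey's filter chain leaves taxon counts
        non-increasing at every step."""
        rng = np.random.default_rng(3)
        ct = CountTable(
            [f"t{i}" for i in range(50)],
            [f"s{j}" for j in range(12)],
            (rng.random((50, 12)) < 0.25).astype(int) * rng.integers(1, 9, (50, 12)),
        )
        counts = [ct.shape[0]]
        cur = ct
        for preset in ("singleton_doubleton", "core"):
            cur, _ = filter_rare_taxa(cur, preset=preset)
            counts.append(cur.shape[0])
        assert counts == sorted(counts, reverse=True)


class TestVennPartition:
    def test_unique_to_one_host(self):
        ct = CountTable(["t"], ["s1", "s2"], np.array([[4, 0]]))
        meta = make_metadata({"s1": ("A", "x"), "s2": ("B", "x")})
        v = venn_partition(ct, meta)
        assert v.count("A") == 1
        assert v.count("A", "B") == 0

    def test_counts_partition_taxa(self):
        rng = np.random.default_rng(4)
        ct = CountTable(
            [f"t{i}" for i in range(40)],
            [f"s{j}" for j in range(9)],
            (rng.random((40, 9)) < 0.4).astype(int),
        )
        meta = make_metadata(
            {f"s{j}": (["A", "B", "C"][j % 3], "x") for j in range(9)}
        )
        v = venn_partition(ct, meta)
        occupied = int(((ct.counts.sum(axis=1)) > 0).sum())
        assert v.total_taxa() == occupied

    def test_generator_planted_structure_recovered(self):
        """10 shared core + 2 unique taxa per host are recovered exactly."""
        cfg = SyntheticConfig(
            hosts=["A", "B", "C"],
            sites_per_host={h: ["x"] for h in "ABC"},
            plants_per_population=25,
            n_core_taxa=10,
            n_sporadic_taxa=0,
            n_unique_per_host=2,
            seed=11,
        )
        ct, meta, tax, truth = generate(cfg)
        v = venn_partition(ct, meta)
        assert v.count("A", "B", "C") == 10
        for h in "ABC":
            assert v.count(h) == 2
            assert all(truth.role[t] == f"unique:{h}" for t in v.taxa_by_subset[frozenset([h])])


class TestRankAbundance:
    def _meta(self, n):
        return make_metadata({f"s{j}": ("A" if j % 2 else "B", "x") for j in range(n)})

    def test_zero_median_ranks_below_positive(self):
        n = 9
        counts = np.ones((2, n), dtype=int)
        counts[0] = [0] * (n - 1) + [50]   # median 0 despite one huge value
        counts[1] = [2] * n                # median positive
        ct = CountTable(["spiky", "steady"], [f"s{j}" for j in range(n)], counts)
        at = hellinger_transform(ct)
        out = rank_abundance_summary(at, self._meta(n), top_n=2)
        assert out["taxon_id"].tolist()[0] == "steady"

    def test_median_ties_broken_by_mean_then_id(self):
        counts = np.array([[1, 1, 3], [1, 1, 9], [1, 1, 3]])
        ct = CountTable(["b", "a", "c"], ["s0", "s1", "s2"], counts)
        at = hellinger_transform(ct)
        out = rank_abundance_summary(at, self._meta(3), top_n=3)
        # equal medians; "a" has the larger mean; "b" beats "c" by id
        assert out["taxon_id"].tolist() == ["a", "b", "c"]

    def test_identical_host_distributions_not_significant(self):
        counts = np.tile(np.array([[5], [3]]), (1, 8))
        ct = CountTable(["x", "y"], [f"s{j}" for j in range(8)], counts)
        at = hellinger_transform(ct)
        out = rank_abundance_summary(at, self._meta(8), top_n=2)
        assert (out["significance"] == "").all()
        assert (out["anova_p"] > 0.9).all()


class TestClassComposition:
    def test_single_class_share_one(self):
        ct = CountTable(["t1", "t2"], ["s1", "s2"], np.array([[3, 1], [2, 2]]))
        tax = make_taxonomy(
            {t: ("Fungi", "Asc", "Dothideomycetes") for t in ("t1", "t2")}
        )
        meta = make_metadata({"s1": ("A", "x"), "s2": ("A", "x")})
        out = class_composition(ct, tax, meta)
        assert np.allclose(out["share"], 1.0)

    def test_shares_sum_to_one_per_group(self):
        rng = np.random.default_rng(5)
        ct = CountTable(
            [f"t{i}" for i in range(20)],
            [f"s{j}" for j in range(6)],
            rng.integers(0, 30, (20, 6)),
        )
        tax = make_taxonomy(
            {f"t{i}": ("Fungi", "Asc", f"Class{i % 5}") for i in range(20)}
        )
        meta = make_metadata(
            {f"s{j}": ("A" if j < 3 else "B", "x" if j % 2 else "y") for j in range(6)}
        )
        out = class_composition(ct, tax, meta, top_k=3)
        sums = out.groupby(["level", "group"])["share"].sum()
        assert np.allclose(sums, 1.0)

    def test_generator_class_mix_recovered(self):
        """Realized class shares match the generator's expected relative
        abundances within sampling error."""
        cfg = SyntheticConfig(
            hosts=["A"],
            sites_per_host={"A": ["x"]},
            plants_per_population=30,
            n_core_taxa=30,
            n_sporadic_taxa=0,
            n_classes=3,
            seed=21,
        )
        ct, meta, tax, truth = generate(cfg)
        out = class_composition(ct, tax, meta, top_k=3)
        host_rows = out[out["level"] == "host"].set_index("class")["share"]
        exp = truth.expected_relative_abundance.loc["A"]
        classes = pd.Series(truth.class_of)
        expected_shares = exp.groupby(classes.loc[exp.index]).sum()
        for cls, share in expected_shares.items():
            assert abs(host_rows.get(cls, 0.0) - share) < 0.06
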