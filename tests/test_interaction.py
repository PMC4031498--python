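"""Percentile filtering, matrix collapsing and quartile/vigintile stratification."""

import logging

import numpy as np
import pandas as pd
import pytest

from mirsites import interaction
from mirsites.io import SiteRecord


def sites(scores, category="conserved", gene="g1"):
    return [SiteRecord(gene, f"miR-{i}", "mmu", category, s) for i, s in enumerate(scores)]


class TestPercentileFilter:
    def test_keeps_strongest_half_of_conserved(self):
        records = sites([-0.9, -0.5, -0.3, -0.1])
        kept = interaction.filter_sites_by_percentile(records, pct_conserved=50)
        assert sorted(kept["context_score"]) == [-0.9, -0.5]

    def test_ties_at_threshold_kept(self):
        records = sites([-0.2, -0.2, -0.2, -0.2])
        kept = interaction.filter_sites_by_percentile(records, pct_conserved=50)
        assert len(kept) == 4

    def test_empty_input(self):
        kept = interaction.filter_sites_by_percentile([])
        assert kept.empty

    def test_categories_filtered_independently(self):
        records = sites([-0.9, -0.1]) + sites([-0.8, -0.6, -0.4, -0.2], "nonconserved")
        kept = interaction.filter_sites_by_percentile(records, 50, 75)
        by_cat = kept.groupby("category")["context_score"].apply(list).to_dict()
        assert by_cat["conserved"] == [-0.9]
        assert by_cat["nonconserved"] == [-0.8]

    @pytest.mark.parametrize("pct", [0, 10, 25, 50, 75, 90, 100])
    def test_matches_sort_based_oracle(self, pct):
        rng = np.random.default_rng(42)
        scores = -np.round(rng.gamma(2.0, 0.2, size=57), 6)
        records = sites(list(scores))
        kept = set(interaction.filter_sites_by_percentile(records, pct_conserved=pct)["mirna_id"])
        # oracle: pure-python sort, threshold at 0-based position ceil((n-1)*pct/100)
        strengths = sorted(-s for s in scores)
        threshold = strengths[-(-((len(strengths) - 1) * pct) // 100)]
        expected = {f"miR-{i}" for i, s in enumerate(scores) if -s >= threshold}
        assert kept == expected

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(0)
        records = sites(list(-rng.random(40)))
        previous = None
        for pct in [90, 75, 50, 25, 0]:
            kept = set(interaction.filter_sites_by_percentile(records, pct_conserved=pct)["mirna_id"])
            if previous is not None:
                assert previous <= kept
            previous = kept

    def test_retained_fraction_near_target(self):
        rng = np.random.default_rng(3)
        n = 400
        records = sites(list(-rng.random(n)))
        for pct in (50, 75):
            kept = interaction.filter_sites_by_percentile(records, pct_conserved=pct)
            assert abs(len(kept) / n - (100 - pct) / 100) <= 1 / n


class TestBinaryMatrix:
    def test_duplicate_sites_collapse_to_one(self):
        records = [SiteRecord("g1", "miR-1", "mmu", "conserved", -0.3)] * 3 + [
            SiteRecord("g1", "miR-2", "mmu", "conserved", -0.4)]
        matrix = interaction.build_binary_matrix(records, "mmu")
        assert matrix.counts["g1"] == 2

    def test_shared_position_counts_once_per_mirna(self):
        records = [SiteRecord("g1", "miR-1", "mmu", "conserved", -0.3, 10, 17),
                   SiteRecord("g1", "miR-2", "mmu", "conserved", -0.3, 10, 17)]
        matrix = interaction.build_binary_matrix(records, "mmu")
        assert matrix.counts["g1"] == 2

    def test_universe_gene_without_sites_gets_zero_row(self):
        records = [SiteRecord("g1", "miR-1", "mmu", "conserved", -0.3)]
        matrix = interaction.build_binary_matrix(records, "mmu", gene_universe=["g1", "g5"])
        assert matrix.counts["g5"] == 0

    def test_species_mismatch_rejected(self):
        records = [SiteRecord("g1", "miR-1", "rno", "conserved", -0.3)]
        with pytest.raises(ValueError, match="species"):
            interaction.build_binary_matrix(records, "mmu")

    def test_idempotent_under_reexpansion(self):
        rng = np.random.default_rng(11)
        records = [SiteRecord(f"g{rng.integers(20)}", f"miR-{rng.integers(10)}",
                              "mmu", "conserved", -0.5) for _ in range(200)]
        matrix = interaction.build_binary_matrix(records, "mmu")
        rebuilt = interaction.build_binary_matrix(matrix.to_records(), "mmu")
        assert rebuilt.incidence.equals(matrix.incidence)

    def test_counts_match_set_cardinality_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            n = int(rng.integers(1, 400))
            rows = [(f"g{rng.integers(200)}", f"miR-{rng.integers(50)}") for _ in range(n)]
            records = [SiteRecord(g, m, "mmu", "conserved", -0.2) for g, m in rows]
            matrix = interaction.build_binary_matrix(records, "mmu")
            oracle = {}
            for g, m in rows:
                oracle.setdefault(g, set()).add(m)
            for g, mirnas in oracle.items():
                assert matrix.counts[g] == len(mirnas)

    def test_entries_are_binary(self, small_dataset):
        matrix = interaction.build_binary_matrix(small_dataset.site_tables["ref"], "ref")
        assert set(np.unique(matrix.incidence.to_numpy())) <= {0, 1}


class TestQuartiles:
    def test_counts_one_to_eight(self):
        counts = pd.Series(range(1, 9), index=[f"g{i}" for i in range(1, 9)])
        strata = interaction.assign_quartile_groups(counts)
        assert (strata.q25_threshold, strata.q75_threshold) == (2, 6)
        assert strata.q1_set == {"g1"}
        assert strata.q4_set == {"g7", "g8"}

    def test_constant_counts_empty_groups(self, caplog):
        counts = pd.Series([10] * 8, index=[f"g{i}" for i in range(8)])
        with caplog.at_level(logging.WARNING, logger="mirsites"):
            strata = interaction.assign_quartile_groups(counts)
        assert strata.q1_set == set() and strata.q4_set == set()
        assert any("constant" in r.message for r in caplog.records)

    def test_single_outlier_is_q4(self):
        counts = pd.Series([0] * 7 + [100], index=[f"g{i}" for i in range(8)])
        strata = interaction.assign_quartile_groups(counts)
        assert strata.q4_set == {"g7"}
        assert strata.q1_set == set()

    def test_q1_q4_disjoint(self, small_dataset):
        matrix = interaction.build_binary_matrix(small_dataset.site_tables["ref"], "ref")
        strata = interaction.assign_quartile_groups(matrix.counts)
        assert not strata.q1_set & strata.q4_set

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            interaction.assign_quartile_groups(pd.Series([1, 2, 3]))


class TestVigintiles:
    def test_forty_distinct_counts_two_per_bin(self):
        counts = pd.Series(range(40), index=[f"g{i:02d}" for i in range(40)])
        assignment = interaction.assign_vigintiles(counts)
        sizes = pd.Series(assignment).value_counts()
        assert (sizes == 2).all()

    def test_forty_one_genes_one_bin_of_three(self):
        counts = pd.Series(range(41), index=[f"g{i:02d}" for i in range(41)])
        sizes = pd.Series(interaction.assign_vigintiles(counts)).value_counts()
        assert sorted(sizes) == [2] * 19 + [3]

    def test_tie_break_deterministic(self):
        counts = pd.Series([5] * 60, index=[f"g{i:02d}" for i in range(60)])
        a = interaction.assign_vigintiles(counts)
        b = interaction.assign_vigintiles(counts.sample(frac=1, random_state=0))
        assert a == b

    def test_partition_of_universe(self, small_dataset):
        matrix = interaction.build_binary_matrix(small_dataset.site_tables["ref"], "ref")
        assignment = interaction.assign_vigintiles(matrix.counts)
        assert set(assignment) == set(matrix.gene_ids)
        sizes = pd.Series(assignment).value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_too_few_genes(self):
        with pytest.raises(ValueError):
            interaction.assign_vigintiles(pd.Series(range(19)))


class TestBinnedMeans:
    def setup_method(self):
        self.counts = pd.Series(range(40), index=[f"g{i:02d}" for i in range(40)])
        self.vig = interaction.assign_vigintiles(self.counts)

    def test_counts_as_y_nondecreasing(self):
        table = interaction.binned_means(self.vig, self.counts, self.counts)
        assert (table["mean_y"].diff().dropna() >= 0).all()

    def test_constant_x(self):
        x = pd.Series(3.0, index=self.counts.index)
        table = interaction.binned_means(self.vig, x, self.counts)
        assert (table["mean_x"] == 3.0).all()

    def test_mean_of_two(self):
        x = pd.Series([1.0, 3.0] * 20, index=self.counts.index)
        table = interaction.binned_means(self.vig, x, self.counts)
        assert table.loc[0, "mean_x"] == pytest.approx(2.0)

    def test_missing_values_excluded_and_empty_bin_flagged(self):
        x = self.counts.astype(float).copy()
        x.iloc[:2] = np.nan  # bin 1 entirely missing
        table = interaction.binned_means(self.vig, x, self.counts)
        assert table.loc[0, "n"] == 0 and np.isnan(table.loc[0, "mean_x"])
        assert table.loc[1, "n"] == 2
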