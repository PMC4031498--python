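"""Conservation aggregation, repeat stratification, UTR length, co-localization."""

import numpy as np
import pandas as pd
import pytest

from mirsites import tracks
from mirsites.io import GeneAnnotation, RepeatAnnotation, ScoreTrack


def track_from(rows):
    return ScoreTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "score"]))


class TestMeanConservation:
    def test_uniform_score(self):
        track = track_from([("chr1", 0, 100, 0.5)])
        assert tracks.mean_conservation(track, [(10, 50)], "chr1") == pytest.approx(0.5)

    def test_length_weighted(self):
        track = track_from([("chr1", 0, 10, 1.0), ("chr1", 10, 40, 0.0)])
        assert tracks.mean_conservation(track, [(0, 40)], "chr1") == pytest.approx(0.25)

    def test_uncovered_bases_excluded_from_denominator(self):
        track = track_from([("chr1", 0, 20, 0.8)])
        assert tracks.mean_conservation(track, [(0, 40)], "chr1") == pytest.approx(0.8)

    def test_fully_uncovered_is_undefined(self):
        track = track_from([("chr1", 0, 20, 0.8)])
        assert tracks.mean_conservation(track, [(100, 140)], "chr1") is None
        assert tracks.mean_conservation(track, [(5, 15)], "chr2") is None

    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(15):
            # random non-overlapping track within 1 kb
            edges = np.sort(rng.choice(np.arange(1, 1000), size=12, replace=False))
            rows, scores_by_base = [], {}
            for i in range(0, len(edges) - 1, 2):
                score = float(rng.random())
                rows.append(("chr1", int(edges[i]), int(edges[i + 1]), score))
                for b in range(int(edges[i]), int(edges[i + 1])):
                    scores_by_base[b] = score
            track = track_from(rows)
            q = sorted(rng.choice(np.arange(0, 1000), size=2, replace=False))
            intervals = [(int(q[0]), int(q[1]))]
            got = tracks.mean_conservation(track, intervals, "chr1")
            covered = [scores_by_base[b] for b in range(*intervals[0]) if b in scores_by_base]
            if not covered:
                assert got is None
            else:
                assert got == pytest.approx(np.mean(covered), abs=1e-12)


class TestRepeatOverlap:
    def ann(self, utr=(100, 200)):
        return GeneAnnotation("g", "chr1", "+", 0, utr3_intervals=[utr])

    def test_internal_overlap(self):
        flag = tracks.flag_repeat_overlap(self.ann(), [RepeatAnnotation("chr1", 150, 160, "LTR")])
        assert flag.has_ltr_sine and flag.overlap_bp == 10

    def test_half_open_abutment_is_no_overlap(self):
        flag = tracks.flag_repeat_overlap(self.ann(), [RepeatAnnotation("chr1", 200, 250, "SINE")])
        assert not flag.has_ltr_sine and flag.overlap_bp == 0

    def test_class_filter(self):
        flag = tracks.flag_repeat_overlap(self.ann(), [RepeatAnnotation("chr1", 150, 160, "LINE")])
        assert not flag.has_ltr_sine


class TestStratifiedMedians:
    def test_medians(self):
        counts = pd.Series({"a": 2, "b": 4, "c": 6, "d": 1, "e": 3})
        flags = {"a": True, "b": True, "c": True, "d": False, "e": False}
        result = tracks.stratified_count_medians(counts, flags)
        assert (result["median_with"], result["median_without"]) == (4, 2)

    def test_identical_strata_p_one(self):
        counts = pd.Series({"a": 2, "b": 4, "c": 6, "d": 2, "e": 4, "f": 6})
        flags = {"a": True, "b": True, "c": True, "d": False, "e": False, "f": False}
        result = tracks.stratified_count_medians(counts, flags)
        assert result["wilcoxon_p"] == pytest.approx(1.0)

    def test_empty_stratum_rejected(self):
        counts = pd.Series({"a": 2, "b": 4})
        flags = {"a": True, "b": True}
        with pytest.raises(ValueError):
            tracks.stratified_count_medians(counts, flags, within={"a", "b"})


class TestUtrLengthVsCounts:
    def anns(self, lengths):
        return [GeneAnnotation(f"g{i}", "chr1", "+", 0, utr3_intervals=[(0, length)])
                for i, length in enumerate(lengths)]

    def test_perfect_relation(self):
        lengths = [100, 200, 300, 400]
        counts = pd.Series({f"g{i}": l // 100 for i, l in enumerate(lengths)})
        _, rho = tracks.utr_length_vs_counts(self.anns(lengths), counts)
        assert rho == pytest.approx(1.0)

    def test_constant_counts_undefined(self):
        lengths = [100, 200, 300]
        counts = pd.Series({f"g{i}": 7 for i in range(3)})
        _, rho = tracks.utr_length_vs_counts(self.anns(lengths), counts)
        assert rho is None

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(7)
        lengths = list(rng.choice(np.arange(50, 5000), size=30, replace=False))
        counts = pd.Series({f"g{i}": int(c) for i, c in
                            enumerate(rng.choice(np.arange(100), size=30, replace=False))})
        _, rho = tracks.utr_length_vs_counts(self.anns(lengths), counts)
        # distinct values: classic 1 - 6*sum(d^2)/(n(n^2-1))
        rank_l = pd.Series(lengths).rank()
        rank_c = counts.reset_index(drop=True).rank()
        d2 = ((rank_l - rank_c) ** 2).sum()
        n = 30
        assert rho == pytest.approx(1 - 6 * d2 / (n * (n**2 - 1)), abs=1e-12)

    def test_missing_utr_dropped(self):
        anns = self.anns([100, 200]) + [GeneAnnotation("g2", "chr1", "+", 0)]
        counts = pd.Series({"g0": 1, "g1": 2, "g2": 3})
        table, _ = tracks.utr_length_vs_counts(anns, counts)
        assert list(table["gene_id"]) == ["g0", "g1"]


class TestColocalization:
    def gene(self, span=(100_000, 105_000)):
        return GeneAnnotation("g", "chr1", "+", span[0],
                              utr3_intervals=[(span[1] - 500, span[1])], span=span)

    def loci(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])

    def test_mirna_inside_gene_span(self):
        result = tracks.colocalize_mirnas(self.loci([("chr1", 101_000, 101_080, "m1")]),
                                          [self.gene()])
        assert result.pairs == {("m1", "g")}

    def test_boundary_exactly_window_upstream_included(self):
        result = tracks.colocalize_mirnas(self.loci([("chr1", 80_000, 80_080, "m1")]),
                                          [self.gene()])
        assert result.pairs == {("m1", "g")}

    def test_beyond_window_excluded(self):
        result = tracks.colocalize_mirnas(self.loci([("chr1", 130_000, 130_080, "m1")]),
                                          [self.gene()])
        assert result.pairs == set()

    def test_other_chromosome_excluded(self):
        result = tracks.colocalize_mirnas(self.loci([("chr2", 101_000, 101_080, "m1")]),
                                          [self.gene()])
        assert result.pairs == set()

    def test_monotone_in_window(self):
        rng = np.random.default_rng(13)
        genes = [GeneAnnotation(f"g{i}", "chr1", "+", int(p), span=(int(p), int(p) + 2000))
                 for i, p in enumerate(rng.choice(np.arange(0, 5_000_000, 3000), 50, replace=False))]
        loci = self.loci([("chr1", int(p), int(p) + 80, f"m{i}") for i, p in
                          enumerate(rng.integers(0, 5_000_000, size=50))])
        previous = None
        for window in (0, 20_000, 50_000):
            pairs = tracks.colocalize_mirnas(loci, genes, window).pairs
            if previous is not None:
                assert previous <= pairs
            previous = pairs

    def test_counts_equal_recomputed_cardinalities(self, small_dataset):
        result = tracks.colocalize_mirnas(small_dataset.mirna_loci, small_dataset.annotations)
        assert result.n_mirnas == len({m for m, _ in result.pairs})
        assert result.n_genes == len({g for _, g in result.pairs})
        assert result.n_genes > 0  # planted intragenic loci must be found
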