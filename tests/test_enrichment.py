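"""Overlap statistics vs a per-base brute-force oracle, plus the exact
arithmetic identities they must satisfy."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from chromstack import synthetic_data as sd
from chromstack.enrichment import (chromosome_enrichment, enrichment_table,
                                   fold_enrichment, grouped_geometric_summary,
                                   jaccard, jaccard_sets,
                                   percelltype_summary, positional_enrichment,
                                   score_average, spearman)
from chromstack.io_formats import AnnotationSet, GenomeAssembly, Segmentation
from conftest import oracle_fold


def random_fixture(rng, n_bins=1000, n_states=4, bin_size=10):
    """Random segmentation + random (non-bin-aligned) annotation."""
    asm = GenomeAssembly("t", {"c1": (n_bins // 2) * bin_size - rng.integers(0, bin_size),
                               "c2": (n_bins - n_bins // 2) * bin_size}, bin_size)
    labels = {c: rng.integers(1, n_states + 1, size=asm.n_bins(c))
              for c in asm.chroms}
    seg = Segmentation(asm, n_states, labels)
    ivs = []
    for _ in range(rng.integers(5, 40)):
        chrom = asm.chroms[rng.integers(2)]
        start = int(rng.integers(0, asm.chrom_sizes[chrom] - 1))
        end = min(int(start + rng.integers(1, 8 * bin_size)), asm.chrom_sizes[chrom])
        if end > start:
            ivs.append((chrom, start, end))
    return seg, AnnotationSet("rand", ivs)


class TestFoldEnrichment:
    def test_state_covering_genome_has_fold_one(self):
        asm = GenomeAssembly("t", {"c": 2000}, 200)
        seg = Segmentation(asm, 1, {"c": np.ones(10, dtype=np.int64)})
        fold, _ = fold_enrichment(seg, AnnotationSet("a", [("c", 100, 700)]))
        assert fold.loc[1] == pytest.approx(1.0)

    def test_toy_counting_example(self):
        # 1000-bin genome, state 1 = 100 bins, annotation = 200 bins of
        # which 100 intersect state 1 -> fold 5.0, percent 50%
        asm = GenomeAssembly("t", {"c": 1000 * 200}, 200)
        lab = np.full(1000, 2, dtype=np.int64)
        lab[:100] = 1
        seg = Segmentation(asm, 2, {"c": lab})
        annot = AnnotationSet("a", [("c", 0, 100 * 200), ("c", 500 * 200, 600 * 200)])
        fold, pct = fold_enrichment(seg, annot)
        assert fold.loc[1] == pytest.approx(5.0)
        assert pct.loc[1] == pytest.approx(0.5)

    def test_annotation_equal_to_state_territory_gives_full_percent(self):
        asm = GenomeAssembly("t", {"c": 2000}, 200)
        lab = np.array([1, 1, 2, 2, 2, 2, 2, 2, 2, 2])
        seg = Segmentation(asm, 2, {"c": lab})
        _, pct = fold_enrichment(seg, AnnotationSet("a", [("c", 0, 400)]))
        assert pct.loc[1] == pytest.approx(1.0)

    def test_empty_annotation_reported_missing(self):
        asm = GenomeAssembly("t", {"c": 2000}, 200)
        seg = Segmentation(asm, 1, {"c": np.ones(10, dtype=np.int64)})
        with pytest.warns(UserWarning, match="empty"):
            fold, _ = fold_enrichment(seg, AnnotationSet("a", []))
        assert fold.isna().all()

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_per_base_oracle_exactly(self, seed):
        rng = np.random.default_rng(seed)
        seg, annot = random_fixture(rng)
        fold, pct = fold_enrichment(seg, annot)
        o_fold, o_inter, o_state, o_annot = oracle_fold(seg, annot.merged())
        np.testing.assert_allclose(fold.to_numpy(), o_fold, rtol=1e-12)
        np.testing.assert_allclose(pct.to_numpy() * o_annot, o_inter, atol=1e-9)

    def test_weighted_identity_holds_per_annotation(self):
        rng = np.random.default_rng(99)
        seg, annot = random_fixture(rng)
        tab = enrichment_table(seg, [annot])
        total = (tab.state_fraction * tab.folds["rand"]).sum()
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_planted_fold_recovered_within_binomial_ci(self, small_truth):
        truth, _ = small_truth
        seg = truth.true_path
        target_fold, n = 3.0, 200
        annot = sd.plant_annotation(seg, state=2, fold=target_fold,
                                    n_intervals=n, seed=21)
        fold, _ = fold_enrichment(seg, annot)
        frac2 = (np.concatenate(list(seg.labels.values())) == 2).mean()
        p = target_fold * frac2
        se = np.sqrt(p * (1 - p) / n)
        assert abs(fold.loc[2] - target_fold) < 4 * se / frac2


class TestJaccard:
    def test_blacklist_arithmetic_from_printed_sizes(self):
        union, j = jaccard(413_502_000, 238_977_200, 193_765_600)
        assert union == 458_713_600
        assert round(j, 2) == 0.42
        assert round(100 * 193_765_600 / 238_977_200, 1) == 81.1

    def test_identical_sets_give_one(self):
        a = AnnotationSet("a", [("c", 0, 100), ("c", 200, 350)])
        _, j = jaccard_sets(a, a)
        assert j == pytest.approx(1.0)

    def test_disjoint_sets_give_zero(self):
        a = AnnotationSet("a", [("c", 0, 100)])
        b = AnnotationSet("b", [("c", 100, 200)])
        union, j = jaccard_sets(a, b)
        assert j == 0.0 and union == 200

    def test_interval_form_matches_per_base_counting(self):
        rng = np.random.default_rng(4)
        mk = lambda: AnnotationSet("x", [("c", int(s), int(s + rng.integers(1, 50)))
                                         for s in rng.integers(0, 2000, size=30)])
        a, b = mk(), mk()
        base = np.zeros(4000, dtype=int)
        for iv in a.intervals:
            base[iv[1]:iv[2]] |= 1
        for iv in b.intervals:
            base[iv[1]:iv[2]] |= 2
        inter, union = int((base == 3).sum()), int((base > 0).sum())
        got_union, got_j = jaccard_sets(a, b)
        assert got_union == union
        assert got_j == pytest.approx(inter / union)

    def test_intersection_larger_than_sets_rejected(self):
        with pytest.raises(ValueError):
            jaccard(10, 10, 11)


class TestPositionalEnrichment:
    def test_single_state_profile_is_flat_one(self):
        asm = GenomeAssembly("t", {"c": 200 * 50}, 200)
        seg = Segmentation(asm, 1, {"c": np.ones(50, dtype=np.int64)})
        anchors = AnnotationSet("tss", [("c", 4000, 4001, "+")])
        prof = positional_enrichment(seg, anchors, window_bins=5)
        assert np.allclose(prof.folds.to_numpy(), 1.0)

    def test_planted_state_peaks_downstream_with_strand_flip(self):
        asm = GenomeAssembly("t", {"c": 200 * 200}, 200)
        lab = np.ones(200, dtype=np.int64)
        anchors = []
        for pos, strand in [(50, "+"), (100, "+"), (150, "-"), (30, "-")]:
            # state 2 planted exactly 2 bins downstream of each anchor
            target = pos + 2 if strand == "+" else pos - 2
            lab[target] = 2
            anchors.append(("c", pos * 200, pos * 200 + 1, strand))
        seg = Segmentation(asm, 2, {"c": lab})
        prof = positional_enrichment(seg, AnnotationSet("tss", anchors),
                                     window_bins=5)
        state2 = prof.folds.loc[2]
        assert state2.idxmax() == 2
        assert state2.loc[2] > 0 and state2.drop(index=2).fillna(0).max() == 0

    def test_empty_anchor_set_rejected(self, small_truth):
        truth, _ = small_truth
        with pytest.raises(ValueError, match="empty"):
            positional_enrichment(truth.true_path, AnnotationSet("x", []))

    def test_edge_anchors_contribute_only_valid_offsets(self):
        asm = GenomeAssembly("t", {"c": 200 * 20}, 200)
        seg = Segmentation(asm, 1, {"c": np.ones(20, dtype=np.int64)})
        anchors = AnnotationSet("tss", [("c", 0, 1, "+")])
        prof = positional_enrichment(seg, anchors, window_bins=5)
        assert np.isnan(prof.folds.loc[1, -5]) or prof.folds.loc[1, -5] == 0


class TestGeometricSummary:
    def test_two_values(self):
        gmean, _ = grouped_geometric_summary([4, 1])
        assert gmean == pytest.approx(2.0)

    def test_zero_replaced_by_min_nonzero(self):
        # [0, 9, 3] -> zeros become 3 -> (3*9*3)^(1/3)
        gmean, _ = grouped_geometric_summary([0, 9, 3])
        assert gmean == pytest.approx((3 * 9 * 3) ** (1 / 3))

    def test_constant_values(self):
        gmean, gsd = grouped_geometric_summary([2.5, 2.5, 2.5])
        assert gmean == pytest.approx(2.5)
        assert gsd == pytest.approx(1.0)

    def test_all_zero_is_undefined(self):
        with pytest.warns(UserWarning):
            gmean, gsd = grouped_geometric_summary([0.0, 0.0])
        assert np.isnan(gmean) and np.isnan(gsd)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0.1, 20, size=12)
        g1, s1 = grouped_geometric_summary(x)
        g2, s2 = grouped_geometric_summary(7.0 * x)
        assert g2 == pytest.approx(7.0 * g1)
        assert s2 == pytest.approx(s1)


class TestChromosomeEnrichment:
    def test_single_chromosome_gives_fold_one(self):
        asm = GenomeAssembly("t", {"c": 2000}, 200)
        seg = Segmentation(asm, 2, {"c": np.array([1, 1, 2, 2, 2, 1, 1, 2, 2, 2])})
        tab = chromosome_enrichment(seg)
        assert np.allclose(tab.folds["c"].to_numpy(), 1.0)

    def test_state_confined_to_one_of_two_equal_chromosomes(self):
        asm = GenomeAssembly("t", {"c1": 2000, "c2": 2000}, 200)
        seg = Segmentation(asm, 2, {"c1": np.full(10, 2, dtype=np.int64),
                                    "c2": np.ones(10, dtype=np.int64)})
        tab = chromosome_enrichment(seg)
        assert tab.folds.loc[1, "c2"] == pytest.approx(2.0)
        assert tab.folds.loc[1, "c1"] == pytest.approx(0.0)
        for chrom in ("c1", "c2"):
            assert (tab.state_fraction * tab.folds[chrom]).sum() == pytest.approx(1.0)


class TestPerCellTypeSummary:
    def test_identical_segmentation_yields_identity(self):
        asm = GenomeAssembly("t", {"c": 200 * 30}, 200)
        rng = np.random.default_rng(0)
        seg = Segmentation(asm, 3, {"c": rng.integers(1, 4, size=30)})
        max_df, probs = percelltype_summary(seg, {"e1": seg}, {"e1": "tissueA"})
        assert list(max_df["e1"]) == [1, 2, 3]
        np.testing.assert_allclose(probs["tissueA"].to_numpy(), np.eye(3),
                                   atol=1e-12)

    def test_two_epigenome_group_average_matches_hand_count(self):
        asm = GenomeAssembly("t", {"c": 4 * 200}, 200)
        full = Segmentation(asm, 2, {"c": np.array([1, 1, 2, 2])})
        e1 = Segmentation(asm, 2, {"c": np.array([1, 2, 2, 2])})
        e2 = Segmentation(asm, 2, {"c": np.array([1, 1, 1, 2])})
        _, probs = percelltype_summary(full, {"e1": e1, "e2": e2},
                                       {"e1": "g", "e2": "g"})
        # full state 1: e1 fractions (1/2, 1/2); e2 fractions (1, 0)
        np.testing.assert_allclose(probs["g"].loc[1], [0.75, 0.25])
        # rows sum to one
        assert np.allclose(probs["g"].sum(axis=1), 1.0, atol=1e-6)

    def test_missing_chromosome_is_named(self):
        asm = GenomeAssembly("t", {"c1": 400, "c2": 400}, 200)
        full = Segmentation(asm, 1, {"c1": np.ones(2, dtype=np.int64),
                                     "c2": np.ones(2, dtype=np.int64)})
        partial = Segmentation(asm, 1, {"c1": np.ones(2, dtype=np.int64)})
        partial.labels.pop("c2", None)
        with pytest.raises(ValueError, match="c2"):
            percelltype_summary(full, {"e1": partial}, {"e1": "g"})


class TestScoreAverage:
    def test_constant_track(self, small_truth):
        truth, _ = small_truth
        scores = {c: np.full(len(l), 0.42)
                  for c, l in truth.true_path.labels.items()}
        avg = score_average(truth.true_path, scores)
        assert np.allclose(avg.to_numpy(), 0.42)

    def test_distinct_constants_per_state_recovered(self):
        asm = GenomeAssembly("t", {"c": 200 * 10}, 200)
        lab = np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2])
        seg = Segmentation(asm, 2, {"c": lab})
        scores = {"c": np.where(lab == 1, 0.2, 0.9)}
        avg = score_average(seg, scores)
        assert avg.loc[1] == pytest.approx(0.2)
        assert avg.loc[2] == pytest.approx(0.9)

    def test_state_without_scored_bases_is_missing(self):
        asm = GenomeAssembly("t", {"c": 200 * 4}, 200)
        seg = Segmentation(asm, 2, {"c": np.array([1, 1, 2, 2])})
        scores = {"c": np.array([0.5, 0.5, np.nan, np.nan])}
        avg = score_average(seg, scores)
        assert avg.loc[1] == pytest.approx(0.5)
        assert np.isnan(avg.loc[2])


class TestSpearman:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, size=20).astype(float)  # heavy ties
        y = rng.integers(0, 5, size=20).astype(float)
        ours = spearman(x, y)
        ref = spearmanr(x, y).statistic
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_exact_on_small_permutations(self):
        # n=4: every displacement checked against the closed form
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) valid without ties
        import itertools
        x = np.arange(4, dtype=float)
        for perm in itertools.permutations(range(4)):
            y = np.array(perm, dtype=float)
            d2 = ((x - y) ** 2).sum()
            assert spearman(x, y) == pytest.approx(1 - 6 * d2 / (4 * 15))
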