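"""Alignment diagnostics: masking, distances, composition, signal."""

import numpy as np
import pytest
from scipy import stats

import transandes as ta
from transandes.dec import DECParams
from transandes.seqdiag import (
    Alignment,
    SiteMask,
    apply_site_mask,
    base_composition_test,
    count_informative_sites,
    fitch_length,
    g1_statistic,
    group_mean_distance,
    pdistance,
    saturation_table,
)
from transandes.simulate import SeqConfig, simulate_alignment, simulate_yule_tree

# the ten ambiguously aligned 12S regions discarded before analysis
RIBOSOMAL_MASK = SiteMask((
    (90, 102), (126, 131), (224, 233), (292, 297), (313, 328),
    (381, 388), (681, 686), (745, 767), (784, 794), (891, 918),
))


class TestSiteMask:
    def test_ribosomal_mask_removes_127_of_975(self):
        aln = Alignment({"s1": "A" * 975, "s2": "C" * 975})
        masked, removed = apply_site_mask(aln, RIBOSOMAL_MASK)
        assert removed == 127
        assert masked.length == 848

    def test_empty_mask_is_identity(self):
        aln = Alignment({"s1": "ACGT", "s2": "ACGA"})
        masked, removed = apply_site_mask(aln, SiteMask(()))
        assert removed == 0
        assert masked.sequences == aln.sequences

    def test_overlapping_ranges_union(self):
        aln = Alignment({"s1": "A" * 20, "s2": "C" * 20})
        _, removed = apply_site_mask(aln, SiteMask(((5, 10), (8, 12))))
        assert removed == 8

    def test_out_of_range_rejected(self):
        aln = Alignment({"s1": "ACGT", "s2": "ACGT"})
        with pytest.raises(ValueError):
            apply_site_mask(aln, SiteMask(((2, 9),)))

    def test_removed_plus_remaining_is_total(self):
        rng = np.random.default_rng(0)
        aln = Alignment({"s1": "A" * 100, "s2": "G" * 100})
        for _ in range(10):
            k = rng.integers(1, 5)
            ranges = []
            for _ in range(k):
                lo = int(rng.integers(1, 95))
                ranges.append((lo, int(rng.integers(lo, 101))))
            masked, removed = apply_site_mask(aln, SiteMask(tuple(ranges)))
            assert removed + masked.length == 100

    def test_mask_text_parsing(self):
        mask = SiteMask.from_text("90-102\n126-131\n")
        assert mask.ranges == ((90, 102), (126, 131))


class TestPDistance:
    def test_single_difference(self):
        dm = pdistance(Alignment({"x": "ACGT", "y": "ACGA"}))
        assert dm.get("x", "y") == pytest.approx(0.25)

    def test_pairwise_deletion_shrinks_denominator(self):
        dm = pdistance(Alignment({"x": "AC-T", "y": "ACGT"}))
        assert dm.get("x", "y") == pytest.approx(0.0)
        assert dm.effective_sites[0, 1] == 3

    def test_identical_sequences(self):
        dm = pdistance(Alignment({"x": "ACGTACGT", "y": "ACGTACGT"}))
        assert dm.get("x", "y") == 0.0

    def test_no_shared_sites_is_nan(self):
        dm = pdistance(Alignment({"x": "AC--", "y": "--GT"}))
        assert np.isnan(dm.get("x", "y"))

    def test_complete_equals_pairwise_without_gaps(self):
        tree = simulate_yule_tree(5, 0.4, seed=8)
        aln = simulate_alignment(tree, SeqConfig(length=300), seed=1)
        a = pdistance(aln, "pairwise")
        b = pdistance(aln, "complete")
        assert np.allclose(a.distances, b.distances)
        assert (a.distances[~np.eye(5, dtype=bool)] <= 1).all()

    def test_ambiguity_treated_as_missing(self):
        dm = pdistance(Alignment({"x": "ANRT", "y": "ACGT"}))
        assert dm.effective_sites[0, 1] == 2


class TestGroupMeans:
    def test_uniform_cross_distance(self):
        # every cross pair at 0.131 -> between-group mean 13.1%
        seqs = {}
        base = "A" * 1000
        seqs["g1a"] = base
        seqs["g1b"] = base
        div = "C" * 131 + "A" * 869
        seqs["g2a"] = div
        seqs["g2b"] = div
        dm = pdistance(Alignment(seqs))
        groups = {"g1a": "G1", "g1b": "G1", "g2a": "G2", "g2b": "G2"}
        means = group_mean_distance(dm, groups)
        assert means[("G1", "G2")] == pytest.approx(0.131)
        assert means[("G1", "G1")] == pytest.approx(0.0)

    def test_singleton_group_no_within_mean(self):
        dm = pdistance(Alignment({"x": "ACGT", "y": "ACGA"}))
        means = group_mean_distance(dm, {"x": "X", "y": "Y"})
        assert means[("X", "X")] is None
        assert means[("X", "Y")] == pytest.approx(0.25)

    def test_taxon_order_invariant(self):
        tree = simulate_yule_tree(6, 0.4, seed=2)
        aln = simulate_alignment(tree, SeqConfig(length=200), seed=3)
        groups = {lab: ("G1" if i % 2 else "G2")
                  for i, lab in enumerate(aln.labels)}
        m1 = group_mean_distance(pdistance(aln), groups)
        reordered = Alignment({lab: aln.sequences[lab]
                               for lab in reversed(aln.labels)})
        m2 = group_mean_distance(pdistance(reordered), groups)
        for k in m1:
            assert m1[k] == pytest.approx(m2[k])


class TestSaturation:
    def test_counts_and_percent(self):
        x = "A" * 300
        y = "C" * 3 + "A" * 297
        aln = Alignment({"x": x, "y": y}).with_cycling_codon_positions()
        (la, lb, pct, subs, sub3), = saturation_table(aln)
        assert pct == pytest.approx(1.0)
        assert subs == 3
        assert sub3 == 1  # positions 1,2,3 -> one third-position site

    def test_identical_pair(self):
        aln = Alignment({"x": "ACGTAC", "y": "ACGTAC"}).with_cycling_codon_positions()
        (_, _, pct, subs, sub3), = saturation_table(aln)
        assert (pct, subs, sub3) == (0.0, 0, 0)

    def test_missing_codon_annotation_rejected(self):
        aln = Alignment({"x": "ACGT", "y": "ACGA"})
        with pytest.raises(ValueError):
            saturation_table(aln)

    def test_substitutions_track_divergence(self):
        tree = simulate_yule_tree(8, 0.15, seed=4)
        aln = simulate_alignment(
            tree, SeqConfig(length=900, annotate_codons=True), seed=5)
        rows = saturation_table(aln)
        pcts = [r[2] for r in rows]
        subs = [r[3] for r in rows]
        rho = stats.spearmanr(pcts, subs).statistic
        assert rho > 0.9


class TestBaseComposition:
    def test_identical_sequences_homogeneous(self):
        aln = Alignment({"x": "ACGTACGT", "y": "ACGTACGT", "z": "ACGTACGT"})
        res = base_composition_test(aln)
        assert res.chisq == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_toy_contingency_value(self):
        # counts (10,10,10,10) vs (40,0,0,0): chi-square 48.0 by hand
        aln = Alignment({"x": "ACGT" * 10, "y": "A" * 40})
        res = base_composition_test(aln)
        assert res.chisq == pytest.approx(48.0)
        ref = stats.chi2_contingency([[10, 10, 10, 10], [40, 0, 0, 0]],
                                     correction=False)
        assert res.chisq == pytest.approx(ref.statistic)
        assert res.df == 3

    def test_frequencies_sum_to_one(self):
        tree = simulate_yule_tree(5, 0.3, seed=6)
        aln = simulate_alignment(tree, SeqConfig(length=400), seed=7)
        res = base_composition_test(aln)
        for f in res.frequencies.values():
            assert sum(f) == pytest.approx(1.0)


class TestInformativeSites:
    def test_examples(self):
        assert count_informative_sites(
            Alignment({"1": "A", "2": "A", "3": "C", "4": "C"})) == 1
        assert count_informative_sites(
            Alignment({"1": "A", "2": "A", "3": "A", "4": "C"})) == 0

    def test_additive_over_concatenation(self):
        tree = simulate_yule_tree(6, 0.3, seed=9)
        a1 = simulate_alignment(tree, SeqConfig(length=300), seed=10)
        a2 = simulate_alignment(tree, SeqConfig(length=200), seed=11)
        joint = Alignment({lab: a1.sequences[lab] + a2.sequences[lab]
                           for lab in a1.labels})
        assert (count_informative_sites(joint)
                == count_informative_sites(a1) + count_informative_sites(a2))


class TestFitchAndG1:
    def test_textbook_fitch_length(self):
        aln = Alignment({"a": "A", "b": "A", "c": "C", "d": "C"})
        topo = [(0, 1), (2, 3), (4, 5)]  # ((a,b),(c,d))
        assert fitch_length(topo, aln.matrix()) == 1

    def test_fitch_label_permutation_invariant(self):
        rng = np.random.default_rng(3)
        seqs = {f"t{i}": "".join(rng.choice(list("ACGT"), 30)) for i in range(5)}
        aln = Alignment(seqs)
        topo = [(0, 1), (5, 2), (6, 3), (7, 4)]
        perm = [2, 0, 4, 1, 3]
        remapped = [(tuple(perm[x] if x < 5 else x for x in pair))
                    for pair in topo]
        M = aln.matrix()
        Mp = M[np.argsort(perm)]
        assert fitch_length(topo, M) == fitch_length(remapped, Mp)

    def test_signal_vs_shuffled(self):
        tree = simulate_yule_tree(10, 0.2, seed=13)
        aln = simulate_alignment(tree, SeqConfig(length=500), seed=14)
        res = g1_statistic(aln, n_trees=3000, seed=15)
        assert res.g1 < -0.2
        # destroy the hierarchical structure column-wise
        rng = np.random.default_rng(16)
        shuffled = {}
        cols = [list(col) for col in zip(*aln.sequences.values())]
        for col in cols:
            rng.shuffle(col)
        labels = list(aln.sequences)
        for i, lab in enumerate(labels):
            shuffled[lab] = "".join(col[i] for col in cols)
        res0 = g1_statistic(Alignment(shuffled), n_trees=3000, seed=17)
        assert abs(res0.g1) < 0.15

    def test_too_few_taxa_rejected(self):
        aln = Alignment({"a": "ACGT", "b": "ACGT", "c": "ACGT"})
        with pytest.raises(ValueError):
            g1_statistic(aln, n_trees=10)
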