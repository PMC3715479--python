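"""Tests for class 1/class 2 partitioning, extent rule, and concordance."""

import numpy as np
import pytest

from crossde.classify import (
    DOWN_A_UP_B,
    UP_A_DOWN_B,
    compare_de_sets,
    confirm_across_datasets,
    cross_dataset_overlap,
    direction_concordance,
    subclassify_extent,
)
from crossde.sam import DEGeneSet
from tests.conftest import make_expression


def de(directions, contrast="x"):
    return DEGeneSet(contrast, dict(directions))


class TestCompareDeSets:
    def test_worked_example(self):
        cc = compare_de_sets(
            de({"g1": "up", "g2": "up", "g3": "down"}),
            de({"g2": "up", "g3": "up", "g4": "down"}),
        )
        assert cc.n_overlap == 2
        assert cc.class1 == {"g2": "up"}
        assert cc.class2 == {"g3": DOWN_A_UP_B}
        assert (cc.n1, cc.n2) == (3, 3)

    def test_disjoint_sets_give_empty_classes(self):
        cc = compare_de_sets(de({"g1": "up"}), de({"g2": "up"}))
        assert cc.n_overlap == 0 and not cc.class1 and not cc.class2

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            compare_de_sets(de({}), de({"g1": "up"}))

    def test_swap_symmetry_preserves_class1_and_flips_orientation(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        a = de({g: rng.choice(["up", "down"]) for g in genes[:35]})
        b = de({g: rng.choice(["up", "down"]) for g in genes[10:]})
        fwd = compare_de_sets(a, b)
        rev = compare_de_sets(b, a)
        assert fwd.class1 == rev.class1
        flip = {UP_A_DOWN_B: DOWN_A_UP_B, DOWN_A_UP_B: UP_A_DOWN_B}
        assert rev.class2 == {g: flip[o] for g, o in fwd.class2.items()}

    def test_partition_invariants_on_random_fixtures(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            pool = [f"g{i}" for i in range(rng.integers(2, 30))]
            a = de({g: rng.choice(["up", "down"]) for g in pool
                    if rng.random() < 0.6} or {"g0": "up"})
            b = de({g: rng.choice(["up", "down"]) for g in pool
                    if rng.random() < 0.6} or {"g0": "up"})
            cc = compare_de_sets(a, b)
            overlap = a.genes & b.genes
            assert set(cc.class1) | set(cc.class2) == overlap
            assert not (set(cc.class1) & set(cc.class2))
            assert cc.n_overlap == len(overlap)


class TestExtentRule:
    def build(self, mean_a, mean_b, direction):
        # 2 samples per group; normal mean 3.0 as neutral reference
        values = np.array([[mean_a, mean_a, mean_b, mean_b, 3.0, 3.0]])
        em = make_expression(values, {"A": 2, "B": 2, "normal": 2})
        cc = compare_de_sets(de({"g0": direction}), de({"g0": direction}))
        return subclassify_extent(cc, em, "A", "B")

    def test_up_in_both_larger_mean_in_a(self):
        ext = self.build(5.0, 4.0, "up")
        assert ext.larger_in_a == {"g0"}

    def test_down_in_both_lower_mean_in_a(self):
        # further below normal in A -> dysregulated to a larger extent in A
        ext = self.build(2.0, 3.0, "down")
        assert ext.larger_in_a == {"g0"}

    def test_up_in_both_larger_mean_in_b(self):
        ext = self.build(4.0, 5.0, "up")
        assert ext.larger_in_b == {"g0"}

    def test_zero_between_subtype_difference_unclassified(self):
        ext = self.build(4.0, 4.0, "up")
        assert ext.unclassified == {"g0"}

    def test_missing_gene_raises(self):
        em = make_expression(np.ones((1, 6)), {"A": 2, "B": 2, "normal": 2})
        cc = compare_de_sets(de({"gX": "up"}), de({"gX": "up"}))
        with pytest.raises(ValueError, match="gX"):
            subclassify_extent(cc, em, "A", "B")

    def test_significance_filter_moves_genes_to_unclassified(self):
        values = np.array([[5.0, 5.0, 4.0, 4.0, 3.0, 3.0]])
        em = make_expression(values, {"A": 2, "B": 2, "normal": 2})
        cc = compare_de_sets(de({"g0": "up"}), de({"g0": "up"}))
        ext = subclassify_extent(cc, em, "A", "B", significant_ab=set())
        assert ext.unclassified == {"g0"}

    def test_subclasses_partition_class1_on_random_fixtures(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(1, 20))
            values = rng.normal(5, 1, size=(n, 9))
            em = make_expression(values, {"A": 3, "B": 3, "normal": 3})
            dirs = {f"g{i}": rng.choice(["up", "down"]) for i in range(n)}
            cc = compare_de_sets(de(dirs), de(dirs))
            ext = subclassify_extent(cc, em, "A", "B")
            union = ext.larger_in_a | ext.larger_in_b | ext.unclassified
            assert union == set(cc.class1)
            assert not (ext.larger_in_a & ext.larger_in_b)


class TestConcordance:
    def test_full_universe_overlap_is_certain(self):
        uni = {f"g{i}" for i in range(10)}
        res = cross_dataset_overlap(uni, uni, uni)
        assert res.hypergeom.p_value == pytest.approx(1.0)

    def test_enumerated_overlap_probability(self):
        uni = {f"g{i}" for i in range(10)}
        a = {f"g{i}" for i in range(5)}
        b = {f"g{i}" for i in range(4)}
        res = cross_dataset_overlap(a, b, uni)
        assert res.overlap == 4
        assert res.hypergeom.p_value == pytest.approx(5 / 210, rel=1e-12)

    def test_zero_overlap_is_uninformative(self):
        uni = {f"g{i}" for i in range(10)}
        res = cross_dataset_overlap({"g0"}, {"g5"}, uni)
        assert res.hypergeom.p_value == pytest.approx(1.0)

    def test_subset_violation_names_offenders(self):
        with pytest.raises(ValueError, match="ghost"):
            cross_dataset_overlap({"ghost"}, {"g0"}, {"g0"})

    def test_three_concordant_genes(self):
        c, k, tail = direction_concordance(
            {"a": "up", "b": "down", "c": "up"},
            {"a": "up", "b": "down", "c": "up"},
        )
        assert (c, k) == (3, 3)
        assert tail.p_value == pytest.approx(0.125)

    def test_independent_coins_give_half_concordance(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(2000)]
        a = {g: rng.choice(["up", "down"]) for g in genes}
        b = {g: rng.choice(["up", "down"]) for g in genes}
        c, k, tail = direction_concordance(a, b)
        assert abs(c / k - 0.5) < 0.05
        assert tail.p_value > 1e-4

    def test_mismatched_gene_sets_rejected(self):
        with pytest.raises(ValueError):
            direction_concordance({"a": "up"}, {"b": "up"})


class TestConfirmation:
    def cc(self, class1, class2):
        from crossde.classify import ClassComparison

        return ClassComparison(n1=0, n2=0, class1=class1, class2=class2)

    def test_class1_same_direction_confirmed(self):
        out = confirm_across_datasets(
            self.cc({"g1": "up"}, {}), self.cc({"g1": "up"}, {})
        )
        assert out.class1 == {"g1": "up"}

    def test_class_switch_not_confirmed(self):
        out = confirm_across_datasets(
            self.cc({"g1": "up"}, {}), self.cc({}, {"g1": UP_A_DOWN_B})
        )
        assert not out.class1 and not out.class2

    def test_flipped_orientation_not_confirmed(self):
        out = confirm_across_datasets(
            self.cc({}, {"g1": UP_A_DOWN_B}), self.cc({}, {"g1": DOWN_A_UP_B})
        )
        assert not out.class2

    def test_direction_mismatch_in_class1_not_confirmed(self):
        out = confirm_across_datasets(
            self.cc({"g1": "up"}, {}), self.cc({"g1": "down"}, {})
        )
        assert not out.class1
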