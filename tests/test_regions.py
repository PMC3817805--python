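import pytest

from paleorder.io import OrthologPair
from paleorder.regions import (
    assign_colors,
    block_color_stats,
    extend_by_homology,
    family_size_table,
    annotate_ancestor,
    similarity_histogram,
)
from paleorder.types import OrthologySet, RegionAssignment
from conftest import make_order


def region(genome, chrom, first, last, color, shade="dark"):
    return RegionAssignment(genome, chrom, first, last, color, shade)


class TestAssignColors:
    def order(self):
        return make_order("A", {"chr1": [(f"g{i}", "+") for i in range(12)]})

    def test_interval_colors_genes(self):
        colored = assign_colors(self.order(), [region("A", "chr1", 1, 10, "red")])
        assert colored["g4"].color == "red" and colored["g4"].shade == "dark"

    def test_outside_interval_uncolored(self):
        colored = assign_colors(self.order(), [region("A", "chr1", 1, 10, "red")])
        assert colored["g11"].color is None

    def test_length_one_interval(self):
        colored = assign_colors(self.order(), [region("A", "chr1", 3, 3, "blue")])
        assert colored["g2"].color == "blue"
        assert colored["g1"].color is None and colored["g3"].color is None

    def test_conflicting_overlap_rejected(self):
        regions = [
            region("A", "chr1", 1, 5, "red"),
            region("A", "chr1", 4, 8, "green"),
        ]
        with pytest.raises(ValueError, match="overlapping"):
            assign_colors(self.order(), regions)


class TestExtendByHomology:
    def setup_method(self):
        self.orders = {
            g: make_order(g, {"chr1": [(f"{g.lower()}1", "+")]}) for g in "ABC"
        }
        self.sets = [OrthologySet("os1", {"A": "a1", "B": "b1", "C": "c1"})]

    def colored(self, b_color, c_color):
        colored = {}
        for g in "ABC":
            regions = []
            if g == "B" and b_color:
                regions = [region("B", "chr1", 1, 1, b_color)]
            if g == "C" and c_color:
                regions = [region("C", "chr1", 1, 1, c_color)]
            colored[g] = assign_colors(self.orders[g], regions)
        return colored

    def test_two_agreeing_donors_extend(self):
        out = extend_by_homology(self.colored("red", "red"), self.sets)
        assert out["A"]["a1"].color == "red"
        assert out["A"]["a1"].source == "homology-extension"

    def test_conflicting_donors_leave_uncolored(self):
        out = extend_by_homology(self.colored("red", "green"), self.sets)
        assert out["A"]["a1"].color is None

    def test_single_donor_insufficient(self):
        out = extend_by_homology(self.colored("red", None), self.sets)
        assert out["A"]["a1"].color is None

    def test_extension_never_removes_color(self):
        colored = self.colored("red", "red")
        before = {
            g: sum(1 for cg in m.values() if cg.color) for g, m in colored.items()
        }
        out = extend_by_homology(colored, self.sets)
        for g, m in out.items():
            after = sum(1 for cg in m.values() if cg.color)
            assert after >= before[g]


class TestBlockStats:
    def test_single_block_same_color_different_region(self):
        order = make_order(
            "A", {"chr1": [("g1", "+"), ("g2", "+"), ("g3", "+"), ("g4", "+")]}
        )
        regions = [
            region("A", "chr1", 1, 2, "red", "dark"),
            region("A", "chr1", 3, 4, "red", "medium"),
        ]
        colored = assign_colors(order, regions)
        pairs = [OrthologPair("g1", "g3", None, "b1"), OrthologPair("g2", "g4", None, "b1")]
        stats = block_color_stats(pairs, colored)
        assert stats["pct_genes_coloured"] == 100.0
        assert stats["pct_blocks"]["one colour"] == 100.0
        assert stats["pct_pairs"]["same colour, different region"] == 100.0

    def test_no_colored_genes(self):
        order = make_order("A", {"chr1": [("g1", "+"), ("g2", "+")]})
        colored = assign_colors(order, [])
        stats = block_color_stats([OrthologPair("g1", "g2", None, "b1")], colored)
        assert stats["pct_genes_coloured"] == 0.0
        assert stats["pct_blocks"]["no colour"] == 100.0

    def test_toy_mixture_percentages(self):
        genes = [(f"g{i}", "+") for i in range(20)]
        order = make_order("A", {"chr1": genes})
        # 7 pairs fully inside two red regions, 2 with one coloured gene, 1 outside
        regions = [
            region("A", "chr1", 1, 7, "red", "dark"),
            region("A", "chr1", 8, 14, "red", "medium"),
        ]
        colored = assign_colors(order, regions)
        pairs = [OrthologPair(f"g{i}", f"g{i + 7}", None, f"b{i}") for i in range(7)]
        pairs += [
            OrthologPair("g0", "g15", None, "b7"),
            OrthologPair("g1", "g16", None, "b8"),
            OrthologPair("g17", "g18", None, "b9"),
        ]
        stats = block_color_stats(pairs, colored)
        assert stats["pct_pairs"]["same colour, different region"] == 70.0
        assert stats["pct_pairs"]["one gene coloured"] == 20.0
        assert stats["pct_pairs"]["neither coloured"] == 10.0


class TestFamilySizes:
    def test_component_of_three(self):
        pairs = [OrthologPair("a", "b", None, None), OrthologPair("b", "c", None, None)]
        table = family_size_table(pairs).set_index("size")["n_families"]
        assert table["3"] == 1 and table["2"] == 0

    def test_disjoint_pairs(self):
        pairs = [OrthologPair(f"a{i}", f"b{i}", None, None) for i in range(5)]
        table = family_size_table(pairs).set_index("size")["n_families"]
        assert table["2"] == 5

    def test_chain_of_four_is_large_family(self):
        pairs = [
            OrthologPair("a", "b", None, None),
            OrthologPair("b", "c", None, None),
            OrthologPair("c", "d", None, None),
        ]
        table = family_size_table(pairs).set_index("size")["n_families"]
        assert table[">=4"] == 1


class TestAnnotateAncestor:
    def inputs(self, flattened):
        sets = {
            "os1": OrthologySet("os1", {"A": "a1", "B": "b1"}),
            "os2": OrthologySet("os2", {"A": "a2", "B": "b2"}),
        }
        orders = {
            "A": make_order("A", {"chr1": [("a1", "+"), ("a2", "+")]}),
            "B": make_order("B", {"chr1": [("b1", "+"), ("b2", "+")]}),
        }
        colored = {
            g: assign_colors(orders[g], [region(g, "chr1", 1, 2, "red")])
            for g in orders
        }
        return flattened, sets, colored

    def test_intact_region_modal_share_one(self):
        flattened, sets, colored = self.inputs({1: [("os1", "+"), ("os2", "+")]})
        table = annotate_ancestor(flattened, sets, colored)
        row = table[table["color"] == "red"].iloc[0]
        assert row["modal_share"] == 1.0

    def test_split_region_half_share(self):
        flattened, sets, colored = self.inputs(
            {1: [("os1", "+")], 2: [("os2", "+")]}
        )
        table = annotate_ancestor(flattened, sets, colored)
        row = table[table["color"] == "red"].iloc[0]
        assert row["modal_share"] == 0.5

    def test_uncolored_reported_as_none(self):
        flattened = {1: [("os1", "+")]}
        sets = {"os1": OrthologySet("os1", {"A": "a1", "B": "b1"})}
        colored = {"A": {}, "B": {}}
        table = annotate_ancestor(flattened, sets, colored)
        assert table.iloc[0]["color"] == "none"


def test_similarity_histogram_bins():
    pairs = [OrthologPair("a", "b", 0.705, None), OrthologPair("c", "d", 0.708, None),
             OrthologPair("e", "f", 0.91, None), OrthologPair("g", "h", None, None)]
    hist = similarity_histogram(pairs)
    assert hist["count"].sum() == 3
    assert hist.loc[hist["bin_left"].round(2) == 0.70, "count"].iloc[0] == 2
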