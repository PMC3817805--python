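import pytest

from paleorder.assembly import (
    ContigProjection,
    SummaryGenome,
    decompose_pieces,
    flatten,
    merge_contigs,
    number_chromosomes,
    project_contigs,
    second_mwm,
)
from paleorder.types import AncestralGenome, Contig, OrthologySet, PipelineConfig
from conftest import make_order


def contig(cid, markers):
    return Contig(cid, markers)


class TestProjection:
    def make_inputs(self, chrom_layout):
        """One contig of three markers; layout gives genome A's chromosomes."""
        sets = {
            f"os{i}": OrthologySet(f"os{i}", {"A": f"a{i}", "B": f"b{i}"})
            for i in range(4)
        }
        c = contig("c1", [("os0", "+"), ("os1", "+"), ("os2", "+")])
        orders = {
            "A": make_order("A", chrom_layout),
            "B": make_order("B", {"c1": [(f"b{i}", "+") for i in range(4)]}),
        }
        return [c], sets, orders

    def test_mean_coordinate(self):
        layout = {"chr3": [("x0", "+"), ("a0", "+"), ("a1", "+"), ("a2", "+")]}
        contigs, sets, orders = self.make_inputs(layout)
        summaries = project_contigs(contigs, sets, orders)
        proj = summaries["A"].projections["c1"]
        assert proj.chromosome == "chr3"
        assert proj.coordinate == pytest.approx(2.0)

    def test_plurality_chromosome_wins(self):
        layout = {
            "chr1": [("a0", "+"), ("a1", "+")],
            "chr2": [("a2", "+")],
        }
        contigs, sets, orders = self.make_inputs(layout)
        summaries = project_contigs(contigs, sets, orders)
        assert summaries["A"].projections["c1"].chromosome == "chr1"

    def test_majority_orientation_tie_is_plus(self):
        layout = {"chr1": [("a0", "+"), ("a1", "+"), ("a2", "-")]}
        contigs, sets, orders = self.make_inputs(layout)
        summaries = project_contigs(contigs, sets, orders)
        assert summaries["A"].projections["c1"].orientation == "+"

    def test_absent_contig_omitted_from_summary(self):
        sets = {"os0": OrthologySet("os0", {"A": "a0", "B": "b0"}),
                "os1": OrthologySet("os1", {"B": "b1", "C": "c1"})}
        contigs = [contig("c1", [("os0", "+")]), contig("c2", [("os1", "+")])]
        orders = {
            "A": make_order("A", {"chr1": [("a0", "+")]}),
            "B": make_order("B", {"chr1": [("b0", "+"), ("b1", "+")]}),
            "C": make_order("C", {"chr1": [("c1", "+")]}),
        }
        summaries = project_contigs(contigs, sets, orders)
        assert "c2" not in summaries["A"].projections
        assert set(summaries["B"].projections) == {"c1", "c2"}


def make_summary(genome_id, layout):
    """layout: chrom -> [(contig_id, orientation, lo, hi)] in order."""
    summary = SummaryGenome(genome_id=genome_id)
    for chrom, entries in layout.items():
        summary.chromosomes[chrom] = [(cid, o) for cid, o, _, _ in entries]
        for pos, (cid, orient, lo, hi) in enumerate(entries):
            summary.projections[cid] = ContigProjection(
                contig_id=cid,
                genome_id=genome_id,
                chromosome=chrom,
                coordinate=(lo + hi) / 2,
                orientation=orient,
                lo=lo,
                hi=hi,
                n_genes=hi - lo + 1,
            )
    return summary


class TestSecondMWM:
    def test_contigs_joined_when_adjacent_in_all_three(self):
        layout = {"chr1": [("c1", "+", 0, 9), ("c2", "+", 10, 19)]}
        summaries = {g: make_summary(g, layout) for g in ("A", "B", "C")}
        kept, new_contigs = second_mwm(summaries, PipelineConfig())
        assert len(new_contigs) == 1
        assert [c for c, _ in new_contigs[0].markers] == ["c1", "c2"]
        assert list(kept.values()) == [3.00]

    def test_single_genome_support_discarded(self):
        joined = {"chr1": [("c1", "+", 0, 9), ("c2", "+", 10, 19)]}
        apart = {
            "chr1": [("c1", "+", 0, 9)],
            "chr2": [("c2", "+", 0, 9)],
        }
        summaries = {
            "A": make_summary("A", joined),
            "B": make_summary("B", apart),
            "C": make_summary("C", apart),
        }
        kept, new_contigs = second_mwm(summaries, PipelineConfig())
        assert kept == {}
        assert len(new_contigs) == 2

    def test_no_adjacencies_preserves_contigs(self):
        layout = {
            "chr1": [("c1", "+", 0, 9)],
            "chr2": [("c2", "+", 0, 9)],
        }
        summaries = {g: make_summary(g, layout) for g in ("A", "B", "C")}
        kept, new_contigs = second_mwm(summaries, PipelineConfig())
        assert kept == {}
        assert sorted(c.markers[0][0] for c in new_contigs) == ["c1", "c2"]


class TestDecompose:
    def test_fully_contiguous_is_one_piece(self):
        layout = {"chr1": [("c1", "+", 0, 9), ("c2", "+", 10, 19), ("c3", "+", 20, 29)]}
        summaries = {g: make_summary(g, layout) for g in ("A", "B")}
        structure = [("c1", "+"), ("c2", "+"), ("c3", "+")]
        assert decompose_pieces(structure, summaries, "A", "B") == [structure]

    def test_break_where_one_genome_disagrees(self):
        layout_a = {"chr1": [("c1", "+", 0, 9), ("c2", "+", 10, 19), ("c3", "+", 20, 29)]}
        layout_b = {
            "chr1": [("c1", "+", 0, 9), ("c2", "+", 10, 19), ("x", "+", 20, 29),
                     ("c3", "+", 30, 39)]
        }
        summaries = {"A": make_summary("A", layout_a), "B": make_summary("B", layout_b)}
        structure = [("c1", "+"), ("c2", "+"), ("c3", "+")]
        pieces = decompose_pieces(structure, summaries, "A", "B")
        assert pieces == [[("c1", "+"), ("c2", "+")], [("c3", "+")]]

    def test_single_contig_single_piece(self):
        layout = {"chr1": [("c1", "+", 0, 9)]}
        summaries = {g: make_summary(g, layout) for g in ("A", "B")}
        assert decompose_pieces([("c1", "+")], summaries, "A", "B") == [[("c1", "+")]]

    def test_jointly_reversed_run_counts(self):
        layout_a = {"chr1": [("c1", "+", 0, 9), ("c2", "+", 10, 19)]}
        layout_b = {"chr1": [("c2", "-", 0, 9), ("c1", "-", 10, 19)]}
        summaries = {"A": make_summary("A", layout_a), "B": make_summary("B", layout_b)}
        structure = [("c1", "+"), ("c2", "+")]
        assert decompose_pieces(structure, summaries, "A", "B") == [structure]


class TestMerge:
    def two_contig_instance(self, gap_a, gap_b):
        layout_a = {"chr1": [("c1", "+", 0, 9), ("c2", "+", 10 + gap_a, 19 + gap_a)]}
        layout_b = {"chr1": [("c1", "+", 0, 9), ("c2", "+", 10 + gap_b, 19 + gap_b)]}
        summaries = {
            "A": make_summary("A", layout_a),
            "B": make_summary("B", layout_b),
            "C": make_summary("C", {}),
        }
        new_contigs = [contig("nc1", [("c1", "+")]), contig("nc2", [("c2", "+")])]
        return new_contigs, summaries

    def test_close_pair_merged(self):
        new_contigs, summaries = self.two_contig_instance(10, 10)
        ancestor, log = merge_contigs(new_contigs, summaries, 500)
        assert ancestor.n_chromosomes() == 1
        assert len(log) == 1 and log[0]["distance"] == 10

    def test_far_on_one_genome_not_merged(self):
        new_contigs, summaries = self.two_contig_instance(10, 600)
        ancestor, log = merge_contigs(new_contigs, summaries, 500)
        assert ancestor.n_chromosomes() == 2
        assert log == []

    def test_chain_merges_in_ascending_distance_order(self):
        layout = {
            "chr1": [
                ("c1", "+", 0, 9),
                ("c2", "+", 15, 24),
                ("c3", "+", 40, 49),
            ]
        }
        summaries = {
            "A": make_summary("A", layout),
            "B": make_summary("B", layout),
            "C": make_summary("C", {}),
        }
        new_contigs = [
            contig("nc1", [("c1", "+")]),
            contig("nc2", [("c2", "+")]),
            contig("nc3", [("c3", "+")]),
        ]
        ancestor, log = merge_contigs(new_contigs, summaries, 500)
        assert ancestor.n_chromosomes() == 1
        assert [entry["distance"] for entry in log] == [5, 15]
        assert [c for c, _ in ancestor.chromosomes[0]] == ["c1", "c2", "c3"]


class TestFlatten:
    def contigs_by_id(self):
        return {
            "c1": contig("c1", [("a", "+"), ("b", "+"), ("c", "+")]),
            "c2": contig("c2", [("d", "+"), ("e", "-")]),
        }

    def test_reversed_contig_flips(self):
        ancestor = AncestralGenome([[("c1", "-")]])
        flat = flatten(ancestor, self.contigs_by_id())
        assert flat[1] == [("c", "-"), ("b", "-"), ("a", "-")]

    def test_marker_conservation(self):
        ancestor = AncestralGenome([[("c1", "+"), ("c2", "-")]])
        flat = flatten(ancestor, self.contigs_by_id())
        assert sorted(m for m, _ in flat[1]) == ["a", "b", "c", "d", "e"]

    def test_empty(self):
        assert flatten(AncestralGenome([]), {}) == {}

    def test_numbering_by_descending_size(self):
        ancestor = AncestralGenome([[("c2", "+")], [("c1", "+")]])
        numbered = number_chromosomes(ancestor, self.contigs_by_id())
        assert numbered.chromosomes[0][0][0] == "c1"  # 3 markers > 2 markers
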