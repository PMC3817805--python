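import numpy as np
import pytest

from paleorder.adjacency import (
    ADJACENT,
    MISSING,
    PRESENT,
    AdjacencyCandidate,
    brute_force_matching_weight,
    build_indexes,
    drop_short_contigs,
    enumerate_adjacencies,
    extract_contigs,
    filter_low_support,
    max_weight_matching,
    restrict_orders,
    weight_adjacency,
)
from paleorder.datasets import (
    focal_pair,
    random_matching_instance,
    weight_pattern_microgenomes,
)
from paleorder.orthology import resolve_orthology_sets, transitive_closure
from paleorder.types import DEFAULT_WEIGHT_TABLE, OrthologySet, end_pair
from conftest import make_order

FOCAL = end_pair(*focal_pair())


def weighted(orders):
    idx = build_indexes(orders)
    return {
        c.ends: weight_adjacency(c, idx, DEFAULT_WEIGHT_TABLE)
        for c in enumerate_adjacencies(orders)
    }


class TestRestrictOrders:
    def setup_method(self):
        self.sets = [
            OrthologySet("os1", {"A": "g1", "B": "h1"}),
            OrthologySet("os2", {"A": "g2", "B": "h2"}),
        ]

    def test_unmatched_genes_removed(self):
        orders = {"A": make_order("A", {"c1": [("g1", "+"), ("x", "+"), ("g2", "-")]})}
        restricted = restrict_orders(orders, self.sets)
        assert restricted["A"]["c1"] == [("os1", "+"), ("os2", "-")]

    def test_all_matched_identity(self):
        orders = {"A": make_order("A", {"c1": [("g1", "+"), ("g2", "-")]})}
        assert restrict_orders(orders, self.sets)["A"]["c1"] == [
            ("os1", "+"),
            ("os2", "-"),
        ]

    def test_empty_chromosome_dropped(self):
        orders = {"A": make_order("A", {"c1": [("x", "+")], "c2": [("g1", "+")]})}
        restricted = restrict_orders(orders, self.sets)
        assert list(restricted["A"]) == ["c2"]


class TestEnumerate:
    def test_same_adjacency_in_all_three(self):
        ab = [("a", "+"), ("b", "+")]
        orders = {g: {"c1": ab} for g in ("G1", "G2", "G3")}
        cands = enumerate_adjacencies(orders)
        assert len(cands) == 1
        assert cands[0].ends == end_pair(("a", "h"), ("b", "t"))
        assert all(v == ADJACENT for v in cands[0].occurrence.values())

    def test_orientation_gives_distinct_candidates(self):
        orders = {
            "G1": {"c1": [("a", "+"), ("b", "+")]},
            "G2": {"c1": [("a", "+"), ("b", "-")]},
            "G3": {"c1": [("a", "+")]},
        }
        pairs = {c.ends for c in enumerate_adjacencies(orders)}
        assert end_pair(("a", "h"), ("b", "t")) in pairs
        assert end_pair(("a", "h"), ("b", "h")) in pairs
        assert len(pairs) == 2

    def test_missing_endpoint_status(self):
        orders = {
            "G1": {"c1": [("a", "+"), ("b", "+")]},
            "G2": {"c1": [("a", "+"), ("b", "+")]},
            "G3": {"c1": [("a", "+")]},
        }
        (cand,) = enumerate_adjacencies(orders)
        assert cand.occurrence == {"G1": ADJACENT, "G2": ADJACENT, "G3": MISSING}


class TestWeightTable:
    @pytest.mark.parametrize("cls", sorted(DEFAULT_WEIGHT_TABLE))
    def test_pattern_maps_to_exact_weight(self, cls):
        orders = weight_pattern_microgenomes()[cls]
        cand = weighted(orders)[FOCAL]
        assert cand.weight_class == cls
        assert cand.weight == DEFAULT_WEIGHT_TABLE[cls]

    def test_inversion_context_flagged(self):
        cand = weighted(weight_pattern_microgenomes()["inv_full"])[FOCAL]
        assert cand.inversion_context

    def test_overlapping_single_genome_pattern_flagged(self):
        cand = weighted(weight_pattern_microgenomes()["adj1_absent2"])[FOCAL]
        assert cand.ambiguous_pattern

    def test_unreachable_pattern_rejected(self):
        cand = AdjacencyCandidate(
            FOCAL, {"G1": PRESENT, "G2": PRESENT, "G3": PRESENT}
        )
        with pytest.raises(ValueError, match="outside the weight table"):
            weight_adjacency(cand, {}, DEFAULT_WEIGHT_TABLE)


class TestMatching:
    def test_empty(self):
        assert max_weight_matching([]) == {}

    def test_heavy_edge_beats_two_light(self):
        # star of three candidates sharing one end: only the best survives
        cands = [
            AdjacencyCandidate(end_pair(("a", "h"), ("b", "t")), {}, weight=3.00),
            AdjacencyCandidate(end_pair(("a", "h"), ("c", "t")), {}, weight=2.00),
            AdjacencyCandidate(end_pair(("a", "h"), ("d", "t")), {}, weight=2.00),
        ]
        matching = max_weight_matching(cands)
        assert list(matching) == [end_pair(("a", "h"), ("b", "t"))]

    def test_four_cycle_takes_heavy_pair(self):
        ends = [("a", "h"), ("b", "t"), ("b", "h"), ("a", "t")]
        weights = [3.00, 2.00, 3.00, 2.00]
        cands = [
            AdjacencyCandidate(end_pair(ends[i], ends[(i + 1) % 4]), {}, weight=w)
            for i, w in enumerate(weights)
        ]
        matching = max_weight_matching(cands)
        assert sum(matching.values()) == pytest.approx(6.00)

    @pytest.mark.parametrize("trial", range(50))
    def test_equals_brute_force_on_random_instances(self, trial):
        rng = np.random.default_rng(2000 + trial)
        cands = random_matching_instance(rng)
        matching = max_weight_matching(cands)
        assert sum(matching.values()) == pytest.approx(
            brute_force_matching_weight(cands)
        )


class TestFilters:
    def test_low_support_dropped(self):
        matching = {
            end_pair(("a", "h"), ("b", "t")): 3.00,
            end_pair(("b", "h"), ("c", "t")): 2.03,
            end_pair(("c", "h"), ("d", "t")): 1.00,
        }
        kept = filter_low_support(matching, 1.49)
        assert sorted(kept.values()) == [2.03, 3.00]

    def test_all_strong_unchanged(self):
        matching = {end_pair(("a", "h"), ("b", "t")): 2.00}
        assert filter_low_support(matching, 1.49) == matching

    def test_zero_threshold_noop(self):
        matching = {end_pair(("a", "h"), ("b", "t")): 0.99}
        assert filter_low_support(matching, 0.0) == matching


class TestContigs:
    def chain(self, markers):
        return {
            end_pair((markers[i], "h"), (markers[i + 1], "t")): 3.00
            for i in range(len(markers) - 1)
        }

    def test_chain_of_five(self):
        markers = ["m1", "m2", "m3", "m4", "m5"]
        contigs = extract_contigs(markers, self.chain(markers))
        assert len(contigs) == 1
        assert contigs[0].markers == [(m, "+") for m in markers]
        assert contigs[0].n_adjacencies == 4

    def test_cycle_broken_at_min_weight(self):
        markers = ["m1", "m2", "m3", "m4", "m5"]
        matching = self.chain(markers)
        matching[end_pair(("m5", "h"), ("m1", "t"))] = 2.00
        contigs = extract_contigs(markers, matching)
        assert len(contigs) == 1
        assert len(contigs[0].markers) == 5
        assert contigs[0].n_adjacencies == 4
        assert 2.00 not in contigs[0].adjacencies.values()

    def test_no_adjacencies_all_singletons(self):
        contigs = extract_contigs(["m1", "m2", "m3"], {})
        assert len(contigs) == 3
        assert all(c.n_adjacencies == 0 for c in contigs)

    def test_count_identity(self):
        markers = [f"m{i}" for i in range(10)]
        matching = self.chain(markers[:4])
        matching.update(self.chain(markers[6:9]))
        contigs = extract_contigs(markers, matching)
        assert len(contigs) == len(markers) - len(matching)

    def test_canonical_orientation_lowest_marker_forward(self):
        matching = {end_pair(("m2", "h"), ("m1", "h")): 3.00}
        (contig,) = extract_contigs(["m1", "m2"], matching)
        strands = dict(contig.markers)
        assert strands[min(strands)] == "+"


class TestDropShort:
    def make(self, n):
        markers = [f"m{i}" for i in range(n)]
        matching = {
            end_pair((markers[i], "h"), (markers[i + 1], "t")): 3.0
            for i in range(n - 1)
        }
        return extract_contigs(markers, matching)[0]

    def test_three_adjacencies_dropped(self):
        assert drop_short_contigs([self.make(4)], 4) == []

    def test_four_adjacencies_kept(self):
        contigs = [self.make(5)]
        assert drop_short_contigs(contigs, 4) == contigs

    def test_zero_threshold_keeps_all(self):
        contigs = [self.make(1), self.make(2)]
        assert drop_short_contigs(contigs, 0) == contigs


class TestConsistentTripleAdjacencies:
    """An adjacency seen in all three genomes with unconflicted ends must be
    matched."""

    def test_on_simulated_data(self, moderate_dataset):
        from paleorder.pipeline import reconstruct

        result = reconstruct(moderate_dataset.genome_orders, moderate_dataset.ortholog_pairs)
        end_use = {}
        for c in result.candidates:
            for e in c.ends:
                end_use[e] = end_use.get(e, 0) + 1
        for c in result.candidates:
            if c.weight == 3.00 and all(end_use[e] == 1 for e in c.ends):
                assert c.ends in result.matching
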