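"""Candidate adjacency enumeration, support weighting, and maximum weight
matching (level 1 of the reconstruction).

A genome restricted to the marker universe is a set of oriented marker
sequences.  For consecutive markers *a* then *b*, the adjacency joins *a*'s
trailing end to *b*'s leading end, so each adjacency is an unordered pair of
marker ends and orientation is carried implicitly.  Every end pair adjacent
in at least one genome becomes a candidate, weighted by its occurrence
pattern across the three genomes; an exact maximum weight matching over the
candidates then selects the ancestral adjacencies, from which maximal paths
of markers (contigs) are read off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .types import (
    Contig,
    End,
    EndPair,
    GenomeOrder,
    OrthologySet,
    PipelineConfig,
    end_pair,
    flip_strand,
    leading_end,
    other_end,
    trailing_end,
)

logger = logging.getLogger("paleorder")

ADJACENT = "adjacent"
PRESENT = "present"  # both endpoints present but not adjacent
MISSING = "missing"  # an endpoint's marker absent from the genome

#: Oriented marker orders per genome: genome -> chromosome -> [(marker, strand)].
Orders = Mapping[str, Mapping[str, Sequence[tuple[str, str]]]]


def restrict_orders(
    genome_orders: Mapping[str, GenomeOrder], sets: Sequence[OrthologySet]
) -> dict[str, dict[str, list[tuple[str, str]]]]:
    """Drop genes outside the marker universe; relabel survivors by set id.

    Orientation is inherited from the gene's strand.  Chromosomes left empty
    are dropped.
    """
    gene_to_set: dict[str, str] = {}
    for s in sets:
        for gene in s.members.values():
            gene_to_set[gene] = s.set_id
    restricted: dict[str, dict[str, list[tuple[str, str]]]] = {}
    for genome_id in sorted(genome_orders):
        order = genome_orders[genome_id]
        chroms: dict[str, list[tuple[str, str]]] = {}
        for chrom in order.chromosomes:
            seq = [
                (gene_to_set[g], s)
                for g, s in order.oriented(chrom)
                if g in gene_to_set
            ]
            if seq:
                chroms[chrom] = seq
        restricted[genome_id] = chroms
    return restricted


class GenomeAdjacencyIndex:
    """Per-genome adjacency partner map and marker presence set."""

    def __init__(self, chromosomes: Mapping[str, Sequence[tuple[str, str]]]):
        self.partner: dict[End, End] = {}
        self.markers: set[str] = set()
        for seq in chromosomes.values():
            for marker, _ in seq:
                self.markers.add(marker)
            for (a, sa), (b, sb) in zip(seq, seq[1:]):
                ea, eb = trailing_end(a, sa), leading_end(b, sb)
                self.partner[ea] = eb
                self.partner[eb] = ea

    def has_adjacency(self, pair: EndPair) -> bool:
        return self.partner.get(pair[0]) == pair[1]

    def status(self, pair: EndPair) -> str:
        if self.has_adjacency(pair):
            return ADJACENT
        if pair[0][0] in self.markers and pair[1][0] in self.markers:
            return PRESENT
        return MISSING


@dataclass
class AdjacencyCandidate:
    """A candidate ancestral adjacency with its cross-genome support."""

    ends: EndPair
    occurrence: dict[str, str]  # genome -> ADJACENT | PRESENT | MISSING
    weight: float = 0.0
    weight_class: str = ""
    inversion_context: bool = False
    ambiguous_pattern: bool = False  # overlapping single-genome weight rows


def build_indexes(orders: Orders) -> dict[str, GenomeAdjacencyIndex]:
    return {g: GenomeAdjacencyIndex(orders[g]) for g in sorted(orders)}


def enumerate_adjacencies(orders: Orders) -> list[AdjacencyCandidate]:
    """One candidate per end pair immediately adjacent in >= 1 genome."""
    indexes = build_indexes(orders)
    pairs: set[EndPair] = set()
    for idx in indexes.values():
        for a, b in idx.partner.items():
            pairs.add(end_pair(a, b))
    candidates = []
    for pair in sorted(pairs):
        occurrence = {g: indexes[g].status(pair) for g in indexes}
        candidates.append(AdjacencyCandidate(pair, occurrence))
    return candidates


def _inversion_class(
    pair: EndPair,
    occurrence: Mapping[str, str],
    indexes: Mapping[str, GenomeAdjacencyIndex],
) -> str | None:
    """Detect the inversion-disruption context for a single-genome adjacency.

    The adjacency *xy* together with some *uv* in its supporting genome, and
    *xu* plus *yv* in another genome, is the two-breakpoint signature of an
    inversion; the weight then depends on what the third genome retains:
    *uv* without both *x* and *y* -> 'inv_partial' (1.50); *uv* plus both
    *x* and *y* -> 'inv_full' (1.49).
    """
    x, y = pair
    (g1,) = [g for g, st in occurrence.items() if st == ADJACENT]
    others = sorted(g for g in occurrence if g != g1)
    for g2 in others:
        idx2 = indexes[g2]
        u = idx2.partner.get(x)
        v = idx2.partner.get(y)
        if u is None or v is None:
            continue
        if u[0] in (x[0], y[0]) or v[0] in (x[0], y[0]) or u[0] == v[0]:
            continue
        if not indexes[g1].has_adjacency(end_pair(u, v)):
            continue
        (g3,) = [g for g in others if g != g2]
        idx3 = indexes[g3]
        if not idx3.has_adjacency(end_pair(u, v)):
            continue
        both_xy_in_third = x[0] in idx3.markers and y[0] in idx3.markers
        return "inv_full" if both_xy_in_third else "inv_partial"
    return None


def weight_adjacency(
    candidate: AdjacencyCandidate,
    indexes: Mapping[str, GenomeAdjacencyIndex],
    weight_table: Mapping[str, float],
) -> AdjacencyCandidate:
    """Assign the support weight from the candidate's occurrence pattern."""
    occ = candidate.occurrence
    n_adj = sum(1 for st in occ.values() if st == ADJACENT)
    if n_adj == 3:
        cls = "adj3"
    elif n_adj == 2:
        (third,) = [st for st in occ.values() if st != ADJACENT]
        cls = "adj2_missing" if third == MISSING else "adj2_present"
    elif n_adj == 1:
        cls = _inversion_class(candidate.ends, occ, indexes)
        if cls is not None:
            candidate.inversion_context = True
        else:
            k = sum(1 for st in occ.values() if st == PRESENT)
            cls = {2: "adj1_present2", 1: "adj1_mixed", 0: "adj1_absent2"}[k]
            # "absent in each" (1.01) vs "present in neither" (1.00) name the
            # same pattern in the published table; we take the 1.01 row and flag.
            candidate.ambiguous_pattern = k == 0
    else:
        raise ValueError(
            f"occurrence pattern {occ} for {candidate.ends}: adjacency seen in "
            "no genome is outside the weight table"
        )
    if cls not in weight_table:
        raise ValueError(f"weight table has no entry for pattern {cls!r}")
    candidate.weight_class = cls
    candidate.weight = weight_table[cls]
    return candidate


def weighted_candidates(
    orders: Orders, weight_table: Mapping[str, float]
) -> list[AdjacencyCandidate]:
    indexes = build_indexes(orders)
    return [
        weight_adjacency(c, indexes, weight_table)
        for c in enumerate_adjacencies(orders)
    ]


def max_weight_matching(
    candidates: Sequence[AdjacencyCandidate],
) -> dict[EndPair, float]:
    """Exact maximum weight matching over candidate end pairs.

    Solved per connected component with the blossom algorithm; weights are
    scaled to integers (they are multiples of 0.01) so optimality is not at
    the mercy of float comparisons.
    """
    g = nx.Graph()
    for cand in sorted(candidates, key=lambda c: c.ends):
        g.add_edge(cand.ends[0], cand.ends[1], weight=round(cand.weight * 100))
    matching: dict[EndPair, float] = {}
    for component in nx.connected_components(g):
        sub = g.subgraph(sorted(component))
        for a, b in nx.max_weight_matching(sub, maxcardinality=False):
            pair = end_pair(a, b)
            matching[pair] = g.edges[pair]["weight"] / 100.0
    return dict(sorted(matching.items()))


def brute_force_matching_weight(candidates: Sequence[AdjacencyCandidate]) -> float:
    """Independent oracle: optimal matching weight by exhaustive enumeration.

    Exponential in the number of candidates; callers keep instances tiny
    (≤ 12 ends).
    """
    edges = [(c.ends, c.weight) for c in candidates]

    def rec(i: int, used: frozenset[End]) -> float:
        if i == len(edges):
            return 0.0
        (a, b), w = edges[i]
        best = rec(i + 1, used)
        if a not in used and b not in used:
            best = max(best, w + rec(i + 1, used | {a, b}))
        return best

    return rec(0, frozenset())


def filter_low_support(
    matching: Mapping[EndPair, float], min_kept_weight: float
) -> dict[EndPair, float]:
    """Discard matched adjacencies with weight below the support threshold.

    At the default threshold of 1.49 the single-genome classes
    (0.99/1.00/1.01) drop while the inversion classes and everything with
    two- or three-genome support survive.
    """
    return {
        pair: w for pair, w in matching.items() if w >= min_kept_weight
    }


def extract_contigs(
    marker_ids: Iterable[str],
    matching: Mapping[EndPair, float],
    prefix: str = "c",
) -> list[Contig]:
    """Read maximal marker paths off the adjacency matching.

    Alternates marker (tail–head) edges with matched adjacency edges.  Any
    cycle is broken at its minimum-weight adjacency (ties: lexicographically
    smallest end pair).  Each contig is reported in canonical orientation:
    its lexicographically smallest marker carries strand '+'.
    """
    partner: dict[End, tuple[End, float]] = {}
    for (a, b), w in matching.items():
        partner[a] = (b, w)
        partner[b] = (a, w)

    marker_ids = sorted(set(marker_ids))
    visited: set[str] = set()
    raw_paths: list[list[tuple[str, str]]] = []

    def walk(start_end: End) -> list[tuple[str, str]]:
        """Follow marker and adjacency edges from a free end."""
        path: list[tuple[str, str]] = []
        endp: End | None = start_end
        while endp is not None:
            marker, side = endp
            visited.add(marker)
            path.append((marker, "+" if side == "t" else "-"))
            nxt = partner.get(other_end(endp))
            endp = None
            if nxt is not None and nxt[0][0] not in visited:
                endp = nxt[0]
        return path

    # paths: start from every free end (marker end with no matched partner)
    for marker in marker_ids:
        if marker in visited:
            continue
        for side in ("t", "h"):
            if (marker, side) not in partner:
                raw_paths.append(walk((marker, side)))
                break
    # cycles: whatever is left; break at the minimum-weight adjacency
    for marker in marker_ids:
        if marker in visited:
            continue
        cycle_pairs: list[tuple[EndPair, float]] = []
        endp: End = (marker, "t")
        seen_here: set[str] = set()
        while endp[0] not in seen_here:
            seen_here.add(endp[0])
            nxt, w = partner[other_end(endp)]
            cycle_pairs.append((end_pair(other_end(endp), nxt), w))
            endp = nxt
        break_pair, break_weight = min(cycle_pairs, key=lambda pw: (pw[1], pw[0]))
        logger.info(
            "breaking cycle at adjacency %s (weight %.2f)", break_pair, break_weight
        )
        for e in break_pair:
            partner.pop(e, None)
        raw_paths.append(walk(break_pair[0]))

    contigs: list[Contig] = []
    for path in raw_paths:
        low = min(m for m, _ in path)
        low_strand = dict(path)[low]
        if low_strand == "-":
            path = [(m, flip_strand(s)) for m, s in reversed(path)]
        adjacencies: dict[EndPair, float] = {}
        for (a, sa), (b, sb) in zip(path, path[1:]):
            pair = end_pair(trailing_end(a, sa), leading_end(b, sb))
            adjacencies[pair] = matching[pair]
        contigs.append(Contig("", list(path), adjacencies))
    contigs.sort(key=lambda c: c.markers[0][0])
    width = max(5, len(str(len(contigs))))
    for i, c in enumerate(contigs):
        c.contig_id = f"{prefix}{i:0{width}d}"
    return contigs


def drop_short_contigs(
    contigs: Sequence[Contig], min_contig_adjacencies: int
) -> list[Contig]:
    """Remove contigs with fewer than the required number of adjacencies.

    The default (4) keeps only contigs with more than three adjacencies,
    filtering out isolated genes and tiny fragments that carry noise rather
    than signal.
    """
    kept = [c for c in contigs if c.n_adjacencies >= min_contig_adjacencies]
    n_dropped = len(contigs) - len(kept)
    if n_dropped:
        n_genes = sum(
            len(c.markers) for c in contigs if c.n_adjacencies < min_contig_adjacencies
        )
        logger.info(
            "dropped %d short contigs carrying %d markers", n_dropped, n_genes
        )
    return kept
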