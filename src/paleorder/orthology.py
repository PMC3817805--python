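"""Harmonising pairwise ortholog calls into orthology sets.

Two steps: (1) impose transitivity on the pairwise calls — if *a* is
orthologous to *b* and *b* to *c*, then *a* is taken as orthologous to *c* —
which turns every connected component of the homology graph into a clique
(same-genome edges excluded); (2) resolve residual paralogy by partitioning
each component into sets of two or three genes with pairwise-distinct
genomes, maximising the sum of squared set sizes (9 per triple, 4 per pair).
Leftover singletons are discarded from the marker universe and logged.

Because closure makes components cliques, the optimal objective depends only
on the per-genome member counts of a component, so the partition is solved
exactly for every component size by enumerating the number of triples; gene
assignment within the counts is lexicographic for determinism.
"""

from __future__ import annotations

import logging
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io import OrthologPair
from .types import GenomeOrder, OrthologySet

logger = logging.getLogger("paleorder")


def transitive_closure(
    pairs: Iterable[OrthologPair | tuple[str, str]],
    genome_of: Mapping[str, str],
) -> nx.Graph:
    """Build the homology graph and close it transitively.

    ``genome_of`` maps gene id -> genome id (typically derived from the gene
    orders); pairs naming unknown genes are dropped with a warning.  The
    result has a ``genome`` attribute per node and all cross-genome edges of
    every connected component (components become cliques minus same-genome
    edges).
    """
    g = nx.Graph()
    n_unknown = 0
    for pair in pairs:
        a, b = pair[0], pair[1]
        if a not in genome_of or b not in genome_of:
            n_unknown += 1
            continue
        if genome_of[a] == genome_of[b] and a != b:
            # within-genome homology (paralogy) is not an orthology edge
            g.add_node(a, genome=genome_of[a])
            g.add_node(b, genome=genome_of[b])
            continue
        g.add_node(a, genome=genome_of[a])
        g.add_node(b, genome=genome_of[b])
        g.add_edge(a, b)
    if n_unknown:
        logger.warning(
            "dropped %d ortholog pairs referencing genes absent from the gene orders",
            n_unknown,
        )
    closed = nx.Graph()
    closed.add_nodes_from(g.nodes(data=True))
    for component in nx.connected_components(g):
        for a, b in combinations(sorted(component), 2):
            if genome_of[a] != genome_of[b]:
                closed.add_edge(a, b)
    return closed


def _best_partition_counts(counts: Sequence[int]) -> tuple[int, list[tuple[int, int]]]:
    """Optimal number of triples and cross-genome pair pattern for a clique.

    ``counts`` are the per-genome member counts (length 3, zeros allowed).
    Returns ``(n_triples, pair_plan)`` where ``pair_plan`` lists genome-index
    pairs, maximising ``9 * n_triples + 4 * n_pairs``.
    """
    best_obj = -1
    best: tuple[int, list[tuple[int, int]]] = (0, [])
    for t in range(min(counts) + 1):
        rem = [c - t for c in counts]
        plan: list[tuple[int, int]] = []
        rem_idx = list(range(len(rem)))
        work = list(rem)
        while True:
            order = sorted(rem_idx, key=lambda i: (-work[i], i))
            i, j = order[0], order[1]
            if work[i] == 0 or work[j] == 0:
                break
            plan.append((i, j))
            work[i] -= 1
            work[j] -= 1
        obj = 9 * t + 4 * len(plan)
        if obj > best_obj:
            best_obj = obj
            best = (t, plan)
    return best


def _drop_tandem_duplicates(
    members: dict[str, list[str]], orders: Mapping[str, GenomeOrder] | None
) -> list[str]:
    """Within one component, drop the later copy of adjacent same-genome pairs.

    Tandem duplicates (same genome, consecutive order_index on one
    chromosome, sharing orthologs by virtue of being in one component) keep
    only the copy with the smaller order_index.
    """
    dropped: list[str] = []
    if orders is None:
        return dropped
    for genome, genes in members.items():
        if genome not in orders or len(genes) < 2:
            continue
        order = orders[genome]
        recs = sorted(
            (order.records[g] for g in genes if g in order),
            key=lambda r: (r.chromosome, r.order_index),
        )
        keep = []
        prev = None
        for rec in recs:
            if (
                prev is not None
                and rec.chromosome == prev.chromosome
                and rec.order_index == prev.order_index + 1
            ):
                dropped.append(rec.gene_id)
            else:
                keep.append(rec.gene_id)
                prev = rec
        members[genome] = sorted(keep)
    return dropped


def resolve_orthology_sets(
    graph: nx.Graph,
    orders: Mapping[str, GenomeOrder] | None = None,
) -> list[OrthologySet]:
    """Partition the closed homology graph into orthology sets.

    Each connected component is split into triples and pairs (distinct
    genomes within a set) maximising Σ(size²); singleton leftovers are
    discarded.  Set ids are assigned in lexicographic order of the smallest
    member gene.
    """
    proto_sets: list[dict[str, str]] = []
    n_singletons = 0
    n_tandem = 0
    for component in sorted(nx.connected_components(graph), key=min):
        members: dict[str, list[str]] = {}
        for gene in sorted(component):
            members.setdefault(graph.nodes[gene]["genome"], []).append(gene)
        n_tandem += len(_drop_tandem_duplicates(members, orders))
        genomes = sorted(members)
        counts = [len(members[g]) for g in genomes]
        while len(counts) < 3:
            counts.append(0)
        t, pair_plan = _best_partition_counts(counts)
        cursor = {g: 0 for g in genomes}
        for _ in range(t):
            proto = {}
            for g in genomes[:3]:
                proto[g] = members[g][cursor[g]]
                cursor[g] += 1
            proto_sets.append(proto)
        for i, j in pair_plan:
            gi, gj = genomes[i], genomes[j]
            proto = {
                gi: members[gi][cursor[gi]],
                gj: members[gj][cursor[gj]],
            }
            cursor[gi] += 1
            cursor[gj] += 1
            proto_sets.append(proto)
        n_singletons += sum(
            len(members[g]) - cursor[g] for g in genomes
        )
    if n_tandem:
        logger.info("dropped %d tandem duplicate genes", n_tandem)
    if n_singletons:
        logger.info(
            "discarded %d singleton genes left over from paralogy resolution",
            n_singletons,
        )
    proto_sets.sort(key=lambda m: min(m.values()))
    width = max(5, len(str(len(proto_sets))))
    return [
        OrthologySet(f"os{idx:0{width}d}", m) for idx, m in enumerate(proto_sets)
    ]


def partition_objective(sets: Iterable[OrthologySet]) -> int:
    """Σ(size²) of a collection of orthology sets."""
    return sum(len(s.members) ** 2 for s in sets)


def brute_force_best_objective(genes: Sequence[str], genome_of: Mapping[str, str]) -> int:
    """Exhaustive Σ(size²) optimum over partitions of a clique component.

    Independent oracle used in tests: enumerates all ways of packing the
    genes into genome-distinct sets of size ≤3.  Exponential; callers keep
    ``len(genes) <= 9``.
    """
    genes = sorted(genes)

    def rec(remaining: tuple[str, ...]) -> int:
        if not remaining:
            return 0
        first, rest = remaining[0], remaining[1:]
        best = rec(rest)  # first stays a singleton (counts 0)
        for i, b in enumerate(rest):
            if genome_of[b] == genome_of[first]:
                continue
            rest2 = rest[:i] + rest[i + 1:]
            best = max(best, 4 + rec(rest2))
            for j, c in enumerate(rest2):
                if genome_of[c] in (genome_of[first], genome_of[b]):
                    continue
                best = max(best, 9 + rec(rest2[:j] + rest2[j + 1:]))
        return best

    return rec(tuple(genes))
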