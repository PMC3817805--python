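"""End-to-end reconstruction driver chaining the seven pipeline steps."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import adjacency, assembly, orthology
from .io import OrthologPair
from .types import (
    AncestralGenome,
    Contig,
    EndPair,
    GenomeOrder,
    OrthologySet,
    PipelineConfig,
)

logger = logging.getLogger("paleorder")


@dataclass
class ReconstructionResult:
    """Everything the pipeline produced, step by step."""

    sets: list[OrthologySet]
    restricted: dict[str, dict[str, list[tuple[str, str]]]]
    candidates: list[adjacency.AdjacencyCandidate]
    matching: dict[EndPair, float]
    kept_matching: dict[EndPair, float]
    contigs_all: list[Contig]
    contigs: list[Contig]
    summaries: dict[str, assembly.SummaryGenome]
    second_matching: dict[EndPair, float]
    new_contigs: list[Contig]
    ancestor: AncestralGenome
    merge_log: list[dict]
    flattened: dict[int, list[tuple[str, str]]] = field(default_factory=dict)

    @property
    def sets_by_id(self) -> dict[str, OrthologySet]:
        return {s.set_id: s for s in self.sets}

    @property
    def contigs_by_id(self) -> dict[str, Contig]:
        return {c.contig_id: c for c in self.contigs}

    def adjacency_audit(self) -> pd.DataFrame:
        """Per-candidate audit: ends, occurrence, weight, kept flag."""
        kept = set(self.kept_matching)
        rows = []
        for c in self.candidates:
            row = {
                "end_a": f"{c.ends[0][0]}:{c.ends[0][1]}",
                "end_b": f"{c.ends[1][0]}:{c.ends[1][1]}",
                "weight": c.weight,
                "weight_class": c.weight_class,
                "inversion_context": c.inversion_context,
                "ambiguous_pattern": c.ambiguous_pattern,
                "matched": c.ends in self.matching,
                "kept": c.ends in kept,
            }
            for genome, status in sorted(c.occurrence.items()):
                row[f"occ_{genome}"] = status
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "reconstruction summary",
            "----------------------",
            f"orthology sets:          {len(self.sets)}",
            f"candidate adjacencies:   {len(self.candidates)}",
            f"matched adjacencies:     {len(self.matching)}",
            f"kept adjacencies:        {len(self.kept_matching)}",
            f"contigs (pre-filter):    {len(self.contigs_all)}",
            f"contigs (kept):          {len(self.contigs)}",
            f"new contigs (level 2):   {len(self.new_contigs)}",
            f"merges applied:          {len(self.merge_log)}",
            f"ancestral chromosomes:   {self.ancestor.n_chromosomes()}",
            f"markers in ancestor:     {sum(len(v) for v in self.flattened.values())}",
        ]
        return "\n".join(lines)


def reconstruct(
    genome_orders: Mapping[str, GenomeOrder],
    ortholog_pairs: Sequence[OrthologPair | tuple[str, str]],
    config: PipelineConfig | None = None,
) -> ReconstructionResult:
    """Run the full two-level reconstruction.

    Steps: transitive closure of the ortholog pairs; paralogy resolution into
    orthology sets; restriction of the gene orders; candidate enumeration and
    support weighting; exact maximum weight matching; removal of
    poorly-supported adjacencies and short contigs; projection into summary
    genomes; second matching at contig resolution; gap-bounded greedy merging
    into ancestral chromosomes.
    """
    if config is None:
        config = PipelineConfig()
    if len(genome_orders) != 3:
        raise ValueError(
            f"the reconstruction needs exactly three genomes, got {len(genome_orders)}"
        )
    genome_of = {
        rec.gene_id: genome_id
        for genome_id, order in genome_orders.items()
        for rec in order
    }
    graph = orthology.transitive_closure(ortholog_pairs, genome_of)
    sets = orthology.resolve_orthology_sets(graph, genome_orders)
    logger.info("resolved %d orthology sets", len(sets))

    restricted = adjacency.restrict_orders(genome_orders, sets)
    indexes = adjacency.build_indexes(restricted)
    candidates = [
        adjacency.weight_adjacency(c, indexes, config.weight_table)
        for c in adjacency.enumerate_adjacencies(restricted)
    ]
    matching = adjacency.max_weight_matching(candidates)
    kept = adjacency.filter_low_support(matching, config.min_kept_weight)
    logger.info(
        "matching: %d adjacencies, %d kept at weight >= %.2f",
        len(matching), len(kept), config.min_kept_weight,
    )
    set_ids = [s.set_id for s in sets]
    contigs_all = adjacency.extract_contigs(set_ids, kept)
    contigs = adjacency.drop_short_contigs(contigs_all, config.min_contig_adjacencies)
    logger.info("contigs: %d before, %d after the short-contig filter",
                len(contigs_all), len(contigs))

    sets_by_id = {s.set_id: s for s in sets}
    summaries = assembly.project_contigs(contigs, sets_by_id, genome_orders)
    second_matching, new_contigs = assembly.second_mwm(summaries, config)
    logger.info("level 2: %d new contigs", len(new_contigs))
    ancestor, merge_log = assembly.merge_contigs(
        new_contigs, summaries, config.merge_cutoff_genes
    )
    contigs_by_id = {c.contig_id: c for c in contigs}
    ancestor = assembly.number_chromosomes(ancestor, contigs_by_id)
    flattened = assembly.flatten(ancestor, contigs_by_id)

    return ReconstructionResult(
        sets=sets,
        restricted=restricted,
        candidates=candidates,
        matching=matching,
        kept_matching=kept,
        contigs_all=contigs_all,
        contigs=contigs,
        summaries=summaries,
        second_matching=second_matching,
        new_contigs=new_contigs,
        ancestor=ancestor,
        merge_log=merge_log,
        flattened=flattened,
    )
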