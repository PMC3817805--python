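"""Level-2 assembly: summary genomes, contig-level matching, and merging.

Surviving contigs are projected back into each extant genome as single
oriented symbols ("summary genomes"), a second maximum weight matching joins
contigs whose adjacency is supported by at least two genomes, and finally
neighbouring contig runs separated by at most a configurable number of genes
on two supporting genomes are merged greedily into ancestral chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import mean
from typing import Mapping, Sequence

from .adjacency import (
    extract_contigs,
    filter_low_support,
    max_weight_matching,
    weighted_candidates,
)
from .types import (
    AncestralGenome,
    Contig,
    EndPair,
    GenomeOrder,
    OrthologySet,
    PipelineConfig,
    flip_strand,
)

logger = logging.getLogger("paleorder")


@dataclass(frozen=True)
class ContigProjection:
    """Where one contig lands in one genome."""

    contig_id: str
    genome_id: str
    chromosome: str
    coordinate: float  # mean order_index of member genes on that chromosome
    orientation: str   # majority gene orientation relative to contig order
    lo: int            # min member-gene order_index on that chromosome
    hi: int            # max member-gene order_index on that chromosome
    n_genes: int


@dataclass
class SummaryGenome:
    """An extant genome re-expressed as ordered oriented contig symbols."""

    genome_id: str
    chromosomes: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    projections: dict[str, ContigProjection] = field(default_factory=dict)


def project_contigs(
    contigs: Sequence[Contig],
    sets_by_id: Mapping[str, OrthologySet],
    genome_orders: Mapping[str, GenomeOrder],
) -> dict[str, SummaryGenome]:
    """Project each contig to one chromosome per genome it has genes in.

    The chromosome holding the plurality of the contig's member genes wins
    (tie: lexicographically smallest); the coordinate is the mean
    order_index of those genes and the orientation the majority gene strand
    relative to the contig's marker orientation (tie: '+').
    """
    summaries = {
        g: SummaryGenome(genome_id=g) for g in sorted(genome_orders)
    }
    for contig in contigs:
        member_any = False
        for genome_id in sorted(genome_orders):
            order = genome_orders[genome_id]
            by_chrom: dict[str, list[tuple[int, str, str]]] = {}
            for marker, contig_strand in contig.markers:
                oset = sets_by_id[marker]
                gene = oset.members.get(genome_id)
                if gene is None or gene not in order:
                    continue
                rec = order.records[gene]
                by_chrom.setdefault(rec.chromosome, []).append(
                    (rec.order_index, rec.strand, contig_strand)
                )
            if not by_chrom:
                continue
            member_any = True
            chrom = max(sorted(by_chrom), key=lambda c: len(by_chrom[c]))
            genes = by_chrom[chrom]
            votes = sum(
                1 if gene_strand == contig_strand else -1
                for _, gene_strand, contig_strand in genes
            )
            proj = ContigProjection(
                contig_id=contig.contig_id,
                genome_id=genome_id,
                chromosome=chrom,
                coordinate=mean(idx for idx, _, _ in genes),
                orientation="+" if votes >= 0 else "-",
                lo=min(idx for idx, _, _ in genes),
                hi=max(idx for idx, _, _ in genes),
                n_genes=len(genes),
            )
            summaries[genome_id].projections[contig.contig_id] = proj
        if not member_any:
            raise ValueError(
                f"contig {contig.contig_id!r} has no member gene in any genome"
            )
    for summary in summaries.values():
        by_chrom: dict[str, list[ContigProjection]] = {}
        for proj in summary.projections.values():
            by_chrom.setdefault(proj.chromosome, []).append(proj)
        summary.chromosomes = {
            chrom: [
                (p.contig_id, p.orientation)
                for p in sorted(projs, key=lambda p: (p.coordinate, p.contig_id))
            ]
            for chrom, projs in sorted(by_chrom.items())
        }
    return summaries


def second_mwm(
    summaries: Mapping[str, SummaryGenome], config: PipelineConfig
) -> tuple[dict[EndPair, float], list[Contig]]:
    """Contig-level matching with the same weight table.

    Adjacencies supported by a single genome — by default the inversion
    classes included — are discarded; the survivors group the contigs into
    new, larger contigs.
    """
    orders = {g: s.chromosomes for g, s in summaries.items()}
    candidates = weighted_candidates(orders, config.weight_table)
    matching = max_weight_matching(candidates)
    kept = filter_low_support(matching, config.second_min_kept_weight)
    contig_ids = sorted(
        {cid for s in summaries.values() for cid in s.projections}
    )
    new_contigs = extract_contigs(contig_ids, kept, prefix="nc")
    return kept, new_contigs


# ---------------------------------------------------------------------------
# Step 7: merging new contigs into chromosomes


Structure = list[tuple[str, str]]  # oriented constituent (level-1) contig ids


def decompose_pieces(
    constituents: Structure,
    summaries: Mapping[str, SummaryGenome],
    genome_a: str,
    genome_b: str,
) -> list[Structure]:
    """Split a contig run into pieces strictly contiguous on two genomes.

    A piece is a maximal run of constituents that sit on one chromosome at
    consecutive summary positions — in a constant direction, so a jointly
    reversed run still counts — in *both* genomes.  Constituents lacking a
    projection in either genome form their own pieces.
    """
    def pos(genome: str, cid: str) -> tuple[str, int] | None:
        summary = summaries[genome]
        proj = summary.projections.get(cid)
        if proj is None:
            return None
        return proj.chromosome, summary.chromosomes[proj.chromosome].index(
            (cid, proj.orientation)
        )

    pieces: list[Structure] = []
    current: Structure = []
    prev: dict[str, tuple[str, int] | None] = {}
    direction: dict[str, int] = {}
    for cid, strand in constituents:
        here = {g: pos(g, cid) for g in (genome_a, genome_b)}
        if not current:
            current = [(cid, strand)]
            prev, direction = here, {}
            continue
        ok = True
        new_dir = dict(direction)
        for g in (genome_a, genome_b):
            p, q = prev[g], here[g]
            if p is None or q is None or p[0] != q[0]:
                ok = False
                break
            step = q[1] - p[1]
            if abs(step) != 1:
                ok = False
                break
            if g in new_dir and new_dir[g] != step:
                ok = False
                break
            new_dir[g] = step
        if ok:
            current.append((cid, strand))
            prev, direction = here, new_dir
        else:
            pieces.append(current)
            current = [(cid, strand)]
            prev, direction = here, {}
    if current:
        pieces.append(current)
    return pieces


def _piece_extent(
    piece: Structure, summary: SummaryGenome, chromosome: str
) -> tuple[int, int] | None:
    los, his = [], []
    for cid, _ in piece:
        proj = summary.projections.get(cid)
        if proj is None or proj.chromosome != chromosome:
            return None
        los.append(proj.lo)
        his.append(proj.hi)
    return min(los), max(his)


def _structure_chromosome(structure: Structure, summary: SummaryGenome) -> str | None:
    """Modal chromosome of a structure's constituents in one genome."""
    counts: dict[str, int] = {}
    for cid, _ in structure:
        proj = summary.projections.get(cid)
        if proj is not None:
            counts[proj.chromosome] = counts.get(proj.chromosome, 0) + 1
    if not counts:
        return None
    return max(sorted(counts), key=lambda c: counts[c])


def _structure_orientation(structure: Structure, summary: SummaryGenome) -> str:
    votes = 0
    for cid, strand in structure:
        proj = summary.projections.get(cid)
        if proj is not None:
            votes += 1 if proj.orientation == strand else -1
    return "+" if votes >= 0 else "-"


def _structure_coordinate(structure: Structure, summary: SummaryGenome, chrom: str) -> float:
    coords = [
        summary.projections[cid].coordinate
        for cid, _ in structure
        if cid in summary.projections
        and summary.projections[cid].chromosome == chrom
    ]
    return mean(coords)


def _pair_distance(
    s1: Structure,
    s2: Structure,
    summaries: Mapping[str, SummaryGenome],
) -> tuple[float, tuple[str, str]] | None:
    """Closest-piece distance between two structures.

    For every genome pair in which both structures sit on the same
    chromosome, both are decomposed into pieces; the candidate distance is
    the intervening gene count between the closest non-overlapping piece
    pair, maximised over the two supporting genomes, then minimised over
    genome pairs.  None when no genome pair supports the merger.
    """
    genomes = sorted(summaries)
    best: tuple[float, tuple[str, str]] | None = None
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            ga, gb = genomes[i], genomes[j]
            chrom_a1 = _structure_chromosome(s1, summaries[ga])
            chrom_a2 = _structure_chromosome(s2, summaries[ga])
            chrom_b1 = _structure_chromosome(s1, summaries[gb])
            chrom_b2 = _structure_chromosome(s2, summaries[gb])
            if None in (chrom_a1, chrom_b1) or chrom_a1 != chrom_a2 or chrom_b1 != chrom_b2:
                continue
            p1 = decompose_pieces(s1, summaries, ga, gb)
            p2 = decompose_pieces(s2, summaries, ga, gb)
            for piece1 in p1:
                e_a1 = _piece_extent(piece1, summaries[ga], chrom_a1)
                e_b1 = _piece_extent(piece1, summaries[gb], chrom_b1)
                if e_a1 is None or e_b1 is None:
                    continue
                for piece2 in p2:
                    e_a2 = _piece_extent(piece2, summaries[ga], chrom_a1)
                    e_b2 = _piece_extent(piece2, summaries[gb], chrom_b1)
                    if e_a2 is None or e_b2 is None:
                        continue
                    gaps = []
                    order_sign = []
                    ok = True
                    for e1, e2 in ((e_a1, e_a2), (e_b1, e_b2)):
                        if e1[1] < e2[0]:
                            gaps.append(e2[0] - e1[1] - 1)
                            order_sign.append(1)
                        elif e2[1] < e1[0]:
                            gaps.append(e1[0] - e2[1] - 1)
                            order_sign.append(-1)
                        else:
                            ok = False  # overlapping extents: not mergeable
                            break
                    if not ok:
                        continue
                    d = max(gaps)
                    if best is None or d < best[0]:
                        best = (d, (ga, gb))
    return best


def merge_contigs(
    new_contigs: Sequence[Contig],
    summaries: Mapping[str, SummaryGenome],
    merge_cutoff_genes: int,
) -> tuple[AncestralGenome, list[dict]]:
    """Greedy merging of contig runs into ancestral chromosomes.

    Repeatedly merges the globally closest pair of structures whose
    closest-piece distance on two supporting genomes is at most the cutoff.
    Merging concatenates whole structures end-to-end (oriented along the
    first supporting genome), so linearity is preserved by construction.
    Returns the ancestor plus a merge log.
    """
    structures: dict[str, Structure] = {
        c.contig_id: list(c.markers) for c in new_contigs
    }
    merge_log: list[dict] = []
    while True:
        ids = sorted(structures)
        best: tuple[float, str, str, tuple[str, str]] | None = None
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                res = _pair_distance(structures[ids[i]], structures[ids[j]], summaries)
                if res is None:
                    continue
                d, genome_pair = res
                if d > merge_cutoff_genes:
                    continue
                if best is None or (d, ids[i], ids[j]) < (best[0], best[1], best[2]):
                    best = (d, ids[i], ids[j], genome_pair)
        if best is None:
            break
        d, id1, id2, (ga, gb) = best
        s1, s2 = structures.pop(id1), structures.pop(id2)
        chrom = _structure_chromosome(s1, summaries[ga])
        if _structure_orientation(s1, summaries[ga]) == "-":
            s1 = [(c, flip_strand(s)) for c, s in reversed(s1)]
        if _structure_orientation(s2, summaries[ga]) == "-":
            s2 = [(c, flip_strand(s)) for c, s in reversed(s2)]
        c1 = _structure_coordinate(s1, summaries[ga], chrom)
        c2 = _structure_coordinate(s2, summaries[ga], chrom)
        merged = s1 + s2 if c1 <= c2 else s2 + s1
        merged_id = min(id1, id2)
        structures[merged_id] = merged
        merge_log.append(
            {
                "merged": merged_id,
                "from": (id1, id2),
                "distance": d,
                "supporting_genomes": (ga, gb),
            }
        )
        logger.info(
            "merged %s + %s (distance %d genes, support %s/%s)", id1, id2, int(d), ga, gb
        )
    return AncestralGenome(chromosomes=list(structures.values())), merge_log


def number_chromosomes(
    ancestor: AncestralGenome, contigs_by_id: Mapping[str, Contig]
) -> AncestralGenome:
    """Order ancestral chromosomes by descending marker count."""

    def size(chrom: Structure) -> int:
        return sum(len(contigs_by_id[cid].markers) for cid, _ in chrom)

    ordered = sorted(
        ancestor.chromosomes, key=lambda ch: (-size(ch), ch[0][0])
    )
    return AncestralGenome(chromosomes=ordered)


def flatten(
    ancestor: AncestralGenome, contigs_by_id: Mapping[str, Contig]
) -> dict[int, list[tuple[str, str]]]:
    """Expand an ancestor to marker resolution, chromosome by chromosome."""
    flattened: dict[int, list[tuple[str, str]]] = {}
    for number, chrom in enumerate(ancestor.chromosomes, start=1):
        seq: list[tuple[str, str]] = []
        for cid, strand in chrom:
            markers = contigs_by_id[cid].markers
            if strand == "+":
                seq.extend(markers)
            else:
                seq.extend((m, flip_strand(s)) for m, s in reversed(markers))
        flattened[number] = seq
    return flattened
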