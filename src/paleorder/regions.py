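"""Triplicated-region colouring and tabulation.

The three homeologous copies of each of the seven pre-tripling chromosomes
are labelled with seven colours in three shades (dark/medium/light, ordered
by retained gene count before homology extension).  Genes inherit the
colour of the interval they fall into; uncoloured genes can be extended by
homology when at least two orthologs in the other genomes agree on a
colour.  Summary tables count colour composition of synteny blocks and gene
pairs, within-genome family sizes, and the colour make-up of a
reconstructed ancestor's chromosomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import OrthologPair
from .types import GenomeOrder, OrthologySet, RegionAssignment

logger = logging.getLogger("paleorder")


@dataclass(frozen=True)
class ColoredGene:
    gene_id: str
    color: str | None
    shade: str | None
    source: str  # "region-interval" | "homology-extension" | "none"


def assign_colors(
    order: GenomeOrder, regions: Sequence[RegionAssignment]
) -> dict[str, ColoredGene]:
    """Colour genes by the (1-based, inclusive) gene-index intervals."""
    colored: dict[str, ColoredGene] = {}
    for rec in order:
        colored[rec.gene_id] = ColoredGene(rec.gene_id, None, None, "none")
    for region in regions:
        if region.genome_id != order.genome_id:
            continue
        genes = order.chromosomes.get(region.chromosome, [])
        for idx in range(region.first_index - 1, min(region.last_index, len(genes))):
            gene = genes[idx]
            prev = colored[gene]
            if prev.color is not None and prev.color != region.color:
                raise ValueError(
                    f"gene {gene!r} covered by overlapping intervals of colours "
                    f"{prev.color!r} and {region.color!r}"
                )
            colored[gene] = ColoredGene(
                gene, region.color, region.shade, "region-interval"
            )
    return colored


def extend_by_homology(
    colored: Mapping[str, Mapping[str, ColoredGene]],
    sets: Sequence[OrthologySet],
) -> dict[str, dict[str, ColoredGene]]:
    """Single-pass colour extension through orthology.

    An uncoloured gene inherits a colour (shade left unset) when at least
    two of its orthologs in the other genomes carry that same colour;
    conflicting donors leave the gene uncoloured (logged).  Extension never
    recolours and never chains.
    """
    out = {g: dict(m) for g, m in colored.items()}
    n_conflicts = 0
    for oset in sets:
        donors: dict[str, str] = {}
        for genome, gene in oset.members.items():
            cg = colored.get(genome, {}).get(gene)
            if cg is not None and cg.color is not None:
                donors[genome] = cg.color
        for genome, gene in oset.members.items():
            cg = colored.get(genome, {}).get(gene)
            if cg is None or cg.color is not None:
                continue
            donor_colors = {c for g, c in donors.items() if g != genome}
            donor_count = sum(1 for g in donors if g != genome)
            if donor_count < 2:
                continue
            if len(donor_colors) > 1:
                n_conflicts += 1
                continue
            out[genome][gene] = ColoredGene(
                gene, donor_colors.pop(), None, "homology-extension"
            )
    if n_conflicts:
        logger.info(
            "homology extension left %d genes uncoloured due to donor conflicts",
            n_conflicts,
        )
    return out


def block_color_stats(
    pairs: Sequence[OrthologPair],
    colored_a: Mapping[str, ColoredGene],
    colored_b: Mapping[str, ColoredGene] | None = None,
) -> dict:
    """Colour composition of synteny blocks and of gene pairs.

    ``colored_b`` defaults to ``colored_a`` (self-comparison).  Block colour
    is the colour held by the majority of its coloured genes; a block is
    "different colour" when two genes of one of its pairs are coloured
    differently.  Pair classes: same colour different region (shade), same
    colour same region, one gene coloured, neither coloured.
    """
    if colored_b is None:
        colored_b = colored_a

    def lookup(gene: str) -> ColoredGene | None:
        return colored_a.get(gene) or colored_b.get(gene)

    genes_in_blocks = sorted(
        {p.gene_a for p in pairs} | {p.gene_b for p in pairs}
    )
    n_colored_genes = sum(
        1 for g in genes_in_blocks if (cg := lookup(g)) and cg.color is not None
    )

    blocks: dict[str, list[OrthologPair]] = {}
    for p in pairs:
        blocks.setdefault(p.block_id if p.block_id is not None else "_", []).append(p)

    block_classes = {"one colour": 0, "no colour": 0, "different colour": 0}
    for block_pairs in blocks.values():
        colors = []
        different = False
        for p in block_pairs:
            ca, cb = lookup(p.gene_a), lookup(p.gene_b)
            col_a = ca.color if ca else None
            col_b = cb.color if cb else None
            colors.extend(c for c in (col_a, col_b) if c is not None)
            if col_a is not None and col_b is not None and col_a != col_b:
                different = True
        if different:
            block_classes["different colour"] += 1
        elif not colors:
            block_classes["no colour"] += 1
        else:
            block_classes["one colour"] += 1

    pair_classes = {
        "same colour, different region": 0,
        "same colour, same region": 0,
        "one gene coloured": 0,
        "neither coloured": 0,
        "different colour": 0,
    }
    n_pairs_colored_blocks = 0
    block_colors = {}
    for bid, block_pairs in blocks.items():
        tally: dict[str, int] = {}
        for p in block_pairs:
            for cg in (lookup(p.gene_a), lookup(p.gene_b)):
                if cg and cg.color:
                    tally[cg.color] = tally.get(cg.color, 0) + 1
        block_colors[bid] = (
            max(sorted(tally), key=lambda c: tally[c]) if tally else None
        )
    for bid, block_pairs in blocks.items():
        in_colored_block = block_colors[bid] is not None
        for p in block_pairs:
            if in_colored_block:
                n_pairs_colored_blocks += 1
            ca, cb = lookup(p.gene_a), lookup(p.gene_b)
            col_a, sh_a = (ca.color, ca.shade) if ca else (None, None)
            col_b, sh_b = (cb.color, cb.shade) if cb else (None, None)
            if col_a is None and col_b is None:
                pair_classes["neither coloured"] += 1
            elif col_a is None or col_b is None:
                pair_classes["one gene coloured"] += 1
            elif col_a != col_b:
                pair_classes["different colour"] += 1
            elif sh_a is not None and sh_a == sh_b:
                pair_classes["same colour, same region"] += 1
            else:
                pair_classes["same colour, different region"] += 1

    n_pairs = len(pairs)
    n_blocks = len(blocks)
    return {
        "n_genes_in_blocks": len(genes_in_blocks),
        "pct_genes_coloured": 100.0 * n_colored_genes / len(genes_in_blocks)
        if genes_in_blocks
        else 0.0,
        "n_blocks": n_blocks,
        "pct_blocks": {
            k: 100.0 * v / n_blocks if n_blocks else 0.0
            for k, v in block_classes.items()
        },
        "n_pairs": n_pairs,
        "pct_pairs_in_coloured_blocks": 100.0 * n_pairs_colored_blocks / n_pairs
        if n_pairs
        else 0.0,
        "pct_pairs": {
            k: 100.0 * v / n_pairs if n_pairs else 0.0
            for k, v in pair_classes.items()
        },
    }


def family_size_table(
    within_genome_pairs: Sequence[OrthologPair],
) -> pd.DataFrame:
    """Family-size frequencies from a genome self-comparison.

    Families are connected components of the within-genome homolog-pair
    graph; sizes are reported as 2, 3 and >=4 (the loss model has no state
    beyond three copies, so larger families are only counted).
    """
    g = nx.Graph()
    for p in within_genome_pairs:
        g.add_edge(p.gene_a, p.gene_b)
    sizes = [len(c) for c in nx.connected_components(g)]
    return pd.DataFrame(
        {
            "size": ["2", "3", ">=4"],
            "n_families": [
                sum(1 for s in sizes if s == 2),
                sum(1 for s in sizes if s == 3),
                sum(1 for s in sizes if s >= 4),
            ],
        }
    )


def annotate_ancestor(
    flattened: Mapping[int, Sequence[tuple[str, str]]],
    sets_by_id: Mapping[str, OrthologySet],
    colored: Mapping[str, Mapping[str, ColoredGene]],
) -> pd.DataFrame:
    """Colour each ancestral marker and summarise regions per chromosome.

    A marker takes the majority colour/shade of its member genes across
    genomes (ties: lexicographically smallest; no coloured member: none).
    Per (color, shade) the table reports the distribution over ancestral
    chromosomes and the share held by the modal chromosome — near 1.0 for
    regions the reconstruction kept intact.
    """
    marker_rows = []
    for chrom, markers in sorted(flattened.items()):
        for set_id, _ in markers:
            oset = sets_by_id[set_id]
            tally: dict[tuple[str, str | None], int] = {}
            for genome, gene in oset.members.items():
                cg = colored.get(genome, {}).get(gene)
                if cg is not None and cg.color is not None:
                    key = (cg.color, cg.shade)
                    tally[key] = tally.get(key, 0) + 1
            if tally:
                color, shade = max(
                    sorted(tally, key=lambda k: (k[0], k[1] or "")),
                    key=lambda k: tally[k],
                )
            else:
                color, shade = "none", "none"
            marker_rows.append(
                {
                    "chromosome": chrom,
                    "set_id": set_id,
                    "color": color,
                    "shade": shade if shade is not None else "none",
                }
            )
    markers_df = pd.DataFrame(marker_rows)
    out = []
    for (color, shade), grp in markers_df.groupby(["color", "shade"]):
        by_chrom = grp.groupby("chromosome")["set_id"].count()
        out.append(
            {
                "color": color,
                "shade": shade,
                "n_markers": len(grp),
                "modal_chromosome": by_chrom.idxmax(),
                "modal_share": by_chrom.max() / len(grp),
                "n_chromosomes": len(by_chrom),
            }
        )
    return pd.DataFrame(out)


def similarity_histogram(
    pairs: Sequence[OrthologPair], bin_width: float = 0.01
) -> pd.DataFrame:
    """Bin the optional similarity column of ortholog pairs (default 1% bins)."""
    sims = np.array([p.similarity for p in pairs if p.similarity is not None])
    if sims.size == 0:
        return pd.DataFrame({"bin_left": [], "count": []})
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    counts, _ = np.histogram(sims, bins=edges)
    return pd.DataFrame({"bin_left": edges[:-1], "count": counts})
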