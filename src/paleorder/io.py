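"""Readers and writers for the pipeline's TSV dialects.

All files are tab-separated with a header row.  The dialects are a minimal
superset of what synteny-based ortholog callers export:

* gene orders — ``genome  chromosome  start  end  strand  gene_id``
* ortholog pairs — ``gene_id_a  gene_id_b  [similarity]  [block_id]``
* region colours — ``genome  chromosome  first_index  last_index  color  shade``
* orthology sets — ``set_id  genome  gene_id``
* ancestor — ``chromosome  rank  orientation  set_id  members``
* GO annotation — ``gene_id  term  namespace``
* family counts — ``lineage  n_triples  n_pairs  [n_singles]``
"""

from __future__ import annotations

import logging
from collections import namedtuple
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import AncestralGenome, Contig, GeneRecord, GenomeOrder, OrthologySet, RegionAssignment

logger = logging.getLogger("paleorder")

OrthologPair = namedtuple(
    "OrthologPair", ["gene_a", "gene_b", "similarity", "block_id"]
)

GENE_ORDER_COLUMNS = ["genome", "chromosome", "start", "end", "strand", "gene_id"]


def read_gene_orders(path) -> dict[str, GenomeOrder]:
    """Read a gene-order TSV into one :class:`GenomeOrder` per genome.

    Genes are sorted by ``start`` within each chromosome and assigned 0-based
    ``order_index`` ranks.  Duplicate gene ids and malformed rows are
    rejected.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    missing = [c for c in GENE_ORDER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    records: dict[str, list[GeneRecord]] = {}
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rec = GeneRecord(
                gene_id=str(row.gene_id),
                genome_id=str(row.genome),
                chromosome=str(row.chromosome),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
        if rec.gene_id in seen:
            raise ValueError(f"{path}: line {i}: duplicate gene id {rec.gene_id!r}")
        seen.add(rec.gene_id)
        records.setdefault(rec.genome_id, []).append(rec)
    return {g: GenomeOrder(g, recs) for g, recs in sorted(records.items())}


def write_gene_orders(orders: dict[str, GenomeOrder] | Iterable[GenomeOrder], path) -> None:
    if isinstance(orders, dict):
        orders = orders.values()
    rows = []
    for order in orders:
        for rec in order:
            rows.append(
                (rec.genome_id, rec.chromosome, rec.start, rec.end, rec.strand, rec.gene_id)
            )
    pd.DataFrame(rows, columns=GENE_ORDER_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ortholog_pairs(path) -> list[OrthologPair]:
    """Read pairwise ortholog calls.

    Pair members are normalised to lexicographic order, exact duplicates are
    dropped (logged), and self-pairs are rejected with a warning.
    ``similarity`` and ``block_id`` columns are optional.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id_a" not in df.columns or "gene_id_b" not in df.columns:
        raise ValueError(f"{path}: need columns gene_id_a and gene_id_b")
    pairs: list[OrthologPair] = []
    seen: set[tuple[str, str]] = set()
    n_dup = n_self = 0
    for row in df.itertuples(index=False):
        a, b = str(row.gene_id_a), str(row.gene_id_b)
        if a == b:
            n_self += 1
            continue
        if a > b:
            a, b = b, a
        if (a, b) in seen:
            n_dup += 1
            continue
        seen.add((a, b))
        sim = getattr(row, "similarity", None)
        block = getattr(row, "block_id", None)
        pairs.append(
            OrthologPair(
                a,
                b,
                float(sim) if sim is not None and not pd.isna(sim) else None,
                str(block) if block is not None and not pd.isna(block) else None,
            )
        )
    if n_self:
        logger.warning("%s: dropped %d self-pairs", path, n_self)
    if n_dup:
        logger.info("%s: deduplicated %d pairs", path, n_dup)
    return sorted(pairs, key=lambda p: (p.gene_a, p.gene_b))


def write_ortholog_pairs(pairs: Sequence[OrthologPair], path) -> None:
    pd.DataFrame(pairs, columns=OrthologPair._fields).rename(
        columns={"gene_a": "gene_id_a", "gene_b": "gene_id_b"}
    ).to_csv(path, sep="\t", index=False)


def read_regions(path) -> list[RegionAssignment]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["genome", "chromosome", "first_index", "last_index", "color", "shade"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        RegionAssignment(
            genome_id=str(r.genome),
            chromosome=str(r.chromosome),
            first_index=int(r.first_index),
            last_index=int(r.last_index),
            color=str(r.color),
            shade=str(r.shade),
        )
        for r in df.itertuples(index=False)
    ]


def write_regions(regions: Sequence[RegionAssignment], path) -> None:
    pd.DataFrame(
        [
            (r.genome_id, r.chromosome, r.first_index, r.last_index, r.color, r.shade)
            for r in regions
        ],
        columns=["genome", "chromosome", "first_index", "last_index", "color", "shade"],
    ).to_csv(path, sep="\t", index=False)


def write_orthology_sets(sets: Sequence[OrthologySet], path) -> None:
    rows = [
        (s.set_id, genome, gene)
        for s in sets
        for genome, gene in sorted(s.members.items())
    ]
    pd.DataFrame(rows, columns=["set_id", "genome", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_orthology_sets(path) -> list[OrthologySet]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    sets = []
    for set_id, grp in df.groupby("set_id", sort=True):
        sets.append(
            OrthologySet(str(set_id), dict(zip(grp["genome"], grp["gene_id"])))
        )
    return sets


ANCESTOR_COLUMNS = ["chromosome", "rank", "orientation", "set_id", "members"]


def write_ancestor(
    flattened: dict[int, list[tuple[str, str]]],
    sets_by_id: dict[str, OrthologySet],
    path,
) -> None:
    """Write a flattened ancestor: one row per marker.

    ``flattened`` maps ancestral chromosome number to the oriented marker
    sequence.  Members are serialised as ``genome:gene_id`` joined by ';'.
    """
    rows = []
    for chrom in sorted(flattened):
        for rank, (set_id, strand) in enumerate(flattened[chrom]):
            members = sets_by_id.get(set_id)
            member_str = (
                ";".join(f"{g}:{gid}" for g, gid in sorted(members.members.items()))
                if members is not None
                else ""
            )
            rows.append((chrom, rank, strand, set_id, member_str))
    pd.DataFrame(rows, columns=ANCESTOR_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ancestor(path) -> tuple[dict[int, list[tuple[str, str]]], dict[str, OrthologySet]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    flattened: dict[int, list[tuple[str, str]]] = {}
    sets_by_id: dict[str, OrthologySet] = {}
    if df.empty:
        return flattened, sets_by_id
    df["chromosome"] = df["chromosome"].astype(int)
    df["rank"] = df["rank"].astype(int)
    for row in df.sort_values(["chromosome", "rank"]).itertuples(index=False):
        flattened.setdefault(row.chromosome, []).append((row.set_id, row.orientation))
        if isinstance(row.members, str) and row.members:
            members = dict(part.split(":", 1) for part in row.members.split(";"))
            sets_by_id[row.set_id] = OrthologySet(row.set_id, members)
    return flattened, sets_by_id


def write_contigs(contigs: Sequence[Contig], path) -> None:
    rows = [
        (c.contig_id, rank, strand, marker)
        for c in contigs
        for rank, (marker, strand) in enumerate(c.markers)
    ]
    pd.DataFrame(rows, columns=["contig_id", "rank", "orientation", "set_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_terms(path) -> pd.DataFrame:
    """GO annotation table with columns gene_id, term, namespace."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    needed = ["gene_id", "term", "namespace"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_family_counts(path) -> pd.DataFrame:
    """Observed family-size counts per lineage for the fractionation model."""
    df = pd.read_csv(path, sep="\t")
    needed = ["lineage", "n_triples", "n_pairs"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df.set_index("lineage")
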