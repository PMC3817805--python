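"""Core domain types shared across the reconstruction pipeline.

A genome is modelled as an *oriented gene order*: per chromosome, an ordered
sequence of genes each carrying a strand.  Algorithmic work is done on 0-based
``order_index`` ranks, so base-pair coordinates are optional (rank-only input
uses ``start == end == rank``).

Markers (genes, orthology sets, contigs) all expose two *ends*: a ``tail``
(5') and a ``head`` (3').  An adjacency is an unordered pair of ends of two
distinct markers; a whole genome is then a pair of matchings on ends — the
trivial tail–head matching within each marker plus the adjacency matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

TAIL = "t"
HEAD = "h"

#: A marker end: ``(marker_id, TAIL | HEAD)``.
End = tuple[str, str]


def marker_ends(marker_id: str) -> tuple[End, End]:
    """The two ends of a marker, tail first."""
    return (marker_id, TAIL), (marker_id, HEAD)


def other_end(end: End) -> End:
    marker, side = end
    return (marker, HEAD if side == TAIL else TAIL)


def leading_end(marker_id: str, strand: str) -> End:
    """End met first when reading a marker left-to-right on the chromosome."""
    return (marker_id, TAIL if strand == "+" else HEAD)


def trailing_end(marker_id: str, strand: str) -> End:
    return (marker_id, HEAD if strand == "+" else TAIL)


def flip_strand(strand: str) -> str:
    return "-" if strand == "+" else "+"


EndPair = tuple[End, End]


def end_pair(a: End, b: End) -> EndPair:
    """Canonical (sorted) unordered pair of ends."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class GeneRecord:
    """One gene on one chromosome of one genome."""

    gene_id: str
    genome_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    order_index: int = -1

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id!r}: start ({self.start}) > end ({self.end})"
            )


class GenomeOrder:
    """Oriented gene order of a single genome.

    Parameters
    ----------
    genome_id:
        Name of the genome.
    records:
        Gene records; they are sorted by ``start`` within each chromosome and
        ``order_index`` is (re)assigned as the 0-based rank along the
        chromosome.
    """

    def __init__(self, genome_id: str, records: Iterable[GeneRecord]):
        self.genome_id = genome_id
        self.records: dict[str, GeneRecord] = {}
        by_chrom: dict[str, list[GeneRecord]] = {}
        for rec in records:
            if rec.genome_id != genome_id:
                raise ValueError(
                    f"record {rec.gene_id!r} belongs to genome {rec.genome_id!r}, "
                    f"not {genome_id!r}"
                )
            if rec.gene_id in self.records:
                raise ValueError(f"duplicate gene id {rec.gene_id!r} in {genome_id!r}")
            self.records[rec.gene_id] = rec
            by_chrom.setdefault(rec.chromosome, []).append(rec)
        self.chromosomes: dict[str, list[str]] = {}
        for chrom in sorted(by_chrom):
            recs = sorted(by_chrom[chrom], key=lambda r: (r.start, r.gene_id))
            ranked = [replace(r, order_index=i) for i, r in enumerate(recs)]
            for r in ranked:
                self.records[r.gene_id] = r
            self.chromosomes[chrom] = [r.gene_id for r in ranked]

    def oriented(self, chromosome: str) -> list[tuple[str, str]]:
        """``(gene_id, strand)`` sequence of a chromosome."""
        return [
            (g, self.records[g].strand) for g in self.chromosomes[chromosome]
        ]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        for chrom in self.chromosomes.values():
            for g in chrom:
                yield self.records[g]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeOrder):
            return NotImplemented
        return self.genome_id == other.genome_id and {
            c: self.oriented(c) for c in self.chromosomes
        } == {c: other.oriented(c) for c in other.chromosomes}


@dataclass(frozen=True)
class OrthologySet:
    """2 or 3 orthologous genes, at most one per genome, acting as one
    ancestral marker."""

    set_id: str
    members: Mapping[str, str]  # genome_id -> gene_id

    def __post_init__(self) -> None:
        if len(self.members) not in (2, 3):
            raise ValueError(
                f"orthology set {self.set_id!r} must have 2 or 3 members, "
                f"got {len(self.members)}"
            )

    @property
    def genomes(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(sorted(self.members.values()))


@dataclass(frozen=True)
class RegionAssignment:
    """A coloured chromosome interval (1-based inclusive gene-index bounds)."""

    genome_id: str
    chromosome: str
    first_index: int
    last_index: int
    color: str
    shade: str

    def __post_init__(self) -> None:
        if self.first_index < 1 or self.last_index < self.first_index:
            raise ValueError(
                f"bad interval [{self.first_index}, {self.last_index}] on "
                f"{self.genome_id}/{self.chromosome}"
            )


# Adjacency weight classes keyed by occurrence pattern.  The scheme: ties between equally frequent but
# contextually different adjacencies are broken by small weight offsets, and
# single-genome adjacencies whose absence elsewhere is explained by an
# inversion get boosted above the discard threshold.
DEFAULT_WEIGHT_TABLE: dict[str, float] = {
    "adj3": 3.00,            # adjacent in all three genomes
    "adj2_missing": 2.03,    # adjacent in two; an endpoint absent from the third
    "adj2_present": 2.00,    # adjacent in two; both endpoints present in the third
    "inv_partial": 1.50,     # single-genome, inversion context; uv but not both x,y in third
    "inv_full": 1.49,        # single-genome, inversion context; x, y and uv all in third
    "adj1_absent2": 1.01,    # single-genome; an endpoint absent in each other genome
    "adj1_mixed": 1.00,      # single-genome; both endpoints present in exactly one other
    "adj1_present2": 0.99,   # single-genome; both endpoints present in both others
}


@dataclass
class PipelineConfig:
    """Tunable settings of the two-level reconstruction.

    ``min_kept_weight`` (default 1.49) discards first-level adjacencies whose
    weight falls below it, i.e. the 0.99/1.00/1.01 single-genome classes.
    ``min_contig_adjacencies`` (default 4) keeps only contigs with more than
    three internal adjacencies.  ``second_min_kept_weight`` (default 2.00)
    discards contig-level adjacencies supported by a single genome, the
    inversion classes included; set it to 1.49 to retain them.
    ``merge_cutoff_genes`` (default 500) bounds the gene distance across which
    neighbouring contig runs may be merged into one chromosome.
    """

    weight_table: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHT_TABLE)
    )
    min_kept_weight: float = 1.49
    min_contig_adjacencies: int = 4
    second_min_kept_weight: float = 2.00
    merge_cutoff_genes: int = 500
    random_seed: int = 0

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weight_table.values()):
            raise ValueError("adjacency weights must be positive")
        if self.min_contig_adjacencies < 0 or self.merge_cutoff_genes < 0:
            raise ValueError("cutoffs must be non-negative")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Read a flat ``key = value`` config file; unknown keys rejected."""
        kwargs: dict = {}
        weight_table = dict(DEFAULT_WEIGHT_TABLE)
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (s.strip() for s in line.split("=", 1))
                if key.startswith("weight."):
                    weight_table[key[len("weight."):]] = float(value)
                elif key in ("min_kept_weight", "second_min_kept_weight"):
                    kwargs[key] = float(value)
                elif key in (
                    "min_contig_adjacencies",
                    "merge_cutoff_genes",
                    "random_seed",
                ):
                    kwargs[key] = int(value)
                else:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
        return cls(weight_table=weight_table, **kwargs)


@dataclass
class Contig:
    """A maximal path of markers linked by retained adjacencies.

    ``markers`` is the ordered, oriented marker sequence in the contig's
    canonical orientation (the lexicographically smallest marker id carries
    strand '+').  ``adjacencies`` maps each internal end pair to its weight;
    there are ``len(markers) - 1`` of them.
    """

    contig_id: str
    markers: list[tuple[str, str]]
    adjacencies: dict[EndPair, float] = field(default_factory=dict)

    @property
    def n_adjacencies(self) -> int:
        return len(self.markers) - 1

    @property
    def marker_ids(self) -> list[str]:
        return [m for m, _ in self.markers]

    def reversed(self) -> "Contig":
        return Contig(
            self.contig_id,
            [(m, flip_strand(s)) for m, s in reversed(self.markers)],
            dict(self.adjacencies),
        )


@dataclass
class AncestralGenome:
    """Reconstructed ancestor: linear chromosomes of oriented contigs.

    Chromosomes are numbered 1.. by descending marker count.
    """

    chromosomes: list[list[tuple[str, str]]]  # each: [(contig_id, strand), ...]

    def n_chromosomes(self) -> int:
        return len(self.chromosomes)
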