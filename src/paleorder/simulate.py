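"""Ground-truthed simulator of hexaploidy, fractionation and rearrangement.

A diploid ancestor of ``n_chromosomes`` (default 7) is tripled into three
identical subgenomes (21 chromosomes, labelled by seven colours in three
shades), stochastically fractionated on the shared branch (per-copy loss
probability ``p``, total family loss prohibited) to yield the *truth
ancestor*, then evolved independently into three leaf genomes by a second
round of fractionation (``q`` per lineage, again conditioned on survival)
and by inversions, translocations, fusions and fissions.  The leaves are
exported in the pipeline's input dialects together with truth files, so a
reconstruction can be scored against the ancestor it should recover.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .io import OrthologPair
from .types import GeneRecord, GenomeOrder, RegionAssignment, flip_strand

logger = logging.getLogger("paleorder")

COLORS = ("red", "orange", "yellow", "green", "paleblue", "blue", "purple")
SHADES = ("dark", "medium", "light")
SUBGENOMES = ("a", "b", "c")

#: Internal genome representation: chromosome -> [(marker_id, strand)].
Chromosomes = dict[str, list[tuple[str, str]]]


@dataclass
class SimulationConfig:
    """Study conditions of the simulator.

    Defaults model a moderately fractionated, mildly rearranged trio:
    3000 ancestral genes on 7 chromosomes, shared-branch loss p=0.5,
    post-radiation loss q=0.3 per lineage, 20 inversions plus 2 fusions per
    branch, 95% ortholog detection with 1% false pairs.
    """

    n_genes: int = 3000
    n_chromosomes: int = 7
    p: float = 0.5
    q: dict[str, float] = field(
        default_factory=lambda: {"A": 0.3, "B": 0.3, "C": 0.3}
    )
    inversions_per_branch: int = 20
    translocations_per_branch: int = 0
    fusions_per_branch: int = 2
    fissions_per_branch: int = 0
    inversion_mean_length: float = 5.0
    detection_rate: float = 0.95
    false_pair_rate: float = 0.01
    similarity_peak: float = 0.70
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < self.n_chromosomes:
            raise ValueError("n_genes must be >= n_chromosomes")
        for name, value in [("p", self.p)] + [
            (f"q[{k}]", v) for k, v in self.q.items()
        ] + [
            ("detection_rate", self.detection_rate),
            ("false_pair_rate", self.false_pair_rate),
        ]:
            if not (0.0 <= value <= 1.0) or (name in ("p",) and value >= 1.0):
                raise ValueError(f"{name} out of range: {value!r}")
        for name in (
            "inversions_per_branch",
            "translocations_per_branch",
            "fusions_per_branch",
            "fissions_per_branch",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TruthRecord:
    """Everything needed to score a reconstruction of the simulated data."""

    ancestor: Chromosomes                      # truth ancestral marker order
    marker_color: dict[str, tuple[str, str]]   # marker -> (color, shade)
    leaf_markers: dict[str, set[str]]          # genome -> surviving markers
    true_pairs: list[tuple[str, str]]          # cross-genome same-marker gene pairs
    family_pattern: pd.DataFrame               # per family: copies per lineage


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genome_orders: dict[str, GenomeOrder]
    ortholog_pairs: list[OrthologPair]
    regions: list[RegionAssignment]
    truth: TruthRecord


def _family(marker: str) -> str:
    return marker[:-1]


def simulate_ancestor(config: SimulationConfig, rng: np.random.Generator) -> Chromosomes:
    """Diploid ancestor: families spread evenly over the chromosomes."""
    width = len(str(config.n_genes))
    genome: Chromosomes = {}
    per = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    per[: config.n_genes % config.n_chromosomes] += 1
    gene = 0
    for i in range(config.n_chromosomes):
        chrom = []
        for _ in range(per[i]):
            strand = "+" if rng.random() < 0.5 else "-"
            chrom.append((f"f{gene:0{width}d}", strand))
            gene += 1
        genome[f"chr{i + 1}"] = chrom
    return genome


def hexaploidize(ancestor: Chromosomes) -> Chromosomes:
    """Triple every chromosome; copies share a family id, distinct suffixes."""
    tripled: Chromosomes = {}
    for chrom, genes in ancestor.items():
        for copy in SUBGENOMES:
            tripled[f"{chrom}{copy}"] = [
                (f"{fam}{copy}", strand) for fam, strand in genes
            ]
    return tripled


def fractionate(
    genome: Chromosomes, loss_prob: float, rng: np.random.Generator
) -> Chromosomes:
    """Lose redundant copies independently; a family never loses them all.

    Families with a single surviving copy carry no redundancy and are left
    untouched; families that would lose every copy are redrawn
    (conditioning on survival, matching the closed-form model).
    """
    if not (0.0 <= loss_prob < 1.0):
        raise ValueError(f"loss probability out of range: {loss_prob!r}")
    families: dict[str, list[str]] = {}
    for genes in genome.values():
        for marker, _ in genes:
            families.setdefault(_family(marker), []).append(marker)
    lost: set[str] = set()
    for fam in sorted(families):
        copies = sorted(families[fam])
        if len(copies) < 2 or loss_prob == 0.0:
            continue
        while True:
            flags = rng.random(len(copies)) < loss_prob
            if not flags.all():
                break
        lost.update(c for c, f in zip(copies, flags) if f)
    return {
        chrom: [(m, s) for m, s in genes if m not in lost]
        for chrom, genes in genome.items()
    }


def rearrange(
    genome: Chromosomes,
    rng: np.random.Generator,
    inversions: int = 0,
    translocations: int = 0,
    fusions: int = 0,
    fissions: int = 0,
    inversion_mean_length: float = 5.0,
) -> Chromosomes:
    """Apply the configured rearrangements in random order.

    Inversions reverse a random within-chromosome segment (geometric
    length) and flip strands; reciprocal translocations swap chromosome
    tails; fusions concatenate two chromosomes (second randomly oriented);
    fissions split a chromosome at a uniform internal point.  Impossible
    draws (e.g. fission of a single-gene chromosome) are resampled.
    """
    chroms = {k: list(v) for k, v in genome.items()}
    ops = (
        ["inv"] * inversions
        + ["tra"] * translocations
        + ["fus"] * fusions
        + ["fis"] * fissions
    )
    rng.shuffle(ops)
    counter = [0]

    def fresh_name() -> str:
        counter[0] += 1
        return f"new{counter[0]}"

    def pick_chrom(min_len: int = 1) -> str | None:
        names = sorted(k for k, v in chroms.items() if len(v) >= min_len)
        if not names:
            return None
        weights = np.array([len(chroms[k]) for k in names], dtype=float)
        return names[rng.choice(len(names), p=weights / weights.sum())]

    for op in ops:
        if op == "inv":
            name = pick_chrom(2)
            if name is None:
                continue
            seq = chroms[name]
            length = min(1 + rng.geometric(1.0 / inversion_mean_length), len(seq))
            start = int(rng.integers(0, len(seq) - length + 1))
            segment = [
                (m, flip_strand(s)) for m, s in reversed(seq[start:start + length])
            ]
            chroms[name] = seq[:start] + segment + seq[start + length:]
        elif op == "tra":
            names = sorted(k for k, v in chroms.items() if len(v) >= 2)
            if len(names) < 2:
                continue
            i, j = rng.choice(len(names), size=2, replace=False)
            a, b = names[int(i)], names[int(j)]
            cut_a = int(rng.integers(1, len(chroms[a])))
            cut_b = int(rng.integers(1, len(chroms[b])))
            chroms[a], chroms[b] = (
                chroms[a][:cut_a] + chroms[b][cut_b:],
                chroms[b][:cut_b] + chroms[a][cut_a:],
            )
        elif op == "fus":
            names = sorted(chroms)
            if len(names) < 2:
                continue
            i, j = rng.choice(len(names), size=2, replace=False)
            a, b = names[int(i)], names[int(j)]
            tail = chroms.pop(b)
            if rng.random() < 0.5:
                tail = [(m, flip_strand(s)) for m, s in reversed(tail)]
            merged = chroms.pop(a) + tail
            chroms[fresh_name()] = merged
        elif op == "fis":
            name = pick_chrom(2)
            if name is None:
                continue
            seq = chroms.pop(name)
            cut = int(rng.integers(1, len(seq)))
            chroms[fresh_name()] = seq[:cut]
            chroms[fresh_name()] = seq[cut:]
    return chroms


def _relabel_chromosomes(genome: Chromosomes) -> Chromosomes:
    """Deterministic leaf chromosome names, largest first."""
    ordered = sorted(genome.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    return {f"chr{i + 1}": genes for i, (_, genes) in enumerate(ordered)}


def _to_genome_order(genome_id: str, chroms: Chromosomes) -> GenomeOrder:
    records = []
    for chrom, genes in chroms.items():
        for rank, (marker, strand) in enumerate(genes):
            records.append(
                GeneRecord(
                    gene_id=f"{genome_id}|{marker}",
                    genome_id=genome_id,
                    chromosome=chrom,
                    start=rank + 1,
                    end=rank + 1,
                    strand=strand,
                )
            )
    return GenomeOrder(genome_id, records)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run the full forward simulation under the configured conditions."""
    rng = np.random.default_rng(config.seed)
    diploid = simulate_ancestor(config, rng)
    hexaploid = hexaploidize(diploid)

    # colour truth: family -> ancestral chromosome colour; copy -> shade
    family_chrom = {
        fam: chrom
        for chrom, genes in diploid.items()
        for fam, _ in genes
    }
    chrom_color = {
        f"chr{i + 1}": COLORS[i % len(COLORS)]
        for i in range(config.n_chromosomes)
    }
    shade_of = dict(zip(SUBGENOMES, SHADES))

    def color_of(marker: str) -> tuple[str, str]:
        return chrom_color[family_chrom[_family(marker)]], shade_of[marker[-1]]

    truth_ancestor = fractionate(hexaploid, config.p, rng)

    leaves: dict[str, Chromosomes] = {}
    for lineage in sorted(config.q):
        branch_rng = np.random.default_rng(
            rng.integers(0, 2**31 - 1)
        )
        leaf = fractionate(truth_ancestor, config.q[lineage], branch_rng)
        leaf = rearrange(
            leaf,
            branch_rng,
            inversions=config.inversions_per_branch,
            translocations=config.translocations_per_branch,
            fusions=config.fusions_per_branch,
            fissions=config.fissions_per_branch,
            inversion_mean_length=config.inversion_mean_length,
        )
        leaves[lineage] = _relabel_chromosomes(leaf)

    genome_orders = {
        lineage: _to_genome_order(lineage, chroms)
        for lineage, chroms in leaves.items()
    }
    leaf_markers = {
        lineage: {m for genes in chroms.values() for m, _ in genes}
        for lineage, chroms in leaves.items()
    }

    # ortholog pairs: true same-marker pairs thinned by the detection rate,
    # plus uniformly random false pairs
    lineages = sorted(leaves)
    true_pairs: list[tuple[str, str]] = []
    emitted: list[OrthologPair] = []
    for i in range(len(lineages)):
        for j in range(i + 1, len(lineages)):
            ga, gb = lineages[i], lineages[j]
            shared = sorted(leaf_markers[ga] & leaf_markers[gb])
            for marker in shared:
                pair = (f"{ga}|{marker}", f"{gb}|{marker}")
                true_pairs.append(pair)
                if rng.random() < config.detection_rate:
                    sim = float(
                        np.clip(rng.beta(
                            config.similarity_peak * 50,
                            (1 - config.similarity_peak) * 50,
                        ), 0.0, 1.0)
                    )
                    emitted.append(OrthologPair(pair[0], pair[1], sim, None))
    n_false = int(round(config.false_pair_rate * len(emitted)))
    all_genes = {
        lineage: sorted(f"{lineage}|{m}" for m in leaf_markers[lineage])
        for lineage in lineages
    }
    existing = {(min(a, b), max(a, b)) for a, b, _, _ in emitted}
    made = 0
    while made < n_false:
        i, j = rng.choice(len(lineages), size=2, replace=False)
        ga, gb = lineages[int(i)], lineages[int(j)]
        a = all_genes[ga][int(rng.integers(0, len(all_genes[ga])))]
        b = all_genes[gb][int(rng.integers(0, len(all_genes[gb])))]
        key = (min(a, b), max(a, b))
        if key in existing:
            continue
        existing.add(key)
        emitted.append(OrthologPair(a, b, None, None))
        made += 1
    emitted.sort(key=lambda p: (p.gene_a, p.gene_b))

    # region truth: maximal same-(color, shade) runs per leaf chromosome
    regions: list[RegionAssignment] = []
    for lineage, chroms in leaves.items():
        for chrom, genes in chroms.items():
            run_start = 0
            for idx in range(1, len(genes) + 1):
                boundary = idx == len(genes) or (
                    color_of(genes[idx][0]) != color_of(genes[run_start][0])
                )
                if boundary:
                    color, shade = color_of(genes[run_start][0])
                    regions.append(
                        RegionAssignment(
                            genome_id=lineage,
                            chromosome=chrom,
                            first_index=run_start + 1,
                            last_index=idx,
                            color=color,
                            shade=shade,
                        )
                    )
                    run_start = idx

    all_markers = sorted(
        {m for genes in truth_ancestor.values() for m, _ in genes}
    )
    pattern = pd.DataFrame(
        {
            lineage: [
                sum(
                    1
                    for copy in SUBGENOMES
                    if f"{_family(m)}{copy}" in leaf_markers[lineage]
                )
                for m in all_markers
            ]
            for lineage in lineages
        },
        index=pd.Index(all_markers, name="marker"),
    )
    truth = TruthRecord(
        ancestor=truth_ancestor,
        marker_color={m: color_of(m) for m in all_markers},
        leaf_markers=leaf_markers,
        true_pairs=true_pairs,
        family_pattern=pattern,
    )
    return SimulatedDataset(
        config=config,
        genome_orders=genome_orders,
        ortholog_pairs=emitted,
        regions=regions,
        truth=truth,
    )


def emit_inputs(dataset: SimulatedDataset, out_dir) -> None:
    """Write pipeline-ready inputs plus a truth/ subdirectory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pio.write_gene_orders(dataset.genome_orders, out / "gene_orders.tsv")
    pio.write_ortholog_pairs(dataset.ortholog_pairs, out / "ortholog_pairs.tsv")
    pio.write_regions(dataset.regions, out / "regions.tsv")
    truth_dir = out / "truth"
    truth_dir.mkdir(exist_ok=True)
    rows = [
        (chrom, rank, strand, marker)
        for chrom, genes in sorted(dataset.truth.ancestor.items())
        for rank, (marker, strand) in enumerate(genes)
    ]
    pd.DataFrame(rows, columns=["chromosome", "rank", "orientation", "marker"]).to_csv(
        truth_dir / "ancestor_order.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        [(m, c, s) for m, (c, s) in sorted(dataset.truth.marker_color.items())],
        columns=["marker", "color", "shade"],
    ).to_csv(truth_dir / "marker_colors.tsv", sep="\t", index=False)
    dataset.truth.family_pattern.to_csv(truth_dir / "family_pattern.tsv", sep="\t")


# ---------------------------------------------------------------------------
# Scoring reconstructions against the simulated truth


def _oriented_adjacencies(
    chromosomes: Sequence[Sequence[tuple[str, str]]]
) -> set[tuple[tuple[str, str], tuple[str, str]]]:
    from .types import end_pair, leading_end, trailing_end

    adjacencies = set()
    for seq in chromosomes:
        for (a, sa), (b, sb) in zip(seq, seq[1:]):
            adjacencies.add(end_pair(trailing_end(a, sa), leading_end(b, sb)))
    return adjacencies


def reconstruction_markers(result, truth: TruthRecord) -> dict[str, str]:
    """Map orthology-set ids to truth marker ids.

    A set maps to a marker only when all its member genes descend from the
    same truth marker; sets glued together by false ortholog pairs map to
    nothing and count against precision.
    """
    mapping: dict[str, str] = {}
    for oset in result.sets:
        markers = {gene.split("|", 1)[1] for gene in oset.members.values()}
        if len(markers) == 1:
            mapping[oset.set_id] = markers.pop()
    return mapping


def evaluate_reconstruction(result, truth: TruthRecord) -> dict:
    """Adjacency precision/recall/F1 of a reconstruction against the truth.

    Both genomes are flattened to oriented marker adjacency sets over the
    markers present in both; the truth order is restricted to those markers
    first, so adjacencies spanning dropped markers contract correctly.
    """
    set_to_marker = reconstruction_markers(result, truth)
    recon_chroms = []
    recon_markers: set[str] = set()
    for chrom in sorted(result.flattened):
        seq = []
        for set_id, strand in result.flattened[chrom]:
            marker = set_to_marker.get(set_id, f"?{set_id}")
            seq.append((marker, strand))
            recon_markers.add(marker)
        recon_chroms.append(seq)
    truth_universe = {
        m for genes in truth.ancestor.values() for m, _ in genes
    }
    common = recon_markers & truth_universe
    if not common:
        raise ValueError("reconstruction and truth share no markers")
    truth_chroms = [
        [(m, s) for m, s in genes if m in common]
        for _, genes in sorted(truth.ancestor.items())
    ]
    truth_adj = _oriented_adjacencies([c for c in truth_chroms if c])
    recon_adj = _oriented_adjacencies(recon_chroms)
    hits = len(truth_adj & recon_adj)
    precision = hits / len(recon_adj) if recon_adj else 0.0
    recall = hits / len(truth_adj) if truth_adj else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    n_truth_chroms = sum(1 for c in truth_chroms if c)
    color_shares = {}
    by_region: dict[tuple[str, str], dict[int, int]] = {}
    for chrom_number, seq in enumerate(recon_chroms, start=1):
        for marker, _ in seq:
            cs = truth.marker_color.get(marker)
            if cs is None:
                continue
            by_region.setdefault(cs, {}).setdefault(chrom_number, 0)
            by_region[cs][chrom_number] += 1
    for cs, counts in sorted(by_region.items()):
        total = sum(counts.values())
        color_shares["/".join(cs)] = max(counts.values()) / total
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n_common_markers": len(common),
        "n_truth_adjacencies": len(truth_adj),
        "n_recon_adjacencies": len(recon_adj),
        "chromosome_count_delta": len(recon_chroms) - n_truth_chroms,
        "region_modal_share": color_shares,
    }
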