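"""Retention categories and normalised GO-term association.

Complete gene families — one to three copies in each of the three genomes —
are scored 1..5 by how many duplicate/triplicate copies they retain; higher
categories are more fractionation-resistant.  GO terms hit by any member are
amalgamated per family, and per (category, term) the share of families
hitting the term is normalised by the share of families with any hit in the
namespace, so that categories with richer annotation (more members, hence
more hits) remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

NAMESPACES = ("Biological function", "Cellular component", "Molecular function")


def retention_category(copy_counts: Sequence[int]) -> int:
    """Score a complete family by its per-genome copy counts.

    1: single-copy everywhere; 2: exactly one genome holds 2–3 copies;
    3: exactly one genome is single-copy (the others hold 2–3);
    4: two copies everywhere; 5: at least two copies everywhere with some
    genome at three.
    """
    counts = tuple(copy_counts)
    if len(counts) != 3:
        raise ValueError(f"need copy counts for exactly 3 genomes, got {len(counts)}")
    if any(c < 1 or c > 3 for c in counts):
        raise ValueError(
            f"incomplete family: copy counts must lie in 1..3, got {counts}"
        )
    n_single = sum(1 for c in counts if c == 1)
    if n_single == 3:
        return 1
    if n_single == 2:
        return 2
    if n_single == 1:
        return 3
    if all(c == 2 for c in counts):
        return 4
    return 5


def amalgamate_terms(
    member_genes: Iterable[str], gene_to_terms: Mapping[str, set[str]]
) -> set[str]:
    """Union of the GO terms hit by any member of a family."""
    terms: set[str] = set()
    for gene in member_genes:
        terms |= set(gene_to_terms.get(gene, ()))
    return terms


@dataclass
class RetentionFamily:
    """One complete family: copy counts per genome plus amalgamated terms."""

    family_id: str
    copy_counts: dict[str, int]  # genome -> copies (1..3)
    go_terms: dict[str, set[str]] = field(default_factory=dict)  # namespace -> terms

    @property
    def category(self) -> int:
        return retention_category(
            [self.copy_counts[g] for g in sorted(self.copy_counts)]
        )


def build_families(
    families_df: pd.DataFrame,
    annotations: pd.DataFrame | None = None,
    slim: Mapping[str, str] | None = None,
) -> list[RetentionFamily]:
    """Assemble :class:`RetentionFamily` objects from tidy tables.

    ``families_df`` has columns family_id, genome, gene_id (one row per
    copy); ``annotations`` has gene_id, term, namespace.  ``slim``
    optionally maps raw terms onto a reduced vocabulary of general
    functional categories before amalgamation.
    """
    gene_terms: dict[str, dict[str, set[str]]] = {}
    if annotations is not None:
        for row in annotations.itertuples(index=False):
            term = str(row.term)
            if slim is not None:
                term = slim.get(term, term)
            gene_terms.setdefault(str(row.gene_id), {}).setdefault(
                str(row.namespace), set()
            ).add(term)
    out = []
    for family_id, grp in families_df.groupby("family_id", sort=True):
        counts = grp.groupby("genome")["gene_id"].count().to_dict()
        terms: dict[str, set[str]] = {}
        for gene in grp["gene_id"]:
            for ns, ts in gene_terms.get(str(gene), {}).items():
                terms.setdefault(ns, set()).update(ts)
        out.append(RetentionFamily(str(family_id), counts, terms))
    return out


def normalized_association(
    families: Sequence[RetentionFamily], namespace: str
) -> pd.DataFrame:
    """Per (category, term) normalised association values in one namespace.

    ``hit_share`` is the fraction of the category's families hitting the
    term; ``anyhit_share`` the fraction with at least one hit in the
    namespace; ``normalized`` their ratio.  Categories with no annotated
    family get missing values.  Full precision is kept; round for display.
    """
    if not any(namespace in f.go_terms for f in families):
        raise ValueError(f"no family carries annotation in namespace {namespace!r}")
    rows = []
    by_cat: dict[int, list[RetentionFamily]] = {}
    for fam in families:
        by_cat.setdefault(fam.category, []).append(fam)
    terms = sorted(
        {t for f in families for t in f.go_terms.get(namespace, ())}
    )
    for cat in sorted(by_cat):
        fams = by_cat[cat]
        n = len(fams)
        n_anyhit = sum(1 for f in fams if f.go_terms.get(namespace))
        anyhit_share = n_anyhit / n
        for term in terms:
            n_hit = sum(
                1 for f in fams if term in f.go_terms.get(namespace, ())
            )
            hit_share = n_hit / n
            normalized = hit_share / anyhit_share if n_anyhit else float("nan")
            rows.append(
                {
                    "namespace": namespace,
                    "category": cat,
                    "term": term,
                    "n_families": n,
                    "hit_share": hit_share,
                    "anyhit_share": anyhit_share,
                    "normalized": normalized,
                }
            )
    return pd.DataFrame(rows)


def normalized_value(n_hit: int, n_anyhit: int, n_total: int) -> tuple[float, float]:
    """Worked single-cell computation from raw counts.

    Returns ``(anyhit_share, normalized)`` where the normalised association
    is the term-hit share divided by the any-hit share.  For display both
    are conventionally rounded to two decimals.
    """
    if n_total <= 0 or n_anyhit <= 0:
        raise ValueError("need positive family counts")
    anyhit_share = n_anyhit / n_total
    hit_share = n_hit / n_total
    return anyhit_share, hit_share / anyhit_share


def association_trends(table: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlation of normalised value against category, per term.

    An explicitly quantified stand-in for eyeballing monotone trends:
    positive rho = association rises with retention.  Off the main path;
    call it explicitly when wanted.
    """
    from scipy import stats

    rows = []
    for term, grp in table.groupby("term"):
        grp = grp.dropna(subset=["normalized"])
        if len(grp) < 3 or grp["normalized"].nunique() == 1:
            continue
        rho, pval = stats.spearmanr(grp["category"], grp["normalized"])
        rows.append({"term": term, "spearman_rho": rho, "pvalue": pval})
    return pd.DataFrame(rows)
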