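"""Hypergeometric over-representation of annotation categories in gene clusters.

Enrichment of a category within a cluster is quantified two ways, matching
the conventions of classical GO over-representation analysis:

* fold enrichment ``(k/m) / (K/N)`` — the category rate inside the cluster
  over the background rate on the array, where ``k`` is the overlap, ``m``
  the cluster size, ``K`` the category size on the array and ``N`` the
  annotated universe size;
* the hypergeometric upper tail ``P(X >= k)``, one-sided for
  over-representation, BH-adjusted per cluster.

Reported rows are filtered to fold >= 2 and adjusted p <= 0.05, and only
clusters with more than 40 members are examined at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .core import DataError

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "cluster", "category", "description", "k", "m", "K", "N", "fold", "p", "adj_p",
]


@dataclass(frozen=True)
class AnnotationSet:
    """Flat gene-set annotation: category id → member genes, plus a universe.

    The universe is the set of annotated genes present on the array — the
    denominator population of the hypergeometric model. Categories must be
    subsets of it and non-empty.
    """

    categories: Mapping[str, frozenset[str]]
    universe: frozenset[str]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.universe:
            raise DataError("annotation universe is empty")
        for cat, genes in self.categories.items():
            if not genes:
                raise DataError(f"category {cat!r} is empty")
            if not genes <= self.universe:
                stray = sorted(genes - self.universe)[:5]
                raise DataError(f"category {cat!r} has genes outside the universe, e.g. {stray}")

    def restrict_to(self, genes: Iterable[str]) -> "AnnotationSet":
        """Intersect the annotation with an array's gene set.

        Categories that become empty are dropped.
        """
        keep = frozenset(genes) & self.universe
        cats = {c: g & keep for c, g in self.categories.items()}
        cats = {c: frozenset(g) for c, g in cats.items() if g}
        return AnnotationSet(cats, keep, dict(self.descriptions))

    def sizes(self) -> dict[str, int]:
        return {c: len(g) for c, g in self.categories.items()}


def hypergeom_upper_tail(k: int, m: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, m): drawing m genes from a
    universe of N containing K category members."""
    if not (0 <= k <= min(m, K)) or m > N or K > N or min(m, K, N) < 0:
        raise DataError(f"impossible hypergeometric counts k={k}, m={m}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, m))


def fold_enrichment(k: int, m: int, K: int, N: int) -> float:
    """(k/m) / (K/N): cluster category rate over array background rate."""
    if m <= 0 or K <= 0 or N <= 0:
        raise DataError(f"fold enrichment undefined for m={m}, K={K}, N={N}")
    return (k / m) / (K / N)


def enrich_cluster(
    cluster: Iterable[str],
    ann: AnnotationSet,
    *,
    cluster_id: str | int = "cluster",
    min_cluster_size: int = 41,
    fold_min: float = 2.0,
    adjp_max: float = 0.05,
) -> pd.DataFrame:
    """Over-representation rows for one cluster.

    Clusters smaller than ``min_cluster_size`` (i.e. not "more than 40
    transcripts") return an empty frame. Genes outside the annotation
    universe are dropped with a logged count; the cluster size ``m`` counts
    the remaining genes. BH adjustment is applied per cluster across all
    categories with non-zero overlap, then rows are filtered to
    fold >= fold_min and adj_p <= adjp_max, sorted by fold descending.
    """
    from .de import benjamini_hochberg  # local import: de also imports nothing from here

    cluster = set(cluster)
    inside = cluster & ann.universe
    dropped = len(cluster) - len(inside)
    if dropped:
        logger.info("cluster %s: dropped %d genes outside the annotation universe",
                    cluster_id, dropped)
    empty = pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    if len(cluster) < min_cluster_size:
        logger.info("cluster %s: size %d below %d, skipped",
                    cluster_id, len(cluster), min_cluster_size)
        return empty
    N = len(ann.universe)
    m = len(inside)
    rows = []
    for cat, genes in ann.categories.items():
        k = len(inside & genes)
        if k == 0:
            continue
        K = len(genes)
        rows.append({
            "cluster": cluster_id,
            "category": cat,
            "description": ann.descriptions.get(cat, ""),
            "k": k, "m": m, "K": K, "N": N,
            "fold": fold_enrichment(k, m, K, N),
            "p": hypergeom_upper_tail(k, m, K, N),
        })
    if not rows:
        return empty
    table = pd.DataFrame(rows)
    table["adj_p"] = benjamini_hochberg(table["p"].to_numpy())
    table = table[(table["fold"] >= fold_min) & (table["adj_p"] <= adjp_max)]
    return table.sort_values(["fold", "p"], ascending=[False, True]).reset_index(drop=True)


def enrich_assignments(assignments: pd.DataFrame, ann: AnnotationSet, **kwargs) -> pd.DataFrame:
    """Run enrich_cluster over every profile class in an assignment table."""
    pieces = []
    for class_id, group in assignments.groupby("class_id"):
        rows = enrich_cluster(group.index, ann, cluster_id=int(class_id), **kwargs)
        if not rows.empty:
            pieces.append(rows)
    if not pieces:
        return pd.DataFrame(columns=ENRICHMENT_COLUMNS)
    return pd.concat(pieces, ignore_index=True)


def read_gmt(path: str | Path) -> AnnotationSet:
    """Read a GMT file: category <tab> description <tab> gene ids.

    Duplicate genes within a category are deduplicated with a warning;
    malformed lines raise with their line number. The universe is the union
    of all member genes (restrict with :meth:`AnnotationSet.restrict_to`
    for an array-specific universe).
    """
    categories: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: GMT line needs category, "
                                f"description and at least one gene")
            cat, desc, genes = fields[0], fields[1], fields[2:]
            if cat in categories:
                raise DataError(f"{path}:{lineno}: duplicate category {cat!r}")
            if any(not g for g in genes):
                raise DataError(f"{path}:{lineno}: empty gene id")
            unique = frozenset(genes)
            if len(unique) < len(genes):
                logger.warning("%s:%d: %d duplicate genes in %s deduplicated",
                               path, lineno, len(genes) - len(unique), cat)
            categories[cat] = unique
            descriptions[cat] = desc
    if not categories:
        raise DataError(f"{path}: no categories")
    universe = frozenset().union(*categories.values())
    return AnnotationSet(categories, universe, descriptions)


def write_gmt(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as handle:
        for cat in sorted(ann.categories):
            genes = "\t".join(sorted(ann.categories[cat]))
            handle.write(f"{cat}\t{ann.descriptions.get(cat, '')}\t{genes}\n")


def write_enrichment(rows: pd.DataFrame, path: str | Path) -> None:
    rows.to_csv(path, sep="\t", index=False)


def read_enrichment(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
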