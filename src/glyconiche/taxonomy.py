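"""Lowest-common-ancestor taxonomy assignment from multiple database hits.

Each gene may carry several alignment hits, each with a ranked lineage and a
score (bit-score or equivalent). Following the DIAMOND-style convention, hits
within a *top fraction* of the best score are retained and the gene is
assigned the deepest lineage prefix shared by all of them. An empty shared
prefix means the gene is unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .io_tables import GeneRecord, parse_lineage


@dataclass(frozen=True)
class Hit:
    """One database hit: a ranked lineage plus a positive alignment score."""

    lineage: tuple[str, ...]
    score: float

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise ValueError(f"hit score must be > 0, got {self.score}")
        if not self.lineage:
            raise ValueError("hit lineage must be non-empty")


def assign_lca(hits: Iterable[Hit], top_fraction: float = 0.1) -> tuple[str, ...]:
    """LCA lineage of the hits within the top score window.

    Hits with ``score >= (1 - top_fraction) * max_score`` are retained (ties at
    the boundary kept), and the longest lineage prefix common to all retained
    hits is returned — possibly empty, meaning unclassified. The result does
    not depend on hit order.
    """
    hits = list(hits)
    if not hits:
        raise ValueError("assign_lca requires at least one hit")
    if not (0 < top_fraction <= 1):
        raise ValueError(f"top_fraction must be in (0, 1], got {top_fraction}")
    best = max(h.score for h in hits)
    threshold = (1.0 - top_fraction) * best
    retained = [h for h in hits if h.score >= threshold]
    prefix = list(retained[0].lineage)
    for h in retained[1:]:
        depth = 0
        for a, b in zip(prefix, h.lineage):
            if a != b:
                break
            depth += 1
        del prefix[depth:]
        if not prefix:
            break
    return tuple(prefix)


def read_hits_table(path) -> dict[str, list[Hit]]:
    """Read a per-hit TSV (columns gene_id, lineage, score) grouped by gene."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "lineage": str, "score": float})
    for col in ("gene_id", "lineage", "score"):
        if col not in df.columns:
            raise ValueError(f"hits table is missing required column {col!r}")
    out: dict[str, list[Hit]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.gene_id), []).append(
            Hit(parse_lineage(row.lineage), float(row.score))
        )
    return out


def resolve_gene_lineages(
    genes: Iterable[GeneRecord],
    hits_by_gene: Mapping[str, list[Hit]],
    top_fraction: float = 0.1,
) -> list[GeneRecord]:
    """Replace each gene's lineage with the LCA of its hits, where hits exist.

    Genes without hits keep their existing lineage (possibly empty). Returns
    new records; inputs are immutable.
    """
    out = []
    for g in genes:
        hits = hits_by_gene.get(g.gene_id)
        if hits:
            lineage = assign_lca(hits, top_fraction=top_fraction)
        else:
            lineage = g.lineage
        out.append(
            GeneRecord(
                gene_id=g.gene_id,
                contig_id=g.contig_id,
                length_bp=g.length_bp,
                reads_mapped=g.reads_mapped,
                lineage=lineage,
                cazyme_families=g.cazyme_families,
                ko_id=g.ko_id,
                secreted=g.secreted,
                contig_bp=g.contig_bp,
            )
        )
    return out
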