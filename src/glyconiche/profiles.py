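"""Gene-abundance normalization and taxon x CAZyme-family profile matrices.

Abundances are expressed as RPKM::

    RPKM = 1e6 * (reads mapped / gene length in kbp) / library size

Profiles restrict to the degradative CAZyme classes (GH, PL, CE, AA, CBM) by
excluding the biosynthetic GTs, drop genes on short contigs (>500 bp are
kept), aggregate taxa at a chosen rank with an explicit unclassified bucket
so that column totals are conserved, and can be collapsed from enzyme
families to substrate categories with a curated map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .io_tables import (
    DEGRADATIVE_CLASSES,
    GeneRecord,
    SampleMeta,
    SubstrateMap,
    family_class,
    lineage_at_rank,
)

logger = logging.getLogger(__name__)

__all__ = [
    "rpkm",
    "TaxonProfile",
    "ProfileMatrix",
    "build_profile_matrix",
    "family_abundance_matrix",
    "cazyme_gene_frequency",
    "to_proportions",
    "substrate_aggregate",
    "niche_table",
]


def rpkm(reads_mapped, length_bp, total_reads):
    """Reads per kilobase of gene per million library reads.

    Accepts scalars or aligned arrays. ``length_bp`` and ``total_reads`` must
    be positive.
    """
    length_bp = np.asarray(length_bp, dtype=float)
    total_reads = np.asarray(total_reads, dtype=float)
    if np.any(length_bp <= 0):
        raise ValueError("length_bp must be positive")
    if np.any(total_reads <= 0):
        raise ValueError("total_reads must be positive")
    value = 1e6 * (np.asarray(reads_mapped, dtype=float) / (length_bp / 1000.0)) / total_reads
    return float(value) if np.ndim(value) == 0 else value


@dataclass(frozen=True)
class TaxonProfile:
    """One taxon's RPKM distribution over CAZyme families in one sample."""

    taxon: str
    sample_id: str
    abundance: pd.Series  # family -> RPKM

    @property
    def N_i(self) -> float:
        """Total degradative CAZyme RPKM of the taxon."""
        return float(self.abundance.sum())


@dataclass(frozen=True)
class ProfileMatrix:
    """Taxa (rows) x CAZyme families (columns) RPKM matrix for one sample."""

    data: pd.DataFrame
    sample_id: str
    rank: str

    def profile(self, taxon: str) -> TaxonProfile:
        return TaxonProfile(taxon, self.sample_id, self.data.loc[taxon])

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def families(self) -> list[str]:
        return list(self.data.columns)


def _taxon_label(gene: GeneRecord, rank: str) -> str:
    name = lineage_at_rank(gene.lineage, rank)
    return name if name is not None else f"unclassified_{rank}"


def _passes_filters(
    gene: GeneRecord,
    exclude_classes: frozenset[str],
    contig_min_bp: int,
    secreted_only: bool,
) -> bool:
    if gene.effective_contig_bp <= contig_min_bp:
        return False
    if secreted_only and not gene.secreted:
        return False
    return any(family_class(f) not in exclude_classes for f in gene.cazyme_families)


def build_profile_matrix(
    genes: Iterable[GeneRecord],
    samples: Mapping[str, SampleMeta],
    sample_id: str,
    rank: str = "genus",
    exclude_classes: Iterable[str] = ("GT",),
    contig_min_bp: int = 500,
    secreted_only: bool = False,
    multi_domain: str = "full",
) -> ProfileMatrix:
    """Aggregate gene RPKM into a taxon x family matrix for one sample.

    * genes on contigs <= ``contig_min_bp`` are excluded (the strict ">" of
      the contig rule: 501 bp passes);
    * families whose class prefix is in ``exclude_classes`` (default the
      biosynthetic GTs) never appear as columns;
    * taxa are aggregated at ``rank``; genes that cannot be resolved at that
      rank land in an ``unclassified_<rank>`` bucket so column totals equal
      the sample-wide family totals;
    * ``multi_domain="full"`` adds the gene's full RPKM to every family it
      carries (family-level tallies of domain annotations);
      ``"split"`` divides the RPKM equally among its families;
    * ``secreted_only=True`` restricts to genes flagged secreted (for the
      secreted-CAZyme pool analysis).
    """
    if sample_id not in samples:
        raise KeyError(f"unknown sample_id {sample_id!r}; declared samples: {sorted(samples)}")
    if multi_domain not in ("full", "split"):
        raise ValueError(f"multi_domain must be 'full' or 'split', got {multi_domain!r}")
    exclude = frozenset(exclude_classes)
    total_reads = samples[sample_id].total_reads

    cells: dict[tuple[str, str], float] = {}
    n_used = 0
    for g in genes:
        if not g.cazyme_families:
            continue
        if not _passes_filters(g, exclude, contig_min_bp, secreted_only):
            continue
        fams = sorted(f for f in g.cazyme_families if family_class(f) not in exclude)
        if not fams:
            continue
        value = rpkm(g.reads_mapped.get(sample_id, 0), g.length_bp, total_reads)
        if multi_domain == "split":
            value /= len(fams)
        taxon = _taxon_label(g, rank)
        for fam in fams:
            cells[(taxon, fam)] = cells.get((taxon, fam), 0.0) + value
        n_used += 1

    if cells:
        ser = pd.Series(cells)
        data = ser.unstack(fill_value=0.0)
        data = data.reindex(sorted(data.index), axis=0).reindex(sorted(data.columns), axis=1)
    else:
        data = pd.DataFrame(dtype=float)
    logger.info(
        "build_profile_matrix[%s@%s]: %d genes aggregated into %d taxa x %d families",
        sample_id, rank, n_used, data.shape[0], data.shape[1],
    )
    return ProfileMatrix(data=data, sample_id=sample_id, rank=rank)


def family_abundance_matrix(
    genes: Iterable[GeneRecord],
    samples: Mapping[str, SampleMeta],
    exclude_classes: Iterable[str] = ("GT",),
    contig_min_bp: int = 500,
    secreted_only: bool = False,
) -> pd.DataFrame:
    """Sample x family RPKM matrix over all samples (community level).

    This is the input to ordination and group comparisons: the taxon
    dimension is summed out.
    """
    exclude = frozenset(exclude_classes)
    genes = list(genes)
    rows = {}
    for sid, meta in samples.items():
        acc: dict[str, float] = {}
        for g in genes:
            if not g.cazyme_families:
                continue
            if not _passes_filters(g, exclude, contig_min_bp, secreted_only):
                continue
            value = rpkm(g.reads_mapped.get(sid, 0), g.length_bp, meta.total_reads)
            for fam in g.cazyme_families:
                if family_class(fam) in exclude:
                    continue
                acc[fam] = acc.get(fam, 0.0) + value
        rows[sid] = acc
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    return df.reindex(sorted(df.columns), axis=1)


def cazyme_gene_frequency(
    genes: Iterable[GeneRecord],
    classes: Iterable[str] = ("GH", "CBM", "CE", "PL"),
) -> float:
    """Percentage of predicted genes carrying >= 1 family from the class set.

    Gene-count based (not abundance weighted); the conventional class set
    excludes AAs, but any subset of classes may be requested.
    """
    class_set = frozenset(classes)
    total = 0
    hits = 0
    for g in genes:
        total += 1
        if any(family_class(f) in class_set for f in g.cazyme_families):
            hits += 1
    if total == 0:
        raise ValueError("cazyme_gene_frequency requires at least one gene")
    return 100.0 * hits / total


def to_proportions(profile) -> pd.Series:
    """Normalize a taxon's family abundances to proportions p_j = a_j / N_i.

    Accepts a :class:`TaxonProfile` or a plain abundance Series. A taxon with
    zero total degradative abundance has no glycan niche, so it is an error.
    """
    if isinstance(profile, TaxonProfile):
        name, abundance = profile.taxon, profile.abundance
    else:
        abundance = pd.Series(profile, dtype=float)
        name = abundance.name or "<profile>"
    if (np.asarray(abundance) < 0).any():
        raise ValueError(f"taxon {name!r}: negative abundance")
    total = float(abundance.sum())
    if total <= 0:
        raise ValueError(f"taxon {name!r} has no degradative CAZyme abundance (N_i = 0)")
    return abundance / total


def substrate_aggregate(matrix: ProfileMatrix, smap: SubstrateMap) -> ProfileMatrix:
    """Collapse family columns into substrate-category columns.

    A family mapped to several categories contributes its full abundance to
    each (multi-mapping). Families absent from the map accumulate in an
    ``"unmapped"`` column so that total abundance is conserved and the gap is
    visible rather than silent.
    """
    data = matrix.data
    out: dict[str, pd.Series] = {}
    unmapped_families = []
    for fam in data.columns:
        cats = smap.categories(fam)
        if not cats:
            unmapped_families.append(fam)
            cats = frozenset({"unmapped"})
        for cat in cats:
            if cat in out:
                out[cat] = out[cat] + data[fam]
            else:
                out[cat] = data[fam].copy()
    if unmapped_families:
        logger.info(
            "substrate_aggregate[%s]: %d unmapped families: %s",
            matrix.sample_id, len(unmapped_families), ", ".join(unmapped_families),
        )
    agg = pd.DataFrame(out)
    agg = agg.reindex(sorted(agg.columns), axis=1)
    return ProfileMatrix(data=agg, sample_id=matrix.sample_id, rank=matrix.rank)


def niche_table(matrix: ProfileMatrix, n: Optional[int] = None, min_total: float = 0.0) -> pd.DataFrame:
    """Per-taxon niche metrics (B, B_A, B_i, N_i) for a profile matrix.

    ``n`` is the dataset-wide count of predicted degradative families used to
    standardize Levins B; it defaults to the number of family columns. Taxa
    with total abundance <= ``min_total`` are skipped (they have no niche).
    """
    from .niche import levins_B, levins_standardized, shannon

    if n is None:
        n = matrix.data.shape[1]
    rows = []
    for taxon in matrix.taxa:
        abundance = matrix.data.loc[taxon]
        total = float(abundance.sum())
        if total <= min_total:
            continue
        p = (abundance / total).to_numpy()
        rows.append(
            {
                "taxon": taxon,
                "N_i": total,
                "B": levins_B(p),
                "B_A": levins_standardized(p, n),
                "B_i": shannon(p),
                "n_families_present": int((abundance > 0).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("taxon") if rows else pd.DataFrame(
        columns=["N_i", "B", "B_A", "B_i", "n_families_present"]
    )
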