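"""Carbohydrate-transporter profiling and uptake-strategy scoring.

Transporter genes (identified by their KEGG KO ids) are aggregated per taxon
into the five sugar-transport classes ABC, PTS, MFS, TonB and SusC. A
taxon's class fractions are then mapped onto the sharer / scavenger /
selfish typology of microbial polysaccharide processing:

* **scavenger** — dominated by low-specificity ABC transporters, taking up
  monomers and oligomers released by others;
* **selfish** — dominated by SusC-like TonB-dependent outer-membrane
  transporters, importing oligosaccharides with little diffusive loss;
* **sharer** — dominated by substrate-specific importers (PTS + MFS + TonB)
  while also secreting an appreciable fraction of its CAZymes for external
  hydrolysis.

The labelling rule is an explicit operationalization (strict argmax over the
three fraction groups; sharer additionally requires a secreted-CAZyme
fraction >= 0.25). The rule and its threshold are echoed in every score so
downstream users can see exactly how a label was produced.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .io_tables import RANKS, GeneRecord, SampleMeta, TransporterKOMap
from .profiles import _taxon_label, rpkm

__all__ = [
    "TransporterProfile",
    "TransporterReport",
    "classify_transporters",
    "StrategyScore",
    "strategy_score",
]

#: classes counted as "substrate-specific" importers for the sharer fraction
SPECIFIC_CLASSES = ("PTS", "MFS", "TonB")

DEFAULT_SECRETED_THRESHOLD = 0.25


@dataclass(frozen=True)
class TransporterProfile:
    """Per-taxon transporter RPKM by class and by KO for one sample."""

    taxon: str
    sample_id: str
    class_abundance: Mapping[str, float]
    ko_abundance: Mapping[str, float]

    @property
    def total(self) -> float:
        return float(sum(self.class_abundance.values()))


@dataclass(frozen=True)
class TransporterReport:
    """Classification output plus the conservation accounting."""

    profiles: tuple[TransporterProfile, ...]
    unmapped_kos: Counter = field(default_factory=Counter)
    n_genes_mapped: int = 0
    n_genes_unmapped: int = 0

    def by_taxon(self) -> dict[str, TransporterProfile]:
        return {p.taxon: p for p in self.profiles}


def classify_transporters(
    genes: Iterable[GeneRecord],
    ko_map: TransporterKOMap,
    rank: str,
    sample_id: str,
    samples: Mapping[str, SampleMeta],
) -> TransporterReport:
    """Aggregate transporter-gene RPKM per taxon at ``rank`` by class and KO.

    Genes whose KO is absent from the map are counted in the unmapped report
    and excluded from class totals (never silently dropped).
    """
    if rank not in RANKS:
        raise ValueError(f"unsupported rank {rank!r}; choose one of {RANKS}")
    if sample_id not in samples:
        raise KeyError(f"unknown sample_id {sample_id!r}")
    total_reads = samples[sample_id].total_reads

    class_acc: dict[str, dict[str, float]] = {}
    ko_acc: dict[str, dict[str, float]] = {}
    unmapped: Counter = Counter()
    n_mapped = n_unmapped = 0
    for g in genes:
        if g.ko_id is None:
            continue
        if g.ko_id not in ko_map:
            unmapped[g.ko_id] += 1
            n_unmapped += 1
            continue
        n_mapped += 1
        taxon = _taxon_label(g, rank)
        value = rpkm(g.reads_mapped.get(sample_id, 0), g.length_bp, total_reads)
        cls_ = ko_map[g.ko_id]
        class_acc.setdefault(taxon, {}).setdefault(cls_, 0.0)
        class_acc[taxon][cls_] += value
        ko_acc.setdefault(taxon, {}).setdefault(g.ko_id, 0.0)
        ko_acc[taxon][g.ko_id] += value

    profiles = tuple(
        TransporterProfile(
            taxon=t,
            sample_id=sample_id,
            class_abundance=dict(sorted(class_acc[t].items())),
            ko_abundance=dict(sorted(ko_acc[t].items())),
        )
        for t in sorted(class_acc)
    )
    return TransporterReport(
        profiles=profiles,
        unmapped_kos=unmapped,
        n_genes_mapped=n_mapped,
        n_genes_unmapped=n_unmapped,
    )


@dataclass(frozen=True)
class StrategyScore:
    """Fractional transporter makeup and the derived strategy label."""

    taxon: str
    f_ABC: float
    f_specific: float  # PTS + MFS + TonB
    f_SusC: float
    label: str  # scavenger | sharer | selfish | mixed
    secreted_cazyme_fraction: float
    rule: str

    def fractions(self) -> dict[str, float]:
        return {"f_ABC": self.f_ABC, "f_specific": self.f_specific, "f_SusC": self.f_SusC}


def strategy_score(
    profile: TransporterProfile,
    secreted_cazyme_fraction: float,
    secreted_threshold: float = DEFAULT_SECRETED_THRESHOLD,
) -> StrategyScore:
    """Score a taxon against the sharer / scavenger / selfish typology.

    The label is a strict argmax over (f_ABC, f_specific, f_SusC):
    scavenger when ABC strictly dominates, selfish when SusC strictly
    dominates, sharer when the specific importers strictly dominate *and*
    ``secreted_cazyme_fraction >= secreted_threshold``; any tie, or a
    specific-dominant taxon below the secretion threshold, is ``mixed``.
    """
    if not (0.0 <= secreted_cazyme_fraction <= 1.0):
        raise ValueError("secreted_cazyme_fraction must be in [0, 1]")
    total = profile.total
    if total <= 0:
        raise ValueError(f"taxon {profile.taxon!r}: zero total transporter abundance")
    ca = profile.class_abundance
    f_abc = ca.get("ABC", 0.0) / total
    f_spec = sum(ca.get(c, 0.0) for c in SPECIFIC_CLASSES) / total
    f_susc = ca.get("SusC", 0.0) / total

    fractions = {"scavenger": f_abc, "sharer": f_spec, "selfish": f_susc}
    best = max(fractions.values())
    winners = [k for k, v in fractions.items() if v == best]
    if len(winners) != 1:
        label = "mixed"
    else:
        label = winners[0]
        if label == "sharer" and secreted_cazyme_fraction < secreted_threshold:
            label = "mixed"
    rule = (
        "strict argmax over (f_ABC, f_specific=PTS+MFS+TonB, f_SusC); "
        f"sharer requires secreted_cazyme_fraction >= {secreted_threshold}; ties -> mixed"
    )
    return StrategyScore(
        taxon=profile.taxon,
        f_ABC=f_abc,
        f_specific=f_spec,
        f_SusC=f_susc,
        label=label,
        secreted_cazyme_fraction=secreted_cazyme_fraction,
        rule=rule,
    )


def strategy_table(
    report: TransporterReport,
    secreted_fractions: Mapping[str, float],
    secreted_threshold: float = DEFAULT_SECRETED_THRESHOLD,
) -> pd.DataFrame:
    """Strategy scores for every profiled taxon, as a tidy DataFrame."""
    rows = []
    for p in report.profiles:
        s = strategy_score(p, secreted_fractions.get(p.taxon, 0.0), secreted_threshold)
        rows.append(
            {
                "taxon": s.taxon,
                "f_ABC": s.f_ABC,
                "f_specific": s.f_specific,
                "f_SusC": s.f_SusC,
                "secreted_cazyme_fraction": s.secreted_cazyme_fraction,
                "label": s.label,
                "total_rpkm": p.total,
            }
        )
    df = pd.DataFrame(rows).set_index("taxon") if rows else pd.DataFrame()
    df.attrs["rule"] = (
        "strict argmax over (f_ABC, f_specific=PTS+MFS+TonB, f_SusC); "
        f"sharer requires secreted_cazyme_fraction >= {secreted_threshold}; ties -> mixed"
    )
    return df
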