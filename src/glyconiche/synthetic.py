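"""Synthetic taxon-structured CAZyme communities with closed-form truth.

The generator emulates the statistical structure that the niche metrics
assume: each taxon owns a proportion vector ``p`` over degradative CAZyme
families (drawn from a symmetric Dirichlet whose concentration controls
evenness, hence niche width), pairwise overlap is planted by mixing a shared
uniform component with weight ``s`` (``p = (1 - s) * private + s * shared``),
and per-sample read counts are multinomial draws over genes with expected
mass proportional to family proportion x gene length x group effect. The
exact generating proportions are recorded, and all truth metrics are
computed from them by an independent straightforward oracle (plain loops) —
never by the package's own niche functions — so recovery tests compare two
independent routes.

Gene lengths are log-normal, bounded below at 500 bp so the contig-length
filter interacts predictably with fixtures (an explicit short-contig
spike-in exercises the filter). Transporter genes follow per-taxon KO
spectra shaped like the scavenger / selfish / sharer archetypes. Everything
derives from a single mandatory seed and is byte-identical across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io_tables import (
    GeneRecord,
    SampleMeta,
    write_gene_table,
    write_sample_metadata,
)

__all__ = ["SimConfig", "SimTruth", "SimResult", "simulate", "truth_metrics", "write_fixture"]

#: sample-group label -> (fraction, layer)
GROUP_META = {
    "SF": ("FL", "surface"),
    "SP": ("PA", "surface"),
    "BF": ("FL", "bottom"),
    "BP": ("PA", "bottom"),
    "S": ("sediment", "sediment"),
}

_DEGRADATIVE_CYCLE = ("GH", "PL", "CE", "AA", "CBM")

#: default per-taxon transporter KO spectra (relative weights) shaped like
#: the scavenger (ABC-heavy), selfish (SusC/TonB-heavy) and sharer
#: (specific-importer-heavy) archetypes; remaining taxa carry none.
DEFAULT_TRANSPORTER_SPECTRA: dict[int, dict[str, float]] = {
    0: {"K02027": 3.0, "K02056": 3.0, "K02058": 2.0, "K02026": 2.0},
    1: {"K21573": 5.0, "K03832": 2.0},
    2: {"K02429": 3.0, "K02777": 2.0, "K03832": 2.0, "K02027": 1.0},
}


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the bundled study-like conditions
    (5 taxa, 40 degradative families, 1e5 reads per sample)."""

    seed: int
    n_taxa: int = 5
    n_families: int = 40
    #: symmetric Dirichlet concentration per taxon (scalar broadcasts);
    #: small -> specialist (narrow niche), large -> even generalist
    alpha: float | Sequence[float] = 1.0
    #: planted overlap: (taxon_i, taxon_k, shared-mass fraction s in [0, 1])
    overlap_design: tuple[tuple[int, int, float], ...] = ((0, 1, 0.6), (2, 3, 0.3))
    #: sample_id -> group label in {SF, SP, BF, BP, S}
    group_design: Mapping[str, str] = field(
        default_factory=lambda: {
            "ST01SF": "SF",
            "ST01SP": "SP",
            "ST01BF": "BF",
            "ST01BP": "BP",
            "ST01S": "S",
        }
    )
    #: group label -> {family label -> abundance multiplier}
    group_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    genes_per_taxon: int = 200
    total_reads: int = 100_000
    taxon_weights: Optional[Sequence[float]] = None
    #: optional per-taxon family index sets (into the family list); default all
    family_sets: Optional[Mapping[int, Sequence[int]]] = None
    length_log_mean: float = math.log(1000.0)
    length_log_sigma: float = 0.35
    length_bounds: tuple[int, int] = (500, 5000)
    transporter_spectra: Mapping[int, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TRANSPORTER_SPECTRA.items()}
    )
    #: transporter read mass per taxon, relative to its CAZyme mass
    transporter_rel_mass: float = 0.05
    secreted_fraction: float | Mapping[int, float] = 0.3
    n_background_genes: int = 0
    background_rel_mass: float = 1.0
    #: biosynthetic GT decoy families, excluded by the profiling step
    n_gt_decoys: int = 2
    gt_rel_mass: float = 0.05
    #: flanking contig sequence beyond the gene; keeps every real gene's
    #: contig strictly above the 500 bp filter even at the length floor
    contig_overhead_bp: int = 150
    #: spike-in genes on 400 bp contigs (removed by the >500 bp filter)
    n_short_contig_spikes: int = 0
    #: Dirichlet-multinomial overdispersion (concentration scale); None = pure
    #: multinomial read sampling
    overdispersion: Optional[float] = None

    def validate(self) -> None:
        if self.n_taxa < 1 or self.n_families < 2:
            raise ValueError("need n_taxa >= 1 and n_families >= 2")
        if self.genes_per_taxon < 1 or self.total_reads < 1:
            raise ValueError("genes_per_taxon and total_reads must be positive")
        alphas = self.alphas()
        if np.any(np.asarray(alphas) <= 0):
            raise ValueError("Dirichlet concentration alpha must be > 0")
        seen: set[int] = set()
        sets = self.resolved_family_sets()
        for i, k, s in self.overlap_design:
            if not (0 <= i < self.n_taxa and 0 <= k < self.n_taxa and i != k):
                raise ValueError(f"overlap pair ({i}, {k}) out of range")
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"shared-mass fraction s={s} outside [0, 1]")
            if i in seen or k in seen:
                raise ValueError(
                    "infeasible overlap design: a taxon appears in more than one pair"
                )
            seen.update((i, k))
            if s > 0 and not (set(sets[i]) & set(sets[k])):
                raise ValueError(
                    f"infeasible overlap design: taxa {i} and {k} share no families but s={s} > 0"
                )
        for t, fams in sets.items():
            if len(fams) == 0:
                raise ValueError(f"taxon {t} has an empty family set")
            if self.genes_per_taxon < len(fams):
                raise ValueError(
                    f"genes_per_taxon={self.genes_per_taxon} < family-set size {len(fams)} "
                    f"for taxon {t}; every supported family needs at least one gene"
                )
        for sid, grp in self.group_design.items():
            if grp not in GROUP_META:
                raise ValueError(f"sample {sid!r}: unknown group label {grp!r}")
        if self.taxon_weights is not None and len(self.taxon_weights) != self.n_taxa:
            raise ValueError("taxon_weights length must equal n_taxa")

    # -- resolved views -----------------------------------------------------

    def alphas(self) -> np.ndarray:
        a = np.asarray(self.alpha, dtype=float)
        return np.full(self.n_taxa, float(a)) if a.ndim == 0 else a

    def family_labels(self) -> list[str]:
        return [f"{_DEGRADATIVE_CYCLE[j % 5]}{j + 1}" for j in range(self.n_families)]

    def gt_decoy_labels(self) -> list[str]:
        return [f"GT{900 + j}" for j in range(self.n_gt_decoys)]

    def taxon_names(self) -> list[str]:
        return [f"Simgenus{i + 1:02d}" for i in range(self.n_taxa)]

    def taxon_lineage(self, i: int) -> tuple[str, ...]:
        t = i + 1
        return (
            "d__Bacteria",
            f"p__Simphylum{t:02d}",
            f"c__Simclass{t:02d}",
            f"o__Simorder{t:02d}",
            f"f__Simfam{t:02d}",
            f"g__Simgenus{t:02d}",
        )

    def resolved_family_sets(self) -> dict[int, tuple[int, ...]]:
        if self.family_sets is None:
            return {i: tuple(range(self.n_families)) for i in range(self.n_taxa)}
        return {i: tuple(self.family_sets.get(i, range(self.n_families))) for i in range(self.n_taxa)}

    def secreted_fraction_of(self, i: int) -> float:
        if isinstance(self.secreted_fraction, Mapping):
            return float(self.secreted_fraction.get(i, 0.0))
        return float(self.secreted_fraction)


# ---------------------------------------------------------------------------
# independent truth oracle (plain loops, no calls into glyconiche.niche)
# ---------------------------------------------------------------------------

def _oracle_levins(p: Sequence[float]) -> float:
    return 1.0 / math.fsum(v * v for v in p)


def _oracle_levins_std(p: Sequence[float], n: int) -> float:
    return (_oracle_levins(p) - 1.0) / (n - 1.0)


def _oracle_shannon(p: Sequence[float]) -> float:
    return -math.fsum(v * math.log(v) for v in p if v > 0)


def _oracle_morisita_horn(pa: Sequence[float], pb: Sequence[float]) -> float:
    num = 2.0 * math.fsum(a * b for a, b in zip(pa, pb))
    den = math.fsum(a * a for a in pa) + math.fsum(b * b for b in pb)
    return num / den


@dataclass(frozen=True)
class SimTruth:
    """Exact metric values implied by the generating proportions."""

    proportions: pd.DataFrame  # taxa x families, rows sum to 1
    niche: pd.DataFrame  # per taxon: B, B_A, B_i
    overlap: pd.DataFrame  # taxa x taxa Morisita-Horn
    n_families: int
    group_effects: Mapping[str, Mapping[str, float]]

    def differential_families(self, fold: float = 1.0) -> dict[str, set[str]]:
        """Families planted with a group multiplier ratio exceeding ``fold``."""
        out: dict[str, set[str]] = {}
        for grp, effects in self.group_effects.items():
            out[grp] = {f for f, m in effects.items() if m >= fold or (m > 0 and 1.0 / m >= fold)}
        return out


def truth_metrics(
    proportions: pd.DataFrame,
    n_families: int,
    group_effects: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> SimTruth:
    """Exact B, B_A, B_i and pairwise O for known proportion vectors.

    Deliberately naive (per-element Python loops with ``math.fsum``) so it
    stays independent of the vectorized production implementations it is
    used to check.
    """
    taxa = list(proportions.index)
    niche_rows = []
    for t in taxa:
        p = [v for v in proportions.loc[t].tolist() if v > 0]
        niche_rows.append(
            {
                "taxon": t,
                "B": _oracle_levins(p),
                "B_A": _oracle_levins_std(p, n_families),
                "B_i": _oracle_shannon(p),
            }
        )
    overlap = pd.DataFrame(np.eye(len(taxa)), index=taxa, columns=taxa)
    for a_i in range(len(taxa)):
        for b_i in range(a_i + 1, len(taxa)):
            pa = proportions.iloc[a_i].tolist()
            pb = proportions.iloc[b_i].tolist()
            o = _oracle_morisita_horn(pa, pb)
            overlap.iloc[a_i, b_i] = o
            overlap.iloc[b_i, a_i] = o
    return SimTruth(
        proportions=proportions,
        niche=pd.DataFrame(niche_rows).set_index("taxon"),
        overlap=overlap,
        n_families=n_families,
        group_effects=dict(group_effects or {}),
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimResult:
    genes: tuple[GeneRecord, ...]
    samples: dict[str, SampleMeta]
    truth: SimTruth
    config: SimConfig


def _draw_proportions(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Per-taxon generating proportions over the degradative families."""
    labels = config.family_labels()
    sets = config.resolved_family_sets()
    alphas = config.alphas()
    P = np.zeros((config.n_taxa, config.n_families))
    private = {}
    for i in range(config.n_taxa):
        idx = np.asarray(sets[i])
        private[i] = rng.dirichlet(np.full(idx.size, alphas[i]))
        P[i, idx] = private[i]
    for i, k, s in config.overlap_design:
        common = sorted(set(sets[i]) & set(sets[k]))
        if s == 0 or not common:
            continue
        shared = np.zeros(config.n_families)
        shared[np.asarray(common)] = 1.0 / len(common)
        for t in (i, k):
            P[t] = (1.0 - s) * P[t] + s * shared
    return pd.DataFrame(P, index=config.taxon_names(), columns=labels)


def simulate(config: SimConfig) -> SimResult:
    """Generate a gene annotation table, sample metadata and exact truth.

    Output tables pass ``io_tables`` validation; identical configs (same
    seed) produce byte-identical outputs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = config.family_labels()
    sets = config.resolved_family_sets()
    weights = (
        np.full(config.n_taxa, 1.0 / config.n_taxa)
        if config.taxon_weights is None
        else np.asarray(config.taxon_weights, dtype=float) / np.sum(config.taxon_weights)
    )
    proportions = _draw_proportions(config, rng)
    truth = truth_metrics(proportions, config.n_families, config.group_effects)

    lo, hi = config.length_bounds

    def draw_length() -> int:
        return int(np.clip(rng.lognormal(config.length_log_mean, config.length_log_sigma), lo, hi))

    genes: list[dict] = []  # staged rows: mass, families, taxon, ...

    def stage(taxon_i, families, mass, *, length=None, contig_bp=None, ko=None, secreted=None):
        length = draw_length() if length is None else length
        genes.append(
            {
                "taxon": taxon_i,
                "families": tuple(families),
                "mass": float(mass),
                "length": int(length),
                "contig_bp": int(contig_bp) if contig_bp is not None
                else int(length) + config.contig_overhead_bp,
                "ko": ko,
                "secreted": secreted,
            }
        )

    # CAZyme genes: one gene per supported family first (so the planted
    # family mass is always representable), then extras drawn from p; a
    # family's mass splits equally over its genes.
    for i in range(config.n_taxa):
        idx = list(sets[i])
        p_i = proportions.iloc[i].to_numpy()[idx]
        n_extra = config.genes_per_taxon - len(idx)
        extra = rng.choice(len(idx), size=n_extra, p=p_i) if n_extra > 0 else np.array([], int)
        counts = np.bincount(extra, minlength=len(idx)) + 1
        sec_frac = config.secreted_fraction_of(i)
        for j_local, fam_idx in enumerate(idx):
            fam_mass = weights[i] * p_i[j_local] / counts[j_local]
            for _ in range(counts[j_local]):
                stage(
                    i,
                    [labels[fam_idx]],
                    fam_mass,
                    secreted=bool(rng.random() < sec_frac),
                )

    mean_caz_mass = float(np.mean([g["mass"] for g in genes])) if genes else 1.0

    # GT decoy genes: excluded by default profiling, present in the table
    for d, gt_label in enumerate(config.gt_decoy_labels()):
        taxon_i = d % config.n_taxa
        stage(taxon_i, [gt_label], config.gt_rel_mass * weights[taxon_i], secreted=False)

    # short-contig spike-ins: real mass, but dropped by the >500 bp filter
    for s_i in range(config.n_short_contig_spikes):
        taxon_i = s_i % config.n_taxa
        fam = labels[sets[taxon_i][0]]
        stage(taxon_i, [fam], mean_caz_mass, length=350, contig_bp=400, secreted=False)

    # transporter genes
    for i in range(config.n_taxa):
        spectrum = config.transporter_spectra.get(i, {})
        if not spectrum:
            continue
        total_w = sum(spectrum.values())
        for ko, w in spectrum.items():
            stage(i, [], config.transporter_rel_mass * weights[i] * w / total_w, ko=ko)

    # background genes (no CAZyme families, no KO): the gene-frequency denominator
    for b in range(config.n_background_genes):
        stage(b % config.n_taxa, [], config.background_rel_mass * mean_caz_mass)

    # per-sample read sampling
    masses = np.array([g["mass"] for g in genes])
    lengths_kb = np.array([g["length"] for g in genes]) / 1000.0
    sample_reads: dict[str, np.ndarray] = {}
    for sid, grp in config.group_design.items():
        effects = config.group_effects.get(grp, {})
        mult = np.array(
            [
                float(np.prod([effects.get(f, 1.0) for f in g["families"]])) if g["families"] else 1.0
                for g in genes
            ]
        )
        w = masses * lengths_kb * mult
        probs = w / w.sum()
        if config.overdispersion is not None:
            probs = rng.dirichlet(probs * config.overdispersion)
        sample_reads[sid] = rng.multinomial(config.total_reads, probs)

    records = []
    for gi, g in enumerate(genes):
        records.append(
            GeneRecord(
                gene_id=f"g{gi + 1:06d}",
                contig_id=f"c{gi + 1:06d}",
                length_bp=g["length"],
                reads_mapped={sid: int(sample_reads[sid][gi]) for sid in config.group_design},
                lineage=config.taxon_lineage(g["taxon"]),
                cazyme_families=frozenset(g["families"]),
                ko_id=g["ko"],
                secreted=g["secreted"],
                contig_bp=g["contig_bp"],
            )
        )
    samples = {
        sid: SampleMeta(
            sample_id=sid,
            fraction=GROUP_META[grp][0],
            layer=GROUP_META[grp][1],
            station="SIM01",
            total_reads=config.total_reads,
        )
        for sid, grp in config.group_design.items()
    }
    return SimResult(genes=tuple(records), samples=samples, truth=truth, config=config)


def write_fixture(result: SimResult, out_dir) -> dict[str, Path]:
    """Write the io_tables-format TSVs plus the truth tables to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "genes.tsv",
        "metadata": out / "metadata.tsv",
        "truth_proportions": out / "truth_proportions.tsv",
        "truth_niche": out / "truth_niche.tsv",
        "truth_overlap": out / "truth_overlap.tsv",
    }
    write_gene_table(result.genes, result.samples, paths["genes"])
    write_sample_metadata(result.samples, paths["metadata"])
    result.truth.proportions.to_csv(paths["truth_proportions"], sep="\t")
    result.truth.niche.to_csv(paths["truth_niche"], sep="\t")
    result.truth.overlap.to_csv(paths["truth_overlap"], sep="\t")
    return paths


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Same conditions, different seed (for replicate studies)."""
    return replace(config, seed=seed)
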