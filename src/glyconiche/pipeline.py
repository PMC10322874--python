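"""End-to-end orchestration: tables in, full glycan-niche report out.

``run_pipeline`` chains the stages in order — validation, optional LCA
taxonomy, per-sample profile matrices, niche metrics, overlap matrices
(full + printed lower-triangle layout), substrate-category matrices,
transporter strategy profiles, and the group comparison (Wilcoxon screen
with BH control, Bray-Curtis, PCoA, PERMANOVA) — and writes a machine
readable manifest with a checksum for every output, so a run can be audited
and reproduced from the manifest alone. Logging is per stage with record
counts in and out.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd
import yaml

from . import __version__
from .io_tables import (
    SubstrateMap,
    TransporterKOMap,
    read_gene_table,
    read_mapping_table,
    read_sample_metadata,
    write_matrix,
)
from .niche import overlap_matrix
from .profiles import (
    build_profile_matrix,
    family_abundance_matrix,
    cazyme_gene_frequency,
    niche_table,
    substrate_aggregate,
)
from .compare import bray_curtis, pcoa, permanova, wilcoxon_screen
from .taxonomy import read_hits_table, resolve_gene_lineages
from .transporters import classify_transporters, strategy_table

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    genes: str
    metadata: str
    out_dir: str
    seed: int
    hits: Optional[str] = None
    substrate_map: Optional[str] = None
    transporter_map: Optional[str] = None
    rank: str = "genus"
    exclude_classes: tuple[str, ...] = ("GT",)
    contig_min_bp: int = 500
    top_fraction: float = 0.1
    n_permutations: int = 999
    #: metadata column used as the PERMANOVA / Wilcoxon grouping factor
    compare_on: str = "fraction"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "exclude_classes" in raw:
            raw["exclude_classes"] = tuple(raw["exclude_classes"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _design_from_metadata(samples, compare_on: str) -> dict[str, str]:
    if compare_on == "fraction":
        # FL vs PA within the water column
        return {s.sample_id: s.fraction for s in samples.values() if s.fraction != "sediment"}
    if compare_on == "habitat":
        return {s.sample_id: ("sediment" if s.layer == "sediment" else "water") for s in samples.values()}
    if compare_on == "layer":
        return {s.sample_id: s.layer for s in samples.values() if s.layer != "sediment"}
    raise ValueError(f"unknown compare_on {compare_on!r}; expected fraction|habitat|layer")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest dictionary (also written to
    ``<out_dir>/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "validate"
    try:
        samples = read_sample_metadata(config.metadata)
        genes = read_gene_table(config.genes, samples)
        logger.info("stage validate: %d genes, %d samples", len(genes), len(samples))

        if config.hits:
            stage = "lca"
            hits = read_hits_table(config.hits)
            genes = resolve_gene_lineages(genes, hits, top_fraction=config.top_fraction)
            logger.info("stage lca: lineages resolved for %d genes with hits", len(hits))

        stage = "mapping_tables"
        smap: SubstrateMap = read_mapping_table(config.substrate_map, kind="substrate")
        tmap: TransporterKOMap = read_mapping_table(config.transporter_map, kind="transporter")

        stage = "profiles"
        niche_frames = []
        strategy_frames = []
        for sid in samples:
            pm = build_profile_matrix(
                genes,
                samples,
                sid,
                rank=config.rank,
                exclude_classes=config.exclude_classes,
                contig_min_bp=config.contig_min_bp,
            )
            p_path = out / f"profile_{sid}.tsv"
            write_matrix(pm.data, p_path)
            outputs[f"profile_{sid}"] = p_path
            if pm.data.empty:
                continue

            nt = niche_table(pm)
            nt.insert(0, "sample_id", sid)
            niche_frames.append(nt)

            if pm.data.shape[0] >= 2:
                profiles = {
                    t: pm.data.loc[t] for t in pm.taxa if pm.data.loc[t].sum() > 0
                }
                if len(profiles) >= 2:
                    om = overlap_matrix(profiles)
                    o_path = out / f"overlap_{sid}.tsv"
                    write_matrix(om, o_path)
                    outputs[f"overlap_{sid}"] = o_path
                    t_path = out / f"overlap_{sid}_table1.tsv"
                    write_matrix(om, t_path, layout="table1_style")
                    outputs[f"overlap_{sid}_table1"] = t_path

            sm = substrate_aggregate(pm, smap)
            s_path = out / f"substrate_{sid}.tsv"
            write_matrix(sm.data, s_path)
            outputs[f"substrate_{sid}"] = s_path

            stage_t = classify_transporters(genes, tmap, config.rank, sid, samples)
            if stage_t.profiles:
                secreted_pm = build_profile_matrix(
                    genes, samples, sid, rank=config.rank,
                    exclude_classes=config.exclude_classes,
                    contig_min_bp=config.contig_min_bp, secreted_only=True,
                )
                sec_frac = {}
                for taxon in pm.taxa:
                    total = pm.data.loc[taxon].sum()
                    sec = (
                        secreted_pm.data.loc[taxon].sum()
                        if taxon in secreted_pm.data.index
                        else 0.0
                    )
                    sec_frac[taxon] = float(sec / total) if total > 0 else 0.0
                st = strategy_table(stage_t, sec_frac)
                st.insert(0, "sample_id", sid)
                strategy_frames.append(st)

        stage = "niche_metrics"
        if niche_frames:
            niche_all = pd.concat(niche_frames)
            n_path = out / "niche_metrics.tsv"
            niche_all.to_csv(n_path, sep="\t")
            outputs["niche_metrics"] = n_path

        stage = "transporters"
        if strategy_frames:
            strat_all = pd.concat(strategy_frames)
            t_path = out / "transporter_strategies.tsv"
            strat_all.to_csv(t_path, sep="\t")
            outputs["transporter_strategies"] = t_path

        stage = "group_compare"
        fam_matrix = family_abundance_matrix(
            genes, samples, exclude_classes=config.exclude_classes, contig_min_bp=config.contig_min_bp
        )
        f_path = out / "family_matrix.tsv"
        write_matrix(fam_matrix, f_path)
        outputs["family_matrix"] = f_path

        design = _design_from_metadata(samples, config.compare_on)
        compare_report: dict = {"design": design, "groups": sorted(set(design.values()))}
        sub = fam_matrix.loc[[s for s in fam_matrix.index if s in design]]
        group_sizes = pd.Series([design[s] for s in sub.index]).value_counts()
        if len(group_sizes) == 2 and group_sizes.min() >= 2:
            dm = bray_curtis(sub)
            d_path = out / "bray_curtis.tsv"
            write_matrix(dm, d_path)
            outputs["bray_curtis"] = d_path

            ord_res = pcoa(dm)
            c_path = out / "pcoa_coordinates.tsv"
            ord_res.coordinates.to_csv(c_path, sep="\t")
            outputs["pcoa_coordinates"] = c_path

            perm = permanova(dm, design, n_permutations=config.n_permutations, seed=config.seed)
            compare_report["permanova"] = {
                "pseudo_F": perm.pseudo_F,
                "R2": perm.R2,
                "p_value": perm.p_value,
                "n_permutations": perm.n_permutations,
                "seed": perm.seed,
            }

            screen = wilcoxon_screen(sub, design)
            w_path = out / "wilcoxon_screen.tsv"
            screen.to_csv(w_path, sep="\t")
            outputs["wilcoxon_screen"] = w_path
            compare_report["n_significant_families"] = int(screen["significant"].sum())
        else:
            compare_report["skipped"] = "need exactly 2 groups with >= 2 samples each"

        compare_report["cazyme_gene_frequency_pct"] = cazyme_gene_frequency(genes)
        r_path = out / "compare_report.json"
        r_path.write_text(json.dumps(compare_report, indent=2, default=str))
        outputs["compare_report"] = r_path
    except Exception as exc:
        raise StageError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in outputs.items()},
    }
    m_path = out / "manifest.json"
    m_path.write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
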