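"""Shared fixtures: tiny hand-written tables and seeded synthetic communities."""

from __future__ import annotations

import pytest

from glyconiche.io_tables import SampleMeta
from glyconiche.synthetic import SimConfig, simulate


@pytest.fixture()
def two_samples() -> dict[str, SampleMeta]:
    return {
        "W1": SampleMeta("W1", "FL", "surface", "ST01", 1_000_000),
        "W2": SampleMeta("W2", "PA", "surface", "ST01", 2_000_000),
    }


@pytest.fixture()
def gene_table_file(tmp_path, two_samples):
    """A 5-row gene table exercising multi-family cells and lineages."""
    rows = [
        "gene_id\tcontig_id\tlength_bp\tlineage\tcazyme_families\tko_id\tsecreted\tW1\tW2",
        "g1\tc1\t1000\td__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Alteromonadales;f__Alteromonadaceae;g__Alteromonas\tGH13;CBM48\t\t1\t100\t40",
        "g2\tc1\t2000\td__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Alteromonadales;f__Alteromonadaceae;g__Alteromonas\tGH13\t\t0\t50\t20",
        "g3\tc2\t1500\td__Bacteria;p__Bacteroidota\tPL1\tK21573\t1\t30\t10",
        "g4\tc3\t800\td__Bacteria;p__Proteobacteria\tGT2\t\t\t10\t5",
        "g5\tc4\t900\t\t\tK02027\t0\t5\t2",
    ]
    path = tmp_path / "genes.tsv"
    path.write_text("\n".join(rows) + "\n")
    return path


@pytest.fixture(scope="session")
def sim_default():
    """One bundled-condition community, shared across tests (read-only)."""
    return simulate(SimConfig(seed=20260926))


@pytest.fixture(scope="session")
def sim_planted_fl_pa():
    """FL-vs-PA design, 6 samples per group, 8 families planted at 4-fold."""
    config = planted_fl_pa_config(seed=20260926)
    return simulate(config)


def planted_fl_pa_config(seed: int) -> SimConfig:
    fams = SimConfig(seed=0).family_labels()
    planted = {fams[j]: 4.0 for j in range(0, 40, 5)}
    groups = {f"ST{i:02d}SF": "SF" for i in range(1, 7)}
    groups |= {f"ST{i:02d}SP": "SP" for i in range(1, 7)}
    return SimConfig(seed=seed, group_design=groups, group_effects={"SP": planted})
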