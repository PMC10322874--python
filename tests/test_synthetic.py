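"""Synthetic community generator: truth correctness, determinism, contracts."""

import dataclasses
import io

import numpy as np
import pandas as pd
import pytest

from glyconiche.io_tables import read_gene_table, read_sample_metadata
from glyconiche.profiles import build_profile_matrix
from glyconiche.synthetic import (
    SimConfig,
    simulate,
    truth_metrics,
    with_seed,
    write_fixture,
)


class TestTruthOracle:
    def test_self_pair_overlap_is_one(self):
        p = pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], index=["a", "b"], columns=["GH1", "PL2"])
        t = truth_metrics(p, 2)
        assert t.overlap.loc["a", "b"] == pytest.approx(1.0)

    def test_planted_half_overlap(self):
        p = pd.DataFrame(
            [[0.5, 0.5, 0.0], [0.0, 0.5, 0.5]], index=["a", "b"], columns=["GH1", "PL2", "CE3"]
        )
        assert truth_metrics(p, 3).overlap.loc["a", "b"] == pytest.approx(0.5)

    def test_levins_bounds_hold(self):
        rng = np.random.default_rng(0)
        raw = rng.random((4, 12))
        p = pd.DataFrame(raw / raw.sum(axis=1, keepdims=True))
        t = truth_metrics(p, 12)
        assert ((t.niche["B"] >= 1.0) & (t.niche["B"] <= 12.0)).all()
        assert ((t.niche["B_A"] >= 0.0) & (t.niche["B_A"] <= 1.0)).all()


class TestPlantedOverlap:
    def test_s_one_forces_identity(self):
        cfg = SimConfig(seed=1, overlap_design=((0, 1, 1.0),))
        r = simulate(cfg)
        assert r.truth.overlap.iloc[0, 1] == pytest.approx(1.0)
        pd.testing.assert_series_equal(
            r.truth.proportions.iloc[0], r.truth.proportions.iloc[1], check_names=False
        )

    def test_disjoint_sets_zero_overlap(self):
        sets = {0: tuple(range(0, 20)), 1: tuple(range(20, 40))}
        cfg = SimConfig(seed=1, n_taxa=2, family_sets=sets, overlap_design=(), genes_per_taxon=40)
        r = simulate(cfg)
        assert r.truth.overlap.iloc[0, 1] == pytest.approx(0.0)

    def test_high_concentration_approaches_full_width(self):
        cfg = SimConfig(
            seed=3, n_taxa=2, n_families=20, alpha=1e4, overlap_design=(), genes_per_taxon=40
        )
        r = simulate(cfg)
        assert (r.truth.niche["B_A"] > 0.98).all()

    def test_infeasible_designs_rejected_before_sampling(self):
        with pytest.raises(ValueError, match="more than one pair"):
            SimConfig(seed=1, overlap_design=((0, 1, 0.5), (1, 2, 0.5))).validate()
        with pytest.raises(ValueError, match="outside"):
            SimConfig(seed=1, overlap_design=((0, 1, 1.5),)).validate()
        sets = {0: (0,), 1: (1,)}
        with pytest.raises(ValueError, match="share no families"):
            SimConfig(
                seed=1, n_taxa=2, family_sets=sets, overlap_design=((0, 1, 0.5),)
            ).validate()


class TestOutputs:
    def test_tables_pass_io_validation(self, sim_default, tmp_path):
        paths = write_fixture(sim_default, tmp_path)
        samples = read_sample_metadata(paths["metadata"])
        recs = read_gene_table(paths["genes"], samples)
        assert len(recs) == len(sim_default.genes)

    def test_byte_identical_for_identical_seed(self, tmp_path):
        cfg = SimConfig(seed=99, genes_per_taxon=60)

        def render(c):
            r = simulate(c)
            d = tmp_path / f"run_{id(c)}"
            paths = write_fixture(r, d)
            return {k: p.read_bytes() for k, p in paths.items()}

        assert render(cfg) == render(SimConfig(seed=99, genes_per_taxon=60))

    def test_different_seed_differs(self):
        a = simulate(SimConfig(seed=1, genes_per_taxon=60))
        b = simulate(SimConfig(seed=2, genes_per_taxon=60))
        assert not a.truth.proportions.equals(b.truth.proportions)

    def test_short_contig_spikes_filtered_from_profiles(self):
        cfg = SimConfig(seed=5, n_short_contig_spikes=3, genes_per_taxon=50)
        r = simulate(cfg)
        spiked = [g for g in r.genes if g.effective_contig_bp == 400]
        assert len(spiked) == 3
        pm = build_profile_matrix(r.genes, r.samples, next(iter(r.samples)))
        # spiked genes carry real reads yet contribute nothing after the filter
        conserved = build_profile_matrix(
            r.genes, r.samples, next(iter(r.samples)), contig_min_bp=0
        )
        assert conserved.data.to_numpy().sum() > pm.data.to_numpy().sum()

    def test_gt_decoys_present_in_table_absent_from_profiles(self, sim_default):
        gt_genes = [
            g
            for g in sim_default.genes
            if any(f.startswith("GT") for f in g.cazyme_families)
        ]
        assert len(gt_genes) == sim_default.config.n_gt_decoys
        pm = build_profile_matrix(sim_default.genes, sim_default.samples, "ST01SF")
        assert not any(c.startswith("GT") for c in pm.data.columns)

    def test_group_effects_shift_expected_direction(self):
        fams = SimConfig(seed=0).family_labels()
        cfg = SimConfig(
            seed=11,
            group_design={"A1": "SF", "A2": "SF", "B1": "SP", "B2": "SP"},
            group_effects={"SP": {fams[0]: 8.0}},
        )
        r = simulate(cfg)
        mats = {
            sid: build_profile_matrix(r.genes, r.samples, sid).data.sum(axis=0)
            for sid in r.samples
        }
        sf = (mats["A1"] + mats["A2"])[fams[0]]
        sp = (mats["B1"] + mats["B2"])[fams[0]]
        assert sp > 2 * sf

    def test_truth_matrices_satisfy_metric_invariants(self, sim_default):
        t = sim_default.truth
        O = t.overlap.to_numpy()
        assert np.allclose(O, O.T)
        assert np.allclose(np.diag(O), 1.0)
        assert (O >= -1e-12).all() and (O <= 1 + 1e-12).all()
        assert np.allclose(t.proportions.sum(axis=1), 1.0)
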