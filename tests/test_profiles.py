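"""RPKM normalization, profile matrices, gene frequency and aggregation."""

import numpy as np
import pandas as pd
import pytest

from glyconiche.io_tables import GeneRecord, SampleMeta, SubstrateMap
from glyconiche.profiles import (
    build_profile_matrix,
    cazyme_gene_frequency,
    family_abundance_matrix,
    rpkm,
    substrate_aggregate,
    to_proportions,
)


class TestRpkm:
    @pytest.mark.parametrize(
        "reads,length,total,expected",
        [
            (100, 1000, 1_000_000, 100.0),  # all scale factors cancel
            (0, 777, 123, 0.0),
            (50, 2000, 10_000_000, 2.5),  # hand evaluation of the formula
        ],
    )
    def test_values(self, reads, length, total, expected):
        assert rpkm(reads, length, total) == pytest.approx(expected, abs=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            rpkm(1, 0, 100)
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)

    def test_joint_scale_invariance(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            reads = rng.integers(0, 1000)
            length = rng.integers(1, 5000)
            total = rng.integers(1, 10**7)
            c = rng.integers(1, 100)
            assert rpkm(reads * c, length, total * c) == pytest.approx(
                rpkm(reads, length, total), rel=1e-12
            )


def _gene(gid, fams, taxon, reads, length=1000, contig=2000, ko=None, secreted=None):
    lineage = (f"d__Bacteria", f"p__P_{taxon}", f"c__C", f"o__O", f"f__F", f"g__{taxon}")
    return GeneRecord(
        gene_id=gid,
        contig_id=f"ctg_{gid}",
        length_bp=length,
        reads_mapped={"W1": reads},
        lineage=lineage,
        cazyme_families=frozenset(fams),
        ko_id=ko,
        secreted=secreted,
        contig_bp=contig,
    )


@pytest.fixture()
def one_sample():
    return {"W1": SampleMeta("W1", "FL", "surface", "ST01", 1_000_000)}


class TestProfileMatrix:
    def test_aggregation_with_gt_exclusion(self, one_sample):
        # equal RPKM 10 per gene: 10 reads on 1 kb genes in a 1e6-read library
        genes = [
            _gene("g1", ["GH13"], "A", 10),
            _gene("g2", ["GH13"], "A", 10),
            _gene("g3", ["GT2"], "A", 10),
            _gene("g4", ["PL1"], "B", 10),
        ]
        pm = build_profile_matrix(genes, one_sample, "W1")
        assert pm.data.loc["A", "GH13"] == pytest.approx(20.0)
        assert pm.data.loc["B", "PL1"] == pytest.approx(10.0)
        assert "GT2" not in pm.data.columns

    def test_exclusion_toggle(self, one_sample):
        genes = [_gene("g1", ["GH13"], "A", 10), _gene("g3", ["GT2"], "A", 10)]
        pm = build_profile_matrix(genes, one_sample, "W1", exclude_classes=())
        assert pm.data.loc["A", "GT2"] == pytest.approx(10.0)

    def test_short_contig_excluded_strictly(self, one_sample):
        genes = [
            _gene("g1", ["GH13"], "A", 10, length=400, contig=400),
            _gene("g2", ["GH13"], "A", 10, length=400, contig=500),  # boundary: excluded
            _gene("g3", ["GH13"], "A", 10, length=400, contig=501),  # strictly above: kept
        ]
        pm = build_profile_matrix(genes, one_sample, "W1")
        assert pm.data.loc["A", "GH13"] == pytest.approx(rpkm(10, 400, 1_000_000))

    def test_multi_domain_full_vs_split(self, one_sample):
        genes = [_gene("g1", ["GH13", "CBM48"], "A", 10)]
        full = build_profile_matrix(genes, one_sample, "W1")
        assert full.data.loc["A", "GH13"] == pytest.approx(10.0)
        assert full.data.loc["A", "CBM48"] == pytest.approx(10.0)
        split = build_profile_matrix(genes, one_sample, "W1", multi_domain="split")
        assert split.data.loc["A"].sum() == pytest.approx(10.0)

    def test_unclassified_bucket_conserves_totals(self, one_sample):
        genes = [
            _gene("g1", ["GH13"], "A", 10),
            GeneRecord("g2", "c", 1000, {"W1": 10}, (), frozenset({"GH13"}), contig_bp=2000),
        ]
        pm = build_profile_matrix(genes, one_sample, "W1")
        assert "unclassified_genus" in pm.data.index
        fam_totals = family_abundance_matrix(genes, one_sample)
        assert pm.data["GH13"].sum() == pytest.approx(fam_totals.loc["W1", "GH13"])

    def test_secreted_only_restriction(self, one_sample):
        genes = [
            _gene("g1", ["GH13"], "A", 10, secreted=True),
            _gene("g2", ["GH13"], "A", 10, secreted=False),
        ]
        pm = build_profile_matrix(genes, one_sample, "W1", secreted_only=True)
        assert pm.data.loc["A", "GH13"] == pytest.approx(10.0)

    def test_unknown_sample_errors(self, one_sample):
        with pytest.raises(KeyError, match="W9"):
            build_profile_matrix([], one_sample, "W9")


class TestGeneFrequency:
    def test_counting_oracle(self, one_sample):
        genes = [_gene(f"g{i}", ["GH1"] if i < 4 else [], "A", 0) for i in range(1000)]
        assert cazyme_gene_frequency(genes) == pytest.approx(0.4)

    def test_bounds(self):
        all_caz = [_gene(f"g{i}", ["PL1"], "A", 0) for i in range(10)]
        assert cazyme_gene_frequency(all_caz) == pytest.approx(100.0)
        assert cazyme_gene_frequency(all_caz, classes={"AA"}) == pytest.approx(0.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cazyme_gene_frequency([])


class TestProportions:
    def test_values(self):
        p = to_proportions(pd.Series({"GH13": 20.0, "PL1": 20.0}))
        assert p.tolist() == [0.5, 0.5]
        p = to_proportions(pd.Series({"GH13": 30.0, "PL1": 10.0}))
        assert p.tolist() == [0.75, 0.25]

    def test_empty_profile_errors(self):
        with pytest.raises(ValueError, match="N_i = 0"):
            to_proportions(pd.Series(dtype=float))


class TestSubstrateAggregate:
    def test_sum_and_multimap_and_unmapped(self, one_sample):
        genes = [
            _gene("g1", ["GH16"], "A", 5),
            _gene("g2", ["GH17"], "A", 3),
            _gene("g3", ["GH5"], "A", 2),  # maps to two categories
            _gene("g4", ["GH9999"], "A", 1),  # unmapped
        ]
        pm = build_profile_matrix(genes, one_sample, "W1")
        agg = substrate_aggregate(pm, SubstrateMap.default())
        assert agg.data.loc["A", "beta_glucan"] == pytest.approx(5 + 3 + 2)
        assert agg.data.loc["A", "cellulose_hemicellulose"] == pytest.approx(2)
        assert agg.data.loc["A", "unmapped"] == pytest.approx(1)

    def test_single_mapping_conserves_total(self, one_sample):
        genes = [_gene("g1", ["GH16"], "A", 5), _gene("g2", ["PL6"], "A", 3)]
        pm = build_profile_matrix(genes, one_sample, "W1")
        agg = substrate_aggregate(pm, SubstrateMap.default())
        assert agg.data.loc["A"].sum() == pytest.approx(pm.data.loc["A"].sum())
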