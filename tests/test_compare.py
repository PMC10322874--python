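"""Rank-sum tests, Bray-Curtis, PCoA and PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu

from glyconiche.compare import (
    bray_curtis,
    pcoa,
    permanova,
    wilcoxon_rank_sum,
    wilcoxon_screen,
)


def enumeration_p(x, y, alternative="two-sided"):
    """Independent oracle: full enumeration of all C(n+m, n) arrangements."""
    n, m = len(x), len(y)
    combined = sorted(x + y)
    us = []
    for pos in itertools.combinations(range(n + m), n):
        xs = [combined[i] for i in pos]
        ys = [combined[i] for i in range(n + m) if i not in pos]
        us.append(sum(1 for a in xs for b in ys if a > b))
    us = np.array(us)
    u_obs = sum(1 for a in x for b in y if a > b)
    cdf = np.mean(us <= u_obs)
    sf = np.mean(us >= u_obs)
    if alternative == "two-sided":
        return min(1.0, 2 * min(cdf, sf))
    return sf if alternative == "greater" else cdf


class TestWilcoxon:
    def test_small_separated(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_value == pytest.approx(1.0)

    def test_extreme_shift_n5(self):
        res = wilcoxon_rank_sum([10, 11, 12, 13, 14], [1, 2, 3, 4, 5])
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 252, abs=1e-12)

    @pytest.mark.parametrize("n,m", [(1, 1), (2, 3), (3, 3), (4, 4), (2, 7), (5, 5)])
    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_matches_enumeration(self, n, m, alternative):
        rng = np.random.default_rng(n * 100 + m)
        for _ in range(5):
            vals = rng.permutation(np.arange(1.0, n + m + 1))
            x, y = list(vals[:n]), list(vals[n:])
            res = wilcoxon_rank_sum(x, y, alternative=alternative)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(
                enumeration_p(x, y, alternative), abs=1e-12
            )

    def test_asymptotic_matches_scipy_with_ties(self):
        rng = np.random.default_rng(0)
        x = list(rng.integers(0, 5, size=10).astype(float))
        y = list(rng.integers(0, 5, size=12).astype(float))
        res = wilcoxon_rank_sum(x, y)
        assert res.method == "asymptotic"
        ref = mannwhitneyu(x, y, method="asymptotic", use_continuity=True)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum([], [1.0])


class TestBrayCurtis:
    def test_worked_values(self):
        m = pd.DataFrame([[1.0, 1.0], [1.0, 3.0], [1.0, 1.0]], index=list("abc"))
        dm = bray_curtis(m)
        assert dm.loc["a", "c"] == pytest.approx(0.0)
        assert dm.loc["a", "b"] == pytest.approx(2 / 6)

    def test_disjoint_support_maximal(self):
        m = pd.DataFrame([[1.0, 0.0], [0.0, 2.0]], index=list("ab"))
        assert bray_curtis(m).loc["a", "b"] == pytest.approx(1.0)

    def test_two_zero_rows_error(self):
        m = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]], index=list("abc"))
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(m)

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            bray_curtis(pd.DataFrame([[1.0, -1.0], [0.0, 1.0]]))


def _euclidean_dm(points):
    n = len(points)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            D[i, j] = np.linalg.norm(np.asarray(points[i]) - np.asarray(points[j]))
    return pd.DataFrame(D, index=[f"s{i}" for i in range(n)], columns=[f"s{i}" for i in range(n)])


class TestPcoa:
    def test_planar_points_recovered(self):
        pts = [(0, 0), (1, 0), (0.3, 2.1), (-1.5, 0.7), (2.2, -0.9)]
        dm = _euclidean_dm(pts)
        res = pcoa(dm)
        emb = res.coordinates.to_numpy()
        D_emb = np.linalg.norm(emb[:, None, :] - emb[None, :, :], axis=-1)
        assert np.abs(D_emb - dm.to_numpy()).max() < 1e-9

    def test_equilateral_triangle_eigenvalues(self):
        dm = pd.DataFrame(1.0 - np.eye(3), index=list("abc"), columns=list("abc"))
        res = pcoa(dm)
        ev = res.eigenvalues
        assert ev[0] == pytest.approx(ev[1], abs=1e-12)
        assert ev[0] > 0
        assert abs(ev[2]) < 1e-12

    def test_two_samples_closed_form(self):
        d = 1.6
        dm = pd.DataFrame([[0, d], [d, 0]], index=list("ab"), columns=list("ab"))
        res = pcoa(dm)
        coords = res.coordinates.to_numpy().ravel()
        assert sorted(np.round(coords, 12)) == pytest.approx([-d / 2, d / 2])

    def test_asymmetric_rejected(self):
        dm = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(dm)

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(5)
        X = rng.random((6, 4))
        dm = bray_curtis(pd.DataFrame(X, index=[f"s{i}" for i in range(6)]))
        ours = pcoa(dm)
        ref = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(dm.to_numpy(), ids=list(dm.index))
        )
        n_pos = ours.coordinates.shape[1]
        ref_ev = np.asarray(ref.eigvals)[:n_pos]
        assert np.allclose(ours.eigenvalues[:n_pos], ref_ev, atol=1e-8)
        for k in range(min(2, n_pos)):
            a = ours.coordinates.iloc[:, k].to_numpy()
            b = np.asarray(ref.samples.iloc[:, k])
            assert np.allclose(a, b, atol=1e-8) or np.allclose(a, -b, atol=1e-8)


def _clustered_dm(rng, n_per_group=5, sep=10.0):
    a = rng.uniform(0.5, 1.5, size=(n_per_group, 3))
    b = rng.uniform(0.5, 1.5, size=(n_per_group, 3)) + sep
    X = np.vstack([a, b])
    labels = {f"s{i}": ("A" if i < n_per_group else "B") for i in range(2 * n_per_group)}
    m = pd.DataFrame(X, index=list(labels))
    return bray_curtis(m), labels


class TestPermanova:
    def test_separated_clusters_minimal_p(self):
        # 10 + 10 samples: permutations recreating the true split are
        # vanishingly rare, so observed F exceeds every permuted F
        dm, labels = _clustered_dm(np.random.default_rng(11), n_per_group=10)
        res = permanova(dm, labels, n_permutations=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.R2 > 0.5

    def test_determinism(self):
        dm, labels = _clustered_dm(np.random.default_rng(2), sep=1.0)
        a = permanova(dm, labels, seed=7)
        b = permanova(dm, labels, seed=7)
        assert a == b

    def test_sample_order_invariance_of_f_and_r2(self):
        dm, labels = _clustered_dm(np.random.default_rng(3), sep=2.0)
        perm_order = list(dm.index)[::-1]
        dm2 = dm.loc[perm_order, perm_order]
        a = permanova(dm, labels, n_permutations=49, seed=0)
        b = permanova(dm2, labels, n_permutations=49, seed=0)
        assert a.pseudo_F == pytest.approx(b.pseudo_F, rel=1e-12)
        assert a.R2 == pytest.approx(b.R2, rel=1e-12)

    def test_r2_bounds_and_p_floor(self):
        # semimetric distances allow a slightly negative between-group SS on
        # structureless data, so R2 may dip marginally below zero there
        dm, labels = _clustered_dm(np.random.default_rng(4), sep=0.0)
        res = permanova(dm, labels, n_permutations=99, seed=0)
        assert -0.2 <= res.R2 <= 1.0
        assert res.p_value >= 1 / 100
        sep_dm, sep_labels = _clustered_dm(np.random.default_rng(4), sep=5.0)
        sep_res = permanova(sep_dm, sep_labels, n_permutations=99, seed=0)
        assert 0.0 <= sep_res.R2 <= 1.0

    def test_singleton_group_rejected(self):
        dm, labels = _clustered_dm(np.random.default_rng(5))
        labels = dict(labels)
        labels["s0"] = "C"
        with pytest.raises(ValueError, match="singleton"):
            permanova(dm, labels, seed=0)

    def test_statistic_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        dm, labels = _clustered_dm(np.random.default_rng(6), sep=2.0)
        ours = permanova(dm, labels, n_permutations=9, seed=0)
        sk_dm = skbio.DistanceMatrix(dm.to_numpy(), ids=list(dm.index))
        ref = skbio.stats.distance.permanova(
            sk_dm, [labels[s] for s in dm.index], permutations=9
        )
        assert ours.pseudo_F == pytest.approx(float(ref["test statistic"]), rel=1e-9)


class TestScreen:
    def test_planted_shift_flagged_with_bh(self):
        rng = np.random.default_rng(8)
        n = 6
        base = rng.uniform(1, 2, size=(2 * n, 20))
        base[n:, :4] *= 8  # strong shift in the first four features
        m = pd.DataFrame(base, index=[f"s{i}" for i in range(2 * n)])
        design = {f"s{i}": ("A" if i < n else "B") for i in range(2 * n)}
        out = wilcoxon_screen(m, design)
        assert out["significant"].iloc[:4].all()
        assert set(out.columns) >= {"U", "p", "q", "significant", "direction"}

    def test_requires_two_groups(self):
        m = pd.DataFrame(np.ones((3, 2)), index=list("abc"))
        with pytest.raises(ValueError, match="2 groups"):
            wilcoxon_screen(m, {"a": "x", "b": "x", "c": "x"})
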