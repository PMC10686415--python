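"""Biweight midcorrelation, adjacency, TOM, modules, trait correlation."""

import numpy as np
import pandas as pd
import pytest

from syndiversity import conet
from syndiversity.profiles import ProfileMatrix


def reference_bicor(x, y, c=9.0):
    """Independent direct coding of the published biweight midcorrelation."""
    def weighted(v):
        med = np.median(v)
        mad = np.median(np.abs(v - med))
        if mad == 0:
            return None
        u = (v - med) / (c * mad)
        w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
        return (v - med) * w

    a, b = weighted(np.asarray(x, float)), weighted(np.asarray(y, float))
    if a is None or b is None:
        a = np.asarray(x, float) - np.mean(x)
        b = np.asarray(y, float) - np.mean(y)
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def reference_tom(A):
    """Brute-force double-loop topological overlap."""
    n = len(A)
    A = np.asarray(A, float).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n))
            T[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return T


def _pm(values, columns=None):
    values = np.asarray(values, float)
    cols = columns or [f"T{i}" for i in range(values.shape[1])]
    vals = pd.DataFrame(values, index=[f"P{i}" for i in range(len(values))],
                        columns=cols)
    meta = pd.DataFrame({"column": cols, "synapse_type": cols})
    return ProfileMatrix(values=vals, columns_meta=meta)


class TestBicor:
    def test_self_correlation_is_one(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        assert conet.bicor(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_antisymmetry(self):
        x = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        assert conet.bicor(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_published_formula_on_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 4.0, 8.0, 16.0])
        assert conet.bicor(x, y) == pytest.approx(reference_bicor(x, y),
                                                  abs=1e-12)

    def test_matches_published_formula_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(5, 30)
            x, y = rng.normal(size=n), rng.normal(size=n)
            assert conet.bicor(x, y) == pytest.approx(
                reference_bicor(x, y), abs=1e-9
            )

    def test_positive_affine_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=12), rng.normal(size=12)
        r0 = conet.bicor(x, y)
        assert conet.bicor(3.5 * x + 7.0, y) == pytest.approx(r0, abs=1e-9)
        assert conet.bicor(x, 0.2 * y - 4.0) == pytest.approx(r0, abs=1e-9)

    def test_zero_mad_falls_back_to_pearson(self):
        x = np.array([1.0, 1.0, 1.0, 1.0, 5.0, 1.0])
        y = np.arange(6, dtype=float)
        expected = np.corrcoef(x, y)[0, 1]
        assert conet.bicor(x, y) == pytest.approx(expected, abs=1e-12)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            conet.bicor(np.ones(3), np.ones(3))

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(2)
        pm = _pm(rng.normal(size=(8, 10)))
        M = conet.bicor_matrix(pm.values)
        for i in range(8):
            for j in range(i + 1, 8):
                assert M.iloc[i, j] == pytest.approx(
                    conet.bicor(pm.values.iloc[i], pm.values.iloc[j]),
                    abs=1e-12,
                )


class TestAdjacency:
    def test_negative_correlation_zeroed(self):
        corr = pd.DataFrame([[1.0, -0.5], [-0.5, 1.0]])
        adj = conet.adjacency_signed_hybrid(corr)
        assert adj.iloc[0, 1] == 0.0

    def test_perfect_correlation_gives_unit_weight(self):
        corr = pd.DataFrame([[1.0, 1.0], [1.0, 1.0]])
        adj = conet.adjacency_signed_hybrid(corr)
        assert adj.iloc[0, 1] == 1.0

    def test_soft_power_six(self):
        corr = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]])
        adj = conet.adjacency_signed_hybrid(corr, beta=6)
        assert adj.iloc[0, 1] == pytest.approx(0.531441, abs=1e-12)

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ValueError):
            conet.adjacency_signed_hybrid(pd.DataFrame([[1.0]]), beta=0)

    def test_raising_beta_increases_sparsity(self):
        rng = np.random.default_rng(3)
        pm = _pm(rng.normal(size=(30, 15)))
        corr = conet.bicor_matrix(pm.values)
        counts = []
        for beta in (2, 4, 6, 8):
            adj = conet.adjacency_signed_hybrid(corr, beta)
            counts.append(len(conet.export_network(adj, 0.1)))
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestTopologicalOverlap:
    def test_identical_fully_connected_rows(self):
        A = pd.DataFrame(np.ones((3, 3)))
        T = conet.topological_overlap(A)
        assert T.iloc[0, 1] == pytest.approx(1.0)

    def test_disconnected_nodes_have_zero_overlap(self):
        A = pd.DataFrame(np.zeros((4, 4)))
        A.iloc[0, 1] = A.iloc[1, 0] = 0.0
        T = conet.topological_overlap(A)
        assert T.iloc[0, 2] == 0.0

    def test_four_node_toy_matches_hand_computation(self):
        # path graph 0-1-2-3 with unit weights
        A = np.zeros((4, 4))
        for i, j in ((0, 1), (1, 2), (2, 3)):
            A[i, j] = A[j, i] = 1.0
        T = conet.topological_overlap(pd.DataFrame(A))
        # nodes 0,1: no shared neighbors, edge 1 -> (0+1)/(1+1-1)=1
        assert T.iloc[0, 1] == pytest.approx(1.0)
        # nodes 0,2: shared neighbor 1, no edge -> 1/(1+1-0)=0.5
        assert T.iloc[0, 2] == pytest.approx(0.5)
        # nodes 0,3: no shared neighbor, no edge -> 0
        assert T.iloc[0, 3] == pytest.approx(0.0)
        np.testing.assert_allclose(T.to_numpy(), reference_tom(A), atol=1e-12)

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            A = rng.uniform(0, 1, (20, 20))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0.0)
            T = conet.topological_overlap(pd.DataFrame(A))
            np.testing.assert_allclose(T.to_numpy(), reference_tom(A),
                                       atol=1e-10)


class TestDetectModules:
    def test_two_perfect_blocks_yield_two_modules(self):
        rng = np.random.default_rng(5)
        f1, f2 = rng.normal(size=15), rng.normal(size=15)
        rows = [f1 * s for s in rng.uniform(0.5, 2.0, 10)] + \
               [f2 * s for s in rng.uniform(0.5, 2.0, 10)]
        pm = _pm(np.array(rows) + rng.normal(0, 1e-6, (20, 15)))
        corr = conet.bicor_matrix(pm.values)
        diss = 1 - conet.topological_overlap(
            conet.adjacency_signed_hybrid(corr)
        )
        labels = conet.detect_modules(diss, matrix=pm, min_module_size=5)
        assert labels.max() == 2
        assert (labels == 0).sum() == 0

    def test_isolated_protein_unassigned(self):
        rng = np.random.default_rng(6)
        f1 = rng.normal(size=15)
        rows = [f1 * s for s in rng.uniform(0.5, 2.0, 12)]
        rows.append(rng.normal(size=15))  # uncorrelated singleton
        pm = _pm(np.array(rows) + rng.normal(0, 1e-3, (13, 15)))
        corr = conet.bicor_matrix(pm.values)
        diss = 1 - conet.topological_overlap(
            conet.adjacency_signed_hybrid(corr)
        )
        labels = conet.detect_modules(diss, matrix=pm, min_module_size=5)
        assert labels.iloc[-1] == 0


class TestEigenproteins:
    def test_identical_profiles_give_unit_correlation(self):
        rng = np.random.default_rng(7)
        prof = rng.normal(size=15)
        pm = _pm(np.tile(prof, (5, 1)))
        labels = pd.Series(1, index=pm.values.index)
        eig = conet.eigenproteins(pm, labels)
        z = (prof - prof.mean()) / prof.std()
        assert abs(np.corrcoef(eig.loc[1], z)[0, 1]) == pytest.approx(1.0)

    def test_sign_aligned_with_module_mean(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            rng2 = np.random.default_rng(seed)
            pm = _pm(rng2.normal(size=(10, 12)))
            labels = pd.Series(1, index=pm.values.index)
            eig = conet.eigenproteins(pm, labels)
            Z = pm.values.sub(pm.values.mean(axis=1), axis=0)
            Z = Z.div(Z.std(axis=1, ddof=1), axis=0)
            assert np.corrcoef(eig.loc[1], Z.mean(axis=0))[0, 1] >= 0

    def test_unit_variance(self):
        rng = np.random.default_rng(9)
        pm = _pm(rng.normal(size=(10, 12)))
        labels = pd.Series(1, index=pm.values.index)
        eig = conet.eigenproteins(pm, labels)
        assert eig.loc[1].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_planted_factor_recovered(self):
        rng = np.random.default_rng(10)
        factor = rng.normal(size=15)
        loading = 0.9
        rows = [loading * factor
                + np.sqrt(1 - loading**2) * rng.normal(size=15)
                for _ in range(50)]
        pm = _pm(np.array(rows))
        labels = pd.Series(1, index=pm.values.index)
        eig = conet.eigenproteins(pm, labels)
        assert abs(np.corrcoef(eig.loc[1], factor)[0, 1]) >= 0.95


class TestModuleTraitCorrelation:
    def _eig(self, rows):
        return pd.DataFrame(rows, index=range(1, len(rows) + 1),
                            columns=[f"T{i}" for i in range(len(rows[0]))])

    def test_identical_trait_gives_unit_correlation(self):
        rng = np.random.default_rng(11)
        e = rng.normal(size=15)
        eig = self._eig([e])
        traits = pd.DataFrame({"tr": e}, index=eig.columns)
        r, p = conet.module_trait_correlation(eig, traits)
        assert r.loc[1, "tr"] == pytest.approx(1.0)
        assert p.loc[1, "tr"] == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_trait_gives_zero(self):
        e = np.array([1.0, -1.0] * 7 + [0.0])
        t = np.array([1.0, 1.0, -1.0, -1.0] * 3 + [1.0, 1.0, -2.0])
        t = t - t.mean()
        t = t - (t @ e) / (e @ e) * e  # exact orthogonalization
        eig = self._eig([e])
        traits = pd.DataFrame({"tr": t}, index=eig.columns)
        r, _ = conet.module_trait_correlation(eig, traits)
        assert r.loc[1, "tr"] == pytest.approx(0.0, abs=1e-9)

    def test_p_value_matches_t_distribution_oracle(self):
        # r = 0.6 at n = 15: t = 0.6 sqrt(13/0.64) = 2.7042, p ~ 0.018
        from scipy import stats

        n = 15
        rng = np.random.default_rng(12)
        e = rng.normal(size=n)
        ez = (e - e.mean()) / np.linalg.norm(e - e.mean())
        resid = rng.normal(size=n)
        resid -= resid.mean() + (resid @ ez) * ez
        resid /= np.linalg.norm(resid)
        target_r = 0.6
        t_vec = target_r * ez + np.sqrt(1 - target_r**2) * resid
        eig = self._eig([e])
        traits = pd.DataFrame({"tr": t_vec}, index=eig.columns)
        r, p = conet.module_trait_correlation(eig, traits)
        assert r.loc[1, "tr"] == pytest.approx(0.6, abs=1e-9)
        t_oracle = 0.6 * np.sqrt((n - 2) / (1 - 0.36))
        p_oracle = 2 * stats.t.sf(t_oracle, n - 2)
        assert p.loc[1, "tr"] == pytest.approx(p_oracle, abs=1e-12)
        assert p_oracle == pytest.approx(0.018, abs=1e-3)

    def test_constant_trait_reported_missing(self):
        rng = np.random.default_rng(13)
        eig = self._eig([rng.normal(size=10)])
        traits = pd.DataFrame({"tr": np.ones(10)}, index=eig.columns)
        r, _ = conet.module_trait_correlation(eig, traits)
        assert np.isnan(r.loc[1, "tr"])


class TestExportNetwork:
    def test_strict_cutoff(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 0.31
        A[1, 2] = A[2, 1] = 0.29
        edges = conet.export_network(pd.DataFrame(A), weight_cutoff=0.3)
        assert len(edges) == 1
        assert edges.iloc[0]["weight"] == pytest.approx(0.31)

    def test_all_below_cutoff_gives_empty_list(self):
        edges = conet.export_network(pd.DataFrame(np.full((4, 4), 0.2)), 0.3)
        assert edges.empty

    def test_each_pair_appears_once(self):
        rng = np.random.default_rng(14)
        A = rng.uniform(0, 1, (10, 10))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        df = pd.DataFrame(A, index=[f"P{i}" for i in range(10)],
                          columns=[f"P{i}" for i in range(10)])
        edges = conet.export_network(df, 0.3)
        # oracle: brute-force enumeration of upper-triangle edges
        expected = {
            (f"P{i}", f"P{j}")
            for i in range(10) for j in range(i + 1, 10)
            if A[i, j] > 0.3
        }
        got = set(zip(edges["source"], edges["target"]))
        assert got == expected
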