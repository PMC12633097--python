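"""bicor, adjacency, TOM, module detection, eigenproteins, kME refinement."""

import numpy as np
import pandas as pd
import pytest

import vascnet as v
from vascnet.network import _one_reassign_sweep, _zscore_impute
from conftest import make_matrix
from _oracles import bicor_oracle, eigenprotein_oracle, tom_oracle


class TestBicor:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=25)
        assert v.bicor(x, x) == pytest.approx(1.0)

    @pytest.mark.parametrize("b", [2.5, -0.7])
    def test_affine_transform_gives_sign(self, b):
        rng = np.random.default_rng(1)
        x = rng.normal(size=25)
        assert v.bicor(x, 3.0 + b * x) == pytest.approx(np.sign(b))

    def test_matches_published_formula_on_random_pairs(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            x = rng.normal(size=20)
            y = 0.5 * x + rng.normal(size=20)
            assert v.bicor(x, y) == pytest.approx(bicor_oracle(x, y),
                                                  abs=1e-12)

    def test_matrix_agrees_with_pairwise(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(6, 30))
        C = v.bicor_matrix(make_matrix(vals)).to_numpy()
        for i in range(6):
            for j in range(6):
                expected = 1.0 if i == j else bicor_oracle(vals[i], vals[j])
                assert C[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_mad_falls_back_to_pearson(self):
        # x constant in the middle: median-absolute-deviation zero
        x = np.array([1.0, 5, 5, 5, 5, 5, 5, 5, 5, 9])
        rng = np.random.default_rng(4)
        y = x + rng.normal(0, 0.1, size=10)
        r = v.bicor(x, y)
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_too_few_pairwise_complete_is_nan(self):
        x = np.array([1.0, 2, 3, np.nan, np.nan, np.nan])
        y = np.array([np.nan, 2, 3, 4.0, 5, np.nan])
        assert np.isnan(v.bicor(x, y))

    def test_pairwise_complete_missing_handling(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = 0.6 * x + rng.normal(size=30)
        xm = x.copy()
        xm[:4] = np.nan
        r = v.bicor(xm, y)
        assert np.isfinite(r)
        assert abs(r) <= 1.0


class TestAdjacency:
    def test_forced_values(self):
        C = np.array([[1.0, 1.0, -1.0, 0.0],
                      [1.0, 1.0, 0.5, 0.2],
                      [-1.0, 0.5, 1.0, 0.1],
                      [0.0, 0.2, 0.1, 1.0]])
        A = v.signed_adjacency(C, beta=8.0)
        assert A[0, 1] == pytest.approx(1.0)
        assert A[0, 2] == pytest.approx(0.0)
        assert A[0, 3] == pytest.approx(0.5 ** 8)
        assert np.allclose(np.diag(A), 1.0)

    def test_undefined_entries_become_zero(self):
        C = np.array([[1.0, np.nan], [np.nan, 1.0]])
        A = v.signed_adjacency(C, beta=8.0)
        assert A[0, 1] == 0.0

    def test_monotone_in_beta(self):
        rng = np.random.default_rng(6)
        C = np.clip(rng.uniform(-0.9, 0.9, size=(5, 5)), -1, 1)
        C = (C + C.T) / 2
        np.fill_diagonal(C, 1.0)
        A8, A12 = v.signed_adjacency(C, 8.0), v.signed_adjacency(C, 12.0)
        off = ~np.eye(5, dtype=bool)
        assert np.all(A12[off] <= A8[off] + 1e-15)


class TestTom:
    def test_zero_offdiagonal(self):
        A = np.eye(5)
        T = v.tom_similarity(A)
        assert np.allclose(T[~np.eye(5, dtype=bool)], 0.0)
        assert np.allclose(np.diag(T), 1.0)

    def test_complete_graph_is_one(self):
        A = np.ones((6, 6))
        assert np.allclose(v.tom_similarity(A), 1.0)

    @pytest.mark.parametrize("denom", ["mean", "min"])
    def test_matches_bruteforce(self, denom):
        rng = np.random.default_rng(7)
        for _ in range(5):
            A = rng.uniform(0, 1, size=(6, 6))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 1.0)
            assert np.allclose(v.tom_similarity(A, denom),
                               tom_oracle(A, denom), atol=1e-12)


class TestDetectModules:
    def test_perfect_correlation_single_module(self):
        rng = np.random.default_rng(8)
        base = rng.normal(size=40)
        vals = np.array([2.0 * base + i for i in range(30)])
        X = make_matrix(vals)
        T = v.tom_similarity(v.signed_adjacency(v.bicor_matrix(X), 8.0))
        _, labels = v.detect_modules(T, v.NetworkParams())
        assert labels.nunique() == 1
        assert (labels == 1).all()

    def test_two_planted_blocks_recovered(self):
        rng = np.random.default_rng(9)
        f1, f2 = rng.standard_normal((2, 60))
        block1 = f1[None, :] + rng.normal(0, 0.2, (50, 60))
        block2 = f2[None, :] + rng.normal(0, 0.2, (50, 60))
        X = make_matrix(np.vstack([block1, block2]))
        T = v.tom_similarity(v.signed_adjacency(v.bicor_matrix(X), 8.0))
        _, labels = v.detect_modules(T, v.NetworkParams())
        arr = labels.to_numpy()
        assert set(arr) == {1, 2}
        assert len(set(arr[:50])) == 1 and len(set(arr[50:])) == 1

    def test_too_few_proteins(self):
        T = pd.DataFrame(np.eye(5), index=list("abcde"), columns=list("abcde"))
        with pytest.raises(ValueError, match="fewer proteins"):
            v.detect_modules(T, v.NetworkParams(min_module_size=10))


class TestEigenproteins:
    def test_identical_copies_give_profile(self):
        rng = np.random.default_rng(10)
        profile = rng.normal(size=30)
        vals = np.array([3.0 * profile + 1, 3.0 * profile + 1,
                         3.0 * profile + 1])
        X = make_matrix(vals)
        labels = pd.Series([1, 1, 1], index=X.protein_ids)
        ME, ve = v.module_eigenproteins(X, labels)
        standardized = (profile - profile.mean()) / profile.std(ddof=1)
        assert np.allclose(ME.loc["M1"], standardized, atol=1e-8)
        assert ve["M1"] == pytest.approx(1.0)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=(4, 25))
        X = make_matrix(vals)
        labels = pd.Series([1] * 4, index=X.protein_ids)
        ME, ve = v.module_eigenproteins(X, labels)
        me_ref, ve_ref = eigenprotein_oracle(_zscore_impute(vals))
        assert np.allclose(np.abs(ME.loc["M1"]), np.abs(me_ref), atol=1e-8)
        assert ve["M1"] == pytest.approx(ve_ref, abs=1e-10)

    def test_sign_convention(self, network_model, corrected):
        Xr = corrected[0]
        net = network_model
        for m in net.eigenproteins.index:
            members = net.labels[net.labels == int(m[1:])].index
            Z = _zscore_impute(Xr.values.loc[members].to_numpy())
            assert v.bicor(net.eigenproteins.loc[m], Z.mean(axis=0)) >= 0

    def test_unit_variance(self, network_model):
        sd = network_model.eigenproteins.std(axis=1, ddof=1)
        assert np.allclose(sd, 1.0, atol=1e-8)

    def test_tiny_module_rejected(self):
        X = make_matrix(np.random.default_rng(0).normal(size=(3, 20)))
        labels = pd.Series([1, 2, 2], index=X.protein_ids)
        with pytest.raises(ValueError, match="fewer than 2"):
            v.module_eigenproteins(X, labels)


class TestKme:
    def test_protein_equal_to_me_has_kme_one(self):
        rng = np.random.default_rng(12)
        profile = rng.normal(size=40)
        vals = np.vstack([profile + rng.normal(0, 0.05, (4, 40)), profile])
        X = make_matrix(vals)
        labels = pd.Series([1, 1, 1, 1, 0], index=X.protein_ids)
        ME, _ = v.module_eigenproteins(X, labels)
        kme = v.kme_table(X, ME)
        assert abs(kme.loc["P4", "M1"]) > 0.99

    def test_matches_direct_bicor(self, network_model, corrected):
        Xr = corrected[0]
        net = network_model
        rng = np.random.default_rng(13)
        for g in rng.choice(len(Xr.protein_ids), 5, replace=False):
            prot = Xr.protein_ids[g]
            for m in net.eigenproteins.index:
                expected = v.bicor(Xr.values.loc[prot],
                                   net.eigenproteins.loc[m])
                assert net.kme.loc[prot, m] == pytest.approx(expected,
                                                             abs=1e-10)


class TestReassignmentRules:
    def _kme(self, rows, modules=("M1", "M2")):
        return pd.DataFrame(rows, columns=modules,
                            index=[f"P{i}" for i in range(len(rows))])

    def test_fixed_point_unchanged(self):
        kme = self._kme([[0.8, 0.2], [0.1, 0.9]])
        labels = pd.Series([1, 2], index=kme.index)
        out = _one_reassign_sweep(kme, labels, 0.10, 0.30)
        assert out.equals(labels)

    def test_gap_rule_moves_protein(self):
        kme = self._kme([[0.2, 0.8], [0.9, 0.1]])
        labels = pd.Series([1, 1], index=kme.index)
        out = _one_reassign_sweep(kme, labels, 0.10, 0.30)
        assert out.iloc[0] == 2

    def test_floor_rule_greys_protein(self):
        kme = self._kme([[0.25, 0.25], [0.9, 0.1]])
        labels = pd.Series([1, 1], index=kme.index)
        out = _one_reassign_sweep(kme, labels, 0.10, 0.30)
        assert out.iloc[0] == 0

    def test_grey_protein_assigned_above_floor(self):
        kme = self._kme([[0.5, 0.1], [0.9, 0.1]])
        labels = pd.Series([0, 1], index=kme.index)
        out = _one_reassign_sweep(kme, labels, 0.10, 0.30)
        assert out.iloc[0] == 1

    def test_final_labels_are_fixed_point(self, network_model):
        net = network_model
        assert net.reassign_converged
        assert v.audit_reassignment(net.kme, net.labels, net.params)


class TestMergeModules:
    def _correlated_modules(self, target_corr, n=40, copies=4, seed=14):
        """Modules of identical copies of vectors with exact pairwise sample
        correlations given by ``target_corr``."""
        rng = np.random.default_rng(seed)
        k = target_corr.shape[0]
        raw = rng.normal(size=(k, n))
        raw -= raw.mean(axis=1, keepdims=True)
        q, _ = np.linalg.qr(raw.T)
        base = q[:, :k].T                       # orthonormal, zero mean
        L = np.linalg.cholesky(target_corr)
        profiles = L @ base
        vals = np.vstack([np.tile(p, (copies, 1))
                          + 0.0 for p in profiles])
        X = make_matrix(vals)
        labels = pd.Series(np.repeat(np.arange(1, k + 1), copies),
                           index=X.protein_ids)
        return X, labels

    def test_identical_mes_merged(self):
        corr = np.array([[1.0, 1.0], [1.0, 1.0]]) + np.eye(2) * 1e-12
        X, labels = self._correlated_modules(np.eye(2))
        # make module 2 a copy of module 1 so MEs coincide
        vals = X.values.to_numpy().copy()
        vals[4:] = vals[:4]
        X2 = make_matrix(vals)
        out = v.merge_close_modules(X2, labels, 0.07)
        assert out.nunique() == 1

    def test_uncorrelated_not_merged(self):
        X, labels = self._correlated_modules(np.eye(2))
        out = v.merge_close_modules(X, labels, 0.07)
        assert sorted(out.unique()) == [1, 2]

    def test_three_modules_chain_merge(self):
        # pairwise ME correlations (0.95, 0.95, 0.94): average linkage joins
        # the 0.05 pair first, then the third at mean(0.05, 0.06) = 0.055,
        # still below the 0.07 cut -> all three merge
        corr = np.array([[1.0, 0.95, 0.95],
                         [0.95, 1.0, 0.94],
                         [0.95, 0.94, 1.0]])
        X, labels = self._correlated_modules(corr)
        out = v.merge_close_modules(X, labels, 0.07)
        assert out.nunique() == 1


def test_module_sizes_nonincreasing(network_model):
    sizes = network_model.module_sizes.to_numpy()
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))


def test_renumber_ties_by_original_label():
    labels = pd.Series([3, 3, 1, 1, 2, 2, 2, 0], index=list("abcdefgh"))
    out = v.renumber_by_size(labels)
    # sizes: label 2 has 3 members -> becomes 1; labels 1 and 3 tie at 2
    # members -> smaller original label first
    assert out.tolist() == [3, 3, 2, 2, 1, 1, 1, 0]
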