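"""Descriptive statistics, correlation, regression, PCA and clustering."""

import numpy as np
import pandas as pd
import pytest

import lipochrom as lc
from lipochrom.retention import SingularDesignError


@pytest.fixture()
def toy():
    rng = np.random.default_rng(11)
    base = rng.normal(0, 1, 18)
    return pd.DataFrame({
        "A": 2 + 1.5 * base + rng.normal(0, 0.2, 18),
        "B": 1 + 0.8 * base + rng.normal(0, 0.2, 18),
        "C": rng.normal(0, 1, 18),
    })


class TestDescribe:
    def test_matches_brute_force(self, toy):
        out = lc.describe_systems(toy)
        for col in toy:
            v = sorted(toy[col])
            n = len(v)
            assert out.loc[col, "mean"] == pytest.approx(sum(v) / n)
            med = (v[n // 2] if n % 2 else (v[n // 2 - 1] + v[n // 2]) / 2)
            assert out.loc[col, "median"] == pytest.approx(med)
            assert out.loc[col, "min"] == v[0]
            assert out.loc[col, "max"] == v[-1]
            assert out.loc[col, "range"] == pytest.approx(v[-1] - v[0])
            m = sum(v) / n
            sd = (sum((x - m) ** 2 for x in v) / (n - 1)) ** 0.5
            assert out.loc[col, "std_dev"] == pytest.approx(sd)

    def test_constant_column(self):
        mat = pd.DataFrame({"k": [3.14] * 18})
        out = lc.describe_systems(mat)
        assert out.loc["k", "std_dev"] == 0
        assert out.loc["k", "range"] == 0
        assert out.loc["k", "mean"] == out.loc["k", "median"] == 3.14

    def test_skips_missing_entries(self):
        mat = pd.DataFrame({"x": [1.0, np.nan, 3.0, 5.0]})
        out = lc.describe_systems(mat)
        assert out.loc["x", "mean"] == pytest.approx(3.0)
        assert out.loc["x", "min"] == 1.0

    def test_unknown_and_all_missing_columns(self, toy):
        with pytest.raises(KeyError):
            lc.describe_systems(toy, ["nope"])
        with pytest.raises(ValueError, match="non-missing"):
            lc.describe_systems(pd.DataFrame({"x": [np.nan, np.nan, 1.0]}))


class TestCorrMatrix:
    def test_symmetric_unit_diagonal_bounded(self, fitted):
        corr = lc.corr_matrix(fitted.lipo_matrix)
        vals = corr.to_numpy()
        assert np.allclose(vals, vals.T, equal_nan=True)
        assert np.all(np.diag(vals) == 1.0)
        finite = vals[np.isfinite(vals)]
        assert finite.min() >= -1 - 1e-12 and finite.max() <= 1 + 1e-12

    def test_matches_covariance_oracle(self):
        x = [1.0, 2.0, 4.0, 4.5, 7.0]
        y = [0.5, 1.9, 3.2, 5.0, 6.1]
        mat = pd.DataFrame({"x": x, "y": y})
        xb, yb = sum(x) / 5, sum(y) / 5
        num = sum((a - xb) * (b - yb) for a, b in zip(x, y))
        den = (sum((a - xb) ** 2 for a in x) * sum((b - yb) ** 2 for b in y)) ** 0.5
        assert lc.corr_matrix(mat).loc["x", "y"] == pytest.approx(num / den, abs=1e-12)

    def test_pairwise_complete_observations(self):
        mat = pd.DataFrame({"x": [1, 2, 3, 4, np.nan],
                            "y": [1.1, 2.2, 2.7, 4.4, 9.9]})
        got = lc.corr_matrix(mat).loc["x", "y"]
        want = np.corrcoef([1, 2, 3, 4], [1.1, 2.2, 2.7, 4.4])[0, 1]
        assert got == pytest.approx(want, abs=1e-12)

    def test_too_few_pairs_marked_missing_with_warning(self):
        mat = pd.DataFrame({"x": [1, 2, np.nan, np.nan],
                            "y": [np.nan, 2.0, 3.0, 4.0]})
        with pytest.warns(UserWarning, match="complete pairs"):
            corr = lc.corr_matrix(mat)
        assert np.isnan(corr.loc["x", "y"])


class TestPairwiseRegression:
    def test_identity_line(self):
        mat = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]})
        mat["y"] = mat["x"]
        reg = lc.pairwise_regression(mat, "x", "y")
        assert reg.slope == pytest.approx(1.0, abs=1e-12)
        assert reg.intercept == pytest.approx(0.0, abs=1e-12)
        assert reg.r == pytest.approx(1.0, abs=1e-12)
        assert reg.s == pytest.approx(0.0, abs=1e-10)

    def test_r_equals_corr_entry_and_swap_invariance(self, toy):
        reg = lc.pairwise_regression(toy, "A", "B")
        rev = lc.pairwise_regression(toy, "B", "A")
        corr = lc.corr_matrix(toy)
        assert reg.r == pytest.approx(abs(corr.loc["A", "B"]), abs=1e-12)
        assert reg.r == pytest.approx(rev.r, abs=1e-14)
        assert reg.f_stat == pytest.approx(rev.f_stat, rel=1e-12)

    def test_uses_complete_pairs_only(self, toy):
        holed = toy.copy()
        holed.loc[0, "A"] = np.nan
        reg = lc.pairwise_regression(holed, "A", "B")
        assert reg.n == 17

    def test_degenerate_x(self):
        mat = pd.DataFrame({"x": [2.0, 2.0, 2.0], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(SingularDesignError):
            lc.pairwise_regression(mat, "x", "y")


class TestPCA:
    def test_two_perfectly_correlated_columns(self):
        x = np.arange(10.0)
        mat = pd.DataFrame({"a": x, "b": 3 * x + 1})
        res = lc.pca_scaled(mat)
        assert res.explained_var[0] == pytest.approx(1.0, abs=1e-12)

    def test_eigenvalues_match_correlation_eigendecomposition(self, toy):
        res = lc.pca_scaled(toy)
        # oracle: eigenvalues of the 3x3 correlation matrix, computed
        # independently from numpy's corrcoef + eigvalsh
        lam = np.sort(np.linalg.eigvalsh(np.corrcoef(toy.to_numpy().T)))[::-1]
        want = lam / lam.sum()
        np.testing.assert_allclose(res.explained_var, want, atol=1e-10)

    def test_matches_sklearn(self, toy):
        from sklearn.decomposition import PCA

        res = lc.pca_scaled(toy)
        scaled = (toy - toy.mean()) / toy.std(ddof=1)
        ref = PCA().fit(scaled.to_numpy())
        np.testing.assert_allclose(
            res.explained_var, ref.explained_variance_ratio_, atol=1e-10)
        # components agree up to sign
        for j in range(3):
            dot = abs(np.dot(res.loadings.to_numpy()[:, j], ref.components_[j]))
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_variance_sum_orthonormality_and_reconstruction(self, fitted, study):
        block = fitted.lipo_matrix.join(study.insilico, how="inner")
        res = lc.pca_scaled(block, missing="impute")
        assert res.explained_var.sum() == pytest.approx(1.0, abs=1e-10)
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
        # distinct-component scores are uncorrelated
        sc = res.scores.to_numpy()
        cc = np.corrcoef(sc[:, :5].T)
        np.testing.assert_allclose(cc - np.diag(np.diag(cc)), 0, atol=1e-10)
        # full reconstruction returns the autoscaled block
        filled = block.fillna(block.mean())
        scaled = (filled - filled.mean()) / filled.std(ddof=1)
        np.testing.assert_allclose(
            res.reconstruct().to_numpy(), scaled.to_numpy(), atol=1e-8)

    def test_column_order_invariance(self, toy):
        ev1 = lc.pca_scaled(toy).explained_var
        ev2 = lc.pca_scaled(toy[["C", "A", "B"]]).explained_var
        np.testing.assert_allclose(ev1, ev2, atol=1e-12)

    def test_sign_convention_deterministic(self, toy):
        res = lc.pca_scaled(toy)
        for j in range(res.n_components):
            col = res.loadings.iloc[:, j].to_numpy()
            assert col[np.argmax(np.abs(col))] > 0

    def test_missing_policy(self, toy):
        holed = toy.copy()
        holed.loc[0, "A"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            lc.pca_scaled(holed)
        dropped = lc.pca_scaled(holed, missing="drop")
        assert "A" not in dropped.loadings.index
        imputed = lc.pca_scaled(holed, missing="impute")
        assert "A" in imputed.loadings.index

    def test_zero_variance_column_dropped_with_warning(self, toy):
        toy2 = toy.assign(Z=1.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            res = lc.pca_scaled(toy2)
        assert res.dropped == ("Z",)


def _corr_to_frame(r_ab, r_ac, r_bc, n=4000, seed=5):
    """Gaussian sample with (approximately) the requested correlations."""
    target = np.array([[1, r_ab, r_ac], [r_ab, 1, r_bc], [r_ac, r_bc, 1]])
    chol = np.linalg.cholesky(target)
    z = np.random.default_rng(seed).normal(size=(n, 3))
    # exact sample decorrelation, then exact target correlation
    z = (z - z.mean(0)) / z.std(0, ddof=1)
    u, _, vt = np.linalg.svd(z, full_matrices=False)
    z_white = u @ vt * np.sqrt(n - 1)
    x = z_white @ chol.T
    return pd.DataFrame(x, columns=["a", "b", "c"])


class TestHCA:
    def test_duplicated_column_merges_at_zero(self, toy):
        mat = toy.assign(A2=toy["A"])
        res = lc.hca_corr(mat)
        assert res.merge_heights.min() == pytest.approx(0.0, abs=1e-12)
        first = res.merges()[0]
        leaves = {res.labels[first["left"]], res.labels[first["right"]]}
        assert leaves == {"A", "A2"}

    def test_manual_complete_linkage_trace(self):
        # correlations: r(a,b)=0.9, r(a,c)=0.5, r(b,c)=0.4
        mat = _corr_to_frame(0.9, 0.5, 0.4)
        res = lc.hca_corr(mat, linkage="complete")
        # hand agglomeration on d = 1 - r: merge {a,b} at 0.1, then c joins
        # at max(0.5, 0.6) = 0.6
        np.testing.assert_allclose(res.merge_heights, [0.1, 0.6], atol=1e-9)

    def test_heights_bounded_and_monotone(self, fitted):
        res = lc.hca_corr(fitted.lipo_matrix.dropna(axis="columns"))
        h = res.merge_heights
        assert h.min() >= 0.0 and h.max() <= 2.0 + 1e-12
        assert np.all(np.diff(h) >= -1e-12)

    def test_relabeling_permutes_leaves_not_heights(self, toy):
        res1 = lc.hca_corr(toy)
        renamed = toy.rename(columns={"A": "zz", "B": "qq", "C": "mm"})
        res2 = lc.hca_corr(renamed)
        np.testing.assert_allclose(res1.merge_heights, res2.merge_heights, atol=1e-12)
        assert set(res2.labels) == {"zz", "qq", "mm"}

    def test_newick_roundtrip(self, toy):
        from io import StringIO

        from skbio.tree import TreeNode

        res = lc.hca_corr(toy)
        tree = TreeNode.read(StringIO(res.to_newick()))
        assert {t.name for t in tree.tips()} == set(toy.columns)

    def test_linkage_choices(self, toy):
        for method in ("complete", "average", "single"):
            assert lc.hca_corr(toy, linkage=method).method == method
        with pytest.raises(ValueError):
            lc.hca_corr(toy, linkage="ward")
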