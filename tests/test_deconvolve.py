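"""SVR/NNLS deconvolution, permutation p-values, absolute and scaled scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from compdecon import (
    BulkDeconvolution,
    CellScoreTable,
    absolute_scores,
    deconvolve_nnls,
    deconvolve_svr,
    permutation_pvalue,
    scale_scores,
)


def _mix(basis: pd.DataFrame, w) -> pd.Series:
    return pd.Series(basis.to_numpy() @ np.asarray(w), index=basis.index)


class TestFractionRecovery:
    def test_pure_sample(self, marker_signature):
        basis, _ = marker_signature
        w = np.zeros(basis.shape[1])
        w[0] = 1.0
        mixture = _mix(basis, w)
        nnls = deconvolve_nnls(mixture, basis)
        svr, diag = deconvolve_svr(mixture, basis)
        assert nnls.iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert svr.iloc[0] >= 0.99
        assert (svr.iloc[1:] <= 0.01).all()
        assert diag["fit_pearson_r"] > 0.99

    def test_two_type_mixture_noiseless(self, marker_signature):
        basis, _ = marker_signature
        w = np.array([0.6, 0.4, 0, 0, 0, 0])
        mixture = _mix(basis, w)
        nnls = deconvolve_nnls(mixture, basis)
        svr, _ = deconvolve_svr(mixture, basis)
        np.testing.assert_allclose(nnls.to_numpy(), w, atol=1e-6)
        np.testing.assert_allclose(svr.to_numpy(), w, atol=0.02)

    def test_svr_nnls_agree_under_low_noise(self, marker_signature):
        basis, _ = marker_signature
        rng = np.random.default_rng(8)
        for _ in range(3):
            w = rng.dirichlet(np.ones(basis.shape[1]))
            noisy = _mix(basis, w) * np.exp(rng.normal(0, 0.05, size=basis.shape[0]))
            nnls = deconvolve_nnls(noisy, basis)
            svr, _ = deconvolve_svr(noisy, basis)
            np.testing.assert_allclose(svr.to_numpy(), nnls.to_numpy(), atol=0.05)

    def test_fraction_scale_invariance_and_absolute_doubling(self, marker_signature):
        basis, _ = marker_signature
        w = np.array([0.3, 0.3, 0.1, 0.1, 0.1, 0.1])
        mixture = _mix(basis, w)
        f1, _ = deconvolve_svr(mixture, basis)
        f2, _ = deconvolve_svr(mixture * 2.0, basis)
        np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), atol=1e-9)
        a1 = absolute_scores(f1, mixture, basis)
        a2 = absolute_scores(f2, mixture * 2.0, basis)
        np.testing.assert_allclose(a2.to_numpy(), 2.0 * a1.to_numpy(), rtol=1e-9)

    def test_too_few_shared_genes_raises(self, marker_signature):
        basis, _ = marker_signature
        mixture = _mix(basis, np.ones(basis.shape[1]) / basis.shape[1])
        with pytest.raises(ValueError, match="signature genes"):
            deconvolve_svr(mixture.iloc[:5], basis)

    def test_zero_mixture_gives_uniform_nnls_with_warning(self, marker_signature):
        basis, _ = marker_signature
        zero = pd.Series(0.0, index=basis.index)
        with pytest.warns(UserWarning, match="uniform"):
            f = deconvolve_nnls(zero, basis)
        np.testing.assert_allclose(f.to_numpy(), 1.0 / basis.shape[1])


class TestAbsoluteScores:
    def test_direct_formula(self):
        genes = [f"g{i}" for i in range(12)]
        basis = pd.DataFrame({"A": [5.0] * 12, "B": [5.0] * 12}, index=genes)
        mixture = pd.Series(10.0, index=genes)
        fractions = pd.Series([0.5, 0.5], index=["A", "B"])
        scores = absolute_scores(fractions, mixture, basis)
        np.testing.assert_allclose(scores.to_numpy(), [1.0, 1.0])
        assert scores.sum() == pytest.approx(2.0)

    def test_zero_fractions_zero_scores(self):
        genes = [f"g{i}" for i in range(12)]
        basis = pd.DataFrame({"A": [5.0] * 12, "B": [4.0] * 12}, index=genes)
        scores = absolute_scores(
            pd.Series([0.0, 0.0], index=["A", "B"]), pd.Series(10.0, index=genes), basis
        )
        assert (scores == 0).all()


class TestPermutation:
    def test_perfect_fit_minimal_p(self, marker_signature):
        basis, _ = marker_signature
        mixture = _mix(basis, np.array([0.5, 0.2, 0.1, 0.1, 0.05, 0.05]))
        p = permutation_pvalue(mixture, basis, n_permutations=19, seed=1)
        assert p == pytest.approx(1.0 / 20.0)

    def test_seeded_determinism(self, marker_signature):
        basis, _ = marker_signature
        rng = np.random.default_rng(3)
        mixture = pd.Series(
            rng.lognormal(2, 1, size=basis.shape[0]), index=basis.index
        )
        p1 = permutation_pvalue(mixture, basis, n_permutations=49, seed=5)
        p2 = permutation_pvalue(mixture, basis, n_permutations=49, seed=5)
        assert p1 == p2

    def test_null_pvalues_uniform(self):
        """Mixtures independent of the signature -> uniform permutation p."""
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(40)]
        basis = pd.DataFrame(
            rng.lognormal(1, 1, size=(40, 3)), index=genes, columns=["A", "B", "C"]
        )
        pvals = []
        for rep in range(200):
            mixture = pd.Series(rng.lognormal(1, 1, size=40), index=genes)
            pvals.append(
                permutation_pvalue(mixture, basis, n_permutations=99, seed=rep)
            )
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
        assert abs(np.mean(pvals) - 0.5) < 0.08

    def test_requires_at_least_one_permutation(self, marker_signature):
        basis, _ = marker_signature
        mixture = _mix(basis, np.ones(6) / 6)
        with pytest.raises(ValueError):
            permutation_pvalue(mixture, basis, n_permutations=0)


class TestScaling:
    def _table(self, values, samples):
        df = pd.DataFrame(values, index=samples, columns=["A", "B"])
        return CellScoreTable(
            fractions=df, absolute=df, diagnostics=pd.DataFrame(index=samples)
        )

    def test_single_stratum_unit_moments(self):
        rng = np.random.default_rng(0)
        samples = [f"s{i}" for i in range(8)]
        table = self._table(rng.uniform(1, 5, size=(8, 2)), samples)
        out = scale_scores(table, pd.Series("all", index=samples))
        np.testing.assert_allclose(out.scaled.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(out.scaled.std(ddof=1), 1.0, atol=1e-9)

    def test_two_strata_scaled_independently(self):
        rng = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(10)]
        table = self._table(rng.uniform(1, 5, size=(10, 2)) +
                            np.repeat([[0], [10]], 5, axis=0), samples)
        strata = pd.Series(["left"] * 5 + ["right"] * 5, index=samples)
        out = scale_scores(table, strata)
        for side in ("left", "right"):
            block = out.scaled[strata == side]
            np.testing.assert_allclose(block.mean(), 0.0, atol=1e-9)
            np.testing.assert_allclose(block.std(ddof=1), 1.0, atol=1e-9)

    def test_constant_column_names_cell_type(self):
        samples = [f"s{i}" for i in range(4)]
        values = np.ones((4, 2))
        values[:, 1] = [1, 2, 3, 4]
        table = self._table(values, samples)
        with pytest.raises(ValueError, match="'A'"):
            scale_scores(table, pd.Series("all", index=samples))

    def test_tiny_stratum_rejected(self):
        samples = ["s0", "s1", "s2"]
        table = self._table(np.random.default_rng(2).uniform(size=(3, 2)), samples)
        with pytest.raises(ValueError, match="fewer than 2"):
            scale_scores(table, pd.Series(["a", "a", "b"], index=samples))


def test_estimator_roundtrip(marker_signature, small_bulk):
    basis, _ = marker_signature
    experiment, truth = small_bulk
    est = BulkDeconvolution(method="svr").fit(basis)
    fractions = est.transform(experiment.tpm)
    assert fractions.shape == (len(experiment.samples), basis.shape[1])
    np.testing.assert_allclose(fractions.sum(axis=1), 1.0, atol=1e-6)
    assert est.diagnostics_["fit_pearson_r"].min() > 0.5
    params = est.get_params()
    assert params["method"] == "svr"
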