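"""NB GLM machinery: normalization, dispersion, fits, LRT, BH, collation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from compdecon import (
    CellScoreTable,
    NegativeBinomialDE,
    bh_adjust,
    collate_celltype_results,
    estimate_dispersion,
    fit_nb_glm,
    run_interaction_lrt,
    size_factors,
    stratify,
)
from compdecon.dge import _pair_design, moderate_dispersions


def _simple_design(n, treatment=None):
    X = pd.DataFrame({"Intercept": np.ones(n)})
    if treatment is not None:
        X["treatment"] = np.asarray(treatment, dtype=float)
    return X


def _nb_draw(rng, mu, alpha, size=None):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=size)


class TestSizeFactors:
    def test_hand_computed_example(self):
        counts = pd.DataFrame([[2, 4], [4, 8]], index=["g1", "g2"], columns=["a", "b"])
        sf = size_factors(counts)
        np.testing.assert_allclose(sf.to_numpy(), [0.70710678, 1.41421356], rtol=1e-6)

    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame(
            np.tile([[3], [7], [1]], (1, 4)), index=list("abc"), columns=list("wxyz")
        )
        np.testing.assert_allclose(size_factors(counts).to_numpy(), 1.0)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(1, 50, size=(30, 3)))
        scaled = counts.copy()
        scaled[2] = counts[2] * 3
        sf, sf3 = size_factors(counts), size_factors(scaled)
        # relative to an untouched sample, the scaled sample's factor triples
        assert (sf3[2] / sf3[0]) / (sf[2] / sf[0]) == pytest.approx(3.0, rel=1e-9)

    def test_no_common_gene_raises(self):
        counts = pd.DataFrame([[0, 1], [1, 0]])
        with pytest.raises(ValueError):
            size_factors(counts)


class TestBH:
    def test_textbook_example(self):
        q, sig = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, 0.04)
        assert sig.all()

    def test_single_p_passthrough(self):
        q, _ = bh_adjust([0.37])
        assert q[0] == pytest.approx(0.37)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=80),
        st.floats(min_value=0.01, max_value=0.3),
    )
    def test_matches_statsmodels_stepup(self, pvals, alpha):
        from statsmodels.stats.multitest import multipletests

        p = np.asarray(pvals)
        q, sig = bh_adjust(p, alpha)
        reject, q_sm, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)
        assert ((q < alpha) == sig).all()

    def test_q_monotone_in_p(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=200)
        q, _ = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestNBGLM:
    def test_matches_statsmodels_fit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n, alpha = 60, 0.15
        X = _simple_design(n, treatment=rng.integers(0, 2, size=n))
        X["covar"] = rng.normal(size=n)
        sf = pd.Series(np.exp(rng.normal(0, 0.2, size=n)))
        mu = sf.to_numpy() * np.exp(1.0 + 0.7 * X["treatment"] - 0.3 * X["covar"])
        y = _nb_draw(rng, mu, alpha)
        ours = fit_nb_glm(y, X, sf, alpha)
        theirs = sm.GLM(
            y,
            X.to_numpy(),
            family=sm.families.NegativeBinomial(alpha=alpha),
            offset=np.log(sf.to_numpy()),
        ).fit()
        np.testing.assert_allclose(ours.coef.to_numpy(), theirs.params, rtol=1e-5)
        np.testing.assert_allclose(ours.se.to_numpy(), theirs.bse, rtol=1e-4)
        assert ours.loglik == pytest.approx(theirs.llf, rel=1e-8)

    def test_offset_invariance(self):
        rng = np.random.default_rng(4)
        n = 40
        X = _simple_design(n, treatment=rng.integers(0, 2, size=n))
        sf = pd.Series(np.ones(n))
        y = _nb_draw(rng, 50.0, 0.05, size=n)
        base = fit_nb_glm(y, X, sf, 1e-8)
        doubled = fit_nb_glm(2 * y, X, 2 * sf, 1e-8)
        np.testing.assert_allclose(
            base.coef.to_numpy(), doubled.coef.to_numpy(), atol=1e-6
        )

    def test_rank_deficient_design_rejected(self):
        X = _simple_design(10)
        X["dup"] = 1.0
        with pytest.raises(ValueError, match="rank"):
            fit_nb_glm(np.ones(10), X, pd.Series(np.ones(10)), 0.1)

    def test_treatment_coefficient_recovery(self):
        """log2FC = 1 planted on 34 pairs, mean 100, alpha 0.1."""
        rng = np.random.default_rng(5)
        n_pairs = 34
        meta = pd.DataFrame(
            {
                "subject": np.repeat([f"S{i}" for i in range(n_pairs)], 2),
                "treatment": ["control", "ethanol"] * n_pairs,
            },
            index=[f"s{i}" for i in range(2 * n_pairs)],
        )
        X = _pair_design(meta)
        sf = pd.Series(np.ones(len(meta)), index=meta.index)
        mu = 100.0 * 2.0 ** X["treatment"].to_numpy()
        hits = 0
        for _ in range(100):
            y = _nb_draw(rng, mu, 0.1)
            fit = fit_nb_glm(y, X, sf, 0.1)
            if abs(fit.coef["treatment"] / np.log(2.0) - 1.0) < 0.3:
                hits += 1
        assert hits >= 90

    def test_null_wald_statistic_calibrated(self):
        rng = np.random.default_rng(6)
        n = 50
        X = _simple_design(n, treatment=np.tile([0, 1], 25))
        sf = pd.Series(np.ones(n))
        stats_ = []
        for _ in range(300):
            y = _nb_draw(rng, 80.0, 0.05, size=n)
            alpha = estimate_dispersion(y, X, sf)
            fit = fit_nb_glm(y, X, sf, alpha)
            stats_.append(fit.coef["treatment"] / fit.se["treatment"])
        z = np.asarray(stats_)
        assert 0.85 < z.std() < 1.2
        assert 0.01 < (np.abs(z) > 1.96).mean() < 0.10


class TestDispersion:
    def test_poisson_gene_small_alpha(self):
        rng = np.random.default_rng(7)
        X = _simple_design(34)
        sf = pd.Series(np.ones(34))
        small = 0
        for _ in range(100):
            y = rng.poisson(100.0, size=34)
            if estimate_dispersion(y, X, sf) < 0.05:
                small += 1
        assert small >= 90

    def test_nb_alpha_half_recovered(self):
        rng = np.random.default_rng(8)
        X = _simple_design(60)
        sf = pd.Series(np.ones(60))
        estimates = [
            estimate_dispersion(_nb_draw(rng, 200.0, 0.5, size=60), X, sf)
            for _ in range(200)
        ]
        assert 0.3 <= float(np.median(estimates)) <= 0.7

    def test_constant_gene_hits_floor(self):
        X = _simple_design(20)
        sf = pd.Series(np.ones(20))
        assert estimate_dispersion(np.full(20, 7.0), X, sf) <= 1e-6

    def test_moderation_pools_pure_noise(self):
        rng = np.random.default_rng(9)
        alphas = pd.Series(np.exp(np.log(0.02) + rng.normal(0, 0.25, size=500)))
        out = moderate_dispersions(alphas, residual_df=31)
        assert out.std() < alphas.std()
        assert np.log(out).std() < 0.1  # noise-only spread pools hard

    def test_moderation_keeps_real_spread(self):
        rng = np.random.default_rng(10)
        true = np.exp(rng.normal(np.log(0.05), 1.5, size=500))
        alphas = pd.Series(true * np.exp(rng.normal(0, 0.2, size=500)))
        out = moderate_dispersions(alphas, residual_df=31)
        # genuine biological spread must survive moderation
        assert np.corrcoef(np.log(out), np.log(true))[0, 1] > 0.9
        assert np.log(out).std() > 1.0


class TestInteractionLRT:
    def test_identical_designs_give_zero_statistic(self):
        rng = np.random.default_rng(11)
        n = 20
        X = _simple_design(n, treatment=np.tile([0, 1], 10))
        sf = pd.Series(np.ones(n))
        y = _nb_draw(rng, 60.0, 0.05, size=n)
        a = fit_nb_glm(y, X, sf, 0.05)
        b = fit_nb_glm(y, X, sf, 0.05)
        stat = max(0.0, 2.0 * (a.loglik - b.loglik))
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert stats.chi2.sf(stat, 1) == pytest.approx(1.0)

    def test_affine_rescaling_of_scores_preserves_lrt(self, small_bulk):
        experiment, truth = small_bulk
        sub = type(experiment)(
            counts=experiment.counts.iloc[:25],
            tpm=experiment.tpm,
            metadata=experiment.metadata,
        )
        rng = np.random.default_rng(12)
        noisy = truth.proportions + rng.normal(0, 0.02, truth.proportions.shape)
        scaled = (noisy - noisy.mean()) / noisy.std(ddof=1)
        table = CellScoreTable(
            fractions=noisy, absolute=noisy,
            diagnostics=pd.DataFrame(index=noisy.index), scaled=scaled,
        )
        res1 = run_interaction_lrt(sub, table, "TA")
        table2 = CellScoreTable(
            fractions=noisy, absolute=noisy,
            diagnostics=pd.DataFrame(index=noisy.index), scaled=scaled * 3.0 + 1.0,
        )
        res2 = run_interaction_lrt(sub, table2, "TA")
        np.testing.assert_allclose(
            res1["stat"].to_numpy(), res2["stat"].to_numpy(), atol=1e-5
        )
        np.testing.assert_allclose(
            res1["log2_fold_change"].to_numpy(),
            res2["log2_fold_change"].to_numpy() * 3.0,
            rtol=1e-4,
        )

    def test_unknown_cell_type_rejected(self, small_bulk):
        experiment, truth = small_bulk
        table = CellScoreTable(
            fractions=truth.proportions, absolute=truth.proportions,
            diagnostics=pd.DataFrame(index=truth.proportions.index),
            scaled=truth.proportions,
        )
        with pytest.raises(ValueError, match="Astrocyte"):
            run_interaction_lrt(experiment, table, "Astrocyte")


class TestCollation:
    def _table(self, genes, p, q, ct):
        df = pd.DataFrame(
            {"p_value": p, "q_value": q, "stat": 1.0, "log2_fold_change": 0.5},
            index=pd.Index(genes, name="gene"),
        )
        return df

    def test_best_type_per_gene_with_ties(self):
        tables = {
            "Stem": self._table(["g1", "g2"], [0.001, 0.5], [0.01, 0.5], "Stem"),
            "TA": self._table(["g1", "g2"], [0.2, 0.5], [0.3, 0.5], "TA"),
        }
        best = collate_celltype_results(tables)
        assert best.loc["g1", "cell_type"] == "Stem"
        # exact tie on p and q -> lexicographic winner
        assert best.loc["g2", "cell_type"] == "Stem"

    def test_matches_bruteforce_argmin(self):
        rng = np.random.default_rng(13)
        genes = [f"g{i}" for i in range(40)]
        tables = {
            ct: self._table(genes, rng.uniform(size=40), rng.uniform(size=40), ct)
            for ct in ["A", "B", "C"]
        }
        best = collate_celltype_results(tables)
        for g in genes:
            expected_ct = min(
                tables, key=lambda ct: (tables[ct].loc[g, "p_value"],
                                        tables[ct].loc[g, "q_value"], ct)
            )
            assert best.loc[g, "cell_type"] == expected_ct


class TestStratify:
    def test_pairs_kept_intact(self, small_bulk):
        experiment, _ = small_bulk
        strata = stratify(experiment, "location")
        assert set(strata) == {"left", "right"}
        for sub in strata.values():
            arms = sub.metadata.groupby("subject")["treatment"].nunique()
            assert (arms == 2).all()

    def test_bad_factor_rejected(self, small_bulk):
        with pytest.raises(ValueError):
            stratify(small_bulk[0], "passage")


def test_estimator_wrapper_dispatch(small_bulk):
    experiment, _ = small_bulk
    sub = type(experiment)(
        counts=experiment.counts.iloc[:15],
        tpm=experiment.tpm,
        metadata=experiment.metadata,
    )
    est = NegativeBinomialDE(model="paired").fit(sub)
    table = est.results_
    assert {"log2_fold_change", "p_value", "q_value", "significant"} <= set(table.columns)
    # significance flag is exactly q < 0.1, and q is monotone in p
    assert ((table["q_value"] < 0.1) == table["significant"]).all()
    order = table["p_value"].argsort()
    assert (np.diff(table["q_value"].to_numpy()[order]) >= -1e-12).all()
    with pytest.raises(ValueError):
        NegativeBinomialDE(model="interaction").fit(sub)
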