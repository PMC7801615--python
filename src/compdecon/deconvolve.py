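"""Mixture deconvolution: nu-SVR cell fractions, absolute scores, scaling.

The mixture (one bulk TPM column) is z-scored by its own moments and regressed
on the signature matrix (z-scored by its global moments, shared across
samples) with a linear-kernel nu-support-vector regression over a small nu
grid; the fit with the lowest reconstruction RMSE wins, negative coefficients
are clamped to zero and the rest normalized to relative fractions.  A
non-negative least squares solver provides the deterministic convex oracle for
the same problem.  Absolute scores rescale fractions by the overall
signature-gene expression of the sample, so totals can differ between arms;
scaled scores are the per-stratum z-scores that enter the DE designs.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator
from sklearn.svm import NuSVR

from .containers import BulkExperiment, CellScoreTable, SignatureMatrix

__all__ = [
    "deconvolve_svr",
    "deconvolve_nnls",
    "permutation_pvalue",
    "absolute_scores",
    "scale_scores",
    "deconvolve_experiment",
    "BulkDeconvolution",
]

DEFAULT_NU_GRID = (0.25, 0.5, 0.75)
_MIN_SHARED_GENES = 10


def _as_frame(signature) -> pd.DataFrame:
    if isinstance(signature, SignatureMatrix):
        return signature.basis
    return signature


def _shared(mixture: pd.Series, signature: pd.DataFrame):
    genes = signature.index.intersection(mixture.index)
    if len(genes) < _MIN_SHARED_GENES:
        raise ValueError(
            f"only {len(genes)} signature genes present in the mixture "
            f"(need >= {_MIN_SHARED_GENES})"
        )
    return signature.loc[genes], mixture.loc[genes]


def _zscore_problem(sig: pd.DataFrame, mix: pd.Series):
    A = sig.to_numpy(dtype=float)
    y = mix.to_numpy(dtype=float)
    a_sd = A.std()
    y_sd = y.std()
    if a_sd == 0 or y_sd == 0:
        raise ValueError("constant signature or mixture; cannot z-score")
    return (A - A.mean()) / a_sd, (y - y.mean()) / y_sd


def _svr_fit(Az: np.ndarray, yz: np.ndarray, nu: float, C: float):
    model = NuSVR(kernel="linear", nu=nu, C=C)
    model.fit(Az, yz)
    coef = np.asarray(model.coef_).ravel()
    recon = model.predict(Az)
    rmse = float(np.sqrt(np.mean((yz - recon) ** 2)))
    if np.std(recon) == 0:
        r = 0.0
    else:
        r = float(stats.pearsonr(yz, recon)[0])
    return coef, r, rmse


def _fractions_from_coef(coef: np.ndarray, columns) -> pd.Series:
    clamped = np.clip(coef, 0.0, None)
    total = clamped.sum()
    if total == 0:
        warnings.warn("all SVR coefficients non-positive; returning uniform fractions")
        clamped = np.full_like(clamped, 1.0)
        total = clamped.sum()
    return pd.Series(clamped / total, index=columns, name="fraction")


def deconvolve_svr(
    mixture: pd.Series,
    signature,
    nu_grid: Sequence[float] = DEFAULT_NU_GRID,
    C: float = 1.0,
) -> tuple[pd.Series, dict]:
    """nu-SVR relative fractions for one mixture; model selected by RMSE.

    Returns ``(fractions, stats)`` with ``stats`` carrying the winning ``nu``,
    ``fit_pearson_r`` and ``fit_rmse`` of the reconstruction on the z-scored
    problem.
    """
    sig, mix = _shared(mixture, _as_frame(signature))
    Az, yz = _zscore_problem(sig, mix)
    best = None
    for nu in nu_grid:
        coef, r, rmse = _svr_fit(Az, yz, nu, C)
        if best is None or rmse < best[2]:
            best = (nu, coef, rmse, r)
    nu, coef, rmse, r = best
    fractions = _fractions_from_coef(coef, sig.columns)
    return fractions, {"nu": nu, "fit_pearson_r": r, "fit_rmse": rmse}


def deconvolve_nnls(mixture: pd.Series, signature) -> pd.Series:
    """Non-negative least squares fractions (the convex oracle), sum one."""
    sig, mix = _shared(mixture, _as_frame(signature))
    coef, _ = optimize.nnls(sig.to_numpy(dtype=float), mix.to_numpy(dtype=float))
    total = coef.sum()
    if total == 0:
        warnings.warn("NNLS returned the zero vector; returning uniform fractions")
        coef = np.full_like(coef, 1.0)
        total = coef.sum()
    return pd.Series(coef / total, index=sig.columns, name="fraction")


def permutation_pvalue(
    mixture: pd.Series,
    signature,
    n_permutations: int = 500,
    seed: Optional[int] = None,
    nu_grid: Sequence[float] = DEFAULT_NU_GRID,
    C: float = 1.0,
) -> float:
    """Empirical deconvolution p-value by shuffling mixture values across genes.

    p = (1 + #{permuted Pearson r >= observed}) / (n_permutations + 1); each
    permutation re-fits the SVR at the observed winning nu.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    sig, mix = _shared(mixture, _as_frame(signature))
    Az, yz = _zscore_problem(sig, mix)
    best = None
    for nu in nu_grid:
        coef, r, rmse = _svr_fit(Az, yz, nu, C)
        if best is None or rmse < best[2]:
            best = (nu, coef, rmse, r)
    nu, _, _, r_obs = best
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        yp = rng.permutation(yz)
        _, r_perm, _ = _svr_fit(Az, yp, nu, C)
        if r_perm >= r_obs:
            exceed += 1
    return (1 + exceed) / (n_permutations + 1)


def absolute_scores(fractions: pd.Series, mixture: pd.Series, signature) -> pd.Series:
    """Absolute-mode scores: fraction x overall signature-gene expression.

    absolute_k = fraction_k * median(mixture TPM over signature genes)
    / median(signature entries).  Totals therefore track how strongly the
    sample expresses the signature overall, so the two arms can differ in
    total score even though relative fractions always sum to one.
    """
    sig, mix = _shared(mixture, _as_frame(signature))
    scale = float(np.median(mix.to_numpy())) / float(np.median(sig.to_numpy()))
    return (fractions * scale).rename("absolute_score")


def scale_scores(table: CellScoreTable, strata: pd.Series) -> CellScoreTable:
    """Center and scale absolute scores per cell type within each stratum.

    Strata are analysis subsets (e.g. all / left / right); each needs >= 2
    samples, and a zero-variance cell-type column raises an error naming it.
    """
    strata = pd.Series(strata).reindex(table.samples)
    if strata.isna().any():
        raise ValueError("every sample needs a stratum label")
    scaled = pd.DataFrame(index=table.absolute.index, columns=table.absolute.columns,
                          dtype=float)
    for stratum, idx in strata.groupby(strata).groups.items():
        block = table.absolute.loc[idx]
        if len(block) < 2:
            raise ValueError(f"stratum {stratum!r} has fewer than 2 samples")
        sd = block.std(ddof=1)
        flat = sd[sd == 0]
        if len(flat):
            raise ValueError(
                f"zero-variance absolute scores in stratum {stratum!r} for "
                f"cell types {list(flat.index)}"
            )
        scaled.loc[idx] = (block - block.mean()) / sd
    return CellScoreTable(
        fractions=table.fractions,
        absolute=table.absolute,
        diagnostics=table.diagnostics,
        scaled=scaled,
        strata=strata,
    )


def deconvolve_experiment(
    experiment: BulkExperiment,
    signature,
    method: str = "svr",
    nu_grid: Sequence[float] = DEFAULT_NU_GRID,
    C: float = 1.0,
    n_permutations: int = 0,
    seed: int = 0,
    strata: Optional[pd.Series] = None,
) -> CellScoreTable:
    """Deconvolve every sample of a bulk experiment and scale per stratum."""
    sig = _as_frame(signature)
    frac_rows, abs_rows, diag_rows = {}, {}, {}
    for i, sample in enumerate(experiment.samples):
        mix = experiment.tpm[sample]
        if method == "svr":
            fractions, diag = deconvolve_svr(mix, sig, nu_grid=nu_grid, C=C)
        elif method == "nnls":
            fractions = deconvolve_nnls(mix, sig)
            diag = {"nu": np.nan, "fit_pearson_r": np.nan, "fit_rmse": np.nan}
        else:
            raise ValueError(f"unknown method {method!r}")
        if n_permutations > 0:
            diag["permutation_p"] = permutation_pvalue(
                mix, sig, n_permutations=n_permutations, seed=seed + i,
                nu_grid=nu_grid, C=C,
            )
        else:
            diag["permutation_p"] = np.nan
        frac_rows[sample] = fractions
        abs_rows[sample] = absolute_scores(fractions, mix, sig)
        diag_rows[sample] = diag
    table = CellScoreTable(
        fractions=pd.DataFrame(frac_rows).T,
        absolute=pd.DataFrame(abs_rows).T,
        diagnostics=pd.DataFrame(diag_rows).T,
    )
    if strata is None:
        strata = pd.Series("all", index=table.samples)
    return scale_scores(table, strata)


class BulkDeconvolution(BaseEstimator):
    """Estimator facade: fit on a signature, transform TPM mixtures.

    ``transform`` returns the sample x cell-type fraction matrix and stores
    per-sample fit diagnostics in ``diagnostics_``.
    """

    def __init__(
        self,
        method: str = "svr",
        nu_grid: Sequence[float] = DEFAULT_NU_GRID,
        C: float = 1.0,
        n_permutations: int = 0,
        seed: int = 0,
    ):
        self.method = method
        self.nu_grid = nu_grid
        self.C = C
        self.n_permutations = n_permutations
        self.seed = seed

    def fit(self, signature, y=None) -> "BulkDeconvolution":
        self.signature_ = _as_frame(signature)
        return self

    def transform(self, tpm: pd.DataFrame) -> pd.DataFrame:
        frac_rows, diag_rows = {}, {}
        for i, sample in enumerate(tpm.columns):
            mix = tpm[sample]
            if self.method == "svr":
                fractions, diag = deconvolve_svr(
                    mix, self.signature_, nu_grid=self.nu_grid, C=self.C
                )
            else:
                fractions = deconvolve_nnls(mix, self.signature_)
                diag = {"nu": np.nan, "fit_pearson_r": np.nan, "fit_rmse": np.nan}
            if self.n_permutations > 0:
                diag["permutation_p"] = permutation_pvalue(
                    mix, self.signature_, n_permutations=self.n_permutations,
                    seed=self.seed + i, nu_grid=self.nu_grid, C=self.C,
                )
            frac_rows[sample] = fractions
            diag_rows[sample] = diag
        self.diagnostics_ = pd.DataFrame(diag_rows).T
        return pd.DataFrame(frac_rows).T

    def score_table(self, experiment: BulkExperiment, strata=None) -> CellScoreTable:
        return deconvolve_experiment(
            experiment,
            self.signature_,
            method=self.method,
            nu_grid=self.nu_grid,
            C=self.C,
            n_permutations=self.n_permutations,
            seed=self.seed,
            strata=strata,
        )
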