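"""Negative-binomial differential expression for the paired organoid design.

Three designs are supported, all log-link NB GLMs with log size factors as
offset and pair indicator covariates:

* unadjusted:  expression ~ pair + treatment                (Wald on treatment)
* adjusted:    expression ~ pair + cell scores + treatment  (Wald on treatment)
* interaction: expression ~ pair + score_k + treatment + treatment:score_k,
               tested against the model without the interaction by a
               likelihood-ratio test on 1 df, one cell type k at a time.

Per-gene dispersions are Cox-Reid adjusted profile maximum likelihood given
Poisson-fitted means (method-of-moments fallback, floored at 1e-8), then
moderated toward the experiment-wide median log-dispersion with a weight set
by the between-gene spread in excess of the expected estimation noise (see
:func:`moderate_dispersions`).  The moderation exists purely for
calibration: with ~30 residual degrees of freedom a raw per-gene estimate is
noisy enough that chance under-estimates inflate the far tail of the Wald and
LRT p-values; squeezing the estimates restores the advertised type-I/FDR
behaviour, which is the contract of this module.  Genes with all-zero counts
or non-convergent fits are excluded before Benjamini-Hochberg correction and
logged in ``result.attrs``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from .containers import TREATED, BulkExperiment, CellScoreTable

__all__ = [
    "size_factors",
    "estimate_dispersion",
    "fit_nb_glm",
    "bh_adjust",
    "run_unadjusted",
    "run_adjusted",
    "run_interaction_lrt",
    "collate_celltype_results",
    "stratify",
    "NegativeBinomialDE",
]

logger = logging.getLogger(__name__)

_ALPHA_FLOOR = 1e-8
_ALPHA_CEIL = 10.0


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors, one per sample.

    Uses only genes observed in every sample; each sample's factor is the
    median ratio of its counts to the per-gene geometric mean.
    """
    X = counts.to_numpy(dtype=float)
    everywhere = (X > 0).all(axis=1)
    if not everywhere.any():
        raise ValueError("no gene has nonzero counts in all samples")
    logX = np.log(X[everywhere])
    log_geo = logX.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logX - log_geo, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    """NB2 log-likelihood with mean mu and variance mu + alpha*mu^2."""
    r = 1.0 / alpha
    mu = np.maximum(mu, 1e-300)
    return float(
        np.sum(
            special.gammaln(y + r)
            - special.gammaln(r)
            - special.gammaln(y + 1.0)
            + y * np.log(alpha * mu / (1.0 + alpha * mu))
            - r * np.log1p(alpha * mu)
        )
    )


@dataclass
class NBFit:
    coef: pd.Series
    se: pd.Series
    loglik: float
    converged: bool
    mu: np.ndarray
    cov: np.ndarray


def _irls_nb(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    alpha: float,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float, bool, np.ndarray]:
    """Iteratively reweighted least squares for the log-link NB GLM."""
    n, p = X.shape
    work = np.log(y + 0.5) - offset
    beta, *_ = np.linalg.lstsq(X, work, rcond=None)
    ll_old = -np.inf
    converged = False
    A = np.eye(p)
    for _ in range(max_iter):
        eta = np.clip(X @ beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        Xw = X * w[:, None]
        A = Xw.T @ X
        b = Xw.T @ z
        try:
            beta_new = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            beta_new, *_ = np.linalg.lstsq(A, b, rcond=None)
        beta = beta_new
        ll = _nb_loglik(y, np.exp(np.clip(X @ beta + offset, -30.0, 30.0)), alpha)
        if abs(ll - ll_old) < tol * (abs(ll) + 0.1):
            converged = True
            break
        ll_old = ll
    eta = np.clip(X @ beta + offset, -30.0, 30.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    A = (X * w[:, None]).T @ X
    ll = _nb_loglik(y, mu, alpha)
    try:
        cov = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(A)
    return beta, cov, ll, converged, mu


def estimate_dispersion(
    y: np.ndarray,
    design: pd.DataFrame,
    size_factors_: pd.Series,
    cox_reid: bool = True,
) -> float:
    """Per-gene NB dispersion: adjusted profile ML given Poisson-fitted means.

    The Cox-Reid term ``-0.5 logdet(X' W X)`` compensates for the nuisance
    coefficients (pair indicators dominate the design), which would otherwise
    bias the dispersion low and inflate downstream test statistics.  Falls
    back to a method-of-moments estimate on failure; floored at 1e-8.
    """
    y = np.asarray(y, dtype=float)
    X = design.to_numpy(dtype=float)
    offset = np.log(size_factors_.to_numpy(dtype=float))
    _, _, _, conv, mu = _irls_nb(y, X, offset, alpha=_ALPHA_FLOOR)
    mu = np.maximum(mu, 1e-8)

    def neg_apl(log_alpha: float) -> float:
        a = math.exp(log_alpha)
        ll = _nb_loglik(y, mu, a)
        if cox_reid:
            w = mu / (1.0 + a * mu)
            sign, logdet = np.linalg.slogdet((X * w[:, None]).T @ X)
            if sign <= 0:
                return 1e300  # keep the bounded optimizer on finite ground
            ll -= 0.5 * logdet
        return -ll if np.isfinite(ll) else 1e300

    def mom() -> float:
        denom = float(np.sum(mu**2))
        if denom <= 0:
            return _ALPHA_FLOOR
        return float(np.clip(np.sum((y - mu) ** 2 - mu) / denom, _ALPHA_FLOOR, _ALPHA_CEIL))

    if not conv:
        return mom()
    try:
        res = optimize.minimize_scalar(
            neg_apl,
            bounds=(math.log(_ALPHA_FLOOR), math.log(_ALPHA_CEIL)),
            method="bounded",
            options={"xatol": 1e-6},
        )
        if not res.success or not np.isfinite(res.fun):
            return mom()
        return max(float(math.exp(res.x)), _ALPHA_FLOOR)
    except Exception:  # pragma: no cover - defensive
        return mom()


def fit_nb_glm(
    y: np.ndarray,
    design: pd.DataFrame,
    size_factors_: pd.Series,
    dispersion: float,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> NBFit:
    """Fit the log-link NB GLM with ``log(size factor)`` offset by IRLS."""
    y = np.asarray(y, dtype=float)
    X = design.to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    offset = np.log(size_factors_.to_numpy(dtype=float))
    beta, cov, ll, converged, mu = _irls_nb(y, X, offset, dispersion, tol, max_iter)
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    return NBFit(
        coef=pd.Series(beta, index=design.columns),
        se=pd.Series(se, index=design.columns),
        loglik=ll,
        converged=converged,
        mu=mu,
        cov=cov,
    )


def bh_adjust(pvalues, alpha: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and significance flags.

    q_i = min_{j >= i} (m * p_(j) / j) on the sorted vector, mapped back to the
    original order; significant means q < alpha.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q, q < alpha


# ---------------------------------------------------------------------------
# design construction


def _pair_design(metadata: pd.DataFrame) -> pd.DataFrame:
    subjects = metadata["subject"]
    dummies = pd.get_dummies(subjects, prefix="pair", dtype=float)
    dummies = dummies.iloc[:, 1:]  # drop first level -> intercept is its baseline
    X = pd.DataFrame({"Intercept": 1.0}, index=metadata.index)
    X = pd.concat([X, dummies], axis=1)
    X["treatment"] = (metadata["treatment"] == TREATED).astype(float)
    return X


def _insert_scores(
    X: pd.DataFrame, scores: CellScoreTable, cell_types: Optional[list[str]] = None
) -> pd.DataFrame:
    if scores.scaled is None:
        raise ValueError("scores must be scaled (per-stratum centered/scaled) first")
    cols = cell_types if cell_types is not None else scores.cell_types
    sc = scores.scaled.loc[X.index, cols]
    X = X.copy()
    pos = X.columns.get_loc("treatment")
    for i, ct in enumerate(cols):
        X.insert(pos + i, f"score_{ct}", sc[ct].to_numpy())
    return X


def _drop_collinear_scores(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Greedily drop the highest-VIF score covariate until full rank."""
    from statsmodels.stats.outliers_influence import variance_inflation_factor

    dropped: list[str] = []
    while np.linalg.matrix_rank(X.to_numpy(dtype=float)) < X.shape[1]:
        score_cols = [c for c in X.columns if c.startswith("score_")]
        if not score_cols:
            raise ValueError("design rank deficient and no score covariate left to drop")
        arr = X.to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vifs = {
                c: variance_inflation_factor(arr, X.columns.get_loc(c)) for c in score_cols
            }
        worst = max(vifs, key=lambda c: (np.inf if not np.isfinite(vifs[c]) else vifs[c]))
        logger.info("dropping collinear covariate %s (VIF=%.3g)", worst, vifs[worst])
        dropped.append(worst)
        X = X.drop(columns=[worst])
    return X, dropped


# ---------------------------------------------------------------------------
# per-gene engines


def moderate_dispersions(alphas: pd.Series, residual_df: int) -> pd.Series:
    """Squeeze per-gene log-dispersions toward their median.

    Normal-normal empirical Bayes in log space: the robust (MAD-based)
    between-gene spread in excess of the expected sampling noise
    ``trigamma(residual_df/2)`` sets the shrinkage weight.  When the observed
    spread is explained by estimation noise alone the estimates pool
    completely; genuine between-gene dispersion differences survive.  This
    stabilization keeps chance under-estimates from inflating the far tail of
    the Wald/LRT p-values.
    """
    if len(alphas) < 3:
        return alphas
    log_a = np.log(np.maximum(alphas.to_numpy(dtype=float), _ALPHA_FLOOR))
    center = float(np.median(log_a))
    v_noise = float(special.polygamma(1, max(residual_df, 1) / 2.0))
    spread = (1.4826 * float(np.median(np.abs(log_a - center)))) ** 2
    excess = max(spread - v_noise, 0.0)
    w = excess / (excess + v_noise)
    return pd.Series(np.exp(w * log_a + (1 - w) * center), index=alphas.index)


def _gene_dispersions(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    sf: pd.Series,
    excluded: list,
) -> pd.Series:
    alphas = {}
    for gene in counts.index:
        y = counts.loc[gene].to_numpy(dtype=float)
        if y.sum() == 0:
            excluded.append((gene, "all_zero"))
            continue
        alphas[gene] = estimate_dispersion(y, design, sf)
    residual_df = max(1, design.shape[0] - design.shape[1])
    return moderate_dispersions(pd.Series(alphas), residual_df)


def _wald_table(
    experiment: BulkExperiment,
    design: pd.DataFrame,
    test_col: str,
    fdr_alpha: float,
) -> pd.DataFrame:
    counts = experiment.counts
    sf = size_factors(counts)
    base_mean = (counts / sf).mean(axis=1)
    rows, tested, excluded = [], [], []
    alphas = _gene_dispersions(counts, design, sf, excluded)
    for gene in alphas.index:
        y = counts.loc[gene].to_numpy(dtype=float)
        alpha = float(alphas[gene])
        fit = fit_nb_glm(y, design, sf, alpha)
        if not fit.converged or fit.se[test_col] == 0:
            excluded.append((gene, "non_convergent"))
            continue
        b = fit.coef[test_col]
        stat = b / fit.se[test_col]
        rows.append(
            {
                "gene": gene,
                "log2_fold_change": b / math.log(2.0),
                "stat": stat,
                "p_value": 2.0 * stats.norm.sf(abs(stat)),
                "base_mean": base_mean[gene],
                "dispersion": alpha,
            }
        )
        tested.append(gene)
    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["log2_fold_change", "stat", "p_value", "base_mean", "dispersion"]
    )
    if len(table):
        q, sig = bh_adjust(table["p_value"].to_numpy(), fdr_alpha)
        table["q_value"] = q
        table["significant"] = sig
    table.attrs["excluded"] = excluded
    table.attrs["fdr_alpha"] = fdr_alpha
    if excluded:
        logger.info("excluded %d genes before BH: %s ...", len(excluded), excluded[:3])
    return table


def run_unadjusted(experiment: BulkExperiment, fdr_alpha: float = 0.1) -> pd.DataFrame:
    """Paired DE: expression ~ pair + treatment, Wald test on treatment."""
    X = _pair_design(experiment.metadata)
    return _wald_table(experiment, X, "treatment", fdr_alpha)


def run_adjusted(
    experiment: BulkExperiment, scores: CellScoreTable, fdr_alpha: float = 0.1
) -> pd.DataFrame:
    """Composition-adjusted DE: expression ~ pair + cell scores + treatment.

    All cell-score covariates enter; if that leaves the design rank deficient,
    score covariates are dropped greedily by variance-inflation factor and the
    drops are reported in ``result.attrs["dropped_covariates"]``.
    """
    X = _insert_scores(_pair_design(experiment.metadata), scores)
    X, dropped = _drop_collinear_scores(X)
    table = _wald_table(experiment, X, "treatment", fdr_alpha)
    table.attrs["dropped_covariates"] = dropped
    return table


def run_interaction_lrt(
    experiment: BulkExperiment,
    scores: CellScoreTable,
    cell_type: str,
    fdr_alpha: float = 0.1,
) -> pd.DataFrame:
    """Cell-type-specific response: LRT for the treatment x score interaction.

    Full model: pair + score_k + treatment + treatment:score_k; reduced model
    drops the interaction.  The statistic 2*(ll_full - ll_reduced) is referred
    to chi-square with 1 df.  The reported coefficient is the interaction term
    in log2 units; BH correction is applied within this cell type's table.
    """
    if cell_type not in scores.cell_types:
        raise ValueError(f"cell type {cell_type!r} not present in scores")
    X_red = _insert_scores(_pair_design(experiment.metadata), scores, [cell_type])
    inter = f"treatment:score_{cell_type}"
    X_full = X_red.copy()
    X_full[inter] = X_full["treatment"] * X_full[f"score_{cell_type}"]

    counts = experiment.counts
    sf = size_factors(counts)
    base_mean = (counts / sf).mean(axis=1)
    rows, excluded = [], []
    alphas = _gene_dispersions(counts, X_full, sf, excluded)
    for gene in alphas.index:
        y = counts.loc[gene].to_numpy(dtype=float)
        alpha = float(alphas[gene])
        fit_full = fit_nb_glm(y, X_full, sf, alpha)
        fit_red = fit_nb_glm(y, X_red, sf, alpha)
        if not (fit_full.converged and fit_red.converged):
            excluded.append((gene, "non_convergent"))
            continue
        stat = max(0.0, 2.0 * (fit_full.loglik - fit_red.loglik))
        rows.append(
            {
                "gene": gene,
                "log2_fold_change": fit_full.coef[inter] / math.log(2.0),
                "stat": stat,
                "p_value": stats.chi2.sf(stat, df=1),
                "base_mean": base_mean[gene],
                "dispersion": alpha,
            }
        )
    table = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["log2_fold_change", "stat", "p_value", "base_mean", "dispersion"]
    )
    if len(table):
        q, sig = bh_adjust(table["p_value"].to_numpy(), fdr_alpha)
        table["q_value"] = q
        table["significant"] = sig
    table.attrs["excluded"] = excluded
    table.attrs["cell_type"] = cell_type
    table.attrs["fdr_alpha"] = fdr_alpha
    return table


def collate_celltype_results(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per gene, keep the most significant interaction across cell types.

    Ties on p are broken by smaller q, then lexicographic cell-type name.
    The input per-type tables are left untouched.
    """
    frames = []
    for ct in sorted(tables):
        t = tables[ct].copy()
        t["cell_type"] = ct
        frames.append(t.reset_index())
    allrows = pd.concat(frames, ignore_index=True)
    allrows = allrows.sort_values(
        ["p_value", "q_value", "cell_type"], kind="mergesort"
    )
    best = allrows.drop_duplicates(subset="gene", keep="first").set_index("gene")
    return best.sort_index()


def stratify(experiment: BulkExperiment, factor: str) -> dict[str, BulkExperiment]:
    """Split an experiment by ``location`` or ``sex``, keeping pairs intact."""
    if factor not in ("location", "sex"):
        raise ValueError("factor must be 'location' or 'sex'")
    per_subject = experiment.metadata.groupby("subject")[factor].nunique()
    if (per_subject > 1).any():
        raise ValueError(f"factor {factor!r} varies within a pair")
    out = {}
    for level, grp in experiment.metadata.groupby(factor, sort=True):
        out[str(level)] = experiment.subset(grp.index)
    return out


class NegativeBinomialDE(BaseEstimator):
    """scikit-learn-style wrapper around the three DE designs.

    Parameters
    ----------
    model : {"paired", "adjusted", "interaction"}
        Which design to fit.
    cell_type : str, optional
        Target cell type for the interaction LRT.
    fdr_alpha : float
        BH significance threshold (significant means q < fdr_alpha).
    """

    def __init__(self, model: str = "paired", cell_type: Optional[str] = None,
                 fdr_alpha: float = 0.1):
        self.model = model
        self.cell_type = cell_type
        self.fdr_alpha = fdr_alpha

    def fit(self, experiment: BulkExperiment, scores: Optional[CellScoreTable] = None):
        if self.model == "paired":
            self.results_ = run_unadjusted(experiment, self.fdr_alpha)
        elif self.model == "adjusted":
            if scores is None:
                raise ValueError("adjusted model requires cell scores")
            self.results_ = run_adjusted(experiment, scores, self.fdr_alpha)
        elif self.model == "interaction":
            if scores is None or self.cell_type is None:
                raise ValueError("interaction model requires scores and cell_type")
            self.results_ = run_interaction_lrt(
                experiment, scores, self.cell_type, self.fdr_alpha
            )
        else:
            raise ValueError(f"unknown model {self.model!r}")
        return self
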