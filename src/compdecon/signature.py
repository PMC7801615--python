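"""Signature-matrix construction by condition-number minimization.

Candidate markers per cell type are genes that pass an expression floor and a
one-vs-rest Welch t-test (on log2(CPM+1)) at BH q below a threshold with a
positive fold change.  For each per-type marker count G in a configured range,
the union of every type's top-G candidates defines a gene x cell-type basis of
mean normalized expression; the basis minimizing the 2-norm condition number
is the signature.  A low condition number means the cell-type columns are well
separated, which is what makes the downstream mixture regression stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .containers import SignatureMatrix
from .dge import bh_adjust
from .reference import normalize_reference

__all__ = [
    "SignatureConfig",
    "condition_number",
    "marker_test",
    "build_signature",
    "SignatureBuilder",
]


@dataclass(frozen=True)
class SignatureConfig:
    """Signature selection parameters.

    ``expression_cutoff`` is a floor on the maximum per-type mean CPM (removes
    never-expressed genes); ``q_threshold`` the BH q cut for candidate markers;
    ``sampling_fraction`` the seeded cell-subsampling fraction; ``g_min``/
    ``g_max`` the sweep range for per-type marker counts; ``n_permutations``
    the default permutation count for downstream deconvolution p-values.
    Quantile normalization is disabled and the flag only documents that.
    """

    expression_cutoff: float = 0.15
    q_threshold: float = 0.001
    sampling_fraction: float = 1.0
    g_min: int = 100
    g_max: int = 600
    quantile_normalization: bool = False
    n_permutations: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.g_min > self.g_max:
            raise ValueError("g_min must not exceed g_max")
        if not 0 < self.q_threshold < 1:
            raise ValueError("q_threshold must lie in (0, 1)")
        if not 0 < self.sampling_fraction <= 1:
            raise ValueError("sampling_fraction must lie in (0, 1]")


def condition_number(basis) -> float:
    """2-norm condition number; +inf for a rank-deficient matrix."""
    arr = np.asarray(basis, dtype=float)
    if arr.size == 0:
        raise ValueError("empty basis")
    s = np.linalg.svd(arr, compute_uv=False)
    if s[0] == 0 or s[-1] <= s[0] * 1e-12:
        return float("inf")
    return float(s[0] / s[-1])


def _get_cpm(ref: ad.AnnData) -> np.ndarray:
    if "cpm" in ref.layers:
        return np.asarray(ref.layers["cpm"])
    return np.asarray(normalize_reference(ref).layers["cpm"])


def marker_test(ref: ad.AnnData, cell_type: str) -> pd.DataFrame:
    """One-vs-rest Welch t-test per gene on log2(CPM+1).

    Returns a frame indexed by gene with ``mean_in``/``mean_out`` (linear CPM),
    ``log2fc`` = log2((mean_in+1)/(mean_out+1)), ``p_value`` and BH ``q_value``
    (one family per cell type).  Genes constant in both groups get p = 1 by
    convention.
    """
    labels = ref.obs["cell_type"].astype(str).to_numpy()
    mask = labels == cell_type
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise ValueError(f"need >= 2 cells in {cell_type!r} and its complement")
    cpm = _get_cpm(ref)
    log_in = np.log2(cpm[mask] + 1.0)
    log_out = np.log2(cpm[~mask] + 1.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        stat, p = stats.ttest_ind(log_in, log_out, axis=0, equal_var=False)
    mean_in = cpm[mask].mean(axis=0)
    mean_out = cpm[~mask].mean(axis=0)
    # constant genes: identical means -> p = 1; degenerate separation -> p = 0
    bad = ~np.isfinite(p)
    equal = np.isclose(log_in.mean(axis=0), log_out.mean(axis=0))
    p = np.where(bad & equal, 1.0, p)
    p = np.where(bad & ~equal, 0.0, p)
    stat = np.where(np.isfinite(stat), stat, 0.0)
    q, _ = bh_adjust(p)
    return pd.DataFrame(
        {
            "mean_in": mean_in,
            "mean_out": mean_out,
            "log2fc": np.log2((mean_in + 1.0) / (mean_out + 1.0)),
            "stat": stat,
            "p_value": p,
            "q_value": q,
        },
        index=ref.var_names,
    )


class SignatureBuilder(BaseEstimator):
    """Builds the deconvolution basis from a labeled single-cell reference.

    Fitted attributes: ``signature_`` (gene x cell-type CPM means),
    ``chosen_g_``, ``condition_number_``, ``candidates_`` (per-type ranked
    candidate gene lists) and ``marker_tests_``.
    """

    def __init__(
        self,
        expression_cutoff: float = 0.15,
        q_threshold: float = 0.001,
        sampling_fraction: float = 1.0,
        g_min: int = 100,
        g_max: int = 600,
        quantile_normalization: bool = False,
        n_permutations: int = 500,
        seed: int = 0,
    ):
        self.expression_cutoff = expression_cutoff
        self.q_threshold = q_threshold
        self.sampling_fraction = sampling_fraction
        self.g_min = g_min
        self.g_max = g_max
        self.quantile_normalization = quantile_normalization
        self.n_permutations = n_permutations
        self.seed = seed

    def _config(self) -> SignatureConfig:
        return SignatureConfig(
            expression_cutoff=self.expression_cutoff,
            q_threshold=self.q_threshold,
            sampling_fraction=self.sampling_fraction,
            g_min=self.g_min,
            g_max=self.g_max,
            quantile_normalization=self.quantile_normalization,
            n_permutations=self.n_permutations,
            seed=self.seed,
        )

    def fit(self, ref: ad.AnnData, y=None) -> "SignatureBuilder":
        config = self._config()  # validates parameters
        if self.quantile_normalization:
            raise ValueError("quantile normalization is disabled in this workflow")
        types = sorted(ref.obs["cell_type"].astype(str).unique())
        if len(types) < 2:
            raise ValueError("need at least two cell types")

        if self.sampling_fraction < 1.0:
            rng = np.random.default_rng(self.seed)
            n_keep = max(2, int(round(self.sampling_fraction * ref.n_obs)))
            keep = np.sort(rng.choice(ref.n_obs, size=n_keep, replace=False))
            ref = ref[keep].copy()

        cpm = _get_cpm(ref)
        labels = ref.obs["cell_type"].astype(str).to_numpy()
        means = pd.DataFrame(
            {ct: cpm[labels == ct].mean(axis=0) for ct in types}, index=ref.var_names
        )
        expressed = means.max(axis=1) >= self.expression_cutoff
        means = means.loc[expressed]
        sub = ref[:, expressed.to_numpy()]

        self.marker_tests_ = {}
        self.candidates_ = {}
        for ct in types:
            res = marker_test(sub, ct)
            self.marker_tests_[ct] = res
            cand = res[(res["q_value"] < self.q_threshold) & (res["log2fc"] > 0)]
            if cand.empty:
                raise ValueError(f"no candidate marker genes for cell type {ct!r}")
            # rank: log2fc desc, then p asc, then gene id asc (fully deterministic)
            cand = cand.sort_index()
            cand = cand.sort_values("p_value", kind="mergesort")
            cand = cand.sort_values("log2fc", ascending=False, kind="mergesort")
            self.candidates_[ct] = list(cand.index)

        min_cand = min(len(v) for v in self.candidates_.values())
        if min_cand < self.g_min:
            warnings.warn(
                f"g_min={self.g_min} exceeds the smallest candidate list "
                f"({min_cand}); capping the sweep at each type's candidate count"
            )
        max_effective = max(len(v) for v in self.candidates_.values())

        best = (np.inf, None, None)
        for g in range(self.g_min, self.g_max + 1):
            union = np.unique(
                np.concatenate([np.asarray(v[:g]) for v in self.candidates_.values()])
            )
            basis = means.loc[union]
            c = condition_number(basis)
            if c < best[0]:
                best = (c, g, union)
            if g >= max_effective:
                break  # larger G cannot change any candidate list

        self.condition_number_, self.chosen_g_, genes = best
        if genes is None:
            # every sweep point was rank-deficient; keep the first union anyway
            g = self.g_min
            genes = np.unique(
                np.concatenate([np.asarray(v[:g]) for v in self.candidates_.values()])
            )
            self.chosen_g_ = g
            self.condition_number_ = condition_number(means.loc[genes])
        self.signature_ = means.loc[genes]
        self.config_ = config
        return self

    def to_signature_matrix(self) -> SignatureMatrix:
        return SignatureMatrix(
            basis=self.signature_,
            chosen_g=self.chosen_g_,
            condition_number=self.condition_number_,
            config=self.config_,
            candidates=self.candidates_,
        )


def build_signature(ref: ad.AnnData, config: SignatureConfig | None = None) -> SignatureMatrix:
    """Functional wrapper over :class:`SignatureBuilder`."""
    config = config or SignatureConfig()
    builder = SignatureBuilder(
        expression_cutoff=config.expression_cutoff,
        q_threshold=config.q_threshold,
        sampling_fraction=config.sampling_fraction,
        g_min=config.g_min,
        g_max=config.g_max,
        quantile_normalization=config.quantile_normalization,
        n_permutations=config.n_permutations,
        seed=config.seed,
    )
    return builder.fit(ref).to_signature_matrix()
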