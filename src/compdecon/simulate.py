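"""Synthetic single-cell references and paired bulk mixtures with known truth.

The generator emulates the structure the downstream analysis assumes: six
colon-crypt epithelial populations (stem, transit-amplifying, immature
colonocyte, immature goblet, enteroendocrine, tuft) with disjoint marker gene
sets, and a paired (treated vs vehicle) bulk experiment in which each subject's
cell composition responds to treatment on the log-proportion scale, with a
location-dependent effect size and optional cell-type-specific expression
interactions.  All counts are negative binomial with a shared dispersion, the
same family the differential-expression stage fits, so parameter recovery is
directly interpretable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import anndata as ad
import numpy as np
import pandas as pd

from .containers import CELL_TYPES, CONTROL, TREATED, BulkExperiment, SyntheticTruth

__all__ = [
    "SimulationConfig",
    "make_profiles",
    "simulate_reference",
    "simulate_paired_bulk",
    "shift_for_standardized_effect",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the paired organoid design the pipeline analyses: 34
    subjects (16 left / 18 right colon), six cell types whose baseline
    composition is a Dirichlet draw shared by the two arms of a pair, a
    treatment that expands the TA compartment at the expense of the immature
    secretory/absorptive lineages, and a weaker response in right-colon
    samples.
    """

    n_genes: int = 1000
    n_cell_types: int = 6
    cell_types: Sequence[str] = CELL_TYPES
    cells_per_type: int = 200
    markers_per_type: int = 150
    marker_log2fc: float = 3.0
    n_subjects: int = 34
    n_left: int = 16
    dirichlet_alpha: Sequence[float] = (1.6, 2.8, 1.6, 1.2, 0.4, 0.4)
    treatment_shift: Sequence[float] = (0.05, 0.35, -0.3, -0.3, 0.05, -0.1)
    location_modifier: float = 0.4  # scaling of treatment_shift for right-colon samples
    interaction_genes_per_type: Union[int, Mapping[str, int]] = 0
    interaction_log2fc: float = 1.5
    nb_dispersion: float = 0.02
    library_size_mean: float = 1e6
    sc_library_size_mean: float = 2e4
    mito_fraction_outliers: float = 0.05
    n_mito_genes: int = 13
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.cells_per_type <= 0 or self.n_subjects <= 0:
            raise ValueError("n_genes, cells_per_type and n_subjects must be positive")
        if self.markers_per_type <= 0:
            raise ValueError("markers_per_type must be positive")
        if len(self.cell_types) != self.n_cell_types:
            raise ValueError("cell_types must have length n_cell_types")
        if len(self.dirichlet_alpha) != self.n_cell_types:
            raise ValueError("dirichlet_alpha must have length n_cell_types")
        if len(self.treatment_shift) != self.n_cell_types:
            raise ValueError("treatment_shift must have length n_cell_types")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha entries must be positive")
        if self.n_cell_types * self.markers_per_type > self.n_genes:
            raise ValueError("marker sets exceed n_genes; marker sets must be disjoint")
        if not 0 <= self.mito_fraction_outliers < 1:
            raise ValueError("mito_fraction_outliers must be a proportion in [0, 1)")
        if self.nb_dispersion <= 0 or self.library_size_mean <= 0:
            raise ValueError("nb_dispersion and library_size_mean must be positive")
        if not 0 <= self.n_left <= self.n_subjects:
            raise ValueError("n_left must lie in [0, n_subjects]")

    def interaction_counts(self) -> dict[str, int]:
        if isinstance(self.interaction_genes_per_type, Mapping):
            bad = set(self.interaction_genes_per_type) - set(self.cell_types)
            if bad:
                raise ValueError(f"unknown cell types in interaction map: {sorted(bad)}")
            return {k: int(self.interaction_genes_per_type.get(k, 0)) for k in self.cell_types}
        return {k: int(self.interaction_genes_per_type) for k in self.cell_types}


def _gene_names(config: SimulationConfig) -> tuple[list[str], np.ndarray]:
    names = [f"G{i + 1:05d}" for i in range(config.n_genes)]
    names += [f"MT-{j + 1:02d}" for j in range(config.n_mito_genes)]
    mito = np.zeros(len(names), dtype=bool)
    mito[config.n_genes :] = True
    return names, mito


def make_profiles(config: SimulationConfig) -> tuple[pd.DataFrame, dict[str, set]]:
    """Expected relative expression per cell type plus the planted marker map.

    Baseline gene abundances are log-normal; each type's markers are elevated
    by ``marker_log2fc`` in that type only.  Mitochondrial genes share one
    profile across types (~4.5% of each column) so QC has realistic input
    without creating spurious between-type differences.  Deterministic given
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    names, mito = _gene_names(config)
    baseline = rng.lognormal(mean=0.0, sigma=1.2, size=config.n_genes)

    order = rng.permutation(config.n_genes)
    markers: dict[str, set] = {}
    profile = np.tile(baseline[:, None], (1, config.n_cell_types))
    for k, ct in enumerate(config.cell_types):
        idx = order[k * config.markers_per_type : (k + 1) * config.markers_per_type]
        markers[ct] = {names[i] for i in idx}
        profile[idx, k] *= 2.0 ** config.marker_log2fc

    mito_base = rng.lognormal(mean=0.0, sigma=0.5, size=config.n_mito_genes)
    mito_base /= mito_base.sum()
    mito_share = 0.045
    colsum = profile.sum(axis=0).mean()
    mito_rows = np.tile(
        (mito_base * mito_share / (1 - mito_share) * colsum)[:, None],
        (1, config.n_cell_types),
    )
    full = np.vstack([profile, mito_rows])
    profiles = pd.DataFrame(full, index=names, columns=list(config.cell_types))
    return profiles, markers


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """Negative binomial draw with mean ``mean`` and variance mean + alpha*mean^2."""
    r = 1.0 / alpha
    p = r / (r + np.maximum(mean, 0.0))
    return rng.negative_binomial(r, p)


def simulate_reference(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Labeled gene x cell count matrix plus planted truth.

    A configured fraction of cells is generated to fail QC, either with a tiny
    library (<250 detected genes) or with an inflated mitochondrial load
    (20-50% of counts), so the filtering stage has something to remove.
    """
    profiles, markers = make_profiles(config)
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    n_total = config.cells_per_type * config.n_cell_types
    labels = np.repeat(list(config.cell_types), config.cells_per_type)
    lib = rng.lognormal(
        mean=math.log(config.sc_library_size_mean) - 0.5 * 0.3**2, sigma=0.3, size=n_total
    )

    n_out = int(round(config.mito_fraction_outliers * n_total))
    outlier_idx = rng.choice(n_total, size=n_out, replace=False)
    low_lib = outlier_idx[: n_out // 2]
    high_mito = outlier_idx[n_out // 2 :]
    lib[low_lib] = rng.uniform(60, 180, size=len(low_lib))

    mito_mask = profiles.index.str.startswith("MT-")
    type_index = {ct: i for i, ct in enumerate(config.cell_types)}
    P = profiles.to_numpy()
    P = P / P.sum(axis=0, keepdims=True)

    counts = np.empty((n_total, P.shape[0]), dtype=np.int64)
    mito_boost = rng.uniform(0.2, 0.5, size=n_total)
    is_high_mito = np.zeros(n_total, dtype=bool)
    is_high_mito[high_mito] = True
    for i in range(n_total):
        p = P[:, type_index[labels[i]]].copy()
        if is_high_mito[i]:
            f = mito_boost[i]
            p_m = np.where(mito_mask, p, 0.0)
            p_n = np.where(mito_mask, 0.0, p)
            p = (1 - f) * p_n / p_n.sum() + f * p_m / p_m.sum()
        counts[i] = _nb_sample(rng, lib[i] * p, config.nb_dispersion)

    obs = pd.DataFrame(
        {
            "cell_type": pd.Categorical(labels, categories=list(config.cell_types)),
            "planted_outlier": np.isin(np.arange(n_total), outlier_idx),
        },
        index=[f"cell{i + 1:05d}" for i in range(n_total)],
    )
    var = pd.DataFrame({"mito": mito_mask}, index=profiles.index)
    adata = ad.AnnData(X=counts.astype(np.float64), obs=obs, var=var)

    truth = SyntheticTruth(markers=markers, profiles=profiles, seed=config.seed)
    return adata, truth


def shift_for_standardized_effect(
    config: SimulationConfig, cell_type: str, effect_sd: float
) -> float:
    """Log-proportion shift producing ~``effect_sd`` x SD(baseline proportion).

    Uses the delta-method linearization d(p)/d(shift) ~ p(1-p) around the
    Dirichlet mean, with SD(p) = sqrt(p(1-p)/(1+sum(alpha))).
    """
    alpha = np.asarray(config.dirichlet_alpha, dtype=float)
    k = list(config.cell_types).index(cell_type)
    p = alpha[k] / alpha.sum()
    sd = math.sqrt(p * (1 - p) / (1 + alpha.sum()))
    return effect_sd * sd / (p * (1 - p))


def _select_interaction_genes(
    config: SimulationConfig,
    profiles: pd.DataFrame,
    markers: dict[str, set],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Pick well-expressed non-marker genes for cell-type-specific effects."""
    counts = config.interaction_counts()
    total = sum(counts.values())
    if total == 0:
        return pd.DataFrame(columns=["gene", "cell_type", "log2fc"])

    all_markers = set().union(*markers.values())
    rel = profiles.to_numpy() / profiles.to_numpy().sum(axis=0, keepdims=True)
    mean_rel = pd.Series(rel.mean(axis=1), index=profiles.index)
    eligible = [
        g
        for g in profiles.index
        if g not in all_markers
        and not g.startswith("MT-")
        and mean_rel[g] * config.library_size_mean >= 120.0
    ]
    if len(eligible) < total:
        raise ValueError(
            f"only {len(eligible)} well-expressed non-marker genes available for "
            f"{total} requested interaction genes"
        )
    chosen = rng.choice(len(eligible), size=total, replace=False)
    genes = [eligible[i] for i in chosen]
    rows = []
    pos = 0
    for ct in config.cell_types:
        for _ in range(counts[ct]):
            rows.append({"gene": genes[pos], "cell_type": ct, "log2fc": config.interaction_log2fc})
            pos += 1
    return pd.DataFrame(rows)


def simulate_paired_bulk(
    config: SimulationConfig,
    reference_profiles: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
    markers: Optional[dict[str, set]] = None,
) -> tuple[BulkExperiment, SyntheticTruth]:
    """Paired bulk mixtures (one control + one treated sample per subject).

    A subject's baseline composition is a single Dirichlet draw shared by both
    arms; the treated arm shifts log-proportions by ``treatment_shift`` scaled
    by the location modifier and renormalizes, so proportions stay in the
    simplex for any effect size.  Planted interaction genes are additionally
    scaled by ``2**(log2fc * proportion_of_target_type)`` in treated samples --
    exactly the signal the treatment x proportion interaction test is built to
    detect.  Expected expression is mixed from the reference profiles and
    counts are drawn negative-binomially; TPM is computed from counts.
    """
    missing = [ct for ct in config.cell_types if ct not in reference_profiles.columns]
    if missing:
        raise ValueError(f"reference profiles missing cell types: {missing}")
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if markers is None:
        markers = make_profiles(config)[1]

    P = reference_profiles[list(config.cell_types)].to_numpy(dtype=float)
    P = P / P.sum(axis=0, keepdims=True)
    genes = reference_profiles.index
    shift = np.asarray(config.treatment_shift, dtype=float)

    interactions = _select_interaction_genes(config, reference_profiles, markers, rng)
    inter_by_type: dict[str, list[tuple[int, float]]] = {}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for _, row in interactions.iterrows():
        inter_by_type.setdefault(row["cell_type"], []).append(
            (gene_pos[row["gene"]], row["log2fc"])
        )

    sample_ids, meta_rows, prop_rows = [], [], []
    expected = np.empty((len(genes), 2 * config.n_subjects))
    col = 0
    type_list = list(config.cell_types)
    for s in range(config.n_subjects):
        subject = f"S{s + 1:02d}"
        location = "left" if s < config.n_left else "right"
        sex = "M" if s % 2 == 0 else "F"
        modifier = 1.0 if location == "left" else config.location_modifier

        base = rng.dirichlet(np.asarray(config.dirichlet_alpha, dtype=float))
        logp = np.log(base) + shift * modifier
        treated = np.exp(logp - logp.max())
        treated /= treated.sum()

        for arm, props in ((CONTROL, base), (TREATED, treated)):
            sid = f"{subject}_{'C' if arm == CONTROL else 'T'}"
            sample_ids.append(sid)
            meta_rows.append(
                {"subject": subject, "treatment": arm, "location": location, "sex": sex}
            )
            prop_rows.append(props)
            mix = P @ props
            if arm == TREATED:
                for ct, entries in inter_by_type.items():
                    pk = props[type_list.index(ct)]
                    for gi, l2 in entries:
                        mix[gi] *= 2.0 ** (l2 * pk)
            expected[:, col] = mix / mix.sum()
            col += 1

    lib = rng.lognormal(
        mean=math.log(config.library_size_mean) - 0.5 * 0.1**2, sigma=0.1, size=expected.shape[1]
    )
    counts = _nb_sample(rng, expected * lib[None, :], config.nb_dispersion).astype(np.int64)
    colsum = counts.sum(axis=0)
    if np.any(colsum == 0):
        raise ValueError("simulated sample with zero total counts; increase library size")
    tpm = counts / colsum[None, :] * 1e6

    metadata = pd.DataFrame(meta_rows, index=sample_ids)
    experiment = BulkExperiment(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        tpm=pd.DataFrame(tpm, index=genes, columns=sample_ids),
        metadata=metadata,
    )
    truth = SyntheticTruth(
        markers=markers,
        profiles=reference_profiles,
        seed=config.seed,
        proportions=pd.DataFrame(prop_rows, index=sample_ids, columns=type_list),
        interaction_effects=interactions,
    )
    return experiment, truth
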