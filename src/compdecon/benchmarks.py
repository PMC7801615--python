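"""Self-contained validation studies of the pipeline on synthetic data.

Each ``check_*`` function regenerates its inputs from a seed, runs the method
under study end to end, and returns the measured quantities as
``{name: {"value": float, "n": int}}``.  They double as the acceptance-style
property studies for the test suite and the reproduction script.  Problem
sizes are the package's desk-scale study conditions: six cell types, ~1000
genes, 34 subject pairs (16 left / 18 right), negative-binomial counts with
dispersion 0.02.
"""

from __future__ import annotations

import math
from dataclasses import replace
import numpy as np
import pandas as pd

from .composition import paired_score_test
from .containers import CellScoreTable
from .deconvolve import (
    absolute_scores,
    deconvolve_experiment,
    deconvolve_nnls,
    deconvolve_svr,
)
from .dge import bh_adjust, run_interaction_lrt, run_unadjusted
from .enrichment import MarkerSets, fisher_enrichment, overlap_table
from .reference import normalize_reference, qc_filter_cells
from .signature import SignatureConfig, build_signature
from .simulate import (
    SimulationConfig,
    make_profiles,
    shift_for_standardized_effect,
    simulate_paired_bulk,
    simulate_reference,
)

__all__ = [
    "check_deconvolution_oracle",
    "check_proportion_recovery",
    "check_signature_selection",
    "check_lrt_calibration",
    "check_effect_recovery",
    "check_composition_shift",
    "check_exact_oracles",
    "check_direction_pattern",
    "run_all_checks",
]


def _metric(value: float, n: int) -> dict:
    return {"value": float(value), "n": int(n)}


def _marker_basis(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Noise-free signature: expected CPM of the true marker genes."""
    profiles, markers = make_profiles(config)
    rel = profiles / profiles.sum(axis=0)
    genes = sorted(set().union(*markers.values()))
    return rel.loc[genes] * 1e6, markers


def check_deconvolution_oracle(seed: int) -> dict:
    """Noiseless mixtures of known proportions: NNLS exact, SVR close.

    Mixtures are exact linear combinations of the true marker-gene basis
    (pure samples, a 0.6/0.4 two-type blend, and a random simplex point).
    """
    config = SimulationConfig(seed=seed)
    basis, _ = _marker_basis(config)
    rng = np.random.default_rng(seed + 101)
    k = basis.shape[1]
    weight_sets = [np.eye(k)[i] for i in range(k)]
    w = np.zeros(k)
    w[[0, 1]] = [0.6, 0.4]
    weight_sets.append(w)
    weight_sets.append(rng.dirichlet(np.ones(k)))

    nnls_err = svr_err = 0.0
    for w in weight_sets:
        mixture = pd.Series(basis.to_numpy() @ w, index=basis.index)
        f_nnls = deconvolve_nnls(mixture, basis)
        f_svr, _ = deconvolve_svr(mixture, basis)
        nnls_err = max(nnls_err, float(np.abs(f_nnls.to_numpy() - w).max()))
        svr_err = max(svr_err, float(np.abs(f_svr.to_numpy() - w).max()))
    n = len(weight_sets) * basis.shape[1]
    return {
        "nnls_max_abs_error": _metric(nnls_err, n),
        "svr_max_abs_error": _metric(svr_err, n),
    }


def check_proportion_recovery(seed: int) -> dict:
    """20 paired mixtures with log-normal (sd 0.1) noise: r and RMSE per type.

    The signature is built along the full reference path (simulate -> QC ->
    CPM -> condition-number sweep); mixture TPM is the expected mix of the
    true profiles under per-gene multiplicative log-normal noise.
    """
    config = SimulationConfig(seed=seed, n_subjects=10, n_left=5)
    ref, truth = simulate_reference(config)
    refn = normalize_reference(qc_filter_cells(ref))
    signature = build_signature(refn, SignatureConfig(seed=seed))

    experiment, btruth = simulate_paired_bulk(config, truth.profiles)
    rng = np.random.default_rng(seed + 202)
    rel = truth.profiles.to_numpy() / truth.profiles.to_numpy().sum(axis=0, keepdims=True)
    order = list(truth.profiles.columns)
    est_rows = {}
    for sample in btruth.proportions.index:
        w = btruth.proportions.loc[sample, order].to_numpy()
        expected = rel @ w
        noisy = expected * np.exp(rng.normal(0.0, 0.1, size=expected.size))
        tpm = pd.Series(noisy / noisy.sum() * 1e6, index=truth.profiles.index)
        est_rows[sample], _ = deconvolve_svr(tpm, signature)
    est = pd.DataFrame(est_rows).T

    min_r, max_rmse = 1.0, 0.0
    for ct in order:
        r = float(np.corrcoef(est[ct], btruth.proportions[ct])[0, 1])
        rmse = float(np.sqrt(np.mean((est[ct] - btruth.proportions[ct]) ** 2)))
        min_r = min(min_r, r)
        max_rmse = max(max_rmse, rmse)
    n = est.shape[0]
    return {
        "fraction_recovery_min_pearson_r": _metric(min_r, n),
        "fraction_recovery_max_rmse": _metric(max_rmse, n),
    }


def check_signature_selection(seed: int) -> dict:
    """Planted markers (log2FC 3, 200 cells/type): selection quality.

    Precision is measured on the genes actually selected into the basis
    (candidates are ranked by fold change, so any spurious candidate sits at
    the tail and is dropped by the condition-number-chosen top-G); recall is
    measured on the candidate lists.  The chosen G is compared against an
    independent brute-force sweep of the condition number over the full range.
    """
    config = SimulationConfig(seed=seed)
    ref, truth = simulate_reference(config)
    refn = normalize_reference(qc_filter_cells(ref))
    from .signature import SignatureBuilder

    builder = SignatureBuilder(seed=seed).fit(refn)

    sel_hit = sel_tot = 0
    cand_hit = marker_tot = 0
    basis_genes = set(builder.signature_.index)
    for ct, cand in builder.candidates_.items():
        selected = [g for g in cand[: builder.chosen_g_] if g in basis_genes]
        sel_hit += len(set(selected) & truth.markers[ct])
        sel_tot += len(selected)
        cand_hit += len(set(cand) & truth.markers[ct])
        marker_tot += len(truth.markers[ct])

    # independent brute-force sweep over the full configured range
    labels = refn.obs["cell_type"].astype(str).to_numpy()
    cpm = np.asarray(refn.layers["cpm"])
    means = pd.DataFrame(
        {ct: cpm[labels == ct].mean(axis=0) for ct in sorted(truth.markers)},
        index=refn.var_names,
    )
    best_g, best_c = None, np.inf
    for g in range(builder.g_min, builder.g_max + 1):
        union = sorted(set().union(*(cand[:g] for cand in builder.candidates_.values())))
        arr = means.loc[union].to_numpy()
        s = np.linalg.svd(arr, compute_uv=False)
        c = np.inf if s[-1] <= s[0] * 1e-12 else s[0] / s[-1]
        if c < best_c:
            best_c, best_g = c, g
    return {
        "signature_precision": _metric(sel_hit / sel_tot, sel_tot),
        "signature_recall": _metric(cand_hit / marker_tot, marker_tot),
        "signature_chosen_g": _metric(builder.chosen_g_, len(basis_genes)),
        "signature_g_matches_bruteforce": _metric(
            1.0 if best_g == builder.chosen_g_ else 0.0, builder.g_max - builder.g_min + 1
        ),
    }


def _null_de_config(seed: int, n_genes: int, interactions) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        n_genes=n_genes,
        markers_per_type=60,
        treatment_shift=(0.0,) * 6,
        interaction_genes_per_type=interactions,
    )


_DE_SIGNATURE = SignatureConfig(g_min=30, g_max=60)


def _scores_for(config: SimulationConfig, experiment) -> CellScoreTable:
    ref, _ = simulate_reference(config)
    refn = normalize_reference(qc_filter_cells(ref))
    signature = build_signature(refn, replace(_DE_SIGNATURE, seed=config.seed))
    return deconvolve_experiment(experiment, signature)


def check_lrt_calibration(seed: int) -> dict:
    """Null data, >= 2000 interaction LRTs at n = 34 pairs: type-I error."""
    config = _null_de_config(seed, n_genes=2100, interactions=0)
    experiment, _ = simulate_paired_bulk(config, make_profiles(config)[0])
    scores = _scores_for(config, experiment)
    table = run_interaction_lrt(experiment, scores, "TA")
    p = table["p_value"].to_numpy()
    return {
        "interaction_lrt_type_i_error": _metric((p < 0.05).mean(), p.size),
        "interaction_lrt_null_discovery_rate": _metric(
            table["significant"].mean(), p.size
        ),
    }


def check_effect_recovery(seed: int) -> dict:
    """Planted TA-specific effects (log2FC 1.5, mean count >= 100): ranking.

    AUROC ranks planted against null genes by LRT statistic; recall and FDR
    are taken at the BH q < 0.1 significance call.
    """
    config = _null_de_config(seed, n_genes=1100, interactions={"TA": 100})
    profiles, markers = make_profiles(config)
    experiment, truth = simulate_paired_bulk(config, profiles, markers=markers)
    scores = _scores_for(config, experiment)
    table = run_interaction_lrt(experiment, scores, "TA")
    planted = table.index.isin(set(truth.interaction_effects["gene"]))
    from sklearn.metrics import roc_auc_score

    auroc = roc_auc_score(planted, table["stat"].to_numpy())
    disc = table["significant"].to_numpy()
    recall = float((disc & planted).sum() / planted.sum())
    fdr = float((disc & ~planted).sum() / max(1, disc.sum()))
    return {
        "interaction_auroc": _metric(auroc, len(table)),
        "interaction_recall_q10": _metric(recall, int(planted.sum())),
        "interaction_fdr_q10": _metric(fdr, int(disc.sum())),
    }


def check_composition_shift(seed: int, n_replicates: int = 100) -> dict:
    """Planted 0.3-SD TA increase under treatment, 100 replicates at n = 34.

    Success = the TA interval excludes zero with the expected sign.  Under
    the (control - treated) convention a treatment-driven TA increase gives a
    NEGATIVE mean difference.  The per-replicate deconvolution uses the NNLS
    estimator (the deterministic convex solver, equivalent to the SVR within
    its tolerance under these low-noise conditions).
    """
    base = SimulationConfig(seed=seed)
    shift = [0.0] * 6
    shift[list(base.cell_types).index("TA")] = shift_for_standardized_effect(
        base, "TA", 0.3
    )
    basis, _ = _marker_basis(base)

    hits = 0
    signs = 0
    for rep in range(n_replicates):
        # location_modifier=1 so every subject carries the full 0.3-SD shift
        config = replace(
            base,
            treatment_shift=tuple(shift),
            location_modifier=1.0,
            seed=seed + 1000 + rep,
        )
        experiment, _ = simulate_paired_bulk(config, basis)
        frac_rows, abs_rows = {}, {}
        for sample in experiment.samples:
            mix = experiment.tpm[sample]
            f = deconvolve_nnls(mix, basis)
            frac_rows[sample] = f
            abs_rows[sample] = absolute_scores(f, mix, basis)
        table = CellScoreTable(
            fractions=pd.DataFrame(frac_rows).T,
            absolute=pd.DataFrame(abs_rows).T,
            diagnostics=pd.DataFrame(index=experiment.samples),
        )
        res = paired_score_test(table, experiment.metadata)
        row = res.loc["TA"]
        if row["mean_difference"] < 0:
            signs += 1
        if row["ci_high"] < 0:
            hits += 1
    return {
        "composition_shift_power": _metric(hits / n_replicates, n_replicates),
        "composition_shift_sign_rate": _metric(signs / n_replicates, n_replicates),
    }


def _bh_bruteforce(p: np.ndarray) -> np.ndarray:
    """Textbook step-up definition, O(m^2), kept independent of bh_adjust."""
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos in range(m):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_pos, m)
        ]
        q[order[rank_pos]] = min(1.0, min(candidates))
    return q


def _hypergeom_tail_bruteforce(N: int, K: int, n: int, a: int) -> float:
    """Exact upper-tail by complete enumeration over feasible tables."""
    total = math.comb(N, n)
    acc = 0
    for k in range(a, min(K, n) + 1):
        if n - k > N - K:
            continue
        acc += math.comb(K, k) * math.comb(N - K, n - k)
    return acc / total


def check_exact_oracles(seed: int) -> dict:
    """BH vs step-up enumeration; Fisher tail vs complete enumeration."""
    rng = np.random.default_rng(seed + 505)
    bh_err = 0.0
    for _ in range(1000):
        m = int(rng.integers(1, 40))
        p = rng.uniform(size=m)
        q, _ = bh_adjust(p)
        bh_err = max(bh_err, float(np.abs(q - _bh_bruteforce(p)).max()))

    fisher_err = 0.0
    trials = 200
    for _ in range(trials):
        N = int(rng.integers(5, 31))
        K = int(rng.integers(1, N + 1))
        n = int(rng.integers(1, N + 1))
        universe = [f"g{i}" for i in range(N)]
        markers = set(universe[:K])
        degs = set(rng.choice(universe, size=n, replace=False))
        res = fisher_enrichment(degs, markers, universe)
        expected = _hypergeom_tail_bruteforce(N, K, n, res.a)
        fisher_err = max(fisher_err, abs(res.p_value - expected))
    return {
        "bh_max_abs_error": _metric(bh_err, 1000),
        "fisher_max_abs_error": _metric(fisher_err, trials),
    }


def check_direction_pattern(seed: int) -> dict:
    """Marker-overlap grid signs under the default treatment response.

    The generator's default shifts expand TA and deplete the immature
    colonocyte/goblet lineages, more strongly in left-colon samples.  The
    unadjusted paired DE is run on the full set and on each location stratum;
    the overlap grid against the true marker sets must show TA up-dominant
    and the two immature lineages down-dominant, with more nominal DEGs on
    the left than the right.
    """
    config = SimulationConfig(seed=seed)
    profiles, markers = make_profiles(config)
    experiment, truth = simulate_paired_bulk(config, profiles, markers=markers)

    grids = {}
    nominal_degs = {}
    from .dge import stratify

    universe = frozenset(experiment.counts.index)
    sets = MarkerSets(sets=truth.markers, universe=universe)
    subsets = {"full": experiment}
    subsets.update(stratify(experiment, "location"))
    for name, sub in subsets.items():
        table = run_unadjusted(sub)
        grids[name] = overlap_table(table, sets)
        nominal_degs[name] = int((table["p_value"] < 0.05).sum())

    checks = []
    for name in ("full", "left"):
        g = grids[name]
        checks.append(g[("TA", "nominal")]["Up"] > g[("TA", "nominal")]["Down"])
        for ct in ("ImmatureColonocyte", "ImmatureGoblet"):
            checks.append(g[(ct, "nominal")]["Down"] > g[(ct, "nominal")]["Up"])
    checks.append(nominal_degs["left"] > nominal_degs["right"])
    return {
        "direction_pattern_match": _metric(np.mean(checks), len(checks)),
        "left_right_nominal_deg_ratio": _metric(
            nominal_degs["left"] / max(1, nominal_degs["right"]), nominal_degs["left"]
        ),
    }


def run_all_checks(seed: int) -> dict:
    """Run every validation study with per-study derived seeds."""
    out = {}
    for i, fn in enumerate(
        (
            check_deconvolution_oracle,
            check_proportion_recovery,
            check_signature_selection,
            check_lrt_calibration,
            check_effect_recovery,
            check_composition_shift,
            check_exact_oracles,
            check_direction_pattern,
        )
    ):
        out.update(fn((seed * 1009 + i) % (2**31)))
    return out
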