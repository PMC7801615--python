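"""Shared data containers for the deconvolution / differential-expression pipeline.

The single-cell reference travels as an :class:`anndata.AnnData` (cells x genes,
``obs["cell_type"]`` labels, ``var["mito"]`` flags, optional ``layers["cpm"]``);
everything else is a small dataclass wrapping pandas frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

CONTROL = "control"
TREATED = "ethanol"

#: The six epithelial populations retained for deconvolution, in canonical order.
CELL_TYPES = (
    "Stem",
    "TA",
    "ImmatureColonocyte",
    "ImmatureGoblet",
    "Enteroendocrine",
    "Tuft",
)


@dataclass
class BulkExperiment:
    """Paired bulk RNA-seq experiment: counts, TPM and per-sample metadata.

    ``metadata`` is indexed by sample id with columns ``subject``, ``treatment``
    (``ethanol``/``control``), ``location`` (``left``/``right``) and ``sex``.
    Every subject must contribute exactly one sample per arm.
    """

    counts: pd.DataFrame
    tpm: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.tpm.columns):
            raise ValueError("counts and tpm must share sample columns")
        if not self.counts.columns.equals(pd.Index(self.metadata.index)):
            raise ValueError("metadata index must match sample columns")
        sums = self.tpm.sum(axis=0).to_numpy()
        if not np.allclose(sums, 1e6, atol=1e-3):
            raise ValueError("TPM columns must sum to 1e6")
        arms = self.metadata.groupby("subject")["treatment"].agg(
            lambda s: tuple(sorted(s))
        )
        bad = arms[arms != (CONTROL, TREATED)]
        if len(bad):
            raise ValueError(
                f"each subject needs one {CONTROL} and one {TREATED} sample; "
                f"offending subjects: {list(bad.index)[:5]}"
            )

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.metadata["subject"]))

    def pairing(self) -> pd.DataFrame:
        """subject -> (control sample, treated sample) table."""
        rows = {}
        for subj, grp in self.metadata.groupby("subject", sort=False):
            ctrl = grp.index[grp["treatment"] == CONTROL][0]
            trt = grp.index[grp["treatment"] == TREATED][0]
            rows[subj] = {"control": ctrl, "treated": trt}
        return pd.DataFrame.from_dict(rows, orient="index")

    def subset(self, samples) -> "BulkExperiment":
        samples = list(samples)
        return BulkExperiment(
            counts=self.counts[samples].copy(),
            tpm=self.tpm[samples].copy(),
            metadata=self.metadata.loc[samples].copy(),
        )


@dataclass
class CellScoreTable:
    """Per-sample deconvolution output.

    ``fractions`` rows sum to one; ``absolute`` carries the absolute-mode scores
    (fraction x overall signature-gene expression); ``scaled`` holds the
    per-stratum centered/scaled scores once :func:`scale_scores` has run.
    ``diagnostics`` has one row per sample: ``nu``, ``fit_pearson_r``,
    ``fit_rmse`` and (optionally) ``permutation_p``.
    """

    fractions: pd.DataFrame
    absolute: pd.DataFrame
    diagnostics: pd.DataFrame
    scaled: Optional[pd.DataFrame] = None
    strata: Optional[pd.Series] = None

    @property
    def cell_types(self) -> list[str]:
        return list(self.fractions.columns)

    @property
    def samples(self) -> pd.Index:
        return self.fractions.index

    def total(self) -> pd.Series:
        """Total absolute score per sample (tracks overall cellularity)."""
        return self.absolute.sum(axis=1).rename("total_absolute_score")


@dataclass
class SignatureMatrix:
    """Gene x cell-type basis of mean normalized expression.

    ``chosen_g`` is the per-type marker count selected by the condition-number
    sweep; ``condition_number`` the 2-norm condition number of the basis.
    """

    basis: pd.DataFrame
    chosen_g: int
    condition_number: float
    config: object = None
    candidates: dict = field(default_factory=dict)

    @property
    def genes(self) -> pd.Index:
        return self.basis.index

    @property
    def cell_types(self) -> list[str]:
        return list(self.basis.columns)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the synthetic-data generator.

    ``proportions``: sample x cell-type matrix (rows sum to 1); ``markers``:
    cell type -> set of true marker gene ids; ``interaction_effects``: one row
    per planted (gene, cell_type, log2fc) cell-type-specific treatment effect;
    ``profiles``: gene x cell-type expected relative expression.
    """

    markers: dict
    profiles: pd.DataFrame
    seed: int
    proportions: Optional[pd.DataFrame] = None
    interaction_effects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "cell_type", "log2fc"])
    )
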