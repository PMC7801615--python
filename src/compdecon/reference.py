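"""Quality filtering and relabeling of the single-cell reference.

Cells are kept when they have strictly more than 250 detected genes and a
mitochondrial count fraction strictly below 15% (both thresholds read
literally; the boundary cell at exactly 15% is removed).  Label handling
drops the populations that cannot be separated reliably in a deconvolution
basis (M cells, the mature absorptive/secretory types, cycling and secretory
TA) and merges the remaining immature-colonocyte and TA subpopulations, which
yields the six populations the signature is built on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd

from .containers import CELL_TYPES

__all__ = [
    "LabelPolicy",
    "DEFAULT_LABEL_POLICY",
    "qc_filter_cells",
    "apply_label_policy",
    "normalize_reference",
]


@dataclass(frozen=True)
class LabelPolicy:
    """Which original labels are dropped and how the rest are merged.

    ``merge_map`` maps original label -> final label; labels that already equal
    a final label are covered implicitly (identity merge).  With ``strict``
    any other label is an error, preventing silent signature contamination.
    """

    drop_types: frozenset = frozenset()
    merge_map: Mapping[str, str] = field(default_factory=dict)
    strict: bool = True

    def __post_init__(self) -> None:
        overlap = set(self.drop_types) & set(self.merge_map)
        if overlap:
            raise ValueError(f"labels both dropped and merged: {sorted(overlap)}")

    def resolve(self, label: str):
        """Final label, or None if dropped; KeyError when unmapped in strict mode."""
        if label in self.drop_types:
            return None
        if label in self.merge_map:
            return self.merge_map[label]
        if label in set(self.merge_map.values()) or not self.strict:
            return label
        raise KeyError(label)


#: Reproduces the six-population grouping used for signature construction.
DEFAULT_LABEL_POLICY = LabelPolicy(
    drop_types=frozenset(
        {
            "M",
            "M cells",
            "Goblet",
            "Mature Goblet",
            "Colonocyte",
            "Mature Colonocyte",
            "Colonocyte Progenitor",
            "Cycling TA",
            "Secretory TA",
        }
    ),
    merge_map={
        "TA1": "TA",
        "TA2": "TA",
        "TA 1": "TA",
        "TA 2": "TA",
        "Immature Colonocyte 1": "ImmatureColonocyte",
        "Immature Colonocyte 2": "ImmatureColonocyte",
        "Immature Colonocytes": "ImmatureColonocyte",
        "Immature Goblet": "ImmatureGoblet",
        **{ct: ct for ct in CELL_TYPES},
    },
)


def _mito_fraction(adata: ad.AnnData) -> np.ndarray:
    X = np.asarray(adata.X)
    total = X.sum(axis=1)
    if "mito" in adata.var:
        mito = X[:, adata.var["mito"].to_numpy(dtype=bool)].sum(axis=1)
    else:
        mito = np.zeros_like(total)
    return np.divide(mito, total, out=np.zeros_like(total, dtype=float), where=total > 0)


def qc_filter_cells(
    raw: ad.AnnData, min_genes: int = 250, max_mito: float = 0.15
) -> ad.AnnData:
    """Keep cells with > ``min_genes`` detected genes and mito fraction < ``max_mito``.

    Both inequalities are strict.  A summary of removed cells is stored in
    ``.uns["qc_report"]`` of the returned copy.  Raises if nothing survives.
    """
    X = np.asarray(raw.X)
    detected = (X > 0).sum(axis=1)
    mito_frac = _mito_fraction(raw)
    keep = (detected > min_genes) & (mito_frac < max_mito)
    if not keep.any():
        raise ValueError(
            "QC removed every cell; review min_genes/max_mito thresholds "
            f"(min_genes={min_genes}, max_mito={max_mito})"
        )
    out = raw[keep].copy()
    out.uns["qc_report"] = {
        "n_input": int(raw.n_obs),
        "n_kept": int(keep.sum()),
        "n_removed_low_genes": int((detected <= min_genes).sum()),
        "n_removed_high_mito": int(((mito_frac >= max_mito) & (detected > min_genes)).sum()),
        "min_genes": int(min_genes),
        "max_mito": float(max_mito),
    }
    return out


def apply_label_policy(ref: ad.AnnData, policy: LabelPolicy) -> ad.AnnData:
    """Drop and merge cell labels; errors on unmapped labels in strict mode."""
    labels = ref.obs["cell_type"].astype(str)
    resolved = {}
    unmapped = []
    for lab in labels.unique():
        try:
            resolved[lab] = policy.resolve(lab)
        except KeyError:
            unmapped.append(lab)
    if unmapped:
        raise ValueError(f"labels not covered by policy: {sorted(unmapped)}")
    new = labels.map(resolved)
    keep = new.notna().to_numpy()
    if not keep.any():
        raise ValueError("label policy dropped every cell")
    out = ref[keep].copy()
    out.obs["cell_type"] = pd.Categorical(new[keep])
    return out


def normalize_reference(ref: ad.AnnData) -> ad.AnnData:
    """Counts-per-million per cell in ``layers["cpm"]`` (linear scale).

    Droplet-style counts carry no usable length model, so normalization is
    depth-only.  Zero-count cells are removed with a warning.
    """
    X = np.asarray(ref.X)
    total = X.sum(axis=1)
    zero = total == 0
    if zero.any():
        warnings.warn(f"removed {int(zero.sum())} zero-count cells before normalization")
        ref = ref[~zero].copy()
        X = np.asarray(ref.X)
        total = X.sum(axis=1)
    else:
        ref = ref.copy()
    ref.layers["cpm"] = X / total[:, None] * 1e6
    return ref
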