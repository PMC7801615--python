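"""Marker-set overlap tabulation and one-sided Fisher enrichment.

The overlap grid counts up- and down-regulated DEGs intersecting each cell
type's marker list at both the nominal-p and FDR significance levels; the
enrichment test is the hypergeometric (one-way Fisher) upper tail against the
universe of genes actually tested in the corresponding DE run -- testing
against the whole annotation would inflate odds ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MarkerSets", "EnrichmentResult", "overlap_table", "fisher_enrichment",
           "enrichment_table"]


@dataclass(frozen=True)
class MarkerSets:
    """Cell type -> marker gene sets, intersected with a nonempty universe."""

    sets: dict
    universe: frozenset

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty gene universe")
        object.__setattr__(
            self,
            "sets",
            {k: frozenset(v) & self.universe for k, v in self.sets.items()},
        )


@dataclass(frozen=True)
class EnrichmentResult:
    cell_type: str
    a: int  # DEG & marker
    b: int  # DEG \ marker
    c: int  # marker \ DEG
    d: int  # neither
    odds_ratio: float
    p_value: float


def fisher_enrichment(de_genes, marker_set, universe) -> EnrichmentResult:
    """Upper-tail hypergeometric test of DEG / marker-set overlap.

    p = P(X >= a) with X ~ Hypergeom(|universe|, |markers|, |DEGs|); the
    sample odds ratio is (a*d)/(b*c), +inf when b*c = 0 with a*d > 0.
    """
    universe = frozenset(universe)
    if not universe:
        raise ValueError("empty gene universe")
    de = frozenset(de_genes) & universe
    mk = frozenset(marker_set) & universe
    a = len(de & mk)
    b = len(de - mk)
    c = len(mk - de)
    d = len(universe) - a - b - c
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = a * d / (b * c)
    p = float(stats.hypergeom.sf(a - 1, len(universe), len(mk), len(de)))
    return EnrichmentResult(cell_type="", a=a, b=b, c=c, d=d, odds_ratio=odds, p_value=p)


def enrichment_table(de_genes, markers: MarkerSets) -> pd.DataFrame:
    """One Fisher enrichment row per cell type."""
    rows = []
    for ct in markers.sets:
        res = fisher_enrichment(de_genes, markers.sets[ct], markers.universe)
        rows.append(
            {
                "cell_type": ct,
                "a": res.a,
                "b": res.b,
                "c": res.c,
                "d": res.d,
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")


def overlap_table(
    de_table: pd.DataFrame,
    markers: MarkerSets,
    nominal_alpha: float = 0.05,
) -> pd.DataFrame:
    """Direction x cell-type grid of DEG / marker overlaps.

    Rows ``Up``/``Down`` (by coefficient sign); columns are a MultiIndex
    (cell_type, level) with level ``nominal`` (p < nominal_alpha) and ``fdr``
    (the table's BH significance flag) -- the bracketed-count convention.
    """
    up = de_table["log2_fold_change"] > 0
    nominal = de_table["p_value"] < nominal_alpha
    fdr = de_table["significant"].astype(bool)
    grid = {}
    for ct, mset in markers.sets.items():
        in_set = de_table.index.isin(list(mset))
        for level, sig in (("nominal", nominal), ("fdr", fdr)):
            grid[(ct, level)] = {
                "Up": int((in_set & sig & up).sum()),
                "Down": int((in_set & sig & ~up).sum()),
            }
    out = pd.DataFrame(grid)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["cell_type", "level"])
    return out.loc[["Up", "Down"]]
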