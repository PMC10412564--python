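"""RefFinder-style rank aggregation and expression-level summaries.

A gene's *comprehensive rank* for one experimental setting is the geometric
mean of its four within-algorithm ranks; combining across settings takes a
further geometric mean over the settings where the gene was detected.
Comprehensive ranks stay real-valued throughout — they are never re-ranked to
integers before cross-setting combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gmean, rankdata

from .algorithms import ALGORITHMS, StabilityTable
from .io import CqMatrix

logger = logging.getLogger(__name__)


@dataclass
class RankProfile:
    """Comprehensive ranks per setting and combined across settings.

    ``per_setting`` is a gene × setting DataFrame (NaN where a gene was
    excluded from a setting); ``dispersion`` is the sample SD (n−1) of each
    gene's per-setting ranks; ``n_settings`` counts contributing settings.
    """

    per_setting: pd.DataFrame
    combined: pd.Series
    dispersion: pd.Series
    n_settings: pd.Series

    def ordering(self) -> list[str]:
        """Genes from most to least stable by combined rank."""
        return list(self.combined.sort_values().index)


def comprehensive_rank(tables: dict[str, StabilityTable]) -> pd.Series:
    """Geometric mean of a gene's four within-algorithm ranks for one setting."""
    missing = [a for a in ALGORITHMS if a not in tables]
    if missing:
        raise ValueError(f"missing algorithm tables: {missing}")
    gene_sets = [set(t.ranks.index) for t in tables.values()]
    common = gene_sets[0]
    for s in gene_sets[1:]:
        if s != common:
            raise ValueError(
                f"algorithm tables cover different gene sets: {sorted(common ^ s)}"
            )
    genes = list(tables[ALGORITHMS[0]].ranks.index)
    mat = np.column_stack([tables[a].ranks.loc[genes].to_numpy(float) for a in ALGORITHMS])
    return pd.Series(gmean(mat, axis=1), index=genes)


def combine_across_settings(
    per_setting: dict[str, pd.Series] | pd.DataFrame,
    scope: list[str] | None = None,
) -> RankProfile:
    """Combine per-setting comprehensive ranks into one profile.

    Genes absent from some settings (non-detect exclusions) are combined over
    the settings where they have a rank; a gene present in zero settings of
    the scope is dropped with a warning.
    """
    if isinstance(per_setting, dict):
        frame = pd.DataFrame(per_setting)
    else:
        frame = per_setting.copy()
    if scope is not None:
        missing = [s for s in scope if s not in frame.columns]
        if missing:
            raise ValueError(f"settings not present: {missing}")
        frame = frame.loc[:, scope]
    if frame.shape[1] < 1:
        raise ValueError("need at least one setting in scope")

    empty = frame.index[frame.notna().sum(axis=1) == 0]
    for gene in empty:
        logger.warning("gene %s has no rank in any setting of the scope; excluded", gene)
    frame = frame.drop(index=empty)

    combined = {}
    dispersion = {}
    n_settings = {}
    for gene, row in frame.iterrows():
        vals = row.dropna().to_numpy(float)
        combined[gene] = float(gmean(vals))
        dispersion[gene] = float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan
        n_settings[gene] = int(len(vals))
    return RankProfile(
        per_setting=frame,
        combined=pd.Series(combined),
        dispersion=pd.Series(dispersion),
        n_settings=pd.Series(n_settings),
    )


@dataclass
class ExpressionLevelSummary:
    """Per-sample-type mean collapsed Cq per gene, with expression-level ranks
    (rank 1 = lowest mean Cq = highest expression) and contributing counts.

    Genes never detected in a sample type appear with NaN mean and rank
    (reported as not detected)."""

    tables: dict[str, pd.DataFrame]  # sample_type -> DataFrame[mean_cq, rank, n]


def expression_level_summary(matrices: dict[str, CqMatrix]) -> ExpressionLevelSummary:
    """Average collapsed Cq per gene within each sample type (Fig-4-style)."""
    if not matrices:
        raise ValueError("no matrices to summarize")
    by_type: dict[str, list[CqMatrix]] = {}
    for m in matrices.values():
        by_type.setdefault(m.sample_type, []).append(m)
    all_genes = sorted({g for m in matrices.values() for g in m.genes})
    tables = {}
    for stype, ms in by_type.items():
        sums = pd.Series(0.0, index=all_genes)
        counts = pd.Series(0, index=all_genes)
        for m in ms:
            sums.loc[m.values.index] += m.values.sum(axis=1)
            counts.loc[m.values.index] += m.values.shape[1]
        mean_cq = sums.where(counts > 0) / counts.where(counts > 0)
        detected = mean_cq.dropna()
        ranks = pd.Series(rankdata(detected.to_numpy(), method="average"), index=detected.index)
        tables[stype] = pd.DataFrame(
            {"mean_cq": mean_cq, "rank": ranks.reindex(all_genes), "n": counts}
        )
    return ExpressionLevelSummary(tables)
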