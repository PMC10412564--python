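"""The four per-setting expression-stability statistics.

All four consume a collapsed gene × sample Cq matrix (raw cycles, no
efficiency transform) and return a :class:`StabilityTable` with a per-gene
stability value — lower is more stable — and average-tie ranks (1 = most
stable).

* comparative delta-Ct: mean over partner genes of the sample SD of the
  pairwise Cq difference across samples.
* geNorm: the same pairwise-variation average M, with stepwise exclusion of
  the least stable gene until two remain.
* BestKeeper: per-gene SD of raw Cq; the BestKeeper index (per-sample
  geometric mean of Cq) and each gene's Pearson r against it are diagnostics.
* NormFinder: variance decomposition of sample-centred Cq, either pooled or
  split into inter-group bias and intra-group variance when condition groups
  are usable.

Since Cq is a log2-scale quantity, a pairwise Cq difference is the log2
expression ratio of the two genes; all SDs use the n−1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gmean, rankdata

from .io import CqMatrix

ALGORITHMS = ("delta_ct", "genorm", "bestkeeper", "normfinder")


class DegenerateMatrixError(ValueError):
    """Matrix too small for the requested statistic."""


@dataclass
class StabilityTable:
    """Per-gene stability values and within-algorithm ranks for one setting."""

    algorithm: str
    setting_id: str
    values: pd.Series  # gene -> stability value (lower = more stable)
    ranks: pd.Series  # gene -> rank (1 = most stable, average ties)
    extras: dict = field(default_factory=dict)


@dataclass
class GeNormTrace:
    """Stepwise-exclusion record: genes removed least-stable-first and the
    M values at each round."""

    exclusion_order: list[str]
    m_by_round: list[dict[str, float]]


def rank_within_algorithm(values: pd.Series) -> pd.Series:
    """Ascending average-tie ranks of stability values (1 = most stable)."""
    if len(values) < 2:
        raise DegenerateMatrixError("need at least 2 values to rank")
    arr = values.to_numpy(float)
    if not np.all(np.isfinite(arr)):
        bad = values.index[~np.isfinite(arr)][0]
        raise ValueError(f"non-finite stability value for gene {bad!r}")
    return pd.Series(rankdata(arr, method="average"), index=values.index)


def _as_array(m: CqMatrix) -> np.ndarray:
    return m.values.to_numpy(float)


def pairwise_sd_matrix(x: np.ndarray) -> np.ndarray:
    """SD across samples of Cq_i − Cq_k for every gene pair (n−1 denominator).

    Uses Var(X_i − X_k) = Var_i + Var_k − 2 Cov_ik from the gene covariance
    matrix, so it is O(G²S) rather than a triple loop.
    """
    if x.shape[1] < 2:
        raise DegenerateMatrixError("pairwise SD needs at least 2 samples")
    c = np.cov(x)  # ddof=1
    c = np.atleast_2d(c)
    d = np.diag(c)
    v = d[:, None] + d[None, :] - 2.0 * c
    np.fill_diagonal(v, 0.0)
    return np.sqrt(np.clip(v, 0.0, None))


def _mean_pairwise_variation(x: np.ndarray) -> np.ndarray:
    """M_i = mean over partners k≠i of SD(Cq_i − Cq_k)."""
    v = pairwise_sd_matrix(x)
    g = x.shape[0]
    return v.sum(axis=1) / (g - 1)


def delta_ct_stability(m: CqMatrix) -> StabilityTable:
    """Comparative delta-Ct: for each gene, the mean SD of its pairwise Cq
    differences with every other candidate across samples."""
    x = _as_array(m)
    if x.shape[0] < 3:
        raise DegenerateMatrixError("delta-Ct needs at least 3 genes")
    if x.shape[1] < 2:
        raise DegenerateMatrixError("delta-Ct needs at least 2 samples")
    values = pd.Series(_mean_pairwise_variation(x), index=m.values.index)
    return StabilityTable("delta_ct", m.setting_id, values, rank_within_algorithm(values))


def genorm_stability(m: CqMatrix) -> tuple[StabilityTable, GeNormTrace]:
    """geNorm M with stepwise exclusion.

    At each round the gene with the highest M (mean pairwise variation with
    the remaining candidates) is removed; its reported value is its M at the
    round of removal.  The final two genes share rank 1.5 and report their
    final-round M.  Ties in the exclusion argmax are broken by removing the
    lexicographically first gene_id.
    """
    genes = list(m.values.index)
    x = _as_array(m)
    if x.shape[0] < 3:
        raise DegenerateMatrixError("geNorm needs at least 3 genes")
    if x.shape[1] < 2:
        raise DegenerateMatrixError("geNorm needs at least 2 samples")

    remaining = list(range(len(genes)))
    values = pd.Series(np.nan, index=genes, dtype=float)
    ranks = pd.Series(np.nan, index=genes, dtype=float)
    exclusion_order: list[str] = []
    m_by_round: list[dict[str, float]] = []
    g_total = len(genes)
    next_rank = float(g_total)
    while len(remaining) > 2:
        sub = x[remaining]
        mvals = _mean_pairwise_variation(sub)
        m_by_round.append({genes[i]: float(v) for i, v in zip(remaining, mvals)})
        worst_m = mvals.max()
        tied = [remaining[j] for j in range(len(remaining)) if mvals[j] == worst_m]
        drop = min(tied, key=lambda i: genes[i])
        values[genes[drop]] = float(mvals[remaining.index(drop)])
        ranks[genes[drop]] = next_rank
        next_rank -= 1.0
        exclusion_order.append(genes[drop])
        remaining.remove(drop)
    final = x[remaining]
    final_m = _mean_pairwise_variation(final)
    m_by_round.append({genes[i]: float(v) for i, v in zip(remaining, final_m)})
    for i, v in zip(remaining, final_m):
        values[genes[i]] = float(v)
        ranks[genes[i]] = 1.5
    table = StabilityTable(
        "genorm", m.setting_id, values, ranks,
        extras={"exclusion_order": exclusion_order, "m_by_round": m_by_round},
    )
    return table, GeNormTrace(exclusion_order, m_by_round)


def bestkeeper_stability(m: CqMatrix) -> StabilityTable:
    """BestKeeper: genes ranked by the SD of their raw Cq across samples.

    Diagnostics: the BestKeeper index (per-sample geometric mean of Cq across
    genes) and each gene's Pearson correlation with it (NaN when either side
    has zero variance).
    """
    x = _as_array(m)
    if x.shape[0] < 2:
        raise DegenerateMatrixError("BestKeeper needs at least 2 genes")
    if x.shape[1] < 2:
        raise DegenerateMatrixError("BestKeeper needs at least 2 samples")
    sd = x.std(axis=1, ddof=1)
    index = gmean(x, axis=0)
    r = np.full(x.shape[0], np.nan)
    idx_dev = index - index.mean()
    idx_ss = float(idx_dev @ idx_dev)
    for i in range(x.shape[0]):
        dev = x[i] - x[i].mean()
        ss = float(dev @ dev)
        if ss > 0 and idx_ss > 0:
            r[i] = float(dev @ idx_dev) / np.sqrt(ss * idx_ss)
    values = pd.Series(sd, index=m.values.index)
    return StabilityTable(
        "bestkeeper", m.setting_id, values, rank_within_algorithm(values),
        extras={
            "index": pd.Series(index, index=m.values.columns),
            "r": pd.Series(r, index=m.values.index),
        },
    )


def normfinder_stability(m: CqMatrix, use_groups: bool | str = "auto") -> StabilityTable:
    """NormFinder-style model-based stability.

    Works on sample-centred Cq, ``z_gs = Cq_gs − mean_g(Cq_·s)``, which removes
    per-sample loading differences.

    Ungrouped: stability = SD across samples of the doubly centred residuals
    (z minus the gene's own mean).

    Grouped (by condition label): for each group the inter-group bias
    ``d_gγ = z̄_gγ − z̄_g`` and intra-group variance ``s²_gγ`` are combined as
    ``mean_γ( |d_gγ| + sqrt(s²_gγ / n_γ) )`` — plain, unshrunk estimators.

    ``use_groups="auto"`` (default) runs grouped only when every condition
    group has ≥2 samples.
    """
    x = _as_array(m)
    if x.shape[0] < 2:
        raise DegenerateMatrixError("NormFinder needs at least 2 genes")
    if x.shape[1] < 2:
        raise DegenerateMatrixError("NormFinder needs at least 2 samples")
    cond = m.condition_of.to_numpy()
    group_labels = pd.unique(cond)
    sizes = {g: int((cond == g).sum()) for g in group_labels}
    if use_groups == "auto":
        use_groups = len(group_labels) >= 2 and all(n >= 2 for n in sizes.values())
    elif use_groups and any(n < 2 for n in sizes.values()):
        raise DegenerateMatrixError(
            "grouped NormFinder needs at least 2 samples in every condition group"
        )

    z = x - x.mean(axis=0, keepdims=True)
    extras: dict = {"grouped": bool(use_groups)}
    if not use_groups:
        resid = z - z.mean(axis=1, keepdims=True)
        values = pd.Series(resid.std(axis=1, ddof=1), index=m.values.index)
    else:
        overall = z.mean(axis=1)
        acc = np.zeros(x.shape[0])
        bias = {}
        for g in group_labels:
            sel = cond == g
            n_g = sizes[g]
            zbar = z[:, sel].mean(axis=1)
            d = zbar - overall
            s2 = z[:, sel].var(axis=1, ddof=1)
            acc += np.abs(d) + np.sqrt(s2 / n_g)
            bias[g] = pd.Series(d, index=m.values.index)
        values = pd.Series(acc / len(group_labels), index=m.values.index)
        extras["group_bias"] = bias
    return StabilityTable(
        "normfinder", m.setting_id, values, rank_within_algorithm(values), extras=extras
    )


def all_stability_tables(m: CqMatrix, *, normfinder_groups: bool | str = "auto") -> dict[str, StabilityTable]:
    """Run the four algorithms on one setting's matrix."""
    genorm_table, _ = genorm_stability(m)
    return {
        "delta_ct": delta_ct_stability(m),
        "genorm": genorm_table,
        "bestkeeper": bestkeeper_stability(m),
        "normfinder": normfinder_stability(m, use_groups=normfinder_groups),
    }


def tables_to_frame(tables: dict[str, StabilityTable]) -> pd.DataFrame:
    """Long-form view of a setting's four tables (gene, algorithm, value, rank)."""
    rows = []
    for algo, t in tables.items():
        for gene in t.values.index:
            rows.append(
                {"setting": t.setting_id, "gene": gene, "algorithm": algo,
                 "stability_value": float(t.values[gene]), "rank": float(t.ranks[gene])}
            )
    return pd.DataFrame(rows)
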