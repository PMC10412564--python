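"""Statistical comparison of gene stability across the whole study.

Each gene contributes its per-setting comprehensive rank values (35 under the
default study design: 20 cell-line, 3 organoid, 8 fresh-frozen, 4 FFPE).  A
one-way permutational ANOVA (gene labels permuted, F recomputed) tests
whether mean stability differs among genes; Dunn's post-hoc test on the joint
midranks, Bonferroni-corrected, localizes the pairwise differences.

The reported difference matrix is on the original comprehensive-rank scale
(difference of per-gene means, row minus column), built from the per-gene
means so that antisymmetry and additivity d(a,b) + d(b,c) = d(a,c) hold
exactly in floating point.  Dunn z statistics and p-values stay on the joint
midrank scale; both views are carried in the result.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

logger = logging.getLogger(__name__)


@dataclass
class RankSample:
    """Per-gene vectors of per-setting comprehensive rank values.

    Vector lengths may differ only through documented non-detect exclusions.
    """

    values_by_gene: dict[str, np.ndarray]

    @classmethod
    def from_per_setting(cls, per_setting: pd.DataFrame) -> "RankSample":
        return cls({
            gene: row.dropna().to_numpy(float) for gene, row in per_setting.iterrows()
        })

    @property
    def genes(self) -> list[str]:
        return list(self.values_by_gene)


@dataclass
class StabilityComparison:
    """Permutation-ANOVA omnibus result plus pairwise comparison matrices."""

    f_obs: float
    p_perm: float
    n_perm: int
    seed: int
    genes: list[str]
    means: pd.Series  # per-gene mean comprehensive rank
    diff_matrix: pd.DataFrame  # row minus column, original rank scale
    z_matrix: pd.DataFrame  # Dunn z on joint midranks
    p_adj_matrix: pd.DataFrame  # Bonferroni-adjusted two-sided p, capped at 1
    alpha: float = 0.05
    extras: dict = field(default_factory=dict)


def _f_statistic(values: np.ndarray, starts: np.ndarray, sizes: np.ndarray) -> np.ndarray:
    """One-way ANOVA F for each row of ``values`` (B × N), groups contiguous.

    Zero within-group variance with positive between-group variance yields
    +inf; zero total variance yields 0 (degenerate convention).
    """
    values = np.atleast_2d(values)
    n_total = values.shape[1]
    k = len(sizes)
    group_sums = np.add.reduceat(values, starts, axis=1)
    group_means = group_sums / sizes
    grand = values.sum(axis=1) / n_total
    ssb = (sizes * (group_means - grand[:, None]) ** 2).sum(axis=1)
    sst = ((values - grand[:, None]) ** 2).sum(axis=1)
    ssw = np.maximum(sst - ssb, 0.0)
    msb = ssb / (k - 1)
    msw = ssw / (n_total - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(sst <= 1e-300, 0.0, np.where(msw > 0, msb / msw, np.where(msb > 0, np.inf, 0.0)))
    return f


def permutation_anova(rs: RankSample, n_perm: int = 1000, seed: int = 1) -> tuple[float, float]:
    """Permutational one-way ANOVA of rank value ~ gene.

    Gene labels are permuted uniformly at random ``n_perm`` times (group sizes
    fixed); the p-value uses the add-one estimator
    ``(1 + #{F_perm ≥ F_obs}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be a positive integer")
    groups = [np.asarray(v, float) for v in rs.values_by_gene.values()]
    if len(groups) < 2:
        raise ValueError("need at least 2 genes")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every gene needs at least 2 rank values")
    values = np.concatenate(groups)
    sizes = np.array([len(g) for g in groups])
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])

    f_obs = float(_f_statistic(values[None, :], starts, sizes)[0])
    if np.ptp(values) == 0.0:
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(values, (n_perm, 1)), axis=1)
    f_perm = _f_statistic(perms, starts, sizes)
    b = int(np.sum(f_perm >= f_obs))
    p_perm = (1 + b) / (n_perm + 1)
    return f_obs, float(p_perm)


def mean_rank_difference_matrix(means: pd.Series) -> pd.DataFrame:
    """Pairwise difference of per-gene means, row minus column.

    Built from the mean vector directly, so the matrix is exactly
    antisymmetric with zero diagonal and exactly additive.
    """
    v = means.to_numpy(float)
    d = v[:, None] - v[None, :]
    return pd.DataFrame(d, index=means.index, columns=means.index)


def dunn_posthoc(
    rs: RankSample, correction: str = "bonferroni", *, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.Series]:
    """Dunn's pairwise post-hoc test with Bonferroni correction.

    Returns ``(diff_matrix, z_matrix, p_adj_matrix, means)``.  ``diff_matrix``
    is the difference of per-gene mean comprehensive ranks (row minus column);
    z statistics are computed on the joint midrank transform with the standard
    tie correction and group-specific n, two-sided normal p-values multiplied
    by the number of gene pairs and capped at 1.
    """
    if correction != "bonferroni":
        raise ValueError(f"unsupported correction {correction!r}")
    usable = {}
    for gene, v in rs.values_by_gene.items():
        v = np.asarray(v, float)
        if len(v) < 2:
            warnings.warn(f"gene {gene!r} has <2 rank values; excluded from post-hoc")
            continue
        usable[gene] = v
    genes = list(usable)
    k = len(genes)
    if k < 2:
        raise ValueError("need at least 2 genes with ≥2 values")
    pooled = np.concatenate([usable[g] for g in genes])
    n_total = len(pooled)
    midranks = rankdata(pooled, method="average")
    # tie correction: sum over tied groups of (t^3 - t) / (12 (N - 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (12.0 * (n_total - 1)))
    a = n_total * (n_total + 1) / 12.0 - tie_term

    sizes = np.array([len(usable[g]) for g in genes])
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    mean_midrank = np.array(
        [midranks[bounds[i]:bounds[i + 1]].mean() for i in range(k)]
    )
    means = pd.Series([usable[g].mean() for g in genes], index=genes)

    se = np.sqrt(a * (1.0 / sizes[:, None] + 1.0 / sizes[None, :]))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (mean_midrank[:, None] - mean_midrank[None, :]) / se
    np.fill_diagonal(z, 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    n_pairs = k * (k - 1) // 2
    p_adj = np.minimum(p * n_pairs, 1.0)
    np.fill_diagonal(p_adj, 1.0)

    diff = mean_rank_difference_matrix(means)
    z_df = pd.DataFrame(z, index=genes, columns=genes)
    p_df = pd.DataFrame(p_adj, index=genes, columns=genes)
    return diff, z_df, p_df, means


def compare_stability(
    rs: RankSample, *, n_perm: int = 1000, seed: int = 1, alpha: float = 0.05
) -> StabilityComparison:
    """Omnibus permutation ANOVA followed by Dunn's Bonferroni post-hoc."""
    f_obs, p_perm = permutation_anova(rs, n_perm=n_perm, seed=seed)
    diff, z, p_adj, means = dunn_posthoc(rs, alpha=alpha)
    return StabilityComparison(
        f_obs=f_obs, p_perm=p_perm, n_perm=n_perm, seed=seed,
        genes=list(diff.index), means=means,
        diff_matrix=diff, z_matrix=z, p_adj_matrix=p_adj, alpha=alpha,
    )


def _fmt_p(p: float) -> str:
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


def table_report(sc: StabilityComparison, alpha: float | None = None) -> str:
    """Human-readable lower-triangular comparison table.

    Each cell shows the mean-rank difference (row minus column, 2 decimals)
    with the Bonferroni-adjusted Dunn p-value in parentheses; significant
    pairs (p_adj < alpha) are starred.
    """
    alpha = sc.alpha if alpha is None else alpha
    genes = sc.genes
    if not genes:
        return ""
    width = 16
    lines = []
    header = "Genes".ljust(10) + "".join(g.ljust(width) for g in genes[:-1])
    lines.append(header)
    for i, row_gene in enumerate(genes[1:], start=1):
        cells = []
        for j in range(i):
            d = sc.diff_matrix.iloc[i, j]
            p = sc.p_adj_matrix.iloc[i, j]
            star = "*" if p < alpha else ""
            cells.append(f"{d:.2f} ({_fmt_p(p)}){star}".ljust(width))
        lines.append(row_gene.ljust(10) + "".join(cells))
    return "\n".join(lines)
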