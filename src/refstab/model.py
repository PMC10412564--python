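"""Model/results interface tying the pipeline stages together.

:class:`ReferenceGeneStability` is built from replicate-level Cq data (a
:class:`~refstab.io.CqDataset`, a tidy DataFrame, or a CSV/TSV path); its
:meth:`~ReferenceGeneStability.fit` runs non-detect handling, imputation,
replicate collapse, the four stability algorithms per setting, RefFinder-style
rank aggregation, and the permutational comparison, returning a
:class:`StabilityResults` with a ``summary()`` table and exporters.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .aggregate import (
    ExpressionLevelSummary,
    RankProfile,
    combine_across_settings,
    comprehensive_rank,
    expression_level_summary,
)
from .algorithms import StabilityTable, all_stability_tables, tables_to_frame
from .inference import RankSample, StabilityComparison, compare_stability, table_report
from .io import (
    CqDataset,
    collapse_replicates,
    dataset_from_frame,
    impute_missing_replicates,
    mark_nondetects,
    read_cq_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved analysis options; embedded in every artifact for provenance."""

    collapse_method: str = "arithmetic_mean"
    nondetect_policy: str = "drop_gene_in_setting"
    normfinder_groups: bool | str = "auto"
    min_observed: int = 2
    n_perm: int = 1000
    seed: int = 1
    alpha: float = 0.05

    def validate(self) -> "PipelineConfig":
        if self.n_perm < 1:
            raise ValueError("n_perm must be a positive integer")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.collapse_method not in ("arithmetic_mean", "geometric_mean"):
            raise ValueError(f"unknown collapse method {self.collapse_method!r}")
        if self.nondetect_policy not in ("drop_gene_in_setting", "drop_sample"):
            raise ValueError(f"unknown non-detect policy {self.nondetect_policy!r}")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class ReferenceGeneStability:
    """Reference-gene stability model over a replicate-level Cq dataset.

    Parameters mirror :class:`PipelineConfig`; keyword arguments override the
    config defaults.
    """

    def __init__(self, dataset: CqDataset, config: PipelineConfig | None = None, **overrides):
        cfg = config or PipelineConfig()
        if overrides:
            cfg = dataclasses.replace(cfg, **overrides)
        self.config = cfg.validate()
        self.dataset = dataset

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "ReferenceGeneStability":
        config_keys = {f.name for f in dataclasses.fields(PipelineConfig)}
        cfg_kw = {k: v for k, v in kwargs.items() if k in config_keys}
        ds_kw = {k: v for k, v in kwargs.items() if k not in config_keys}
        return cls(dataset_from_frame(df, **ds_kw), **cfg_kw)

    @classmethod
    def from_csv(cls, path, dialect: str = "csv", **kwargs) -> "ReferenceGeneStability":
        return cls(read_cq_table(path, dialect=dialect), **kwargs)

    def fit(self) -> "StabilityResults":
        cfg = self.config
        ds = mark_nondetects(self.dataset, policy=cfg.nondetect_policy)
        ds = impute_missing_replicates(ds, min_observed=cfg.min_observed)
        matrices = collapse_replicates(ds, method=cfg.collapse_method)
        logger.info("collapsed %d settings", len(matrices))

        tables: dict[str, dict[str, StabilityTable]] = {}
        per_setting: dict[str, pd.Series] = {}
        for setting_id, m in matrices.items():
            tabs = all_stability_tables(m, normfinder_groups=cfg.normfinder_groups)
            tables[setting_id] = tabs
            per_setting[setting_id] = comprehensive_rank(tabs)
        profile = combine_across_settings(per_setting)
        levels = expression_level_summary(matrices)

        rs = RankSample.from_per_setting(profile.per_setting)
        comparison = compare_stability(rs, n_perm=cfg.n_perm, seed=cfg.seed, alpha=cfg.alpha)
        return StabilityResults(
            model=self,
            dataset=ds,
            matrices=matrices,
            stability_tables=tables,
            rank_profile=profile,
            expression_levels=levels,
            comparison=comparison,
        )


@dataclass
class StabilityResults:
    """Fitted stability analysis: per-setting tables, aggregated ranks, and
    the permutational comparison of genes."""

    model: ReferenceGeneStability
    dataset: CqDataset
    matrices: dict
    stability_tables: dict[str, dict[str, StabilityTable]]
    rank_profile: RankProfile
    expression_levels: ExpressionLevelSummary
    comparison: StabilityComparison
    version: str = field(default=__version__)

    @property
    def config(self) -> PipelineConfig:
        return self.model.config

    def stability_frame(self) -> pd.DataFrame:
        """All per-setting algorithm values/ranks in long form."""
        return pd.concat(
            [tables_to_frame(t) for t in self.stability_tables.values()],
            ignore_index=True,
        )

    def combined_frame(self) -> pd.DataFrame:
        p = self.rank_profile
        return pd.DataFrame({
            "combined_rank": p.combined,
            "sd": p.dispersion,
            "n_settings": p.n_settings,
        }).rename_axis("gene").sort_values("combined_rank")

    def summary(self) -> str:
        """Plain-text report: combined ranking, omnibus test, post-hoc table."""
        cfg = self.config
        lines = [
            f"Reference-gene stability analysis (refstab {self.version})",
            f"settings: {len(self.matrices)}   genes: {len(self.rank_profile.combined)}   "
            f"collapse: {cfg.collapse_method}   non-detects: {cfg.nondetect_policy}",
            "",
            "Combined stability ranking (geometric mean of per-setting comprehensive ranks;",
            "lower = more stable):",
            self.combined_frame().to_string(float_format=lambda v: f"{v:.3f}"),
            "",
            f"Permutational one-way ANOVA: F = {self.comparison.f_obs:.3f}, "
            f"p = {self.comparison.p_perm:.4f} ({self.comparison.n_perm} permutations, "
            f"seed {self.comparison.seed})",
            "",
            f"Dunn post-hoc, Bonferroni-corrected (alpha = {cfg.alpha}; * significant):",
            table_report(self.comparison),
        ]
        return "\n".join(lines)

    def table_report(self, alpha: float | None = None) -> str:
        return table_report(self.comparison, alpha=alpha)

    def plot_combined_ranks(self, ax=None):
        """Bar plot of combined ranks with per-setting-SD error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        frame = self.combined_frame()
        ax.bar(frame.index, frame["combined_rank"], yerr=frame["sd"].fillna(0.0), capsize=3)
        ax.set_ylabel("combined stability rank (lower = more stable)")
        ax.tick_params(axis="x", rotation=60)
        return ax

    def to_dir(self, outdir) -> None:
        """Write the TSV/JSON result bundle."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.stability_frame().to_csv(out / "stability_tables.tsv", sep="\t", index=False)
        (self.rank_profile.per_setting
            .rename_axis("gene")
            .reset_index()
            .melt(id_vars="gene", var_name="setting", value_name="comprehensive_rank")
            .dropna()
            .to_csv(out / "comprehensive_ranks.tsv", sep="\t", index=False))
        self.combined_frame().to_csv(out / "combined_ranks.tsv", sep="\t")
        self.comparison.diff_matrix.to_csv(out / "diff_matrix.tsv", sep="\t")
        self.comparison.p_adj_matrix.to_csv(out / "p_adj_matrix.tsv", sep="\t")
        rows = []
        for stype, tab in self.expression_levels.tables.items():
            t = tab.rename_axis("gene").reset_index()
            t.insert(0, "sample_type", stype)
            rows.append(t)
        pd.concat(rows, ignore_index=True).to_csv(out / "expression_levels.tsv", sep="\t", index=False)
        (out / "comparison_table.txt").write_text(self.summary() + "\n")
        summary = {
            "version": self.version,
            "config": self.config.to_dict(),
            "dataset_metadata": _jsonable(self.dataset.metadata),
            "n_settings": len(self.matrices),
            "genes": list(self.rank_profile.combined.index),
            "combined_ranks": {g: float(v) for g, v in self.rank_profile.combined.items()},
            "f_obs": self.comparison.f_obs,
            "p_perm": self.comparison.p_perm,
            "n_perm": self.comparison.n_perm,
            "seed": self.comparison.seed,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def run_pipeline(cfg: PipelineConfig, dataset: CqDataset, outdir=None) -> StabilityResults:
    """End-to-end convenience wrapper: fit the model and optionally export."""
    results = ReferenceGeneStability(dataset, config=cfg).fit()
    if outdir is not None:
        results.to_dir(outdir)
    return results
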