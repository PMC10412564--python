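"""Reading, validation, imputation and replicate collapse of raw Cq tables.

The on-disk format is a tidy CSV/TSV with one row per technical replicate:

    gene,sample,sample_type,setting,condition,replicate,cq

``cq`` is the raw quantification cycle (a positive number of PCR cycles) or a
non-detect token (default ``"ND"``) for reactions that never crossed the
fluorescence threshold.  Non-detects are a biological signal (no amplifiable
template) and are kept distinct from *missing* replicates, which are simply
absent rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import gmean

logger = logging.getLogger(__name__)

SAMPLE_TYPES = ("cell_line", "organoid", "fresh_frozen", "ffpe")
CONDITIONS = ("control", "treated")

#: columns required in a Cq table, in canonical order
CQ_COLUMNS = ["gene", "sample", "sample_type", "setting", "condition", "replicate", "cq"]

DEFAULT_ND_TOKEN = "ND"
DEFAULT_MAX_CYCLES = 45.0


class CqFormatError(ValueError):
    """Malformed input table (bad header, unparseable field)."""


class CqValidationError(ValueError):
    """Structurally valid table violating a Cq-data invariant."""


class UnresolvedCellError(ValueError):
    """(gene, sample) cells with too few observed replicates to impute."""

    def __init__(self, cells):
        self.cells = list(cells)
        super().__init__(
            "cells with fewer observed replicates than min_observed: "
            + ", ".join(f"{g}/{s}" for g, s in self.cells)
        )


class DegenerateSettingError(ValueError):
    """A setting left with <2 genes or <2 samples after exclusions."""


@dataclass
class CqDataset:
    """Replicate-level Cq records plus provenance metadata.

    ``records`` is a long-form DataFrame with the columns of
    :data:`CQ_COLUMNS`; ``cq`` is float with NaN marking non-detects
    (never missing replicates — those are absent rows).
    """

    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    n_replicates: int = 3

    def copy(self) -> "CqDataset":
        return CqDataset(self.records.copy(), dict(self.metadata), self.n_replicates)

    @property
    def genes(self) -> list[str]:
        return sorted(self.records["gene"].unique())

    @property
    def settings(self) -> list[str]:
        return list(pd.unique(self.records["setting"]))


@dataclass
class CqMatrix:
    """Collapsed gene × sample Cq matrix for one experimental setting."""

    values: pd.DataFrame  # index = gene, columns = sample
    condition_of: pd.Series  # sample -> condition
    setting_id: str
    sample_type: str = ""

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def __post_init__(self):
        if self.values.isna().any().any():
            raise CqValidationError(
                f"setting {self.setting_id!r}: collapsed matrix contains missing entries"
            )


def _validate_records(df: pd.DataFrame, max_cycles: float) -> None:
    bad = df["cq"].notna() & ((df["cq"] <= 0) | (df["cq"] > max_cycles))
    if bad.any():
        row = df.index[bad][0]
        raise CqValidationError(
            f"row {row}: cq={df.loc[row, 'cq']} outside (0, {max_cycles}] "
            f"(gene={df.loc[row, 'gene']}, sample={df.loc[row, 'sample']})"
        )
    dup = df.duplicated(subset=["gene", "sample", "replicate"])
    if dup.any():
        row = df.index[dup][0]
        raise CqValidationError(
            f"duplicate (gene, sample, replicate) at row {row}: "
            f"({df.loc[row, 'gene']}, {df.loc[row, 'sample']}, {df.loc[row, 'replicate']})"
        )
    bad_type = ~df["sample_type"].isin(SAMPLE_TYPES)
    if bad_type.any():
        raise CqValidationError(
            f"unknown sample_type {df.loc[df.index[bad_type][0], 'sample_type']!r}"
        )
    bad_cond = ~df["condition"].isin(CONDITIONS)
    if bad_cond.any():
        raise CqValidationError(
            f"unknown condition {df.loc[df.index[bad_cond][0], 'condition']!r}"
        )
    if (df["replicate"] < 1).any():
        raise CqValidationError("replicate indices must be positive integers")


def dataset_from_frame(
    df: pd.DataFrame,
    *,
    nd_token: str = DEFAULT_ND_TOKEN,
    max_cycles: float = DEFAULT_MAX_CYCLES,
    n_replicates: int | None = None,
    metadata: Mapping | None = None,
) -> CqDataset:
    """Validate a long-form DataFrame and wrap it as a :class:`CqDataset`."""
    missing = [c for c in CQ_COLUMNS if c not in df.columns]
    if missing:
        raise CqFormatError(f"missing required columns: {missing}")
    df = df.loc[:, CQ_COLUMNS].copy()
    cq_raw = df["cq"]
    if cq_raw.dtype == object:
        is_nd = cq_raw.astype(str).str.strip() == nd_token
        cq = pd.to_numeric(cq_raw.mask(is_nd), errors="coerce")
        unparseable = cq.isna() & ~is_nd & cq_raw.notna()
        if unparseable.any():
            row = df.index[unparseable][0]
            raise CqFormatError(f"row {row}: cq value {cq_raw.loc[row]!r} is not a number or {nd_token!r}")
        df["cq"] = cq
    else:
        df["cq"] = cq_raw.astype(float)
    df["replicate"] = df["replicate"].astype(int)
    for col in ("gene", "sample", "sample_type", "setting", "condition"):
        df[col] = df[col].astype(str)
    _validate_records(df, max_cycles)
    n_rep = int(n_replicates if n_replicates is not None else df["replicate"].max())
    return CqDataset(df.reset_index(drop=True), dict(metadata or {}), n_rep)


def read_cq_table(
    path,
    dialect: str = "csv",
    *,
    nd_token: str = DEFAULT_ND_TOKEN,
    max_cycles: float = DEFAULT_MAX_CYCLES,
    n_replicates: int | None = None,
) -> CqDataset:
    """Read and validate a replicate-level Cq table.

    Parameters
    ----------
    path
        CSV/TSV file with header ``gene,sample,sample_type,setting,
        condition,replicate,cq``.
    dialect
        ``"csv"`` or ``"tsv"``.
    nd_token
        Token marking non-detected reactions (default ``"ND"``).
    max_cycles
        Upper sanity bound on Cq (default 45 cycles).
    """
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype={"cq": object})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise CqFormatError(f"cannot parse {path}: {exc}") from exc
    ds = dataset_from_frame(
        df, nd_token=nd_token, max_cycles=max_cycles, n_replicates=n_replicates,
        metadata={"source": str(path)},
    )
    return ds


def write_cq_table(ds: CqDataset, path, dialect: str = "csv", *, nd_token: str = DEFAULT_ND_TOKEN) -> None:
    """Write a dataset back to the tidy text format (round-trip safe)."""
    sep = "," if dialect == "csv" else "\t"
    out = ds.records.copy()
    out["cq"] = out["cq"].map(lambda v: nd_token if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep=sep, index=False)


def impute_missing_replicates(ds: CqDataset, min_observed: int = 2) -> CqDataset:
    """Fill in missing technical replicates with the geometric mean of the
    observed replicates of the same (gene, sample) cell.

    Cells containing a non-detect are left untouched (they are handled by
    :func:`mark_nondetects`).  A cell whose observed replicate count is below
    ``min_observed`` raises :class:`UnresolvedCellError`.  Idempotent.
    """
    df = ds.records
    n_rep = ds.n_replicates
    counts = df.groupby(["gene", "sample"], sort=False).size()
    incomplete = counts[counts < n_rep]
    if incomplete.empty:
        return ds.copy()

    nd_cells = set(map(tuple, df.loc[df["cq"].isna(), ["gene", "sample"]].itertuples(index=False)))
    new_rows = []
    unresolved = []
    imputation_log = []
    grouped = df.set_index(["gene", "sample"]).sort_index()
    for (gene, sample), n_obs in incomplete.items():
        if (gene, sample) in nd_cells:
            continue
        cell = grouped.loc[(gene, sample)]
        if isinstance(cell, pd.Series):
            cell = cell.to_frame().T
        if n_obs < min_observed:
            unresolved.append((gene, sample))
            continue
        value = float(gmean(cell["cq"].to_numpy(float)))
        present = set(cell["replicate"].astype(int))
        for r in range(1, n_rep + 1):
            if r in present:
                continue
            row = cell.iloc[0].copy()
            row["replicate"] = r
            row["cq"] = value
            new_rows.append({"gene": gene, "sample": sample, **row[["sample_type", "setting", "condition"]].to_dict(),
                             "replicate": r, "cq": value})
            imputation_log.append({"gene": gene, "sample": sample, "replicate": r, "imputed_cq": value})
            logger.info("imputed %s/%s replicate %d with geometric mean %.4f", gene, sample, r, value)
    if unresolved:
        raise UnresolvedCellError(unresolved)
    if not new_rows:
        return ds.copy()
    out = pd.concat([df, pd.DataFrame(new_rows)[CQ_COLUMNS]], ignore_index=True)
    meta = dict(ds.metadata)
    meta.setdefault("imputations", []).extend(imputation_log)
    return CqDataset(out, meta, n_rep)


def mark_nondetects(ds: CqDataset, policy: str = "drop_gene_in_setting") -> CqDataset:
    """Resolve non-detect (ND) reactions.

    Under ``drop_gene_in_setting`` (default) a gene with at least one
    non-detect replicate anywhere in a setting is excluded from that whole
    setting's analysis — the convention used when a transcript fails to
    amplify in degraded material such as FFPE.  Under ``drop_sample`` the
    affected sample is removed instead.  All removals are logged and recorded
    in metadata.
    """
    if policy not in ("drop_gene_in_setting", "drop_sample"):
        raise ValueError(f"unknown non-detect policy {policy!r}")
    df = ds.records
    nd = df["cq"].isna()
    if not nd.any():
        return ds.copy()
    removals = []
    if policy == "drop_gene_in_setting":
        bad = df.loc[nd, ["setting", "gene"]].drop_duplicates()
        keep = ~pd.MultiIndex.from_frame(df[["setting", "gene"]]).isin(
            pd.MultiIndex.from_frame(bad)
        )
        for setting, gene in bad.itertuples(index=False):
            removals.append({"policy": policy, "setting": setting, "gene": gene})
            logger.info("non-detect: dropping gene %s from setting %s", gene, setting)
    else:
        bad = df.loc[nd, ["setting", "sample"]].drop_duplicates()
        keep = ~pd.MultiIndex.from_frame(df[["setting", "sample"]]).isin(
            pd.MultiIndex.from_frame(bad)
        )
        for setting, sample in bad.itertuples(index=False):
            removals.append({"policy": policy, "setting": setting, "sample": sample})
            logger.info("non-detect: dropping sample %s from setting %s", sample, setting)
    out = df[keep].reset_index(drop=True)
    for setting, sub in out.groupby("setting"):
        if sub["gene"].nunique() < 2 or sub["sample"].nunique() < 2:
            raise DegenerateSettingError(
                f"setting {setting!r} left with <2 genes or <2 samples after non-detect removal"
            )
    meta = dict(ds.metadata)
    meta.setdefault("nondetect_removals", []).extend(removals)
    return CqDataset(out, meta, ds.n_replicates)


def collapse_replicates(ds: CqDataset, method: str = "arithmetic_mean") -> dict[str, CqMatrix]:
    """Collapse technical replicates into one Cq per (gene, sample) and split
    by setting.

    Returns a mapping ``setting_id -> CqMatrix``.  Requires all non-detects to
    be resolved first (:func:`mark_nondetects`); missing replicates that were
    not imputed are averaged over the observed replicates.
    """
    if method not in ("arithmetic_mean", "geometric_mean"):
        raise ValueError(f"unknown collapse method {method!r}")
    df = ds.records
    if df["cq"].isna().any():
        raise CqValidationError(
            "dataset contains unresolved non-detects; run mark_nondetects first"
        )
    if method == "arithmetic_mean":
        collapsed = df.groupby(["setting", "gene", "sample"], sort=False)["cq"].mean()
    else:
        logs = df.assign(cq=np.log(df["cq"]))
        collapsed = np.exp(logs.groupby(["setting", "gene", "sample"], sort=False)["cq"].mean())
    matrices: dict[str, CqMatrix] = {}
    cond = df.drop_duplicates(["setting", "sample"]).set_index(["setting", "sample"])["condition"]
    stype = df.drop_duplicates("setting").set_index("setting")["sample_type"]
    for setting in pd.unique(df["setting"]):
        sub = collapsed.loc[setting].unstack("sample")
        sub = sub.sort_index(axis=0)
        sample_order = list(pd.unique(df.loc[df["setting"] == setting, "sample"]))
        sub = sub.loc[:, sample_order]
        matrices[setting] = CqMatrix(
            values=sub,
            condition_of=cond.loc[setting].loc[sample_order],
            setting_id=str(setting),
            sample_type=str(stype.loc[setting]),
        )
    return matrices


def write_cq_matrix(m: CqMatrix, path, dialect: str = "csv") -> None:
    """Write a collapsed matrix in wide format (first column gene)."""
    sep = "," if dialect == "csv" else "\t"
    m.values.rename_axis("gene").to_csv(path, sep=sep)
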