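"""Seeded replicate-level Cq simulator mirroring the study design.

The generative model for gene g, sample s (in setting t), replicate r is

    Cq_{gsr} = mu_g + a_s + delta_g * 1[s treated] + w_{gt} + eps_{gsr}

with independent zero-mean normal terms: a_s a per-sample loading shift,
w_{gt} a per-setting gene wobble, eps technical-replicate noise.  Treatment
effects delta_g are additive in cycles, i.e. multiplicative in transcript
abundance.  Sporadic missing replicates and FFPE gene non-detects are
Bernoulli events layered on top.  Everything is reproducible from the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import CQ_COLUMNS, CqDataset

logger = logging.getLogger(__name__)

#: the 14 candidate housekeeping genes with plausible baseline Cq levels
#: (cycles).  GAPDH/ACTB/B2M are high expressers (low Cq); TBP sits in the
#: lower-expression half of the panel.
DEFAULT_BASELINES = {
    "ACTB": 16.5,
    "B2M": 17.5,
    "G6PD": 24.0,
    "GAPDH": 16.0,
    "GUSB": 25.0,
    "HMBS": 26.0,
    "HPRT1": 24.5,
    "IPO8": 25.5,
    "PGK1": 20.0,
    "PPIA": 19.0,
    "TBP": 24.2,
    "TFRC": 23.0,
    "UBC": 21.0,
    "YWHAZ": 19.5,
}

CELL_LINES = (
    "Caco2", "COLO205", "DLD1", "HCT116", "HCT15",
    "HT29", "RKO", "SW1116", "SW480", "SW620",
)
DOSES = ("2Gy", "10Gy")


@dataclass(frozen=True)
class SettingSpec:
    setting_id: str
    sample_type: str
    n_pairs: int = 1


@dataclass
class StudyDesign:
    """Gene panel and experimental-setting layout.

    Defaults reproduce the study accounting of 20 cell-line settings
    (10 lines × 2 radiation doses) + 3 organoid + 8 fresh-frozen + 4 FFPE
    paired settings = 35 stability rankings per gene, 3 technical replicates
    per reaction.
    """

    baselines: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASELINES))
    settings: list[SettingSpec] = field(default_factory=list)
    replicates: int = 3

    @property
    def genes(self) -> list[str]:
        return list(self.baselines)

    @property
    def n_settings(self) -> int:
        return len(self.settings)


@dataclass
class SimulationParams:
    """Noise magnitudes (cycles), treatment effects and dropout rates."""

    loading_sd: float = 0.3
    noise_sd: float = 0.15
    effect_of: dict[str, float] = field(default_factory=dict)
    gene_setting_sd: float = 0.2
    dropout_prob_ffpe: float = 0.05
    missing_replicate_prob: float = 0.02
    seed: int = 1

    def __post_init__(self):
        for name in ("loading_sd", "noise_sd", "gene_setting_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dropout_prob_ffpe", "missing_replicate_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


def make_study_design() -> StudyDesign:
    """The default design: 14 genes, 10 cell lines × 2 doses, 3 organoid,
    8 fresh-frozen and 4 FFPE control/treated pairs, 3 technical replicates."""
    settings = [
        SettingSpec(f"{line}_{dose}", "cell_line") for line in CELL_LINES for dose in DOSES
    ]
    settings += [SettingSpec(f"organoid_{i}", "organoid") for i in range(1, 4)]
    settings += [SettingSpec(f"ff_{i}", "fresh_frozen") for i in range(1, 9)]
    settings += [SettingSpec(f"ffpe_{i}", "ffpe") for i in range(1, 5)]
    return StudyDesign(settings=settings)


def _simulate_once(design: StudyDesign, params: SimulationParams, rng: np.random.Generator):
    genes = design.genes
    mu = np.array([design.baselines[g] for g in genes])
    delta = np.array([params.effect_of.get(g, 0.0) for g in genes])
    n_rep = design.replicates

    rows_gene = []
    rows_sample = []
    rows_stype = []
    rows_setting = []
    rows_cond = []
    rows_rep = []
    rows_cq = []
    degenerate = False

    for spec in design.settings:
        w = rng.normal(0.0, params.gene_setting_sd, size=len(genes)) if params.gene_setting_sd > 0 else np.zeros(len(genes))
        samples = []
        for p in range(1, spec.n_pairs + 1):
            samples.append((f"{spec.setting_id}_ctrl{p}", "control"))
            samples.append((f"{spec.setting_id}_irr{p}", "treated"))
        # FFPE non-detects: a dropped gene fails to amplify in one sample of
        # the setting (all replicates ND)
        nd_cells: set[tuple[int, int]] = set()
        if spec.sample_type == "ffpe" and params.dropout_prob_ffpe > 0:
            drops = rng.random(len(genes)) < params.dropout_prob_ffpe
            for gi in np.flatnonzero(drops):
                si = int(rng.integers(len(samples)))
                nd_cells.add((int(gi), si))
            if drops.sum() >= len(genes) - 1:
                degenerate = True
        for si, (sample_id, condition) in enumerate(samples):
            a_s = rng.normal(0.0, params.loading_sd) if params.loading_sd > 0 else 0.0
            base = mu + a_s + w + (delta if condition == "treated" else 0.0)
            eps = (
                rng.normal(0.0, params.noise_sd, size=(len(genes), n_rep))
                if params.noise_sd > 0 else np.zeros((len(genes), n_rep))
            )
            cq = base[:, None] + eps
            # sporadic missing replicate: at most one per cell, so >=2 remain
            miss = rng.random(len(genes)) < params.missing_replicate_prob
            miss_rep = rng.integers(n_rep, size=len(genes))
            for gi, gene in enumerate(genes):
                nd = (gi, si) in nd_cells
                for r in range(n_rep):
                    if not nd and miss[gi] and r == miss_rep[gi] and n_rep > 2:
                        continue
                    rows_gene.append(gene)
                    rows_sample.append(sample_id)
                    rows_stype.append(spec.sample_type)
                    rows_setting.append(spec.setting_id)
                    rows_cond.append(condition)
                    rows_rep.append(r + 1)
                    rows_cq.append(np.nan if nd else float(cq[gi, r]))
    df = pd.DataFrame({
        "gene": rows_gene, "sample": rows_sample, "sample_type": rows_stype,
        "setting": rows_setting, "condition": rows_cond,
        "replicate": rows_rep, "cq": rows_cq,
    })[CQ_COLUMNS]
    return df, degenerate


def simulate_dataset(
    design: StudyDesign | None = None,
    params: SimulationParams | None = None,
    *,
    seed: int | None = None,
    max_retries: int = 5,
) -> CqDataset:
    """Draw a replicate-level dataset from the generative model.

    ``seed`` overrides ``params.seed``.  If forced FFPE dropout would leave a
    setting with fewer than 2 genes, the draw is retried (logged, capped at
    ``max_retries``).
    """
    design = design or make_study_design()
    params = params or SimulationParams()
    if seed is not None:
        params = replace(params, seed=seed)
    if len(design.genes) < 2:
        raise ValueError("design needs at least 2 genes")
    rng = np.random.default_rng(params.seed)
    for attempt in range(max_retries + 1):
        df, degenerate = _simulate_once(design, params, rng)
        if not degenerate:
            break
        logger.warning("simulated setting degenerate after dropout; retry %d", attempt + 1)
    else:
        raise RuntimeError("simulation kept producing degenerate settings")
    metadata = {
        "seed": params.seed,
        "params": {
            "loading_sd": params.loading_sd,
            "noise_sd": params.noise_sd,
            "gene_setting_sd": params.gene_setting_sd,
            "dropout_prob_ffpe": params.dropout_prob_ffpe,
            "missing_replicate_prob": params.missing_replicate_prob,
            "effect_of": dict(params.effect_of),
        },
        "n_settings": design.n_settings,
        "replicates": design.replicates,
    }
    return CqDataset(df, metadata, design.replicates)
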