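"""Synthetic normalized qPCR expression tables.

Stands in for mPFC Real-Time RT-PCR measurements of seven
plasticity-related genes (BDNF, CREB, Synapsin I, CamKII, c-fos, c-jun,
Arc) across five groups: naive cage controls (Control), box controls for
each training stage (BC50%CR, BC100%CR), incompletely trained animals
(50%CR) and fully trained animals (100%CR).  Values are generated
directly on the normalized percent-of-control scale (Control mean =
100), as Gaussian draws truncated at zero with a common standard
deviation, using the group mean increments reported for each gene at
each learning stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

GENES = ("BDNF", "CREB", "SynapsinI", "CamKII", "cfos", "cjun", "Arc")
GROUPS = ("Control", "BC50%CR", "50%CR", "BC100%CR", "100%CR")
CONTROL_GROUPS = ("Control", "BC50%CR", "BC100%CR")


@dataclass(frozen=True)
class EffectConfig:
    """Group means (percent of control) per gene plus the noise model.

    Control-type groups sit at 100 by construction.  ``noise_sd`` is on
    the percent scale and common to all groups; ``n_per_group`` defaults
    to the six animals per group used in the experiment.
    """

    means: dict[str, dict[str, float]]
    noise_sd: float = 9.0
    n_per_group: int = 6

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for gene, groups in self.means.items():
            if gene not in GENES:
                raise ValueError(f"unknown gene {gene!r}")
            for group, mean in groups.items():
                if group not in GROUPS:
                    raise ValueError(f"unknown group {group!r} for gene {gene}")
                if mean <= 0:
                    raise ValueError(f"mean for {gene}/{group} must be > 0")

    def with_n(self, n_per_group: int) -> "EffectConfig":
        return replace(self, n_per_group=n_per_group)


def default_effects() -> EffectConfig:
    """Default effect sizes: the reported mean increments per gene.

    Each entry is the group mean as a percent of the cage-control value.
    The learning-stage means come from the reported pairwise changes
    (e.g. BDNF +31.9% in 50%CR vs its box control, then an 18.9% drop
    from 50%CR to 100%CR giving 131.9 * 0.811 = 106.97).  Where a gene's
    trained-stage increment was reported only against its own box
    control, that value is used directly.  Arc's trained-stage increment
    was reported as significant without a printed percentage; 114 is
    assumed, in line with the other immediate early genes.
    """
    m = {
        "BDNF": {"50%CR": 131.9, "100%CR": round(131.9 * (1 - 0.189), 2)},
        "CREB": {"50%CR": 131.0, "100%CR": 114.7},
        "SynapsinI": {"50%CR": 127.4, "100%CR": 116.3},
        "CamKII": {"50%CR": 118.7, "100%CR": 115.2},
        "cfos": {"50%CR": 126.5, "100%CR": 114.0},
        "cjun": {"50%CR": 129.8, "100%CR": 114.2},
        "Arc": {"50%CR": 130.0, "100%CR": 114.0},  # assumed trained-stage mean
    }
    means = {
        gene: {**{g: 100.0 for g in CONTROL_GROUPS}, **stage_means}
        for gene, stage_means in m.items()
    }
    return EffectConfig(means=means)


def generate(config: EffectConfig, seed: int) -> pd.DataFrame:
    """Draw a long-format expression table, deterministic per seed.

    Values ~ Normal(group mean, noise_sd) truncated at zero, on the
    percent-of-control scale.  Columns: gene, group, replicate, value.
    """
    rng = np.random.default_rng(seed)
    records = []
    for gene in GENES:
        if gene not in config.means:
            raise ValueError(f"no effect configuration for gene {gene!r}")
        for group in GROUPS:
            mean = config.means[gene].get(group, 100.0)
            a = (0.0 - mean) / config.noise_sd  # truncate at zero
            values = stats.truncnorm.rvs(
                a, np.inf, loc=mean, scale=config.noise_sd,
                size=config.n_per_group, random_state=rng,
            )
            for r, v in enumerate(values):
                records.append((gene, group, r, float(v)))
    return pd.DataFrame(records, columns=["gene", "group", "replicate", "value"])


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
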