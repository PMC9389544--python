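"""Differential serum-metabolite screening between tumour and healthy arms.

The screen follows the common metabolomics convention: fold change as the
ratio of arithmetic group means on the raw intensity scale, significance from
an empirical-Bayes moderated t on log2 intensities, BH FDR across all
metabolites, and strict thresholds (FDR < 0.05 and FC > 1.2 or FC < 5/6 by
default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import AnalysisConfig, MetaboliteAbundanceMatrix
from .stats import benjamini_hochberg, moderated_t_two_group

__all__ = ["DemThresholds", "fold_change", "screen_dems", "DifferentialAbundance", "DifferentialAbundanceResults"]


@dataclass
class DemThresholds:
    fdr_max: float = 0.05
    fc_up: float = 1.2
    fc_down: float = 5.0 / 6.0

    def __post_init__(self) -> None:
        if not (0.0 < self.fc_down < 1.0 < self.fc_up):
            raise ValueError("need 0 < fc_down < 1 < fc_up")
        if not (0.0 < self.fdr_max < 1.0):
            raise ValueError("fdr_max must be in (0,1)")


def fold_change(
    matrix: MetaboliteAbundanceMatrix, group: str = "GC", reference: str = "healthy"
) -> pd.Series:
    """Per-metabolite ratio of arithmetic group means, raw intensity scale."""
    levels = matrix.require_two_groups()
    if group not in levels or reference not in levels:
        group, reference = levels[1], levels[0]
    g_cols = matrix.group.index[matrix.group == group]
    r_cols = matrix.group.index[matrix.group == reference]
    fc = matrix.values[g_cols].mean(axis=1) / matrix.values[r_cols].mean(axis=1)
    fc.name = "fc"
    return fc


def screen_dems(
    matrix: MetaboliteAbundanceMatrix,
    thresholds: DemThresholds | None = None,
    group: str = "GC",
    reference: str = "healthy",
) -> pd.DataFrame:
    """Screen differentially abundant metabolites.

    Returns a per-metabolite table with columns ``fc``, ``log2fc``, ``p``,
    ``fdr`` and ``direction`` in {up, down, ns}.  ``up`` requires fdr <
    fdr_max and fc > fc_up strictly; ``down`` requires fdr < fdr_max and
    fc < fc_down strictly.
    """
    thresholds = thresholds or DemThresholds()
    levels = matrix.require_two_groups()
    if group not in levels or reference not in levels:
        group, reference = levels[1], levels[0]
    counts = matrix.group.value_counts()
    if (counts < 2).any():
        raise ValueError("each group needs >= 2 samples")

    fc = fold_change(matrix, group=group, reference=reference)
    log2 = np.log2(matrix.values)
    fit = moderated_t_two_group(log2, matrix.group[log2.columns], group=group, reference=reference)
    p = fit.table["p"]
    fdr = pd.Series(benjamini_hochberg(p.to_numpy()), index=p.index)

    direction = pd.Series("ns", index=fc.index)
    direction[(fdr < thresholds.fdr_max) & (fc > thresholds.fc_up)] = "up"
    direction[(fdr < thresholds.fdr_max) & (fc < thresholds.fc_down)] = "down"

    return pd.DataFrame(
        {
            "fc": fc,
            "log2fc": fit.table["log2fc"],
            "p": p,
            "fdr": fdr,
            "direction": direction,
        }
    )


class DifferentialAbundance:
    """Two-group differential-abundance model for a serum metabolome.

    Parameters
    ----------
    matrix
        Metabolite intensities with group labels attached.
    thresholds
        Screening thresholds; defaults to FDR < 0.05 with FC > 1.2 / < 5/6.
    """

    def __init__(
        self,
        matrix: MetaboliteAbundanceMatrix,
        thresholds: DemThresholds | None = None,
        group: str = "GC",
        reference: str = "healthy",
    ):
        matrix.require_two_groups()
        self.matrix = matrix
        self.thresholds = thresholds or DemThresholds()
        self.group = group
        self.reference = reference

    @classmethod
    def from_config(
        cls, matrix: MetaboliteAbundanceMatrix, config: AnalysisConfig
    ) -> "DifferentialAbundance":
        return cls(
            matrix,
            DemThresholds(config.dem_fdr_max, config.dem_fc_up, config.dem_fc_down),
        )

    def fit(self) -> "DifferentialAbundanceResults":
        table = screen_dems(self.matrix, self.thresholds, self.group, self.reference)
        return DifferentialAbundanceResults(self, table)


class DifferentialAbundanceResults:
    def __init__(self, model: DifferentialAbundance, table: pd.DataFrame):
        self.model = model
        self.table = table

    @property
    def n_total(self) -> int:
        return len(self.table)

    @property
    def n_up(self) -> int:
        return int((self.table["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["direction"] == "down").sum())

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["direction"] != "ns"]

    def summary(self) -> str:
        thr = self.model.thresholds
        lines = [
            "Differential metabolite screen",
            f"  comparison : {self.model.group} vs {self.model.reference}",
            f"  criteria   : FDR < {thr.fdr_max:g}, FC > {thr.fc_up:g} or < {thr.fc_down:g}",
            f"  metabolites: {self.n_total}",
            f"  up         : {self.n_up}",
            f"  down       : {self.n_down}",
        ]
        return "\n".join(lines)
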