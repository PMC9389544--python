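"""Typed containers for the matrices, tables and gene sets the pipeline moves around.

All matrices are features x samples (rows are genes or metabolites, columns are
samples); the convention is enforced at load time and assumed everywhere else.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "MetaboliteAbundanceMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "AnalysisConfig",
]


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].tolist()
        raise ValueError(f"duplicate {what} id(s): {dup[:5]}")


@dataclass
class ExpressionMatrix:
    """Gene-expression matrix on log2 scale, genes x samples."""

    values: pd.DataFrame  # index = feature ids, columns = sample ids

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "feature")
        _check_unique(self.values.columns, "sample")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not np.issubdtype(np.asarray(self.values).dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class MetaboliteAbundanceMatrix:
    """Raw (strictly positive) metabolite intensities, metabolites x samples.

    ``group`` maps each sample to a cohort arm (conventionally ``GC`` /
    ``healthy``).  It may be attached after loading via :meth:`with_groups`;
    two-group screening requires it.
    """

    values: pd.DataFrame
    group: pd.Series | None = None  # sample id -> group label

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "metabolite")
        _check_unique(self.values.columns, "sample")
        if self.values.isna().any().any():
            raise ValueError("metabolite matrix contains missing values")
        arr = np.asarray(self.values, dtype=float)
        if not (arr > 0).all():
            bad = np.argwhere(~(arr > 0))[0]
            raise ValueError(
                "non-positive intensity at "
                f"({self.values.index[bad[0]]!r}, {self.values.columns[bad[1]]!r})"
            )
        if self.group is not None:
            self.group = pd.Series(self.group).reindex(self.values.columns)
            if self.group.isna().any():
                missing = self.group[self.group.isna()].index.tolist()
                raise ValueError(f"samples without group label: {missing[:5]}")

    def with_groups(self, group: Mapping[str, str] | pd.Series) -> "MetaboliteAbundanceMatrix":
        return MetaboliteAbundanceMatrix(self.values, pd.Series(dict(group) if isinstance(group, Mapping) else group))

    def require_two_groups(self) -> tuple[str, str]:
        """Return the two group levels, raising unless exactly two are present."""
        if self.group is None:
            raise ValueError("no group labels attached; call with_groups() first")
        levels = sorted(self.group.unique())
        if len(levels) != 2:
            raise ValueError(f"two-group screening needs exactly 2 groups, got {levels}")
        return levels[0], levels[1]

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


_CLINICAL_COLUMNS = [
    "sample_id", "group", "os_time", "os_event", "dss_time", "dss_event",
    "stage", "grade", "her2_ihc", "immune_subtype",
]


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations (survival, stage/grade, HER2 IHC)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if "sample_id" not in df.columns:
            raise ValueError("clinical table needs a 'sample_id' column")
        _check_unique(pd.Index(df["sample_id"]), "sample")
        for col in _CLINICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        for tcol in ("os_time", "dss_time"):
            t = pd.to_numeric(df[tcol], errors="coerce")
            if (t.dropna() < 0).any():
                raise ValueError(f"negative {tcol}")
            df[tcol] = t
        for ecol in ("os_event", "dss_event"):
            e = pd.to_numeric(df[ecol], errors="coerce")
            bad = e.dropna()[~e.dropna().isin([0, 1])]
            if len(bad):
                raise ValueError(f"{ecol} values outside {{0,1}}: {bad.unique().tolist()}")
            df[ecol] = e
        her2 = pd.to_numeric(df["her2_ihc"], errors="coerce")
        bad = her2.dropna()[~her2.dropna().isin([0, 1, 2, 3])]
        if len(bad):
            raise ValueError(f"her2_ihc outside 0-3: {bad.unique().tolist()}")
        df["her2_ihc"] = her2
        self.table = df.reset_index(drop=True)

    def indexed(self) -> pd.DataFrame:
        return self.table.set_index("sample_id")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])


@dataclass
class GeneSetCollection:
    """Named gene sets (ordered membership), GMT-compatible."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.sets) != len(set(self.sets)):
            raise ValueError("duplicate set names")
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set: {name!r}")
            if len(members) != len(set(members)):
                seen: set[str] = set()
                deduped = [m for m in members if not (m in seen or seen.add(m))]
                warnings.warn(f"set {name!r} lists duplicate members; de-duplicated")
                self.sets[name] = deduped

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterable[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()


@dataclass
class AnalysisConfig:
    """All downstream thresholds and parameters with their published defaults."""

    # differential metabolite screen
    dem_fdr_max: float = 0.05
    dem_fc_up: float = 1.2
    dem_fc_down: float = 5.0 / 6.0
    # weighted metabolite co-expression network
    wmcna_rsq_target: float = 0.85
    wmcna_powers: tuple[int, ...] = tuple(range(1, 21))
    wmcna_min_module_size: int = 5
    wmcna_cut_height: float = 0.92
    wmcna_mm_min: float = 0.7
    wmcna_mes_min: float = 0.15
    wmcna_trait_method: str = "pearson"  # or "spearman"
    # metabolite-metabolite interaction network
    mmi_r_threshold: float = 0.4
    # consensus clustering
    consensus_k: int = 3
    consensus_reps: int = 100
    consensus_p_item: float = 0.8
    consensus_p_feature: float = 1.0
    # ssGSEA
    ssgsea_alpha: float = 0.25
    ssgsea_normalize: bool = True
    # missing-value policy for metabolite matrices: reject | min-impute
    missing_policy: str = "reject"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.dem_fdr_max < 1):
            raise ValueError("dem_fdr_max must be in (0,1)")
        if not (0 < self.dem_fc_down < 1 < self.dem_fc_up):
            raise ValueError("need 0 < fc_down < 1 < fc_up")
        if self.consensus_k < 2:
            raise ValueError("consensus_k must be >= 2")
        if self.consensus_reps < 1:
            raise ValueError("consensus_reps must be >= 1")
        if not (0 < self.consensus_p_item <= 1):
            raise ValueError("consensus_p_item must be in (0,1]")
        if not (0 < self.consensus_p_feature <= 1):
            raise ValueError("consensus_p_feature must be in (0,1]")
        if self.ssgsea_alpha < 0:
            raise ValueError("ssgsea_alpha must be >= 0")
        if not (0 < self.wmcna_cut_height <= 1):
            raise ValueError("wmcna_cut_height must be in (0,1]")
        if self.missing_policy not in ("reject", "min-impute"):
            raise ValueError("missing_policy must be 'reject' or 'min-impute'")
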