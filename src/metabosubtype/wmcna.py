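"""Weighted metabolite co-expression network analysis.

WGCNA-style workflow applied to metabolite abundances: Pearson correlation on
standardized log2 intensities, soft-threshold selection against a scale-free
fit target, unsigned adjacency |r|^beta, topological overlap, average-linkage
module detection with a static height cut, module eigenmetabolites
(first principal components), module-trait statistics against an ordinal
HER2 IHC trait, and hub selection by module membership (MM) and metabolite
trait significance (MES).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import AnalysisConfig, MetaboliteAbundanceMatrix

__all__ = [
    "SoftThresholdScan",
    "ModulePartition",
    "ModuleTraitStats",
    "HubCriteria",
    "standardize_log2",
    "metabolite_correlation",
    "soft_threshold_scan",
    "adjacency_matrix",
    "tom_matrix",
    "detect_modules",
    "module_eigenmetabolites",
    "module_trait_stats",
    "select_hub_metabolites",
    "MetaboliteNetwork",
    "MetaboliteNetworkResults",
]


@dataclass
class SoftThresholdScan:
    table: pd.DataFrame  # per power: signed_rsq, mean_connectivity
    chosen_power: int | None
    rsq_target: float


@dataclass
class ModulePartition:
    labels: pd.Series  # metabolite -> module id (1..K by decreasing size), 0 = unassigned
    merge_heights: np.ndarray
    cut_height: float
    min_module_size: int

    def modules(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for met, lab in self.labels.items():
            if lab > 0:
                out.setdefault(int(lab), []).append(met)
        return out


@dataclass
class ModuleTraitStats:
    module_table: pd.DataFrame      # per module: size, trait_r, trait_p
    metabolite_table: pd.DataFrame  # per metabolite: module, mm, mes


@dataclass
class HubCriteria:
    mm_min: float = 0.7
    mes_min: float = 0.15

    def __post_init__(self) -> None:
        if not (0 < self.mm_min < 1 and 0 < self.mes_min < 1):
            raise ValueError("thresholds must be in (0,1)")


def standardize_log2(matrix: MetaboliteAbundanceMatrix) -> pd.DataFrame:
    """log2-transform and z-score each metabolite across samples.

    Zero-variance metabolites are excluded with a warning.
    """
    log2 = np.log2(matrix.values.to_numpy(dtype=float))
    sd = log2.std(axis=1, ddof=1)
    # tolerance absorbs rounding in the mean of an exactly-constant profile
    keep = sd > 1e-10 * np.maximum(np.abs(log2).max(axis=1), 1.0)
    if not keep.all():
        dropped = list(np.asarray(matrix.metabolite_ids)[~keep])
        warnings.warn(f"excluding zero-variance metabolites: {dropped[:5]}")
    z = (log2[keep] - log2[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return pd.DataFrame(
        z, index=np.asarray(matrix.metabolite_ids)[keep], columns=matrix.sample_ids
    )


def metabolite_correlation(matrix: MetaboliteAbundanceMatrix) -> pd.DataFrame:
    """Symmetric Pearson correlation of standardized log2 metabolite profiles."""
    if matrix.shape[1] < 4:
        raise ValueError("need >= 4 samples")
    z = standardize_log2(matrix)
    cor = np.corrcoef(z.to_numpy())
    np.fill_diagonal(cor, 1.0)
    return pd.DataFrame(cor, index=z.index, columns=z.index)


def adjacency_matrix(cor: pd.DataFrame | np.ndarray, power: float) -> np.ndarray:
    """Unsigned soft-threshold adjacency |r|^power with zero diagonal."""
    if power < 1:
        raise ValueError("power must be >= 1")
    r = np.asarray(cor, dtype=float)
    a = np.abs(r) ** power
    np.fill_diagonal(a, 0.0)
    return a


def soft_threshold_scan(
    cor: pd.DataFrame | np.ndarray,
    powers=tuple(range(1, 21)),
    rsq_target: float = 0.85,
    n_bins: int = 10,
) -> SoftThresholdScan:
    """Scale-free topology scan over candidate soft-threshold powers.

    For each power: adjacency |r|^beta, connectivity k_i = sum_j a_ij, then a
    log-log regression of connectivity-bin frequency on bin mean connectivity
    over ``n_bins`` equal-width bins.  The signed fit is -sign(slope)*R^2; the
    chosen power is the smallest one reaching ``rsq_target``.
    """
    r = np.asarray(cor, dtype=float)
    if r.shape[0] < 20:
        raise ValueError("need >= 20 nodes for a meaningful scale-free fit")
    rows = []
    chosen: int | None = None
    for beta in powers:
        a = adjacency_matrix(r, beta)
        k = a.sum(axis=1)
        rsq = _scale_free_fit(k, n_bins)
        rows.append({"power": beta, "signed_rsq": rsq, "mean_connectivity": float(k.mean())})
        if chosen is None and not np.isnan(rsq) and rsq >= rsq_target:
            chosen = int(beta)
    return SoftThresholdScan(
        table=pd.DataFrame(rows).set_index("power"), chosen_power=chosen, rsq_target=rsq_target
    )


def _scale_free_fit(k: np.ndarray, n_bins: int) -> float:
    if k.max() <= k.min():
        return np.nan
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq, mean_k = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() > 0 and k[mask].mean() > 0:
            freq.append(mask.sum())
            mean_k.append(k[mask].mean())
    if len(freq) < 3:
        return np.nan
    x = np.log10(np.asarray(mean_k))
    y = np.log10(np.asarray(freq, dtype=float))
    if np.allclose(x, x[0]):
        return np.nan
    slope, _, r_val, _, _ = sps.linregress(x, y)
    return float(-np.sign(slope) * r_val**2)


def tom_matrix(a: np.ndarray) -> np.ndarray:
    """Topological overlap similarity.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1.
    """
    a = np.asarray(a, dtype=float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if (a < 0).any() or (a > 1).any():
        raise ValueError("adjacency entries must be in [0,1]")
    k = a.sum(axis=1)
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    np.fill_diagonal(tom, 1.0)
    return tom


def detect_modules(
    diss_tom: pd.DataFrame | np.ndarray,
    min_module_size: int = 5,
    cut_height: float = 0.92,
    ids: list[str] | None = None,
) -> ModulePartition:
    """Average-linkage module detection with a static height cut.

    The dendrogram over the TOM dissimilarity (which lives in [0, 1]) is cut
    at the absolute height ``cut_height``; resulting clusters smaller than
    ``min_module_size`` are left unassigned (label 0).  Module ids 1..K are
    ordered by decreasing size (ties broken by first member position).
    """
    if min_module_size < 2:
        raise ValueError("min_module_size must be >= 2")
    d = np.asarray(diss_tom, dtype=float)
    if ids is None:
        ids = list(diss_tom.index) if isinstance(diss_tom, pd.DataFrame) else [
            f"n{i}" for i in range(d.shape[0])
        ]
    condensed = squareform(d, checks=False)
    z = linkage(condensed, method="average")
    heights = z[:, 2]
    cut = float(cut_height)
    raw = fcluster(z, t=cut, criterion="distance")

    sizes: dict[int, int] = {}
    first_pos: dict[int, int] = {}
    for pos, lab in enumerate(raw):
        sizes[lab] = sizes.get(lab, 0) + 1
        first_pos.setdefault(lab, pos)
    kept = [lab for lab, s in sizes.items() if s >= min_module_size]
    kept.sort(key=lambda lab: (-sizes[lab], first_pos[lab]))
    relabel = {lab: i + 1 for i, lab in enumerate(kept)}
    labels = pd.Series([relabel.get(lab, 0) for lab in raw], index=ids, dtype=int)
    return ModulePartition(
        labels=labels,
        merge_heights=heights,
        cut_height=cut,
        min_module_size=min_module_size,
    )


def module_eigenmetabolites(
    matrix_standardized: pd.DataFrame, partition: ModulePartition
) -> pd.DataFrame:
    """First principal component of each module (per-sample scores).

    Scores are scaled to unit variance and sign-oriented to correlate
    positively with the module's mean profile.  A single-member module's
    eigenmetabolite is that metabolite's own standardized profile.
    """
    eigens = {}
    for mod, members in sorted(partition.modules().items()):
        x = matrix_standardized.loc[members].to_numpy()  # members x samples
        if x.shape[0] == 1:
            e = x[0].copy()
        else:
            u, s, vt = np.linalg.svd(x - x.mean(axis=1, keepdims=True), full_matrices=False)
            e = vt[0] * s[0]
        sd = e.std(ddof=1)
        if sd > 0:
            e = e / sd
        mean_profile = x.mean(axis=0)
        if np.corrcoef(e, mean_profile)[0, 1] < 0:
            e = -e
        eigens[mod] = e
    return pd.DataFrame(eigens, index=matrix_standardized.columns).T


def _pairwise_cor(x: np.ndarray, y: np.ndarray, method: str = "pearson") -> tuple[float, float]:
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 4:
        raise ValueError("need >= 4 complete pairs")
    if method == "spearman":
        r, p = sps.spearmanr(x[ok], y[ok])
    else:
        r, p = sps.pearsonr(x[ok], y[ok])
    return float(r), float(p)


def module_trait_stats(
    matrix_standardized: pd.DataFrame,
    partition: ModulePartition,
    eigens: pd.DataFrame,
    trait: pd.Series,
    method: str = "pearson",
) -> ModuleTraitStats:
    """Module- and metabolite-level trait statistics.

    Per module: correlation (with p) of the eigenmetabolite with the trait.
    Per metabolite: MM = |cor(metabolite, own module eigenmetabolite)| and
    MES = |cor(metabolite, trait)|.  Samples with missing trait are dropped
    pairwise.
    """
    trait = trait.reindex(matrix_standardized.columns).astype(float)
    t = trait.to_numpy()
    if np.unique(t[~np.isnan(t)]).size < 2:
        raise ValueError("trait is constant")

    mod_rows = []
    for mod, members in sorted(partition.modules().items()):
        r, p = _pairwise_cor(eigens.loc[mod].to_numpy(), t, method)
        mod_rows.append({"module": mod, "size": len(members), "trait_r": r, "trait_p": p})
    module_table = pd.DataFrame(mod_rows).set_index("module") if mod_rows else pd.DataFrame(
        columns=["size", "trait_r", "trait_p"]
    )

    met_rows = []
    for met in matrix_standardized.index:
        mod = int(partition.labels.get(met, 0))
        x = matrix_standardized.loc[met].to_numpy()
        mm = np.nan
        if mod > 0:
            mm = abs(np.corrcoef(x, eigens.loc[mod].to_numpy())[0, 1])
        mes, _ = _pairwise_cor(x, t, method)
        met_rows.append({"metabolite": met, "module": mod, "mm": mm, "mes": abs(mes)})
    metabolite_table = pd.DataFrame(met_rows).set_index("metabolite")
    return ModuleTraitStats(module_table=module_table, metabolite_table=metabolite_table)


def select_hub_metabolites(
    stats: ModuleTraitStats,
    criteria: HubCriteria | None = None,
    trait_p_max: float = 0.05,
) -> list[str]:
    """Hub metabolites: members of trait-significant modules with MM > mm_min
    and MES > mes_min (both strict), ordered by MM descending then id."""
    criteria = criteria or HubCriteria()
    sig = stats.module_table.index[stats.module_table["trait_p"] < trait_p_max]
    if len(sig) == 0:
        warnings.warn("no trait-significant modules; empty hub list")
        return []
    tab = stats.metabolite_table
    mask = (
        tab["module"].isin(sig)
        & (tab["mm"] > criteria.mm_min)
        & (tab["mes"] > criteria.mes_min)
    )
    hubs = tab[mask].sort_values(["mm"], ascending=False)
    hubs = hubs.sort_values(["mm"], ascending=False, kind="mergesort")
    # deterministic tie-break on id
    hubs = hubs.reset_index().sort_values(["mm", "metabolite"], ascending=[False, True], kind="mergesort")
    return list(hubs["metabolite"])


# ---------------------------------------------------------------------------
# model / results wrappers


class MetaboliteNetwork:
    """Weighted co-expression network model of a metabolite abundance matrix.

    Parameters
    ----------
    matrix
        Positive raw intensities (log2-transformed and standardized
        internally).
    trait
        Per-sample numeric trait (e.g. HER2 IHC 0-3); optional, needed for
        module-trait statistics and hub selection.
    """

    def __init__(
        self,
        matrix: MetaboliteAbundanceMatrix,
        trait: pd.Series | None = None,
        config: AnalysisConfig | None = None,
    ):
        self.matrix = matrix
        self.trait = trait
        self.config = config or AnalysisConfig()

    def fit(self, power: int | None = None) -> "MetaboliteNetworkResults":
        cfg = self.config
        cor = metabolite_correlation(self.matrix)
        scan = None
        if power is None:
            scan = soft_threshold_scan(cor, cfg.wmcna_powers, cfg.wmcna_rsq_target)
            power = scan.chosen_power
            if power is None:
                warnings.warn(
                    "no power reached the scale-free target; falling back to the "
                    "best-fitting power"
                )
                best = scan.table["signed_rsq"].idxmax()
                power = int(best) if not np.isnan(scan.table["signed_rsq"]).all() else 6
        a = adjacency_matrix(cor.to_numpy(), power)
        tom = tom_matrix(a)
        partition = detect_modules(
            pd.DataFrame(1.0 - tom, index=cor.index, columns=cor.index),
            min_module_size=cfg.wmcna_min_module_size,
            cut_height=cfg.wmcna_cut_height,
        )
        z = standardize_log2(self.matrix)
        eigens = module_eigenmetabolites(z, partition)
        stats = None
        if self.trait is not None and len(partition.modules()) > 0:
            stats = module_trait_stats(z, partition, eigens, self.trait, cfg.wmcna_trait_method)
        return MetaboliteNetworkResults(
            model=self, correlation=cor, scan=scan, power=int(power),
            partition=partition, eigens=eigens, trait_stats=stats,
        )


@dataclass
class MetaboliteNetworkResults:
    model: MetaboliteNetwork
    correlation: pd.DataFrame
    scan: SoftThresholdScan | None
    power: int
    partition: ModulePartition
    eigens: pd.DataFrame
    trait_stats: ModuleTraitStats | None

    def hub_metabolites(self, criteria: HubCriteria | None = None) -> list[str]:
        if self.trait_stats is None:
            raise ValueError("no trait supplied; hub selection unavailable")
        cfg = self.model.config
        criteria = criteria or HubCriteria(cfg.wmcna_mm_min, cfg.wmcna_mes_min)
        return select_hub_metabolites(self.trait_stats, criteria)

    def summary(self) -> str:
        mods = self.partition.modules()
        n_unassigned = int((self.partition.labels == 0).sum())
        lines = [
            "Weighted metabolite co-expression network",
            f"  metabolites     : {len(self.partition.labels)}",
            f"  soft power      : {self.power}"
            + (
                f" (signed R^2 = {self.scan.table.loc[self.power, 'signed_rsq']:.2f})"
                if self.scan is not None and self.power in self.scan.table.index
                else ""
            ),
            f"  modules         : {len(mods)}",
            f"  unassigned      : {n_unassigned}",
        ]
        if self.trait_stats is not None:
            sig = (self.trait_stats.module_table["trait_p"] < 0.05).sum()
            lines.append(f"  trait-linked    : {int(sig)} module(s) at p < 0.05")
            lines.append(f"  hub metabolites : {len(self.hub_metabolites())}")
        return "\n".join(lines)
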