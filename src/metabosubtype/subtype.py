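"""Two-pathway metabolic subtyping by consensus clustering.

For each of the two KEGG pathways (alanine-aspartate-glutamate metabolism,
"AAG", and glycolysis/gluconeogenesis, "GG") the pathway genes are consensus-
clustered (Monti resampling: reps of item subsampling, Ward linkage on
1 - Pearson distance, k clusters) and the most strongly coexpressed gene
cluster is kept.  Each sample is scored by the median z-scored expression of
the selected genes of each pathway, and assigned to one of four quadrant
subtypes: quiescent (AAG <= 0, GG <= 0), AAG (> 0, <= 0), GG (<= 0, > 0),
mixed (> 0, > 0).  Downstream calls: subtype-specific molecules, per-feature
Kruskal-Wallis group tests, and Kaplan-Meier / log-rank survival comparison.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .datatypes import AnalysisConfig, ClinicalTable, ExpressionMatrix
from .stats import (
    SurvivalCurve,
    TestResult,
    benjamini_hochberg,
    km_curve,
    kruskal_wallis,
    logrank_test,
    moderated_t_two_group,
)

__all__ = [
    "ConsensusParams",
    "ConsensusResult",
    "subset_pathway_genes",
    "consensus_cluster",
    "select_coexpressed_group",
    "pathway_score",
    "assign_subtypes",
    "specific_molecules",
    "subtype_group_tests",
    "subtype_survival",
    "MetabolicSubtyper",
    "MetabolicSubtypeResults",
]

QUADRANT_LABELS = ("quiescent", "AAG", "GG", "mixed")


@dataclass
class ConsensusParams:
    k: int = 3
    reps: int = 100
    p_item: float = 0.8
    p_feature: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not (0 < self.p_item <= 1):
            raise ValueError("p_item must be in (0,1]")
        if not (0 < self.p_feature <= 1):
            raise ValueError("p_feature must be in (0,1]")


@dataclass
class ConsensusResult:
    consensus: pd.DataFrame        # items x items, in [0,1]
    labels: pd.Series              # item -> cluster 1..k
    cosampled: pd.DataFrame        # co-sampling counts
    per_cluster_mean_consensus: dict
    n_never_cosampled: int


def subset_pathway_genes(
    expr: ExpressionMatrix, gene_set: list[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Restrict the expression matrix to a gene set (set order preserved).

    Returns the submatrix and the list of set genes absent from the matrix.
    """
    present = [g for g in gene_set if g in expr.values.index]
    missing = [g for g in gene_set if g not in expr.values.index]
    if not present:
        raise ValueError("gene set has no overlap with the expression matrix")
    return expr.values.loc[present], missing


def _item_draw(seed: int, rep: int, item_id: str) -> float:
    """Per-(item, rep) uniform draw from an id-keyed stream.

    Keyed by a CRC of the item id so the consensus matrix does not depend on
    the input order of items.
    """
    key = zlib.crc32(item_id.encode()) & 0x7FFFFFFF
    return float(np.random.default_rng([seed & 0x7FFFFFFF, rep, key]).random())


def _ward_labels(sub: np.ndarray, k: int) -> np.ndarray:
    """Ward clustering of items (rows) on 1 - Pearson distance, cut at k."""
    if sub.shape[0] == 1:
        return np.array([1])
    with np.errstate(invalid="ignore"):
        cor = np.corrcoef(sub)
    cor = np.nan_to_num(cor, nan=0.0)
    d = 1.0 - cor
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    z = linkage(squareform(np.clip(d, 0.0, None), checks=False), method="ward")
    return fcluster(z, t=min(k, sub.shape[0]), criterion="maxclust")


def consensus_cluster(
    features: pd.DataFrame, params: ConsensusParams | None = None
) -> ConsensusResult:
    """Monti consensus clustering of the rows (items) of ``features``.

    Each rep subsamples ceil(p_item * n_items) items (and ceil(p_feature *
    n_samples) sample columns), Ward-clusters them on 1 - Pearson distance at
    k, and accumulates co-clustering counts.  The consensus matrix is
    connected / co-sampled (0/0 counted as 0 and flagged); final labels come
    from Ward clustering of 1 - consensus.
    """
    params = params or ConsensusParams()
    items = list(features.index)
    n = len(items)
    if params.k > n:
        raise ValueError(f"k={params.k} exceeds item count {n}")
    x = features.to_numpy(dtype=float)
    n_samp = x.shape[1]
    if n_samp < 4:
        raise ValueError("need >= 4 samples")

    n_draw = int(np.ceil(params.p_item * n))
    n_feat = int(np.ceil(params.p_feature * n_samp))
    connected = np.zeros((n, n))
    cosampled = np.zeros((n, n))

    for rep in range(params.reps):
        draws = np.array([_item_draw(params.seed, rep, it) for it in items])
        sel = np.sort(np.argsort(draws, kind="mergesort")[:n_draw])
        if n_feat < n_samp:
            feat_rng = np.random.default_rng([params.seed & 0x7FFFFFFF, rep, 0x5EED])
            cols = np.sort(feat_rng.permutation(n_samp)[:n_feat])
            sub = x[np.ix_(sel, cols)]
        else:
            sub = x[sel]
        labs = _ward_labels(sub, params.k)
        same = labs[:, None] == labs[None, :]
        cosampled[np.ix_(sel, sel)] += 1.0
        connected[np.ix_(sel, sel)] += same

    with np.errstate(invalid="ignore"):
        m = np.where(cosampled > 0, connected / np.maximum(cosampled, 1), 0.0)
    never = int((np.triu(cosampled, 1) == 0).sum() - (n * (n - 1)) // 2 * 0)
    never = int(((cosampled == 0) & ~np.eye(n, dtype=bool)).sum() // 2)
    if never:
        warnings.warn(f"{never} item pair(s) never co-sampled; consensus set to 0")
    np.fill_diagonal(m, 1.0)
    m = (m + m.T) / 2.0

    d = 1.0 - m
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="ward")
    labels = pd.Series(fcluster(z, t=params.k, criterion="maxclust"), index=items)

    per_cluster = {}
    for lab in sorted(labels.unique()):
        idx = np.where(labels.to_numpy() == lab)[0]
        if len(idx) == 1:
            per_cluster[int(lab)] = 1.0
        else:
            block = m[np.ix_(idx, idx)]
            per_cluster[int(lab)] = float(block[np.triu_indices(len(idx), 1)].mean())

    return ConsensusResult(
        consensus=pd.DataFrame(m, index=items, columns=items),
        labels=labels,
        cosampled=pd.DataFrame(cosampled, index=items, columns=items),
        per_cluster_mean_consensus=per_cluster,
        n_never_cosampled=never,
    )


def select_coexpressed_group(submatrix: pd.DataFrame, labels: pd.Series) -> list[str]:
    """Return the gene cluster with the highest mean pairwise (signed) Pearson r.

    Ties break to the larger cluster, then the lowest label.  Size-1 clusters
    carry no coexpression evidence and are skipped; all-singletons is an error.
    """
    best: tuple[float, int, int] | None = None
    best_genes: list[str] | None = None
    for lab in sorted(labels.unique()):
        members = list(labels.index[labels == lab])
        if len(members) < 2:
            continue
        cor = np.corrcoef(submatrix.loc[members].to_numpy())
        mean_r = float(cor[np.triu_indices(len(members), 1)].mean())
        key = (mean_r, len(members), -int(lab))
        if best is None or key > best:
            best = key
            best_genes = members
    if best_genes is None:
        raise ValueError("no cluster with >= 2 members; no coexpression evidence")
    return best_genes


def pathway_score(expr: ExpressionMatrix | pd.DataFrame, selected_genes: list[str]) -> pd.Series:
    """Per-sample median of z-scored expression over the selected genes."""
    values = expr.values if isinstance(expr, ExpressionMatrix) else expr
    missing = [g for g in selected_genes if g not in values.index]
    if missing:
        raise ValueError(f"selected genes absent from matrix: {missing[:5]}")
    if values.shape[1] < 2:
        raise ValueError("z-scores undefined with a single sample")
    x = values.loc[selected_genes].to_numpy(dtype=float)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=1, keepdims=True)) / sd
    return pd.Series(np.median(z, axis=0), index=values.columns, name="score")


def assign_subtypes(aag_scores: pd.Series, gg_scores: pd.Series) -> pd.DataFrame:
    """Quadrant rule: quiescent (AAG<=0, GG<=0), AAG (>0, <=0), GG (<=0, >0),
    mixed (>0, >0).  Samples missing either score are excluded with a warning."""
    common = aag_scores.index.intersection(gg_scores.index)
    a = aag_scores[common].astype(float)
    g = gg_scores[common].astype(float)
    ok = ~(a.isna() | g.isna())
    if not ok.all():
        warnings.warn(f"excluding {int((~ok).sum())} sample(s) with missing scores")
    a, g = a[ok], g[ok]
    label = np.where(
        a > 0, np.where(g > 0, "mixed", "AAG"), np.where(g > 0, "GG", "quiescent")
    )
    return pd.DataFrame({"aag_score": a, "gg_score": g, "label": label})


def specific_molecules(
    features: pd.DataFrame,
    labels: pd.Series,
    fdr_max: float = 0.05,
) -> dict:
    """Subtype-specific molecules.

    A feature is specific to subtype s iff, against every other subtype
    separately, it is upregulated (log2fc > 0) with BH FDR < ``fdr_max``
    (FDR computed across features within each pairwise comparison).
    Subtypes with < 2 samples are excluded from comparisons with a warning.
    """
    labels = labels.reindex(features.columns)
    counts = labels.value_counts()
    usable = [s for s in counts.index if counts[s] >= 2]
    dropped = [s for s in counts.index if counts[s] < 2]
    if dropped:
        warnings.warn(f"subtypes with < 2 samples excluded: {dropped}")
    result: dict[str, list[str]] = {}
    details: dict[tuple[str, str], pd.DataFrame] = {}
    for s in usable:
        others = [o for o in usable if o != s]
        if not others:
            result[s] = []
            continue
        spec_mask = pd.Series(True, index=features.index)
        for o in others:
            cols = labels.index[labels.isin([s, o])]
            fit = moderated_t_two_group(features[cols], labels[cols], group=s, reference=o)
            fdr = benjamini_hochberg(fit.table["p"].to_numpy())
            comp = pd.DataFrame(
                {"log2fc": fit.table["log2fc"], "p": fit.table["p"], "fdr": fdr},
                index=features.index,
            )
            details[(s, o)] = comp
            spec_mask &= (comp["log2fc"] > 0) & (comp["fdr"] < fdr_max)
        result[s] = list(features.index[spec_mask])
    return {"specific": result, "comparisons": details}


def subtype_group_tests(
    feature_matrix: pd.DataFrame, labels: pd.Series, p_max: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature Kruskal-Wallis across subtypes; retain features at p < p_max."""
    labels = labels.reindex(feature_matrix.columns)
    levels = sorted(labels.dropna().unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 subtype levels")
    rows = []
    for feat in feature_matrix.index:
        groups = [
            feature_matrix.loc[feat, labels.index[labels == lev]].to_numpy()
            for lev in levels
        ]
        res = kruskal_wallis(groups)
        rows.append({"feature": feat, "H": res.statistic, "p": res.p})
    full = pd.DataFrame(rows).set_index("feature")
    retained = full[full["p"] < p_max]
    return full, retained


def subtype_survival(
    clinical: ClinicalTable,
    labels: pd.Series,
    endpoint: str = "OS",
) -> dict:
    """Kaplan-Meier curves per subtype and the k-group log-rank test.

    Samples with missing time or event for the endpoint are excluded.
    """
    endpoint = endpoint.upper()
    if endpoint not in ("OS", "DSS"):
        raise ValueError("endpoint must be 'OS' or 'DSS'")
    tcol, ecol = (f"{endpoint.lower()}_time", f"{endpoint.lower()}_event")
    df = clinical.indexed()
    df = df.loc[df.index.intersection(labels.index)]
    lab = labels.reindex(df.index)
    ok = df[tcol].notna() & df[ecol].notna() & lab.notna()
    if not ok.any():
        raise ValueError("all samples excluded (missing follow-up)")
    df, lab = df[ok], lab[ok]
    curves: dict[str, SurvivalCurve] = {}
    for lev in sorted(lab.unique()):
        sel = lab == lev
        curves[str(lev)] = km_curve(df.loc[sel, tcol], df.loc[sel, ecol].astype(int))
    test = logrank_test(df[tcol], df[ecol].astype(int), lab)
    return {"curves": curves, "test": test, "n": int(ok.sum()), "endpoint": endpoint}


# ---------------------------------------------------------------------------
# model / results


class MetabolicSubtyper:
    """Consensus-clustering quadrant subtyper for an expression cohort.

    Parameters
    ----------
    expr
        log2 expression matrix (genes x samples).
    gene_sets
        Collection containing the two pathway sets.
    aag_set, gg_set
        Names of the AAG and GG pathway sets; auto-detected from names
        containing ``AAG``/``ALANINE`` and ``GG``/``GLYCOLYSIS`` when omitted.
    clinical
        Optional clinical table enabling survival comparisons.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        gene_sets,
        aag_set: str | None = None,
        gg_set: str | None = None,
        clinical: ClinicalTable | None = None,
        params: ConsensusParams | None = None,
    ):
        self.expr = expr
        self.gene_sets = gene_sets
        self.clinical = clinical
        self.params = params or ConsensusParams()
        names = list(gene_sets)
        if aag_set is None:
            aag_set = _find_set(names, ("AAG", "ALANINE"))
        if gg_set is None:
            gg_set = _find_set(names, ("GG", "GLYCOLYSIS"))
        self.aag_set, self.gg_set = aag_set, gg_set

    @classmethod
    def from_config(cls, expr, gene_sets, clinical=None, config: AnalysisConfig | None = None):
        config = config or AnalysisConfig()
        params = ConsensusParams(
            k=config.consensus_k,
            reps=config.consensus_reps,
            p_item=config.consensus_p_item,
            p_feature=config.consensus_p_feature,
            seed=config.seed,
        )
        return cls(expr, gene_sets, clinical=clinical, params=params)

    def fit(self) -> "MetabolicSubtypeResults":
        consensus = {}
        selected = {}
        scores = {}
        for pw, set_name in (("AAG", self.aag_set), ("GG", self.gg_set)):
            sub, missing = subset_pathway_genes(self.expr, self.gene_sets[set_name])
            if missing:
                warnings.warn(f"{set_name}: {len(missing)} set gene(s) absent from matrix")
            res = consensus_cluster(sub, self.params)
            genes = select_coexpressed_group(sub, res.labels)
            consensus[pw] = res
            selected[pw] = genes
            scores[pw] = pathway_score(self.expr, genes)
        assignment = assign_subtypes(scores["AAG"], scores["GG"])
        return MetabolicSubtypeResults(
            model=self,
            consensus=consensus,
            selected_genes=selected,
            scores=assignment,
        )


def _find_set(names: list[str], keys: tuple[str, ...]) -> str:
    for name in names:
        upper = name.upper()
        if any(k in upper for k in keys):
            return name
    raise ValueError(f"no gene set name matching any of {keys}")


@dataclass
class MetabolicSubtypeResults:
    model: MetabolicSubtyper
    consensus: dict
    selected_genes: dict
    scores: pd.DataFrame  # per sample: aag_score, gg_score, label

    @property
    def labels(self) -> pd.Series:
        return self.scores["label"]

    def subtype_counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(QUADRANT_LABELS, fill_value=0)

    def survival(self, endpoint: str = "OS") -> dict:
        if self.model.clinical is None:
            raise ValueError("no clinical table supplied")
        return subtype_survival(self.model.clinical, self.labels, endpoint)

    def specific_molecules(self, features: pd.DataFrame | None = None, fdr_max: float = 0.05) -> dict:
        if features is None:
            features = self.model.expr.values
        return specific_molecules(features, self.labels, fdr_max)

    def group_tests(self, feature_matrix: pd.DataFrame, p_max: float = 0.05):
        return subtype_group_tests(feature_matrix, self.labels, p_max)

    def crosstab(self, variable: str) -> pd.DataFrame:
        """Cross-tabulate metabolic subtype against a clinical variable."""
        if self.model.clinical is None:
            raise ValueError("no clinical table supplied")
        clin = self.model.clinical.indexed()
        var = clin[variable].reindex(self.labels.index)
        return pd.crosstab(self.labels, var)

    def summary(self) -> str:
        counts = self.subtype_counts()
        lines = [
            "Metabolic quadrant subtyping",
            f"  samples       : {len(self.labels)}",
            f"  AAG genes kept: {len(self.selected_genes['AAG'])}",
            f"  GG genes kept : {len(self.selected_genes['GG'])}",
        ]
        for lab in QUADRANT_LABELS:
            lines.append(f"  {lab:<10}    : {int(counts[lab])}")
        return "\n".join(lines)
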