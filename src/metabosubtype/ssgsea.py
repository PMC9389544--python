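"""Single-sample GSEA scoring, score-based sample grouping, two-group GSEA
with permutation NES, and trait-score correlation.

The per-sample enrichment score is the integrated difference between the
weighted in-set rank CDF and the out-of-set CDF: with genes ordered by
decreasing expression and r_j the (mid-)rank of gene j (largest expression ->
rank N),

    ES = sum_i [ P_in^w(i) - P_out(i) ],
    P_in^w(i) = sum_{j<=i, j in S} r_j^alpha / sum_{j in S} r_j^alpha,
    P_out(i)  = #{j<=i, j not in S} / (N - |S|),

with alpha = 0.25 by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import ExpressionMatrix, GeneSetCollection
from .stats import benjamini_hochberg, moderated_t_two_group

__all__ = [
    "SsgseaParams",
    "ssgsea_es",
    "ssgsea_matrix",
    "partition_high_low",
    "gsea_two_group",
    "score_trait_correlation",
]


@dataclass
class SsgseaParams:
    alpha: float = 0.25
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


def ssgsea_es(
    sample_expression: pd.Series | np.ndarray,
    gene_set: list[str],
    params: SsgseaParams | None = None,
    gene_ids: list[str] | None = None,
) -> float:
    """Enrichment score of one gene set in one sample."""
    params = params or SsgseaParams()
    if isinstance(sample_expression, pd.Series):
        gene_ids = list(sample_expression.index)
        values = sample_expression.to_numpy(dtype=float)
    else:
        values = np.asarray(sample_expression, dtype=float)
        if gene_ids is None:
            raise ValueError("gene_ids required for array input")
    n = values.size
    if n < 2:
        raise ValueError("need >= 2 genes")
    member = np.isin(np.asarray(gene_ids, dtype=object), list(gene_set))
    n_in = int(member.sum())
    if n_in == 0:
        raise ValueError(f"gene set has no overlap with expression genes")
    if n_in == n:
        raise ValueError("gene set covers all genes; out-of-set CDF undefined")

    ranks = sps.rankdata(values)  # mid-ranks, largest expression -> N
    order = np.argsort(-values, kind="mergesort")
    member_o = member[order]
    rw = np.where(member_o, ranks[order] ** params.alpha, 0.0)
    p_in = np.cumsum(rw) / rw.sum()
    p_out = np.cumsum(~member_o) / (n - n_in)
    return float(np.sum(p_in - p_out))


def ssgsea_matrix(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    params: SsgseaParams | None = None,
) -> pd.DataFrame:
    """ssGSEA score for every (gene set, sample) pair.

    Sets with no overlapping genes are dropped with a warning.  When
    ``params.normalize`` every score is divided by the global max - min over
    the whole matrix.
    """
    params = params or SsgseaParams()
    genes = np.asarray(expr.feature_ids, dtype=object)
    values = expr.values.to_numpy(dtype=float)
    kept: dict[str, np.ndarray] = {}
    for name, members in sets.items():
        mask = np.isin(genes, members)
        if not mask.any():
            warnings.warn(f"set {name!r} has no overlap with expression genes; dropped")
            continue
        if mask.all():
            warnings.warn(f"set {name!r} covers all genes; dropped")
            continue
        kept[name] = mask
    if not kept:
        raise ValueError("every gene set was dropped (no overlap)")

    n = len(genes)
    out = np.empty((len(kept), values.shape[1]))
    for s in range(values.shape[1]):
        col = values[:, s]
        ranks = sps.rankdata(col)
        order = np.argsort(-col, kind="mergesort")
        ranks_o = ranks[order] ** params.alpha
        for i, mask in enumerate(kept.values()):
            member_o = mask[order]
            rw = np.where(member_o, ranks_o, 0.0)
            p_in = np.cumsum(rw) / rw.sum()
            p_out = np.cumsum(~member_o) / (n - member_o.sum())
            out[i, s] = np.sum(p_in - p_out)
    scores = pd.DataFrame(out, index=list(kept), columns=expr.sample_ids)
    if params.normalize:
        span = float(out.max() - out.min())
        if span > 0:
            scores = scores / span
    return scores


def partition_high_low(
    values: pd.Series, fraction: float = 0.3
) -> tuple[list[str], list[str]]:
    """Split samples into the top and bottom ``floor(fraction*n)`` by value.

    Ties are broken by input order: the earlier sample wins a place in the
    high group, the later sample a place in the low group.
    """
    n = len(values)
    m = int(np.floor(fraction * n))
    if m < 1:
        raise ValueError(f"floor({fraction} * {n}) = 0 samples per side")
    v = values.to_numpy(dtype=float)
    idx = np.arange(n)
    if np.unique(v).size == 1:
        warnings.warn("all values equal; partition falls back to input order")
    high_order = np.lexsort((idx, -v))
    low_order = np.lexsort((-idx, v))
    ids = np.asarray(values.index, dtype=object)
    return list(ids[high_order[:m]]), list(ids[low_order[:m]])


def _running_es(t_ranked: np.ndarray, member_ranked: np.ndarray, weight_exponent: float = 1.0) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score (signed max deviation)."""
    n = t_ranked.size
    n_in = int(member_ranked.sum())
    w = np.where(member_ranked, np.abs(t_ranked) ** weight_exponent, 0.0)
    total = w.sum()
    if total == 0:
        return 0.0
    p_hit = np.cumsum(w) / total
    p_miss = np.cumsum(~member_ranked) / (n - n_in)
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


@dataclass
class GseaResult:
    table: pd.DataFrame  # per set: es, nes, p, q
    n_permutations: int
    seed: int


def gsea_two_group(
    expr: ExpressionMatrix,
    group_high: list[str],
    group_low: list[str],
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
) -> GseaResult:
    """Two-group GSEA: moderated-t gene ranking, weighted-KS ES, permutation
    NES/p (sample-label permutations), BH q across sets."""
    if len(group_high) < 3 or len(group_low) < 3:
        raise ValueError("each group needs >= 3 samples")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives coarse permutation p-values")

    cols = list(group_high) + list(group_low)
    sub = expr.values[cols]
    labels = np.array(["high"] * len(group_high) + ["low"] * len(group_low))

    def ranked_t(lab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        fit = moderated_t_two_group(sub, lab, group="high", reference="low")
        t = fit.table["t"].to_numpy()
        if np.allclose(t, t[0]):
            raise ValueError("degenerate ranking: all gene statistics equal")
        order = np.argsort(-t, kind="mergesort")
        return t[order], order

    t_obs, order_obs = ranked_t(labels)
    genes = np.asarray(expr.feature_ids, dtype=object)
    masks = {name: np.isin(genes, members) for name, members in sets.items()}
    es_obs = {
        name: _running_es(t_obs, mask[order_obs]) for name, mask in masks.items()
    }

    rng = np.random.default_rng(seed)
    es_perm = {name: [] for name in masks}
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        try:
            t_p, order_p = ranked_t(perm)
        except ValueError:
            continue
        for name, mask in masks.items():
            es_perm[name].append(_running_es(t_p, mask[order_p]))

    rows = []
    for name, es in es_obs.items():
        perms = np.asarray(es_perm[name])
        same_sign = perms[np.sign(perms) == np.sign(es)] if es != 0 else perms
        if same_sign.size:
            nes = es / np.mean(np.abs(same_sign))
            p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + same_sign.size)
        else:
            nes, p = np.nan, 1.0 / (n_perm + 1.0)
        rows.append({"set": name, "es": es, "nes": nes, "p": p})
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = benjamini_hochberg(table["p"].to_numpy())
    return GseaResult(table=table, n_permutations=n_perm, seed=seed)


def score_trait_correlation(
    feature_values: pd.Series,
    scores: pd.DataFrame,
    method: str = "spearman",
) -> pd.DataFrame:
    """Per-set correlation of a per-sample feature with enrichment scores.

    Spearman rho (default) or Pearson r with a t-approximation p and BH q.
    """
    common = [s for s in scores.columns if s in feature_values.index]
    if len(common) < 4:
        raise ValueError("need >= 4 paired observations")
    x = feature_values[common].to_numpy(dtype=float)
    if np.unique(x).size == 1:
        raise ValueError("constant feature vector; correlation undefined")
    rows = []
    for name in scores.index:
        y = scores.loc[name, common].to_numpy(dtype=float)
        if method == "spearman":
            rho, p = sps.spearmanr(x, y)
        elif method == "pearson":
            rho, p = sps.pearsonr(x, y)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"set": name, "rho": float(rho), "p": float(p)})
    table = pd.DataFrame(rows).set_index("set")
    table["q"] = benjamini_hochberg(table["p"].to_numpy())
    return table
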