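"""Score-vs-transcriptome correlation, pre-ranked GSEA over hallmark-style
gene sets, and immune checkpoint / infiltration association.

The GSEA enrichment score is the maximum-deviation weighted
Kolmogorov-Smirnov running-sum statistic over a list of genes ranked by
their Spearman correlation with the family score, with weights |scc|^p
(p = 1 by default). The permutation null draws random gene-label sets of
the same size; NES divides the ES by the mean |null ES| of matching sign,
and the permutation p-value uses the matching-sign tail with +1 smoothing,
so p >= 1/(n_perm + 1) always.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_adjust, ranksum_test, spearman_test
from .core_io import ExpressionMatrix, GeneSet
from .family_score import ScoreTable

logger = logging.getLogger(__name__)

MIN_SET_GENES = 5
MIN_PERMUTATIONS = 100


@dataclass(frozen=True)
class CorrelationRecord:
    feature: str
    category: str
    scc: float
    p_value: float
    padj: float


@dataclass(frozen=True)
class GseaRecord:
    set_name: str
    es: float
    nes: float
    p_value: float
    padj: float
    direction: int
    n_genes: int


@dataclass(frozen=True)
class GroupComparison:
    feature: str
    median_high: float
    median_low: float
    statistic: float
    p_value: float
    padj: float


def rank_genes_by_score_correlation(
    scores: ScoreTable | pd.Series, matrix: ExpressionMatrix
) -> pd.DataFrame:
    """Spearman correlation of every gene's expression with the score.

    Samples are aligned by id; genes are returned sorted by SCC descending,
    ties broken by gene id so the ordering is deterministic under any
    permutation of the input sample order.
    """
    s = scores.scores if isinstance(scores, ScoreTable) else pd.Series(scores)
    shared = [c for c in matrix.values.columns if c in s.index]
    if len(shared) < 3:
        raise ValueError("need >= 3 samples shared between scores and matrix")
    sv = s.loc[shared].to_numpy(dtype=float)
    from scipy import stats as sps

    expr = matrix.values[shared].to_numpy(dtype=float)
    # vectorized Spearman: rank rows and the score vector, then Pearson
    r_expr = sps.rankdata(expr, axis=1)
    r_s = sps.rankdata(sv)
    r_expr_c = r_expr - r_expr.mean(axis=1, keepdims=True)
    r_s_c = r_s - r_s.mean()
    denom = np.sqrt((r_expr_c ** 2).sum(axis=1) * (r_s_c ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        scc = np.where(denom > 0, (r_expr_c @ r_s_c) / denom, np.nan)
    out = pd.DataFrame({"gene": matrix.values.index, "scc": scc}).dropna()
    out = out.sort_values(["scc", "gene"], ascending=[False, True],
                          kind="stable").reset_index(drop=True)
    return out


def _running_es(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Maximum-deviation weighted KS statistic over one ranked list."""
    w = np.where(in_set, weights, 0.0)
    w_total = w.sum()
    n_out = int((~in_set).sum())
    if w_total == 0 or n_out == 0:
        return 0.0
    step = np.where(in_set, w / w_total, -1.0 / n_out)
    running = np.cumsum(step)
    i = int(np.argmax(np.abs(running)))
    return float(running[i])


def preranked_gsea(
    ranked: pd.DataFrame,
    gene_sets: list[GeneSet],
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
) -> list[GseaRecord]:
    """Pre-ranked GSEA of gene sets against a (gene, scc) ranked list.

    ``ranked`` is the output of :func:`rank_genes_by_score_correlation`.
    Sets intersecting the ranked universe in fewer than 5 genes are skipped
    with a log entry. The null permutes gene labels (random same-size sets).
    """
    if n_perm < MIN_PERMUTATIONS:
        raise ValueError(f"n_perm must be >= {MIN_PERMUTATIONS} for a stable null")
    genes = ranked["gene"].to_numpy()
    weights = np.abs(ranked["scc"].to_numpy(dtype=float)) ** weight_p
    n = genes.size
    index_of = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)
    records = []
    for gs in gene_sets:
        idx = np.array(sorted(index_of[g] for g in gs.genes if g in index_of), dtype=int)
        if idx.size < MIN_SET_GENES:
            logger.info("gene set %s: %d genes in universe (< %d), skipped",
                        gs.name, idx.size, MIN_SET_GENES)
            continue
        in_set = np.zeros(n, dtype=bool)
        in_set[idx] = True
        es = _running_es(in_set, weights)
        null = np.empty(n_perm)
        size = idx.size
        for b in range(n_perm):
            perm = rng.choice(n, size=size, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[perm] = True
            null[b] = _running_es(mask, weights)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if same_sign.size == 0:
            nes = float("nan")
            p = 1.0 / (n_perm + 1)
        else:
            nes = es / np.mean(np.abs(same_sign))
            p = (1 + int(np.sum(np.abs(same_sign) >= abs(es)))) / (same_sign.size + 1)
        records.append(GseaRecord(gs.name, es, float(nes), float(p),
                                  float("nan"), int(np.sign(es)), size))
    padj = bh_adjust([r.p_value for r in records])
    return [
        GseaRecord(r.set_name, r.es, r.nes, r.p_value, float(q), r.direction, r.n_genes)
        for r, q in zip(records, padj)
    ]


def correlate_score_with_features(
    scores: ScoreTable | pd.Series,
    features: pd.DataFrame,
    category_map: pd.Series | dict | None = None,
) -> list[CorrelationRecord]:
    """Spearman correlation of the score with each immune feature.

    ``features`` is sample x feature; BH adjustment runs across the panel.
    Zero-variance features yield an NA record (logged) and do not join the
    BH family.
    """
    s = scores.scores if isinstance(scores, ScoreTable) else pd.Series(scores)
    shared = features.index.intersection(s.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 samples shared between scores and features")
    cat = dict(category_map) if category_map is not None else {}
    sv = s.loc[shared].to_numpy(dtype=float)
    tested, skipped = [], []
    for feature in features.columns:
        x = features.loc[shared, feature].to_numpy(dtype=float)
        scc, p = spearman_test(sv, x)
        if np.isnan(scc):
            logger.warning("feature %s has zero variance; reported as NA", feature)
            skipped.append(feature)
            continue
        tested.append((feature, scc, p))
    padj = bh_adjust([t[2] for t in tested])
    records = [
        CorrelationRecord(f, str(cat.get(f, "")), scc, p, float(q))
        for (f, scc, p), q in zip(tested, padj)
    ]
    records.extend(
        CorrelationRecord(f, str(cat.get(f, "")), float("nan"), float("nan"),
                          float("nan"))
        for f in skipped
    )
    return records


def compare_feature_groups(
    features: pd.DataFrame, groups: pd.Series
) -> list[GroupComparison]:
    """High-vs-low Wilcoxon rank-sum per immune feature, BH across the panel."""
    groups = pd.Series(groups)
    shared = features.index.intersection(groups.index)
    g = groups.loc[shared]
    high = shared[(g == "high").to_numpy()]
    low = shared[(g == "low").to_numpy()]
    if len(high) == 0 or len(low) == 0:
        raise ValueError("both high and low groups must be non-empty")
    rows = []
    for feature in features.columns:
        a = features.loc[high, feature].to_numpy(dtype=float)
        b = features.loc[low, feature].to_numpy(dtype=float)
        stat, p = ranksum_test(a, b)
        rows.append((feature, float(np.median(a)), float(np.median(b)), stat, p))
    padj = bh_adjust([r[4] for r in rows])
    return [
        GroupComparison(f, mh, ml, stat, p, float(q))
        for (f, mh, ml, stat, p), q in zip(rows, padj)
    ]
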