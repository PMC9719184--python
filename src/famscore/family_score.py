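"""Single-sample gene-set enrichment "family score" (ssGSEA).

For one sample the N genes are replaced by their expression ranks
(highest expression = rank N, average ranks for ties) and walked from the
highest rank to the lowest. At step i the weighted in-set ECDF is

    P_G^w(i) = sum_{set genes among first i} r_j^alpha
               / sum_{all set genes} r_j^alpha

and the out-of-set ECDF is P_NG(i) = (# non-set genes among first i) /
(N - N_G). The enrichment score is the sum (a discrete integral) of their
difference over all N steps:

    ES(G, S) = sum_{i=1..N} [P_G^w(i) - P_NG(i)]

with alpha = 1/4 by default, a modest rank weight. The raw ES is reported
by default; an optional cohort-level range normalization (dividing every
score by max - min across samples) is available for compatibility with
GSVA-style pipelines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25


@dataclass
class ScoreTable:
    """Per-sample enrichment scores, optionally dichotomized into groups."""

    scores: pd.Series          # index: sample id, values: ES
    alpha: float
    normalized: bool
    groups: pd.Series | None = None   # "high" / "low" after dichotomization
    meta: dict | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.scores.index)


def ssgsea_es(
    expression: pd.Series | np.ndarray,
    gene_set: GeneSet | frozenset | set,
    alpha: float = DEFAULT_ALPHA,
) -> float:
    """Enrichment score of one gene set in one sample.

    ``expression`` maps gene id -> expression value (a pandas Series). The
    set must intersect the expressed genes and must not cover the whole
    universe (the out-of-set ECDF is undefined otherwise). Ties receive
    average ranks; the score depends on the expression values only through
    their ranks.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if not isinstance(expression, pd.Series):
        raise TypeError("expression must be a pandas Series indexed by gene")
    genes = set(gene_set.genes) if isinstance(gene_set, GeneSet) else set(gene_set)
    values = expression.to_numpy(dtype=float)
    N = values.size
    if N < 2:
        raise ValueError("need at least 2 genes")
    in_set = expression.index.isin(genes)
    N_G = int(in_set.sum())
    if N_G == 0:
        raise ValueError("gene set does not intersect the expressed genes")
    if N_G == N:
        raise ValueError("gene set covers the whole universe; out-of-set ECDF undefined")

    ranks = stats.rankdata(values, method="average")  # 1..N, highest expr = N
    # walk genes from highest rank to lowest; break rank ties by gene id so
    # the walk order is deterministic
    order = np.lexsort((expression.index.to_numpy(), -ranks))
    in_set_ord = in_set[order]
    r_ord = ranks[order]
    w = np.abs(r_ord) ** alpha
    w[~in_set_ord] = 0.0
    p_g = np.cumsum(w) / w.sum()
    p_ng = np.cumsum(~in_set_ord) / (N - N_G)
    return float(np.sum(p_g - p_ng))


def score_cohort(
    matrix: ExpressionMatrix,
    gene_set: GeneSet,
    alpha: float = DEFAULT_ALPHA,
    normalize: bool = False,
) -> ScoreTable:
    """Score every sample of a (preprocessed, log-scale) cohort matrix.

    Set genes absent from the matrix are dropped with a logged count. With
    ``normalize=True`` all scores are divided by (max - min) across the
    cohort (GSVA-compatible range normalization).
    """
    present = frozenset(g for g in gene_set.genes if g in matrix.values.index)
    n_missing = len(gene_set.genes) - len(present)
    if n_missing:
        logger.info("gene set %s: %d genes absent from the matrix, dropped",
                    gene_set.name, n_missing)
    if not present:
        raise ValueError(f"gene set {gene_set.name!r}: no genes present in matrix")
    scores = {}
    for sample in matrix.values.columns:
        try:
            scores[sample] = ssgsea_es(matrix.values[sample], present, alpha=alpha)
        except ValueError as exc:
            raise ValueError(f"sample {sample!r}: {exc}") from exc
    series = pd.Series(scores, name="es")
    if normalize:
        span = series.max() - series.min()
        if span == 0:
            raise ValueError("cannot range-normalize constant scores")
        series = series / span
    return ScoreTable(scores=series, alpha=alpha, normalized=normalize,
                      meta={"gene_set": gene_set.name, "n_set_genes": len(present)})


def dichotomize_scores(
    scores: ScoreTable,
    method: str = "median",
    clinical: pd.DataFrame | None = None,
    minprop: float = 0.1,
) -> ScoreTable:
    """Assign high/low group labels by median split or survival cutpoint.

    ``median``: samples with score strictly above the median are "high";
    ties at the median go to the low group. ``survival_cutpoint``: the
    threshold maximizing the standardized log-rank statistic (requires a
    clinical table; delegates to
    :func:`famscore.clinical_endpoints.optimal_cutpoint`).
    """
    s = scores.scores
    if s.nunique() < 2:
        raise ValueError("constant scores: no valid split")
    if method == "median":
        threshold = float(s.median())
        groups = pd.Series(np.where(s > threshold, "high", "low"), index=s.index)
        meta = {"method": "median", "threshold": threshold}
    elif method == "survival_cutpoint":
        if clinical is None:
            raise ValueError("survival_cutpoint requires a clinical table")
        from .clinical_endpoints import optimal_cutpoint

        shared = s.index.intersection(clinical.index)
        cut = optimal_cutpoint(
            clinical.loc[shared, "time"].to_numpy(dtype=float),
            clinical.loc[shared, "event"].to_numpy(dtype=int),
            s.loc[shared].to_numpy(dtype=float),
            minprop=minprop,
        )
        threshold = cut.cutpoint
        groups = pd.Series(np.where(s > threshold, "high", "low"), index=s.index)
        groups[~s.index.isin(shared)] = "NA"
        meta = {"method": "survival_cutpoint", "threshold": threshold}
    else:
        raise ValueError(f"unknown dichotomization method {method!r}")
    out_meta = dict(scores.meta or {})
    out_meta.update(meta)
    return ScoreTable(scores=s, alpha=scores.alpha, normalized=scores.normalized,
                      groups=groups, meta=out_meta)
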