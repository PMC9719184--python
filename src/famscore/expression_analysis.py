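"""Expression preprocessing, tumor/normal differential expression and
sub-class co-expression structure.

Preprocessing follows three fixed steps: technical replicate columns from
the same (patient, status) are averaged on the FPKM scale, genes with
FPKM = 0 in more than 70% of the remaining samples are removed (strictly
more), and values become log2(FPKM + 1). Differential expression runs a
two-sided Wilcoxon rank-sum per family gene in every cancer with at least
five normal samples, BH-adjusted within cancer; a gene is differential at
FDR < 0.05. Co-expression compares the Spearman coefficients of
within-sub-class family pairs against between-sub-class pairs and reports
strong pairs (SCC > 0.75, BH-adjusted p < 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, ranksum_test, spearman_test
from .core_io import ExpressionMatrix, FamilyAnnotation

logger = logging.getLogger(__name__)

ZERO_FRACTION_LIMIT = 0.70   # genes with FPKM = 0 in > 70% of samples removed
DE_FDR = 0.05
STRONG_SCC = 0.75
STRONG_PADJ = 0.05


@dataclass(frozen=True)
class DEResult:
    gene: str
    cancer: str
    log2_fc: float      # tumor mean minus normal mean, log2 scale
    p_value: float
    fdr: float
    differential: bool


@dataclass
class CoexpressionSummary:
    cancer: str
    within_scc: list[float]
    between_scc: list[float]
    comparison_p: float
    strong_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)


def preprocess_expression(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average replicates, drop near-silent genes, move to log2(FPKM + 1).

    Idempotent: a matrix already flagged ``log_scale`` is returned unchanged
    (averaging and filtering have already been applied).
    """
    if matrix.log_scale:
        return matrix
    meta = matrix.sample_meta.loc[matrix.values.columns]
    # average technical replicates within (patient, status) on the FPKM scale
    groups = meta.groupby(["patient", "status", "cancer"], sort=False).groups
    cols, col_meta = {}, []
    for _key, samples in groups.items():
        samples = list(samples)
        name = samples[0]
        cols[name] = matrix.values[samples].mean(axis=1)
        row = meta.loc[name].copy()
        col_meta.append(row.rename(name))
    values = pd.DataFrame(cols)
    new_meta = pd.DataFrame(col_meta)
    zero_frac = (values == 0).mean(axis=1)
    keep = zero_frac <= ZERO_FRACTION_LIMIT
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("removed %d genes with FPKM = 0 in > %.0f%% of samples",
                    n_removed, 100 * ZERO_FRACTION_LIMIT)
    values = values.loc[keep]
    if values.empty:
        raise ValueError("no genes left after expression filtering")
    values = np.log2(values + 1.0)
    meta_out = dict(matrix.meta)
    meta_out.update(pseudocount=1.0, log_base=2,
                    n_genes_removed=n_removed)
    return ExpressionMatrix(values=values, sample_meta=new_meta,
                            log_scale=True, meta=meta_out)


def differential_expression(
    matrix: ExpressionMatrix,
    family: FamilyAnnotation,
    min_normals: int = 5,
) -> list[DEResult]:
    """Tumor vs normal Wilcoxon rank-sum per family gene, per cancer.

    Cancers with fewer than ``min_normals`` normal samples are skipped with
    a logged notice. BH adjustment runs across family genes within each
    cancer; log2 fold-change is the difference of group means on the log
    scale.
    """
    if not matrix.log_scale:
        raise ValueError("differential_expression requires a preprocessed (log-scale) matrix")
    meta = matrix.sample_meta.loc[matrix.values.columns]
    fam_genes = [g for g in family.genes if g in matrix.values.index]
    results: list[DEResult] = []
    any_cancer = False
    for cancer, cmeta in meta.groupby("cancer", sort=True):
        tumors = cmeta.index[cmeta["status"] == "tumor"]
        normals = cmeta.index[cmeta["status"] == "normal"]
        if len(normals) < min_normals:
            logger.info("cancer %s skipped: %d normal samples (< %d)",
                        cancer, len(normals), min_normals)
            continue
        any_cancer = True
        rows = []
        for gene in fam_genes:
            t = matrix.values.loc[gene, tumors].to_numpy(dtype=float)
            n = matrix.values.loc[gene, normals].to_numpy(dtype=float)
            if np.ptp(np.concatenate([t, n])) == 0:
                p = 1.0
            else:
                _, p = ranksum_test(t, n)
            rows.append((gene, float(t.mean() - n.mean()), p))
        fdr = bh_adjust([r[2] for r in rows])
        for (gene, lfc, p), q in zip(rows, fdr):
            results.append(DEResult(gene, str(cancer), lfc, p, float(q), q < DE_FDR))
    if not any_cancer:
        raise ValueError(f"no cancer has >= {min_normals} normal samples")
    return results


def subclass_coexpression(
    matrix: ExpressionMatrix,
    family: FamilyAnnotation,
    cancer: str,
    adjusted: bool = True,
) -> CoexpressionSummary:
    """Within- vs between-sub-class co-expression of family genes.

    All pairwise Spearman coefficients over tumor samples of one cancer are
    partitioned by whether the pair shares a sub-class; the two partitions
    are compared by a two-sided Wilcoxon rank-sum. Strong pairs satisfy
    SCC > 0.75 and (BH-adjusted, or raw with ``adjusted=False``) p < 0.05.
    """
    meta = matrix.sample_meta.loc[matrix.values.columns]
    tumors = meta.index[(meta["cancer"] == cancer) & (meta["status"] == "tumor")]
    if len(tumors) < 3:
        raise ValueError(f"cancer {cancer!r}: need >= 3 tumor samples")
    fam_genes = [g for g in family.genes if g in matrix.values.index]
    subclass = {g: family[g].subclass for g in fam_genes}
    if len(set(subclass.values())) < 2 or len(fam_genes) < 2:
        raise ValueError("need >= 2 family genes in >= 2 sub-classes")
    expr = matrix.values.loc[fam_genes, tumors].to_numpy(dtype=float)
    n = len(tumors)
    rows = []
    for (i, g1), (j, g2) in combinations(enumerate(fam_genes), 2):
        scc, p = spearman_test(expr[i], expr[j])
        kind = "within_subclass" if subclass[g1] == subclass[g2] else "between_subclass"
        rows.append((g1, g2, kind, scc, p))
    pairs = pd.DataFrame(rows, columns=["gene1", "gene2", "pair_class", "scc", "p_value"])
    pairs["padj"] = bh_adjust(pairs["p_value"].fillna(1.0).to_numpy())
    within = pairs.loc[pairs["pair_class"] == "within_subclass", "scc"].dropna()
    between = pairs.loc[pairs["pair_class"] == "between_subclass", "scc"].dropna()
    if len(within) and len(between):
        _, comparison_p = ranksum_test(within, between)
    else:
        comparison_p = float("nan")
    crit = pairs["padj"] if adjusted else pairs["p_value"]
    strong = pairs.loc[(pairs["scc"] > STRONG_SCC) & (crit < STRONG_PADJ)].reset_index(drop=True)
    return CoexpressionSummary(
        cancer=cancer,
        within_scc=within.tolist(),
        between_scc=between.tolist(),
        comparison_p=float(comparison_p),
        strong_pairs=strong,
    )
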