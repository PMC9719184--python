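"""Shared fixtures: tiny annotations, synthetic cohorts, independent oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from famscore.core_io import (
    DomainRecord,
    ExpressionMatrix,
    FamilyAnnotation,
    FamilyGene,
    load_bundled_family_annotation,
)


@pytest.fixture(scope="session")
def bundled_annotation() -> FamilyAnnotation:
    return load_bundled_family_annotation()


@pytest.fixture
def tiny_annotation() -> FamilyAnnotation:
    """Two sub-classes, three genes, overlapping and disjoint domains."""
    return FamilyAnnotation([
        FamilyGene("GA", "S1", 500, (
            DomainRecord("RING", 10, 60), DomainRecord("SPRY", 301, 420),
        )),
        FamilyGene("GB", "S1", 400, (DomainRecord("RING", 5, 50),)),
        FamilyGene("GC", "S2", 300, (DomainRecord("CC", 100, 180),)),
    ])


@pytest.fixture
def hotspot_annotation() -> FamilyAnnotation:
    """One gene whose single domain covers exactly 20% of the protein."""
    return FamilyAnnotation([
        FamilyGene("HOTG", "S1", 500, (DomainRecord("HOT", 101, 200),)),
    ])


def make_expression(n_genes=20, n_samples=10, seed=0, family_genes=(),
                    log_scale=False) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    genes = list(family_genes) + [f"G{i:03d}" for i in range(n_genes - len(family_genes))]
    samples = [f"S{i:03d}" for i in range(n_samples)]
    values = pd.DataFrame(
        rng.lognormal(1.0, 1.0, size=(len(genes), n_samples)),
        index=genes, columns=samples,
    )
    if log_scale:
        values = np.log2(values + 1)
    status = ["tumor" if i < n_samples // 2 else "normal" for i in range(n_samples)]
    meta = pd.DataFrame(
        {"patient": samples, "cancer": "CAN", "status": status},
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionMatrix(values=values, sample_meta=meta, log_scale=log_scale)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately written as explicit loops / exact
# arithmetic, sharing no code with the implementation paths they check)
# ---------------------------------------------------------------------------


def ssgsea_oracle(expr: pd.Series, genes, alpha: float) -> float:
    """Brute-force ssGSEA: materialize both ECDF vectors explicitly."""
    genes = set(genes)
    ranks = pd.Series(sps.rankdata(expr.to_numpy()), index=expr.index)
    order = sorted(expr.index, key=lambda g: (-ranks[g], g))
    set_total = sum(abs(ranks[g]) ** alpha for g in order if g in genes)
    n_out = sum(1 for g in order if g not in genes)
    p_g, p_ng = [], []
    g_acc = ng_acc = 0.0
    for g in order:
        if g in genes:
            g_acc += abs(ranks[g]) ** alpha / set_total
        else:
            ng_acc += 1.0 / n_out
        p_g.append(g_acc)
        p_ng.append(ng_acc)
    return sum(a - b for a, b in zip(p_g, p_ng))


def binomial_tail_oracle(k: int, N: int, L_domain: int, L_g: int) -> float:
    """Exact rational term-by-term summation of P(X >= k)."""
    from fractions import Fraction
    from math import comb

    p = Fraction(L_domain, L_g)
    tail = sum(comb(N, x) * p ** x * (1 - p) ** (N - x) for x in range(k, N + 1))
    return float(tail)


def gsea_es_oracle(in_set, weights) -> float:
    """Brute-force running-sum maximum-deviation statistic."""
    w_total = sum(w for w, f in zip(weights, in_set) if f)
    n_out = sum(1 for f in in_set if not f)
    running, best = 0.0, 0.0
    for w, f in zip(weights, in_set):
        running += (w / w_total) if f else (-1.0 / n_out)
        if abs(running) > abs(best):
            best = running
    return best


def fisher_2x2_oracle(table) -> float:
    """Full hypergeometric enumeration of the two-sided 2x2 Fisher p."""
    from math import comb

    (a, b), (c, d) = table
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, r1)

    def pr(x: int) -> float:
        return comb(c1, x) * comb(n - c1, r1 - x) / denom

    p_obs = pr(a)
    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    return sum(pr(x) for x in range(lo, hi + 1) if pr(x) <= p_obs * (1 + 1e-9))
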