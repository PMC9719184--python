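"""Domain-aware somatic-mutation statistics for a gene family.

Four statistics:

* sub-family mutation frequency
  ``Mut(i, j) = (m(i,j)/M(j)) * (n(i,j)/N(i))`` where ``m`` counts mutated
  samples of sub-class *i* in cancer *j*, ``M`` all mutated samples in *j*,
  ``n`` the sub-class members mutated in *j* and ``N`` the sub-class size;
* per-domain-name mutation frequency ``f(a, j) = d(a,j)/N(j)`` with ``d``
  the distinct mutated samples hitting any instance of domain name *a*;
* a binomial domain-enrichment test: with ``N`` mutation events in a gene
  and domain coverage ``p_ri = L_domain / L_g``, the in-domain count ``k``
  is Binomial(N, p_ri) under the null, the p-value is the upper tail
  ``P(X >= k)`` and the enrichment ratio is ``E = k / (N * p_ri)``.
  Domains with ``padj < 0.05``, ``E > 2`` and ``k >= 3`` are significant
  (strict inequalities; domains with fewer than 3 events are not tested and
  are excluded from the BH family);
* in-domain vs out-of-domain comparison of per-mutation functional impact
  scores (two-sided Wilcoxon rank-sum per score type).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, ranksum_test
from .core_io import FamilyAnnotation, impact_score_columns

logger = logging.getLogger(__name__)

PAN_CANCER = "pan-cancer"

SIGNIFICANCE_PADJ = 0.05
SIGNIFICANCE_E = 2.0
MIN_DOMAIN_MUTATIONS = 3


@dataclass(frozen=True)
class SubtypeMutationFrequency:
    subtype: str
    cancer: str
    m: int              # mutated samples of this subtype in the cancer
    M: int              # all mutated samples in the cancer
    n: int              # subtype members mutated in the cancer
    N_members: int      # subtype size
    mut_freq: float


@dataclass(frozen=True)
class DomainFrequency:
    domain: str
    cancer: str
    d: int              # distinct mutated samples hitting the domain name
    N_j: int            # mutated samples in the cancer
    f: float


@dataclass(frozen=True)
class EnrichmentResult:
    gene: str
    domain: str
    cancer: str         # PAN_CANCER for the pooled mode
    k: int              # mutation events inside the domain
    N: int              # mutation events in the gene
    p_ri: float         # L_domain / L_g
    p_value: float
    padj: float
    E: float
    significant: bool


@dataclass(frozen=True)
class ImpactComparison:
    score_name: str
    n_in: int
    n_out: int
    statistic: float
    p_value: float
    direction: int      # sign of (in-domain minus out-of-domain) location


def _mutated_samples(mutations: pd.DataFrame, cancer: str) -> pd.DataFrame:
    sub = mutations.loc[mutations["cancer"] == cancer]
    if sub["sample"].nunique() == 0:
        raise ValueError(f"no mutated samples in cancer {cancer!r}")
    return sub


def subtype_mutation_frequency(
    mutations: pd.DataFrame, annotation: FamilyAnnotation, cancer: str
) -> list[SubtypeMutationFrequency]:
    """Sub-family mutation frequency for every sub-class in one cancer.

    A sample counts as mutated for sub-class *i* if it carries at least one
    mutation in any member of *i*; ``M`` counts samples with at least one
    mutation in any gene of the table (family or not).
    """
    sub = _mutated_samples(mutations, cancer)
    M = sub["sample"].nunique()
    out = []
    for subclass in annotation.subclasses:
        members = set(annotation.members_of(subclass))
        hits = sub.loc[sub["gene"].isin(members)]
        m = hits["sample"].nunique()
        n = hits["gene"].nunique()
        freq = (m / M) * (n / len(members))
        out.append(
            SubtypeMutationFrequency(subclass, cancer, m, M, n, len(members), freq)
        )
    return out


def domain_mutation_frequency(
    mutations: pd.DataFrame, annotation: FamilyAnnotation, cancer: str
) -> list[DomainFrequency]:
    """Per-domain-name mutation frequency in one cancer.

    ``d`` counts distinct samples with >= 1 mutation inside any instance of
    the domain name, pooled across family genes.
    """
    sub = _mutated_samples(mutations, cancer)
    N_j = sub["sample"].nunique()
    hit_samples: dict[str, set] = {name: set() for name in annotation.domain_names()}
    fam = sub.loc[sub["gene"].isin(set(annotation.genes))]
    for row in fam.itertuples():
        gene = annotation.get(row.gene)
        for dom in gene.domains:
            if dom.contains(row.protein_pos):
                hit_samples[dom.name].add(row.sample)
    out = []
    for name, samples in hit_samples.items():
        if not samples:
            logger.warning("domain %s has no mutations in cancer %s", name, cancer)
        out.append(DomainFrequency(name, cancer, len(samples), N_j, len(samples) / N_j))
    return out


def domain_binomial_test(
    k: int, N: int, L_domain: int, L_g: int
) -> tuple[float, float]:
    """Binomial upper-tail test and enrichment ratio for one domain.

    Returns ``(p_value, E)`` with ``p_value = P(X >= k)`` for
    X ~ Binomial(N, L_domain/L_g), computed via the survival function (no
    catastrophic cancellation for tiny tails), and ``E = k/(N * L_domain/L_g)``.
    """
    if N <= 0:
        raise ValueError("binomial domain test undefined for N = 0")
    if not (0 <= k <= N):
        raise ValueError(f"need 0 <= k <= N, got k={k}, N={N}")
    if not (1 <= L_domain <= L_g):
        raise ValueError(f"need 1 <= L_domain <= L_g, got {L_domain}, {L_g}")
    p_ri = L_domain / L_g
    if k == 0:
        return 1.0, 0.0
    p_value = float(stats.binom.sf(k - 1, N, p_ri))
    E = k / (N * p_ri)
    return p_value, E


def prioritize_enriched_domains(
    mutations: pd.DataFrame,
    annotation: FamilyAnnotation,
    pooling: str = PAN_CANCER,
) -> list[EnrichmentResult]:
    """Binomial enrichment over every (gene, domain) with >= 3 mutation events.

    ``pooling`` is ``"pan-cancer"`` (default: all cancers combined per gene)
    or ``"per-cancer"``. BH adjustment runs over all tested pairs in this
    invocation; pairs with fewer than 3 in-domain events are excluded from
    testing and from the BH family.
    """
    if pooling not in (PAN_CANCER, "per-cancer"):
        raise ValueError(f"unknown pooling {pooling!r}")
    fam = mutations.loc[mutations["gene"].isin(set(annotation.genes))]
    units = (
        [(PAN_CANCER, fam)]
        if pooling == PAN_CANCER
        else list(fam.groupby("cancer", sort=True))
    )
    tested: list[tuple[str, str, str, int, int, float, float, float]] = []
    for cancer, table in units:
        for gene_id, gene_table in table.groupby("gene", sort=True):
            gene = annotation[gene_id]
            N = len(gene_table)
            pos = gene_table["protein_pos"].to_numpy()
            for dom in gene.domains:
                k = int(((pos >= dom.start) & (pos <= dom.end)).sum())
                if k < MIN_DOMAIN_MUTATIONS:
                    continue
                p_value, E = domain_binomial_test(k, N, dom.length, gene.protein_length)
                tested.append(
                    (gene_id, dom.name, str(cancer), k, N,
                     dom.length / gene.protein_length, p_value, E)
                )
    padj = bh_adjust([t[6] for t in tested])
    results = []
    for (gene_id, dom_name, cancer, k, N, p_ri, p_value, E), q in zip(tested, padj):
        significant = (q < SIGNIFICANCE_PADJ) and (E > SIGNIFICANCE_E) and (
            k >= MIN_DOMAIN_MUTATIONS
        )
        results.append(
            EnrichmentResult(gene_id, dom_name, cancer, k, N, p_ri,
                             p_value, float(q), E, significant)
        )
    return results


def compare_impact_scores(
    mutations: pd.DataFrame,
    annotation: FamilyAnnotation,
    damaging_orient_sift: bool = True,
) -> list[ImpactComparison]:
    """In-domain vs out-of-domain Wilcoxon rank-sum per impact-score type.

    SIFT scores (smaller = more damaging) are transformed to ``1 - SIFT``
    before comparison so that larger means more damaging for every score;
    pass ``damaging_orient_sift=False`` to compare raw values. Score types
    with an empty stratum are skipped with a warning.
    """
    fam = mutations.loc[mutations["gene"].isin(set(annotation.genes))].copy()
    in_domain = np.zeros(len(fam), dtype=bool)
    for i, row in enumerate(fam.itertuples()):
        gene = annotation[row.gene]
        in_domain[i] = any(d.contains(row.protein_pos) for d in gene.domains)
    out = []
    for score in impact_score_columns(fam):
        values = fam[score].to_numpy(dtype=float)
        if damaging_orient_sift and score.lower() == "sift":
            values = 1.0 - values
        ok = ~np.isnan(values)
        a = values[ok & in_domain]
        b = values[ok & ~in_domain]
        if a.size == 0 or b.size == 0:
            logger.warning("impact score %s: empty stratum, skipped", score)
            continue
        statistic, p_value = ranksum_test(a, b)
        direction = int(np.sign(np.median(a) - np.median(b)))
        out.append(ImpactComparison(score, a.size, b.size, statistic, p_value, direction))
    return out


def residue_mutation_tally(
    mutations: pd.DataFrame, annotation: FamilyAnnotation
) -> pd.DataFrame:
    """Per-residue mutation counts for lollipop-style plots.

    Returns one row per (gene, protein_pos, ref_aa, alt_aa) with the number
    of mutation events and of distinct samples carrying it.
    """
    fam = mutations.loc[mutations["gene"].isin(set(annotation.genes))]
    tally = (
        fam.groupby(["gene", "protein_pos", "ref_aa", "alt_aa"])
        .agg(n_events=("sample", "size"), n_samples=("sample", "nunique"))
        .reset_index()
        .sort_values(["gene", "protein_pos"], kind="stable")
        .reset_index(drop=True)
    )
    return tally
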