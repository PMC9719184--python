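"""Synthetic cohorts with planted, machine-readable ground truth.

Each generator emulates the statistical structure of one input class of the
pipeline — somatic mutation tables with optional domain hotspots, log-normal
FPKM matrices with sub-class co-expression blocks and planted tumor/normal
shifts, survival/response outcomes driven by a log-linear hazard and a
logistic link in the family score, and compositional immune features with
target rank correlations to the score — and returns a truth record stating
exactly what was planted.

Everything is deterministic given the config seed: each stage derives its
own child generator from ``(stage_id, seed)``, so rerunning any stage with
the same config reproduces its output byte for byte.
"""

from __future__ import annotations

import string
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core_io import ExpressionMatrix, FamilyAnnotation, ValidationError
from .family_score import ScoreTable

_STAGE_IDS = {"mutations": 1, "expression": 2, "clinical": 3, "immune": 4}

AA_LETTERS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _stage_rng(stage: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STAGE_IDS[stage], seed])


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class MutationSimConfig:
    #: mean mutation events per (sample, gene); Poisson counts
    per_gene_rate: float = 0.02
    #: planted hotspots: (gene, domain name, fold concentration theta >= 1)
    enriched: list = field(default_factory=list)
    #: upward shift of the latent damaging score for in-domain mutations
    impact_shift: float = 1.0


@dataclass
class ExpressionSimConfig:
    n_background_genes: int = 500
    #: log2-units shift added to family-gene means in tumor samples
    tumor_shift: float = 1.5
    #: equicorrelation of family genes within one sub-class, in [0, 1)
    subclass_correlation: float = 0.5
    noise_sd: float = 1.0
    tumor_fraction: float = 0.5
    #: mean and sd of per-gene baseline log2 expression
    baseline_mean: float = 3.0
    baseline_sd: float = 1.0


@dataclass
class SurvivalSimConfig:
    #: log hazard ratio per SD of the score (log 2 = HR 2 per SD)
    log_hazard_slope: float = float(np.log(2.0))
    censoring_fraction: float = 0.3
    baseline_hazard: float = 1.0 / 365.0


@dataclass
class ResponseSimConfig:
    logit_intercept: float = 0.0
    logit_slope: float = 1.0


@dataclass
class ImmuneSimConfig:
    #: feature name -> target Spearman correlation with the score, |scc| < 1
    target_scc: dict = field(default_factory=lambda: {
        "CD8_T_cells": 0.6, "NK_cells": 0.4, "B_cells": 0.2,
        "Macrophages_M2": -0.4, "Neutrophils": 0.0, "Other_cells": 0.0,
        "PDCD1": 0.5, "CD274": 0.3, "CTLA4": 0.0,
    })
    #: features forming the compositional cell-fraction block (sum to 1)
    fraction_features: list = field(default_factory=lambda: [
        "CD8_T_cells", "NK_cells", "B_cells", "Macrophages_M2",
        "Neutrophils", "Other_cells",
    ])


@dataclass
class SimulationConfig:
    seed: int
    n_cancers: int = 1
    samples_per_cancer: int = 120
    mutation: MutationSimConfig = field(default_factory=MutationSimConfig)
    expression: ExpressionSimConfig = field(default_factory=ExpressionSimConfig)
    survival: SurvivalSimConfig = field(default_factory=SurvivalSimConfig)
    response: ResponseSimConfig = field(default_factory=ResponseSimConfig)
    immune: ImmuneSimConfig = field(default_factory=ImmuneSimConfig)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("seed is mandatory (no wall-clock seeding)")
        if not 0 <= self.expression.subclass_correlation < 1:
            raise ValidationError("subclass_correlation must be in [0, 1)")
        if not 0 <= self.survival.censoring_fraction < 1:
            raise ValidationError("censoring_fraction must be in [0, 1)")
        for _, _, theta in self.mutation.enriched:
            if theta < 1:
                raise ValidationError("enrichment fold theta must be >= 1")
        for name, scc in self.immune.target_scc.items():
            if not -1 < scc < 1:
                raise ValidationError(f"target_scc[{name}] must be in (-1, 1)")

    @classmethod
    def from_dict(cls, data: Mapping) -> "SimulationConfig":
        data = dict(data)
        parts = {}
        for key, sub_cls in [("mutation", MutationSimConfig),
                             ("expression", ExpressionSimConfig),
                             ("survival", SurvivalSimConfig),
                             ("response", ResponseSimConfig),
                             ("immune", ImmuneSimConfig)]:
            sub = dict(data.pop(key, {}))
            _check_keys(sub, sub_cls, key)
            if key == "mutation" and "enriched" in sub:
                sub["enriched"] = [tuple(e) for e in sub["enriched"]]
            parts[key] = sub_cls(**sub)
        _check_keys(data, cls, "simulate")
        return cls(**data, **parts)

    def to_dict(self) -> dict:
        return asdict(self)


def _check_keys(data: Mapping, cls, where: str) -> None:
    allowed = set(cls.__dataclass_fields__) - {
        "mutation", "expression", "survival", "response", "immune"
    }
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(f"unknown config keys under {where!r}: {sorted(unknown)}")


def load_simulation_config(path: str | Path) -> SimulationConfig:
    with open(path, encoding="utf-8") as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))


def _cancer_names(n: int) -> list[str]:
    return [f"SIM{string.ascii_uppercase[i % 26]}{i // 26}" if n > 26
            else f"SIM{string.ascii_uppercase[i]}" for i in range(n)]


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationTruth:
    per_gene_rate: float
    impact_shift: float
    enriched: tuple   # of (gene, domain, theta)

    def to_dict(self) -> dict:
        return {"per_gene_rate": self.per_gene_rate,
                "impact_shift": self.impact_shift,
                "enriched": [list(e) for e in self.enriched]}


def simulate_mutations(
    annotation: FamilyAnnotation, config: SimulationConfig
) -> tuple[pd.DataFrame, MutationTruth]:
    """Somatic mutation table with optional planted domain hotspots.

    Per (sample, gene) the event count is Poisson with the configured mean.
    Positions are uniform over the protein except in planted genes, where
    the density inside the named domain is multiplied by theta and
    renormalized: P(in domain) = theta*f / (theta*f + 1 - f) for coverage
    f = L_domain / L_g. Impact scores derive from a latent damaging value
    that is stochastically larger in-domain by ``impact_shift``.
    """
    if len(annotation) == 0:
        raise ValidationError("annotation is empty")
    cfg = config.mutation
    hotspot: dict[str, tuple] = {}
    for gene, domain, theta in cfg.enriched:
        fam = annotation.get(gene)
        if fam is None:
            raise ValidationError(f"enriched references unknown gene {gene!r}")
        doms = [d for d in fam.domains if d.name == domain]
        if not doms:
            raise ValidationError(f"enriched references unknown domain {gene}/{domain}")
        hotspot[gene] = (doms[0], float(theta))
    rng = _stage_rng("mutations", config.seed)
    rows = []
    for cancer in _cancer_names(config.n_cancers):
        for s in range(config.samples_per_cancer):
            sample = f"{cancer}-S{s:04d}"
            for fam in annotation:
                count = rng.poisson(cfg.per_gene_rate)
                for _ in range(count):
                    pos = _draw_position(rng, fam, hotspot.get(fam.gene))
                    rows.append((sample, cancer, fam.gene, pos))
    df = pd.DataFrame(rows, columns=["sample", "cancer", "gene", "protein_pos"])
    n = len(df)
    ref = rng.choice(AA_LETTERS, size=n)
    alt = rng.choice(AA_LETTERS, size=n)
    clash = ref == alt
    alt[clash] = AA_LETTERS[(np.searchsorted(AA_LETTERS, alt[clash]) + 1) % len(AA_LETTERS)]
    in_dom = np.array([
        any(d.contains(p) for d in annotation[g].domains)
        for g, p in zip(df["gene"], df["protein_pos"])
    ], dtype=bool) if n else np.zeros(0, dtype=bool)
    damaging = rng.normal(0.0, 1.0, size=n) + cfg.impact_shift * in_dom
    df["ref_aa"], df["alt_aa"] = ref, alt
    df["sift"] = 1.0 / (1.0 + np.exp(damaging))        # low = damaging
    df["polyphen"] = 1.0 / (1.0 + np.exp(-damaging))   # high = damaging
    df["cadd"] = 10.0 + 5.0 * damaging
    df["conservation"] = damaging
    truth = MutationTruth(cfg.per_gene_rate, cfg.impact_shift, tuple(cfg.enriched))
    return df, truth


def _draw_position(rng, fam, hotspot) -> int:
    L = fam.protein_length
    if hotspot is None:
        return int(rng.integers(1, L + 1))
    dom, theta = hotspot
    f = dom.length / L
    p_in = theta * f / (theta * f + (1 - f))
    if rng.random() < p_in:
        return int(rng.integers(dom.start, dom.end + 1))
    # uniform over the out-of-domain positions
    pos = int(rng.integers(1, L - dom.length + 1))
    if pos >= dom.start:
        pos += dom.length
    return pos


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionTruth:
    tumor_shift: float
    subclass_correlation: float
    family_genes: tuple
    shifted_genes: tuple

    def to_dict(self) -> dict:
        return {"tumor_shift": self.tumor_shift,
                "subclass_correlation": self.subclass_correlation,
                "family_genes": list(self.family_genes),
                "shifted_genes": list(self.shifted_genes)}


def simulate_expression(
    annotation: FamilyAnnotation, config: SimulationConfig
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """FPKM matrix with sub-class co-expression blocks and tumor shifts.

    Log2-scale values are multivariate normal: family genes in the same
    sub-class share an equicorrelation rho, all other pairs are
    uncorrelated; family genes gain ``tumor_shift`` log2 units in tumor
    samples. The matrix is exported on the FPKM scale via 2^x - 1,
    truncated at 0.
    """
    cfg = config.expression
    fam_genes = annotation.genes
    if cfg.n_background_genes < len(fam_genes):
        raise ValidationError("n_background_genes must be >= family size")
    rho = cfg.subclass_correlation
    rng = _stage_rng("expression", config.seed)
    bg_genes = [f"BG{i:05d}" for i in range(cfg.n_background_genes)]
    genes = fam_genes + bg_genes
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=len(genes))

    columns, meta_rows = [], []
    values = []
    subclasses = annotation.subclasses
    sub_of = {g: annotation[g].subclass for g in fam_genes}
    for cancer in _cancer_names(config.n_cancers):
        n = config.samples_per_cancer
        n_tumor = int(round(cfg.tumor_fraction * n))
        status = np.array(["tumor"] * n_tumor + ["normal"] * (n - n_tumor))
        shared = rng.normal(size=(len(subclasses), n))   # one latent per sub-class
        shared_of = {s: shared[i] for i, s in enumerate(subclasses)}
        block = np.empty((len(genes), n))
        for gi, g in enumerate(genes):
            eps = rng.normal(size=n)
            if g in sub_of and rho > 0:
                z = np.sqrt(rho) * shared_of[sub_of[g]] + np.sqrt(1 - rho) * eps
            else:
                z = eps
            x = baseline[gi] + cfg.noise_sd * z
            if g in sub_of:
                x = x + cfg.tumor_shift * (status == "tumor")
            block[gi] = x
        values.append(block)
        for s in range(n):
            sample = f"{cancer}-S{s:04d}"
            columns.append(sample)
            meta_rows.append((sample, sample, cancer, status[s]))
    log2 = np.concatenate(values, axis=1)
    fpkm = np.clip(np.exp2(log2) - 1.0, 0.0, None)
    vdf = pd.DataFrame(fpkm, index=pd.Index(genes, name="gene"), columns=columns)
    meta = pd.DataFrame(meta_rows, columns=["sample", "patient", "cancer", "status"]
                        ).set_index("sample")
    truth = ExpressionTruth(cfg.tumor_shift, rho, tuple(fam_genes), tuple(fam_genes))
    return ExpressionMatrix(values=vdf, sample_meta=meta, log_scale=False), truth


# ---------------------------------------------------------------------------
# Clinical outcomes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClinicalTruth:
    log_hazard_slope: float
    baseline_hazard: float
    censoring_fraction: float
    achieved_censoring: float
    logit_intercept: float
    logit_slope: float
    responder_split: str = "responders CR:PR = 1:2; non-responders SD:PD = 1:1"

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_clinical(
    scores: ScoreTable | pd.Series, config: SimulationConfig
) -> tuple[pd.DataFrame, ClinicalTruth]:
    """Survival and RECIST response outcomes driven by the score.

    Event times are exponential with hazard lambda_0 * exp(beta * z) for
    the standardized score z; censoring is independent uniform on
    (0, c_max) with c_max tuned by bisection so the realized censored
    fraction matches the request. Response is Bernoulli through a logistic
    link in z; responders split CR:PR = 1:2, non-responders SD:PD = 1:1.
    """
    s = scores.scores if isinstance(scores, ScoreTable) else pd.Series(scores)
    if len(s) == 0:
        raise ValidationError("scores are empty")
    cfg = config.survival
    rng = _stage_rng("clinical", config.seed)
    z = (s - s.mean()) / (s.std(ddof=0) if s.std(ddof=0) > 0 else 1.0)
    z = z.to_numpy(dtype=float)
    n = z.size
    hazard = cfg.baseline_hazard * np.exp(cfg.log_hazard_slope * z)
    t_event = rng.exponential(1.0 / hazard)
    if cfg.censoring_fraction > 0:
        u = rng.uniform(size=n)
        c_max = _tune_censoring(t_event, u, cfg.censoring_fraction)
        c = u * c_max
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)

    rcfg = config.response
    p_resp = 1.0 / (1.0 + np.exp(-(rcfg.logit_intercept + rcfg.logit_slope * z)))
    responder = rng.uniform(size=n) < p_resp
    u2 = rng.uniform(size=n)
    response = np.where(
        responder,
        np.where(u2 < 1 / 3, "CR", "PR"),
        np.where(u2 < 1 / 2, "SD", "PD"),
    )
    df = pd.DataFrame(
        {"time": time, "event": event, "response": response},
        index=pd.Index(s.index, name="sample"),
    )
    truth = ClinicalTruth(cfg.log_hazard_slope, cfg.baseline_hazard,
                          cfg.censoring_fraction, float(1 - event.mean()),
                          rcfg.logit_intercept, rcfg.logit_slope)
    return df, truth


def _tune_censoring(t_event, u, target: float) -> float:
    """Bisection on c_max so that mean(u * c_max < t_event) ~= target."""
    lo, hi = 1e-9, float(t_event.max() / max(u.min(), 1e-12)) + 1.0

    def censored_frac(c_max):
        return float(np.mean(u * c_max < t_event))

    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if censored_frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Immune features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImmuneTruth:
    target_scc: dict
    fraction_features: tuple

    def to_dict(self) -> dict:
        return {"target_scc": dict(self.target_scc),
                "fraction_features": list(self.fraction_features)}


def simulate_immune_features(
    scores: ScoreTable | pd.Series, config: SimulationConfig
) -> tuple[pd.DataFrame, ImmuneTruth]:
    """Immune features with target rank correlations to the score.

    A Gaussian copula: the score is replaced by its normal scores, each
    feature's latent normal is generated with the Pearson correlation
    2*sin(pi*scc/6) that maps to the requested Spearman value, and latents
    are pushed through a log-normal transform to non-negative values. The
    configured cell-fraction block is then renormalized to sum to 1 per
    sample (which perturbs the rank correlations only slightly; see
    docs/methods.md).
    """
    s = scores.scores if isinstance(scores, ScoreTable) else pd.Series(scores)
    cfg = config.immune
    missing = set(cfg.fraction_features) - set(cfg.target_scc)
    if missing:
        raise ValidationError(f"fraction features without a target: {sorted(missing)}")
    rng = _stage_rng("immune", config.seed)
    n = len(s)
    ranks = stats.rankdata(s.to_numpy(dtype=float))
    z_score = stats.norm.ppf((ranks - 0.5) / n)
    data = {}
    for feature, scc in cfg.target_scc.items():
        rho_p = 2.0 * np.sin(np.pi * scc / 6.0)
        latent = rho_p * z_score + np.sqrt(1 - rho_p ** 2) * rng.normal(size=n)
        data[feature] = np.exp(0.5 * latent)
    df = pd.DataFrame(data, index=pd.Index(s.index, name="sample"))
    frac = list(cfg.fraction_features)
    if frac:
        block = df[frac]
        df[frac] = block.div(block.sum(axis=1), axis=0)
    truth = ImmuneTruth(dict(cfg.target_scc), tuple(frac))
    return df, truth
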