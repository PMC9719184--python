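"""Clinical association stages: ROC classification of tumor vs normal,
maximally-selected survival cutpoints, log-rank / Cox association with a
risky-vs-protective call, Kaplan-Meier export, and therapy-response tests.

The risky/protective rule: a score is a risky factor when HR > 1 with
Cox p < 0.05, protective when HR < 1 with p < 0.05, otherwise not
significant. The p-value attached to cutpoint-derived groups is the naive
log-rank p on the selected split (the survminer workflow); it is
optimistically biased under maximal selection — see docs/methods.md.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger(__name__)

COX_SIGNIFICANCE = 0.05
#: |beta| above this is treated as monotone-likelihood separation.
_SEPARATION_BETA = 15.0


@dataclass
class RocResult:
    auc: float
    n_pos: int
    n_neg: int
    curve: pd.DataFrame        # columns: cutoff, sensitivity, specificity


@dataclass(frozen=True)
class LogrankResult:
    statistic: float           # chi-square, 1 df
    z: float                   # signed standardized statistic (group-1 excess)
    p_value: float


@dataclass
class CutpointResult:
    cutpoint: float
    statistic: float           # |z| of the selected split
    groups: pd.Series | np.ndarray = None   # "high" / "low" labels


@dataclass(frozen=True)
class SurvivalAssociation:
    hr: float
    ci_low: float
    ci_high: float
    cox_p: float
    logrank_p: float
    cutpoint: float
    classification: str        # risky / protective / ns
    separated: bool = False


@dataclass
class ResponseAssociation:
    table: pd.DataFrame        # groups x response counts
    fisher_p: float
    responder_definition: str


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def roc_auc(scores, labels) -> RocResult:
    """ROC analysis of a score against tumor/normal labels.

    AUC is the Mann-Whitney probability estimate U/(n_pos * n_neg) with
    ties contributing 1/2; the curve covers all distinct cutoffs so that
    trapezoidal integration of the curve reproduces the AUC exactly.
    """
    from sklearn.metrics import roc_curve

    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if str(l) == "tumor" else 0 for l in labels])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes (tumor and normal) must be present")
    u = stats.mannwhitneyu(scores[y == 1], scores[y == 0],
                           alternative="two-sided").statistic
    auc = float(u) / (n_pos * n_neg)
    fpr, tpr, thresholds = roc_curve(y, scores, drop_intermediate=False)
    curve = pd.DataFrame({
        "cutoff": thresholds,
        "sensitivity": tpr,
        "specificity": 1.0 - fpr,
    })
    return RocResult(auc=auc, n_pos=n_pos, n_neg=n_neg, curve=curve)


# ---------------------------------------------------------------------------
# Log-rank / cutpoint
# ---------------------------------------------------------------------------


def _logrank_oe(time, event, in_group1) -> tuple[float, float, float]:
    """Observed minus expected events and hypergeometric variance for the
    two-group log-rank statistic (group 1 = ``in_group1`` True)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    g1 = np.asarray(in_group1, dtype=bool)
    order = np.argsort(time, kind="stable")
    t, e, g = time[order], event[order], g1[order]
    n = t.size
    # at-risk counts just before each index
    at_risk_total = n - np.arange(n)
    # number of group-1 subjects with time >= t_i
    g_cum_from_end = np.cumsum(g[::-1])[::-1]
    o_minus_e = 0.0
    var = 0.0
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d = int(e[i:j].sum())             # events at this time
        if d > 0:
            nj = int(at_risk_total[i])
            n1 = int(g_cum_from_end[i])
            d1 = int(e[i:j][g[i:j]].sum())
            o_minus_e += d1 - d * n1 / nj
            if nj > 1:
                var += d * (n1 / nj) * (1 - n1 / nj) * (nj - d) / (nj - 1)
        i = j
    return o_minus_e, var, float(event.sum())


def logrank_test(time, event, group) -> LogrankResult:
    """Standard two-group log-rank test (chi-square, 1 df, two-sided).

    ``group`` is any two-level labelling; the signed z statistic is positive
    when the lexicographically *second* group (e.g. "high" after "low")
    experiences more events than expected.
    """
    group = np.asarray(group)
    levels = sorted(pd.unique(group).tolist())
    if len(levels) != 2:
        raise ValueError(f"logrank_test needs exactly 2 groups, got {levels}")
    in_g1 = group == levels[1]
    if in_g1.all() or not in_g1.any():
        raise ValueError("each group must be non-empty")
    o_minus_e, var, _ = _logrank_oe(time, event, in_g1)
    if var <= 0:
        return LogrankResult(0.0, 0.0, 1.0)
    z = o_minus_e / np.sqrt(var)
    chi2 = z * z
    return LogrankResult(float(chi2), float(z), float(stats.chi2.sf(chi2, df=1)))


def optimal_cutpoint(time, event, score, minprop: float = 0.1) -> CutpointResult:
    """Maximally-selected survival cutpoint (surv_cutpoint-style).

    Candidate thresholds are the midpoints between consecutive distinct
    scores leaving at least ``minprop`` of the samples on each side; the
    returned threshold maximizes the absolute standardized two-group
    log-rank statistic, ties broken toward the lower threshold. Samples
    with score strictly above the cutpoint form the "high" group.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    score = np.asarray(score, dtype=float)
    n = score.size
    if event.sum() < 1:
        raise ValueError("need at least one event")
    distinct = np.unique(score)
    if distinct.size < 2:
        raise ValueError("constant score: no valid split")
    candidates = (distinct[:-1] + distinct[1:]) / 2.0
    best = None
    for c in candidates:
        high = score > c
        n_high = int(high.sum())
        if n_high < minprop * n or (n - n_high) < minprop * n:
            continue
        o_minus_e, var, _ = _logrank_oe(time, event, high)
        if var <= 0:
            continue
        z = abs(o_minus_e) / np.sqrt(var)
        if best is None or z > best[0] + 1e-12:
            best = (z, c)
    if best is None:
        raise ValueError(f"no feasible split with minprop={minprop}")
    z, c = best
    groups = np.where(score > c, "high", "low")
    return CutpointResult(cutpoint=float(c), statistic=float(z), groups=groups)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------


def cox_univariable(time, event, covariate,
                    logrank_p: float = float("nan"),
                    cutpoint: float = float("nan")) -> SurvivalAssociation:
    """Single-covariate Cox proportional-hazards fit (Breslow ties).

    The covariate may be the continuous score or a 0/1 high-group
    indicator. Returns the hazard ratio exp(beta) with a Wald 95% CI and
    p-value, plus the risky/protective classification. Monotone-likelihood
    separation yields a flagged result with infinite-CI sentinels rather
    than a crash.
    """
    import statsmodels.api as sm

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    x = np.asarray(covariate, dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("covariate must take at least 2 distinct values")
    if event.sum() < 1:
        raise ValueError("need at least one event (all-censored data)")
    try:
        model = sm.PHReg(time, x[:, None], status=event, ties="breslow")
        fit = model.fit(disp=False)
        beta = float(fit.params[0])
        se = float(fit.bse[0])
    except Exception:  # numerical failure == separation for this purpose
        beta, se = np.inf, np.inf
    separated = not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > _SEPARATION_BETA
    if separated:
        hr = float(np.inf) if beta > 0 else 0.0
        return SurvivalAssociation(hr, 0.0, float(np.inf), float("nan"),
                                   logrank_p, cutpoint, "ns", separated=True)
    hr = float(np.exp(beta))
    delta = 1.959963984540054 * se
    ci_low, ci_high = float(np.exp(beta - delta)), float(np.exp(beta + delta))
    p = float(2 * stats.norm.sf(abs(beta) / se)) if se > 0 else float("nan")
    if p < COX_SIGNIFICANCE and hr > 1:
        classification = "risky"
    elif p < COX_SIGNIFICANCE and hr < 1:
        classification = "protective"
    else:
        classification = "ns"
    return SurvivalAssociation(hr, ci_low, ci_high, p, logrank_p, cutpoint,
                               classification)


def survival_association(scores, clinical: pd.DataFrame,
                         minprop: float = 0.1,
                         covariate: str = "group") -> SurvivalAssociation:
    """Cutpoint -> log-rank -> Cox workflow for one cohort.

    ``scores`` is a sample-indexed Series; ``clinical`` has ``time`` and
    ``event``. ``covariate`` selects the Cox covariate: the high/low group
    indicator (default) or the continuous score (``"score"``).
    """
    scores = pd.Series(scores)
    shared = scores.index.intersection(clinical.index)
    if len(shared) < 4:
        raise ValueError("need >= 4 samples shared between scores and clinical table")
    s = scores.loc[shared].to_numpy(dtype=float)
    t = clinical.loc[shared, "time"].to_numpy(dtype=float)
    e = clinical.loc[shared, "event"].to_numpy(dtype=int)
    cut = optimal_cutpoint(t, e, s, minprop=minprop)
    lr = logrank_test(t, e, cut.groups)
    x = (cut.groups == "high").astype(float) if covariate == "group" else s
    return cox_univariable(t, e, x, logrank_p=lr.p_value, cutpoint=cut.cutpoint)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------


def km_estimate(time, event, group) -> pd.DataFrame:
    """Product-limit survival estimates per group, with Greenwood variance.

    Returns a long table (group, time, survival, variance, ci_low, ci_high)
    suitable for step-function plotting; the estimate at t = 0 is 1.
    """
    from lifelines import KaplanMeierFitter

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    frames = []
    for g in pd.unique(group):
        mask = group == g
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask])
        sf = kmf.survival_function_.iloc[:, 0]
        ci = kmf.confidence_interval_
        # Greenwood variance backed out of the log-log CI is fragile; use
        # the plain Greenwood formula directly.
        var = _greenwood_variance(time[mask], event[mask], sf.index.to_numpy())
        frames.append(pd.DataFrame({
            "group": g,
            "time": sf.index.to_numpy(dtype=float),
            "survival": sf.to_numpy(dtype=float),
            "variance": var,
            "ci_low": ci.iloc[:, 0].to_numpy(dtype=float),
            "ci_high": ci.iloc[:, 1].to_numpy(dtype=float),
        }))
    return pd.concat(frames, ignore_index=True)


def _greenwood_variance(time, event, grid) -> np.ndarray:
    order = np.argsort(time, kind="stable")
    t, e = time[order], event[order]
    n = t.size
    uniq = np.unique(t[e == 1])
    s = 1.0
    cum = 0.0
    steps = []
    for u in uniq:
        at_risk = int((t >= u).sum())
        d = int(((t == u) & (e == 1)).sum())
        s *= 1 - d / at_risk
        if at_risk > d:
            cum += d / (at_risk * (at_risk - d))
        steps.append((u, s * s * cum))
    out = np.zeros(len(grid))
    for i, g in enumerate(grid):
        v = 0.0
        for u, val in steps:
            if u <= g:
                v = val
        out[i] = v
    return out


# ---------------------------------------------------------------------------
# Therapy response
# ---------------------------------------------------------------------------

RESPONSE_LEVELS = ("PD", "SD", "PR", "CR")
RESPONDERS = frozenset({"CR", "PR"})


def fisher_exact_2xk(table: np.ndarray) -> float:
    """Two-sided exact conditional test for a 2 x K contingency table.

    Enumerates all tables with the observed margins; the p-value sums the
    conditional (multivariate hypergeometric) probabilities of tables no
    more probable than the observed one (the standard two-sided ordering,
    matching R's fisher.test). Exact to full floating precision via
    log-gamma arithmetic.
    """
    table = np.asarray(table, dtype=int)
    if table.min() < 0:
        raise ValueError("counts must be non-negative")
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    n = int(table.sum())

    def log_prob(first_row: tuple[int, ...]) -> float:
        lp = -(gammaln(n + 1) - gammaln(row[0] + 1) - gammaln(row[1] + 1))
        for c, a in zip(col, first_row):
            b = c - a
            lp += gammaln(c + 1) - gammaln(a + 1) - gammaln(b + 1)
        return lp

    obs = log_prob(tuple(table[0]))
    k = len(col)

    total = 0.0
    extreme = 0.0

    def rec(idx: int, remaining: int, prefix: list[int]) -> None:
        nonlocal total, extreme
        if idx == k - 1:
            if remaining <= col[idx]:
                lp = log_prob(tuple(prefix + [remaining]))
                p = np.exp(lp)
                total += p
                if lp <= obs + 1e-9:
                    extreme += p
            return
        lo = max(0, remaining - int(col[idx + 1:].sum()))
        hi = min(col[idx], remaining)
        for a in range(lo, hi + 1):
            rec(idx + 1, remaining - a, prefix + [a])

    rec(0, int(row[0]), [])
    return float(min(1.0, extreme / total))


def response_association(groups, response, mode: str = "collapse") -> ResponseAssociation:
    """Association of score group with RECIST therapy response.

    ``mode="collapse"`` (default) tests responders {CR, PR} vs
    non-responders {SD, PD} in a two-sided 2x2 Fisher exact test;
    ``mode="full"`` keeps the 2x4 table and runs the exact conditional test
    over its margin-fixed distribution. Samples with response "NA" are
    dropped.
    """
    df = pd.DataFrame({"group": np.asarray(groups), "response": np.asarray(response)})
    df = df.loc[df["response"].isin(RESPONSE_LEVELS)]
    levels = sorted(df["group"].unique().tolist())
    if len(levels) != 2 or df.groupby("group").size().min() == 0:
        raise ValueError("need two non-empty groups")
    if mode == "collapse":
        df["resp2"] = np.where(df["response"].isin(RESPONDERS),
                               "responder", "non-responder")
        table = pd.crosstab(df["group"], df["resp2"]).reindex(
            index=levels, columns=["responder", "non-responder"], fill_value=0
        )
        _, p = stats.fisher_exact(table.to_numpy(), alternative="two-sided")
        definition = "responder = {CR, PR} vs non-responder = {SD, PD}"
    elif mode == "full":
        table = pd.crosstab(df["group"], df["response"]).reindex(
            index=levels, columns=list(RESPONSE_LEVELS), fill_value=0
        )
        p = fisher_exact_2xk(table.to_numpy())
        definition = "full 2x4 PD/SD/PR/CR table"
    else:
        raise ValueError(f"unknown response mode {mode!r}")
    return ResponseAssociation(table=table, fisher_p=float(p),
                               responder_definition=definition)
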