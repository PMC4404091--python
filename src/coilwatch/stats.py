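"""Nonparametric statistics for the longitudinal comparison.

Small retrospective cohorts call for exact nonparametric tests: one-tailed
paired Wilcoxon signed-rank tests for sac growth (alternative: growth > 0)
and coil compaction (alternative: growth < 0), a one-tailed Mann-Whitney
U test comparing the coil-center translation between cohorts, an empirical
ROC curve with Youden-optimal cutoff for candidate biomarkers, and the
coefficient of determination for the investigator-sensitivity comparison.

Exact null distributions are used at the study's sample sizes (signed-rank
by dynamic programming over doubled midranks for n <= 25; rank-sum by exact
DP without ties or full subset enumeration with ties, falling back to the
tie-corrected, continuity-corrected normal approximation for large samples).
Zero differences are dropped before ranking (Wilcoxon's original
convention); tied magnitudes receive midranks.  One-tailed p-values are
P(statistic at least as extreme as observed), observed value included.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy.stats import norm

from .metrics import VSG_DEFINITIONS, SubjectVolumes, compute_vcg, compute_vsg

_EPS = 1e-9


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _midranks(magnitudes: np.ndarray) -> np.ndarray:
    order = np.argsort(magnitudes, kind="mergesort")
    ranks = np.empty(len(magnitudes))
    sorted_m = magnitudes[order]
    i = 0
    while i < len(sorted_m):
        j = i
        while j < len(sorted_m) and sorted_m[j] <= sorted_m[i] + _EPS * max(1.0, sorted_m[i]):
            j += 1
        ranks[order[i:j]] = 0.5 * (i + 1 + j)
        i = j
    return ranks


def _signed_rank_exact_cdf(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of 2*W+ over all 2^n sign patterns, by polynomial DP."""
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    return counts


def wilcoxon_signed_rank_one_tailed(
    diffs, alternative: str = "greater", exact_limit: int = 25
) -> float:
    """One-tailed paired Wilcoxon signed-rank p-value.

    ``alternative="greater"`` tests for a positive location shift (the sum of
    positive ranks W+ is large); ``"less"`` for a negative one.  Exact for at
    most ``exact_limit`` nonzero differences, otherwise a tie-corrected
    normal approximation with continuity correction.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    d = np.asarray(diffs, dtype=float)
    d = d[np.abs(d) > _EPS]  # drop zeros (Wilcoxon's convention)
    n = len(d)
    if n == 0:
        raise ValueError("all differences are zero; the signed-rank test is undefined")
    ranks = _midranks(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if alternative == "less":
        # by symmetry: small W+ is extreme; test W- = n(n+1)/2 - W+ as large
        w_plus = n * (n + 1) / 2.0 - w_plus

    if n <= exact_limit:
        doubled = np.round(2 * ranks).astype(int)
        counts = _signed_rank_exact_cdf(doubled)
        w2 = int(round(2 * w_plus))
        return float(counts[w2:].sum() / 2.0**n)

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.round(ranks, 6), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = (w_plus - 0.5 - mu) / sqrt(var)
    return float(norm.sf(z))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _rank_sum_exact_dp(nx: int, ny: int) -> np.ndarray:
    """Counts of U over all C(nx+ny, nx) orderings (no ties): Gaussian binomial."""
    # recurrence c(u; a, b) = c(u - b; a-1, b) + c(u; a, b-1)
    table: dict[tuple[int, int], np.ndarray] = {}

    def f(a: int, b: int) -> np.ndarray:
        if (a, b) in table:
            return table[(a, b)]
        if a == 0 or b == 0:
            out = np.zeros(a * b + 1)
            out[0] = 1.0
        else:
            out = np.zeros(a * b + 1)
            fa = f(a - 1, b)
            fb = f(a, b - 1)
            out[b : b + len(fa)] += fa
            out[: len(fb)] += fb
        table[(a, b)] = out
        return out

    return f(nx, ny)


def mann_whitney_one_tailed(
    x,
    y,
    alternative: str = "greater",
    max_enumeration: int = 200_000,
) -> tuple[float, float]:
    """Mann-Whitney U statistic of x over y and its one-tailed p-value.

    ``alternative="greater"`` tests that x is stochastically larger than y.
    Tied observations contribute 1/2 to U (midranks).  The exact null
    distribution is used when feasible (DP without ties; subset enumeration
    with ties), else a tie-corrected normal approximation with continuity
    correction.
    """
    if alternative not in ("greater", "less", "two-sided"):
        raise ValueError("alternative must be 'greater', 'less' or 'two-sided'")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled - pooled.min() + 1.0)
    rx = float(ranks[:nx].sum())
    u = rx - nx * (nx + 1) / 2.0

    if alternative == "less":
        u_test = nx * ny - u
    else:
        u_test = u

    has_ties = len(np.unique(np.round(ranks, 6))) < nx + ny

    def p_greater(u_obs: float) -> float:
        if not has_ties and nx * ny <= 400:
            counts = _rank_sum_exact_dp(nx, ny)
            return float(counts[int(round(u_obs)) :].sum() / counts.sum())
        if comb(nx + ny, nx) <= max_enumeration:
            total = ranks.sum()
            count = 0
            n_all = 0
            base = nx * (nx + 1) / 2.0
            for subset in itertools.combinations(range(nx + ny), nx):
                u_perm = ranks[list(subset)].sum() - base
                count += u_perm >= u_obs - _EPS
                n_all += 1
            return count / n_all
        mu = nx * ny / 2.0
        n = nx + ny
        _, t = np.unique(np.round(ranks, 6), return_counts=True)
        var = nx * ny / 12.0 * (n + 1 - np.sum(t**3 - t) / (n * (n - 1)))
        z = (u_obs - 0.5 - mu) / sqrt(var)
        return float(norm.sf(z))

    if alternative == "two-sided":
        p = 2.0 * p_greater(max(u, nx * ny - u))
        return float(u), float(min(p, 1.0))
    return float(u), float(p_greater(u_test))


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class RocResult:
    """Empirical ROC of a score for a binary outcome.

    ``thresholds[i]`` classifies positive when score >= threshold; the
    optimal threshold maximizes Youden's J (sensitivity + specificity - 1),
    ties broken toward the lower threshold.
    """

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    auc: float
    optimal_threshold: float
    youden_j: float


def roc(scores, labels) -> RocResult:
    """ROC curve, AUC and Youden-optimal cutoff.

    AUC is computed as the pairwise concordance (concordant + half of tied
    pairs over all positive/negative pairs), which equals the trapezoidal
    area under the empirical curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    pos, neg = scores[labels], scores[~labels]
    n1, n0 = len(pos), len(neg)

    diff = pos[:, None] - neg[None, :]
    auc = (np.sum(diff > _EPS) + 0.5 * np.sum(np.abs(diff) <= _EPS)) / (n1 * n0)

    thresholds = np.unique(scores)
    sens = np.array([(pos >= t - _EPS).mean() for t in thresholds])
    spec = np.array([(neg < t - _EPS).mean() for t in thresholds])
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first (lowest threshold) among ties
    return RocResult(
        thresholds=thresholds,
        sensitivities=sens,
        specificities=spec,
        auc=float(auc),
        optimal_threshold=float(thresholds[best]),
        youden_j=float(j[best]),
    )


# ---------------------------------------------------------------------------
# Investigator sensitivity
# ---------------------------------------------------------------------------

def r_squared(x, y) -> float:
    """Coefficient of determination: squared Pearson correlation of paired
    measurements by two investigators."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need paired samples of equal length >= 2")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

@dataclass
class CohortSummary:
    """One row of the growth-outcome table (per definition, per cohort)."""

    cohort: str
    definition: str          # "V_SG", "V_SG1".."V_SG4", "V_CG"
    mean_cc: float | None
    sd_cc: float | None
    mean_pct: float | None
    sd_pct: float | None
    p_value: float | None
    n: int


def _row(cohort, label, diffs, pcts, alternative) -> CohortSummary:
    n = len(diffs)
    if n == 0:
        return CohortSummary(cohort, label, None, None, None, None, None, 0)
    diffs = np.asarray(diffs, float)
    pcts = np.asarray(pcts, float)
    try:
        p = wilcoxon_signed_rank_one_tailed(diffs, alternative=alternative)
    except ValueError:  # all differences zero
        p = None
    return CohortSummary(
        cohort,
        label,
        float(diffs.mean()),
        float(diffs.std(ddof=1)) if n >= 2 else None,
        float(pcts.mean()),
        float(pcts.std(ddof=1)) if n >= 2 else None,
        p,
        n,
    )


def summarize_cohort(subjects: list[SubjectVolumes], cohort: str) -> list[CohortSummary]:
    """Growth-outcome rows for one cohort.

    One row for the prioritized sac-growth definition (V_SG, alternative
    'greater'), one per fixed definition V_SG1..V_SG4 over the subjects where
    that definition is computable, and one for coil growth V_CG (alternative
    'less': the compaction hypothesis).  Definitions with no computable
    subjects degrade to empty rows rather than errors.
    """
    members = [sv for sv in subjects if sv.cohort == cohort]
    rows: list[CohortSummary] = []

    prio_d, prio_p = [], []
    for sv in members:
        try:
            vsg, definition = compute_vsg(sv)
        except ValueError:
            continue
        initial = getattr(sv, VSG_DEFINITIONS[definition][1])
        prio_d.append(vsg)
        prio_p.append(100.0 * vsg / initial)
    rows.append(_row(cohort, "V_SG", prio_d, prio_p, "greater"))

    for definition, (follow, initial_name) in VSG_DEFINITIONS.items():
        d, p = [], []
        for sv in members:
            vf, vi = getattr(sv, follow), getattr(sv, initial_name)
            if vf is not None and vi is not None:
                d.append(vf - vi)
                p.append(100.0 * (vf - vi) / vi)
        rows.append(_row(cohort, f"V_SG{definition}", d, p, "greater"))

    d, p = [], []
    for sv in members:
        out = compute_vcg(sv)
        if out is not None:
            d.append(out[0])
            p.append(out[1])
    rows.append(_row(cohort, "V_CG", d, p, "less"))
    return rows


def summary_frame(subjects: list[SubjectVolumes]) -> pd.DataFrame:
    """Both cohorts' outcome rows as a table (growth-outcome layout)."""
    rows = summarize_cohort(subjects, "recurrence") + summarize_cohort(subjects, "control")
    return pd.DataFrame(
        {
            "cohort": r.cohort,
            "definition": r.definition,
            "mean_growth_cc": r.mean_cc,
            "sd_growth_cc": r.sd_cc,
            "mean_pct_growth": r.mean_pct,
            "sd_pct_growth": r.sd_pct,
            "p_value": r.p_value,
            "n": r.n,
        }
        for r in rows
    )
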