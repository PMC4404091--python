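"""Exact nonparametric tests against brute-force enumeration oracles."""

import itertools
from math import comb

import numpy as np
import pytest

from coilwatch import (
    SubjectVolumes,
    mann_whitney_one_tailed,
    r_squared,
    roc,
    summarize_cohort,
    summary_frame,
    wilcoxon_signed_rank_one_tailed,
)


# ---------------------------------------------------------------------------
# Brute-force oracles (independent of the implementation)
# ---------------------------------------------------------------------------

def midranks(values):
    values = np.asarray(values, float)
    order = np.argsort(values)
    ranks = np.empty(len(values))
    sorted_v = values[order]
    i = 0
    while i < len(sorted_v):
        j = i
        while j < len(sorted_v) and np.isclose(sorted_v[j], sorted_v[i]):
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    return ranks


def wilcoxon_oracle(diffs, alternative="greater"):
    """Enumerate all 2^n sign patterns of the ranked magnitudes."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = midranks(np.abs(d))
    w_obs = ranks[d > 0].sum()
    if alternative == "less":
        w_obs = n * (n + 1) / 2 - w_obs
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, bool)].sum()
        if w >= w_obs - 1e-9:
            count += 1
    return count / 2**n


def mannwhitney_oracle(x, y, alternative="greater"):
    """Enumerate all C(n, nx) assignments of the pooled midranks."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    ranks = midranks(np.concatenate([x, y]))
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    if alternative == "less":
        u_obs = nx * ny - u_obs
    count = total = 0
    for subset in itertools.combinations(range(nx + ny), nx):
        u = ranks[list(subset)].sum() - nx * (nx + 1) / 2
        if u >= u_obs - 1e-9:
            count += 1
        total += 1
    return count / total


def auc_oracle(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos, neg = scores[labels], scores[~labels]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_all_positive_five(self):
        # only the all-positive sign pattern reaches W+ = 15
        assert wilcoxon_signed_rank_one_tailed([1, 2, 3, 4, 5], "greater") == pytest.approx(
            1 / 32
        )

    def test_tied_pair_enumeration(self):
        # {+2, -2}: W+ = 1.5; three of four patterns reach it
        p = wilcoxon_signed_rank_one_tailed([2, -2], "greater")
        assert p == pytest.approx(wilcoxon_oracle([2, -2])) == pytest.approx(0.75)

    def test_all_negative_boundary(self):
        # W+ = 0 is reached by every pattern: p = 1 under the >= convention
        p = wilcoxon_signed_rank_one_tailed([-1, -2, -3], "greater")
        assert p == pytest.approx(wilcoxon_oracle([-1, -2, -3])) == pytest.approx(1.0)
        assert wilcoxon_signed_rank_one_tailed([-1, -2, -3], "less") == pytest.approx(1 / 8)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank_one_tailed([0.0, 0.0])

    def test_zeros_dropped(self):
        assert wilcoxon_signed_rank_one_tailed(
            [0, 1, 2, 3, 4, 5, 0], "greater"
        ) == pytest.approx(1 / 32)

    def test_matches_enumeration_oracle_small_n(self, rng):
        # ties, zeros and mixed signs over 100 random integer datasets
        for _ in range(100):
            n = int(rng.integers(2, 9))
            d = rng.integers(-4, 5, size=n).astype(float)
            if np.all(d == 0):
                continue
            for alt in ("greater", "less"):
                assert wilcoxon_signed_rank_one_tailed(d, alt) == pytest.approx(
                    wilcoxon_oracle(d, alt)
                ), f"diffs={d} alt={alt}"

    def test_normal_approximation_close_to_exact(self, rng):
        d = rng.normal(0.3, 1.0, size=30)
        exact = wilcoxon_signed_rank_one_tailed(d, "greater", exact_limit=40)
        approx = wilcoxon_signed_rank_one_tailed(d, "greater", exact_limit=10)
        assert approx == pytest.approx(exact, abs=0.01)


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

class TestMannWhitney:
    def test_separated_three_vs_three(self):
        u, p = mann_whitney_one_tailed([4, 5, 6], [1, 2, 3], "greater")
        assert u == 9
        assert p == pytest.approx(1 / 20)

    def test_single_tied_pair_convention(self):
        # identical singletons: U = 1/2 in both assignments -> p = 1
        u, p = mann_whitney_one_tailed([5.0], [5.0], "greater")
        assert u == pytest.approx(0.5)
        assert p == pytest.approx(mannwhitney_oracle([5.0], [5.0])) == pytest.approx(1.0)

    def test_full_separation_nine_vs_nine(self):
        x = np.arange(10, 19, dtype=float)
        y = np.arange(1, 10, dtype=float)
        _, p = mann_whitney_one_tailed(x, y, "greater")
        assert p == pytest.approx(1 / comb(18, 9))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_tailed([], [1.0])

    def test_matches_enumeration_oracle_small_n(self, rng):
        for _ in range(100):
            nx, ny = int(rng.integers(1, 8)), int(rng.integers(1, 8))
            x = rng.integers(0, 6, nx).astype(float)
            y = rng.integers(0, 6, ny).astype(float)
            for alt in ("greater", "less"):
                _, p = mann_whitney_one_tailed(x, y, alt)
                assert p == pytest.approx(
                    mannwhitney_oracle(x, y, alt)
                ), f"x={x} y={y} alt={alt}"

    def test_two_sided_matches_scipy_without_ties(self, rng):
        from scipy.stats import mannwhitneyu

        x = rng.normal(0.5, 1, 8)
        y = rng.normal(0.0, 1, 9)
        u, p = mann_whitney_one_tailed(x, y, "two-sided")
        u_ref, p_ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref)

    def test_large_sample_normal_approximation(self, rng):
        x = rng.normal(1.0, 1.0, 40)
        y = rng.normal(0.0, 1.0, 35)
        from scipy.stats import mannwhitneyu

        u, p = mann_whitney_one_tailed(x, y, "greater")
        u_ref, p_ref = mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        assert u == pytest.approx(u_ref)
        assert p == pytest.approx(p_ref, rel=0.05)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

class TestRoc:
    def test_perfect_separation(self):
        r = roc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.youden_j == pytest.approx(1.0)
        assert r.optimal_threshold == 10

    def test_constant_score_chance_level(self):
        r = roc([5, 5, 5, 5], [0, 1, 0, 1])
        assert r.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1, 2, 3], [1, 1, 1])

    def test_auc_equals_u_statistic_identity(self, rng):
        for _ in range(100):
            n1, n0 = int(rng.integers(2, 12)), int(rng.integers(2, 12))
            pos = rng.integers(0, 8, n1).astype(float)
            neg = rng.integers(0, 8, n0).astype(float)
            scores = np.concatenate([pos, neg])
            labels = np.array([1] * n1 + [0] * n0)
            r = roc(scores, labels)
            u, _ = mann_whitney_one_tailed(pos, neg)
            assert r.auc == pytest.approx(u / (n1 * n0))
            assert r.auc == pytest.approx(auc_oracle(scores, labels))

    def test_matches_sklearn_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=40)
        labels = rng.random(40) > 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        assert roc(scores, labels).auc == pytest.approx(roc_auc_score(labels, scores))

    def test_youden_tie_breaks_to_lower_threshold(self):
        # every threshold has J = 0; the lowest must be reported
        r = roc([1.0, 2.0], [1, 0])
        assert r.optimal_threshold == 1.0


# ---------------------------------------------------------------------------
# R^2
# ---------------------------------------------------------------------------

class TestRSquared:
    def test_perfect_and_affine(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert r_squared(x, x) == pytest.approx(1.0)
        assert r_squared(x, 2 * x + 3) == pytest.approx(1.0)

    def test_perturbed_matches_definition(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.5, 4.0])
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        expected = sxy**2 / (np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert r_squared(x, y) == pytest.approx(expected)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


# ---------------------------------------------------------------------------
# Cohort summaries
# ---------------------------------------------------------------------------

def volume_table(rng, n=15, growth=0.20, noise=0.03, cohort="recurrence"):
    """Synthetic measured-volume table: initial volumes with multiplicative
    growth and small measurement error; stable coils."""
    out = []
    for i in range(n):
        v1 = rng.uniform(0.1, 0.5)
        err = lambda: 1 + rng.normal(0, noise)
        sv = SubjectVolumes(
            subject_id=f"{cohort[:1]}{i}",
            cohort=cohort,
            vs1m=v1 * err(),
            vs1p=v1 * err(),
            vs2m=v1 * (1 + growth) * err(),
            vs2p=None if cohort == "control" else v1 * (1 + growth) * err(),
            vc1p=0.3 * v1 * err(),
            vc2m=0.3 * v1 * err(),
        )
        out.append(sv)
    return out


class TestSummaries:
    def test_control_has_no_definition_1_or_2_rows(self, rng):
        rows = summarize_cohort(volume_table(rng, 5, 0.0, cohort="control"), "control")
        by_def = {r.definition: r for r in rows}
        assert by_def["V_SG1"].n == 0 and by_def["V_SG1"].p_value is None
        assert by_def["V_SG2"].n == 0
        assert by_def["V_SG"].n == 5  # prioritized falls through to definition 3

    def test_single_subject_sd_undefined(self, rng):
        rows = summarize_cohort(volume_table(rng, 1), "recurrence")
        vsg = next(r for r in rows if r.definition == "V_SG")
        assert vsg.n == 1 and vsg.sd_cc is None and vsg.mean_cc is not None

    def test_programmed_growth_detected(self, rng):
        rows = summarize_cohort(volume_table(rng, 15, 0.20, 0.03), "recurrence")
        vsg = next(r for r in rows if r.definition == "V_SG")
        assert vsg.p_value < 0.05
        assert vsg.mean_pct == pytest.approx(20, abs=8)

    def test_compaction_direction_is_less(self, rng):
        # programmed compaction: V_CG must reach significance one-tailed-less
        subjects = volume_table(rng, 12, 0.0, 0.01)
        for sv in subjects:
            sv.vc2m = sv.vc1p * 0.8
        rows = summarize_cohort(subjects, "recurrence")
        vcg = next(r for r in rows if r.definition == "V_CG")
        assert vcg.p_value < 0.05 and vcg.mean_cc < 0

    def test_summary_frame_layout(self, rng):
        frame = summary_frame(volume_table(rng, 4) + volume_table(rng, 3, 0.0, cohort="control"))
        assert set(frame["definition"]) == {"V_SG", "V_SG1", "V_SG2", "V_SG3", "V_SG4", "V_CG"}
        assert len(frame) == 12  # 6 rows per cohort


def test_type_one_error_calibration(rng):
    """Null volume tables rejected at ~5% under the exact signed-rank test."""
    rejections = 0
    reps = 200
    for _ in range(reps):
        diffs = rng.normal(0.0, 1.0, size=15)
        p = wilcoxon_signed_rank_one_tailed(diffs, "greater")
        rejections += p < 0.05
    rate = rejections / reps
    assert abs(rate - 0.05) < 0.035
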