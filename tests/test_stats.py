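"""Behavioral statistics: effects tables and the test battery."""

import itertools
import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

from oculater import (
    bonferroni_alpha,
    condition_effects,
    friedman,
    jzs_bf_paired,
    mixed_anova,
    paired_t,
    rm_anova,
    sequential_effects,
    wilcoxon_signed_rank,
)


def singles_table(latencies_by, n_per_cell, rng, participants=10):
    """Minimal single-trial table: latencies_by maps reward level to a
    latency sampler taking (rng, size)."""
    rows = []
    for i in range(participants):
        for level, sampler in latencies_by.items():
            lat = sampler(rng, n_per_cell)
            for x in lat:
                rows.append({
                    "participant_id": f"p{i:02d}", "trial_type": "single",
                    "outcome": "hit",
                    "target_side": "right" if level == "high" else "left",
                    "high_reward_side": "right", "latency_ms": float(x)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# condition effects
# ---------------------------------------------------------------------------

def test_known_effect_recovered():
    """A built-in 30 ms low-reward delay is estimated within 5 ms."""
    rng = np.random.default_rng(60)
    df = singles_table(
        {"high": lambda r, n: r.normal(190, 25, n),
         "low": lambda r, n: r.normal(220, 25, n)},
        n_per_cell=40, rng=rng, participants=25)
    table = condition_effects(df, [])
    agg = table.aggregate.iloc[0]
    assert agg.mean_diff == pytest.approx(30, abs=5)
    assert agg.ci_low < 30 < agg.ci_high
    assert agg.n_participants == 25


def test_null_difference_ci_coverage():
    """With identical latency distributions the 95% CI covers zero in at
    least 93 of 100 seeded replicates."""
    rng = np.random.default_rng(61)
    covered = 0
    for _ in range(100):
        df = singles_table(
            {"high": lambda r, n: r.normal(200, 25, n),
             "low": lambda r, n: r.normal(200, 25, n)},
            n_per_cell=15, rng=rng, participants=8)
        agg = condition_effects(df, []).aggregate.iloc[0]
        covered += agg.ci_low <= 0 <= agg.ci_high
    assert covered >= 93


def test_single_trial_cells_pass_through():
    rng = np.random.default_rng(62)
    df = singles_table({"high": lambda r, n: np.array([180.0]),
                        "low": lambda r, n: np.array([210.0])},
                       n_per_cell=1, rng=rng, participants=1)
    table = condition_effects(df, [])
    got = dict(zip(table.per_participant.reward_level,
                   table.per_participant.mean_latency))
    assert got == {"high": 180.0, "low": 210.0}
    assert table.aggregate.iloc[0].mean_diff == 30.0


def test_sequential_requires_labels():
    df = singles_table({"high": lambda r, n: r.normal(200, 10, n)},
                       5, np.random.default_rng(0), participants=2)
    with pytest.raises(ValueError, match="prev_type"):
        sequential_effects(df)


# ---------------------------------------------------------------------------
# paired t and Bonferroni
# ---------------------------------------------------------------------------

def test_paired_t_symmetric_differences():
    res = paired_t([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
    assert res.t == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0, abs=1e-12)
    assert res.df == 2


def test_paired_t_constant_differences_error():
    with pytest.raises(ValueError, match="zero-variance"):
        paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


def test_paired_t_matches_formula():
    rng = np.random.default_rng(63)
    x, y = rng.normal(size=20), rng.normal(size=20)
    res = paired_t(x, y)
    d = x - y
    t = d.mean() / (d.std(ddof=1) / math.sqrt(d.size))
    assert res.t == pytest.approx(t, abs=1e-12)
    assert res.p == pytest.approx(2 * sps.t.sf(abs(t), 19), abs=1e-12)
    assert res.mean_diff == pytest.approx(d.mean(), abs=1e-12)


@pytest.mark.parametrize("alpha, m, expected", [
    (0.05, 6, pytest.approx(0.008333, abs=5e-7)),
    (0.05, 1, 0.05),
    (0.01, 4, 0.0025)])
def test_bonferroni(alpha, m, expected):
    assert bonferroni_alpha(alpha, m) == expected


def test_bonferroni_rejects_zero_comparisons():
    with pytest.raises(ValueError):
        bonferroni_alpha(0.05, 0)


def test_paired_t_type_one_error_controlled():
    rng = np.random.default_rng(64)
    rejections = 0
    for _ in range(2000):
        x = rng.normal(size=25)
        y = rng.normal(size=25)
        rejections += paired_t(x, y).p < 0.05
    assert rejections / 2000 <= 0.06


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------

def test_jzs_properties():
    assert jzs_bf_paired(0.0, 25) < 1.0
    assert jzs_bf_paired(2.0, 25) == pytest.approx(jzs_bf_paired(-2.0, 25),
                                                   rel=1e-9)
    bfs = [jzs_bf_paired(t, 25) for t in (0.0, 0.5, 1.0, 2.0, 4.0)]
    assert np.all(np.diff(bfs) > 0)
    with pytest.raises(ValueError):
        jzs_bf_paired(np.nan, 25)
    with pytest.raises(ValueError):
        jzs_bf_paired(1.0, 1)


@pytest.mark.parametrize("t, n", [(0.43, 25), (2.12, 25), (0.06, 8), (3.5, 12)])
def test_jzs_matches_independent_implementation(t, n):
    """Cross-check the quadrature against pingouin's JZS implementation."""
    ours = jzs_bf_paired(t, n)
    theirs = float(pg.bayesfactor_ttest(t, n, paired=True))
    assert ours == pytest.approx(theirs, rel=1e-3)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _long(matrix, levels=None):
    n, k = matrix.shape
    levels = levels or [f"l{j}" for j in range(k)]
    return pd.DataFrame(
        [(f"s{i}", levels[j], matrix[i, j]) for i in range(n) for j in range(k)],
        columns=["participant_id", "cond", "y"])


def test_rm_anova_constant_data_f_zero():
    data = _long(np.full((6, 3), 7.0))
    row = rm_anova(data, "y", "cond").iloc[0]
    assert row.F == 0.0 and row.p_unc == 1.0


def test_rm_anova_two_levels_equals_squared_t():
    rng = np.random.default_rng(65)
    mat = rng.normal(size=(12, 2))
    row = rm_anova(_long(mat), "y", "cond").iloc[0]
    t = paired_t(mat[:, 0], mat[:, 1])
    assert row.F == pytest.approx(t.t ** 2, abs=1e-9)
    assert row.p_unc == pytest.approx(t.p, abs=1e-9)


def test_rm_anova_matches_brute_force_decomposition():
    """Explicit sums-of-squares decomposition reproduces F to 1e-9."""
    rng = np.random.default_rng(66)
    mat = rng.normal(size=(10, 4)) + np.array([0.0, 0.3, 0.1, -0.2])
    n, k = mat.shape
    gm = mat.mean()
    ss_effect = n * ((mat.mean(axis=0) - gm) ** 2).sum()
    ss_subject = k * ((mat.mean(axis=1) - gm) ** 2).sum()
    ss_total = ((mat - gm) ** 2).sum()
    ss_error = ss_total - ss_effect - ss_subject
    f_oracle = (ss_effect / (k - 1)) / (ss_error / ((n - 1) * (k - 1)))

    row = rm_anova(_long(mat), "y", "cond").iloc[0]
    assert row.F == pytest.approx(f_oracle, abs=1e-9)
    assert (row.df1, row.df2) == (k - 1, (n - 1) * (k - 1))
    assert 1.0 / (k - 1) - 1e-9 <= row.eps <= 1.0 + 1e-9
    assert 0.0 <= row.p_gg <= 1.0


def test_rm_anova_two_within_factors():
    rng = np.random.default_rng(67)
    rows = [(f"s{i}", a, b, rng.normal() + (0.8 if a == "a2" else 0.0))
            for i in range(12) for a in ("a1", "a2") for b in ("b1", "b2", "b3")]
    data = pd.DataFrame(rows, columns=["participant_id", "A", "B", "y"])
    res = rm_anova(data, "y", ["A", "B"]).set_index("effect")
    assert {"A", "B", "A * B"} <= set(res.index)
    assert res.loc["A", "p_unc"] < 0.01


def test_rm_anova_rejects_unbalanced():
    data = _long(np.random.default_rng(68).normal(size=(6, 3)))
    with pytest.raises(ValueError, match="balanced|missing"):
        rm_anova(data.iloc[:-1], "y", "cond")


def test_rm_anova_type_one_error_controlled():
    rng = np.random.default_rng(69)
    rejections = 0
    n_sim = 2000
    for _ in range(n_sim):
        mat = rng.normal(size=(25, 3))
        rejections += rm_anova(_long(mat), "y", "cond").iloc[0].p_unc < 0.05
    assert rejections / n_sim <= 0.06


def test_mixed_anova_detects_between_effect():
    rng = np.random.default_rng(70)
    rows = []
    for i in range(16):
        group = "g1" if i < 8 else "g2"
        shift = 0.0 if group == "g1" else 1.5
        for w in ("w1", "w2"):
            rows.append((f"s{i}", group, w, rng.normal() + shift))
    data = pd.DataFrame(rows, columns=["participant_id", "group", "w", "y"])
    res = mixed_anova(data, "y", within="w", between="group").set_index("effect")
    assert res.loc["group", "p_unc"] < 0.01


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def test_wilcoxon_all_positive_n8():
    """Eight positive differences: W- = 0 and z = -18/sqrt(51) = -2.5205."""
    res = wilcoxon_signed_rank(np.arange(1.0, 9.0))
    assert res.W == 0.0
    assert res.z == pytest.approx(-2.5205, abs=1e-4)
    assert res.p_exact == pytest.approx(2 / 256, abs=1e-12)


def test_wilcoxon_single_difference():
    res = wilcoxon_signed_rank([3.0])
    assert res.W in (0.0, 1.0)
    assert res.p_exact == 1.0


def test_wilcoxon_drops_zeros_and_rejects_all_zero():
    res = wilcoxon_signed_rank([0.0, 0.0, 2.0, -1.0, 3.0])
    assert res.n == 3
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([0.0, 0.0])


def test_wilcoxon_exact_matches_enumeration():
    """Exact p agrees with literal enumeration of all 2^n sign patterns."""
    mags = np.array([1.3, 2.1, 0.7, 3.5, 1.9])
    ranks = sps.rankdata(mags)
    all_w = [sum(r for r, s in zip(ranks, signs) if s < 0)
             for signs in itertools.product([1, -1], repeat=5)]
    all_w = np.array(all_w)
    for signs in itertools.product([1, -1], repeat=5):
        d = mags * np.array(signs)
        res = wilcoxon_signed_rank(d)
        lower = np.mean(all_w <= res.W)
        upper = np.mean(all_w >= res.W)
        p_enum = min(1.0, 2 * min(lower, upper))
        assert res.p_exact == pytest.approx(p_enum, abs=1e-12)


def test_wilcoxon_exact_matches_scipy():
    rng = np.random.default_rng(71)
    for n in (6, 10, 14):
        d = rng.normal(0.3, 1.0, size=n)
        res = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, method="exact")
        assert res.p_exact == pytest.approx(ref.pvalue, abs=1e-10)


def test_wilcoxon_normal_approximation_converges():
    rng = np.random.default_rng(72)
    for _ in range(10):
        d = rng.normal(0.2, 1.0, size=25)
        res = wilcoxon_signed_rank(d)
        if res.p_exact is not None and 0.05 < res.p_exact < 0.95:
            assert abs(res.p_exact - res.p_approx) < 0.03


# ---------------------------------------------------------------------------
# Friedman
# ---------------------------------------------------------------------------

def test_friedman_identical_columns():
    res = friedman(np.tile([[1.0], [2.0], [3.0]], (1, 3)))
    assert res.chi2 == 0.0 and res.p == 1.0 and res.df == 2


def test_friedman_ordered_rows():
    mat = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]], dtype=float)
    res = friedman(mat)
    assert res.chi2 == pytest.approx(6.0, abs=1e-12)
    assert res.df == 2
    assert res.p == pytest.approx(sps.chi2.sf(6.0, 2), abs=1e-12)


def test_friedman_matches_rank_formula():
    """chi2 equals the explicit mean-rank formula on tie-free matrices."""
    rng = np.random.default_rng(73)
    for _ in range(5):
        mat = rng.normal(size=(4, 3))
        n, k = mat.shape
        ranks = np.vstack([sps.rankdata(row) for row in mat])
        rbar = ranks.mean(axis=0)
        chi2 = 12 * n / (k * (k + 1)) * ((rbar - (k + 1) / 2) ** 2).sum()
        assert friedman(mat).chi2 == pytest.approx(chi2, abs=1e-9)


def test_friedman_rejects_missing_cells():
    with pytest.raises(ValueError):
        friedman(np.array([[1.0, np.nan, 2.0], [3.0, 1.0, 2.0]]))
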