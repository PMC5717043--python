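"""Condition effects, sequential effects, and the statistical test battery.

Implements the analyses run on preprocessed single-trial latencies:
per-participant condition means and low-minus-high reward differences,
N-1 (previous-trial) contrasts, paired t-tests with Bonferroni-corrected
alpha, JZS (default-prior) Bayes factors for the paired t, repeated-
measures ANOVA with Greenhouse-Geisser correction, Wilcoxon signed-rank
tests (normal approximation without continuity correction plus the exact
small-sample p), and the Friedman test.

ANOVAs are delegated to :mod:`pingouin`; the Bayes factor and the
Wilcoxon test are implemented directly because the exact conventions
(numerical integration over the Cauchy-prior mixing variable; Z without
continuity correction; exact p for n <= 25) are part of this package's
contract.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import integrate, stats as sps

DEFAULT_RSCALE = math.sqrt(2.0) / 2.0


# ---------------------------------------------------------------------------
# condition and sequential effects
# ---------------------------------------------------------------------------

def add_reward_level(df: pd.DataFrame) -> pd.DataFrame:
    """Label single-trials 'high'/'low' by whether the target was the
    highly rewarded hemifield (choice-trials get 'choice')."""
    out = df.copy()
    out["reward_level"] = np.where(
        out["trial_type"] == "choice", "choice",
        np.where(out["target_side"] == out["high_reward_side"], "high", "low"))
    return out


def _analysis_singles(df: pd.DataFrame) -> pd.DataFrame:
    """Window-passed hit single-trials with a reward_level column."""
    if "reward_level" not in df.columns:
        df = add_reward_level(df)
    return df[(df["trial_type"] == "single") & (df["outcome"] == "hit")]


@dataclass(frozen=True)
class EffectTable:
    """Per-participant condition means plus across-participant aggregates."""

    grouping: tuple
    per_participant: pd.DataFrame  # participant x grouping x reward_level means
    aggregate: pd.DataFrame        # per grouping cell: means, low-high diff, CI


def condition_effects(df: pd.DataFrame, grouping: Sequence[str]) -> EffectTable:
    """Mean latency per participant and condition cell, and the low-minus-
    high reward difference aggregated across participants with a 95%
    t-interval.  Cells without trials are left absent (NaN)."""
    singles = _analysis_singles(df)
    grouping = list(grouping)
    keys = ["participant_id", *grouping, "reward_level"]
    per_part = (singles.groupby(keys, sort=False, observed=True)["latency_ms"]
                .mean().rename("mean_latency").reset_index())

    wide = per_part.pivot_table(index=["participant_id", *grouping],
                                columns="reward_level", values="mean_latency")
    for col in ("low", "high"):
        if col not in wide.columns:
            wide[col] = np.nan
    wide["diff"] = wide["low"] - wide["high"]

    rows = []
    level = grouping[0] if len(grouping) == 1 else grouping
    group_iter = (wide.groupby(level=level, sort=False) if grouping
                  else [((), wide)])
    for cell, grp in group_iter:
        d = grp["diff"].dropna()
        n = len(d)
        mean_diff = float(d.mean()) if n else np.nan
        if n >= 2:
            half = float(sps.t.ppf(0.975, n - 1) * d.std(ddof=1) / math.sqrt(n))
            ci = (mean_diff - half, mean_diff + half)
        else:
            ci = (np.nan, np.nan)
        cell = cell if isinstance(cell, tuple) else (cell,)
        rows.append({**dict(zip(grouping, cell)),
                     "mean_low": float(grp["low"].mean()),
                     "mean_high": float(grp["high"].mean()),
                     "mean_diff": mean_diff, "ci_low": ci[0], "ci_high": ci[1],
                     "n_participants": n})
    return EffectTable(tuple(grouping), per_part, pd.DataFrame(rows))


def sequential_effects(df: pd.DataFrame) -> pd.DataFrame:
    """N-1 contrasts on single-trial latency, per reward level.

    Two contrasts, each computed per participant then averaged:
    ``after_choice_vs_single`` (mean latency after a choice-trial minus
    after a single-trial) and ``after_opposite_vs_same`` (after a
    single-trial in the opposite vs the same direction).  Requires the
    ``prev_type``/``prev_direction`` labels from
    :func:`~oculater.preprocess.label_previous_trial`.
    """
    if "prev_type" not in df.columns or "prev_direction" not in df.columns:
        raise ValueError("records lack prev_type/prev_direction labels; run "
                         "label_previous_trial on the unfiltered table first")
    singles = _analysis_singles(df)
    rows = []
    for level, grp in singles.groupby("reward_level", sort=False):
        # after choice vs after single
        sub = grp[grp["prev_type"].isin(["choice", "single"])]
        m = sub.pivot_table(index="participant_id", columns="prev_type",
                            values="latency_ms")
        if {"choice", "single"} <= set(m.columns):
            d = (m["choice"] - m["single"]).dropna()
            rows.append({"reward_level": level,
                         "contrast": "after_choice_vs_single",
                         "mean_diff": float(d.mean()),
                         "sd": float(d.std(ddof=1)) if len(d) > 1 else np.nan,
                         "n_participants": int(len(d))})
        # direction of the previous single-trial
        sub = grp[(grp["prev_type"] == "single")
                  & grp["prev_direction"].isin(["same", "opposite"])]
        m = sub.pivot_table(index="participant_id", columns="prev_direction",
                            values="latency_ms")
        if {"same", "opposite"} <= set(m.columns):
            d = (m["opposite"] - m["same"]).dropna()
            rows.append({"reward_level": level,
                         "contrast": "after_opposite_vs_same",
                         "mean_diff": float(d.mean()),
                         "sd": float(d.std(ddof=1)) if len(d) > 1 else np.nan,
                         "n_participants": int(len(d))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# parametric tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    sd_diff: float


def paired_t(x, y) -> PairedTResult:
    """Classical two-sided paired t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 2")
    d = x - y
    sd = float(d.std(ddof=1))
    if sd == 0:
        raise ValueError("zero-variance differences: t undefined")
    res = sps.ttest_rel(x, y)
    return PairedTResult(t=float(res.statistic), df=x.size - 1,
                         p=float(res.pvalue), mean_diff=float(d.mean()), sd_diff=sd)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison alpha level."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def jzs_bf_paired(t: float, n: int, rscale: float = DEFAULT_RSCALE) -> float:
    """JZS Bayes factor (BF10) for a one-sample / paired t statistic.

    Cauchy prior with scale ``rscale`` on the standardized effect size
    (the contemporary BayesFactor-package default sqrt(2)/2), evaluated by
    numerical integration over the inverse-gamma mixing variable g:

        BF10 = int_0^inf (1+ngr^2)^(-1/2) (1 + t^2/((1+ngr^2) nu))^(-(nu+1)/2)
               (2 pi)^(-1/2) g^(-3/2) e^(-1/(2g)) dg
               / (1 + t^2/nu)^(-(nu+1)/2),   nu = n - 1.
    """
    if not (np.isfinite(t) and np.isfinite(rscale)):
        raise ValueError("t and rscale must be finite")
    if n < 2:
        raise ValueError("n must be >= 2")
    nu = n - 1
    r2 = rscale * rscale

    def integrand(g):
        a = 1.0 + n * g * r2
        return (a ** -0.5 * (1.0 + t * t / (a * nu)) ** (-(nu + 1) / 2.0)
                * (2.0 * math.pi) ** -0.5 * g ** -1.5 * math.exp(-1.0 / (2.0 * g)))

    num, _ = integrate.quad(integrand, 0.0, np.inf)
    den = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    return num / den


# ---------------------------------------------------------------------------
# ANOVA (pingouin-backed)
# ---------------------------------------------------------------------------

def _check_balanced(data, dv, factors, subject):
    counts = data.groupby([subject, *factors], sort=False)[dv].count()
    if counts.empty or counts.nunique() != 1:
        raise ValueError("unbalanced or incomplete design: every subject needs "
                         "the same number of observations in every cell")
    n_sub = data[subject].nunique()
    full = n_sub * int(np.prod([data[f].nunique() for f in factors]))
    if len(counts) != full:
        raise ValueError("missing cells: design is not complete")


def rm_anova(data: pd.DataFrame, dv: str, within: Sequence[str] | str,
             subject: str = "participant_id") -> pd.DataFrame:
    """Repeated-measures ANOVA (1 or 2 within factors) with GG correction.

    Returns one row per effect with columns ``effect, F, df1, df2, p_unc,
    eps, p_gg``.  Both the uncorrected and the Greenhouse-Geisser-corrected
    p-value are always reported.  Requires a balanced complete design.
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("within must name 1 or 2 factors")
    _check_balanced(data, dv, within, subject)
    if data[subject].nunique() < 2:
        raise ValueError("need >= 2 subjects")
    with warnings.catch_warnings():
        # zero-variance cells make pingouin emit 0/0 warnings; the
        # degenerate result is mapped to F = 0, p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.rm_anova(data=data, dv=dv,
                          within=within if len(within) > 1 else within[0],
                          subject=subject, correction=True, detailed=True)
    rows = []
    if "ddof1" in res.columns:  # two-way layout
        for _, r in res.iterrows():
            rows.append(_anova_row(r["Source"], r["SS"], r["F"], r["ddof1"],
                                   r["ddof2"], r["p_unc"],
                                   r.get("eps", np.nan), r.get("p_GG_corr", np.nan)))
    else:  # one-way detailed layout: effect row + Error row
        eff = res[res["Source"] != "Error"].iloc[0]
        err = res[res["Source"] == "Error"].iloc[0]
        # on zero-variance data pingouin omits the F/p columns entirely
        rows.append(_anova_row(eff["Source"], eff["SS"], eff.get("F", np.nan),
                               eff["DF"], err["DF"], eff.get("p_unc", np.nan),
                               eff.get("eps", np.nan),
                               eff.get("p_GG_corr", np.nan)))
    return pd.DataFrame(rows)


def _anova_row(effect, ss, F, df1, df2, p_unc, eps, p_gg):
    # a factor with no variance anywhere yields 0/0; report F = 0, p = 1
    if not np.isfinite(F) and np.isclose(ss, 0.0):
        F, p_unc, p_gg, eps = 0.0, 1.0, 1.0, 1.0
    return {"effect": effect, "F": float(F), "df1": int(df1), "df2": int(df2),
            "p_unc": float(p_unc), "eps": float(eps) if np.isfinite(eps) else np.nan,
            "p_gg": float(p_gg) if np.isfinite(p_gg) else np.nan}


def mixed_anova(data: pd.DataFrame, dv: str, within: str, between: str,
                subject: str = "participant_id") -> pd.DataFrame:
    """Two-way ANOVA with one within- and one between-subject factor."""
    _check_balanced(data, dv, [within], subject)
    res = pg.mixed_anova(data=data, dv=dv, within=within, between=between,
                         subject=subject, correction=True)
    rows = []
    for _, r in res.iterrows():
        rows.append(_anova_row(r["Source"], r["SS"], r["F"], r["DF1"], r["DF2"],
                               r["p_unc"], r.get("eps", np.nan),
                               r.get("p_GG_corr", np.nan)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    """Signed-rank test summary.

    ``W`` is the sum of ranks of the negative differences; ``z`` is the
    normal approximation without continuity correction, so a sample of
    uniformly positive differences gives a negative z.  ``p_exact`` is the
    two-sided exact tail probability from the signed-rank null (reported
    for n <= 25 and no rank ties).
    """

    W: float
    z: float
    p_approx: float
    p_exact: float | None
    n: int


def _signed_rank_null_cdf(n: int) -> np.ndarray:
    """Null pmf of the signed-rank sum via dynamic-programming convolution
    over the 2^n sign patterns."""
    m = n * (n + 1) // 2
    counts = np.zeros(m + 1)
    counts[0] = 1.0
    for rank in range(1, n + 1):
        shifted = np.zeros_like(counts)
        shifted[rank:] = counts[:-rank] if rank else counts
        counts = counts + shifted
    return counts / 2.0 ** n


def wilcoxon_signed_rank(differences) -> WilcoxonResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking; ties get average ranks.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = d.size
    if n < 1:
        raise ValueError("all differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_neg = float(ranks[d < 0].sum())
    mean = n * (n + 1) / 4.0
    sd = math.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)
    z = (w_neg - mean) / sd
    p_approx = float(2.0 * sps.norm.sf(abs(z)))

    p_exact = None
    has_ties = np.unique(np.abs(d)).size < n
    if n <= 25 and not has_ties:
        pmf = _signed_rank_null_cdf(n)
        w = int(round(w_neg))
        lower = float(pmf[:w + 1].sum())
        upper = float(pmf[w:].sum())
        p_exact = float(min(1.0, 2.0 * min(lower, upper)))
    return WilcoxonResult(W=w_neg, z=float(z), p_approx=p_approx,
                          p_exact=p_exact, n=n)


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    df: int
    p: float


def friedman(data) -> FriedmanResult:
    """Friedman test on a participants x conditions matrix."""
    mat = np.asarray(data, dtype=float)
    if mat.ndim != 2 or mat.shape[1] < 2:
        raise ValueError("need a 2-d matrix with >= 2 condition columns")
    if np.any(np.isnan(mat)):
        raise ValueError("missing cells are not allowed")
    if np.all(mat.min(axis=1) == mat.max(axis=1)):
        # every row completely tied: no between-condition rank variation
        return FriedmanResult(chi2=0.0, df=mat.shape[1] - 1, p=1.0)
    chi2, p = sps.friedmanchisquare(*mat.T)
    return FriedmanResult(chi2=float(chi2), df=mat.shape[1] - 1, p=float(p))
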