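"""Behavioral analysis: response pruning, repeated-measures ANOVAs with
Tukey-Kramer post-hocs, per-participant adaptation magnitude, and the
a-priori sample-size computation.

Estimates are analysed per participant and condition after a quartile-based
pruning of dialing errors: responses above twice the upper quartile or below
half the lower quartile of that participant/condition distribution are
discarded. ("Below twice the lower quartile" is read as the reciprocal
bound Q1/2 — the literal reading x < 2*Q1 would discard the bulk of normal
responses.) Quartiles use linear interpolation (type 7).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class PrunedEstimates:
    kept: np.ndarray
    removed_fraction: float          # percent of input values removed
    bounds_used: tuple               # (lower, upper) in dots


@dataclass
class AnovaResult:
    """Repeated-measures ANOVA effect: F, (df1, df2), p, effect sizes and
    (for one-way analyses) Tukey-Kramer adjusted pairwise p-values."""
    F: float
    df: tuple
    p: float
    eta_squared: float               # SS_effect / SS_total
    eta_squared_partial: float       # SS_effect / (SS_effect + SS_error)
    posthoc: dict | None = None      # (level_a, level_b) -> adjusted p


@dataclass(frozen=True)
class PowerSpec:
    """A-priori power computation for a one-way within-subject ANOVA,
    noncentral-F framework with lambda = f^2 * n * m / (1 - rho)."""
    f: float = 0.30                  # Cohen's f
    alpha: float = 0.05
    power: float = 0.90
    n_measurements: int = 3
    corr_rep_measures: float = 0.5   # rho, correlation among repeated measures
    nonsphericity: float = 1.0       # epsilon

    def __post_init__(self):
        if self.f <= 0:
            raise ValueError("effect size f must be > 0")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if not 0 <= self.corr_rep_measures < 1:
            raise ValueError("correlation must be in [0, 1)")
        if not 0 < self.nonsphericity <= 1:
            raise ValueError("nonsphericity epsilon must be in (0, 1]")


# --------------------------------------------------------------------------
# pruning
# --------------------------------------------------------------------------

def prune_estimates(values) -> PrunedEstimates:
    """Discard estimates outside [Q1/2, 2*Q3] of the response distribution."""
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValueError("need at least 4 values to define quartiles")
    q1, q3 = np.quantile(values, [0.25, 0.75])  # linear interpolation
    lower, upper = q1 / 2.0, 2.0 * q3
    keep = (values >= lower) & (values <= upper)
    removed = 100.0 * (1.0 - keep.mean())
    return PrunedEstimates(kept=values[keep], removed_fraction=removed,
                           bounds_used=(lower, upper))


def participant_condition_means(table: pd.DataFrame, numerosity: int | None = None,
                                prune: bool = True) -> pd.DataFrame:
    """Participant x condition mean estimates (rows: participant).

    Restricted to one test numerosity when given; pruning is applied per
    participant/condition cell before averaging.
    """
    df = table if numerosity is None else table[table["numerosity"] == numerosity]
    if df.empty:
        raise ValueError(f"no trials for numerosity {numerosity}")

    def cell_mean(v):
        v = np.asarray(v, dtype=float)
        return prune_estimates(v).kept.mean() if (prune and v.size >= 4) else v.mean()

    means = (df.groupby(["participant", "condition"], observed=True)["estimate"]
               .apply(cell_mean).unstack("condition"))
    if means.isna().any().any():
        p, c = next(zip(*np.where(means.isna())))
        raise ValueError(
            f"missing cell: participant {means.index[p]} has no trials in "
            f"condition {means.columns[c]!r}")
    return means


# --------------------------------------------------------------------------
# repeated-measures ANOVA (from-scratch sums of squares)
# --------------------------------------------------------------------------

def _oneway_rm_from_matrix(y: np.ndarray, levels) -> AnovaResult:
    """One-way within-subject ANOVA on an n x k matrix of condition means."""
    n, k = y.shape
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    ss_cond = n * ((y.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((y.mean(axis=1) - grand) ** 2).sum()
    ss_err = ss_total - ss_cond - ss_subj
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_err = ss_err / df2
    F = (ss_cond / df1) / ms_err if ms_err > 0 else 0.0
    if ss_cond <= 1e-12 * max(ss_total, 1.0):
        F = 0.0
    p = stats.f.sf(F, df1, df2)

    # Tukey-Kramer on the RM error term (balanced -> plain Tukey HSD)
    posthoc = {}
    se = np.sqrt(ms_err / n)
    cond_means = y.mean(axis=0)
    for i, j in combinations(range(k), 2):
        if se > 0:
            q = abs(cond_means[i] - cond_means[j]) / se
            padj = stats.studentized_range.sf(q, k, df2)
        else:
            padj = 1.0
        posthoc[(levels[i], levels[j])] = float(min(1.0, padj))

    return AnovaResult(
        F=float(F), df=(df1, df2), p=float(p),
        eta_squared=float(ss_cond / ss_total) if ss_total > 0 else 0.0,
        eta_squared_partial=(float(ss_cond / (ss_cond + ss_err))
                             if (ss_cond + ss_err) > 0 else 0.0),
        posthoc=posthoc)


def rm_anova_oneway(table: pd.DataFrame, numerosity: int | None = 30,
                    prune: bool = True) -> AnovaResult:
    """One-way RM-ANOVA over conditions (Baseline, Adaptation, Neutral) on
    per-participant mean estimates of the test numerosity."""
    means = participant_condition_means(table, numerosity=numerosity, prune=prune)
    return _oneway_rm_from_matrix(means.to_numpy(), list(means.columns))


def rm_anova_twoway(table: pd.DataFrame,
                    conditions=("Baseline", "Neutral"),
                    numerosities=(22, 26, 35, 41),
                    prune: bool = True) -> dict:
    """Two-way within-subject ANOVA Condition x Numerosity on filling-trial
    estimates. Returns {'condition', 'numerosity', 'interaction'} effects,
    each tested against its own subject-interaction error term."""
    df = table[table["condition"].isin(conditions)
               & table["numerosity"].isin(numerosities)]
    if df.empty:
        raise ValueError("no trials match the requested design")

    def cell_mean(v):
        v = np.asarray(v, dtype=float)
        return prune_estimates(v).kept.mean() if (prune and v.size >= 4) else v.mean()

    cells = (df.groupby(["participant", "condition", "numerosity"], observed=True)
               ["estimate"].apply(cell_mean))
    participants = sorted(df["participant"].unique())
    n, a, b = len(participants), len(conditions), len(numerosities)
    y = np.empty((n, a, b))
    for ip, p in enumerate(participants):
        for ia, c in enumerate(conditions):
            for ib, m in enumerate(numerosities):
                key = (p, c, m)
                if key not in cells.index:
                    raise ValueError(f"incomplete design: missing cell {key}")
                y[ip, ia, ib] = cells.loc[key]

    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    mA = y.mean(axis=(0, 2)); mB = y.mean(axis=(0, 1)); mS = y.mean(axis=(1, 2))
    ss_A = n * b * ((mA - grand) ** 2).sum()
    ss_B = n * a * ((mB - grand) ** 2).sum()
    ss_S = a * b * ((mS - grand) ** 2).sum()
    mAB = y.mean(axis=0); mAS = y.mean(axis=2); mBS = y.mean(axis=1)
    ss_AB = n * ((mAB - mA[:, None] - mB[None, :] + grand) ** 2).sum()
    ss_AS = b * ((mAS - mS[:, None] - mA[None, :] + grand) ** 2).sum()
    ss_BS = a * ((mBS - mS[:, None] - mB[None, :] + grand) ** 2).sum()
    ss_ABS = ss_total - ss_A - ss_B - ss_S - ss_AB - ss_AS - ss_BS

    def effect(ss, df1, ss_err, df_err):
        ms_err = ss_err / df_err
        F = (ss / df1) / ms_err if ms_err > 0 else 0.0
        if ss <= 1e-12 * max(ss_total, 1.0):
            F = 0.0
        return AnovaResult(
            F=float(F), df=(df1, df_err), p=float(stats.f.sf(F, df1, df_err)),
            eta_squared=float(ss / ss_total) if ss_total > 0 else 0.0,
            eta_squared_partial=(float(ss / (ss + ss_err))
                                 if (ss + ss_err) > 0 else 0.0))

    return {
        "condition": effect(ss_A, a - 1, ss_AS, (n - 1) * (a - 1)),
        "numerosity": effect(ss_B, b - 1, ss_BS, (n - 1) * (b - 1)),
        "interaction": effect(ss_AB, (a - 1) * (b - 1), ss_ABS,
                              (n - 1) * (a - 1) * (b - 1)),
    }


def adaptation_magnitude(table: pd.DataFrame, numerosity: int | None = 30,
                         prune: bool = True) -> pd.DataFrame:
    """Per-participant adaptation effect: Neutral mean - Adaptation mean,
    and the percent change 100 * (Neutral - Adaptation) / Neutral."""
    means = participant_condition_means(table, numerosity=numerosity, prune=prune)
    for cond in ("Neutral", "Adaptation"):
        if cond not in means.columns:
            raise ValueError(f"condition {cond!r} absent from table")
    if (means["Neutral"] == 0).any():
        raise ValueError("zero Neutral mean; percent change undefined")
    diff = means["Neutral"] - means["Adaptation"]
    return pd.DataFrame({
        "neutral_mean": means["Neutral"],
        "adaptation_mean": means["Adaptation"],
        "difference": diff,
        "percent": 100.0 * diff / means["Neutral"],
    })


# --------------------------------------------------------------------------
# power analysis
# --------------------------------------------------------------------------

def rm_anova_power(n: int, spec: PowerSpec) -> float:
    """Power of the within-factor RM-ANOVA F-test at sample size n."""
    m, eps = spec.n_measurements, spec.nonsphericity
    lam = spec.f ** 2 * n * m / (1.0 - spec.corr_rep_measures)
    df1 = (m - 1) * eps
    df2 = (n - 1) * (m - 1) * eps
    fcrit = stats.f.isf(spec.alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def required_sample_size(spec: PowerSpec, n_max: int = 10000) -> int:
    """Smallest n whose RM-ANOVA power reaches the target."""
    for n in range(2, n_max + 1):
        if rm_anova_power(n, spec) >= spec.power:
            return n
    raise ValueError(f"target power {spec.power} not reachable with n <= {n_max}")
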