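"""Model / Results presentation of the two statistical analyses.

`BehavioralAdaptation` fits the behavioral side (pruning, condition means,
repeated-measures ANOVAs with Tukey-Kramer post-hocs, per-participant
adaptation magnitude); `PointwiseContrast` fits the electrophysiological
side (time-point-wise paired bootstrap with FDR and persistence control).
Both follow the familiar pattern: build the model from data, call `fit()`,
read estimates and diagnostics off the results object or print `summary()`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import behavior as bh
from . import resampling as rs
from .containers import ErpWaveform
from .preprocess import cluster_average


class BehavioralAdaptation:
    """Behavioral numerosity-adaptation model over a trial table.

    Parameters
    ----------
    table : DataFrame
        Columns participant, condition, numerosity, estimate (block and
        hemifield are carried along but not modelled).
    test_numerosity : int
        The numerosity whose estimates carry the adaptation contrast.
    """

    def __init__(self, table: pd.DataFrame, test_numerosity: int = 30):
        required = {"participant", "condition", "numerosity", "estimate"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"table is missing columns: {sorted(missing)}")
        self.table = table
        self.test_numerosity = test_numerosity

    @classmethod
    def from_dataframe(cls, table, test_numerosity: int = 30):
        return cls(table, test_numerosity)

    @classmethod
    def from_csv(cls, path, test_numerosity: int = 30):
        return cls(pd.read_csv(path), test_numerosity)

    def fit(self, prune: bool = True) -> "BehavioralAdaptationResults":
        means = bh.participant_condition_means(
            self.table, numerosity=self.test_numerosity, prune=prune)
        anova = bh.rm_anova_oneway(self.table, numerosity=self.test_numerosity,
                                   prune=prune)
        magnitudes = bh.adaptation_magnitude(
            self.table, numerosity=self.test_numerosity, prune=prune)

        fillings = sorted(set(self.table["numerosity"]) - {self.test_numerosity})
        twoway = None
        if len(fillings) >= 2:
            twoway = bh.rm_anova_twoway(self.table, numerosities=tuple(fillings),
                                        prune=prune)
        return BehavioralAdaptationResults(
            model=self, participant_means=means, anova=anova,
            anova_twoway=twoway, magnitudes=magnitudes)


@dataclass
class BehavioralAdaptationResults:
    model: BehavioralAdaptation
    participant_means: pd.DataFrame       # participant x condition
    anova: bh.AnovaResult                 # one-way Condition RM-ANOVA
    anova_twoway: dict | None             # Condition x Numerosity effects
    magnitudes: pd.DataFrame              # per-participant adaptation effect

    @property
    def condition_means(self) -> pd.Series:
        return self.participant_means.mean(axis=0)

    @property
    def condition_sem(self) -> pd.Series:
        return self.participant_means.sem(axis=0)

    @property
    def mean_underestimation_percent(self) -> float:
        return float(self.magnitudes["percent"].mean())

    def summary(self) -> str:
        a = self.anova
        lines = ["Behavioral numerosity adaptation", "=" * 40]
        for cond, m in self.condition_means.items():
            lines.append(f"  {cond:<12} mean estimate {m:6.1f} dots "
                         f"(SEM {self.condition_sem[cond]:.2f})")
        lines.append(f"  Condition RM-ANOVA: F({a.df[0]},{a.df[1]}) = {a.F:.2f}, "
                     f"p = {a.p:.3g}, eta2 = {a.eta_squared:.3f}")
        for (ca, cb), p in (a.posthoc or {}).items():
            lines.append(f"    {ca} vs {cb}: adjusted p = {p:.3g}")
        lines.append(f"  Adaptation magnitude: "
                     f"{self.mean_underestimation_percent:.1f}% underestimation "
                     f"(Neutral vs Adaptation), "
                     f"{int((self.magnitudes['difference'] > 0).sum())}/"
                     f"{len(self.magnitudes)} participants positive")
        if self.anova_twoway is not None:
            c = self.anova_twoway["condition"]
            i = self.anova_twoway["interaction"]
            lines.append(f"  Filling trials Condition effect: "
                         f"F({c.df[0]},{c.df[1]}) = {c.F:.3f}, p = {c.p:.3g}")
            lines.append(f"  Condition x Numerosity interaction: "
                         f"F({i.df[0]},{i.df[1]}) = {i.F:.3f}, p = {i.p:.3g}")
        return "\n".join(lines)


class PointwiseContrast:
    """Point-wise bootstrap contrast between two paired conditions.

    Built either from matrices (participants x time, aligned rows) or from
    per-participant ERPs via :meth:`from_erps`, which cluster-averages each
    participant's waveform and restricts testing to post-stimulus samples.
    """

    def __init__(self, cond_a: np.ndarray, cond_b: np.ndarray,
                 time_ms=None, pair=None, cluster=None):
        self.cond_a = np.atleast_2d(np.asarray(cond_a, dtype=float))
        self.cond_b = np.atleast_2d(np.asarray(cond_b, dtype=float))
        if self.cond_a.shape != self.cond_b.shape:
            raise ValueError("condition matrices must share shape")
        self.time_ms = (np.arange(self.cond_a.shape[1], dtype=float)
                        if time_ms is None else np.asarray(time_ms, dtype=float))
        self.pair = pair
        self.cluster = cluster

    @classmethod
    def from_erps(cls, erps: dict, pair, cluster="posterior",
                  post_stimulus_only: bool = True) -> "PointwiseContrast":
        cond_a, cond_b = pair
        rows_a, rows_b, time_ms = [], [], None
        for p in sorted(erps):
            wa, wb = erps[p][cond_a], erps[p][cond_b]
            time_ms = wa.time_ms if time_ms is None else time_ms
            rows_a.append(cluster_average(wa, cluster))
            rows_b.append(cluster_average(wb, cluster))
        a, b = np.array(rows_a), np.array(rows_b)
        if post_stimulus_only:
            sel = time_ms >= 0
            a, b, time_ms = a[:, sel], b[:, sel], time_ms[sel]
        return cls(a, b, time_ms=time_ms, pair=tuple(pair), cluster=cluster)

    def fit(self, n_boot: int = 20000, alpha: float = 0.05, min_run: int = 4,
            seed=None) -> "PointwiseContrastResults":
        res = rs.pointwise_bootstrap(self.cond_a, self.cond_b, n_boot=n_boot,
                                     seed=seed, time_ms=self.time_ms)
        res.p_fdr = rs.fdr_correct(res.p_raw, alpha)
        res.sig_mask = rs.persistence_filter(res.p_fdr < alpha, min_run)
        res.min_run = min_run
        res.alpha = alpha
        res.pair = self.pair
        res.cluster = self.cluster
        se = (self.cond_a - self.cond_b).std(axis=0, ddof=1)
        se = se / np.sqrt(self.cond_a.shape[0])
        return PointwiseContrastResults(model=self, pointwise=res, se=se)


@dataclass
class PointwiseContrastResults:
    model: PointwiseContrast
    pointwise: rs.PointwiseTestResult
    se: np.ndarray                         # SEM of the paired difference

    def __getattr__(self, name):
        # delegate time_ms / mean_diff / p_raw / p_fdr / sig_mask / ...
        return getattr(self.pointwise, name)

    def significant_windows(self) -> list:
        return self.pointwise.significant_windows()

    def summary(self) -> str:
        r = self.pointwise
        pair = f"{r.pair[0]} - {r.pair[1]}" if r.pair else "A - B"
        cluster = r.cluster or "all channels"
        lines = [f"Point-wise bootstrap contrast: {pair} ({cluster})",
                 "=" * 52,
                 f"  {r.time_ms.size} time points, {r.n_boot} bootstrap "
                 f"iterations, alpha = {r.alpha}, "
                 f"persistence >= {r.min_run} samples"]
        wins = self.significant_windows()
        if wins:
            for w0, w1 in wins:
                sel = (r.time_ms >= w0) & (r.time_ms <= w1)
                lines.append(f"  significant {w0:.0f}-{w1:.0f} ms, "
                             f"mean diff {r.mean_diff[sel].mean():+.2f} uV")
        else:
            lines.append("  no significant windows")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Difference waveform with SEM band and significant samples."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        r = self.pointwise
        ax.plot(r.time_ms, r.mean_diff, color="crimson", label="mean difference")
        ax.fill_between(r.time_ms, r.mean_diff - self.se, r.mean_diff + self.se,
                        color="crimson", alpha=0.25, linewidth=0)
        if r.sig_mask is not None and r.sig_mask.any():
            ax.plot(r.time_ms[r.sig_mask],
                    np.zeros(r.sig_mask.sum()), "r.", label="significant")
        ax.axhline(0, color="k", linewidth=0.6)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("amplitude difference (uV)")
        ax.legend(frameon=False)
        return ax
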