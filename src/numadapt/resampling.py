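"""Non-parametric ERP statistics: time-point-wise paired bootstrap with
FDR and temporal-persistence control, window amplitudes and their bootstrap
distributions, electrode-cluster topographies, and brain-behavior rank
correlation.

The testing scheme: for each post-stimulus time point, participants are
resampled with replacement (20,000 iterations by default) and the mean
paired condition difference is recomputed, giving a two-sided bootstrap p
per time point; Benjamini-Hochberg FDR is applied across the post-stimulus
time points of the contrast, and surviving points are reported only when
they form runs of at least four consecutive samples (16 ms at 250 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ErpWaveform
from .montage import cluster_indices
from .preprocess import cluster_average

CONTRAST_PAIRS = (("Baseline", "Adaptation"), ("Baseline", "Neutral"),
                  ("Adaptation", "Neutral"))


@dataclass
class PointwiseTestResult:
    """Per-time-point contrast between two paired conditions."""

    time_ms: np.ndarray
    mean_diff: np.ndarray            # condA - condB, microvolts
    p_raw: np.ndarray
    p_fdr: np.ndarray | None = None
    sig_mask: np.ndarray | None = None
    n_boot: int = 0
    min_run: int = 0
    alpha: float = 0.05
    pair: tuple | None = None
    cluster: str | None = None

    def significant_windows(self) -> list:
        """Contiguous significant intervals as (start_ms, end_ms) pairs."""
        if self.sig_mask is None or not self.sig_mask.any():
            return []
        out, mask, t = [], self.sig_mask, self.time_ms
        idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
        for start, stop in zip(idx[::2], idx[1::2]):
            out.append((float(t[start]), float(t[stop - 1])))
        return out


@dataclass
class WindowAmplitude:
    window_ms: tuple
    value: float                     # microvolts
    cluster: str | None = None
    participant: str | int = ""
    condition: str = ""


@dataclass
class WindowBootstrap:
    """Bootstrap distribution of a mean paired window-amplitude difference."""
    distribution: np.ndarray
    mean_diff: float
    ci: tuple                        # central percentile interval
    null_excluded: bool              # 0 outside the central interval
    n_boot: int


# --------------------------------------------------------------------------
# core resampling
# --------------------------------------------------------------------------

def _bootstrap_means(diff: np.ndarray, n_boot: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Bootstrap distribution of the participant-mean difference.

    Resampling participants with replacement is equivalent to drawing
    multinomial resample counts, which keeps memory at n_boot x n_times.
    """
    n = diff.shape[0]
    counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)
    return counts @ diff / n


def bootstrap_p_two_sided(boot: np.ndarray, n_boot: int) -> np.ndarray:
    """2 * min(tail proportions) with the (count+1)/(n_boot+1) correction."""
    p_le = ((boot <= 0).sum(axis=0) + 1.0) / (n_boot + 1.0)
    p_ge = ((boot >= 0).sum(axis=0) + 1.0) / (n_boot + 1.0)
    return np.minimum(1.0, 2.0 * np.minimum(p_le, p_ge))


def pointwise_bootstrap(cond_a: np.ndarray, cond_b: np.ndarray,
                        n_boot: int = 20000, seed=None,
                        time_ms: np.ndarray | None = None) -> PointwiseTestResult:
    """Per-time-point bootstrap test of the paired difference cond_a - cond_b.

    Parameters
    ----------
    cond_a, cond_b : ndarray (n_participants, n_times)
        Row i of both matrices is the same participant.
    n_boot : int
        Bootstrap iterations (>= 1000).
    seed : int or Generator, optional

    Returns the uncorrected result (``p_fdr`` and ``sig_mask`` unset).
    """
    a = np.atleast_2d(np.asarray(cond_a, dtype=float))
    b = np.atleast_2d(np.asarray(cond_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError(f"condition shapes differ: {a.shape} vs {b.shape}")
    if n_boot < 1000:
        raise ValueError("n_boot must be >= 1000")
    if a.shape[0] < 5:
        import logging
        logging.getLogger(__name__).warning(
            "only %d participants; bootstrap p-values are coarse", a.shape[0])
    rng = np.random.default_rng(seed)
    diff = a - b
    boot = _bootstrap_means(diff, n_boot, rng)
    p = bootstrap_p_two_sided(boot, n_boot)
    if time_ms is None:
        time_ms = np.arange(a.shape[1], dtype=float)
    return PointwiseTestResult(time_ms=np.asarray(time_ms, dtype=float),
                               mean_diff=diff.mean(axis=0), p_raw=p,
                               n_boot=n_boot)


def fdr_correct(p_raw, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    return multipletests(p, alpha=alpha, method="fdr_bh")[1]


def persistence_filter(sig, min_run: int = 4) -> np.ndarray:
    """Zero out significant runs shorter than ``min_run`` consecutive
    samples; never adds new significant points."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    mask = np.asarray(sig, dtype=bool).copy()
    idx = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    for start, stop in zip(idx[::2], idx[1::2]):
        if stop - start < min_run:
            mask[start:stop] = False
    return mask


def contrast_conditions(erps: dict, pair, cluster="posterior",
                        n_boot: int = 20000, alpha: float = 0.05,
                        min_run: int = 4, seed=None,
                        post_stimulus_only: bool = True) -> PointwiseTestResult:
    """Full point-wise contrast between two conditions on a cluster average.

    Parameters
    ----------
    erps : dict participant -> dict condition -> ErpWaveform
    pair : (condition_a, condition_b)
    cluster : cluster name or channel list
    post_stimulus_only : bool
        Test from stimulus onset to the end of the epoch only.
    """
    cond_a, cond_b = pair
    rows_a, rows_b, time_ms = [], [], None
    for p in sorted(erps):
        by_cond = erps[p]
        for cond in pair:
            if cond not in by_cond:
                raise ValueError(f"participant {p} is missing condition {cond!r}")
        wa, wb = by_cond[cond_a], by_cond[cond_b]
        if time_ms is None:
            time_ms = wa.time_ms
        rows_a.append(cluster_average(wa, cluster))
        rows_b.append(cluster_average(wb, cluster))
    a, b = np.array(rows_a), np.array(rows_b)
    if post_stimulus_only:
        sel = time_ms >= 0
        a, b, time_ms = a[:, sel], b[:, sel], time_ms[sel]
    res = pointwise_bootstrap(a, b, n_boot=n_boot, seed=seed, time_ms=time_ms)
    res.p_fdr = fdr_correct(res.p_raw, alpha)
    res.sig_mask = persistence_filter(res.p_fdr < alpha, min_run)
    res.min_run = min_run
    res.alpha = alpha
    res.pair = tuple(pair)
    res.cluster = cluster if isinstance(cluster, str) else tuple(cluster)
    return res


# --------------------------------------------------------------------------
# window amplitudes and distributions
# --------------------------------------------------------------------------

def _window_mask(time_ms: np.ndarray, window) -> np.ndarray:
    start, end = window
    if start >= end:
        raise ValueError("window start must precede end")
    if start < time_ms[0] or end > time_ms[-1]:
        raise ValueError(f"window {window} outside epoch "
                         f"({time_ms[0]:g}..{time_ms[-1]:g} ms)")
    return (time_ms >= start) & (time_ms <= end)


def window_amplitude(erp: ErpWaveform, window=(200.0, 250.0),
                     cluster="posterior") -> WindowAmplitude:
    """Mean cluster-average amplitude over a time window."""
    mask = _window_mask(erp.time_ms, window)
    wave = cluster_average(erp, cluster)
    return WindowAmplitude(window_ms=tuple(window),
                           value=float(wave[mask].mean()),
                           cluster=cluster if isinstance(cluster, str) else None,
                           participant=erp.participant, condition=erp.condition)


def window_bootstrap_distribution(amplitudes_a, amplitudes_b,
                                  n_boot: int = 20000, seed=None,
                                  ci_level: float = 0.95) -> WindowBootstrap:
    """Bootstrap distribution of the mean paired difference of window
    amplitudes, with a central percentile interval and a flag for whether
    the null value 0 lies outside it."""
    a = np.asarray(amplitudes_a, dtype=float)
    b = np.asarray(amplitudes_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("amplitude vectors must be 1D and paired")
    rng = np.random.default_rng(seed)
    boot = _bootstrap_means((a - b)[:, None], n_boot, rng)[:, 0]
    q = 100 * (1 - ci_level) / 2
    lo, hi = np.percentile(boot, [q, 100 - q])
    return WindowBootstrap(distribution=boot, mean_diff=float((a - b).mean()),
                           ci=(float(lo), float(hi)),
                           null_excluded=bool(0 < lo or 0 > hi), n_boot=n_boot)


def brain_behavior_correlation(behavior_diff, eeg_diff):
    """Spearman rank correlation between per-participant behavioral and
    electrophysiological adaptation effects. Returns (rho, p)."""
    x = np.asarray(behavior_diff, dtype=float)
    y = np.asarray(eeg_diff, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1D and paired")
    if x.size < 5:
        raise ValueError("need at least 5 participants")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def topography_difference(erps: dict, pair, windows) -> np.ndarray:
    """Grand-average per-channel condition difference in each time window.

    Returns an (n_channels, n_windows) matrix of cond_a - cond_b means.
    """
    cond_a, cond_b = pair
    diffs = []
    for p in sorted(erps):
        wa, wb = erps[p][cond_a], erps[p][cond_b]
        diffs.append(wa.data - wb.data)
    grand = np.mean(diffs, axis=0)
    time_ms = next(iter(erps.values()))[cond_a].time_ms
    out = np.empty((grand.shape[0], len(windows)))
    for j, window in enumerate(windows):
        out[:, j] = grand[:, _window_mask(time_ms, window)].mean(axis=1)
    return out
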