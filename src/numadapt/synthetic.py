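"""Synthetic behavioral estimates and epoched EEG for numerosity adaptation.

The generators emulate the statistical structure of a numerosity-adaptation
experiment: verbal estimates of a 30-dot test stimulus that are accurate at
Baseline and after a Neutral adaptor but underestimated by ~20% after a
high-numerosity adaptor, and 30-channel epoched EEG in which the same
adaptation selectively reduces the posterior P2p component (~200-250 ms)
over left-posterior sensors, while physical numerosity changes modulate the
N1 bilaterally and the P2p over right-posterior sensors.

EEG epochs are built from a parametric forward model: a sum of Gaussian
temporal kernels (one per ERP component) with fixed spatial topographies,
plus 1/f background noise, an alpha-band sinusoid with random phase, and
white trial-to-trial amplitude jitter. This is an effect-structure emulator,
not a biophysical head-model simulation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import EpochSet
from .montage import CHANNELS_30, channel_positions

CONDITIONS = ("Baseline", "Adaptation", "Neutral")
NUMEROSITY_CONDITIONS = ("LowNum", "HighNum")


# --------------------------------------------------------------------------
# behavioral generator
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BehavioralGenSpec:
    """Parameters of the behavioral estimate generator.

    Estimates are integer dot counts: condition mean + participant bias +
    Gaussian trial noise, rounded and truncated at 1 dot. The adaptation
    effect is multiplicative: the Adaptation mean is
    ``true_numerosity * (1 - underestimation_fraction)``; Baseline and
    Neutral share the veridical mean.
    """

    n_participants: int = 25
    true_numerosity: int = 30
    underestimation_fraction: float = 0.20
    participant_bias_sd: float = 1.5   # dots
    trial_noise_sd: float = 4.0        # dots, ~Weber fraction 0.15 x 30
    trials_per_condition: int = 80     # verbal reports per condition, test numerosity
    filling_numerosities: tuple = (22, 26, 35, 41)
    filling_trials_per_cell: int = 8   # reports per condition x filling numerosity
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.underestimation_fraction < 1:
            raise ValueError("underestimation_fraction must be in [0, 1)")
        if self.trial_noise_sd <= 0:
            raise ValueError("trial_noise_sd must be > 0")
        if self.n_participants < 1 or self.trials_per_condition < 1:
            raise ValueError("counts must be >= 1")


def generate_behavior(spec: BehavioralGenSpec,
                      participant_effect: np.ndarray | None = None) -> pd.DataFrame:
    """Generate a trial table of verbal numerosity estimates.

    Parameters
    ----------
    spec : BehavioralGenSpec
    participant_effect : ndarray, optional
        Per-participant multiplicative scaling of the underestimation
        fraction (length ``n_participants``, mean ~1). Used to couple the
        behavioral and electrophysiological adaptation effects through a
        shared latent; default is no scaling.

    Returns
    -------
    DataFrame with columns participant, block, condition, numerosity,
    hemifield, estimate. One row per reported trial; the test numerosity
    rows carry ``trials_per_condition`` reports per condition, filling
    numerosities ``filling_trials_per_cell`` each.
    """
    rng = np.random.default_rng(spec.seed)
    if participant_effect is None:
        participant_effect = np.ones(spec.n_participants)
    participant_effect = np.asarray(participant_effect, dtype=float)
    if participant_effect.shape != (spec.n_participants,):
        raise ValueError("participant_effect must have length n_participants")

    bias = rng.normal(0.0, spec.participant_bias_sd, size=spec.n_participants)

    rows = []
    numerosities = [(spec.true_numerosity, spec.trials_per_condition)]
    numerosities += [(n, spec.filling_trials_per_cell) for n in spec.filling_numerosities]
    for p in range(spec.n_participants):
        u_p = spec.underestimation_fraction * participant_effect[p]
        for num, n_trials in numerosities:
            for cond in CONDITIONS:
                mean = num * (1.0 - u_p) if cond == "Adaptation" else float(num)
                est = mean + bias[p] + rng.normal(0.0, spec.trial_noise_sd, n_trials)
                est = np.maximum(np.rint(est), 1.0)
                hemis = np.where(np.arange(n_trials) % 2 == 0, "left", "right")
                n_blocks = 5 if cond == "Baseline" else 10
                blocks = np.arange(n_trials) % n_blocks + 1
                rows.append(pd.DataFrame({
                    "participant": p,
                    "block": blocks,
                    "condition": cond,
                    "numerosity": num,
                    "hemifield": hemis,
                    "estimate": est,
                }))
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# EEG forward model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ErpComponentSpec:
    """One ERP component: Gaussian temporal kernel + fixed topography.

    ``channel_weights`` maps channel name -> unitless topography weight
    (unlisted channels get 0); ``amplitude_by_condition`` maps condition
    label -> peak amplitude in microvolts at a unit-weight channel.
    """

    name: str
    latency_ms: float
    width_ms: float                      # Gaussian SD of the temporal kernel
    channel_weights: dict
    amplitude_by_condition: dict

    def __post_init__(self):
        if self.width_ms <= 0:
            raise ValueError("width_ms must be > 0")

    def kernel(self, time_ms: np.ndarray) -> np.ndarray:
        t = np.asarray(time_ms, dtype=float)
        return np.exp(-0.5 * ((t - self.latency_ms) / self.width_ms) ** 2)

    def weights(self, channels) -> np.ndarray:
        unknown = set(self.channel_weights) - set(channels)
        if unknown:
            raise ValueError(f"weights refer to channels outside the montage: {sorted(unknown)}")
        return np.array([self.channel_weights.get(c, 0.0) for c in channels])


@dataclass(frozen=True)
class EegGenSpec:
    """Parameters of the epoched-EEG generator."""

    components: tuple
    channels: tuple = CHANNELS_30
    fs: float = 250.0
    epoch_window_ms: tuple = (-200.0, 600.0)
    n_trials_per_condition: int = 24
    noise_1f_exponent: float = 1.0
    noise_scale: float = 3.0             # microvolt RMS of the 1/f background
    alpha_amp: float = 1.0               # microvolt, alpha-band sinusoid
    alpha_freq: float = 10.0             # Hz
    trial_amplitude_jitter_sd: float = 0.5  # microvolt, per trial and component
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0:
            raise ValueError("fs must be > 0")
        start, end = self.epoch_window_ms
        if not start < 0 < end:
            raise ValueError("epoch window must straddle stimulus onset")
        if self.n_trials_per_condition < 1:
            raise ValueError("need at least one trial")
        object.__setattr__(self, "components", tuple(self.components))

    def time_ms(self) -> np.ndarray:
        # half-open [start, end): onset sample included, end sample excluded
        start, end = self.epoch_window_ms
        i0 = int(round(start * self.fs / 1000.0))
        i1 = int(round(end * self.fs / 1000.0))
        return np.arange(i0, i1) * (1000.0 / self.fs)

    def known_conditions(self) -> tuple:
        known = set()
        for c in self.components:
            known |= set(c.amplitude_by_condition)
        return tuple(sorted(known))


def gaussian_topography(peak: str, sigma_rad: float = 0.5,
                        channels=CHANNELS_30) -> dict:
    """Topography weights falling off as a Gaussian of great-circle distance
    from a peak electrode (weight 1 at the peak)."""
    pos = channel_positions(tuple(channels))
    peak_idx = list(channels).index(peak)
    cosang = np.clip(pos @ pos[peak_idx], -1.0, 1.0)
    ang = np.arccos(cosang)
    w = np.exp(-0.5 * (ang / sigma_rad) ** 2)
    return {c: float(wi) for c, wi in zip(channels, w) if wi > 1e-4}


def bilateral_topography(peak_left: str, peak_right: str, sigma_rad: float = 0.5,
                         channels=CHANNELS_30) -> dict:
    """Sum of two Gaussian falloffs, one per hemisphere peak."""
    wl = gaussian_topography(peak_left, sigma_rad, channels)
    wr = gaussian_topography(peak_right, sigma_rad, channels)
    out: dict = {}
    for c in set(wl) | set(wr):
        out[c] = wl.get(c, 0.0) + wr.get(c, 0.0)
    return out


def _one_over_f(rng: np.random.Generator, shape: tuple, n_t: int,
                exponent: float, fs: float) -> np.ndarray:
    """Spectrally shaped Gaussian noise with PSD ~ 1/f^exponent, unit RMS."""
    freqs = np.fft.rfftfreq(n_t, d=1.0 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2.0)
    white = rng.standard_normal(shape + (n_t,))
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * gain, n=n_t, axis=-1)
    # Parseval: var(x_t) = (1/n) * sum over two-sided bins of gain^2
    weights = np.full(freqs.size, 2.0)
    weights[0] = 1.0
    if n_t % 2 == 0:
        weights[-1] = 1.0
    rms = np.sqrt((weights * gain ** 2).sum() / n_t)
    return shaped / rms


def _condition_seed(seed: int, condition: str, participant: int) -> list:
    return [int(seed), zlib.crc32(condition.encode()), int(participant)]


def generate_epochs(spec: EegGenSpec, condition: str,
                    participant: int = 0) -> EpochSet:
    """Generate one participant's epochs for one condition.

    data[trial, channel, t] = sum over components of
    (amplitude + jitter[trial]) * weight[channel] * Gaussian(t; latency, width)
    + 1/f noise + alpha sinusoid (random phase per trial/channel).

    Deterministic given (spec.seed, condition, participant).
    """
    known = spec.known_conditions()
    for comp in spec.components:
        if condition not in comp.amplitude_by_condition:
            raise ValueError(
                f"condition {condition!r} unknown to component {comp.name}; "
                f"known conditions: {known}")

    rng = np.random.default_rng(_condition_seed(spec.seed, condition, participant))
    time = spec.time_ms()
    n_t, n_ch, n_tr = time.size, len(spec.channels), spec.n_trials_per_condition

    data = np.zeros((n_tr, n_ch, n_t))
    for comp in spec.components:
        amp = comp.amplitude_by_condition[condition]
        jitter = (rng.normal(0.0, spec.trial_amplitude_jitter_sd, n_tr)
                  if spec.trial_amplitude_jitter_sd > 0 else np.zeros(n_tr))
        w = comp.weights(spec.channels)
        k = comp.kernel(time)
        data += (amp + jitter)[:, None, None] * w[None, :, None] * k[None, None, :]

    if spec.noise_scale > 0:
        data += spec.noise_scale * _one_over_f(
            rng, (n_tr, n_ch), n_t, spec.noise_1f_exponent, spec.fs)
    if spec.alpha_amp > 0:
        phase = rng.uniform(0, 2 * np.pi, size=(n_tr, n_ch, 1))
        data += spec.alpha_amp * np.sin(
            2 * np.pi * spec.alpha_freq * time[None, None, :] / 1000.0 + phase)

    return EpochSet(
        data=data, fs=spec.fs, time_ms=time, channel_names=spec.channels,
        channel_positions=channel_positions(tuple(spec.channels)),
        condition=condition, participant=participant,
    )


# --------------------------------------------------------------------------
# packaged scenario
# --------------------------------------------------------------------------

@dataclass
class Scenario:
    """A full study parameterization: behavioral spec, per-condition EEG
    specs, and the latent coupling the two adaptation effects."""

    behavioral: BehavioralGenSpec
    eeg: dict                      # condition -> EegGenSpec
    p2p_reduction_uv: float = 1.0  # Adaptation P2p deficit at the peak channel
    effect_latent_sd: float = 0.3  # relative spread of the effect across participants
    coupling: float = 0.8          # correlation of behavioral and EEG latents

    def __iter__(self):
        yield self.behavioral
        yield self.eeg


def default_scenario(seed: int = 0) -> Scenario:
    """The packaged adaptation scenario.

    Effect structure: ~20% behavioral underestimation in Adaptation only;
    P1 elevated equally in Adaptation and Neutral relative to Baseline
    (adaptor brightness artifact); P2p reduced by 1 microvolt in Adaptation
    only, with the deficit confined to the left-hemisphere P2p source; for
    physical numerosity (LowNum = 22/26 dots vs HighNum = 35/41), the N1
    scales bilaterally and the P2p scales on the right-hemisphere source.
    """
    left = gaussian_topography("PO7", 0.5)
    right = gaussian_topography("PO8", 0.5)

    components = (
        ErpComponentSpec(
            "P1", latency_ms=100, width_ms=20,
            channel_weights=gaussian_topography("POz", 0.7),
            amplitude_by_condition={
                "Baseline": 2.0, "Adaptation": 3.0, "Neutral": 3.0,
                "LowNum": 2.5, "HighNum": 2.5,
            }),
        ErpComponentSpec(
            "N1", latency_ms=170, width_ms=25,
            channel_weights=bilateral_topography("PO7", "PO8", 0.5),
            amplitude_by_condition={
                "Baseline": -3.0, "Adaptation": -3.0, "Neutral": -3.0,
                "LowNum": -2.0, "HighNum": -3.0,
            }),
        # two lateralized P2p sources: the adaptation deficit lives on the
        # left one, physical-numerosity scaling on the right one
        ErpComponentSpec(
            "P2p_left", latency_ms=220, width_ms=30, channel_weights=left,
            amplitude_by_condition={
                "Baseline": 3.0, "Adaptation": 2.0, "Neutral": 3.0,
                "LowNum": 2.5, "HighNum": 2.5,
            }),
        ErpComponentSpec(
            "P2p_right", latency_ms=220, width_ms=30, channel_weights=right,
            amplitude_by_condition={
                "Baseline": 3.0, "Adaptation": 3.0, "Neutral": 3.0,
                "LowNum": 2.0, "HighNum": 3.0,
            }),
        ErpComponentSpec(
            "P3", latency_ms=350, width_ms=50,
            channel_weights=gaussian_topography("Pz", 0.8),
            amplitude_by_condition={
                "Baseline": 2.5, "Adaptation": 2.5, "Neutral": 2.5,
                "LowNum": 2.5, "HighNum": 2.5,
            }),
    )
    eeg = EegGenSpec(components=components, seed=seed)
    behavioral = BehavioralGenSpec(seed=seed)
    conditions = CONDITIONS + NUMEROSITY_CONDITIONS
    return Scenario(behavioral=behavioral, eeg={c: eeg for c in conditions})


def simulate_experiment(scenario: Scenario, seed: int,
                        conditions=CONDITIONS) -> dict:
    """Simulate one full experiment: behavior plus per-participant epochs.

    A per-participant latent scales the adaptation effect; correlated copies
    of the latent drive the behavioral underestimation and the left-P2p
    amplitude deficit, giving a recoverable brain-behavior correlation.

    Returns a dict with keys ``behavior`` (trial DataFrame), ``epochs``
    (participant -> condition -> EpochSet) and ``latents``.
    """
    behav_spec = replace(scenario.behavioral, seed=int(seed) % (2 ** 31))
    n_p = behav_spec.n_participants
    rng = np.random.default_rng([int(seed) % (2 ** 31), 0xC0FFEE])

    c = scenario.coupling
    z = rng.standard_normal(n_p)
    z_beh = 1.0 + scenario.effect_latent_sd * (
        c * z + np.sqrt(1 - c ** 2) * rng.standard_normal(n_p))
    z_eeg = 1.0 + scenario.effect_latent_sd * (
        c * z + np.sqrt(1 - c ** 2) * rng.standard_normal(n_p))

    behavior = generate_behavior(behav_spec, participant_effect=z_beh)

    epochs: dict = {}
    for p in range(n_p):
        epochs[p] = {}
        for cond in conditions:
            spec = scenario.eeg[cond]
            if cond == "Adaptation" and scenario.p2p_reduction_uv != 0:
                spec = _scale_adaptation_deficit(spec, scenario.p2p_reduction_uv,
                                                 z_eeg[p])
            spec = replace(spec, seed=int(seed) % (2 ** 31))
            epochs[p][cond] = generate_epochs(spec, cond, participant=p)
    return {"behavior": behavior, "epochs": epochs,
            "latents": {"behavior": z_beh, "eeg": z_eeg}}


def _scale_adaptation_deficit(spec: EegGenSpec, reduction: float,
                              scale: float) -> EegGenSpec:
    """Rescale the left-P2p Adaptation deficit by a participant latent."""
    comps = []
    for comp in spec.components:
        if comp.name == "P2p_left" and "Adaptation" in comp.amplitude_by_condition:
            amps = dict(comp.amplitude_by_condition)
            base = amps.get("Neutral", amps["Adaptation"] + reduction)
            amps["Adaptation"] = base - reduction * scale
            comp = replace(comp, amplitude_by_condition=amps)
        comps.append(comp)
    return replace(spec, components=tuple(comps))
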