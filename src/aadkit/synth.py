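"""Synthetic dual-speaker trials with known ground-truth attentional state.

Generates speech-like stimulus envelopes, a smooth temporal response
function (TRF) kernel, attention-modulated mixing weights with a step
switch, and the convolutional neural-response generative model

    e_t = w_t^(1) (s^(1) * h)_t + w_t^(2) (s^(2) * h)_t + mu + u_t

(decoding-model variant, single synthetic channel) together with an
encoding-model analogue in which attention modulates the TRF itself.
Every downstream stage of the pipeline is testable against these trials
without any recorded data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "StimulusPair",
    "TrfKernel",
    "AttentionWeights",
    "SimTrial",
    "CASE_WEIGHTS",
    "DEFAULT_KERNEL_COMPONENTS",
    "make_speechlike_envelope",
    "make_trf_kernel",
    "make_attention_weights",
    "simulate_decoding_trial",
    "simulate_encoding_trial",
]

#: (attended, unattended) noiseless weight levels per separation case.
#: Case 1 is the easiest (largest separation), case 3 the hardest.
CASE_WEIGHTS = {1: (0.40, 0.10), 2: (0.30, 0.20), 3: (0.26, 0.24)}

#: Default sparse lag components (lag_s, amplitude) of the TRF kernel:
#: a positive M50-like peak and a dominant negative M100-like peak, with
#: smaller components at higher latencies.
DEFAULT_KERNEL_COMPONENTS = ((0.050, 0.5), (0.100, -1.0), (0.150, 0.2), (0.200, -0.2))


@dataclass
class StimulusPair:
    """The two speakers' amplitude envelopes on a common clock."""

    envelope1: np.ndarray
    envelope2: np.ndarray
    fs: float
    duration_s: float

    def __post_init__(self) -> None:
        self.envelope1 = np.asarray(self.envelope1, dtype=float)
        self.envelope2 = np.asarray(self.envelope2, dtype=float)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.envelope1.shape != self.envelope2.shape or self.envelope1.ndim != 1:
            raise ValueError("envelopes must be 1-D and of identical length")
        if not (np.isfinite(self.envelope1).all() and np.isfinite(self.envelope2).all()):
            raise ValueError("envelopes must be finite")

    @property
    def n_samples(self) -> int:
        return self.envelope1.size


@dataclass
class TrfKernel:
    """Impulse response h_t sampled on a uniform lag grid starting at 0."""

    lags_s: np.ndarray
    values: np.ndarray
    smoothing_std_s: float = 0.010

    def __post_init__(self) -> None:
        self.lags_s = np.asarray(self.lags_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags_s.shape != self.values.shape:
            raise ValueError("lag grid and values must align")


@dataclass
class AttentionWeights:
    """Per-sample mixing weights w_t^(1), w_t^(2) plus their noiseless parts."""

    w1: np.ndarray
    w2: np.ndarray
    w1_clean: np.ndarray
    w2_clean: np.ndarray
    switch_times_s: list[float]
    noise_var: float
    case_id: int
    fs: float

    @property
    def attended(self) -> np.ndarray:
        """Per-sample attended speaker (1 or 2) from the noiseless weights."""
        return np.where(self.w1_clean > self.w2_clean, 1, 2)


@dataclass
class SimTrial:
    """A simulated trial: stimuli, neural response, and ground truth."""

    stimuli: StimulusPair
    neural: np.ndarray
    weights: AttentionWeights | None
    attended: np.ndarray  # per-sample attended speaker in {1, 2}
    mean_offset: float
    noise_var: float
    seed: int
    mode: str = "decoding"
    extras: dict = field(default_factory=dict)

    @property
    def fs(self) -> float:
        return self.stimuli.fs

    def instance_truth(self, W: int) -> np.ndarray:
        """Attended-speaker label per length-``W`` instance (majority vote).

        Instance k (1-based) covers samples (k-1)W..kW-1; the label is the
        speaker attended for the majority of samples in that instance.
        """
        K = self.attended.size // W
        blocks = self.attended[: K * W].reshape(K, W)
        # attended entries are 1/2; majority via the block mean
        return np.where(blocks.mean(axis=1) < 1.5, 1, 2)


def make_speechlike_envelope(duration_s: float, fs: float, seed: int,
                             cutoff_hz: float = 8.0, std: float = 0.05,
                             floor: float = 0.05) -> np.ndarray:
    """Generate a non-negative, slowly modulated speech-like envelope.

    Rectified low-pass-filtered Gaussian noise (4th-order Butterworth,
    default cutoff 8 Hz) rescaled to standard deviation ``std`` plus a
    positive ``floor``, emulating the 1-8 Hz slow modulation structure of
    speech envelopes. Deterministic given ``seed``.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n + int(fs))  # extra second to flush transients
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    slow = signal.sosfilt(sos, white)[int(fs):]
    env = np.maximum(slow, 0.0)
    s = env.std()
    if s > 0:
        env *= std / s
    return env + floor


def make_trf_kernel(fs: float,
                    components=DEFAULT_KERNEL_COMPONENTS,
                    smoothing_std_s: float = 0.010,
                    lag_max_s: float | None = None) -> TrfKernel:
    """Place sparse lag components on the 1/fs grid and Gaussian-smooth them.

    The smoothing kernel has unit area (in the discrete sum), so the sum of
    the returned values equals the sum of the component amplitudes.
    ``smoothing_std_s = 0`` returns the raw spike train.
    """
    components = list(components)
    if any(lag < 0 for lag, _ in components):
        raise ValueError("component lags must be non-negative")
    if lag_max_s is None:
        lag_max_s = max(lag for lag, _ in components) + 6.0 * smoothing_std_s + 2.0 / fs
    n = int(round(lag_max_s * fs)) + 1
    lags = np.arange(n) / fs
    spikes = np.zeros(n)
    for lag, amp in components:
        spikes[int(round(lag * fs))] += amp
    if smoothing_std_s > 0:
        half = int(np.ceil(4 * smoothing_std_s * fs))
        g_t = np.arange(-half, half + 1) / fs
        g = np.exp(-0.5 * (g_t / smoothing_std_s) ** 2)
        g /= g.sum()
        values = np.convolve(spikes, g)[half: half + n]
    else:
        values = spikes
    return TrfKernel(lags_s=lags, values=values, smoothing_std_s=smoothing_std_s)


def make_attention_weights(duration_s: float, fs: float, switch_times_s,
                           case_id: int, noise_var: float = 4e-4,
                           seed: int = 0) -> AttentionWeights:
    """Piecewise-constant attention weights with step exchanges.

    Speaker 1 holds the attended (larger) level until the first switch time;
    every switch exchanges the two levels. Independent Gaussian noise with
    variance ``noise_var`` models background neural processes contaminating
    the per-speaker contributions.
    """
    if case_id not in CASE_WEIGHTS:
        raise ValueError(f"unknown case_id {case_id!r}; expected one of {sorted(CASE_WEIGHTS)}")
    switch_times_s = sorted(switch_times_s)
    if any(not (0 < t < duration_s) for t in switch_times_s):
        raise ValueError("switch times must lie strictly inside (0, duration_s)")
    n = int(round(duration_s * fs))
    hi, lo = CASE_WEIGHTS[case_id]
    w1 = np.full(n, hi)
    w2 = np.full(n, lo)
    attend_1 = True
    edges = [int(round(t * fs)) for t in switch_times_s] + [n]
    start = 0
    for edge in edges:
        if attend_1:
            w1[start:edge], w2[start:edge] = hi, lo
        else:
            w1[start:edge], w2[start:edge] = lo, hi
        attend_1 = not attend_1
        start = edge
    rng = np.random.default_rng(seed)
    sd = np.sqrt(noise_var)
    return AttentionWeights(
        w1=w1 + sd * rng.standard_normal(n),
        w2=w2 + sd * rng.standard_normal(n),
        w1_clean=w1,
        w2_clean=w2,
        switch_times_s=list(switch_times_s),
        noise_var=noise_var,
        case_id=case_id,
        fs=fs,
    )


def _causal_conv(x: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Causal convolution with zero pre-history, truncated to len(x)."""
    return np.convolve(x, h)[: x.size]


def simulate_decoding_trial(stimuli: StimulusPair, kernel: TrfKernel,
                            weights: AttentionWeights,
                            mean_offset: float = 0.02,
                            noise_var: float = 2.5e-5,
                            seed: int = 0) -> SimTrial:
    """Simulate a neural response from the convolutional generative model.

    e_t = w_t^(1) (s^(1) * h)_t + w_t^(2) (s^(2) * h)_t + mu + u_t, with
    causal convolution (zero initial history) and u_t iid N(0, noise_var).
    """
    n = stimuli.n_samples
    if weights.w1.size != n:
        raise ValueError("weights and envelopes must have equal length")
    r1 = _causal_conv(stimuli.envelope1, kernel.values)
    r2 = _causal_conv(stimuli.envelope2, kernel.values)
    rng = np.random.default_rng(seed)
    noise = np.sqrt(noise_var) * rng.standard_normal(n) if noise_var > 0 else 0.0
    e = weights.w1 * r1 + weights.w2 * r2 + mean_offset + noise
    return SimTrial(
        stimuli=stimuli,
        neural=e,
        weights=weights,
        attended=weights.attended,
        mean_offset=mean_offset,
        noise_var=noise_var,
        seed=seed,
        mode="decoding",
    )


def simulate_encoding_trial(stimuli: StimulusPair, kernel_attended: TrfKernel,
                            kernel_unattended: TrfKernel,
                            truth_schedule: np.ndarray,
                            noise_var: float = 2.5e-5,
                            mean_offset: float = 0.0,
                            seed: int = 0) -> SimTrial:
    """Simulate an auditory response with attention-modulated TRFs.

    E_t = (s^(a) * h_att)_t + (s^(u) * h_unatt)_t + mu + u_t where at each
    sample (a, u) are the attended/unattended speakers per
    ``truth_schedule`` (values in {1, 2}). The attended kernel is expected
    to carry the larger-magnitude negative (M100-like) component near the
    0.1 s lag.
    """
    n = stimuli.n_samples
    truth_schedule = np.asarray(truth_schedule, dtype=int)
    if truth_schedule.size != n:
        raise ValueError("truth_schedule and envelopes must have equal length")
    if kernel_attended.lags_s.size != kernel_unattended.lags_s.size:
        raise ValueError("kernels must share the lag grid")
    conv = {
        (1, "a"): _causal_conv(stimuli.envelope1, kernel_attended.values),
        (1, "u"): _causal_conv(stimuli.envelope1, kernel_unattended.values),
        (2, "a"): _causal_conv(stimuli.envelope2, kernel_attended.values),
        (2, "u"): _causal_conv(stimuli.envelope2, kernel_unattended.values),
    }
    is1 = truth_schedule == 1
    e = (np.where(is1, conv[(1, "a")], conv[(1, "u")])
         + np.where(is1, conv[(2, "u")], conv[(2, "a")])
         + mean_offset)
    if noise_var > 0:
        rng = np.random.default_rng(seed)
        e = e + np.sqrt(noise_var) * rng.standard_normal(n)
    return SimTrial(
        stimuli=stimuli,
        neural=e,
        weights=None,
        attended=truth_schedule,
        mean_offset=mean_offset,
        noise_var=noise_var,
        seed=seed,
        mode="encoding",
    )
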