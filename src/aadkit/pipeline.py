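"""End-to-end orchestration: simulate -> estimate -> markers -> smooth -> evaluate.

Also houses the forward-lag sweep experiment (robustness of the fixed-lag
smoother vs. the batch benchmark as a function of K_F) and the
transition-delay measurement after an abrupt attention switch.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import synth
from .adaptive import (FilterConfig, estimate_coefficients,
                       iter_decoding_windows, iter_encoding_windows,
                       make_gaussian_dictionary)
from .markers import MarkerSeries, marker_stream
from .statespace import (AttentionTrajectory, FixedLagConfig, StateSpaceParams,
                         batch_estimate, built_in_delay_s, classify_instances,
                         compute_mse, fit_lognormal_supervised,
                         realtime_estimate)

__all__ = [
    "ExperimentConfig",
    "DelayReport",
    "UNATTENDED_KERNEL_COMPONENTS",
    "simulate_trial",
    "estimate_trial_coefficients",
    "compute_markers",
    "fit_tuning_params",
    "run_pipeline",
    "run_trial",
    "sweep_forward_lag",
    "measure_transition_delay",
    "instance_times_s",
]

#: Unattended-TRF lag components for the encoding-model simulation: the
#: M100-like negative component is weaker than the attended kernel's,
#: while the earlier M50-like component is attention-independent.
UNATTENDED_KERNEL_COMPONENTS = ((0.050, 0.5), (0.100, -0.4), (0.150, 0.2), (0.200, -0.2))


@dataclass
class ExperimentConfig:
    """Complete configuration of a simulated dual-speaker experiment."""

    mode: str = "eeg_decoding"  # "eeg_decoding" | "meg_encoding"
    marker_type: str = "correlation"  # correlation | l1 | m100
    case_id: int = 1
    duration_s: float = 60.0
    tuning_duration_s: float = 15.0
    switch_times_s: tuple = (30.0,)
    fs: float = 200.0
    W: int = 50
    lam: float = 0.95
    gamma: float = 0.001
    L_d: int = 80
    L_e: int = 80
    dictionary: bool = False
    dictionary_std_s: float = 0.020
    dictionary_spacing_s: float = 0.005
    solver_tol: float = 0.01
    solver_max_iter: int = 500
    weight_noise_var: float = 4e-4
    mean_offset: float = 0.02
    response_noise_var: float = 2.5e-5
    smoother_window_s: float = 15.0
    forward_lag_s: float = 1.5
    outer_iters: int = 20
    inner_iters: int = 1
    batch_iters: int = 20
    c0: float = 1.0
    a0: float = 2.008
    b0: float = 0.2016
    seed: int = 0
    output_dir: str = "."
    extra: dict = field(default_factory=dict)

    @classmethod
    def meg_encoding(cls, **kw) -> "ExperimentConfig":
        """Encoding-model (MEG-like) defaults: Gaussian dictionary on,
        l1 weight 1, forgetting factor 0.975, M100 marker."""
        base = dict(mode="meg_encoding", marker_type="m100", gamma=1.0,
                    lam=0.975, dictionary=True, mean_offset=0.0,
                    response_noise_var=2.5e-5)
        base.update(kw)
        return cls(**base)

    def filter_config(self) -> FilterConfig:
        return FilterConfig(fs=self.fs, W=self.W, lam=self.lam,
                            gamma=self.gamma, L_d=self.L_d, L_e=self.L_e,
                            dictionary=self.dictionary,
                            dictionary_std_s=self.dictionary_std_s,
                            dictionary_spacing_s=self.dictionary_spacing_s,
                            solver_tol=self.solver_tol,
                            solver_max_iter=self.solver_max_iter)

    def smoother_config(self) -> FixedLagConfig:
        return FixedLagConfig.from_seconds(self.fs, self.W,
                                           window_s=self.smoother_window_s,
                                           forward_s=self.forward_lag_s,
                                           outer_iters=self.outer_iters,
                                           inner_iters=self.inner_iters)

    def built_in_delay_s(self) -> float:
        kf = self.smoother_config().K_F
        if self.mode == "meg_encoding":
            return built_in_delay_s("encoding", self.W, self.fs, kf)
        return built_in_delay_s("decoding", self.W, self.fs, kf, L_d=self.L_d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["switch_times_s"] = list(d["switch_times_s"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        d["switch_times_s"] = tuple(d.get("switch_times_s", ()))
        return cls(**d)


@dataclass
class DelayReport:
    """Decomposition of the total attention-switch detection delay."""

    built_in_delay_s: float
    transition_delay_s: float
    never_crossed: bool = False

    @property
    def total_delay_s(self) -> float:
        return self.built_in_delay_s + self.transition_delay_s


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def simulate_trial(config: ExperimentConfig, seed: int | None = None,
                   duration_s: float | None = None,
                   switch_times_s=None) -> synth.SimTrial:
    """Generate one trial under the configured generative model."""
    seed = config.seed if seed is None else seed
    duration = config.duration_s if duration_s is None else duration_s
    switches = config.switch_times_s if switch_times_s is None else switch_times_s
    s_env1, s_env2, s_w, s_noise = _child_seeds(seed, 4)
    env1 = synth.make_speechlike_envelope(duration, config.fs, s_env1)
    env2 = synth.make_speechlike_envelope(duration, config.fs, s_env2)
    stim = synth.StimulusPair(env1, env2, config.fs, duration)
    if config.mode == "meg_encoding":
        n = stim.n_samples
        truth = np.full(n, 1)
        for t in switches:
            truth[int(round(t * config.fs)):] = 3 - truth[int(round(t * config.fs))]
        h_att = synth.make_trf_kernel(config.fs)
        h_unatt = synth.make_trf_kernel(config.fs,
                                        components=UNATTENDED_KERNEL_COMPONENTS)
        return synth.simulate_encoding_trial(stim, h_att, h_unatt, truth,
                                             noise_var=config.response_noise_var,
                                             mean_offset=config.mean_offset,
                                             seed=s_noise)
    weights = synth.make_attention_weights(duration, config.fs, switches,
                                           config.case_id,
                                           noise_var=config.weight_noise_var,
                                           seed=s_w)
    kernel = synth.make_trf_kernel(config.fs)
    return synth.simulate_decoding_trial(stim, kernel, weights,
                                         mean_offset=config.mean_offset,
                                         noise_var=config.response_noise_var,
                                         seed=s_noise)


def estimate_trial_coefficients(trial: synth.SimTrial, config: ExperimentConfig):
    """Run the streaming sparse estimator on a trial.

    Returns ``(coefficients, designs)`` in the layout
    :func:`aadkit.markers.marker_stream` expects: per-speaker dicts in
    decoding mode, a single shared state list in encoding mode.
    """
    fc = config.filter_config()
    if config.mode == "meg_encoding":
        G = None
        if config.dictionary:
            G = make_gaussian_dictionary(
                config.fs, lag_max_s=config.L_e / config.fs,
                kernel_std_s=config.dictionary_std_s,
                spacing_s=config.dictionary_spacing_s).G
        wins = list(iter_encoding_windows(trial.stimuli.envelope1,
                                          trial.stimuli.envelope2,
                                          trial.neural, config.W, config.L_e))
        states = estimate_coefficients(iter(wins), fc, G=G)
        return states, wins
    coeffs, designs = {}, {}
    for spk, env in ((1, trial.stimuli.envelope1), (2, trial.stimuli.envelope2)):
        wins = list(iter_decoding_windows(trial.neural, env, config.W,
                                          config.L_d, pad_end=True))
        designs[spk] = wins
        coeffs[spk] = estimate_coefficients(iter(wins), fc)
    return coeffs, designs


def compute_markers(coefficients, designs, config: ExperimentConfig) -> MarkerSeries:
    if config.marker_type == "m100":
        return marker_stream(coefficients, None, "m100", fs=config.fs)
    return marker_stream(coefficients, designs, config.marker_type)


def fit_tuning_params(config: ExperimentConfig, seed: int) -> StateSpaceParams:
    """Supervised initialization from a short constant-attention sample trial.

    A separate tuning trial of ``tuning_duration_s`` seconds (speaker 1
    attended throughout) is generated from the same model, the full
    estimator + marker chain is run on it, and the attended/unattended
    Log-Normal laws are fit to its labeled markers.
    """
    tune = simulate_trial(config, seed=seed,
                          duration_s=config.tuning_duration_s,
                          switch_times_s=())
    coeffs, designs = estimate_trial_coefficients(tune, config)
    mk = compute_markers(coeffs, designs, config)
    labels = tune.instance_truth(config.W)[: mk.K]
    from .markers import MARKER_FLOOR
    return fit_lognormal_supervised(mk, labels, c0=config.c0,
                                    a0=config.a0, b0=config.b0,
                                    exclude_floored=MARKER_FLOOR)


def instance_times_s(K: int, W: int, fs: float) -> np.ndarray:
    """Window-end timestamps t_k = k W / fs of instances k = 1..K."""
    return np.arange(1, K + 1) * W / fs


def run_pipeline(config: ExperimentConfig, seed: int | None = None,
                 run_batch: bool = True) -> dict:
    """Execute the full chain in memory and return all stage outputs."""
    seed = config.seed if seed is None else seed
    trial = simulate_trial(config, seed=seed)
    coeffs, designs = estimate_trial_coefficients(trial, config)
    mk = compute_markers(coeffs, designs, config)
    params0 = fit_tuning_params(config, seed=seed + 1)
    sc = config.smoother_config()
    delay = config.built_in_delay_s()
    traj_rt = realtime_estimate(mk, params0, sc, delay_s=delay)
    truth = trial.instance_truth(config.W)[: mk.K]
    out = {
        "trial": trial,
        "coefficients": coeffs,
        "designs": designs,
        "markers": mk,
        "params0": params0,
        "trajectory_realtime": traj_rt,
        "truth": truth,
        "summary": {},
    }
    summary = classify_instances(traj_rt, truth)
    out["classification"] = summary
    out["summary"] = {
        "hit_rate": summary.hit_rate,
        "false_alarm_rate": summary.false_alarm_rate,
        "unclassified_rate": summary.unclassified_rate,
        "built_in_delay_s": delay,
        "K": int(mk.K),
    }
    if run_batch:
        traj_b = batch_estimate(mk, params0, outer_iters=config.batch_iters,
                                inner_iters=config.batch_iters)
        out["trajectory_batch"] = traj_b
        out["summary"]["mse_vs_batch"] = compute_mse(traj_rt, traj_b)
    if config.switch_times_s:
        rep = measure_transition_delay(
            traj_rt.p, instance_times_s(mk.K, config.W, config.fs),
            config.switch_times_s[0], delay)
        out["delay_report"] = rep
        out["summary"]["transition_delay_s"] = rep.transition_delay_s
    return out


def measure_transition_delay(p: np.ndarray, times_s: np.ndarray,
                             switch_time_s: float,
                             built_in_delay_s: float) -> DelayReport:
    """Time after the switch for the attended-speaker probability to reach 0.5.

    ``times_s`` are the instances' attributed (window-end) times, i.e. the
    delay-calibrated time axis on which real-time trajectories are
    reported: the estimate for instance k only becomes available
    ``built_in_delay_s`` seconds of wall-clock time later, so measuring on
    this axis isolates the transition delay from the structural one. The
    switch moves attention away from speaker 1, so the crossing is the
    first calibrated time at or after the switch with p <= 0.5. If the
    trajectory never crosses, the trial-end sentinel is reported with
    ``never_crossed`` set.
    """
    p = np.asarray(p, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if not (t[0] <= switch_time_s <= t[-1]):
        raise ValueError("switch time outside the trial")
    after = (t >= switch_time_s) & (p <= 0.5)
    if not after.any():
        return DelayReport(built_in_delay_s=built_in_delay_s,
                           transition_delay_s=float(t[-1] - switch_time_s),
                           never_crossed=True)
    t_cross = float(t[np.flatnonzero(after)[0]])
    return DelayReport(built_in_delay_s=built_in_delay_s,
                       transition_delay_s=t_cross - switch_time_s)


def sweep_forward_lag(config: ExperimentConfig, kf_values_s,
                      seeds) -> pd.DataFrame:
    """Realtime-vs-batch MSE as a function of the forward lag K_F.

    For each seed the trial, markers and batch benchmark are computed
    once; the realtime smoother is then re-run per forward lag on the
    identical marker series. Returns one row per K_F with the seed-mean
    MSE and the incremental (successive-difference) MSE.
    """
    kf_values_s = list(kf_values_s)
    if len(kf_values_s) < 2:
        raise ValueError("need at least two forward-lag values")
    mse = np.zeros((len(seeds), len(kf_values_s)))
    for i, seed in enumerate(seeds):
        trial = simulate_trial(config, seed=seed)
        coeffs, designs = estimate_trial_coefficients(trial, config)
        mk = compute_markers(coeffs, designs, config)
        params0 = fit_tuning_params(config, seed=seed + 1)
        traj_b = batch_estimate(mk, params0, outer_iters=config.batch_iters,
                                inner_iters=config.batch_iters)
        for j, kf_s in enumerate(kf_values_s):
            sc = FixedLagConfig.from_seconds(config.fs, config.W,
                                             window_s=config.smoother_window_s,
                                             forward_s=kf_s,
                                             outer_iters=config.outer_iters,
                                             inner_iters=config.inner_iters)
            traj_rt = realtime_estimate(mk, params0, sc)
            mse[i, j] = compute_mse(traj_rt, traj_b)
    mean_mse = mse.mean(axis=0)
    inc = np.concatenate([[np.nan], np.diff(mean_mse)])
    kf_windows = [int(kf_s * config.fs // config.W) for kf_s in kf_values_s]
    return pd.DataFrame({"K_F_s": kf_values_s, "K_F": kf_windows,
                         "mean_mse": mean_mse, "incremental_mse": inc})


# ---------------------------------------------------------------------------
# on-disk trial format

def coefficient_rows(coeffs, fs: float, W: int) -> list[pd.DataFrame]:
    """Long-format frames (k, t_s, speaker, lag_s, value) of the effective
    lag-domain coefficients, intercept dropped. Encoding-mode states hold
    both speakers' blocks and are split into per-speaker rows."""
    rows = []
    if isinstance(coeffs, dict):
        items = coeffs.items()
    else:
        items = [(None, coeffs)]
    for spk, states in items:
        for k, st in enumerate(states, start=1):
            eff = st.effective_coeffs[1:]
            if spk is None:  # dual-speaker encoding state
                n_lag = eff.size // 2
                blocks = [(1, eff[:n_lag]), (2, eff[n_lag:])]
            else:
                blocks = [(spk, eff)]
            for s, block in blocks:
                rows.append(pd.DataFrame({
                    "k": k, "t_s": k * W / fs, "speaker": s,
                    "lag_s": np.arange(block.size) / fs, "value": block}))
    return rows

def write_trial_dir(result: dict, config: ExperimentConfig, out_dir) -> None:
    """Write every pipeline stage of ``result`` to TSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trial: synth.SimTrial = result["trial"]
    fs, W = config.fs, config.W
    n = trial.stimuli.n_samples
    t = np.arange(1, n + 1) / fs
    pd.DataFrame({"t_s": t, "env1": trial.stimuli.envelope1,
                  "env2": trial.stimuli.envelope2}).to_csv(
        out / "stimuli.tsv", sep="\t", index=False)
    pd.DataFrame({"t_s": t, "value": trial.neural}).to_csv(
        out / "neural.tsv", sep="\t", index=False)
    truth = result["truth"]
    K = truth.size
    pd.DataFrame({"k": np.arange(1, K + 1),
                  "t_start_s": (np.arange(K) * W) / fs,
                  "attended": truth}).to_csv(out / "truth.tsv", sep="\t",
                                             index=False)
    (out / "meta.json").write_text(json.dumps(config.to_dict(), indent=2))
    mk: MarkerSeries = result["markers"]
    times = instance_times_s(mk.K, W, fs)
    pd.DataFrame({"k": np.arange(1, mk.K + 1), "t_s": times,
                  "m1": mk.m1, "m2": mk.m2,
                  "marker_type": mk.marker_type}).to_csv(
        out / "markers.tsv", sep="\t", index=False)
    pd.concat(coefficient_rows(result["coefficients"], fs, W),
              ignore_index=True).to_csv(out / "coefficients.tsv",
                                        sep="\t", index=False)
    for name in ("trajectory_realtime", "trajectory_batch"):
        if name not in result:
            continue
        traj: AttentionTrajectory = result[name]
        pd.DataFrame({"k": np.arange(1, traj.K + 1), "t_s": times,
                      "p": traj.p, "ci_lo": traj.ci_lo, "ci_hi": traj.ci_hi,
                      "z_mean": traj.z_mean, "z_var": traj.z_var,
                      "responsibility": traj.responsibilities,
                      "mode": traj.mode}).to_csv(
            out / f"{name}.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(json.dumps(result["summary"], indent=2))


def run_trial(config: ExperimentConfig, out_dir=None, seed: int | None = None) -> dict:
    """Run the full pipeline and (optionally) persist every stage."""
    result = run_pipeline(config, seed=seed)
    if out_dir is not None:
        write_trial_dir(result, config, out_dir)
    return result
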