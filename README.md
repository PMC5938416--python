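# aadkit — real-time auditory attention decoding

In a two-speaker ("cocktail party") scene, a listener's neural response
tracks the envelope of the *attended* talker more strongly than the
ignored one. `aadkit` turns that effect into a real-time estimate of who
is being attended, from a single trial and with minimal supervised
tuning — the setting of emerging applications such as neuro-steered
hearing aids, where offline multi-trial training is not available.

The pipeline has three modules:

1. **Streaming sparse regression** (`aadkit.adaptive`). Per-speaker
   decoding (response → envelope) or joint encoding (envelopes →
   response) coefficients are re-estimated every window of `W` samples by
   solving

       θ̂_k = argmin_θ  Σ_{j≤k} λ^{k−j} ‖y_j − X_j θ‖² + γ‖θ‖₁ ,

   a forgetting-factor RLS-LASSO, via forward-backward splitting
   (proximal gradient with momentum) over recursively updated sufficient
   statistics. `W/(1−λ)` is the effective data length; an optional
   Gaussian-kernel dictionary yields smooth temporal response functions
   (TRFs).

2. **Attention markers** (`aadkit.markers`). Each window maps to a
   positive scalar m_k^(i) per speaker whose distribution separates
   attended from unattended: the reconstruction correlation
   |corr(y_k, X_k θ̂_k)|, the decoder's ℓ₁ norm, or the magnitude of the
   negative TRF peak near the 100 ms lag (M100).

3. **Fixed-lag Bayesian smoothing** (`aadkit.statespace`). A logistic
   state-space model, p_k = σ(z_k) with z_k = c₀z_{k−1} + N(0, η_k),
   η_k ~ Inverse-Gamma(a₀, b₀), and Log-Normal marker observations
   linked by the attended-speaker indicator, estimated by nested EM with
   a Laplace E-step over a sliding window of K_A = K_B + K_F + 1
   instances. The forward lag K_F trades delay for robustness; the
   output is P(attending speaker 1) with 90% credible intervals, in near
   real time with a built-in delay of (L_d + K_F·W)/f_s (decoding) or
   K_F·W/f_s (encoding).

A generative simulation (`aadkit.synth`) provides dual-speaker trials
with known ground truth — speech-like envelopes, a convolutional
response model with attention-modulated mixing weights and a step
attention switch — so the full chain is testable without recordings.
`aadkit.pipeline` and the `aadkit` CLI wire everything together.

## Worked example

Run a 60 s simulated trial with a strong attention modulation (Case 1),
a step switch at 30 s, decoders estimated with λ = 0.95, γ = 0.001,
W = 50 at f_s = 200 Hz, correlation markers, and the fixed-lag smoother
(15 s window, 1.5 s forward lag):

```python
from aadkit.pipeline import ExperimentConfig, run_pipeline

res = run_pipeline(ExperimentConfig(case_id=1, seed=101))
print(res["summary"])
```

```
{'hit_rate': 0.9, 'false_alarm_rate': 0.0, 'unclassified_rate': 0.1,
 'built_in_delay_s': 1.9, 'K': 240, 'mse_vs_batch': 0.003,
 'transition_delay_s': 0.5}
```

Reading the numbers: of the 240 quarter-second instances, 90% are
classified correctly (the whole 90% credible interval of the oriented
attention probability lies above 0.5), none incorrectly, and 10% are
left unclassified because the interval straddles 0.5. The structural
reporting delay is 1.9 s (0.4 s of decoder lags plus the 1.5 s forward
lag); after calibrating for it, the estimate crosses p = 0.5 half a
second after the 30 s switch. The realtime trajectory differs from the
whole-trial batch benchmark by a mean squared probability error of
0.003.

The same analysis from the shell:

```bash
aadkit run-all --seed 101 --out trial_101/
aadkit sweep-kf --seed 0 --n-seeds 10 --out sweep.tsv   # K_F robustness sweep
```

`trial_101/` then holds every stage as TSV/JSON: `stimuli.tsv`,
`neural.tsv`, `truth.tsv`, `coefficients.tsv`, `markers.tsv`,
`trajectory_realtime.tsv`, `trajectory_batch.tsv`, `summary.json`.
Each stage can also be run separately (`simulate`, `decode`, `encode`,
`markers`, `smooth`, `evaluate`) from a trial directory.

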