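"""Fixed-lag Bayesian state-space smoothing of attention markers.

The latent attentional state follows a logistic random walk,

    p_k = P(n_k = 1) = 1 / (1 + exp(-z_k)),
    z_k = c0 z_{k-1} + w_k,   w_k ~ N(0, eta_k),
    eta_k ~ Inverse-Gamma(a0, b0),

and the two marker observations at instance k are Log-Normal, with
(precision, log-mean) = (rho_a, mu_a) for the attended speaker and
(rho_u, mu_u) for the unattended one; (rho, mu) carry conjugate
Gamma-Normal priors. Inference runs over a sliding active window of
K_A = K_B + K_F + 1 instances (fixed-lag smoothing: at position k0 the
estimate at k* = k0 - K_F is emitted and frozen) by two nested EM loops:

* E-step: responsibilities P(n_k = 1 | m, z) at the current state, then
  the MAP trajectory z_{1:K_A} of the chain by Newton iterations on the
  tridiagonal-Hessian objective, with posterior variances from the
  inverse curvature (Laplace / Gaussian approximation);
* inner M-step: conjugate Inverse-Gamma posterior-mode updates of each
  eta_k; outer M-step: conjugate Gamma-Normal updates of (rho, mu).

Running a single window over the whole trial (K_A = K) gives the
batch-mode estimator used as a robustness benchmark.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky_banded, cho_solve_banded

__all__ = [
    "LogNormalParams",
    "GammaNormalPrior",
    "StateSpaceParams",
    "FixedLagConfig",
    "AttentionTrajectory",
    "ClassificationSummary",
    "lognormal_logpdf",
    "fit_lognormal_supervised",
    "responsibilities",
    "estimate_window",
    "realtime_estimate",
    "batch_estimate",
    "compute_mse",
    "classify_instances",
    "inverse_gamma_mean",
    "inverse_gamma_var",
    "built_in_delay_s",
]

_LOG_2PI = math.log(2.0 * math.pi)
_CI_Z = 1.645  # 90% interval


@dataclass
class LogNormalParams:
    """(precision, log-mean) of a Log-Normal marker distribution."""

    rho: float
    mu: float


@dataclass
class GammaNormalPrior:
    """Conjugate prior on (rho, mu): rho ~ Gamma(shape, scale) and
    mu | rho ~ N(mu0, 1/(kappa0*rho)) (Normal-Gamma, rho as precision
    scale). Prior mean of rho is shape*scale, variance shape*scale^2.

    ``ref_n`` > 0 marks a prior re-centered on a supervised fit of that
    pool size: when used in an EM M-step its pseudo-counts are rescaled
    so it keeps the same *relative* strength for any window length
    (a fixed-count anchor would vanish against long batch windows and
    lose its role of pinning the attended/unattended identities)."""

    shape: float = 0.0
    scale: float = float("inf")
    mu0: float = 0.0
    kappa0: float = 0.0
    ref_n: float = 0.0

    @property
    def rate(self) -> float:
        return 0.0 if not np.isfinite(self.scale) else 1.0 / self.scale


@dataclass
class StateSpaceParams:
    """All hyperparameters and current observation-model estimates."""

    attended: LogNormalParams
    unattended: LogNormalParams
    prior_attended: GammaNormalPrior = field(default_factory=GammaNormalPrior)
    prior_unattended: GammaNormalPrior = field(default_factory=GammaNormalPrior)
    c0: float = 1.0
    a0: float = 2.008
    b0: float = 0.2016
    rho_max: float = 1e8
    #: marker values at or below this are imputed placeholders for
    #: undefined markers; they carry no evidence about the attended
    #: speaker and are treated as missing observations.
    marker_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 <= self.c0 <= 1.0):
            raise ValueError("c0 must lie in [0, 1]")
        if self.a0 <= 2.0 or self.b0 <= 0.0:
            raise ValueError("need a0 > 2 and b0 > 0 for a proper eta prior")

    @property
    def eta_prior_mean(self) -> float:
        return inverse_gamma_mean(self.a0, self.b0)

    def copy(self) -> "StateSpaceParams":
        return copy.deepcopy(self)


@dataclass
class FixedLagConfig:
    """Fixed-lag window geometry and EM iteration counts."""

    K_B: int
    K_F: int
    outer_iters: int = 20
    inner_iters: int = 1

    def __post_init__(self) -> None:
        if self.K_B < 0 or self.K_F < 0:
            raise ValueError("lags must be non-negative")

    @property
    def K_A(self) -> int:
        return self.K_B + self.K_F + 1

    @classmethod
    def from_seconds(cls, fs: float, W: int, window_s: float = 15.0,
                     forward_s: float = 1.5, outer_iters: int = 20,
                     inner_iters: int = 1) -> "FixedLagConfig":
        """Window of ``window_s`` seconds with ``forward_s`` forward lag:
        K_A = floor(window_s*fs/W), K_F = floor(forward_s*fs/W)."""
        K_A = int(window_s * fs // W)
        K_F = int(forward_s * fs // W)
        return cls(K_B=K_A - K_F - 1, K_F=K_F,
                   outer_iters=outer_iters, inner_iters=inner_iters)


@dataclass
class AttentionTrajectory:
    """Per-instance posterior summary of the attentional state."""

    z_mean: np.ndarray
    z_var: np.ndarray
    eta: np.ndarray
    responsibilities: np.ndarray
    mode: str  # "batch" | "realtime"
    built_in_delay_s: float = 0.0

    @property
    def p(self) -> np.ndarray:
        return _sigmoid(self.z_mean)

    @property
    def ci_lo(self) -> np.ndarray:
        return _sigmoid(self.z_mean - _CI_Z * np.sqrt(self.z_var))

    @property
    def ci_hi(self) -> np.ndarray:
        return _sigmoid(self.z_mean + _CI_Z * np.sqrt(self.z_var))

    @property
    def K(self) -> int:
        return self.z_mean.size


def _sigmoid(x):
    out = np.empty_like(np.asarray(x, dtype=float))
    x = np.asarray(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def inverse_gamma_mean(a0: float, b0: float) -> float:
    """Mean b0/(a0-1) of an Inverse-Gamma(a0, b0) (a0 > 1)."""
    if a0 <= 1:
        raise ValueError("mean undefined for a0 <= 1")
    return b0 / (a0 - 1.0)


def inverse_gamma_var(a0: float, b0: float) -> float:
    """Variance b0^2 / ((a0-1)^2 (a0-2)) of an Inverse-Gamma (a0 > 2)."""
    if a0 <= 2:
        raise ValueError("variance undefined for a0 <= 2")
    return b0 ** 2 / ((a0 - 1.0) ** 2 * (a0 - 2.0))


def built_in_delay_s(mode: str, W: int, fs: float, K_F: int, L_d: int = 0) -> float:
    """Structural reporting delay: (L_d + K_F W)/fs decoding, K_F W/fs encoding."""
    if mode == "decoding":
        return (L_d + K_F * W) / fs
    if mode == "encoding":
        return K_F * W / fs
    raise ValueError(f"unknown mode {mode!r}")


def lognormal_logpdf(m, rho: float, mu: float):
    """Log-density of Log-Normal(rho, mu):
    -ln m + (1/2) ln rho - (rho/2)(ln m - mu)^2 - (1/2) ln(2 pi)."""
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError("marker values must be positive")
    if rho <= 0:
        raise ValueError("precision must be positive")
    lm = np.log(m)
    out = -lm + 0.5 * math.log(rho) - 0.5 * rho * (lm - mu) ** 2 - 0.5 * _LOG_2PI
    return float(out) if out.ndim == 0 else out


def _weighted_gamma_normal_fit(x: np.ndarray, w: np.ndarray,
                               prior: GammaNormalPrior,
                               rho_max: float) -> LogNormalParams:
    """Conjugate Gamma-Normal update from weighted log-marker data.

    Returns the posterior-mean precision alpha_n/rate_n and posterior mean
    log-mean mu_n; with a non-informative prior this reduces to the
    weighted ML fit (rho = n/SS, mu = weighted mean).
    """
    n = float(np.sum(w))
    if n <= 0:
        raise ValueError("empty pool")
    xbar = float(np.sum(w * x) / n)
    ss = float(np.sum(w * (x - xbar) ** 2))
    s = n / prior.ref_n if prior.ref_n > 0 else 1.0  # relative-strength scale
    shape, rate, kappa0 = s * prior.shape, s * prior.rate, s * prior.kappa0
    kappa_n = kappa0 + n
    mu_n = (kappa0 * prior.mu0 + n * xbar) / kappa_n
    alpha_n = shape + 0.5 * n
    rate_n = rate + 0.5 * ss
    if kappa0 > 0:
        rate_n += 0.5 * kappa0 * n * (xbar - prior.mu0) ** 2 / kappa_n
    rho = alpha_n / rate_n if rate_n > 0 else float("inf")
    return LogNormalParams(rho=min(rho, rho_max), mu=mu_n)


def fit_lognormal_supervised(markers, labels, priors: tuple[GammaNormalPrior, GammaNormalPrior] | None = None,
                             inflation: float = 10.0, kappa0: float = 0.1,
                             c0: float = 1.0, a0: float = 2.008,
                             b0: float = 0.2016, rho_max: float = 1e8,
                             exclude_floored: float | None = None) -> StateSpaceParams:
    """Fit attended/unattended Log-Normal laws from labeled instances.

    ``labels`` gives the attended speaker (1 or 2) per instance; markers
    of the attended speaker pool into the attended law and vice versa.
    The returned parameters also carry Gamma-Normal priors re-centered on
    the fits with inflated variances (``inflation`` times the squared
    fitted precision), keeping them nearly non-informative for the
    subsequent EM.

    ``exclude_floored`` drops marker values at or below the given floor
    from the pools: floored markers are imputed placeholders for
    undefined values (e.g. a zero-variance reconstruction), and a single
    log(floor) outlier would otherwise collapse the fitted precision.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.size != markers.K:
        raise ValueError("labels and markers must align")
    att = np.concatenate([markers.m1[labels == 1], markers.m2[labels == 2]])
    unatt = np.concatenate([markers.m1[labels == 2], markers.m2[labels == 1]])
    if exclude_floored is not None:
        att = att[att > exclude_floored]
        unatt = unatt[unatt > exclude_floored]
    if att.size < 2 or unatt.size < 2:
        raise ValueError("need at least 2 attended and 2 unattended markers")
    if priors is None:
        priors = (GammaNormalPrior(), GammaNormalPrior())
    fits = []
    for pool, prior in zip((att, unatt), priors):
        fits.append(_weighted_gamma_normal_fit(np.log(pool), np.ones(pool.size),
                                               prior, rho_max))
    new_priors = []
    for pool, fit in zip((att, unatt), fits):
        # Re-center the Gamma prior on the fit with `inflation` times the
        # sampling variance of the fitted precision (~2 rho^2/n), keeping
        # it weakly informative while anchoring the attended/unattended
        # identities against label switching in the subsequent EM.
        n = pool.size
        shape = n / (2.0 * inflation)
        scale = 2.0 * inflation * fit.rho / n
        new_priors.append(GammaNormalPrior(shape=shape, scale=scale,
                                           mu0=fit.mu,
                                           kappa0=max(n / inflation, kappa0),
                                           ref_n=float(n)))
    return StateSpaceParams(attended=fits[0], unattended=fits[1],
                            prior_attended=new_priors[0],
                            prior_unattended=new_priors[1],
                            c0=c0, a0=a0, b0=b0, rho_max=rho_max)


def responsibilities(m1, m2, z, params: StateSpaceParams):
    """P(n_k = 1 | m_k^(1), m_k^(2), z_k), computed in log-space.

    Equals sigma(z + d) with d the log-likelihood-ratio contrast
    (lf_a(m1) - lf_u(m1)) - (lf_a(m2) - lf_u(m2)); the antisymmetric form
    keeps the speaker-swap symmetry exact. Markers at or below the
    configured floor are treated as missing (zero contrast): an imputed
    placeholder carries no evidence, while its extreme tail density under
    the wider of the two laws would otherwise dominate the posterior.
    """
    a, u = params.attended, params.unattended

    def contrast(m):
        m = np.asarray(m, dtype=float)
        d = (lognormal_logpdf(m, a.rho, a.mu)
             - lognormal_logpdf(m, u.rho, u.mu))
        return np.where(m <= params.marker_floor, 0.0, d)

    r = _sigmoid(np.asarray(z, dtype=float) + (contrast(m1) - contrast(m2)))
    # keep the open interval: saturated contrasts would otherwise round
    # to exactly 0/1 in floating point
    return np.clip(r, 1e-12, 1.0 - 1e-12)


def _laplace_z(r: np.ndarray, eta: np.ndarray, z0: float, c0: float,
               z_init: np.ndarray, max_newton: int = 50,
               grad_tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """MAP of the logistic chain given soft labels r; Laplace covariance.

    Maximizes  sum_k [r_k z_k - log(1 + e^{z_k})]
             - sum_k (z_k - c0 z_{k-1})^2 / (2 eta_k),  z_0 fixed,
    by damped Newton on the (negative-definite, tridiagonal) Hessian.
    Returns the mode and the dense inverse of the negative Hessian.
    """
    K = r.size
    z = z_init.astype(float).copy()

    def neg_obj(zz):
        prev = np.concatenate(([z0], zz[:-1]))
        chain = np.sum((zz - c0 * prev) ** 2 / (2.0 * eta))
        ll = np.sum(r * zz - np.logaddexp(0.0, zz))
        return chain - ll

    f = neg_obj(z)
    for _ in range(max_newton):
        p = _sigmoid(z)
        prev = np.concatenate(([z0], z[:-1]))
        grad = -(z - c0 * prev) / eta + (r - p)
        grad[:-1] += c0 * (z[1:] - c0 * z[:-1]) / eta[1:]
        if np.max(np.abs(grad)) < grad_tol:
            break
        diag = 1.0 / eta + p * (1.0 - p)
        diag[:-1] += c0 ** 2 / eta[1:]
        off = np.zeros(K)
        off[1:] = -c0 / eta[1:]  # superdiagonal entries of -H
        ab = np.vstack([off, diag])
        cb = cholesky_banded(ab, lower=False)
        delta = cho_solve_banded((cb, False), grad)
        step = 1.0
        for _ in range(30):
            z_new = z + step * delta
            f_new = neg_obj(z_new)
            if f_new <= f + 1e-12:
                break
            step *= 0.5
        z, f = z_new, f_new
    # final curvature at the mode
    p = _sigmoid(z)
    diag = 1.0 / eta + p * (1.0 - p)
    diag[:-1] += c0 ** 2 / eta[1:]
    M = np.diag(diag)
    if K > 1:
        od = -c0 / eta[1:]
        M[np.arange(K - 1), np.arange(1, K)] = od
        M[np.arange(1, K), np.arange(K - 1)] = od
    cov = np.linalg.inv(M)
    return z, cov


def _eta_mstep(z: np.ndarray, cov: np.ndarray, z0: float, c0: float,
               a0: float, b0: float) -> np.ndarray:
    """Inverse-Gamma posterior-mode update of each state variance:
    eta_k = (b0 + v_k/2) / (a0 + 3/2) with v_k = E[(z_k - c0 z_{k-1})^2]
    under the Laplace posterior (including the chain cross-covariance)."""
    K = z.size
    prev = np.concatenate(([z0], z[:-1]))
    v = (z - c0 * prev) ** 2 + np.diag(cov)
    if K > 1:
        var_prev = np.diag(cov)[:-1]
        cross = cov[np.arange(1, K), np.arange(K - 1)]
        v[1:] += c0 ** 2 * var_prev - 2.0 * c0 * cross
    return (b0 + 0.5 * v) / (a0 + 1.5)


def estimate_window(m1: np.ndarray, m2: np.ndarray, params: StateSpaceParams,
                    outer_iters: int = 20, inner_iters: int = 1,
                    z_init: np.ndarray | None = None, z0: float = 0.0,
                    eta_init: np.ndarray | None = None,
                    update_obs_params: bool = True):
    """Nested-EM inference over one active window.

    Outer EM updates the Log-Normal observation parameters; the inner EM
    alternates the Laplace E-step for z with conjugate Inverse-Gamma
    updates of eta. Returns ``(z, z_var, eta, resp, params)`` where
    ``params`` is an updated copy serving as the next window's
    initialization.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    K = m1.size
    params = params.copy()
    z = np.zeros(K) if z_init is None else np.asarray(z_init, float).copy()
    eta = (np.full(K, params.eta_prior_mean) if eta_init is None
           else np.asarray(eta_init, float).copy())
    cov = np.zeros((K, K))
    r = np.full(K, 0.5)
    for _ in range(outer_iters):
        r = responsibilities(m1, m2, z, params)
        for _ in range(inner_iters):
            z, cov = _laplace_z(r, eta, z0, params.c0, z)
            eta = _eta_mstep(z, cov, z0, params.c0, params.a0, params.b0)
        if update_obs_params:
            # refresh the responsibilities at the updated state before the
            # observation M-step: the pool assignment must reflect the
            # current posterior, or the first M-step is driven by the
            # symmetric (uninformative) initialization instead of the data
            r = responsibilities(m1, m2, z, params)
            x = np.concatenate([np.log(m1), np.log(m2)])
            w_att = np.concatenate([r, 1.0 - r])
            # floored markers are missing observations: no pool weight
            valid = np.concatenate([m1, m2]) > params.marker_floor
            params.attended = _weighted_gamma_normal_fit(
                x, np.where(valid, w_att, 0.0), params.prior_attended,
                params.rho_max)
            params.unattended = _weighted_gamma_normal_fit(
                x, np.where(valid, 1.0 - w_att, 0.0),
                params.prior_unattended, params.rho_max)
    # final self-consistent E-step with the updated parameters
    r = responsibilities(m1, m2, z, params)
    z, cov = _laplace_z(r, eta, z0, params.c0, z)
    return z, np.diag(cov).copy(), eta, r, params


def _joint_log_posterior(m1, m2, z, eta, params: StateSpaceParams) -> float:
    """Joint log posterior of (z, eta, rho, mu) given the marker series.

    Used to rank candidate EM solutions: the mixture posterior has a
    label-swapped mirror mode, and EM can converge to the lower one.
    """
    prev = np.concatenate(([0.0], z[:-1]))
    lp = float(np.sum(-0.5 * np.log(eta)
                      - (z - params.c0 * prev) ** 2 / (2.0 * eta)))
    lp += float(np.sum(-(params.a0 + 1.0) * np.log(eta) - params.b0 / eta))
    a, u = params.attended, params.unattended
    v1 = m1 > params.marker_floor
    v2 = m2 > params.marker_floor
    fa1 = np.where(v1, lognormal_logpdf(np.maximum(m1, 1e-300), a.rho, a.mu), 0.0)
    fu1 = np.where(v1, lognormal_logpdf(np.maximum(m1, 1e-300), u.rho, u.mu), 0.0)
    fa2 = np.where(v2, lognormal_logpdf(np.maximum(m2, 1e-300), a.rho, a.mu), 0.0)
    fu2 = np.where(v2, lognormal_logpdf(np.maximum(m2, 1e-300), u.rho, u.mu), 0.0)
    lp += float(np.sum(np.logaddexp(-np.logaddexp(0.0, -z) + fa1 + fu2,
                                    -np.logaddexp(0.0, z) + fu1 + fa2)))
    n = float(v1.sum() + v2.sum()) / 2.0
    for law, pr in ((a, params.prior_attended), (u, params.prior_unattended)):
        s = n / pr.ref_n if pr.ref_n > 0 else 1.0
        if pr.shape > 0:
            lp += (s * pr.shape - 1.0) * math.log(law.rho) - s * pr.rate * law.rho
        if pr.kappa0 > 0:
            lp += (0.5 * math.log(law.rho)
                   - 0.5 * s * pr.kappa0 * law.rho * (law.mu - pr.mu0) ** 2)
    return lp


def batch_estimate(markers, params0: StateSpaceParams,
                   outer_iters: int = 20, inner_iters: int = 20,
                   delay_s: float = 0.0) -> AttentionTrajectory:
    """State-space inference over the whole trial at once (K_A = K).

    The whole-trial mixture posterior is bimodal (the label-swapped mirror
    solution always exists); EM is run from a neutral start and from both
    signs of a block-smoothed state informed by the supervised-fit
    responsibilities, and the highest-posterior solution is kept.
    """
    m1, m2 = markers.m1, markers.m2
    K = m1.size
    r0 = responsibilities(m1, m2, np.zeros(K), params0)
    with np.errstate(divide="ignore"):
        logit = np.log(r0) - np.log1p(-r0)
    width = max(min(K, 15), 1)
    smooth = np.convolve(logit, np.ones(width) / width, mode="same")
    z_informed = 2.0 * np.sign(smooth)
    best = None
    for z_init in (np.zeros(K), z_informed, -z_informed):
        z, z_var, eta, r, prm = estimate_window(
            m1, m2, params0, outer_iters=outer_iters,
            inner_iters=inner_iters, z_init=z_init)
        lp = _joint_log_posterior(m1, m2, z, eta, prm)
        if best is None or lp > best[0]:
            best = (lp, z, z_var, eta, r)
    _, z, z_var, eta, r = best
    return AttentionTrajectory(z_mean=z, z_var=z_var, eta=eta,
                               responsibilities=r, mode="batch",
                               built_in_delay_s=delay_s)


def realtime_estimate(markers, params0: StateSpaceParams,
                      config: FixedLagConfig,
                      delay_s: float = 0.0) -> AttentionTrajectory:
    """Fixed-lag sliding-window inference.

    The active window of K_A instances slides one instance at a time; at
    position k0 the estimate at k* = k0 - K_F is emitted and frozen
    (instances past the trailing edge stay fixed and anchor the chain).
    Parameters estimated in each window initialize the next. The final
    K_F instances are emitted from the last window.
    """
    K = markers.K
    KA, KF = config.K_A, config.K_F
    z_work = np.zeros(K)
    var_work = np.zeros(K)
    eta_work = np.full(K, params0.eta_prior_mean)
    r_work = np.full(K, 0.5)
    z_frozen = np.zeros(K)
    var_frozen = np.zeros(K)
    eta_frozen = eta_work.copy()
    r_frozen = r_work.copy()
    params = params0.copy()
    for k0 in range(1, K + 1):
        start = max(1, k0 - KA + 1)
        sl = slice(start - 1, k0)
        z0 = z_frozen[start - 2] if start > 1 else 0.0
        z, z_var, eta, r, params = estimate_window(
            markers.m1[sl], markers.m2[sl], params,
            outer_iters=config.outer_iters, inner_iters=config.inner_iters,
            z_init=z_work[sl], z0=z0, eta_init=eta_work[sl])
        z_work[sl], var_work[sl], eta_work[sl], r_work[sl] = z, z_var, eta, r
        kstar = k0 - KF
        if kstar >= 1:
            i = kstar - start  # index inside the window
            z_frozen[kstar - 1] = z[i]
            var_frozen[kstar - 1] = z_var[i]
            eta_frozen[kstar - 1] = eta[i]
            r_frozen[kstar - 1] = r[i]
    # flush the trailing K_F instances from the final window
    if KF > 0 and K > 0:
        start = max(1, K - KA + 1)
        tail = slice(max(K - KF, start - 1), K)
        z_frozen[tail] = z_work[tail]
        var_frozen[tail] = var_work[tail]
        eta_frozen[tail] = eta_work[tail]
        r_frozen[tail] = r_work[tail]
    return AttentionTrajectory(z_mean=z_frozen, z_var=var_frozen,
                               eta=eta_frozen, responsibilities=r_frozen,
                               mode="realtime", built_in_delay_s=delay_s)


def compute_mse(traj_realtime: AttentionTrajectory,
                traj_batch: AttentionTrajectory) -> float:
    """Mean squared difference of the two probability trajectories:
    (1/K) sum_k (sigma(z_k^batch) - sigma(z_k^realtime))^2."""
    if traj_realtime.K != traj_batch.K:
        raise ValueError("trajectories must have equal length")
    return float(np.mean((traj_batch.p - traj_realtime.p) ** 2))


@dataclass
class ClassificationSummary:
    hit_rate: float
    false_alarm_rate: float
    unclassified_rate: float
    labels: np.ndarray  # per-instance: 1 correct, -1 incorrect, 0 unclassified

    @property
    def n_correct(self) -> int:
        return int(np.sum(self.labels == 1))

    @property
    def n_incorrect(self) -> int:
        return int(np.sum(self.labels == -1))


def classify_instances(traj: AttentionTrajectory, truth,
                       excluded=None) -> ClassificationSummary:
    """Confidence-interval classification of instances.

    The probability is oriented toward the attended speaker (p for
    truth = 1, 1 - p with swapped CI bounds otherwise); an instance is
    correct if its whole 90% CI lies above 0.5, incorrect if below, and
    unclassified otherwise. Rates are over non-excluded instances.
    """
    truth = np.asarray(truth, dtype=int)
    if truth.size != traj.K:
        raise ValueError("truth and trajectory must align")
    lo, hi = traj.ci_lo.copy(), traj.ci_hi.copy()
    swap = truth == 2
    lo[swap], hi[swap] = 1.0 - traj.ci_hi[swap], 1.0 - traj.ci_lo[swap]
    labels = np.zeros(traj.K, dtype=int)
    labels[lo > 0.5] = 1
    labels[hi < 0.5] = -1
    mask = np.ones(traj.K, dtype=bool)
    if excluded is not None:
        mask &= ~np.asarray(excluded, dtype=bool)
    n = int(mask.sum())
    labels = np.where(mask, labels, 0)
    hit = float(np.sum(labels[mask] == 1)) / n if n else 0.0
    fa = float(np.sum(labels[mask] == -1)) / n if n else 0.0
    return ClassificationSummary(hit_rate=hit, false_alarm_rate=fa,
                                 unclassified_rate=1.0 - hit - fa,
                                 labels=labels)
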