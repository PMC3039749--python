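"""Variational Bayesian inversion of the skin-conductance forward model.

Given a pre-processed 60-s epoch, the inversion estimates the sudomotor
burst train (onsets and amplitudes) most likely to have generated the
observed trace.  The scheme is variational Laplace: a Gaussian posterior
over per-burst log-amplitude and onset is optimized by damped Gauss-Newton
ascent on the free energy (evidence lower bound), alternated with exact
mean-field updates of a Gamma posterior over the observation-noise
precision.  Candidate bursts are initialized on a regular grid at the
model's maximum burst rate (30/min, so one candidate per 2 s); unused
candidates shrink toward a tiny prior-mean amplitude, used candidates move
(the onset is a free parameter) and grow to fit the data.

Observation model: y = g(theta) + e,  e ~ N(0, 1/lambda),
with g the ODE convolution of the Gaussian burst input, theta the stacked
log-amplitudes and onsets, and lambda ~ Gamma(a0, b0).

The free energy evaluated here is the standard variational-Laplace bound

    F = E_q[ln p(y | theta, lambda)] - KL(q(theta) || p(theta))
        - KL(q(lambda) || p(lambda)),

with the expected residual sum of squares under q(theta) taken to second
order via the local linearization of g (r'r + tr(J S J')).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import linalg as sla
from scipy.special import digamma, gammaln

from .forward import (
    BURST_SIGMA_S,
    MAX_BURST_RATE_PER_MIN,
    BurstTrain,
    KernelParams,
    gaussian_input,
    impulse_response,
    simulate,
)
from .preproc import ConductanceSeries, Epoch

_LN2PI = math.log(2.0 * math.pi)


@dataclass
class InversionConfig:
    """Tunable knobs of the variational inversion.

    ``max_rate`` caps the candidate-burst density (bursts/min); ``sigma`` is
    the Gaussian burst width (s).  ``prior_amp_mean`` is the prior mean of
    the log-amplitude (default ln 0.01, i.e. a prior-median fluctuation of
    0.01 μS, so unused candidates are negligible), ``prior_amp_sd`` its SD in
    log units.  ``prior_onset_sd`` (s) is the SD of each candidate's
    Gaussian onset prior centred on its grid position.  ``tol`` is the
    free-energy convergence tolerance in nats.  ``merge_window`` (s) is the
    single-linkage radius within which posterior bursts are merged into one
    (amplitudes summed) before reporting.
    """

    max_rate: float = MAX_BURST_RATE_PER_MIN
    sigma: float = BURST_SIGMA_S
    prior_amp_mean: float = math.log(0.01)
    prior_amp_sd: float = 2.0
    prior_onset_sd: float = 1.0
    tol: float = 1e-2
    max_iter: int = 200
    seed: int = 0
    noise_shape: float = 1e-2
    noise_rate: float = 1e-2
    merge_window: float = 0.4
    oversample: int = 2

    def __post_init__(self) -> None:
        if not (self.max_rate > 0):
            raise ValueError("max_rate must be positive")
        if not (self.tol > 0):
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")


@dataclass
class Posterior:
    """Gaussian posterior over [log-amplitudes, onsets] + Gamma over precision."""

    mean: np.ndarray        # length 2N: [z_1..z_N, mu_1..mu_N]
    cov: np.ndarray         # (2N, 2N)
    noise_shape: float      # Gamma a
    noise_rate: float       # Gamma b

    @property
    def n_candidates(self) -> int:
        return self.mean.size // 2


@dataclass
class InversionResult:
    bursts: BurstTrain
    amp_sd: np.ndarray
    onset_sd: np.ndarray
    noise_precision: float
    free_energy: float
    fitted: ConductanceSeries
    residual_sd: float
    n_iter: int
    converged: bool
    f_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    posterior: Posterior | None = None


class _Problem:
    """Precomputed machinery for one epoch: grids, kernel, priors, bound."""

    def __init__(self, epoch: Epoch, params: KernelParams, cfg: InversionConfig):
        y = epoch.series.samples
        if not np.all(np.isfinite(y)):
            raise ValueError("epoch contains non-finite samples")
        self.y = y
        self.n = y.size
        self.rate = epoch.series.rate
        self.t0 = epoch.series.t0
        self.duration = epoch.series.duration
        self.cfg = cfg
        self.params = params

        self.N = int(np.ceil(self.duration * cfg.max_rate / 60.0))
        # candidate grid: centres of N equal bins across the epoch
        self.grid = self.t0 + (np.arange(self.N) + 0.5) * self.duration / self.N

        self.os = max(1, int(cfg.oversample))
        self.rate_i = self.rate * self.os
        self.n_i = self.n * self.os
        self.t_i = self.t0 + np.arange(self.n_i) / self.rate_i
        h = impulse_response(params, self.duration, self.rate_i)  # includes gain
        self.h_dt = h / self.rate_i  # kernel premultiplied by dt
        self._nfft = sfft.next_fast_len(2 * self.n_i - 1, real=True)
        self._H = np.fft.rfft(self.h_dt, self._nfft)

        # prior moments: theta = [z (log-amp), mu (onset)]
        self.m0 = np.concatenate([
            np.full(self.N, cfg.prior_amp_mean), self.grid
        ])
        self.p0 = np.concatenate([
            np.full(self.N, 1.0 / cfg.prior_amp_sd**2),
            np.full(self.N, 1.0 / cfg.prior_onset_sd**2),
        ])
        self.logdet_prior_cov = float(-np.sum(np.log(self.p0)))
        self.a0 = cfg.noise_shape
        self.b0 = cfg.noise_rate

    # -- forward map and Jacobian -------------------------------------------
    def linearize(self, m: np.ndarray):
        """Return (g, J) at posterior mean m, on the epoch's sample grid."""
        N = self.N
        z, mu = m[:N], m[N:]
        a = np.exp(np.clip(z, -30.0, 10.0))
        sig = self.cfg.sigma
        d = self.t_i[:, None] - mu[None, :]
        phi = np.exp(-(d**2) / (2.0 * sig**2))
        phi[np.abs(d) > 5.0 * sig] = 0.0
        dphi = phi * d / sig**2  # d phi / d mu
        basis = np.concatenate([phi, dphi], axis=1)
        spec = np.fft.rfft(basis, self._nfft, axis=0)
        conv = np.fft.irfft(spec * self._H[:, None], self._nfft, axis=0)[: self.n_i]
        psi = conv[:: self.os]  # (n, 2N)
        g = psi[:, :N] @ a
        J = psi * np.concatenate([a, a])[None, :]
        return g, J

    def posterior_cov(self, J: np.ndarray, e_lam: float):
        """Optimal Gaussian covariance S = (E[lam] J'J + P0)^-1 and its logdet."""
        H = e_lam * (J.T @ J) + np.diag(self.p0)
        cf = sla.cho_factor(H, lower=True)
        S = sla.cho_solve(cf, np.eye(H.shape[0]))
        logdet_S = -2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        return S, logdet_S

    def bound_at(self, m: np.ndarray, a: float, b: float) -> float:
        """Free energy at mean ``m`` with the optimal covariance."""
        g, J = self.linearize(m)
        r = self.y - g
        S, logdet_S = self.posterior_cov(J, a / b)
        return self.bound(r, J, S, logdet_S, m, a, b)

    def gn_ascend(self, m: np.ndarray, a: float, b: float, n_steps: int,
                  nu: float = 1e-3):
        """Up to ``n_steps`` damped Gauss-Newton steps, each accepted only on
        a free-energy increase.  Returns (m, f, nu)."""
        g, J = self.linearize(m)
        r = self.y - g
        S, logdet_S = self.posterior_cov(J, a / b)
        f = self.bound(r, J, S, logdet_S, m, a, b)
        e_lam = a / b
        d = m.size
        for _ in range(n_steps):
            grad = e_lam * (J.T @ r) - self.p0 * (m - self.m0)
            JtJ = J.T @ J
            accepted = False
            for _ in range(10):
                H = e_lam * JtJ + np.diag(self.p0)
                H[np.diag_indices(d)] += nu * np.diag(H)
                try:
                    dm = sla.cho_solve(sla.cho_factor(H, lower=True), grad)
                except sla.LinAlgError:
                    nu *= 10.0
                    continue
                m_c = m + dm
                g_c, J_c = self.linearize(m_c)
                r_c = self.y - g_c
                S_c, logdet_Sc = self.posterior_cov(J_c, e_lam)
                f_c = self.bound(r_c, J_c, S_c, logdet_Sc, m_c, a, b)
                if f_c >= f:
                    m, g, J, r, f = m_c, g_c, J_c, r_c, f_c
                    nu = max(nu * 0.3, 1e-8)
                    accepted = True
                    break
                nu *= 10.0
            if not accepted:
                break
        return m, f, nu

    # -- free energy --------------------------------------------------------
    def bound(self, r, J, S, logdet_S, m, a, b) -> float:
        n, d = self.n, m.size
        e_lam = a / b
        e_lnlam = digamma(a) - math.log(b)
        e_rss = float(r @ r) + float(np.sum((J @ S) * J))
        accuracy = 0.5 * n * (e_lnlam - _LN2PI) - 0.5 * e_lam * e_rss
        dm = m - self.m0
        kl_theta = 0.5 * (
            float(self.p0 @ np.diag(S))
            + float(dm @ (self.p0 * dm))
            - d
            + self.logdet_prior_cov
            - logdet_S
        )
        a0, b0 = self.a0, self.b0
        kl_lam = (
            (a - a0) * digamma(a)
            - gammaln(a)
            + gammaln(a0)
            + a0 * (math.log(b) - math.log(b0))
            + a * (b0 - b) / b
        )
        return accuracy - kl_theta - kl_lam


def free_energy(
    epoch: Epoch,
    params: KernelParams,
    posterior: Posterior,
    cfg: InversionConfig | None = None,
) -> float:
    """Evaluate the variational free energy for a given posterior.

    Deterministic given its inputs; uses the posterior's own covariance (no
    re-optimization).  Equals the expected Gaussian log-likelihood minus the
    KL divergences of the Gaussian parameter posterior and the Gamma
    precision posterior from their priors.
    """
    cfg = cfg or InversionConfig()
    if posterior.noise_shape <= 0 or posterior.noise_rate <= 0:
        raise ValueError("noise precision posterior must have positive shape/rate")
    if not (np.all(np.isfinite(posterior.mean)) and np.all(np.isfinite(posterior.cov))):
        raise ValueError("posterior moments must be finite")
    prob = _Problem(epoch, params, cfg)
    if posterior.mean.size != 2 * prob.N:
        raise ValueError(
            f"posterior has {posterior.mean.size} parameters, expected {2 * prob.N}"
        )
    g, J = prob.linearize(posterior.mean)
    r = prob.y - g
    sign, logdet_S = np.linalg.slogdet(posterior.cov)
    if sign <= 0:
        raise ValueError("posterior covariance must be positive definite")
    return prob.bound(
        r, J, posterior.cov, logdet_S, posterior.mean,
        posterior.noise_shape, posterior.noise_rate,
    )


def _merge_bursts(onsets, amps, amp_sd, onset_sd, window):
    """Single-linkage merge of bursts closer than ``window`` seconds.

    Amplitudes sum (co-located Gaussians superpose into one burst of the
    summed amplitude); merged onset is the amplitude-weighted mean.
    """
    order = np.argsort(onsets, kind="stable")
    onsets, amps = onsets[order], amps[order]
    amp_sd, onset_sd = amp_sd[order], onset_sd[order]
    groups = []
    start = 0
    for i in range(1, len(onsets) + 1):
        if i == len(onsets) or onsets[i] - onsets[i - 1] > window:
            groups.append(slice(start, i))
            start = i
    m_on, m_amp, m_asd, m_osd = [], [], [], []
    for g in groups:
        a = amps[g]
        w = a / a.sum() if a.sum() > 0 else np.full(a.size, 1.0 / a.size)
        m_on.append(float(w @ onsets[g]))
        m_amp.append(float(a.sum()))
        m_asd.append(float(np.sqrt(np.sum(amp_sd[g] ** 2))))
        m_osd.append(float(w @ onset_sd[g]))
    return (np.array(m_on), np.array(m_amp), np.array(m_asd), np.array(m_osd))


def invert_epoch(
    epoch: Epoch, params: KernelParams, cfg: InversionConfig | None = None
) -> InversionResult:
    """Variational-Laplace inversion of one pre-processed epoch.

    Alternates (i) an exact mean-field update of the Gamma noise-precision
    posterior, (ii) the closed-form optimal Gaussian covariance, and (iii) a
    Levenberg-damped Gauss-Newton step on the posterior mean accepted only
    if it increases the free energy.  Each sub-step maximizes (or cannot
    decrease) the bound, so the recorded free-energy trace is non-decreasing.
    Terminates when the per-iteration gain drops below ``cfg.tol`` nats or
    after ``cfg.max_iter`` iterations (then ``converged=False``; no
    exception).
    """
    cfg = cfg or InversionConfig()
    prob = _Problem(epoch, params, cfg)
    n, d = prob.n, 2 * prob.N

    m = prob.m0.copy()
    g, J = prob.linearize(m)
    r = prob.y - g
    a = prob.a0 + 0.5 * n
    b = prob.b0 + 0.5 * float(r @ r)

    f_trace: list[float] = []
    converged = False
    nu = 1e-3
    f_prev = -np.inf
    n_iter = 0
    for n_iter in range(1, cfg.max_iter + 1):
        # (i) noise-precision update, (ii) optimal covariance (iterated once
        # more so S reflects the updated precision)
        S, logdet_S = prob.posterior_cov(J, a / b)
        b = prob.b0 + 0.5 * (float(r @ r) + float(np.sum((J @ S) * J)))
        S, logdet_S = prob.posterior_cov(J, a / b)
        f_cur = prob.bound(r, J, S, logdet_S, m, a, b)
        f_trace.append(f_cur)
        if f_cur - f_prev < cfg.tol and n_iter > 1:
            converged = True
            break
        f_prev = f_cur

        # (iii) damped Gauss-Newton step on the mean, accepted on F increase
        e_lam = a / b
        grad = e_lam * (J.T @ r) - prob.p0 * (m - prob.m0)
        JtJ = J.T @ J
        accepted = False
        for _ in range(12):
            H = e_lam * JtJ + np.diag(prob.p0)
            H[np.diag_indices(d)] += nu * np.diag(H)
            try:
                dm = sla.cho_solve(sla.cho_factor(H, lower=True), grad)
            except sla.LinAlgError:
                nu *= 10.0
                continue
            m_c = m + dm
            g_c, J_c = prob.linearize(m_c)
            r_c = prob.y - g_c
            S_c, logdet_Sc = prob.posterior_cov(J_c, e_lam)
            f_c = prob.bound(r_c, J_c, S_c, logdet_Sc, m_c, a, b)
            if f_c >= f_cur:
                m, g, J, r = m_c, g_c, J_c, r_c
                f_trace.append(f_c)
                nu = max(nu * 0.3, 1e-8)
                accepted = True
                break
            nu *= 10.0
        if not accepted:
            converged = True  # local maximum: no damped step improves F
            f_trace.append(f_cur)
            break

    # Discrete merge proposals: two candidates splitting one burst's
    # amplitude is a local optimum (the convex log-amplitude prior rewards
    # sharing, and noise rewards slight offsets).  Propose summing each
    # close active pair into a single burst, polish with a few Gauss-Newton
    # steps, and keep the merge only if the free energy improves.
    f_cur = f_trace[-1]
    for _ in range(2 * prob.N):
        z_c, mu_c = m[: prob.N], m[prob.N :]
        amps_c = np.exp(z_c)
        active = np.flatnonzero(amps_c > 0.03)
        if active.size < 2:
            break
        order_a = active[np.argsort(mu_c[active])]
        gaps = np.diff(mu_c[order_a])
        close = np.flatnonzero(gaps < 1.0)
        merged_any = False
        for ci in close[np.argsort(gaps[close])]:
            i, j = order_a[ci], order_a[ci + 1]
            m_p = m.copy()
            tot = amps_c[i] + amps_c[j]
            m_p[i] = math.log(tot)
            m_p[prob.N + i] = (amps_c[i] * mu_c[i] + amps_c[j] * mu_c[j]) / tot
            m_p[j] = cfg.prior_amp_mean
            m_p[prob.N + j] = prob.grid[j]
            m_p, f_p, _ = prob.gn_ascend(m_p, a, b, 8)
            if f_p > f_cur + 1e-6:
                m = m_p
                g, J = prob.linearize(m)
                r = prob.y - g
                S, _ = prob.posterior_cov(J, a / b)
                b = prob.b0 + 0.5 * (float(r @ r) + float(np.sum((J @ S) * J)))
                f_trace.append(f_p)
                f_cur = prob.bound_at(m, a, b)
                f_trace.append(f_cur)
                merged_any = True
                break
        if not merged_any:
            break

    S, logdet_S = prob.posterior_cov(J, a / b)
    posterior = Posterior(mean=m.copy(), cov=S, noise_shape=a, noise_rate=b)

    N = prob.N
    z, mu = m[:N], m[N:]
    amps = np.exp(z)
    sd = np.sqrt(np.clip(np.diag(S), 0.0, None))
    amp_sd = amps * sd[:N]        # delta method on exp(z)
    onset_sd = sd[N:]
    m_on, m_amp, m_asd, m_osd = _merge_bursts(
        mu, amps, amp_sd, onset_sd, cfg.merge_window
    )
    # the fitted trace uses everything the posterior found, including bursts
    # whose onsets drifted before the window start (tails of pre-epoch
    # activity / the noise floor offset left by minimum subtraction) ...
    order_all = np.lexsort((-m_amp, m_on))
    full_train = BurstTrain(m_on[order_all], m_amp[order_all], sigma=cfg.sigma)
    fitted = simulate(params, full_train, prob.duration, prob.rate, t0=prob.t0)
    residual = prob.y - fitted.samples
    # ... but only bursts onset inside the epoch are reported as responses
    inside = (m_on >= prob.t0) & (m_on < prob.t0 + prob.duration)
    m_on, m_amp = m_on[inside], m_amp[inside]
    m_asd, m_osd = m_asd[inside], m_osd[inside]
    order = np.lexsort((-m_amp, m_on))
    train = BurstTrain(m_on[order], m_amp[order], sigma=cfg.sigma)
    return InversionResult(
        bursts=train,
        amp_sd=m_asd[order],
        onset_sd=m_osd[order],
        noise_precision=a / b,
        free_energy=f_trace[-1],
        fitted=fitted,
        residual_sd=float(np.std(residual)),
        n_iter=n_iter,
        converged=converged,
        f_trace=np.asarray(f_trace),
        posterior=posterior,
    )


def extract_sna(result: InversionResult, duration: float, rate: float) -> np.ndarray:
    """Continuous sudomotor-activity trace implied by the posterior bursts."""
    return gaussian_input(result.bursts, duration, rate, t0=result.fitted.t0)
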