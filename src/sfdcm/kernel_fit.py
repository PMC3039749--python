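"""Estimating the canonical response function and fitting the ODE kernel.

Two stages: (1) an uninformed finite-impulse-response (FIR) model estimates
the canonical response function (CRF) — the stereotyped conductance waveform
evoked by a single burst — from epochs with known burst onsets, by ordinary
least squares on a design of lagged indicators (overlapping responses
superpose linearly and share one kernel); (2) the three ODE rates and the
gain are fit so the kernel's impulse response matches a given CRF, as a
maximum-a-posteriori estimate with Gaussian priors on the log-rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .forward import KernelParams, impulse_response
from .preproc import Epoch


class FIRDesignError(ValueError):
    """Raised when the FIR design matrix is rank deficient."""


class KernelFitError(RuntimeError):
    """Raised when the ODE fit fails to converge; carries the best attempt."""

    def __init__(self, message: str, params: KernelParams, rmse: float):
        super().__init__(message)
        self.params = params
        self.rmse = rmse


@dataclass
class CRF:
    """Canonical response function: μS per unit event, sampled at ``rate``."""

    samples: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("CRF samples must be finite")
        if not (self.rate > 0):
            raise ValueError("rate must be positive")
        if self.window < 10.0:
            raise ValueError("CRF window must cover at least 10 s of decay")

    @property
    def window(self) -> float:
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("t_s,value\n")
            for t, v in zip(self.times, self.samples):
                fh.write(f"{t:.9g},{v:.9g}\n")

    @classmethod
    def from_csv(cls, path) -> "CRF":
        import pandas as pd

        df = pd.read_csv(path)
        t = df.iloc[:, 0].to_numpy(float)
        rate = 1.0 / np.median(np.diff(t))
        return cls(df.iloc[:, 1].to_numpy(float), rate=float(round(rate, 9)))


@dataclass
class KernelFitResult:
    params: KernelParams
    rmse: float
    converged: bool
    n_restarts: int


def fir_design(n: int, onset_indices, L: int) -> np.ndarray:
    """Lagged-indicator design for one epoch: column l is 1 at onset+l."""
    X = np.zeros((n, L))
    for j in onset_indices:
        lags = np.arange(L)
        rows = j + lags
        keep = rows < n
        X[rows[keep], lags[keep]] += 1.0
    return X


def estimate_crf_fir(
    epochs: list[Epoch], onsets: list, window: float = 30.0
) -> CRF:
    """Least-squares FIR estimate of the CRF from epochs with known onsets.

    Each epoch's trace is modelled as the sum, over its onsets, of one
    shared kernel shifted to that onset.  Onsets (seconds, per epoch) are
    rounded to the nearest sample.  The solution is the ordinary
    least-squares fit of the stacked lagged-indicator design.
    """
    if len(epochs) != len(onsets):
        raise ValueError("need one onset list per epoch")
    if sum(len(o) for o in onsets) == 0:
        raise ValueError("at least one onset is required")
    rate = epochs[0].series.rate
    L = int(round(window * rate))
    blocks_X, blocks_y = [], []
    for ep, ons in zip(epochs, onsets):
        if ep.series.rate != rate:
            raise ValueError("all epochs must share one sampling rate")
        n = ep.series.n
        idx = [int(round((o - ep.series.t0) * rate)) for o in ons]
        if any(j < 0 or j >= n for j in idx):
            raise ValueError("onset outside its epoch")
        blocks_X.append(fir_design(n, idx, L))
        blocks_y.append(ep.series.samples)
    X = np.vstack(blocks_X)
    y = np.concatenate(blocks_y)
    if X.shape[0] <= L:
        raise FIRDesignError(
            "fewer samples than FIR coefficients; use longer data or a shorter window"
        )
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < L:
        raise FIRDesignError(
            f"FIR design is rank deficient (rank {rank} < {L}); "
            "use longer data or a shorter window"
        )
    return CRF(beta, rate=rate)


def _model_response(k, rate, n_out, input_sigma):
    """Impulse response, optionally smeared by the Gaussian burst waveform.

    With ``input_sigma`` set, the modelled curve is the response to a
    unit-peak Gaussian burst centred at t = 0 (what a lagged-indicator FIR
    estimates when onsets mark burst centres), rather than to a Dirac pulse.
    """
    if not input_sigma:
        return impulse_response(KernelParams(*k), n_out / rate, rate)
    half = int(np.ceil(5.0 * input_sigma * rate))
    tg = np.arange(-half, half + 1) / rate
    g = np.exp(-(tg**2) / (2.0 * input_sigma**2)) / rate  # unit-peak * dt
    h = impulse_response(KernelParams(*k), (n_out + half) / rate, rate)
    full = np.convolve(h, g)
    return full[half : half + n_out]


def _penalized_objective(log_rates, crf_samples, rate, duration, mu0, prior_sd,
                         obs_sd, input_sigma=None):
    """Negative log-posterior with the gain profiled out in closed form."""
    k = np.exp(log_rates)
    h = _model_response(k, rate, crf_samples.size, input_sigma)
    hh = h @ h
    if hh <= 0:
        return np.inf, 0.0
    gain = (h @ crf_samples) / hh
    resid = gain * h - crf_samples
    nll = 0.5 * (resid @ resid) / obs_sd**2
    prior = 0.5 * np.sum(((log_rates - mu0) / prior_sd) ** 2)
    return nll + prior, gain


def fit_ode_to_crf(
    crf: CRF,
    init: KernelParams,
    prior_sd: float = 1.0,
    obs_sd: float | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    tol: float = 1e-10,
    input_sigma: float | None = None,
) -> KernelFitResult:
    """MAP fit of the third-order kernel to a canonical response function.

    Optimizes the log-rates (Gaussian prior, mean = log of ``init`` rates,
    SD ``prior_sd`` in log units) with the gain profiled out by linear least
    squares; ``obs_sd`` (default 1% of the CRF peak) sets the data weighting.
    A deterministic start at ``init`` plus up to ``n_restarts`` seeded
    jittered restarts guard against local optima.  Returned rates are sorted
    descending (the kernel is symmetric under pole permutation).

    If the CRF was estimated from burst onsets (so it is the response to a
    whole Gaussian burst, not to an impulse), pass the burst width as
    ``input_sigma`` so the fit deconvolves the burst shape.
    """
    y = crf.samples
    peak = float(np.max(np.abs(y)))
    if peak == 0:
        raise ValueError("CRF is identically zero")
    if obs_sd is None:
        obs_sd = 0.01 * peak
    duration = crf.samples.size / crf.rate
    mu0 = np.log(init.rates)
    rng = np.random.default_rng(seed)
    starts = [mu0] + [
        mu0 + 0.3 * rng.standard_normal(3) for _ in range(n_restarts)
    ]
    best = None
    any_ok = False
    for x0 in starts:
        res = optimize.minimize(
            lambda lr: _penalized_objective(lr, y, crf.rate, duration, mu0,
                                            prior_sd, obs_sd, input_sigma)[0],
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": tol, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
        any_ok = any_ok or res.success
    obj, gain = _penalized_objective(best.x, y, crf.rate, duration, mu0,
                                     prior_sd, obs_sd, input_sigma)
    k = np.sort(np.exp(best.x))[::-1]
    params = KernelParams(k1=k[0], k2=k[1], k3=k[2], gain=gain)
    h = gain * _model_response(np.exp(best.x), crf.rate, y.size, input_sigma)
    rmse = float(np.sqrt(np.mean((h - y) ** 2)))
    result = KernelFitResult(
        params=params, rmse=rmse, converged=any_ok, n_restarts=len(starts) - 1
    )
    if not any_ok:
        raise KernelFitError(
            f"kernel fit did not converge (best RMSE {rmse:.3g})", params, rmse
        )
    return result
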