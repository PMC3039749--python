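"""Generative model: Gaussian sudomotor bursts through a third-order ODE.

Sudomotor nerve activity (SNA) is modelled as a train of Gaussian bumps of
fixed width (SD 0.3 s) and variable amplitude, with a maximum burst rate of
30 per minute.  The mapping from SNA to skin conductance is a linear
time-invariant system

    d3x/dt3 + c2 d2x/dt2 + c1 dx/dt + c0 x = u(t),      y = gain * x,

a third-order ODE whose characteristic polynomial has roots ``-k1, -k2,
-k3`` (all rates positive, so the impulse response is a stable sum of
decaying exponentials — a biphasic-decay convolution kernel).  Amplitudes
are expressed in skin-conductance-equivalent units: after
:func:`calibrate_gain`, a unit-amplitude burst produces a fluctuation with a
peak of exactly 1 μS, so a burst of amplitude ``a`` peaks at ``a`` μS and
amplitude thresholds in μS apply directly to burst amplitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg, signal

#: Width (SD, seconds) of the Gaussian burst waveform.
BURST_SIGMA_S = 0.3

#: Maximum plausible burst rate, per minute.
MAX_BURST_RATE_PER_MIN = 30.0

#: Gaussians are evaluated over +/- this many SDs (truncation error < 1e-5).
_GAUSS_TRUNC_SD = 5.0

#: Minimum internal integration rate (Hz) for the ODE solution.
_MIN_INTERNAL_RATE = 100.0


class CalibrationError(RuntimeError):
    """Raised when gain calibration is impossible (degenerate kernel)."""


@dataclass(frozen=True)
class KernelParams:
    """Rate coefficients and output gain of the conductance response kernel.

    ``k1, k2, k3`` are the (positive) decay rates in 1/s — the negated poles
    of the transfer function ``gain / ((s+k1)(s+k2)(s+k3))``.  ``gain``
    scales the output; :func:`calibrate_gain` fixes it so that a unit burst
    yields a 1 μS peak at ``calibrated_at_rate_hz``.
    """

    k1: float
    k2: float
    k3: float
    gain: float = 1.0
    calibrated_at_rate_hz: float | None = None

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "k3"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive (stable kernel)")
        if not np.isfinite(self.gain):
            raise ValueError("gain must be finite")

    @property
    def rates(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3])

    def state_space(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Companion-form realization (A, B, C) with y = gain * x1."""
        c2 = self.k1 + self.k2 + self.k3
        c1 = self.k1 * self.k2 + self.k1 * self.k3 + self.k2 * self.k3
        c0 = self.k1 * self.k2 * self.k3
        A = np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [-c0, -c1, -c2]])
        B = np.array([[0.0], [0.0], [1.0]])
        C = np.array([[self.gain, 0.0, 0.0]])
        return A, B, C

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"k1 = {self.k1!r}\n")
            fh.write(f"k2 = {self.k2!r}\n")
            fh.write(f"k3 = {self.k3!r}\n")
            fh.write(f"gain = {self.gain!r}\n")
            if self.calibrated_at_rate_hz is not None:
                fh.write(f"calibrated_at_rate_hz = {self.calibrated_at_rate_hz!r}\n")

    @classmethod
    def from_file(cls, path) -> "KernelParams":
        fields: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                fields[key.strip()] = float(value)
        return cls(**fields)


@dataclass
class BurstTrain:
    """Ordered (onset, amplitude) pairs describing SNA input.

    Onsets are in seconds and must be non-decreasing; amplitudes are
    non-negative and, under a calibrated kernel, equal the peak conductance
    (μS) the burst alone would produce.  ``sigma`` is the Gaussian burst
    width (seconds).
    """

    onsets: np.ndarray
    amplitudes: np.ndarray
    sigma: float = BURST_SIGMA_S

    def __post_init__(self) -> None:
        self.onsets = np.atleast_1d(np.asarray(self.onsets, dtype=float))
        self.amplitudes = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        if self.onsets.shape != self.amplitudes.shape:
            raise ValueError("onsets and amplitudes must have equal length")
        if self.onsets.size and np.any(np.diff(self.onsets) < 0):
            raise ValueError("onsets must be non-decreasing")
        if np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")
        if not (self.sigma > 0):
            raise ValueError("sigma must be positive")

    def __len__(self) -> int:
        return self.onsets.size

    def check_rate(self, duration: float,
                   max_rate: float = MAX_BURST_RATE_PER_MIN) -> None:
        """Validate mean burst density against the model's maximum rate."""
        if len(self) > np.ceil(duration * max_rate / 60.0):
            raise ValueError(
                f"{len(self)} bursts in {duration} s exceeds {max_rate}/min"
            )

    @classmethod
    def empty(cls, sigma: float = BURST_SIGMA_S) -> "BurstTrain":
        return cls(np.empty(0), np.empty(0), sigma=sigma)


def default_kernel() -> KernelParams:
    """Package default response kernel, calibrated at 10 Hz.

    A synthetic canonical parameter set (no empirically fitted coefficients
    are shipped): the rates were chosen to reproduce the stereotyped
    fluctuation shape reported for electrodermal responses — a rise to peak
    at about 3 s and a biphasic decay with a fast (~1.3 s) and a slow
    (~5 s) time constant.  See docs/methods.md for the provenance note.
    """
    p = KernelParams(k1=2.0, k2=0.8, k3=0.2)
    return calibrate_gain(p, rate=10.0)


def gaussian_input(train: BurstTrain, duration: float, rate: float,
                   t0: float = 0.0) -> np.ndarray:
    """Evaluate the summed Gaussian burst waveform on the sample grid.

    ``u(t) = sum_i a_i exp(-(t - mu_i)^2 / (2 sigma^2))`` with the unit-peak
    convention (no area normalization).  Each Gaussian is truncated at
    +/- 5 SD; superposition over bursts is exact.
    """
    if not (duration > 0 and rate > 0):
        raise ValueError("duration and rate must be positive")
    n = int(round(duration * rate))
    t = t0 + np.arange(n) / rate
    u = np.zeros(n)
    half = _GAUSS_TRUNC_SD * train.sigma
    inv2s2 = 1.0 / (2.0 * train.sigma**2)
    for mu, a in zip(train.onsets, train.amplitudes):
        lo = int(np.searchsorted(t, mu - half))
        hi = int(np.searchsorted(t, mu + half))
        if hi > lo:
            u[lo:hi] += a * np.exp(-((t[lo:hi] - mu) ** 2) * inv2s2)
    return u


def impulse_response(params: KernelParams, duration: float, rate: float) -> np.ndarray:
    """Impulse response ``h(t)`` on the sample grid, zero initial conditions.

    Computed exactly on the grid by propagating the state with the matrix
    exponential: ``h(k/rate) = C expm(A/rate)^k B``.  The system has relative
    degree 3, so ``h(0) = h'(0) = 0``.
    """
    if not (duration > 0 and rate > 0):
        raise ValueError("duration and rate must be positive")
    A, B, C = params.state_space()
    n = int(round(duration * rate))
    Ad = linalg.expm(A / rate)
    h = np.empty(n)
    x = B[:, 0].copy()
    for k in range(n):
        h[k] = C[0] @ x
        x = Ad @ x
    return h


def _internal_oversample(rate: float) -> int:
    return max(1, int(np.ceil(_MIN_INTERNAL_RATE / rate)))


def simulate(
    params: KernelParams,
    train: BurstTrain,
    duration: float,
    rate: float,
    t0: float = 0.0,
):
    """Drive the ODE with a burst train and return the conductance trace.

    The linear system is discretized exactly at an internal rate of at least
    100 Hz using first-order-hold sampling of the Gaussian input (the input
    is piecewise-linear between internal samples), integrated with a direct
    recursion, and decimated to the output rate.  No adaptive-solver
    tolerances are involved, so results are bit-stable.
    """
    from .preproc import ConductanceSeries  # local import to avoid a cycle

    if not (duration > 0 and rate > 0):
        raise ValueError("duration and rate must be positive")
    n = int(round(duration * rate))
    if len(train) == 0:
        return ConductanceSeries(np.zeros(n), rate=rate, t0=t0)
    os_ = _internal_oversample(rate)
    rate_i = rate * os_
    A, B, C = params.state_space()
    u = gaussian_input(train, duration, rate_i, t0=t0)
    Ad, Bd, Cd, Dd, _ = signal.cont2discrete(
        (A, B, C, np.zeros((1, 1))), 1.0 / rate_i, method="foh"
    )
    num, den = signal.ss2tf(Ad, Bd, Cd, Dd)
    y_i = signal.lfilter(num[0], den, u)
    return ConductanceSeries(y_i[::os_][:n].copy(), rate=rate, t0=t0)


def calibrate_gain(params: KernelParams, rate: float = 10.0) -> KernelParams:
    """Rescale ``gain`` so a single unit burst peaks at exactly 1 μS.

    The peak is the maximum of the simulated trace on the ``rate`` grid for
    one unit-amplitude burst placed mid-epoch (grid-aligned), matching the
    convention that burst amplitudes are in fluctuation-peak μS.
    """
    duration = 60.0
    train = BurstTrain(np.array([duration / 2.0]), np.array([1.0]))
    trace = simulate(params, train, duration=duration, rate=rate)
    peak = float(trace.samples.max())
    if not np.isfinite(peak) or peak <= 0:
        raise CalibrationError("kernel produces no positive response")
    return replace(
        params, gain=params.gain / peak, calibrated_at_rate_hz=float(rate)
    )
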