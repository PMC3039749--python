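"""Seeded synthetic burst trains, epochs and two-condition studies.

The generator emulates the statistical structure the analysis assumes:
60-s epochs at 10 Hz containing Gaussian-burst-driven fluctuations of
0.1-1 μS scale, additive white measurement noise, and a slow drift, in a
two-condition (baseline vs anticipation) design where the anticipation
condition raises the burst rate.  All randomness flows from a single study
seed through ``numpy.random.SeedSequence`` spawning, so equal seeds give
bit-identical studies.  Ground-truth trains are returned alongside the
epochs for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forward import MAX_BURST_RATE_PER_MIN, BurstTrain, KernelParams, simulate
from .preproc import ConductanceSeries, Epoch, baseline_subtract


@dataclass
class StudyDesign:
    """Layout and signal statistics of a synthetic two-condition study.

    Defaults: 6 subjects with 4 epochs each (first half baseline, second
    half anticipation), burst rates 6/min at baseline and 12/min under
    anticipation (within the 3-22/min range reported for sudomotor bursts),
    amplitudes uniform on [0.2, 1.0] μS, white noise SD 0.05 μS and a
    0.1 μS slow drift.  ``design`` is "within" (every subject sees both
    conditions) or "between" (half the subjects get the anticipation rate
    in their anticipation epochs; the control half stays at baseline rate).
    """

    n_subjects: int = 6
    epochs_per_subject: int = 4
    design: str = "within"
    baseline_rate: float = 6.0
    anticipation_rate: float = 12.0
    amp_low: float = 0.2
    amp_high: float = 1.0
    noise_sd: float = 0.05
    drift_amp: float = 0.1
    duration: float = 60.0
    rate: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("within", "between"):
            raise ValueError("design must be 'within' or 'between'")
        if max(self.baseline_rate, self.anticipation_rate) > MAX_BURST_RATE_PER_MIN:
            raise ValueError("burst rates must not exceed 30/min")
        if not (0 < self.amp_low <= self.amp_high):
            raise ValueError("need 0 < amp_low <= amp_high")
        if self.epochs_per_subject < 2:
            raise ValueError("need at least 2 epochs per subject (>=1 baseline)")


@dataclass
class Study:
    """Generated epochs with condition labels and their true burst trains."""

    epochs: list[Epoch]
    trains: list[BurstTrain]
    labels: list[str]           # "baseline" / "anticipation" per epoch
    subjects: list[str]
    groups: dict[str, str] = field(default_factory=dict)  # between designs

    @property
    def states(self) -> np.ndarray:
        """Binary state per epoch: 1 for anticipation, 0 for baseline."""
        return np.array([1 if l == "anticipation" else 0 for l in self.labels])


def generate_burst_train(
    rate: float,
    amp_low: float,
    amp_high: float,
    duration: float,
    seed,
    sigma: float = 0.3,
    min_spacing: float = 1.0,
) -> BurstTrain:
    """Poisson burst train thinned to a minimum spacing, uniform amplitudes.

    Onsets are a homogeneous Poisson process at ``rate`` bursts/min over
    ``[0, duration)``, thinned by dropping any onset within ``min_spacing``
    seconds of the previously kept one (so ground-truth bursts are
    unambiguous for onset matching); amplitudes are i.i.d. uniform on
    ``[amp_low, amp_high]``.  ``seed`` may be an int or a SeedSequence.
    """
    if rate > MAX_BURST_RATE_PER_MIN:
        raise ValueError(f"rate {rate}/min exceeds the model maximum of 30/min")
    if not (duration > 0):
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    if rate <= 0:
        return BurstTrain.empty(sigma=sigma)
    n_max = rng.poisson(rate * duration / 60.0)
    raw = np.sort(rng.uniform(0.0, duration, size=n_max))
    kept = []
    for t in raw:
        if not kept or t - kept[-1] >= min_spacing:
            kept.append(t)
    if not kept:
        return BurstTrain.empty(sigma=sigma)
    amps = rng.uniform(amp_low, amp_high, size=len(kept))
    return BurstTrain(np.array(kept), amps, sigma=sigma)


def generate_epoch(
    train: BurstTrain,
    params: KernelParams,
    noise_sd: float,
    drift_amp: float,
    duration: float,
    rate: float,
    seed,
    label: str | None = None,
    subject: str | None = None,
) -> Epoch:
    """Forward-simulate a train, add noise and drift, baseline-subtract.

    Noise is white Gaussian with SD ``noise_sd`` μS; drift is a half-period
    sinusoid of amplitude ``drift_amp`` μS across the epoch (a bounded,
    seed-free stand-in for slow peripheral baseline movement).  The result
    is minimum-subtracted, matching the processing convention.
    """
    rng = np.random.default_rng(seed)
    clean = simulate(params, train, duration=duration, rate=rate)
    t = clean.times
    drift = drift_amp * np.sin(np.pi * t / duration)
    noise = noise_sd * rng.standard_normal(clean.n) if noise_sd > 0 else 0.0
    series = ConductanceSeries(clean.samples + drift + noise, rate=rate)
    return Epoch(series=baseline_subtract(series), label=label, subject=subject)


def generate_study(design: StudyDesign, params: KernelParams) -> Study:
    """Generate a full labelled study plus ground truth.

    Within designs: every subject's anticipation epochs use
    ``anticipation_rate``.  Between designs: subjects alternate between the
    "speech" group (anticipation epochs at ``anticipation_rate``) and the
    "control" group (all epochs at ``baseline_rate``); the group is recorded
    in ``Study.groups``.
    """
    root = np.random.SeedSequence(design.seed)
    n_base = design.epochs_per_subject // 2
    epochs, trains, labels, subjects = [], [], [], []
    groups: dict[str, str] = {}
    subject_seeds = root.spawn(design.n_subjects)
    for s in range(design.n_subjects):
        sid = f"S{s + 1:02d}"
        if design.design == "between":
            groups[sid] = "speech" if s % 2 == 0 else "control"
        epoch_seeds = subject_seeds[s].spawn(design.epochs_per_subject)
        for e in range(design.epochs_per_subject):
            label = "baseline" if e < n_base else "anticipation"
            rate = design.baseline_rate
            if label == "anticipation":
                if design.design == "within" or groups.get(sid) == "speech":
                    rate = design.anticipation_rate
            train_seed, noise_seed = epoch_seeds[e].spawn(2)
            train = generate_burst_train(
                rate, design.amp_low, design.amp_high, design.duration, train_seed
            )
            epoch = generate_epoch(
                train, params, design.noise_sd, design.drift_amp,
                design.duration, design.rate, noise_seed,
                label=label, subject=sid,
            )
            epochs.append(epoch)
            trains.append(train)
            labels.append(label)
            subjects.append(sid)
    return Study(epochs=epochs, trains=trains, labels=labels,
                 subjects=subjects, groups=groups)
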