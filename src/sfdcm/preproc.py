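"""Reading, writing and pre-processing of skin-conductance time series.

The processing chain mirrors standard electrodermal practice: a zero-phase
(bidirectional) first-order Butterworth low-pass at 5 Hz, decimation to a
10 Hz working rate, segmentation into fixed-length epochs (default 60 s),
and per-epoch subtraction of the segment minimum so that each epoch starts
from a zero tonic baseline.  Conductance is in microsiemens (μS) throughout;
input files carry no units and are assumed to be μS (a ``scale`` argument on
:func:`read_series` permits conversion).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal


class ParseError(ValueError):
    """Raised when a conductance file contains a non-numeric payload."""


@dataclass
class ConductanceSeries:
    """A uniformly sampled skin-conductance trace.

    Parameters
    ----------
    samples : ndarray
        Conductance values in μS.
    rate : float
        Sampling rate in Hz; must be positive.
    t0 : float
        Time of the first sample in seconds.  Sample ``k`` is at
        ``t0 + k / rate`` (0-based indexing).
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size < 2:
            raise ValueError("a conductance series needs at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not (self.rate > 0):
            raise ValueError(f"rate must be positive, got {self.rate}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Span covered by the closed-open sample window, in seconds."""
        return self.n / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate


@dataclass
class Epoch:
    """A fixed-length analysis segment with optional condition metadata."""

    series: ConductanceSeries
    label: str | None = None
    subject: str | None = None
    excluded: bool = False
    reason: str = ""

    def __post_init__(self) -> None:
        if self.excluded and not self.reason:
            raise ValueError("excluded epochs must carry a reason string")


def read_series(
    path,
    format: str = "plain",
    rate: float = 10.0,
    column: str | int = "scl",
    scale: float = 1.0,
) -> ConductanceSeries:
    """Read a conductance trace from a plain-text or CSV file.

    ``plain`` files hold one conductance value per line; lines starting with
    ``#`` are treated as comments.  ``csv`` files follow RFC 4180 with a
    header; the conductance column is named ``scl`` (case-insensitive) by
    default, or selected by name/0-based index via ``column``.
    """
    if not (rate > 0):
        raise ValueError(f"rate must be positive, got {rate}")
    if format == "plain":
        values = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                text = line.strip()
                if not text or text.startswith("#"):
                    continue
                try:
                    values.append(float(text))
                except ValueError:
                    raise ParseError(
                        f"{path}: non-numeric value {text!r} on line {lineno}"
                    ) from None
        return ConductanceSeries(np.array(values), rate=rate)
    if format == "csv":
        with open(path) as fh:
            body = [ln for ln in fh if not ln.startswith("#")]
        df = pd.read_csv(io.StringIO("".join(body)))
        if isinstance(column, int):
            col = df.columns[column]
        else:
            matches = [c for c in df.columns if c.strip().lower() == column.lower()]
            if not matches:
                raise ParseError(
                    f"{path}: no column named {column!r} (have {list(df.columns)})"
                )
            col = matches[0]
        raw = pd.to_numeric(df[col], errors="coerce")
        if raw.isna().any():
            bad = int(np.flatnonzero(raw.isna().to_numpy())[0])
            # +2: one for the header row, one for 1-based line numbering
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[bad]!r} on line {bad + 2}"
            )
        return ConductanceSeries(raw.to_numpy() * scale, rate=rate)
    raise ValueError(f"unknown format {format!r}; expected 'plain' or 'csv'")


def write_series(series: ConductanceSeries, path, format: str = "csv",
                 meta: dict | None = None) -> None:
    """Write a trace as one-value-per-line text or a ``t_s,scl`` CSV.

    ``meta`` key/value pairs are embedded as ``#``-prefixed header lines,
    which :func:`read_series` skips on input.
    """
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        if format == "plain":
            for v in series.samples:
                fh.write(f"{v:.9g}\n")
        elif format == "csv":
            fh.write("t_s,scl\n")
            for t, v in zip(series.times, series.samples):
                fh.write(f"{t:.9g},{v:.9g}\n")
        else:
            raise ValueError(f"unknown format {format!r}")


def lowpass_resample(
    series: ConductanceSeries, cutoff: float = 5.0, target_rate: float = 10.0
) -> ConductanceSeries:
    """Zero-phase first-order Butterworth low-pass, then decimate.

    The filter is applied forward and backward (``filtfilt``), which squares
    the magnitude response and cancels phase; the low-pass doubles as the
    anti-alias stage for the subsequent decimation.  When the series is
    already at ``target_rate`` only the filter is applied.  Decimation keeps
    every ``rate/target_rate``-th sample starting from the first, so the
    factor must be an integer.
    """
    if cutoff >= series.rate / 2:
        raise ValueError(
            f"cutoff {cutoff} Hz must be below the Nyquist rate {series.rate / 2} Hz"
        )
    if target_rate > series.rate:
        raise ValueError("target_rate may not exceed the input rate")
    b, a = signal.butter(1, cutoff, fs=series.rate)
    # reflect-pad by ~3 filter time constants to suppress edge transients
    padlen = min(series.n - 1, int(round(3.0 * series.rate / cutoff)))
    filtered = signal.filtfilt(b, a, series.samples, padtype="even", padlen=padlen)
    factor = series.rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"rate {series.rate} Hz is not an integer multiple of target {target_rate} Hz"
        )
    factor = int(round(factor))
    return ConductanceSeries(filtered[::factor].copy(), rate=target_rate, t0=series.t0)


def baseline_subtract(series: ConductanceSeries) -> ConductanceSeries:
    """Subtract the segment minimum so the epoch floor is exactly zero."""
    return ConductanceSeries(
        series.samples - series.samples.min(), rate=series.rate, t0=series.t0
    )


def segment_epochs(
    series: ConductanceSeries,
    starts,
    duration: float = 60.0,
    labels=None,
    subjects=None,
) -> list[Epoch]:
    """Cut closed-open windows ``[start, start + duration)`` into epochs.

    Each epoch is independently baseline-subtracted, following the
    segment-wise minimum-subtraction convention.
    """
    n_per = int(round(duration * series.rate))
    if labels is not None and len(labels) != len(starts):
        raise ValueError("labels must match starts in length")
    if subjects is not None and len(subjects) != len(starts):
        raise ValueError("subjects must match starts in length")
    epochs = []
    for i, start in enumerate(starts):
        k0 = int(round((start - series.t0) * series.rate))
        if k0 < 0 or k0 + n_per > series.n:
            raise ValueError(
                f"epoch starting at {start} s (+{duration} s) exceeds the series span"
            )
        window = ConductanceSeries(
            series.samples[k0 : k0 + n_per].copy(), rate=series.rate, t0=start
        )
        epochs.append(
            Epoch(
                series=baseline_subtract(window),
                label=None if labels is None else labels[i],
                subject=None if subjects is None else subjects[i],
            )
        )
    return epochs
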