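"""Noise estimation and threshold-crossing event extraction.

Noise statistics are computed robustly: samples more than three scaled
median absolute deviations (MAD) from the signal median are treated as
outliers (spikes), and the noise median M_n and standard deviation sigma_n
are computed on what remains. The detection threshold is then
``V_D = M_n - n_sigma * sigma_n`` for negative-phase detection (or ``+`` for
positive). Events are maximal contiguous runs of samples beyond V_D; the
event time is the time of the extremal sample in the run.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "MAD_SCALE",
    "NoiseEstimate",
    "DetectionSettings",
    "Event",
    "DegenerateNoiseError",
    "scaled_mad",
    "estimate_noise",
    "detection_threshold",
    "detect_events",
]

#: Normal-consistency constant -1 / (sqrt(2) * erfcinv(3/2)) ~= 1.4826, which
#: makes the scaled MAD an unbiased estimate of sigma for Gaussian noise.
MAD_SCALE = float(-1.0 / (np.sqrt(2.0) * special.erfcinv(1.5)))


class DegenerateNoiseError(ValueError):
    """Raised when outlier rejection leaves no samples to estimate noise from."""


@dataclass(frozen=True)
class NoiseEstimate:
    """Robust noise statistics of one electrode trace (volts)."""

    m_n: float  # noise median
    sigma_n: float  # noise standard deviation
    mad_sc: float  # scaled MAD of the full trace
    n_excluded: int  # samples rejected as outliers


@dataclass(frozen=True)
class DetectionSettings:
    """User-facing detection parameters.

    ``n_sigma`` is the threshold multiplier (number of noise standard
    deviations); ``polarity`` selects whether the negative or positive phase
    of the spikes is detected. ``keep_edge_events`` keeps threshold runs that
    touch the start/end of the trace (their peak may sit at the edge).
    """

    n_sigma: float
    polarity: str = "negative"
    keep_edge_events: bool = True

    def __post_init__(self) -> None:
        if self.n_sigma <= 0:
            raise ValueError("n_sigma must be positive")
        if self.polarity not in ("negative", "positive"):
            raise ValueError("polarity must be 'negative' or 'positive'")


@dataclass(frozen=True)
class Event:
    """One threshold-crossing event on one electrode."""

    electrode_index: int  # 1-based position along the microchannel
    t_peak: float  # seconds
    v_peak: float  # volts
    span: tuple[float, float]  # half-open [start, end) of the threshold run
    peak_sample: int  # sample index of the peak in the trace


def scaled_mad(signal: np.ndarray) -> float:
    """Scaled median absolute deviation ``C * median(|S - median(S)|)``.

    ``C = MAD_SCALE ~= 1.4826`` so the result estimates the standard
    deviation for Gaussian data.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    return MAD_SCALE * float(np.median(np.abs(signal - np.median(signal))))


def estimate_noise(signal: np.ndarray) -> NoiseEstimate:
    """Median/std of the noise after 3-scaled-MAD outlier rejection."""
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    med = float(np.median(signal))
    mad = scaled_mad(signal)
    keep = np.abs(signal - med) <= 3.0 * mad
    if not keep.any():
        raise DegenerateNoiseError("all samples rejected as outliers (MAD degenerate)")
    rest = signal[keep]
    return NoiseEstimate(
        m_n=float(np.median(rest)),
        sigma_n=float(np.std(rest)),
        mad_sc=mad,
        n_excluded=int(signal.size - rest.size),
    )


def detection_threshold(noise: NoiseEstimate, settings: DetectionSettings) -> float:
    """``V_D = M_n -/+ n_sigma * sigma_n`` (negative/positive polarity)."""
    if noise.sigma_n == 0.0:
        warnings.warn("sigma_n is zero; detection threshold equals the noise median")
    if settings.polarity == "negative":
        return noise.m_n - settings.n_sigma * noise.sigma_n
    return noise.m_n + settings.n_sigma * noise.sigma_n


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of True runs."""
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[0::2], edges[1::2]))


def detect_events(
    signal: np.ndarray,
    v_d: float,
    settings: DetectionSettings,
    sampling_rate: float,
    t0: float = 0.0,
    electrode_index: int = 1,
) -> list[Event]:
    """Extract threshold-crossing events from one trace.

    Each maximal contiguous run of samples beyond ``v_d`` (below for negative
    polarity, above for positive) yields one event at the time of the run's
    extremal sample; ties take the earliest sample. Events are disjoint and
    returned sorted by peak time.
    """
    signal = np.asarray(signal, dtype=float)
    mask = signal < v_d if settings.polarity == "negative" else signal > v_d
    pick = np.argmin if settings.polarity == "negative" else np.argmax
    events: list[Event] = []
    for start, stop in _runs(mask):
        if not settings.keep_edge_events and (start == 0 or stop == signal.size):
            continue
        k = start + int(pick(signal[start:stop]))
        events.append(
            Event(
                electrode_index=electrode_index,
                t_peak=t0 + k / sampling_rate,
                v_peak=float(signal[k]),
                span=(t0 + start / sampling_rate, t0 + stop / sampling_rate),
                peak_sample=k,
            )
        )
    return events
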