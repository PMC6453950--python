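"""Propagation-velocity estimation.

Two complementary estimators are provided.

SPV (single-sequence propagation velocity) cross-correlates the voltage
waveforms of one sequence on two electrodes, each windowed to
``t_p +/- W * D(i,j)`` about its event peak (``W = 7.5 s/m``), so the
admissible shape-lag range spans ``2 W D`` and corresponds to a minimum
speed of ``1/(2W) ~= 0.067 m/s``. The velocity is
``D(i,j) / tau_peak`` with the sign convention ``j > i``: positive =
anterograde, negative = retrograde. The cross-correlation is normalized by
the zero-lag energy of the reference (i-th) waveform so that every
autocorrelation is 1 at zero lag; the peak value is the confidence index
CI_S (it can exceed 1 for amplitude-mismatched pairs and is reported
unclipped).

CPV (cluster propagation velocity) is computed from realignment times tied
to the peak of a cluster's mean waveform: events of one cluster on one
electrode are aligned by cross-correlation inside +/-1.0 ms windows around
their peaks, the aligned mean waveform is formed, and each event's
realignment time t*_{p,i} is the recording time of the sample that maps to
the mean-waveform peak. The velocity of sequence p over pair (i, j) is
``D(i,j) / (t*_{p,j} - t*_{p,i})``. Averaging over the cluster makes the
peak timing robust to per-event noise, which is why CPV outperforms SPV at
low signal-to-noise ratios.

All lags are kept at sample resolution (no sub-sample interpolation) unless
``interpolate=True`` is passed, matching the quantization behavior of the
estimators: every SPV lies on the grid ``D(i,j) * f / k``, k integer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence as SequenceT

import numpy as np
from scipy import signal as sps

from .sequences import PropagationSequence, extract_window

__all__ = [
    "W_DEFAULT",
    "REALIGN_WINDOW",
    "CrossCorrelogram",
    "VelocityEstimate",
    "ClusterAlignment",
    "InvalidVelocityError",
    "windowed_xcorr",
    "spv",
    "spv_mean",
    "realign_cluster_events",
    "cpv",
    "cluster_confidence",
]

#: Cross-correlation time-window constant (s/m).
W_DEFAULT = 7.5
#: Half-width of the realignment / confidence cross-correlation window (s).
REALIGN_WINDOW = 1.0e-3


class InvalidVelocityError(ValueError):
    """Raised when a velocity estimate is undefined (zero lag / zero energy)."""


@dataclass
class CrossCorrelogram:
    """Normalized cross-correlation of one electrode pair for one sequence."""

    lags: np.ndarray  # seconds, symmetric about 0
    values: np.ndarray  # dimensionless
    inv_velocity_axis: np.ndarray  # s/m, lag / D(i,j)
    pair: tuple[int, int]


@dataclass(frozen=True)
class VelocityEstimate:
    """A signed velocity (+ anterograde, - retrograde) with its confidence."""

    value: float  # m/s
    method: str  # 'SPV' | 'SPV_mean' | 'CPV'
    pair: tuple[int, int] | str
    confidence: float


@dataclass
class ClusterAlignment:
    """Realignment of one cluster's events on one electrode."""

    electrode: int
    t_star: np.ndarray  # (n_ev,) realignment times, seconds
    lags: np.ndarray  # (n_ev,) alignment lags in samples
    mean_waveform: np.ndarray  # volts, aligned-coordinate mean
    peak_index_of_mean: int  # sample index of the mean-waveform peak


def _argmax_lag(values: np.ndarray, lags: np.ndarray) -> int:
    """Index of the maximum; ties prefer the smallest |lag|, then positive lag."""
    best = np.flatnonzero(values == values.max())
    return int(min(best, key=lambda k: (abs(lags[k]), -np.sign(lags[k]))))


def _parabolic_refine(values: np.ndarray, k: int) -> float:
    """Sub-sample peak offset by parabolic interpolation around index k."""
    if k == 0 or k == len(values) - 1:
        return 0.0
    y0, y1, y2 = values[k - 1], values[k], values[k + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0.0:
        return 0.0
    return 0.5 * (y0 - y2) / denom


def _pair_distance(seq: PropagationSequence, i: int, j: int) -> float:
    if not j > i:
        raise ValueError("electrode pair must satisfy j > i")
    return seq.group.distance(i, j)


def windowed_xcorr(
    seq: PropagationSequence, i: int, j: int, w: float = W_DEFAULT
) -> CrossCorrelogram:
    """Normalized cross-correlation ``X_{i,j}(tau)`` of sequence waveforms.

    Each trace is windowed to ``t_p +/- w * D(i,j)`` about its own event
    peak, and the full cross-correlation of the windows is divided by the
    zero-lag energy of the windowed reference trace (electrode i), so the
    autocorrelation of any waveform with itself is 1 at zero lag. The lag
    axis is expressed in recording time: a positive peak lag means
    electrode j fires after electrode i, and identical waveforms peak
    exactly at the peak-time difference.
    """
    d = _pair_distance(seq, i, j)
    fs = seq.group.sampling_rate
    half = int(round(w * d * fs))
    k_i = int(seq.peak_samples[i - 1])
    k_j = int(seq.peak_samples[j - 1])
    a = extract_window(seq.group.trace(i), k_i - half, k_i + half + 1)
    b = extract_window(seq.group.trace(j), k_j - half, k_j + half + 1)
    energy = float(np.dot(a, a))
    if energy == 0.0:
        raise InvalidVelocityError(
            f"zero-energy reference window on electrode {i}; correlation undefined"
        )
    values = sps.correlate(b, a, mode="full") / energy
    rel = sps.correlation_lags(b.size, a.size, mode="full")
    lags = (k_j - k_i + rel) / fs
    with np.errstate(divide="ignore"):
        inv_v = lags / d
    return CrossCorrelogram(lags=lags, values=values, inv_velocity_axis=inv_v, pair=(i, j))


def spv(
    seq: PropagationSequence,
    i: int,
    j: int,
    w: float = W_DEFAULT,
    interpolate: bool = False,
) -> VelocityEstimate:
    """Single-sequence propagation velocity ``D(i,j) / tau_peak`` for one pair.

    ``tau_peak`` is the lag maximizing the windowed cross-correlation; the
    confidence index CI_S is the peak correlation value.
    """
    xc = windowed_xcorr(seq, i, j, w=w)
    k = _argmax_lag(xc.values, xc.lags)
    tau = float(xc.lags[k])
    if interpolate:
        tau += _parabolic_refine(xc.values, k) / seq.group.sampling_rate
    if tau == 0.0:
        raise InvalidVelocityError(
            f"zero peak lag for pair {(i, j)}: velocity estimate undefined"
        )
    d = _pair_distance(seq, i, j)
    return VelocityEstimate(
        value=d / tau, method="SPV", pair=(i, j), confidence=float(xc.values[k])
    )


def spv_mean(
    seq: PropagationSequence, w: float = W_DEFAULT, interpolate: bool = False
) -> VelocityEstimate:
    """Arithmetic mean of the pairwise SPVs over all pairs ``j > i``.

    The confidence is the lowest pairwise peak correlation. Pairs with an
    undefined estimate (zero peak lag) are excluded with a warning.
    """
    values, cis = [], []
    n_e = seq.n_e
    for i in range(1, n_e):
        for j in range(i + 1, n_e + 1):
            try:
                est = spv(seq, i, j, w=w, interpolate=interpolate)
            except InvalidVelocityError:
                warnings.warn(f"pair {(i, j)} excluded from mean SPV (invalid estimate)")
                continue
            values.append(est.value)
            cis.append(est.confidence)
    if not values:
        raise InvalidVelocityError("no valid pairwise SPV estimate")
    return VelocityEstimate(
        value=float(np.mean(values)),
        method="SPV_mean",
        pair="all",
        confidence=float(np.min(cis)),
    )


def _event_window(
    seq: PropagationSequence, electrode: int, center_sample: int, half: int
) -> np.ndarray:
    return extract_window(
        seq.group.trace(electrode), center_sample - half, center_sample + half + 1
    )


def realign_cluster_events(
    cluster_seqs: SequenceT[PropagationSequence],
    electrode: int,
    window: float = REALIGN_WINDOW,
    n_iter: int = 2,
) -> ClusterAlignment:
    """Realign one cluster's events on one electrode to the cluster mean.

    Each event is cross-correlated (within ``+/- window`` of its peak)
    against the running cluster mean; the lag of the correlation maximum
    re-centers the event, and the mean is rebuilt from the re-centered
    waveforms. Two passes suffice for consistent lags. The realignment time
    t*_{p} of each event is the recording time of the sample corresponding
    to the peak of the final mean waveform.
    """
    seqs = list(cluster_seqs)
    if not seqs:
        raise ValueError("empty cluster")
    group = seqs[0].group
    fs = group.sampling_rate
    half = int(round(window * fs))
    centers = np.array([int(s.peak_samples[electrode - 1]) for s in seqs])
    polarity_pick = np.argmin if seqs[0].peak_voltages[electrode - 1] <= 0 else np.argmax

    lags = np.zeros(len(seqs), dtype=int)
    snippets = np.stack([_event_window(s, electrode, c, half) for s, c in zip(seqs, centers)])
    mean = snippets.mean(axis=0)
    for _ in range(n_iter):
        if len(seqs) == 1:
            break
        new_lags = np.empty_like(lags)
        for p, (s, c) in enumerate(zip(seqs, centers)):
            snip = _event_window(s, electrode, c + lags[p], half)
            xc = sps.correlate(snip, mean, mode="full")
            xl = sps.correlation_lags(snip.size, mean.size, mode="full")
            keep = np.abs(xl) <= half  # realignment stays inside the window
            k = _argmax_lag(xc[keep], xl[keep])
            # snip ~ mean delayed by xl[k]; shifting the extraction center by
            # that lag re-centers the event on the mean
            new_lags[p] = lags[p] + int(xl[keep][k])
        lags = new_lags
        snippets = np.stack(
            [_event_window(s, electrode, c + lags[p], half) for p, (s, c) in enumerate(zip(seqs, centers))]
        )
        mean = snippets.mean(axis=0)

    m_star = int(polarity_pick(mean))
    # sample of event p mapping to the mean peak: window start + m_star
    t_star = (centers + lags - half + m_star) / fs + group.parent.t0
    return ClusterAlignment(
        electrode=electrode,
        t_star=np.asarray(t_star, dtype=float),
        lags=lags,
        mean_waveform=mean,
        peak_index_of_mean=m_star,
    )


def cpv(
    cluster_seqs: SequenceT[PropagationSequence],
    p: int,
    i: int,
    j: int,
    alignments: dict[int, ClusterAlignment] | None = None,
    window: float = REALIGN_WINDOW,
) -> VelocityEstimate:
    """Cluster propagation velocity of the p-th member over pair ``(i, j)``.

    ``v = D(i,j) / (t*_{p,j} - t*_{p,i})`` from the cluster realignment
    times; the confidence is ``min(CI_{Cp,i}, CI_{Cp,j})``. Timing errors
    shrink with electrode distance, so the most distant pair is the usual
    choice.
    """
    seqs = list(cluster_seqs)
    if not seqs:
        raise ValueError("empty cluster")
    if not j > i:
        raise ValueError("electrode pair must satisfy j > i")
    if alignments is None:
        alignments = {}
    for e in (i, j):
        if e not in alignments:
            alignments[e] = realign_cluster_events(seqs, e, window=window)
    dt = float(alignments[j].t_star[p] - alignments[i].t_star[p])
    if dt == 0.0:
        raise InvalidVelocityError(f"equal realignment times for pair {(i, j)}")
    d = seqs[0].group.distance(i, j)
    ci = min(
        cluster_confidence(seqs, p, i, window=window),
        cluster_confidence(seqs, p, j, window=window),
    )
    return VelocityEstimate(value=d / dt, method="CPV", pair=(i, j), confidence=ci)


def cluster_confidence(
    cluster_seqs: SequenceT[PropagationSequence],
    p: int,
    electrode: int,
    window: float = REALIGN_WINDOW,
) -> float:
    """Similarity of event p to the rest of its cluster on one electrode.

    ``CI_{Cp,i}`` is the mean, over the other events q, of the peak
    cross-correlation between p and q normalized by the zero-lag energy of
    event p (so identical waveforms give 1; a waveform with twice the
    amplitude contributes 2). A single-event cluster has confidence 1 by
    convention.
    """
    seqs = list(cluster_seqs)
    n_ev = len(seqs)
    if n_ev == 0:
        raise ValueError("empty cluster")
    if n_ev == 1:
        warnings.warn("single-event cluster: confidence defined as 1.0")
        return 1.0
    fs = seqs[0].group.sampling_rate
    half = int(round(window * fs))
    ref = _event_window(seqs[p], electrode, int(seqs[p].peak_samples[electrode - 1]), half)
    energy = float(np.dot(ref, ref))
    if energy == 0.0:
        raise InvalidVelocityError("zero-energy reference event")
    peaks = []
    for q, s in enumerate(seqs):
        if q == p:
            continue
        other = _event_window(s, electrode, int(s.peak_samples[electrode - 1]), half)
        peaks.append(float(sps.correlate(ref, other, mode="full").max()) / energy)
    return float(np.mean(peaks))
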