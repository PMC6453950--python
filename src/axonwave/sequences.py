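"""Linking per-electrode events into propagation sequences.

A traveling action potential shows up as temporally linked threshold
crossings on every electrode of a microchannel. Starting from each event on
a seed electrode near the channel center, candidate events on the other
electrodes are collected inside distance-scaled search windows and the
candidate set is admitted as a propagation sequence only if all three
criteria hold:

1. an event exists on every electrode inside its search window
   ``t_p1 +/- C_s * D(1, i)`` (``C_s`` corresponds to a minimum propagation
   speed, 0.1 m/s by default);
2. the first-to-last timing corresponds to a speed below 100 m/s;
3. the Kendall rank coefficient between electrode order and event times
   satisfies ``|tau_b| > 0.8``.

Admitted sequences carry waveform snippets wide enough for both velocity
estimators, and a direction label (anterograde = away from the somal side).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detection import DetectionSettings, detect_events, detection_threshold, estimate_noise
from .io import ChannelGroup

__all__ = [
    "C_S_DEFAULT",
    "V_BOUND_MAX",
    "TAU_B_MIN",
    "SearchWindow",
    "PropagationSequence",
    "search_window",
    "kendall_tau_b",
    "check_velocity_bound",
    "classify_direction",
    "detect_sequences",
    "extract_window",
]

#: Search-window coefficient (s/m): reciprocal of the 0.1 m/s minimum speed.
C_S_DEFAULT = 10.0
#: Maximum physiologically admissible first-to-last speed (m/s).
V_BOUND_MAX = 100.0
#: Admission threshold on |tau_b|.
TAU_B_MIN = 0.8
#: Cross-correlation window constant (s/m) used to size stored snippets.
W_DEFAULT = 7.5


@dataclass(frozen=True)
class SearchWindow:
    t_min: float
    t_max: float
    electrode_index: int

    def contains(self, t: float) -> bool:
        return self.t_min <= t <= self.t_max


@dataclass
class PropagationSequence:
    """One traveling action potential observed across all electrodes.

    ``times[i-1]`` is the peak time on electrode ``i``; ``snippets`` holds a
    waveform window around each peak (rows = electrodes) and
    ``snippet_starts`` the sample index of each snippet's first sample in
    the parent recording (may be negative at trace edges, where the snippet
    is zero-padded).
    """

    id: int
    times: np.ndarray  # (n_E,) seconds
    peak_voltages: np.ndarray  # (n_E,) volts
    peak_samples: np.ndarray  # (n_E,) sample indices
    tau_b: float
    v_bound: float  # m/s, first-to-last magnitude
    direction: str  # 'anterograde' | 'retrograde'
    snippets: np.ndarray  # (n_E, L) volts
    snippet_starts: np.ndarray  # (n_E,) sample indices
    group: ChannelGroup = field(repr=False)

    @property
    def n_e(self) -> int:
        return len(self.times)


def search_window(t_p1: float, d_1i: float, c_s: float = C_S_DEFAULT, electrode_index: int = 0) -> SearchWindow:
    """Window ``[t_p1 - c_s*d_1i, t_p1 + c_s*d_1i]`` for the electrode at
    distance ``d_1i`` from electrode 1."""
    if d_1i < 0:
        raise ValueError("distance must be non-negative")
    half = c_s * d_1i
    return SearchWindow(t_p1 - half, t_p1 + half, electrode_index)


def kendall_tau_b(e: np.ndarray, t: np.ndarray) -> float:
    """Kendall rank coefficient between electrode indices and event times.

    ``tau_b = 2 * sum_{i<j} sign((e_i - e_j)(t_i - t_j)) / (n (n - 1))``,
    with tied pairs contributing 0. For distinct electrode indices and no
    tied times this is the classical Kendall tau.
    """
    e = np.asarray(e, dtype=float)
    t = np.asarray(t, dtype=float)
    if e.shape != t.shape or e.ndim != 1:
        raise ValueError("e and t must be 1-D vectors of equal length")
    n = e.size
    if n < 2:
        raise ValueError("need at least two electrodes")
    de = np.sign(e[:, None] - e[None, :])
    dt = np.sign(t[:, None] - t[None, :])
    upper = np.triu_indices(n, k=1)
    s = float(np.sum(de[upper] * dt[upper]))
    return 2.0 * s / (n * (n - 1))


def check_velocity_bound(times: np.ndarray, d_1n: float) -> tuple[bool, float]:
    """First-to-last speed check ``d_1n / |t_n - t_1| < 100 m/s``.

    Returns (passed, speed magnitude). Equal first/last times mean an
    infinite apparent speed and fail the check.
    """
    times = np.asarray(times, dtype=float)
    dt = abs(float(times[-1] - times[0]))
    if dt == 0.0:
        return False, math.inf
    v = d_1n / dt
    return v < V_BOUND_MAX, v


def classify_direction(times: np.ndarray) -> str:
    """'anterograde' if the wave travels from electrode 1 toward n_E."""
    times = np.asarray(times, dtype=float)
    return "anterograde" if times[-1] > times[0] else "retrograde"


def extract_window(trace: np.ndarray, start: int, stop: int) -> np.ndarray:
    """``trace[start:stop]`` with zero padding outside the trace bounds."""
    n = trace.size
    out = np.zeros(stop - start, dtype=float)
    lo, hi = max(start, 0), min(stop, n)
    if lo < hi:
        out[lo - start : hi - start] = trace[lo:hi]
    return out


def default_seed_electrode(n_e: int) -> int:
    """Electrode closest to the microchannel center; ``ceil(n_E / 2)`` when
    the count is even (electrode 2 of 4)."""
    return math.ceil(n_e / 2)


def detect_sequences(
    group: ChannelGroup,
    settings: DetectionSettings,
    c_s: float = C_S_DEFAULT,
    seed_electrode: int | None = None,
    snippet_halfwidth: float | None = None,
) -> list[PropagationSequence]:
    """Detect propagation sequences on one microchannel.

    Noise statistics and the detection threshold are computed once per
    electrode over the full trace. Events on the seed electrode are visited
    in time order; each other electrode contributes the available event
    nearest to ``t_p1`` inside its search window. Events joining an admitted
    sequence are consumed, so each event belongs to at most one sequence.

    ``snippet_halfwidth`` (seconds) sets the stored waveform window around
    each peak; the default ``max(1 ms, W * D(1, n_E))`` is wide enough for
    both the cross-correlation velocity window and cluster realignment.
    """
    n_e = group.n_e
    fs = group.sampling_rate
    t0 = group.parent.t0
    seed = seed_electrode if seed_electrode is not None else default_seed_electrode(n_e)
    if not 1 <= seed <= n_e:
        raise ValueError(f"seed electrode {seed} outside 1..{n_e}")

    events_by_e = []
    for e in range(1, n_e + 1):
        trace = group.trace(e)
        noise = estimate_noise(trace)
        v_d = detection_threshold(noise, settings)
        events_by_e.append(
            detect_events(trace, v_d, settings, fs, t0=t0, electrode_index=e)
        )
    times_by_e = [np.array([ev.t_peak for ev in evs]) for evs in events_by_e]
    available = [np.ones(len(evs), dtype=bool) for evs in events_by_e]

    if snippet_halfwidth is None:
        snippet_halfwidth = max(1e-3, W_DEFAULT * group.distance(1, n_e))
    half = int(round(snippet_halfwidth * fs))

    def nearest_available(e: int, center: float, window: SearchWindow) -> int | None:
        """Index of the available event on electrode e inside window, nearest
        to ``center``; None if there is none."""
        t = times_by_e[e - 1]
        if t.size == 0:
            return None
        lo = np.searchsorted(t, window.t_min, side="left")
        hi = np.searchsorted(t, window.t_max, side="right")
        cand = [k for k in range(lo, hi) if available[e - 1][k]]
        if not cand:
            return None
        return min(cand, key=lambda k: (abs(t[k] - center), t[k]))

    electrode_order = np.arange(1, n_e + 1, dtype=float)
    d_1n = group.distance(1, n_e)
    sequences: list[PropagationSequence] = []

    for k_seed, seed_ev in enumerate(events_by_e[seed - 1]):
        if not available[seed - 1][k_seed]:
            continue
        # Anchor the sequence at electrode 1: the available electrode-1 event
        # nearest the seed event inside the seed's own search-window radius.
        if seed == 1:
            k1 = k_seed
        else:
            w1 = search_window(seed_ev.t_peak, group.distance(1, seed), c_s, 1)
            k1 = nearest_available(1, seed_ev.t_peak, w1)
            if k1 is None:
                continue
        t_p1 = times_by_e[0][k1]

        chosen = {1: k1, seed: k_seed}
        if seed != 1:
            # the seed event must itself sit in its window about t_p1
            if not search_window(t_p1, group.distance(1, seed), c_s, seed).contains(
                seed_ev.t_peak
            ):
                continue
        ok = True
        for e in range(1, n_e + 1):
            if e in chosen:
                continue
            win = search_window(t_p1, group.distance(1, e), c_s, e)
            k = nearest_available(e, t_p1, win)
            if k is None:
                ok = False
                break
            chosen[e] = k
        if not ok:
            continue  # criterion 1: an event on every electrode

        times = np.array([times_by_e[e - 1][chosen[e]] for e in range(1, n_e + 1)])
        passed, v_bound = check_velocity_bound(times, d_1n)
        if not passed:
            continue  # criterion 2
        tau = kendall_tau_b(electrode_order, times)
        if not abs(tau) > TAU_B_MIN:
            continue  # criterion 3

        peak_samples = np.array(
            [events_by_e[e - 1][chosen[e]].peak_sample for e in range(1, n_e + 1)]
        )
        peak_voltages = np.array(
            [events_by_e[e - 1][chosen[e]].v_peak for e in range(1, n_e + 1)]
        )
        starts = peak_samples - half
        snippets = np.stack(
            [
                extract_window(group.trace(e), starts[e - 1], peak_samples[e - 1] + half + 1)
                for e in range(1, n_e + 1)
            ]
        )
        for e in range(1, n_e + 1):
            available[e - 1][chosen[e]] = False
        sequences.append(
            PropagationSequence(
                id=len(sequences),
                times=times,
                peak_voltages=peak_voltages,
                peak_samples=peak_samples,
                tau_b=tau,
                v_bound=v_bound,
                direction=classify_direction(times),
                snippets=snippets,
                snippet_starts=starts,
                group=group,
            )
        )
    return sequences
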