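"""Kymographs and audio rendering for qualitative propagation assessment.

A kymograph maps voltage to color intensity in time-electrode space: a
traveling action potential appears as a diagonal streak whose slope is the
reciprocal of the propagation speed (0.5 m/s over 100 um spacing = 2 ms per
mm). The audio renderer assigns an ascending musical note to each electrode
and modulates each tone with the (time-dilated) voltage envelope, so an
anterograde wave is heard as an ascending arpeggio and a retrograde one as
descending.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.ndimage import uniform_filter1d

from .io import ChannelGroup

__all__ = [
    "Kymograph",
    "kymograph",
    "kymo_line_velocity",
    "render_audio",
    "TIME_DILATION",
    "AUDIO_RATE",
]

#: Playback slow-down factor: 0.2 s of recording becomes 100 s of audio.
TIME_DILATION = 500.0
AUDIO_RATE = 44100
#: Just-intonation major scale starting at middle C (261.6 Hz).
MAJOR_SCALE = (1.0, 9 / 8, 5 / 4, 4 / 3, 3 / 2, 5 / 3, 15 / 8, 2.0)
BASE_NOTE_HZ = 261.6
PEAK_DBFS = -3.0


@dataclass
class Kymograph:
    """Voltage-to-intensity image in time-electrode space."""

    intensity: np.ndarray  # (n_E, n_time_bins) in [0, 1]
    time_axis: np.ndarray  # seconds
    electrode_axis: np.ndarray  # 1..n_E


def _slice_samples(group: ChannelGroup, t_range: tuple[float, float] | None):
    rec = group.parent
    if t_range is None:
        return 0, rec.n_samples
    k0 = rec.time_to_sample(t_range[0])
    k1 = rec.time_to_sample(t_range[1])
    if not (0 <= k0 < k1 <= rec.n_samples):
        raise ValueError(f"time range {t_range} outside the recording")
    return k0, k1


def kymograph(
    group: ChannelGroup,
    t_range: tuple[float, float] | None = None,
    out: str | Path | None = None,
    symmetric: bool = False,
) -> Kymograph:
    """Build (and optionally save) the kymograph of a channel group.

    Intensity is a linear map of voltage over the window's min/max;
    ``symmetric=True`` centers the map on the median instead (useful for
    bipolar signals). A uniform window (e.g. all zeros) renders mid-gray.
    """
    k0, k1 = _slice_samples(group, t_range)
    rec = group.parent
    data = np.stack([group.trace(e)[k0:k1] for e in range(1, group.n_e + 1)])
    if symmetric:
        center = np.median(data)
        span = np.max(np.abs(data - center))
        intensity = 0.5 if span == 0 else 0.5 + (data - center) / (2 * span)
    else:
        lo, hi = data.min(), data.max()
        intensity = np.full_like(data, 0.5) if hi == lo else (data - lo) / (hi - lo)
    intensity = np.broadcast_to(intensity, data.shape).astype(float)
    km = Kymograph(
        intensity=intensity,
        time_axis=rec.sample_to_time(np.arange(k0, k1)),
        electrode_axis=np.arange(1, group.n_e + 1),
    )
    if out is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 2.5))
        ax.imshow(
            km.intensity,
            aspect="auto",
            origin="lower",
            cmap="viridis",
            extent=(km.time_axis[0], km.time_axis[-1], 0.5, group.n_e + 0.5),
        )
        ax.set_xlabel("time (s)")
        ax.set_ylabel("electrode")
        fig.savefig(out, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return km


def kymo_line_velocity(
    p1: tuple[float, int], p2: tuple[float, int], spacing: float
) -> float:
    """Velocity of a line drawn on the kymograph between (time, electrode)
    points.

    The line is read from ``p1`` to ``p2``: the sign follows the electrode
    direction of the stroke (positive toward higher electrode indices,
    i.e. anterograde), the magnitude is distance over elapsed time.
    """
    (t1, e1), (t2, e2) = p1, p2
    if e1 == e2:
        raise ValueError("endpoints must lie on different electrodes")
    dt = abs(t2 - t1)
    if dt == 0:
        raise ValueError("endpoints are simultaneous; velocity undefined")
    return (e2 - e1) * spacing / dt


def render_audio(
    group: ChannelGroup,
    t_range: tuple[float, float] | None = None,
    out: str | Path = "playback.wav",
    dilation: float = TIME_DILATION,
    audio_rate: int = AUDIO_RATE,
) -> np.ndarray:
    """Render a channel group to a WAV file.

    Electrode i drives a fixed tone (ascending major scale from 261.6 Hz);
    the tone's instantaneous amplitude follows the electrode's rectified
    voltage envelope, slowed ``dilation``-fold. The output duration equals
    ``dilation * input duration`` exactly (to one sample); a silent input
    yields a silent file. Peak level is -3 dBFS.
    """
    k0, k1 = _slice_samples(group, t_range)
    fs = group.sampling_rate
    in_duration = (k1 - k0) / fs
    n_out = int(round(in_duration * dilation * audio_rate))
    t_out = np.arange(n_out) / audio_rate  # output-clock seconds
    t_in = t_out / dilation + (k0 / fs)
    mix = np.zeros(n_out)
    sample_times = np.arange(k0, k1) / fs
    # envelope smoothing over one dilated spike width keeps the modulation
    # band far below the tone frequencies
    smooth = max(1, int(round(1.5e-3 * fs)))
    for e in range(1, group.n_e + 1):
        env = uniform_filter1d(np.abs(group.trace(e)[k0:k1]), smooth)
        env_out = np.interp(t_in, sample_times, env)
        freq = BASE_NOTE_HZ * MAJOR_SCALE[(e - 1) % len(MAJOR_SCALE)] * (
            2 ** ((e - 1) // len(MAJOR_SCALE))
        )
        mix += env_out * np.sin(2 * np.pi * freq * t_out)
    peak = np.max(np.abs(mix))
    if peak > 0:
        mix *= 10 ** (PEAK_DBFS / 20) / peak
    wavfile.write(out, audio_rate, (mix * 32767).astype(np.int16))
    return mix
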