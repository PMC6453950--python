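"""Reading and writing multi-electrode recordings and result tables.

Recordings come in as CSV (rows = samples, columns = electrodes; custom
setups) or HDF5 in the MultiChannel Systems (MCS) layout. Internally
everything is volts and seconds: CSV files are assumed to be in microvolts
unless told otherwise, HDF5 ADC integers are scaled by the per-channel
conversion factor.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "ChannelGroup",
    "read_recording_csv",
    "read_recording_hdf5",
    "select_channel_group",
    "export_sequences",
    "MCS_DEFAULT_DATASET",
]

#: Default dataset path inside an MCS HDF5 file (channels x samples).
MCS_DEFAULT_DATASET = "Data/Recording_0/AnalogStream/Stream_0/ChannelData"

MAX_GROUP_SIZE = 16


@dataclass
class Recording:
    """A sampled multi-electrode voltage matrix.

    Parameters
    ----------
    voltages : ndarray, shape (n_samples, n_channels)
        Signal in volts; one column per electrode.
    sampling_rate : float
        Samples per second (Hz).
    labels : list of str
        Ordered channel identifiers. MCS devices use the row-number +
        column-letter convention (e.g. ``"B9"``); custom data may use
        anything.
    t0 : float
        Time of sample 0 in seconds (nonzero when a sub-range of a longer
        file was loaded). Sample ``k`` maps to time ``t0 + k / sampling_rate``.
    """

    voltages: np.ndarray
    sampling_rate: float
    labels: list[str] = field(default_factory=list)
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        if self.voltages.ndim != 2:
            raise ValueError("voltages must be a 2-D (n_samples, n_channels) array")
        if self.voltages.shape[0] < 1 or self.voltages.shape[1] < 1:
            raise ValueError("recording must contain at least one sample and one channel")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.labels:
            self.labels = [f"ch{i + 1}" for i in range(self.voltages.shape[1])]
        if len(self.labels) != self.voltages.shape[1]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.voltages.shape[1]} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def sample_to_time(self, k: int | np.ndarray) -> float | np.ndarray:
        return self.t0 + np.asarray(k) / self.sampling_rate

    def time_to_sample(self, t: float) -> int:
        """Nearest sample index for a time in seconds."""
        return int(round((t - self.t0) * self.sampling_rate))


@dataclass
class ChannelGroup:
    """An ordered electrode series along one microchannel.

    Electrode 1 is the electrode nearest the somal compartment; electrodes
    are uniformly spaced (center-to-center). Electrode numbers in the public
    API are 1-based, matching the series convention ``E = [1 2 ... n_E]``.
    """

    parent: Recording
    electrode_indices: list[int]  # 0-based column indices into parent
    spacing: float  # meters

    def __post_init__(self) -> None:
        n = len(self.electrode_indices)
        if not (2 <= n <= MAX_GROUP_SIZE):
            raise ValueError(f"a channel group needs 2-{MAX_GROUP_SIZE} electrodes, got {n}")
        if len(set(self.electrode_indices)) != n:
            raise ValueError("electrode indices must be distinct")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def n_e(self) -> int:
        return len(self.electrode_indices)

    @property
    def sampling_rate(self) -> float:
        return self.parent.sampling_rate

    @property
    def labels(self) -> list[str]:
        return [self.parent.labels[i] for i in self.electrode_indices]

    def distance(self, i: int, j: int) -> float:
        """Center-to-center distance D(i, j) between electrodes i and j (1-based)."""
        for e in (i, j):
            if not 1 <= e <= self.n_e:
                raise IndexError(f"electrode {e} outside 1..{self.n_e}")
        return abs(j - i) * self.spacing

    def trace(self, e: int) -> np.ndarray:
        """Voltage trace of electrode ``e`` (1-based)."""
        if not 1 <= e <= self.n_e:
            raise IndexError(f"electrode {e} outside 1..{self.n_e}")
        return self.parent.voltages[:, self.electrode_indices[e - 1]]

    def reversed(self) -> "ChannelGroup":
        """Same electrodes in the opposite order (flips direction conventions)."""
        return ChannelGroup(self.parent, list(self.electrode_indices[::-1]), self.spacing)


def _looks_like_header(row: list[str]) -> bool:
    for cell in row:
        try:
            float(cell)
        except ValueError:
            return True
    return False


def read_recording_csv(
    path: str | Path,
    sampling_rate: float,
    units: str = "uV",
    t0: float = 0.0,
) -> Recording:
    """Read a CSV recording (rows = samples, columns = electrodes).

    A single optional header row provides channel labels; otherwise columns
    are auto-labeled ``ch1..chN``. ``units`` is ``"uV"`` (default, common MEA
    practice) or ``"V"``.
    """
    scale = {"uV": 1e-6, "V": 1.0}.get(units)
    if scale is None:
        raise ValueError(f"unknown units {units!r} (use 'uV' or 'V')")
    path = Path(path)
    labels: list[str] = []
    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for row in reader:
            if not row:
                continue
            if not rows and not labels and _looks_like_header(row):
                labels = [c.strip() for c in row]
                continue
            rows.append(row)
    if not rows:
        raise ValueError(f"{path}: no data rows")
    width = len(rows[0])
    data = np.empty((len(rows), width), dtype=float)
    for r, row in enumerate(rows):
        if len(row) != width:
            raise ValueError(
                f"{path}: ragged row {r + 1} has {len(row)} cells, expected {width}"
            )
        for c, cell in enumerate(row):
            try:
                data[r, c] = float(cell)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {r + 1}, column {c + 1}"
                ) from exc
    return Recording(data * scale, sampling_rate, labels, t0=t0)


def _mcs_channel_info(stream: h5py.Group) -> tuple[list[str], np.ndarray, float | None]:
    """Labels, per-channel volt conversion factors and sampling rate from an
    MCS ``InfoChannel`` table, when present."""
    if "InfoChannel" not in stream:
        return [], np.array([]), None
    info = stream["InfoChannel"][()]
    names = info.dtype.names or ()

    def col(name):
        return info[name] if name in names else None

    labels = []
    raw_labels = col("Label")
    if raw_labels is not None:
        labels = [
            lbl.decode() if isinstance(lbl, bytes) else str(lbl) for lbl in raw_labels
        ]
    factors = np.array([])
    conv, expo = col("ConversionFactor"), col("Exponent")
    if conv is not None:
        expo = expo if expo is not None else np.zeros(len(conv))
        factors = np.asarray(conv, dtype=float) * 10.0 ** np.asarray(expo, dtype=float)
    rate = None
    tick = col("Tick")  # microseconds per sample
    if tick is not None and len(tick) and tick[0] > 0:
        rate = 1e6 / float(tick[0])
    return labels, factors, rate


def read_recording_hdf5(
    path: str | Path,
    dataset_path: str = MCS_DEFAULT_DATASET,
    time_range: tuple[float, float] | None = None,
    sampling_rate: float | None = None,
    conversion_factor: float | np.ndarray | None = None,
    labels: Sequence[str] | None = None,
    channels_first: bool = True,
) -> Recording:
    """Read an HDF5 recording in the MultiChannel Systems layout.

    ``dataset_path`` must resolve to a 2-D dataset (channels x samples by
    default; set ``channels_first=False`` for samples x channels). Labels,
    volt conversion factors and the sampling rate are taken from a sibling
    ``InfoChannel`` table when present; explicit arguments override them.
    ``time_range`` restricts the result to ``[start, stop)`` seconds and sets
    ``t0`` accordingly.
    """
    path = Path(path)
    with h5py.File(path, "r") as fh:
        if dataset_path not in fh:
            parent = dataset_path.rsplit("/", 1)[0]
            available = []
            fh.visit(available.append)
            raise KeyError(
                f"{path}: dataset {dataset_path!r} not found; available nodes: "
                + ", ".join(available[:40])
            )
        dset = fh[dataset_path]
        if dset.ndim != 2:
            raise ValueError(f"{dataset_path} is {dset.ndim}-D, expected 2-D")
        stream = fh[dataset_path].parent
        info_labels, info_factors, info_rate = _mcs_channel_info(stream)
        rate = sampling_rate or info_rate
        if rate is None:
            raise ValueError("sampling rate not present in file; pass sampling_rate=")
        n_samples = dset.shape[1] if channels_first else dset.shape[0]
        if time_range is not None:
            start_t, stop_t = time_range
            k0 = int(round(start_t * rate))
            k1 = int(round(stop_t * rate))
            if not (0 <= k0 < k1 <= n_samples):
                raise ValueError(
                    f"time_range {time_range} outside recording of "
                    f"{n_samples / rate:.3f} s"
                )
            t0 = k0 / rate
        else:
            k0, k1, t0 = 0, n_samples, 0.0
        raw = dset[:, k0:k1].T if channels_first else dset[k0:k1, :]
        data = np.asarray(raw, dtype=float)
        if conversion_factor is None and info_factors.size:
            conversion_factor = info_factors
        if conversion_factor is not None:
            data = data * np.atleast_1d(np.asarray(conversion_factor, dtype=float))
        use_labels = list(labels) if labels is not None else info_labels
    return Recording(data, rate, use_labels, t0=t0)


def select_channel_group(
    rec: Recording, labels: Sequence[str], spacing: float
) -> ChannelGroup:
    """Select the ordered electrode series of one microchannel by label.

    The first label is the electrode nearest the somal compartment, so
    ``D(1, i) = (i - 1) * spacing``. Reversing the label list reverses the
    electrode order and flips all downstream direction signs.
    """
    indices = []
    for lbl in labels:
        try:
            indices.append(rec.labels.index(lbl))
        except ValueError:
            raise KeyError(f"channel label {lbl!r} not in recording {rec.labels}") from None
    return ChannelGroup(rec, indices, spacing)


def export_sequences(seqs, path: str | Path, clusters=None, w: float = 7.5) -> pd.DataFrame:
    """Write one CSV row per propagation sequence.

    Columns: sequence id, per-electrode peak times (s) and peak voltages (V),
    direction, Kendall tau_b, first-to-last-pair SPV and its confidence, mean
    SPV and its confidence, and — when ``clusters`` is given — the cluster id
    and CPV (most distant pair) with its confidence. Times are written at full
    float precision so the table round-trips exactly.
    """
    from . import velocity as vel  # local import: io must not depend on velocity at import time

    cluster_of: dict[int, int] = {}
    cpv_of: dict[int, "vel.VelocityEstimate"] = {}
    if clusters is not None:
        for cl in clusters:
            for sid in cl.member_ids:
                cluster_of[sid] = cl.id
            if cl.sequences and cl.id != 0:
                n_e = cl.sequences[0].n_e
                try:
                    aligns = {
                        e: vel.realign_cluster_events(cl.sequences, e) for e in (1, n_e)
                    }
                    for p, seq in enumerate(cl.sequences):
                        cpv_of[seq.id] = vel.cpv(cl.sequences, p, 1, n_e, alignments=aligns)
                except vel.InvalidVelocityError:
                    pass

    records = []
    for seq in seqs:
        row: dict[str, object] = {"id": seq.id}
        for e in range(1, seq.n_e + 1):
            row[f"t_peak_{e}"] = seq.times[e - 1]
            row[f"v_peak_{e}"] = seq.peak_voltages[e - 1]
        row["direction"] = seq.direction
        row["tau_b"] = seq.tau_b
        try:
            first_last = vel.spv(seq, 1, seq.n_e, w=w)
            row["spv"] = first_last.value
            row["spv_ci"] = first_last.confidence
        except vel.InvalidVelocityError:
            row["spv"] = row["spv_ci"] = np.nan
        try:
            mean_est = vel.spv_mean(seq, w=w)
            row["spv_mean"] = mean_est.value
            row["spv_mean_ci"] = mean_est.confidence
        except vel.InvalidVelocityError:
            row["spv_mean"] = row["spv_mean_ci"] = np.nan
        if clusters is not None:
            row["cluster"] = cluster_of.get(seq.id, 0)
            est = cpv_of.get(seq.id)
            row["cpv"] = est.value if est else np.nan
            row["cpv_ci"] = est.confidence if est else np.nan
        records.append(row)

    if records:
        df = pd.DataFrame.from_records(records)
    else:  # header-only file for an empty result set
        cols = ["id", "direction", "tau_b", "spv", "spv_ci", "spv_mean", "spv_mean_ci"]
        df = pd.DataFrame(columns=cols)
    df.to_csv(path, index=False, float_format="%.17g")
    return df


def load_group_config(path: str | Path) -> dict:
    """Read a JSON config describing channel groups (labels, spacing, units)."""
    with open(path) as fh:
        return json.load(fh)
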