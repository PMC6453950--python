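"""ROI-based spike sorting of propagation sequences into source clusters.

Sorting is user-driven, not automatic: on the peak-aligned spike overlay of
one chosen "event electrode", rectangular regions of interest (ROIs) select
up to four source clusters. A sequence joins a cluster when its
event-electrode waveform passes through the cluster's ROIs (through every
ROI with the default ``all`` logic; ``any`` is available). Clusters are
filled sequentially 1 -> 4 and assigned sequences leave the pool, so
earlier clusters take precedence; whatever remains forms cluster 0.
Because every event on the event electrode belongs to a propagation
sequence, the sorting carries over to all electrodes of the microchannel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence as SequenceT

import numpy as np
import pandas as pd

from .sequences import PropagationSequence
from . import velocity as vel

__all__ = ["ROI", "SortingConfig", "Cluster", "assign_clusters", "cluster_summary", "overlay_coordinates"]

MAX_SORTED_CLUSTERS = 4
MAX_ROIS_PER_CLUSTER = 2


@dataclass(frozen=True)
class ROI:
    """A rectangle on the overlay: time (ms, relative to the aligned peak)
    by voltage (volts)."""

    t_range: tuple[float, float]  # ms
    v_range: tuple[float, float]  # volts

    def __post_init__(self) -> None:
        if not self.t_range[0] < self.t_range[1]:
            raise ValueError("t_range must be a non-degenerate interval")
        if not self.v_range[0] < self.v_range[1]:
            raise ValueError("v_range must be a non-degenerate interval")

    def contains(self, t_ms: np.ndarray, v: np.ndarray) -> bool:
        """True if any sample (t_ms, v) falls inside the rectangle."""
        inside = (
            (t_ms >= self.t_range[0])
            & (t_ms <= self.t_range[1])
            & (v >= self.v_range[0])
            & (v <= self.v_range[1])
        )
        return bool(inside.any())


@dataclass
class SortingConfig:
    """Event electrode plus ROI sets per cluster id (1-4).

    ``roi_logic``: ``"all"`` (default) requires the waveform to pass through
    every ROI of a cluster, ``"any"`` through at least one.
    """

    event_electrode: int
    rois: dict[int, list[ROI]] = field(default_factory=dict)
    roi_logic: str = "all"

    def __post_init__(self) -> None:
        if self.roi_logic not in ("all", "any"):
            raise ValueError("roi_logic must be 'all' or 'any'")
        for cid, roi_list in self.rois.items():
            if not 1 <= int(cid) <= MAX_SORTED_CLUSTERS:
                raise ValueError(f"cluster id {cid} outside 1..{MAX_SORTED_CLUSTERS}")
            if not roi_list:
                raise ValueError(f"cluster {cid} declared with no ROI")
            if len(roi_list) > MAX_ROIS_PER_CLUSTER:
                raise ValueError(
                    f"cluster {cid} has {len(roi_list)} ROIs (max {MAX_ROIS_PER_CLUSTER})"
                )

    @classmethod
    def from_json(cls, path: str | Path) -> "SortingConfig":
        """Load ``{event_electrode, roi_logic?, clusters: {id: [{t_ms, v_uV}]}}``."""
        with open(path) as fh:
            raw = json.load(fh)
        rois = {
            int(cid): [
                ROI(tuple(r["t_ms"]), tuple(np.asarray(r["v_uV"], dtype=float) * 1e-6))
                for r in roi_list
            ]
            for cid, roi_list in raw.get("clusters", {}).items()
        }
        return cls(
            event_electrode=int(raw["event_electrode"]),
            rois=rois,
            roi_logic=raw.get("roi_logic", "all"),
        )


@dataclass
class Cluster:
    """A set of propagation sequences attributed to one axonal source."""

    id: int
    member_ids: list[int]
    sequences: list[PropagationSequence]

    @property
    def n_ev(self) -> int:
        return len(self.sequences)


def overlay_coordinates(
    seq: PropagationSequence, electrode: int
) -> tuple[np.ndarray, np.ndarray]:
    """(t_ms relative to the aligned peak, volts) of a sequence's snippet on
    one electrode — the coordinates ROIs are drawn in."""
    snip = seq.snippets[electrode - 1]
    fs = seq.group.sampling_rate
    center = int(seq.peak_samples[electrode - 1]) - int(seq.snippet_starts[electrode - 1])
    t_ms = (np.arange(snip.size) - center) / fs * 1e3
    return t_ms, snip


def assign_clusters(
    seqs: SequenceT[PropagationSequence], config: SortingConfig
) -> list[Cluster]:
    """Partition sequences into clusters 1-4 plus the remainder cluster 0.

    Deterministic: memberships depend only on (seqs, config); contested
    sequences land in the lowest-numbered matching cluster.
    """
    seqs = list(seqs)
    if seqs and not 1 <= config.event_electrode <= seqs[0].n_e:
        raise ValueError(
            f"event electrode {config.event_electrode} absent from the channel group"
        )
    pool = list(range(len(seqs)))
    clusters: list[Cluster] = []
    combine = all if config.roi_logic == "all" else any
    for cid in range(1, MAX_SORTED_CLUSTERS + 1):
        if cid not in config.rois:
            continue
        taken, members = [], []
        for k in pool:
            t_ms, v = overlay_coordinates(seqs[k], config.event_electrode)
            if combine(roi.contains(t_ms, v) for roi in config.rois[cid]):
                taken.append(k)
                members.append(seqs[k])
        pool = [k for k in pool if k not in taken]
        clusters.append(Cluster(cid, [seqs[k].id for k in taken], members))
    clusters.append(Cluster(0, [seqs[k].id for k in pool], [seqs[k] for k in pool]))
    return clusters


def cluster_summary(cluster: Cluster, pair: tuple[int, int] | None = None) -> dict:
    """Spike count, timings, intra-cluster CPV mean +/- std and mean
    confidence for one cluster (most distant pair by default)."""
    if cluster.n_ev == 0:
        return {
            "cluster": cluster.id,
            "n_ev": 0,
            "timings": [],
            "cpv_mean": float("nan"),
            "cpv_std": float("nan"),
            "confidence_mean": float("nan"),
        }
    n_e = cluster.sequences[0].n_e
    i, j = pair if pair is not None else (1, n_e)
    alignments = {e: vel.realign_cluster_events(cluster.sequences, e) for e in (i, j)}
    velocities, confidences = [], []
    for p in range(cluster.n_ev):
        try:
            est = vel.cpv(cluster.sequences, p, i, j, alignments=alignments)
            velocities.append(est.value)
            confidences.append(est.confidence)
        except vel.InvalidVelocityError:
            pass
    return {
        "cluster": cluster.id,
        "n_ev": cluster.n_ev,
        "timings": [float(s.times[i - 1]) for s in cluster.sequences],
        "cpv_mean": float(np.mean(velocities)) if velocities else float("nan"),
        "cpv_std": float(np.std(velocities)) if velocities else float("nan"),
        "confidence_mean": float(np.mean(confidences)) if confidences else float("nan"),
    }


def summary_table(clusters: SequenceT[Cluster], pair: tuple[int, int] | None = None) -> pd.DataFrame:
    return pd.DataFrame([cluster_summary(c, pair) for c in clusters])
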