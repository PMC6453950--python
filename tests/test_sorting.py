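import json

import numpy as np
import pytest

from axonwave.detection import DetectionSettings
from axonwave.io import ChannelGroup, Recording
from axonwave.sequences import detect_sequences
from axonwave.sorting import (
    ROI,
    SortingConfig,
    assign_clusters,
    cluster_summary,
    overlay_coordinates,
)

FS = 20e3


def two_source_group(amps=(-60e-6, -30e-6), velocities=(0.5, 0.5), n_each=6):
    """Interleaved spikes from two sources with distinct trough amplitudes
    (and optionally distinct velocities) on a 4-electrode channel."""
    spacing = 100e-6
    s = 30
    lobe = np.sin(np.pi * np.arange(s) / s)
    n = int(5e4) * 2
    v = np.zeros((n, 4))
    truth = []
    at = 2000
    for m in range(2 * n_each):
        src = m % 2
        delay = int(round(spacing / velocities[src] * FS))
        for e in range(4):
            k = at + e * delay
            v[k : k + s, e] += amps[src] * lobe
        truth.append(src)
        at += 4000
    rec = Recording(v, FS)
    return ChannelGroup(rec, [0, 1, 2, 3], spacing), truth


@pytest.fixture(scope="module")
def two_source():
    group, truth = two_source_group()
    with np.errstate(all="ignore"):
        seqs = detect_sequences(group, DetectionSettings(2.0))
    assert len(seqs) == len(truth)
    return seqs, truth


class TestRoi:
    def test_degenerate_intervals_rejected(self):
        with pytest.raises(ValueError):
            ROI((0.0, 0.0), (-1.0, 1.0))
        with pytest.raises(ValueError):
            ROI((0.0, 1.0), (1.0, -1.0))

    def test_containment_is_any_sample(self, two_source):
        seqs, _ = two_source
        t_ms, v = overlay_coordinates(seqs[0], 2)
        roi = ROI((-0.1, 0.1), (-70e-6, -45e-6))
        assert roi.contains(t_ms, v)  # -60 uV trough sits at t = 0
        assert not ROI((-0.1, 0.1), (10e-6, 20e-6)).contains(t_ms, v)


class TestAssignClusters:
    def test_full_overlay_roi_takes_everything(self, two_source):
        seqs, _ = two_source
        cfg = SortingConfig(2, {1: [ROI((-3.0, 3.0), (-1.0, 1.0))]})
        clusters = assign_clusters(seqs, cfg)
        assert [c.id for c in clusters] == [1, 0]
        assert clusters[0].n_ev == len(seqs) and clusters[1].n_ev == 0

    def test_amplitude_gate_separates_sources(self, two_source):
        seqs, truth = two_source
        cfg = SortingConfig(2, {1: [ROI((-0.2, 0.2), (-70e-6, -45e-6))]})
        c1, c0 = assign_clusters(seqs, cfg)
        big = {s.id for k, s in enumerate(seqs) if truth[k] == 0}
        assert set(c1.member_ids) == big
        assert set(c0.member_ids) == {s.id for s in seqs} - big

    def test_sequential_precedence_on_overlap(self, two_source):
        seqs, _ = two_source
        wide = ROI((-3.0, 3.0), (-1.0, 1.0))
        cfg = SortingConfig(2, {1: [wide], 2: [wide]})
        c1, c2, c0 = assign_clusters(seqs, cfg)
        assert c1.n_ev == len(seqs) and c2.n_ev == 0 and c0.n_ev == 0

    def test_partition_property(self, two_source):
        seqs, _ = two_source
        cfg = SortingConfig(
            2,
            {
                1: [ROI((-0.2, 0.2), (-70e-6, -45e-6))],
                3: [ROI((-0.2, 0.2), (-45e-6, -20e-6))],
            },
        )
        clusters = assign_clusters(seqs, cfg)
        ids = [sid for c in clusters for sid in c.member_ids]
        assert sorted(ids) == sorted(s.id for s in seqs)  # no loss, no duplicates

    def test_non_overlapping_rois_order_independent(self, two_source):
        seqs, _ = two_source
        lo = ROI((-0.2, 0.2), (-70e-6, -45e-6))
        hi = ROI((-0.2, 0.2), (-45e-6, -20e-6))
        a = assign_clusters(seqs, SortingConfig(2, {1: [lo], 2: [hi]}))
        b = assign_clusters(seqs, SortingConfig(2, {1: [hi], 2: [lo]}))
        assert set(a[0].member_ids) == set(b[1].member_ids)
        assert set(a[1].member_ids) == set(b[0].member_ids)

    def test_two_roi_logic_all_vs_any(self, two_source):
        seqs, truth = two_source
        trough = ROI((-0.2, 0.2), (-70e-6, -45e-6))
        # a region the -30 uV waveforms pass through but -60 uV ones also do
        baseline = ROI((-2.0, -1.0), (-5e-6, 5e-6))
        conj = assign_clusters(seqs, SortingConfig(2, {1: [trough, baseline]}))
        disj = assign_clusters(
            seqs, SortingConfig(2, {1: [trough, baseline]}, roi_logic="any")
        )
        n_big = sum(1 for t in truth if t == 0)
        assert conj[0].n_ev == n_big  # both rectangles required
        assert disj[0].n_ev == len(seqs)  # baseline region matches everyone

    def test_determinism(self, two_source):
        seqs, _ = two_source
        cfg = SortingConfig(2, {1: [ROI((-0.2, 0.2), (-70e-6, -45e-6))]})
        a = assign_clusters(seqs, cfg)
        b = assign_clusters(seqs, cfg)
        assert [c.member_ids for c in a] == [c.member_ids for c in b]

    def test_bad_event_electrode(self, two_source):
        seqs, _ = two_source
        with pytest.raises(ValueError, match="event electrode"):
            assign_clusters(seqs, SortingConfig(9, {1: [ROI((-1, 1), (-1, 1))]}))

    def test_config_limits(self):
        with pytest.raises(ValueError):
            SortingConfig(1, {5: [ROI((-1, 1), (-1, 1))]})
        with pytest.raises(ValueError):
            SortingConfig(1, {1: []})
        with pytest.raises(ValueError):
            SortingConfig(1, {1: [ROI((-1, 1), (-1, 1))] * 3})


class TestClusterSummary:
    def test_two_velocity_sources_report_distinct_cpv(self):
        from axonwave.sorting import Cluster

        # 0.4 and 2/3 m/s give 5- and 3-sample inter-electrode delays
        v_slow, v_fast = 0.4, 100e-6 * 20e3 / 3
        group, truth = two_source_group(
            amps=(-60e-6, -60e-6), velocities=(v_slow, v_fast), n_each=5
        )
        with np.errstate(all="ignore"):
            seqs = detect_sequences(group, DetectionSettings(2.0))
        assert len(seqs) == len(truth)
        # sort by velocity signature: 0.4 m/s -> first-to-last spread 0.75 ms
        slow_ids = {s.id for s in seqs if (s.times[3] - s.times[0]) > 0.6e-3}
        slow = Cluster(1, sorted(slow_ids), [s for s in seqs if s.id in slow_ids])
        fast_members = [s for s in seqs if s.id not in slow_ids]
        fast = Cluster(2, [s.id for s in fast_members], fast_members)
        s1 = cluster_summary(slow)
        s2 = cluster_summary(fast)
        assert s1["n_ev"] == 5 and s2["n_ev"] == 5
        assert s1["cpv_mean"] == pytest.approx(v_slow, rel=1e-6)
        assert s2["cpv_mean"] == pytest.approx(v_fast, rel=1e-6)
        assert s1["cpv_std"] == pytest.approx(0.0, abs=1e-6)

    def test_empty_cluster_reports_missing(self):
        from axonwave.sorting import Cluster

        s = cluster_summary(Cluster(3, [], []))
        assert s["n_ev"] == 0 and np.isnan(s["cpv_mean"])

    def test_noiseless_single_source(self, clean_seqs):
        from axonwave.sorting import Cluster

        c = Cluster(1, [s.id for s in clean_seqs], list(clean_seqs))
        s = cluster_summary(c)
        assert s["n_ev"] == 40
        assert s["cpv_mean"] == pytest.approx(0.5, rel=1e-9)
        assert s["cpv_std"] == pytest.approx(0.0, abs=1e-9)
        assert s["confidence_mean"] == pytest.approx(1.0)


class TestJsonConfig:
    def test_roundtrip(self, tmp_path):
        raw = {
            "event_electrode": 2,
            "roi_logic": "all",
            "clusters": {"1": [{"t_ms": [-0.3, -0.1], "v_uV": [-80, -45]}]},
        }
        p = tmp_path / "rois.json"
        p.write_text(json.dumps(raw))
        cfg = SortingConfig.from_json(p)
        assert cfg.event_electrode == 2
        roi = cfg.rois[1][0]
        assert roi.t_range == (-0.3, -0.1)
        assert roi.v_range == pytest.approx((-80e-6, -45e-6))
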