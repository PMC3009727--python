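"""Fusion-event classification: both criteria sets, staging, summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from ldfuse.fusion import (
    CriteriaConfig,
    classify_bostrom,
    classify_refined,
    classify_stage,
    summarize_events,
)
from ldfuse.tracking import LinkConfig, MergeCandidate, Track, link_tracks, find_merge_candidates
from ldfuse.pipeline import analyze_droplet_table

from conftest import (
    FUSION_CRITERIA,
    classify_scene,
    make_fusion_scene,
    match_events,
)


def build_tracks(specs):
    """specs: {track_id: [(frame, x, y, z, r, circ, cxy, cxz), ...]}"""
    tracks = {}
    for tid, rows in specs.items():
        df = pd.DataFrame(
            rows,
            columns=[
                "frame", "x", "y", "z", "radius_um", "circularity",
                "connected_in_xy", "connected_in_xz",
            ],
        )
        df.insert(1, "id", tid)
        tracks[tid] = Track(track_id=tid, observations=df)
    return tracks


def synthetic_candidate(
    gap=0.0, r1=0.5, r2=0.5, r_acc=None, r_next_ratio=1.0, capture_end=10
):
    if r_acc is None:
        r_acc = (r1**3 + r2**3) ** (1 / 3)
    specs = {
        0: [(f, 1.0, 1.0, 1.0, r1, 1.0, True, True) for f in range(3)],
        1: [(f, 1.0 + r1 + r2 + gap, 1.0, 1.0, r2, 1.0, True, True) for f in range(3)],
        2: [
            (f, 1.5, 1.0, 1.0, r_acc * (r_next_ratio if f > 3 else 1.0), 1.0, True, True)
            for f in range(3, capture_end + 1)
        ],
    }
    tracks = build_tracks(specs)
    cand = MergeCandidate(donor_a=0, donor_b=1, acceptor=2, last_donor_frame=2, merge_frame=3)
    return cand, tracks


class TestBostromCriteria:
    def test_distant_donors_fail_distance_flag(self):
        cand, tracks = synthetic_candidate(gap=4.0)
        v = classify_bostrom(cand, tracks, FUSION_CRITERIA)
        assert not v.distance_ok
        assert v.surface_distance == pytest.approx(4.0)
        assert v.center_distance == pytest.approx(5.0)
        assert not v.verdict

    def test_volume_exactly_conserved_passes(self):
        cand, tracks = synthetic_candidate()
        v = classify_bostrom(cand, tracks, FUSION_CRITERIA)
        assert v.volume_ok
        assert v.volume_excess == pytest.approx(0.0, abs=1e-9)
        assert v.verdict

    def test_55pct_excess_fails_volume_flag(self):
        r1 = r2 = (3.0 / (4 * math.pi)) ** (1 / 3)  # unit-volume donors
        r_acc = (3.1 * 3 / (4 * math.pi)) ** (1 / 3)  # 3.1 µm³ > 1.5 * 2
        cand, tracks = synthetic_candidate(r1=r1, r2=r2, r_acc=r_acc)
        v = classify_bostrom(cand, tracks, FUSION_CRITERIA)
        assert not v.volume_ok
        assert v.volume_excess == pytest.approx(0.55, abs=1e-9)

    def test_volume_change_after_merge_fails_persistence(self):
        cand, tracks = synthetic_candidate(r_next_ratio=1.1)  # +33% volume
        v = classify_bostrom(cand, tracks, FUSION_CRITERIA)
        assert not v.persistence_ok

    def test_missing_next_observation_is_flag_not_error(self):
        cand, tracks = synthetic_candidate(capture_end=3)
        v = classify_bostrom(cand, tracks, FUSION_CRITERIA)
        assert not v.persistence_ok


class TestRefinedCriteria:
    def test_scripted_one_stage_mid_capture_passes_all(self, mixed_scenes):
        passed = 0
        for truth, result in mixed_scenes:
            for ev in result.events:
                if ev.refined.verdict == "pass":
                    assert ev.refined.persists_ok
                    assert ev.refined.continuity_ok
                    assert ev.refined.sphericity_ok
                    passed += 1
        assert passed > 30

    def test_docking_pairs_rejected(self, docking_artifact_scene):
        truth, result = docking_artifact_scene
        _, _, false_accepts = match_events(truth, result.events, result.tracks)
        assert false_accepts == []
        # at least one docking distractor surfaced as a candidate and failed
        fails = [e for e in result.events if e.refined.verdict == "fail"]
        assert len(fails) >= 1
        assert all(not e.refined.sphericity_ok for e in fails)

    def test_bostrom_accepts_superset_of_refined_on_artifact_fixture(
        self, docking_artifact_scene
    ):
        truth, result = docking_artifact_scene
        bostrom = {
            (e.donor_a, e.donor_b) for e in result.events if e.bostrom.verdict
        }
        refined = {
            (e.donor_a, e.donor_b)
            for e in result.events
            if e.refined.verdict == "pass"
        }
        assert refined <= bostrom
        assert len(bostrom) > len(refined)  # docking inflates the published count

    def test_merge_near_capture_end_is_indeterminate(self):
        cand, tracks = synthetic_candidate(capture_end=4)
        # shift merge into the second half of the capture
        v = classify_refined(cand, tracks, FUSION_CRITERIA, capture_end_frame=4)
        assert v.verdict == "indeterminate"

    def test_two_stage_within_two_minutes_passes_sphericity(self, mixed_scenes):
        found = 0
        for truth, result in mixed_scenes:
            pairs, _, _ = match_events(truth, result.events, result.tracks)
            for tv, ev in pairs:
                if ev.stage and ev.stage.stage == "two_stage":
                    assert ev.refined.sphericity_ok
                    found += 1
        assert found >= 5

    def test_criterion_monotonicity_in_thresholds(self, mixed_scenes):
        # loosening any single threshold never decreases accepted events
        truth, _ = mixed_scenes[0]
        df = truth.detection_like_table()

        def n_accepted(criteria):
            res = analyze_droplet_table(
                df, LinkConfig(max_link_distance=3.0), criteria
            )
            return sum(1 for e in res.events if e.refined.verdict == "pass")

        base = CriteriaConfig(frame_interval=10.0)
        n0 = n_accepted(base)
        looser = [
            CriteriaConfig(frame_interval=10.0, sphericity_threshold=0.8),
            CriteriaConfig(frame_interval=10.0, sphericity_recovery_window=240.0),
            CriteriaConfig(frame_interval=10.0, refined_min_persist_fraction=0.25),
            CriteriaConfig(frame_interval=10.0, split_volume_drop=0.6),
        ]
        for crit in looser:
            assert n_accepted(crit) >= n0


class TestStaging:
    def test_one_stage_for_subframe_core_merge(self, mixed_scenes):
        for truth, result in mixed_scenes:
            pairs, _, _ = match_events(truth, result.events, result.tracks)
            for tv, ev in pairs:
                if tv.core_merge_frame == tv.membrane_merge_frame:
                    assert ev.stage.stage == "one_stage"

    def test_two_stage_core_time_recovered_within_one_frame(self, mixed_scenes):
        ok = tot = 0
        for truth, result in mixed_scenes:
            pairs, _, _ = match_events(truth, result.events, result.tracks)
            for tv, ev in pairs:
                true_frames = tv.core_merge_frame - tv.membrane_merge_frame + 1
                if true_frames > 1 and ev.stage.stage == "two_stage":
                    tot += 1
                    if abs(ev.stage.core_merge_time - true_frames * 10.0) <= 10.0:
                        ok += 1
        assert tot >= 10
        assert ok / tot >= 0.9

    def test_hundred_second_core_merge(self):
        # the typical two-stage event: spherical within ~100 s of membrane
        # fusion at 10 s frames
        from ldfuse.synthetic import FusionScript, SceneConfig, ScheduledFusion, build_scene

        cfg = SceneConfig(
            field_size=(20, 20, 5), frame_interval=10.0, n_frames=30,
            n_droplets=6, seed=23, cluster_fraction=0.0, radius_range=(0.5, 0.8),
        )
        script = FusionScript(
            events=[ScheduledFusion(0, 1, 2, core_merge_duration=100.0)]
        )
        truth = build_scene(cfg, script)
        res = analyze_droplet_table(
            truth.detection_like_table(),
            LinkConfig(max_link_distance=3.0),
            CriteriaConfig(frame_interval=10.0),
        )
        staged = [e for e in res.events if e.stage is not None]
        assert len(staged) == 1
        assert staged[0].stage.stage == "two_stage"
        assert staged[0].stage.core_merge_time == pytest.approx(100.0, abs=10.0)

    def test_merge_in_final_frame_is_indeterminate(self):
        cand, tracks = synthetic_candidate(capture_end=3)
        res = classify_stage(cand, tracks, FUSION_CRITERIA, capture_end_frame=3)
        assert res.stage == "indeterminate"


class TestSummaries:
    def test_empty_events_all_zero(self):
        s = summarize_events([], n_droplets=50)
        assert s["n_candidates"] == 0
        assert s["one_stage_fraction"] == 0.0
        assert s["fraction_droplets_fusing_refined"] == 0.0

    def test_stage_fractions_counted(self, mixed_scenes):
        truth, result = mixed_scenes[0]
        s = result.summary
        assert s["one_stage"] + s["two_stage"] == s["n_staged"]
        if s["n_staged"]:
            assert s["one_stage_fraction"] == pytest.approx(
                s["one_stage"] / s["n_staged"]
            )

    def test_classifier_precision_and_recall(self, mixed_scenes):
        tp = fn = fp = 0
        for truth, result in mixed_scenes:
            pairs, unmatched_truth, false_accepts = match_events(
                truth, result.events, result.tracks
            )
            tp += len(pairs)
            fn += len(unmatched_truth)
            fp += len(false_accepts)
        assert tp + fn >= 50  # scripted event count across scenes
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        assert precision >= 0.9
        assert recall >= 0.9
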