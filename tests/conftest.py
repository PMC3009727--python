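"""Shared fixtures: scripted scenes at the standard study conditions.

Fusion-detail scenes use fast 10 s captures over 4 minutes, moderately
clustered fields of 30 droplets, and scripts mixing one-stage fusions,
two-stage fusions (core merge 30-100 s) and sub-resolution docking
distractors. The emulated-detection route (``detection_like_table``) keeps
the classifier tests fast; a smaller rendered scene exercises the full
image pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ldfuse.fusion import CriteriaConfig, classify_events
from ldfuse.pipeline import analyze_droplet_table
from ldfuse.synthetic import (
    FusionScript,
    SceneConfig,
    SceneGroundTruth,
    build_scene,
    random_script,
)
from ldfuse.tracking import LinkConfig


FUSION_SCENE_KW = dict(
    field_size=(30.0, 30.0, 5.0),
    voxel_size=(0.1, 0.1, 0.3),
    frame_interval=10.0,
    n_frames=24,
    n_droplets=30,
    radius_range=(0.3, 1.0),
    cluster_fraction=0.5,
    diffusion_coefficient=5e-4,
)

FUSION_LINK = LinkConfig(max_link_distance=3.0)
FUSION_CRITERIA = CriteriaConfig(frame_interval=10.0)


def make_fusion_scene(seed: int, n_fusion: int = 7, n_docking: int = 3,
                      two_stage_fraction: float = 0.3) -> SceneGroundTruth:
    cfg = SceneConfig(seed=seed, **FUSION_SCENE_KW)
    rng = np.random.default_rng(seed + 10_000)
    script = random_script(
        cfg,
        n_fusion=n_fusion,
        n_docking=n_docking,
        rng=rng,
        start_frames=(2, 8),
        two_stage_fraction=two_stage_fraction,
        two_stage_durations=(30.0, 100.0),
    )
    return build_scene(cfg, script)


def classify_scene(truth: SceneGroundTruth):
    table = truth.detection_like_table()
    return analyze_droplet_table(table, FUSION_LINK, FUSION_CRITERIA)


def match_events(truth: SceneGroundTruth, events, tracks):
    """Match classified events to ground-truth fusions by time and place.

    Returns (matched_pairs, unmatched_truth, unmatched_detected) where
    detected events are those with a refined 'pass'.
    """
    tracks = {tr.track_id: tr for tr in tracks}
    accepted = [e for e in events if e.refined.verdict == "pass"]
    used = set()
    pairs = []
    unmatched_truth = []
    for tv in truth.events:
        # last frame at which both donors exist as distinct objects
        st = truth.frame_states(tv.membrane_merge_frame - 1)
        da = st[st["id"] == tv.donor_a]
        db = st[st["id"] == tv.donor_b]
        center = np.concatenate(
            [da[["x", "y", "z"]].to_numpy(), db[["x", "y", "z"]].to_numpy()]
        ).mean(axis=0)
        hit = None
        for k, ev in enumerate(accepted):
            if k in used:
                continue
            if not (
                tv.membrane_merge_frame
                <= ev.merge_frame
                <= tv.core_merge_frame + 1
            ):
                continue
            acc = tracks[ev.acceptor]
            pos = acc.centroid_at(ev.merge_frame)
            if pos is not None and np.linalg.norm(pos - center) < 1.5:
                hit = k
                break
        if hit is None:
            unmatched_truth.append(tv)
        else:
            used.add(hit)
            pairs.append((tv, accepted[hit]))
    unmatched_detected = [e for k, e in enumerate(accepted) if k not in used]
    return pairs, unmatched_truth, unmatched_detected


@pytest.fixture(scope="session")
def mixed_scenes():
    """Eight scripted scenes: 56 fusions + 24 docking distractors in total."""
    out = []
    for seed in range(8):
        truth = make_fusion_scene(seed, n_fusion=7, n_docking=3)
        result = classify_scene(truth)
        out.append((truth, result))
    return out


@pytest.fixture(scope="session")
def docking_artifact_scene():
    """One-stage fusions plus docking pairs only (the artifact fixture)."""
    truth = make_fusion_scene(77, n_fusion=5, n_docking=5, two_stage_fraction=0.0)
    result = classify_scene(truth)
    return truth, result


@pytest.fixture(scope="session")
def rendered_scene():
    """A small fully rendered movie with scripted fusions and one docking pair."""
    from ldfuse.synthetic import DockingPair, ScheduledFusion, render_movie

    cfg = SceneConfig(
        field_size=(16.0, 16.0, 4.8),
        voxel_size=(0.1, 0.1, 0.3),
        frame_interval=10.0,
        n_frames=16,
        n_droplets=10,
        radius_range=(0.4, 0.8),
        cluster_fraction=0.0,
        min_separation=0.5,
        seed=11,
    )
    script = FusionScript(
        events=[
            ScheduledFusion(0, 1, 3, core_merge_duration=5.0),
            ScheduledFusion(2, 3, 4, core_merge_duration=40.0),
        ],
        docking=[DockingPair(4, 5, dock_frame=3, docked_gap=0.05)],
    )
    truth = build_scene(cfg, script)
    movie = render_movie(truth, cfg)
    return cfg, script, truth, movie
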