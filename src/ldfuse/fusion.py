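"""Classification of track-merge candidates as fusion or artifact.

Two criteria sets are implemented. The published screening criteria
("Boström criteria"): donors no more than 3.5 µm apart, fused volume not
exceeding the combined donor volume by more than 50%, and presence at the
next timepoint without a change in volume. And the stricter refined
criteria: (1) the fused droplet persists as a single entity for the rest of
the capture, which must cover at least half of it; (2) no discontinuity in
either a single x-y or x-z plane at any post-merge frame; (3) the droplet
becomes increasingly spherical, recovering circularity within a bounded
window. The refined set screens out the rendered-3D docking artifact, in
which juxtaposed sub-resolution droplets masquerade as a fusion.

Accepted events are staged: one-stage events are spherical within one frame
of the merge; two-stage events show fast membrane continuity followed by
slower core merging, with the core-merge time read off the circularity
series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tracking import MergeCandidate, Track

__all__ = [
    "CriteriaConfig",
    "BostromVerdict",
    "RefinedVerdict",
    "StageResult",
    "FusionEvent",
    "classify_bostrom",
    "classify_refined",
    "classify_stage",
    "classify_events",
    "summarize_events",
]


@dataclass
class CriteriaConfig:
    """Thresholds for both criteria sets.

    ``bostrom_max_distance`` (3.5 µm) and ``bostrom_max_volume_excess``
    (50%) are the published values. Donor separation uses the
    surface-to-surface gap by default (``bostrom_distance_convention``);
    the center-to-center distance is always computed alongside. The
    sphericity threshold (circularity 0.9 in the bisecting plane) is a
    configurable surrogate for "increasingly spherical", deliberately above
    the 0.8 floor of the particle-analysis roundness filter.
    """

    frame_interval: float = 30.0  # s
    bostrom_max_distance: float = 3.5  # µm
    bostrom_max_volume_excess: float = 0.5
    bostrom_volume_change_tolerance: float = 0.10
    bostrom_distance_convention: str = "surface"  # or "center"
    refined_min_persist_fraction: float = 0.5
    sphericity_recovery_window: float = 120.0  # s
    sphericity_threshold: float = 0.9
    split_volume_drop: float = 0.35  # consecutive-frame volume drop read as a split

    def __post_init__(self) -> None:
        if self.bostrom_distance_convention not in ("surface", "center"):
            raise ValueError("distance convention must be 'surface' or 'center'")
        for name in (
            "frame_interval",
            "bostrom_max_distance",
            "sphericity_recovery_window",
            "sphericity_threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class BostromVerdict:
    distance_ok: bool
    volume_ok: bool
    persistence_ok: bool
    surface_distance: float
    center_distance: float
    volume_excess: float
    verdict: bool = field(init=False)

    def __post_init__(self) -> None:
        self.verdict = self.distance_ok and self.volume_ok and self.persistence_ok


@dataclass
class RefinedVerdict:
    persists_ok: bool
    continuity_ok: bool
    sphericity_ok: bool
    verdict: str = field(init=False)  # "pass" | "fail" | "indeterminate"
    indeterminate: bool = False

    def __post_init__(self) -> None:
        if self.indeterminate:
            self.verdict = "indeterminate"
        elif self.persists_ok and self.continuity_ok and self.sphericity_ok:
            self.verdict = "pass"
        else:
            self.verdict = "fail"


@dataclass
class StageResult:
    stage: str  # "one_stage" | "two_stage" | "indeterminate"
    membrane_merge_time: float | None  # s
    core_merge_time: float | None  # s, from fusion onset to sphere reformation


@dataclass
class FusionEvent:
    """A classified merge candidate with all criteria flags and stage times."""

    donor_a: int
    donor_b: int
    acceptor: int
    merge_frame: int
    r1: float
    r2: float
    acceptor_first_radius: float
    bostrom: BostromVerdict
    refined: RefinedVerdict
    stage: StageResult | None

    def to_record(self) -> dict:
        return {
            "donor_a": self.donor_a,
            "donor_b": self.donor_b,
            "acceptor": self.acceptor,
            "merge_frame": self.merge_frame,
            "r1": self.r1,
            "r2": self.r2,
            "acceptor_first_radius": self.acceptor_first_radius,
            "bostrom_distance_ok": self.bostrom.distance_ok,
            "bostrom_volume_ok": self.bostrom.volume_ok,
            "bostrom_persistence_ok": self.bostrom.persistence_ok,
            "bostrom_verdict": self.bostrom.verdict,
            "surface_distance_um": self.bostrom.surface_distance,
            "center_distance_um": self.bostrom.center_distance,
            "volume_excess": self.bostrom.volume_excess,
            "refined_persists_ok": self.refined.persists_ok,
            "refined_continuity_ok": self.refined.continuity_ok,
            "refined_sphericity_ok": self.refined.sphericity_ok,
            "refined_verdict": self.refined.verdict,
            "stage": self.stage.stage if self.stage else None,
            "membrane_merge_time_s": self.stage.membrane_merge_time if self.stage else None,
            "core_merge_time_s": self.stage.core_merge_time if self.stage else None,
        }


def _volume(r: float) -> float:
    return 4.0 / 3.0 * math.pi * r**3


def _last_obs(track: Track, frame: int) -> pd.Series:
    row = track.observations[track.observations["frame"] == frame]
    return row.iloc[0]


def classify_bostrom(
    candidate: MergeCandidate,
    tracks: dict[int, Track],
    config: CriteriaConfig | None = None,
) -> BostromVerdict:
    """Apply the published screening criteria to one merge candidate.

    Distance is evaluated at the last pre-merge frame; the volume test
    compares the acceptor's first measured volume with 1.5x the combined
    donor volumes; persistence requires an acceptor observation at the frame
    after the merge with a relative volume change within the measurement
    tolerance (a missing observation fails the flag, it is not an error).
    """
    config = config or CriteriaConfig()
    a = tracks[candidate.donor_a]
    b = tracks[candidate.donor_b]
    acc = tracks[candidate.acceptor]
    t = candidate.last_donor_frame
    oa, ob = _last_obs(a, t), _last_obs(b, t)
    center_dist = float(
        np.linalg.norm(
            oa[["x", "y", "z"]].to_numpy(dtype=float)
            - ob[["x", "y", "z"]].to_numpy(dtype=float)
        )
    )
    surface_dist = max(0.0, center_dist - float(oa["radius_um"]) - float(ob["radius_um"]))
    dist = surface_dist if config.bostrom_distance_convention == "surface" else center_dist
    distance_ok = dist <= config.bostrom_max_distance

    v_donors = _volume(float(oa["radius_um"])) + _volume(float(ob["radius_um"]))
    first = _last_obs(acc, candidate.merge_frame)
    v_acc = _volume(float(first["radius_um"]))
    excess = v_acc / v_donors - 1.0
    volume_ok = excess <= config.bostrom_max_volume_excess

    nxt = acc.observations[acc.observations["frame"] == candidate.merge_frame + 1]
    if len(nxt):
        v_next = _volume(float(nxt.iloc[0]["radius_um"]))
        persistence_ok = abs(v_next - v_acc) / v_acc <= config.bostrom_volume_change_tolerance
    else:
        persistence_ok = False

    return BostromVerdict(
        distance_ok=distance_ok,
        volume_ok=volume_ok,
        persistence_ok=persistence_ok,
        surface_distance=surface_dist,
        center_distance=center_dist,
        volume_excess=excess,
    )


def classify_refined(
    candidate: MergeCandidate,
    tracks: dict[int, Track],
    config: CriteriaConfig | None = None,
    capture_end_frame: int | None = None,
) -> RefinedVerdict:
    """Apply the refined three-point criteria to one merge candidate.

    Requires per-observation plane-continuity flags (``connected_in_xy``,
    ``connected_in_xz``) and circularities in the track table, as produced
    by the detector. If the remaining capture after the merge is shorter
    than the persistence floor the verdict is indeterminate, a first-class
    outcome distinct from fail.
    """
    config = config or CriteriaConfig()
    acc = tracks[candidate.acceptor]
    if capture_end_frame is None:
        capture_end_frame = max(tr.end_frame for tr in tracks.values())
    total_frames = capture_end_frame  # capture spans frames 0..capture_end_frame
    remaining = capture_end_frame - candidate.merge_frame
    if total_frames <= 0 or remaining < config.refined_min_persist_fraction * total_frames:
        return RefinedVerdict(False, False, False, indeterminate=True)

    post = acc.observations[acc.observations["frame"] >= candidate.merge_frame]

    # (1) persists as a single entity to the end of the capture: track
    # reaches the final frame and the volume never collapses between
    # consecutive observations (a split halves the volume in one step)
    vols = _volume(post["radius_um"].to_numpy(dtype=float))
    no_split = True
    if len(vols) >= 2:
        ratios = vols[1:] / vols[:-1]
        no_split = bool(np.all(ratios >= 1.0 - config.split_volume_drop))
    persists_ok = acc.end_frame == capture_end_frame and no_split

    # (2) continuity in single x-y and x-z planes at every post-merge frame
    continuity_ok = bool(
        post["connected_in_xy"].astype(bool).all()
        and post["connected_in_xz"].astype(bool).all()
    )

    # (3) sphericity recovered within the window and retained afterwards
    circ = post["circularity"].to_numpy(dtype=float)
    frames = post["frame"].to_numpy()
    above = circ >= config.sphericity_threshold - 1e-12
    sphericity_ok = False
    if above.any():
        k = int(np.argmax(above))
        reach_time = (frames[k] - candidate.merge_frame) * config.frame_interval
        sphericity_ok = reach_time <= config.sphericity_recovery_window and bool(
            above[k:].all()
        )

    return RefinedVerdict(
        persists_ok=persists_ok,
        continuity_ok=continuity_ok,
        sphericity_ok=sphericity_ok,
    )


def classify_stage(
    candidate: MergeCandidate,
    tracks: dict[int, Track],
    config: CriteriaConfig | None = None,
    capture_end_frame: int | None = None,
) -> StageResult:
    """Stage an accepted event as one- or two-stage and time its phases.

    One-stage: the droplet is already spherical (circularity at or above the
    threshold) at the first post-merge frame. Two-stage: membrane continuity
    is immediate but the core merges slowly; the core-merge time runs from
    fusion onset (the last frame showing two droplets) to the first frame at
    the sphericity threshold. A merge in the final frame is indeterminate
    and excluded from stage fractions.
    """
    config = config or CriteriaConfig()
    acc = tracks[candidate.acceptor]
    if capture_end_frame is None:
        capture_end_frame = max(tr.end_frame for tr in tracks.values())
    if candidate.merge_frame >= capture_end_frame:
        return StageResult("indeterminate", None, None)
    post = acc.observations[acc.observations["frame"] >= candidate.merge_frame]
    circ = post["circularity"].to_numpy(dtype=float)
    frames = post["frame"].to_numpy()
    dt = config.frame_interval
    membrane_time = (candidate.merge_frame - candidate.last_donor_frame) * dt
    if circ[0] >= config.sphericity_threshold - 1e-12:
        return StageResult("one_stage", membrane_time, membrane_time)
    above = circ >= config.sphericity_threshold - 1e-12
    if not above.any():
        return StageResult("indeterminate", membrane_time, None)
    k = int(np.argmax(above))
    core_time = (frames[k] - candidate.last_donor_frame) * dt
    return StageResult("two_stage", membrane_time, core_time)


def classify_events(
    candidates: list[MergeCandidate],
    tracks: list[Track] | dict[int, Track],
    config: CriteriaConfig | None = None,
) -> list[FusionEvent]:
    """Run both criteria sets and staging over all merge candidates."""
    config = config or CriteriaConfig()
    if not isinstance(tracks, dict):
        tracks = {tr.track_id: tr for tr in tracks}
    capture_end = max(tr.end_frame for tr in tracks.values()) if tracks else 0
    events = []
    for cand in candidates:
        a = tracks[cand.donor_a]
        b = tracks[cand.donor_b]
        acc = tracks[cand.acceptor]
        oa = _last_obs(a, cand.last_donor_frame)
        ob = _last_obs(b, cand.last_donor_frame)
        first = _last_obs(acc, cand.merge_frame)
        bostrom = classify_bostrom(cand, tracks, config)
        refined = classify_refined(cand, tracks, config, capture_end)
        stage = (
            classify_stage(cand, tracks, config, capture_end)
            if refined.verdict == "pass"
            else None
        )
        if refined.verdict == "pass":
            acc.fate = "merged_into"
        events.append(
            FusionEvent(
                donor_a=cand.donor_a,
                donor_b=cand.donor_b,
                acceptor=cand.acceptor,
                merge_frame=cand.merge_frame,
                r1=float(oa["radius_um"]),
                r2=float(ob["radius_um"]),
                acceptor_first_radius=float(first["radius_um"]),
                bostrom=bostrom,
                refined=refined,
                stage=stage,
            )
        )
    return events


def summarize_events(events: list[FusionEvent], n_droplets: int | None = None) -> dict:
    """Counts and fractions per verdict and stage.

    ``fraction_droplets_fusing`` counts two donors per accepted event over
    the total droplet population, the statistic comparable across captures.
    """
    n = len(events)
    bostrom_pass = sum(1 for e in events if e.bostrom.verdict)
    refined_pass = sum(1 for e in events if e.refined.verdict == "pass")
    refined_indet = sum(1 for e in events if e.refined.verdict == "indeterminate")
    staged = [e for e in events if e.stage is not None and e.stage.stage != "indeterminate"]
    one = sum(1 for e in staged if e.stage.stage == "one_stage")
    two = sum(1 for e in staged if e.stage.stage == "two_stage")
    out = {
        "n_candidates": n,
        "bostrom_accepted": bostrom_pass,
        "refined_accepted": refined_pass,
        "refined_indeterminate": refined_indet,
        "n_staged": len(staged),
        "one_stage": one,
        "two_stage": two,
        "one_stage_fraction": one / len(staged) if staged else 0.0,
        "two_stage_fraction": two / len(staged) if staged else 0.0,
    }
    if n_droplets:
        out["fraction_droplets_fusing_bostrom"] = 2.0 * bostrom_pass / n_droplets
        out["fraction_droplets_fusing_refined"] = 2.0 * refined_pass / n_droplets
    return out
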