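"""End-to-end orchestration: movie -> droplets -> tracks -> events.

Thin glue over the stage modules so the full analysis can run in one call,
both from the command line and inside tests. Each stage consumes and
produces the plain interchange tables, so the pipeline can also be entered
mid-way (e.g. from a pre-segmented droplet table).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .detection import DetectionConfig, detect_droplets
from .fusion import CriteriaConfig, FusionEvent, classify_events, summarize_events
from .tracking import LinkConfig, MergeCandidate, Track, find_merge_candidates, link_tracks

__all__ = ["detect_movie", "analyze_droplet_table", "PipelineResult"]


@dataclass
class PipelineResult:
    droplets: pd.DataFrame
    tracks: list[Track]
    candidates: list[MergeCandidate]
    events: list[FusionEvent]
    summary: dict


def detect_movie(
    movie: np.ndarray,
    voxel_size: tuple[float, float, float],
    config: DetectionConfig | None = None,
    include_nonround: bool = True,
) -> pd.DataFrame:
    """Run droplet detection on every timepoint of a (T, Z, Y, X) movie.

    By default observations failing the roundness filter are kept (subject
    to the minimum-radius cut): the circularity band is a particle-counting
    filter, while tracking and fusion classification must see fusing
    dumbbells and docked doublets, whose circularity is intentionally low.
    """
    from .detection import observations_to_table

    config = config or DetectionConfig()
    per_frame = []
    for t in range(movie.shape[0]):
        res = detect_droplets(movie[t], voxel_size, config, frame=t)
        obs = list(res.accepted)
        if include_nonround:
            obs += [o for o in res.rejected if o.radius >= config.min_radius]
        obs.sort(key=lambda o: o.droplet_id)
        per_frame.append(obs)
    return observations_to_table(per_frame)


def analyze_droplet_table(
    droplets: pd.DataFrame,
    link_config: LinkConfig | None = None,
    criteria: CriteriaConfig | None = None,
    n_droplets: int | None = None,
) -> PipelineResult:
    """Track a droplet table and classify all merge candidates."""
    link_config = link_config or LinkConfig()
    criteria = criteria or CriteriaConfig()
    tracks = link_tracks(droplets, link_config)
    candidates = find_merge_candidates(tracks, link_config.max_link_distance)
    events = classify_events(candidates, tracks, criteria)
    if n_droplets is None:
        first = droplets[droplets["frame"] == droplets["frame"].min()]
        n_droplets = len(first)
    summary = summarize_events(events, n_droplets=n_droplets)
    return PipelineResult(
        droplets=droplets,
        tracks=tracks,
        candidates=candidates,
        events=events,
        summary=summary,
    )
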