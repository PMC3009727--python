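"""Motility, clustering and count statistics for droplet populations.

These are the population-level summaries used to characterize droplet
behaviour: per-track path length vs net displacement (droplets typically
wander locally, giving µm-scale paths but sub-µm displacements), the
fraction of droplets in close proximity to a neighbour (clustering), and
paired/unpaired t-tests for count and size changes between conditions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .tracking import Track

logger = logging.getLogger(__name__)

__all__ = [
    "MotilitySummary",
    "ClusterSummary",
    "motility_summary",
    "clustering_fraction",
    "count_change_test",
    "radius_change_test",
]


@dataclass
class MotilitySummary:
    mean_path_length: float  # µm
    sem_path_length: float
    mean_net_displacement: float  # µm
    sem_net_displacement: float
    n_tracks: int
    n_singletons_excluded: int
    capture_duration: float | None = None  # s


@dataclass
class ClusterSummary:
    fraction_clustered: float
    n_droplets: int
    proximity_threshold: float  # µm, surface-to-surface


def motility_summary(tracks: list[Track], frame_interval: float | None = None) -> MotilitySummary:
    """Per-track path length and net displacement, aggregated as mean ± SEM.

    Tracks with fewer than two observations carry no motion information and
    are excluded (their count is logged and reported).
    """
    usable = [tr for tr in tracks if tr.n_obs >= 2]
    excluded = len(tracks) - len(usable)
    if excluded:
        logger.info("motility_summary: excluded %d singleton tracks", excluded)
    if not usable:
        raise ValueError("no track with >= 2 observations")
    paths = np.array([tr.path_length for tr in usable])
    disps = np.array([tr.net_displacement for tr in usable])
    n = len(usable)
    sem = lambda v: float(np.std(v, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    duration = None
    if frame_interval is not None:
        duration = frame_interval * max(
            tr.end_frame - tr.start_frame for tr in usable
        )
    return MotilitySummary(
        mean_path_length=float(paths.mean()),
        sem_path_length=sem(paths),
        mean_net_displacement=float(disps.mean()),
        sem_net_displacement=sem(disps),
        n_tracks=n,
        n_singletons_excluded=excluded,
        capture_duration=duration,
    )


def clustering_fraction(
    centroids: np.ndarray,
    radii: np.ndarray,
    proximity_threshold: float = 0.3,
) -> ClusterSummary:
    """Fraction of droplets within a surface-to-surface gap of a neighbour.

    A droplet counts as clustered iff the minimum over neighbours of
    ``center distance − r_i − r_j`` is at or below the threshold (300 nm by
    default). Proximity is edge-to-edge: a center-to-center reading would be
    vacuous for droplets whose radii exceed the threshold.
    """
    centroids = np.asarray(centroids, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(radii)
    if n < 2:
        return ClusterSummary(0.0, n, proximity_threshold)
    d = np.linalg.norm(centroids[:, None, :] - centroids[None, :, :], axis=2)
    gap = d - radii[:, None] - radii[None, :]
    np.fill_diagonal(gap, np.inf)
    clustered = (gap.min(axis=1) <= proximity_threshold).sum()
    return ClusterSummary(float(clustered) / n, n, proximity_threshold)


def count_change_test(first_counts, last_counts) -> tuple[float, float]:
    """Paired t-test comparing per-cell droplet counts between two frames.

    Returns the classical paired t statistic and the two-sided p-value.
    Zero variance of the paired differences is reported explicitly: t = 0,
    p = 1 when all differences vanish, otherwise an error (the statistic is
    unbounded).
    """
    a = np.asarray(first_counts, dtype=float)
    b = np.asarray(last_counts, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    diff = b - a
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, 1.0
        raise ValueError("paired differences have zero variance but nonzero mean")
    res = sps.ttest_rel(b, a)
    return float(res.statistic), float(res.pvalue)


def radius_change_test(group_a, group_b) -> tuple[float, float]:
    """Welch's unpaired two-tailed t-test (unequal variance) on radii.

    Returns (t, p) with Welch-Satterthwaite degrees of freedom. Two
    zero-variance groups with equal means return (0, 1) by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need n >= 2")
    if np.allclose(a.std(ddof=1), 0.0) and np.allclose(b.std(ddof=1), 0.0):
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
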