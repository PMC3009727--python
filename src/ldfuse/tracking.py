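"""Frame-to-frame droplet linking with gap closing and merge detection.

Linking follows the Brownian-motion assumption: per frame pair, an optimal
bipartite assignment minimizes total squared displacement, with links beyond
the search radius forbidden. Track ends may re-link to later track starts
across a bounded number of missing frames (gap closing). Merge topology —
two tracks ending while a single nearby track continues — is emitted as raw
candidates for the fusion classifier; no fusion verdict is made here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "LinkConfig",
    "Track",
    "MergeCandidate",
    "link_tracks",
    "find_merge_candidates",
    "tracks_to_table",
]


@dataclass
class LinkConfig:
    """Linking parameters.

    ``max_link_distance`` is the per-step search radius in µm (default 20,
    a generous bound for droplets that move well under a micron between
    frames). ``max_gap`` is a frame count: a droplet missed by detection for
    up to this many consecutive frames can be re-linked.
    """

    max_link_distance: float = 20.0
    max_gap: int = 2
    max_volume_growth: float = 0.3  # fractional per-step growth beyond which a link is forbidden

    def __post_init__(self) -> None:
        if self.max_link_distance <= 0:
            raise ValueError("max_link_distance must be positive")
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.max_volume_growth <= 0:
            raise ValueError("max_volume_growth must be positive")


@dataclass
class Track:
    """A time-ordered sequence of droplet observations.

    ``observations`` is a DataFrame slice of the droplet table (columns
    frame, id, x, y, z, radius_um, ...), strictly increasing in frame, with
    gaps up to the configured limit.
    """

    track_id: int
    observations: pd.DataFrame
    fate: str = "ended"  # "open" | "ended" | "merged_into"
    merged_into: int | None = None
    merge_frame: int | None = None

    def __post_init__(self) -> None:
        frames = self.observations["frame"].to_numpy()
        if len(frames) and np.any(np.diff(frames) <= 0):
            raise ValueError("track frames must be strictly increasing")

    @property
    def start_frame(self) -> int:
        return int(self.observations["frame"].iloc[0])

    @property
    def end_frame(self) -> int:
        return int(self.observations["frame"].iloc[-1])

    @property
    def n_obs(self) -> int:
        return len(self.observations)

    def centroid_at(self, frame: int) -> np.ndarray | None:
        row = self.observations[self.observations["frame"] == frame]
        if not len(row):
            return None
        return row[["x", "y", "z"]].to_numpy(dtype=float)[0]

    @property
    def path_length(self) -> float:
        xyz = self.observations[["x", "y", "z"]].to_numpy(dtype=float)
        if len(xyz) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(xyz, axis=0), axis=1).sum())

    @property
    def net_displacement(self) -> float:
        xyz = self.observations[["x", "y", "z"]].to_numpy(dtype=float)
        if len(xyz) < 2:
            return 0.0
        return float(np.linalg.norm(xyz[-1] - xyz[0]))


@dataclass
class MergeCandidate:
    """Raw merge topology: two donor tracks end, one acceptor continues."""

    donor_a: int
    donor_b: int
    acceptor: int
    last_donor_frame: int
    merge_frame: int


def _assign(
    pos_a: np.ndarray,
    pos_b: np.ndarray,
    max_dist: float,
    rad_a: np.ndarray | None = None,
    rad_b: np.ndarray | None = None,
    max_volume_growth: float | None = None,
):
    """Optimal assignment between two point sets; returns index pairs.

    Pairs with distance above ``max_dist`` are forbidden, as are links whose
    volume grows by more than ``max_volume_growth`` (a droplet cannot gain
    volume in one step; a merged blob roughly doubles it, so the merged
    object starts a fresh track and the merge surfaces as track topology
    instead of silently continuing one donor). Equal-cost solutions are
    resolved deterministically by an infinitesimal preference for low index
    pairs.
    """
    if len(pos_a) == 0 or len(pos_b) == 0:
        return []
    d2 = ((pos_a[:, None, :] - pos_b[None, :, :]) ** 2).sum(axis=2)
    feasible = d2 <= max_dist**2
    if rad_a is not None and rad_b is not None and max_volume_growth is not None:
        growth = (rad_b[None, :] / rad_a[:, None]) ** 3 - 1.0
        feasible &= growth <= max_volume_growth
    if not feasible.any():
        return []
    big = 4.0 * max_dist**2 * max(len(pos_a), len(pos_b)) + 1.0
    cost = np.where(feasible, d2, big)
    # deterministic tie-break: lowest combined index wins among equal costs
    eps = 1e-9 * max_dist**2 / max(len(pos_a) + len(pos_b), 1)
    cost = cost + eps * (np.arange(len(pos_a))[:, None] + np.arange(len(pos_b))[None, :])
    rows, cols = linear_sum_assignment(cost)
    return [(i, j) for i, j in zip(rows, cols) if feasible[i, j]]


def link_tracks(droplets: pd.DataFrame, config: LinkConfig | None = None) -> list[Track]:
    """Link a per-frame droplet table into tracks.

    Parameters
    ----------
    droplets
        Droplet table with columns frame, id, x, y, z (and any measurement
        columns, which are carried through). (frame, id) must be unique.
    config
        Linking parameters.

    Returns
    -------
    list of Track, each owning a disjoint subset of the observations;
    every observation belongs to exactly one track.
    """
    config = config or LinkConfig()
    df = droplets.sort_values(["frame", "id"]).reset_index(drop=True)
    if df.duplicated(subset=["frame", "id"]).any():
        raise ValueError("duplicate (frame, id) pairs in droplet table")
    if not len(df):
        return []

    frames = sorted(df["frame"].unique())
    by_frame = {f: df[df["frame"] == f] for f in frames}
    # segment id per observation row index
    seg_of_row: dict[int, int] = {}
    segments: dict[int, list[int]] = {}
    next_seg = 0

    prev_rows: list[int] = []
    for fi, f in enumerate(frames):
        cur = by_frame[f]
        cur_rows = list(cur.index)
        if fi == 0 or not prev_rows:
            matched_cur: set[int] = set()
            links = []
        else:
            prev_f = frames[fi - 1]
            if f - prev_f == 1:
                pos_prev = df.loc[prev_rows, ["x", "y", "z"]].to_numpy(dtype=float)
                pos_cur = df.loc[cur_rows, ["x", "y", "z"]].to_numpy(dtype=float)
                if "radius_um" in df.columns:
                    rad_prev = df.loc[prev_rows, "radius_um"].to_numpy(dtype=float)
                    rad_cur = df.loc[cur_rows, "radius_um"].to_numpy(dtype=float)
                else:
                    rad_prev = rad_cur = None
                links = _assign(
                    pos_prev,
                    pos_cur,
                    config.max_link_distance,
                    rad_prev,
                    rad_cur,
                    config.max_volume_growth,
                )
            else:
                links = []
            matched_cur = set()
            for i, j in links:
                seg = seg_of_row[prev_rows[i]]
                segments[seg].append(cur_rows[j])
                seg_of_row[cur_rows[j]] = seg
                matched_cur.add(cur_rows[j])
        for r in cur_rows:
            if r not in matched_cur:
                segments[next_seg] = [r]
                seg_of_row[r] = next_seg
                next_seg += 1
        prev_rows = cur_rows

    # --- gap closing: re-link segment ends to later segment starts ---------
    if config.max_gap > 0:
        merged_into_seg: dict[int, int] = {}

        def root(s: int) -> int:
            while s in merged_into_seg:
                s = merged_into_seg[s]
            return s

        changed = True
        while changed:
            changed = False
            live = sorted({root(s) for s in segments})
            ends = []
            starts = []
            for s in live:
                rows = segments[s]
                ends.append((s, rows[-1]))
                starts.append((s, rows[0]))
            end_list = []
            start_list = []
            for (se, re_) in ends:
                for (ss, rs) in starts:
                    if se == ss:
                        continue
                    gap = df.loc[rs, "frame"] - df.loc[re_, "frame"] - 1
                    if 1 <= gap <= config.max_gap:
                        dist = np.linalg.norm(
                            df.loc[rs, ["x", "y", "z"]].to_numpy(dtype=float)
                            - df.loc[re_, ["x", "y", "z"]].to_numpy(dtype=float)
                        )
                        if dist <= config.max_link_distance:
                            end_list.append((dist, se, ss))
            # greedy lowest-distance pairing, ids break ties
            used_e: set[int] = set()
            used_s: set[int] = set()
            for dist, se, ss in sorted(end_list, key=lambda t: (t[0], t[1], t[2])):
                # chains (A<-B<-C) resolve over further passes of the loop
                if se in used_e or se in used_s or ss in used_s or ss in used_e:
                    continue
                segments[se].extend(segments[ss])
                del segments[ss]
                merged_into_seg[ss] = se
                used_e.add(se)
                used_s.add(ss)
                changed = True

    tracks: list[Track] = []
    last_frame = frames[-1]
    for tid, seg in enumerate(sorted(segments, key=lambda s: (df.loc[segments[s][0], "frame"], df.loc[segments[s][0], "id"]))):
        obs = df.loc[segments[seg]].sort_values("frame").reset_index(drop=True)
        fate = "open" if int(obs["frame"].iloc[-1]) == last_frame else "ended"
        tracks.append(Track(track_id=tid, observations=obs, fate=fate))
    return tracks


def find_merge_candidates(
    tracks: list[Track], max_link_distance: float = 20.0
) -> list[MergeCandidate]:
    """Emit raw track-merge candidates: two droplets becoming one.

    A candidate requires two tracks ending at the same frame ``t`` and
    exactly one unexplained appearance at ``t + 1`` — the first observation
    of a new track — within ``max_link_distance`` of both donors' final
    centroids. (Linking forbids large volume growth, so a merged object
    always starts a new track rather than continuing a donor.) No fusion
    verdict is made — docking, detection dropouts and true fusions all
    surface here and are separated by the classifier.
    """
    ends_by_frame: dict[int, list[Track]] = {}
    for tr in tracks:
        ends_by_frame.setdefault(tr.end_frame, []).append(tr)
    candidates: list[MergeCandidate] = []
    for t, enders in sorted(ends_by_frame.items()):
        if len(enders) < 2:
            continue
        continuing = [
            tr
            for tr in tracks
            if tr.start_frame == t + 1 and tr.centroid_at(t + 1) is not None
        ]
        for ia in range(len(enders)):
            for ib in range(ia + 1, len(enders)):
                a, b = enders[ia], enders[ib]
                ca, cb = a.centroid_at(t), b.centroid_at(t)
                if ca is None or cb is None:
                    continue
                near = [
                    tr
                    for tr in continuing
                    if np.linalg.norm(tr.centroid_at(t + 1) - ca) <= max_link_distance
                    and np.linalg.norm(tr.centroid_at(t + 1) - cb) <= max_link_distance
                ]
                if len(near) == 1:
                    candidates.append(
                        MergeCandidate(
                            donor_a=a.track_id,
                            donor_b=b.track_id,
                            acceptor=near[0].track_id,
                            last_donor_frame=t,
                            merge_frame=t + 1,
                        )
                    )
    return candidates


def tracks_to_table(tracks: list[Track]) -> pd.DataFrame:
    """Track table: the droplet table plus track_id and fate columns."""
    parts = []
    for tr in tracks:
        obs = tr.observations.copy()
        obs["track_id"] = tr.track_id
        obs["fate"] = tr.fate
        parts.append(obs)
    if not parts:
        return pd.DataFrame()
    return pd.concat(parts, ignore_index=True)
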