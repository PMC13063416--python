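"""Frame-to-frame linking and track-quality filtering.

Detections are linked across consecutive frames by minimum-total-distance
bipartite assignment (Hungarian method) with a hard association gate:
pairings farther than ``max_assoc_dist_px`` (default 100 px, boundary
inclusive) are infeasible. Unassigned detections start new tracks;
unassigned tracks accumulate misses and terminate after ``max_gap_frames``
consecutive misses.

Quality control mirrors the experimental protocol: tracks whose contour area
jumps by more than ``max_area_change_frac`` between consecutive frames are
excluded as irregular morphology (segmentation merges, dividing or defocusing
cells); tracks shorter than ``min_track_frames`` or with total path length
below ``min_total_disp_px`` are dropped as incomplete / zero-velocity
artifacts. A seeded uniform subset of the retained tracks is exposed for
reporting.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .types import Detection, Track, TrackingParams

__all__ = ["link_frames", "build_tracks", "filter_tracks", "tracks_to_frame"]

# Finite stand-in for an infeasible pairing: far larger than any admissible
# cost, keeps the assignment solver away from gated pairs whenever a feasible
# alternative (including leaving both unmatched) exists.
_INFEASIBLE = 1.0e12


def link_frames(
    active_tracks: Sequence[Track],
    detections: Sequence[Detection],
    params: TrackingParams,
) -> tuple[dict[int, Detection], list[Detection], list[int]]:
    """Optimally assign one frame's detections to active tracks.

    Returns ``(matches, births, missed)`` where ``matches`` maps track_id to
    its Detection, ``births`` are unassigned detections and ``missed`` lists
    track_ids that received no detection. The assignment minimises total
    Euclidean centroid distance over pairings within the gate
    (distance <= ``max_assoc_dist_px``).
    """
    if detections:
        frames = {d.frame_index for d in detections}
        if len(frames) > 1:
            raise ValueError(f"detections span multiple frames: {sorted(frames)}")
    tracks = sorted(active_tracks, key=lambda t: t.track_id)  # deterministic tie-break
    if not tracks or not detections:
        return {}, list(detections), [t.track_id for t in tracks]

    t_pos = np.array([t.last_centroid() for t in tracks])
    d_pos = np.array([d.centroid_px for d in detections])
    cost = np.linalg.norm(t_pos[:, None, :] - d_pos[None, :, :], axis=-1)
    feasible = cost <= params.max_assoc_dist_px
    solver_cost = np.where(feasible, cost, _INFEASIBLE)
    rows, cols = linear_sum_assignment(solver_cost)

    matches: dict[int, Detection] = {}
    used = np.zeros(len(detections), dtype=bool)
    for i, j in zip(rows, cols):
        if feasible[i, j]:
            matches[tracks[i].track_id] = detections[j]
            used[j] = True
    births = [d for d, u in zip(detections, used) if not u]
    missed = [t.track_id for t in tracks if t.track_id not in matches]
    return matches, births, missed


def build_tracks(
    detections_by_frame: Mapping[int, Sequence[Detection]],
    params: TrackingParams | None = None,
) -> list[Track]:
    """Link detections frame by frame into Tracks.

    Frames are processed in increasing index order; a detection whose
    ``frame_index`` disagrees with its key is a validation error. Returned
    tracks carry status ``terminated`` (ran to completion or timed out on
    misses) or ``excluded`` with reason ``morphology``.
    """
    if params is None:
        params = TrackingParams()
    frames = sorted(detections_by_frame)
    for f in frames:
        for d in detections_by_frame[f]:
            if d.frame_index != f:
                raise ValueError(
                    f"detection frame_index {d.frame_index} under key {f}: out-of-order input"
                )

    tracks: list[Track] = []
    active: list[Track] = []
    next_id = 0
    for f in frames:
        dets = list(detections_by_frame[f])
        matches, births, missed = link_frames(active, dets, params)
        still_active: list[Track] = []
        for tr in active:
            if tr.track_id in matches:
                det = matches[tr.track_id]
                prev_area = tr.areas_px2[-1]
                tr.frames.append(f)
                tr.centroids_px.append(det.centroid_px)
                tr.areas_px2.append(det.area_px2)
                tr.misses = 0
                if prev_area > 0 and abs(det.area_px2 - prev_area) / prev_area > params.max_area_change_frac:
                    tr.status = "excluded"
                    tr.exclusion_reason = "morphology"
                    continue
                still_active.append(tr)
            else:
                tr.misses += 1
                if tr.misses > params.max_gap_frames:
                    tr.status = "terminated"
                else:
                    still_active.append(tr)
        for det in births:
            tr = Track(
                track_id=next_id,
                frames=[f],
                centroids_px=[det.centroid_px],
                areas_px2=[det.area_px2],
            )
            next_id += 1
            tracks.append(tr)
            still_active.append(tr)
        active = still_active
    for tr in tracks:
        if tr.status == "active":
            tr.status = "terminated"
    return tracks


def filter_tracks(
    tracks: Sequence[Track], params: TrackingParams | None = None
) -> tuple[list[Track], list[Track]]:
    """Apply completeness and zero-velocity gates; draw the reporting subset.

    Returns ``(retained, subset)``. Tracks already excluded upstream stay
    excluded; short tracks get reason ``too_short``; tracks whose cumulative
    path length is below ``min_total_disp_px`` get reason ``zero_velocity``.
    The subset is a seeded uniform sample of ``min(subset_n, n_retained)``
    retained tracks, identical across re-runs.
    """
    if params is None:
        params = TrackingParams()
    retained: list[Track] = []
    for tr in tracks:
        if tr.status == "excluded":
            continue
        if len(tr) < params.min_track_frames:
            tr.status = "excluded"
            tr.exclusion_reason = "too_short"
            continue
        pts = tr.centroid_array_px
        path_len = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
        if path_len < params.min_total_disp_px:
            tr.status = "excluded"
            tr.exclusion_reason = "zero_velocity"
            continue
        retained.append(tr)

    rng = np.random.default_rng(params.seed)
    k = min(params.subset_n, len(retained))
    idx = rng.choice(len(retained), size=k, replace=False) if k else np.array([], dtype=int)
    subset = [retained[i] for i in sorted(idx)]
    return retained, subset


def tracks_to_frame(
    tracks: Sequence[Track], pixel_scale_um: float = 1.0, frame_interval_s: float = 1.0
) -> pd.DataFrame:
    """Flatten tracks into the long-format CSV schema."""
    rows = []
    for tr in tracks:
        for f, (x, y), a in zip(tr.frames, tr.centroids_px, tr.areas_px2):
            rows.append(
                (tr.track_id, f, f * frame_interval_s, x, y,
                 x * pixel_scale_um, y * pixel_scale_um, a, tr.status, tr.exclusion_reason)
            )
    return pd.DataFrame(
        rows,
        columns=["track_id", "frame", "time_s", "x_px", "y_px", "x_um", "y_um",
                 "area_px2", "status", "exclusion_reason"],
    )
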