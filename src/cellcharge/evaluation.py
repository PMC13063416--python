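"""Scoring of pipeline output against synthetic ground truth.

Utilities to match detections and tracks to the generator's truth table:
detection recall/precision/RMSE, track-identity assignment by per-frame
nearest-truth voting, and frame-link agreement. These power the package's
benchmark suite; they are never used inside the pipeline itself.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .types import Detection, Track

__all__ = ["detection_metrics", "assign_track_identities", "link_agreement"]


def _match_points(truth_xy: np.ndarray, det_xy: np.ndarray, max_dist_px: float
                  ) -> list[tuple[int, int]]:
    """Optimal one-to-one matching of truth to detections within a radius."""
    if len(truth_xy) == 0 or len(det_xy) == 0:
        return []
    cost = np.linalg.norm(truth_xy[:, None, :] - det_xy[None, :, :], axis=-1)
    big = 1e9
    rows, cols = linear_sum_assignment(np.where(cost <= max_dist_px, cost, big))
    return [(i, j) for i, j in zip(rows, cols) if cost[i, j] <= max_dist_px]


def detection_metrics(
    truth: pd.DataFrame,
    detections_by_frame: Mapping[int, Sequence[Detection]],
    max_dist_px: float = 5.0,
) -> dict:
    """Recall, precision and centroid RMSE of detections vs the truth table."""
    n_truth = n_det = n_matched = 0
    sq_err: list[float] = []
    for f, sub in truth.groupby("frame"):
        dets = detections_by_frame.get(int(f), [])
        t_xy = sub[["x_px", "y_px"]].to_numpy(float)
        d_xy = np.array([d.centroid_px for d in dets]) if dets else np.empty((0, 2))
        pairs = _match_points(t_xy, d_xy, max_dist_px)
        n_truth += len(t_xy)
        n_det += len(d_xy)
        n_matched += len(pairs)
        sq_err.extend(float(np.sum((t_xy[i] - d_xy[j]) ** 2)) for i, j in pairs)
    return {
        "recall": n_matched / n_truth if n_truth else np.nan,
        "precision": n_matched / n_det if n_det else np.nan,
        "rmse_px": float(np.sqrt(np.mean(sq_err))) if sq_err else np.nan,
        "n_truth": n_truth,
        "n_detections": n_det,
        "n_matched": n_matched,
    }


def assign_track_identities(
    tracks: Sequence[Track], truth: pd.DataFrame, max_dist_px: float = 5.0
) -> dict[int, int]:
    """Map each track to the truth cell it follows (per-frame nearest voting).

    Returns ``{track_id: cell_id}``; tracks with no truth point within the
    radius in any frame are omitted.
    """
    by_frame = {int(f): sub for f, sub in truth.groupby("frame")}
    out: dict[int, int] = {}
    for tr in tracks:
        votes: dict[int, int] = {}
        for f, (x, y) in zip(tr.frames, tr.centroids_px):
            sub = by_frame.get(f)
            if sub is None or len(sub) == 0:
                continue
            d = np.hypot(sub["x_px"].to_numpy() - x, sub["y_px"].to_numpy() - y)
            k = int(np.argmin(d))
            if d[k] <= max_dist_px:
                cid = int(sub["cell_id"].iloc[k])
                votes[cid] = votes.get(cid, 0) + 1
        if votes:
            out[tr.track_id] = max(votes, key=lambda c: (votes[c], -c))
    return out


def link_agreement(
    tracks: Sequence[Track], truth: pd.DataFrame, max_dist_px: float = 5.0
) -> float:
    """Fraction of within-track frame-to-frame links that keep one true identity.

    A link between consecutive track points agrees with ground truth when the
    nearest truth cell (within the radius) is the same at both ends.
    """
    by_frame = {int(f): sub for f, sub in truth.groupby("frame")}

    def nearest_cell(f: int, x: float, y: float) -> int | None:
        sub = by_frame.get(f)
        if sub is None or len(sub) == 0:
            return None
        d = np.hypot(sub["x_px"].to_numpy() - x, sub["y_px"].to_numpy() - y)
        k = int(np.argmin(d))
        return int(sub["cell_id"].iloc[k]) if d[k] <= max_dist_px else None

    n_links = n_agree = 0
    for tr in tracks:
        ids = [nearest_cell(f, x, y) for f, (x, y) in zip(tr.frames, tr.centroids_px)]
        for a, b in zip(ids[:-1], ids[1:]):
            n_links += 1
            if a is not None and a == b:
                n_agree += 1
    return n_agree / n_links if n_links else np.nan
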