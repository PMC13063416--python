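"""Per-frame cell segmentation.

Pipeline per frame: polarity normalisation (cells appear dark in DIC, so the
frame is inverted to work on bright objects), Gaussian blurring, adaptive
(Gaussian-weighted local mean) thresholding, morphological opening+closing,
then connected-component analysis with two contour gates:

* area strictly greater than ``min_area_px2`` (default 50 px^2), and
* minimum enclosing circle radius strictly greater than
  ``min_enclosing_radius_px`` (default 4 px).

Centroids are binary-mask centroids (intensity-unweighted), sub-pixel.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from skimage.filters import gaussian, threshold_local
from skimage.measure import label, regionprops
from skimage.morphology import closing, disk, opening

from .types import Detection, SegmentationParams

__all__ = ["preprocess_frame", "detect_cells", "segment_stack", "detections_to_frame"]

logger = logging.getLogger(__name__)


def preprocess_frame(frame: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Convert one grayscale frame into a binary candidate-cell mask."""
    if frame.ndim != 2 or frame.size == 0:
        raise ValueError("frame must be a non-empty 2-D grayscale image")
    work = np.asarray(frame, dtype=float)
    if params.dark_cells:
        work = 255.0 - work
    if params.blur_sigma_px > 0:
        work = gaussian(work, sigma=params.blur_sigma_px, preserve_range=True)
    # threshold = local Gaussian-weighted mean + adaptive_offset; foreground
    # must exceed its neighbourhood by the offset, which kills flat noise
    thresh = threshold_local(
        work,
        block_size=params.adaptive_block_px,
        method="gaussian",
        offset=-params.adaptive_offset,
    )
    mask = work > thresh
    if params.morph_radius_px > 0:
        selem = disk(params.morph_radius_px)
        mask = closing(opening(mask, selem), selem)
    if mask.all():
        logger.warning("segmentation produced an all-foreground mask (parameter pathology)")
    elif not mask.any():
        logger.debug("segmentation produced an empty mask")
    return mask


def _min_enclosing_radius(coords: np.ndarray) -> float:
    """Radius of the minimum enclosing circle of pixel centres (row, col)."""
    pts = shapely.multipoints(coords[:, ::-1])  # (x, y) order
    return float(shapely.minimum_bounding_radius(pts))


def detect_cells(
    mask: np.ndarray, params: SegmentationParams, frame_index: int = 0
) -> list[Detection]:
    """Extract gated Detections from a binary mask.

    Components failing either the area gate or the enclosing-radius gate are
    discarded. An empty result is valid.
    """
    labeled = label(mask.astype(bool), connectivity=2)
    detections: list[Detection] = []
    for region in regionprops(labeled):
        area = float(region.area)
        if not area > params.min_area_px2:
            continue
        radius = _min_enclosing_radius(region.coords)
        if not radius > params.min_enclosing_radius_px:
            continue
        cy, cx = region.centroid  # binary centroid, sub-pixel (row, col)
        detections.append(
            Detection(
                frame_index=frame_index,
                centroid_px=(float(cx), float(cy)),
                area_px2=area,
                enclosing_radius_px=radius,
            )
        )
    return detections


def segment_stack(
    stack: np.ndarray, params: SegmentationParams | None = None
) -> dict[int, list[Detection]]:
    """Segment every frame of a (n_frames, h, w) stack into Detections."""
    if params is None:
        params = SegmentationParams()
    if stack.ndim != 3:
        raise ValueError("stack must have shape (n_frames, height, width)")
    out: dict[int, list[Detection]] = {}
    for f in range(stack.shape[0]):
        mask = preprocess_frame(stack[f], params)
        out[f] = detect_cells(mask, params, frame_index=f)
    return out


def detections_to_frame(detections_by_frame: dict[int, Sequence[Detection]]) -> pd.DataFrame:
    """Flatten detections into the per-frame CSV schema."""
    rows = [
        (f, d.centroid_px[0], d.centroid_px[1], d.area_px2, d.enclosing_radius_px)
        for f in sorted(detections_by_frame)
        for d in detections_by_frame[f]
    ]
    return pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "area_px2", "radius_px"])
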