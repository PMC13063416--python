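"""Shared fixtures: ground-truthed synthetic scenes, rendered and segmented once.

The two session-scoped scenes reproduce the package's benchmark conditions:

* ``brownian_bench`` — field off, 100 cells on a wide grid, D = 0.16 um^2/s,
  150 frames at 0.2 s, 0.093 um/px (diffusion-recovery and detection-fidelity
  substrate).
* ``field_bench`` — field on at 380 V/m for 50 frames, 100 cells with
  lognormal charge magnitudes in one x-band each (end-to-end charge-recovery
  substrate).
"""

from __future__ import annotations

import numpy as np
import pytest

from cellcharge import segmentation as sg
from cellcharge import synthetic as syn
from cellcharge import tracking as trk
from cellcharge.types import (
    CellModel,
    FieldSchedule,
    MediumConditions,
    SceneSpec,
    SegmentationParams,
    Track,
    TrackingParams,
)


def make_track(positions_px, track_id=0, frame0=0, area=100.0) -> Track:
    """Build a Track from an (n, 2) array of pixel centroids."""
    pts = np.asarray(positions_px, dtype=float)
    return Track(
        track_id=track_id,
        frames=list(range(frame0, frame0 + len(pts))),
        centroids_px=[(float(x), float(y)) for x, y in pts],
        areas_px2=[area] * len(pts),
        status="terminated",
    )


@pytest.fixture
def track_factory():
    return make_track


def grid_cells(n_side: int, spacing_px: float, margin_px: float, scene: SceneSpec,
               charges=None, radius_m: float = 5.0e-7) -> list[CellModel]:
    """Cells on a regular grid (row-major ids)."""
    cells = []
    i = 0
    for r in range(n_side):
        for c in range(n_side):
            q = 0.0 if charges is None else float(charges[i])
            x = (margin_px + c * spacing_px) * scene.pixel_scale_um
            y = (margin_px + r * spacing_px) * scene.pixel_scale_um
            cells.append(CellModel(cell_id=i, radius_m=radius_m, charge_C=q, start_xy_um=(x, y)))
            i += 1
    return cells


@pytest.fixture(scope="session")
def brownian_bench():
    """Field-off benchmark: stack, truth table, scene, ground-truth tracks."""
    scene = SceneSpec(
        width_px=1040, height_px=1040, n_frames=150, pixel_scale_um=0.093,
        frame_interval_s=0.2, noise_sigma=3.0, seed=11,
    )
    cells = grid_cells(10, 100.0, 70.0, scene)
    medium = MediumConditions(diffusion_um2_per_s=0.16)
    field = FieldSchedule(E_V_per_m=0.0)
    rng = np.random.default_rng(12)
    gt = syn.simulate_trajectories(cells, medium, field, scene, seed=rng)
    stack, truth = syn.render_frames(gt, scene, cells=cells, seed=np.random.default_rng(13))
    return {"stack": stack, "truth": truth, "scene": scene, "gt_tracks": gt,
            "medium": medium}


@pytest.fixture(scope="session")
def brownian_segmented(brownian_bench):
    """Detections for every frame of the field-off benchmark."""
    return sg.segment_stack(brownian_bench["stack"], SegmentationParams())


@pytest.fixture(scope="session")
def brownian_tracks(brownian_bench, brownian_segmented):
    """Retained tracks from the field-off benchmark."""
    params = TrackingParams(seed=14)
    tracks = trk.build_tracks(brownian_segmented, params)
    retained, subset = trk.filter_tracks(tracks, params)
    return {"all": tracks, "retained": retained, "subset": subset, "params": params}


@pytest.fixture(scope="session")
def field_bench():
    """Field-on benchmark: lognormal charges, E = 380 V/m, 50 frames."""
    scene = SceneSpec(
        width_px=5000, height_px=1000, n_frames=50, pixel_scale_um=0.093,
        frame_interval_s=0.2, noise_sigma=3.0, seed=21,
    )
    cells = syn.sample_charge_population(100, seed=22)
    cells = syn.place_cells(
        cells, scene, x_banded=True, y_band_px=(880, 970), seed=23
    )
    medium = MediumConditions(diffusion_um2_per_s=0.16)
    field = FieldSchedule(E_V_per_m=380.0, on_intervals=((0.0, np.inf),))
    gt = syn.simulate_trajectories(cells, medium, field, scene, seed=np.random.default_rng(24))
    stack, truth = syn.render_frames(gt, scene, cells=cells, seed=np.random.default_rng(25))
    return {"stack": stack, "truth": truth, "scene": scene, "cells": cells,
            "gt_tracks": gt, "medium": medium, "field": field}


@pytest.fixture(scope="session")
def field_tracks(field_bench):
    detections = sg.segment_stack(field_bench["stack"], SegmentationParams())
    params = TrackingParams(seed=26)
    tracks = trk.build_tracks(detections, params)
    retained, _ = trk.filter_tracks(tracks, params)
    return {"detections": detections, "all": tracks, "retained": retained}
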