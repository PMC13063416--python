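"""Model/Results interface over the kinematics and electrokinetics layers.

Two small fitted-model classes present the analysis the way statistical
packages do: construct a model from data (tracks), call ``fit()``, get a
results object carrying estimates, uncertainties and a ``summary()`` table.

* :class:`BrownianDiffusionModel` — field-off baseline: MSD -> diffusion
  coefficient, step isotropy, axis-velocity null.
* :class:`ForceBalanceModel` — field-on analysis: per-cell signed axis
  velocity -> effective surface charge via the Stokes-drag force balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import electrokinetics as ek
from . import kinematics as km
from .types import (
    ChargeEstimate,
    FieldConditions,
    MediumConditions,
    MsdResult,
    Track,
    TrackMetrics,
)

__all__ = ["BrownianDiffusionModel", "BrownianDiffusionResults",
           "ForceBalanceModel", "ForceBalanceResults", "tracks_from_dataframe"]


def tracks_from_dataframe(df: pd.DataFrame) -> list[Track]:
    """Rebuild Track objects from the long-format tracks table.

    Expects columns track_id, frame, x_px, y_px and optionally area_px2,
    status, exclusion_reason (as written by the tracking stage).
    """
    tracks = []
    for tid, sub in df.groupby("track_id", sort=True):
        sub = sub.sort_values("frame")
        tracks.append(
            Track(
                track_id=int(tid),
                frames=[int(f) for f in sub["frame"]],
                centroids_px=list(zip(sub["x_px"].astype(float), sub["y_px"].astype(float))),
                areas_px2=list(sub["area_px2"].astype(float)) if "area_px2" in sub else [0.0] * len(sub),
                status=str(sub["status"].iloc[0]) if "status" in sub else "terminated",
                exclusion_reason=str(sub["exclusion_reason"].iloc[0]) if "exclusion_reason" in sub else "none",
            )
        )
    return tracks


class BrownianDiffusionModel:
    """Field-off Brownian baseline fitted to a set of tracks.

    Parameters
    ----------
    tracks
        Tracks (length >= 2 each are used).
    pixel_scale_um, frame_interval_s
        Imaging calibration.
    axis_unit_vector
        Axis used for the drift-null diagnostic (default +y, the direction
        the field will point in later experiments).
    """

    def __init__(
        self,
        tracks: Sequence[Track],
        pixel_scale_um: float,
        frame_interval_s: float,
        axis_unit_vector: tuple[float, float] = (0.0, 1.0),
    ) -> None:
        self.tracks = [t for t in tracks if len(t) >= 2]
        if not self.tracks:
            raise ValueError("no usable tracks (length >= 2)")
        self.pixel_scale_um = float(pixel_scale_um)
        self.frame_interval_s = float(frame_interval_s)
        self.axis_unit_vector = axis_unit_vector

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, pixel_scale_um: float,
                       frame_interval_s: float, **kw) -> "BrownianDiffusionModel":
        return cls(tracks_from_dataframe(df), pixel_scale_um, frame_interval_s, **kw)

    def fit(self, max_lag_frames: int | None = None, fit_fraction: float = 1.0
            ) -> "BrownianDiffusionResults":
        """Estimate D from the MSD slope; run isotropy and drift-null checks."""
        msd = km.compute_msd(
            self.tracks, self.pixel_scale_um, self.frame_interval_s, max_lag_frames
        )
        msd = km.fit_diffusion(msd, fit_fraction=fit_fraction)
        iso = km.step_isotropy(self.tracks, self.pixel_scale_um, self.frame_interval_s)
        axis_vels = np.array(
            [
                km.axis_projected_velocity(
                    t, self.axis_unit_vector, self.pixel_scale_um, self.frame_interval_s
                )
                for t in self.tracks
            ]
        )
        return BrownianDiffusionResults(
            model=self,
            msd=msd,
            isotropy=iso,
            axis_velocities_um_s=axis_vels,
        )


@dataclass
class BrownianDiffusionResults:
    """Diffusion estimate with diagnostics from a field-off track set."""

    model: BrownianDiffusionModel
    msd: MsdResult
    isotropy: dict
    axis_velocities_um_s: np.ndarray

    @property
    def D_um2_s(self) -> float:
        return self.msd.D_um2_s

    @property
    def r_squared(self) -> float:
        return self.msd.r_squared

    @property
    def mean_axis_velocity_um_s(self) -> float:
        return float(np.mean(self.axis_velocities_um_s))

    @property
    def se_axis_velocity_um_s(self) -> float:
        v = self.axis_velocities_um_s
        return float(np.std(v, ddof=1) / np.sqrt(v.size)) if v.size > 1 else np.nan

    def summary(self) -> str:
        lines = [
            "Brownian diffusion fit (MSD slope / 4)",
            "=" * 46,
            f"tracks                 {len(self.model.tracks):>10d}",
            f"pooled steps           {self.isotropy['n']:>10d}",
            f"D  [um^2/s]            {self.D_um2_s:>10.4f}",
            f"MSD slope [um^2/s]     {self.msd.slope_um2_s:>10.4f}",
            f"fit R^2                {self.r_squared:>10.4f}  ({self.msd.n_fit_points} lags)",
            f"mean axis velocity     {self.mean_axis_velocity_um_s:>10.4f} um/s"
            f" (SE {self.se_axis_velocity_um_s:.4f})",
            f"Rayleigh isotropy p    {self.isotropy['rayleigh_p']:>10.4g}",
        ]
        return "\n".join(lines)

    def plot_msd(self, ax=None):
        """MSD curve with the fitted line; returns the matplotlib Axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.msd.lags_s, self.msd.msd_um2, "o", ms=3, label="MSD")
        xs = self.msd.lags_s[: self.msd.n_fit_points]
        ax.plot(xs, self.msd.intercept_um2 + self.msd.slope_um2_s * xs, "-",
                label=f"fit: D = {self.D_um2_s:.3f} um$^2$/s, R$^2$ = {self.r_squared:.3f}")
        ax.set_xlabel("lag (s)")
        ax.set_ylabel("MSD (um$^2$)")
        ax.legend()
        return ax


def _crop_to_intervals(
    track: Track, intervals: Sequence[tuple[float, float]], frame_interval_s: float
) -> Track:
    """Restrict a track to frames whose time falls in the field-on windows.

    Brownian-only (field-off) segments would dilute the drift average, so the
    inversion uses on-window steps exclusively.
    """
    keep = [
        i for i, f in enumerate(track.frames)
        if any(t0 <= f * frame_interval_s < t1 for t0, t1 in intervals)
    ]
    return Track(
        track_id=track.track_id,
        frames=[track.frames[i] for i in keep],
        centroids_px=[track.centroids_px[i] for i in keep],
        areas_px2=[track.areas_px2[i] for i in keep],
        status=track.status,
        exclusion_reason=track.exclusion_reason,
    )


class ForceBalanceModel:
    """Electrophoretic force-balance model fitted to field-on tracks.

    Each track's signed mean velocity along the anode->cathode axis is
    inverted to an effective surface charge q = 6 pi eta r v / E. If
    ``on_intervals`` is given, tracks are first cropped to those windows so
    that field-off (purely Brownian) segments do not dilute the drift.
    """

    def __init__(
        self,
        tracks: Sequence[Track],
        conditions: FieldConditions,
        medium: MediumConditions | None = None,
        radius_m: float = 5.0e-7,
        pixel_scale_um: float = 0.093,
        frame_interval_s: float = 0.2,
        axis_unit_vector: tuple[float, float] = (0.0, 1.0),
        labels: Mapping[str, object] | None = None,
        on_intervals: Sequence[tuple[float, float]] | None = None,
    ) -> None:
        if on_intervals:
            tracks = [
                _crop_to_intervals(t, on_intervals, frame_interval_s) for t in tracks
            ]
        self.tracks = [t for t in tracks if len(t) >= 2]
        if not self.tracks:
            raise ValueError("no usable tracks (length >= 2)")
        self.conditions = conditions
        self.medium = medium if medium is not None else MediumConditions()
        self.radius_m = float(radius_m)
        self.pixel_scale_um = float(pixel_scale_um)
        self.frame_interval_s = float(frame_interval_s)
        self.axis_unit_vector = axis_unit_vector
        self.labels = dict(labels or {})

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, conditions: FieldConditions, **kw
                       ) -> "ForceBalanceModel":
        return cls(tracks_from_dataframe(df), conditions, **kw)

    def fit(self) -> "ForceBalanceResults":
        metrics = [
            km.track_metrics(
                t, self.pixel_scale_um, self.frame_interval_s, self.axis_unit_vector
            )
            for t in self.tracks
        ]
        estimates = ek.population_charges(
            metrics,
            self.conditions,
            medium=self.medium,
            radius_m=self.radius_m,
            frame_interval_s=self.frame_interval_s,
            labels=self.labels,
        )
        return ForceBalanceResults(model=self, metrics=metrics, estimates=estimates)


@dataclass
class ForceBalanceResults:
    """Per-cell charge estimates with population summary and group tests."""

    model: ForceBalanceModel
    metrics: list[TrackMetrics]
    estimates: list[ChargeEstimate]
    _summary: dict = dc_field(default_factory=dict)

    @property
    def charges_C(self) -> np.ndarray:
        return np.array([e.q_C for e in self.estimates])

    @property
    def se_charges_C(self) -> np.ndarray:
        return np.array([e.se_q_C for e in self.estimates])

    @property
    def mean_axis_velocities_um_s(self) -> np.ndarray:
        return np.array([e.mean_axis_vel_um_s for e in self.estimates])

    def population_summary(self) -> dict:
        if not self._summary:
            self._summary = ek.summarize_charges(self.estimates)
        return self._summary

    def to_frame(self) -> pd.DataFrame:
        return ek.charges_to_frame(self.estimates)

    def summary(self) -> str:
        s = self.population_summary()
        lines = [
            "Effective surface charge (force-balance inversion)",
            "=" * 50,
            f"cells                  {s['n']:>12d}",
            f"E [V/m]                {self.model.conditions.E_V_per_m:>12.1f}",
            f"eta [Pa s]             {self.model.medium.viscosity_Pa_s:>12.2e}",
            f"r [m]                  {self.model.radius_m:>12.2e}",
            f"mean |q|  [C]          {s['mean_abs_C']:>12.3e}",
            f"median |q| [C]         {s['median_abs_C']:>12.3e}",
            f"IQR |q| [C]            {s['iqr_abs_C']:>12.3e}",
            f"range |q| [C]          {s['min_abs_C']:>12.3e} .. {s['max_abs_C']:.3e}",
            f"sign                   {s['sign_note']:>12s}",
        ]
        return "\n".join(lines)

    def plot_charge_histogram(self, ax=None, bins=20):
        """Histogram of |q| with the sign annotation; returns the Axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(np.abs(self.charges_C), bins=bins, edgecolor="k")
        ax.set_xlabel("|q| (C)")
        ax.set_ylabel("cells")
        ax.set_title(self.population_summary()["sign_note"])
        return ax
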