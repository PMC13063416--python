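"""Force-balance charge inversion and population-level statistics.

A cell of effective surface charge q in a uniform field E experiences an
electrostatic force qE and a Stokes drag 6 pi eta r v. Because the Reynolds
number is tiny, drift reaches steady state essentially instantly, so the net
force vanishes and

    q = 6 pi eta r v / E,

with v the signed time-averaged velocity along the anode->cathode axis
measured while the field is on. Brownian motion is nondirectional, so its
contribution to the time-averaged axis velocity decays as 1/sqrt(K) with
track length K; the residual noise floor on q is quantified by
:func:`charge_noise_floor`.

Sign convention: the axis unit vector points anode -> cathode; a cell moving
toward the anode has negative axis velocity and therefore negative charge.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    SIX_PI,
    ChargeEstimate,
    FieldConditions,
    MediumConditions,
    TrackMetrics,
)

__all__ = [
    "field_strength",
    "charge_from_velocity",
    "charge_noise_floor",
    "population_charges",
    "summarize_charges",
    "field_independence_test",
    "compare_groups",
    "isoelectric_scan",
    "charges_to_frame",
]


def field_strength(
    current_A: float, conductivity_S_per_m: float, cross_section_m2: float
) -> float:
    """Uniform field from a constant-current drive: E = I / (sigma A), V/m.

    Ohm's law in a channel of uniform cross-section: current density I/A over
    conductivity sigma. Zero current is allowed (field off); non-positive
    conductivity or area is not.
    """
    if conductivity_S_per_m <= 0 or cross_section_m2 <= 0:
        raise ValueError("conductivity and cross-section must be > 0")
    if current_A < 0:
        raise ValueError("current must be >= 0")
    return current_A / (conductivity_S_per_m * cross_section_m2)


def charge_from_velocity(
    mean_axis_vel_m_s: float,
    E_V_per_m: float,
    viscosity_Pa_s: float = 1.0e-3,
    radius_m: float = 5.0e-7,
) -> float:
    """Invert the steady-state force balance: q = 6 pi eta r v / E, in C.

    ``mean_axis_vel_m_s`` is the signed axis velocity in m/s; the sign of q
    equals the sign of v (anode-ward motion => negative charge). E must be
    strictly positive — the inversion is undefined for a field-off segment.
    """
    if E_V_per_m <= 0:
        raise ZeroDivisionError(
            "charge inversion undefined at E <= 0: velocity carries no charge information"
        )
    if viscosity_Pa_s <= 0 or radius_m <= 0:
        raise ValueError("viscosity and radius must be > 0")
    return SIX_PI * viscosity_Pa_s * radius_m * mean_axis_vel_m_s / E_V_per_m


def charge_noise_floor(
    n_steps: int,
    diffusion_um2_per_s: float,
    frame_interval_s: float,
    E_V_per_m: float,
    viscosity_Pa_s: float = 1.0e-3,
    radius_m: float = 5.0e-7,
) -> float:
    """Predicted SE of q-hat from Brownian noise alone, in C.

    The per-step axis velocity has sd sqrt(2 D / dt); averaging K independent
    steps and propagating through the inversion gives
    SE(q) = 6 pi eta r sqrt(2 D / dt) / (E sqrt(K)).
    """
    v_sd_m_s = np.sqrt(2.0 * diffusion_um2_per_s / frame_interval_s) * 1e-6
    return SIX_PI * viscosity_Pa_s * radius_m * v_sd_m_s / (E_V_per_m * np.sqrt(n_steps))


def population_charges(
    metrics: Sequence[TrackMetrics],
    conditions: FieldConditions,
    medium: MediumConditions | None = None,
    radius_m: float = 5.0e-7,
    frame_interval_s: float = 0.2,
    labels: Mapping[str, object] | None = None,
) -> list[ChargeEstimate]:
    """Invert every track's mean axis velocity to a ChargeEstimate.

    ``labels`` (pH / field_level / growth_phase) are attached verbatim to
    each estimate for downstream grouping. Per-estimate SEs use the medium's
    diffusion coefficient as the Brownian noise scale.
    """
    medium = medium if medium is not None else MediumConditions()
    labels = dict(labels or {})
    out: list[ChargeEstimate] = []
    for m in metrics:
        q = charge_from_velocity(
            m.mean_axis_vel_um_s * 1e-6,
            conditions.E_V_per_m,
            medium.viscosity_Pa_s,
            radius_m,
        )
        se = charge_noise_floor(
            max(m.n_steps, 1),
            medium.diffusion_um2_per_s,
            frame_interval_s,
            conditions.E_V_per_m,
            medium.viscosity_Pa_s,
            radius_m,
        )
        out.append(
            ChargeEstimate(
                track_id=m.track_id,
                mean_axis_vel_um_s=m.mean_axis_vel_um_s,
                q_C=q,
                E_V_per_m=conditions.E_V_per_m,
                viscosity_Pa_s=medium.viscosity_Pa_s,
                radius_m=radius_m,
                n_steps=m.n_steps,
                se_q_C=se,
                pH=labels.get("pH"),
                field_level=labels.get("field_level"),
                growth_phase=labels.get("growth_phase"),
            )
        )
    return out


def summarize_charges(estimates: Sequence[ChargeEstimate], n_bins: int = 20) -> dict:
    """Population summary of |q|: count, quantiles, histogram, sign note.

    Histograms report charge magnitude with an explicit annotation of the
    dominant sign, matching the convention of plotting |q| for an
    all-negative population.
    """
    q = np.array([e.q_C for e in estimates])
    if q.size == 0:
        return {"n": 0, "note": "empty estimate set"}
    mags = np.abs(q)
    counts, edges = np.histogram(mags, bins=n_bins)
    n_neg = int(np.sum(q < 0))
    if n_neg == q.size:
        sign_note = "all charges negative"
    elif n_neg == 0:
        sign_note = "all charges positive"
    else:
        sign_note = f"{n_neg}/{q.size} charges negative"
    q25, q50, q75 = np.quantile(mags, [0.25, 0.5, 0.75])
    return {
        "n": int(q.size),
        "mean_abs_C": float(np.mean(mags)),
        "median_abs_C": float(q50),
        "iqr_abs_C": float(q75 - q25),
        "q25_abs_C": float(q25),
        "q75_abs_C": float(q75),
        "min_abs_C": float(np.min(mags)),
        "max_abs_C": float(np.max(mags)),
        "hist_counts": counts.tolist(),
        "hist_edges_C": edges.tolist(),
        "sign_note": sign_note,
    }


def field_independence_test(estimates: Sequence[ChargeEstimate]) -> dict:
    """Pearson correlation of q against field level across cells.

    A physically meaningful effective charge must not depend on the probing
    field; p > alpha across a range of field strengths supports that the
    inversion measures a field-invariant cell property.
    """
    pairs = [(e.field_level, e.q_C) for e in estimates if e.field_level is not None]
    if not pairs:
        raise ValueError("no estimates carry a field_level label")
    E = np.array([p[0] for p in pairs], dtype=float)
    q = np.array([p[1] for p in pairs], dtype=float)
    levels, counts = np.unique(E, return_counts=True)
    if levels.size < 2 or np.any(counts < 3):
        raise ValueError("need >= 2 field levels with >= 3 estimates each")
    if np.ptp(q) == 0 or np.ptp(E) == 0:
        raise ValueError("correlation undefined for constant inputs")
    r, p = stats.pearsonr(E, q)
    return {"pearson_r": float(r), "p_value": float(p), "n": int(E.size), "levels": levels.tolist()}


def compare_groups(groups: Mapping[str, Sequence[float]]) -> dict:
    """One-way ANOVA across charge groups plus Bonferroni-corrected pairwise t-tests.

    ``groups`` maps a label (e.g. growth phase L/E/S) to its charge values.
    Returns ANOVA F and p, and per-pair corrected p-values.
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2:
        raise ValueError("need >= 2 groups")
    for name, arr in zip(names, arrays):
        if arr.size < 3:
            raise ValueError(f"group {name!r} has < 3 values")
    F, p = stats.f_oneway(*arrays)
    pairs = list(combinations(range(len(names)), 2))
    pairwise = {}
    for i, j in pairs:
        _, p_ij = stats.ttest_ind(arrays[i], arrays[j], equal_var=False)
        pairwise[f"{names[i]} vs {names[j]}"] = float(min(1.0, p_ij * len(pairs)))
    return {
        "anova_F": float(F),
        "anova_p": float(p),
        "pairwise_p": pairwise,
        "group_means": {k: float(np.mean(a)) for k, a in zip(names, arrays)},
    }


def isoelectric_scan(groups_by_pH: Mapping[float, Sequence[float]]) -> dict:
    """Mean signed charge per pH and the isoelectric-point bracket.

    The IEP is where the population mean charge changes sign as pH rises
    (protonation of surface groups makes cells positive below it). Reported
    as the bracketing (pH_lo, pH_hi) interval with a linear-interpolated
    crossing, or ``None`` if the means never change sign.
    """
    if len(groups_by_pH) < 2:
        raise ValueError("need >= 2 pH levels")
    phs = sorted(groups_by_pH)
    means = np.array([np.mean(np.asarray(groups_by_pH[ph], dtype=float)) for ph in phs])
    iep_interval = None
    iep_pH = None
    for i in range(len(phs) - 1):
        m0, m1 = means[i], means[i + 1]
        if m0 == 0.0:
            iep_interval, iep_pH = (phs[i], phs[i]), float(phs[i])
            break
        if m0 * m1 < 0:
            iep_interval = (phs[i], phs[i + 1])
            iep_pH = float(phs[i] + (phs[i + 1] - phs[i]) * m0 / (m0 - m1))
            break
    return {
        "mean_q_per_pH": {float(ph): float(m) for ph, m in zip(phs, means)},
        "iep_interval": iep_interval,
        "iep_pH": iep_pH,
    }


def charges_to_frame(estimates: Sequence[ChargeEstimate]) -> pd.DataFrame:
    """Flatten charge estimates into the CSV schema."""
    return pd.DataFrame(
        [
            (e.track_id, e.mean_axis_vel_um_s, e.q_C, e.se_q_C, e.E_V_per_m,
             e.pH, e.growth_phase)
            for e in estimates
        ],
        columns=["track_id", "mean_axis_vel_um_s", "q_C", "se_q_C", "E_V_per_m", "pH", "phase"],
    )
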