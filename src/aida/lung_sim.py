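"""Forward single-breath deposition simulator.

A deliberately simple two-part model of the inflated lung predicts the
particle recovery of the single-breath maneuver:

* a symmetric conducting tree (per-generation count, length, diameter —
  default: a Weibel-type table, generations 0-15) through which the aerosol
  is convected; each generation loses particles by laminar diffusional
  deposition (Gormley–Kennedy), with the flow split equally among its tubes;
* a distal airspace represented as a sphere of effective radius r, in which
  the aerosol resides during the breath hold (plus the convective head and
  tail of the breath) and deposits by diffusion to the wall.

The predicted recovery is

    R_pred = P_tree(inhale) * F_sphere(t_res) * P_tree(exhale)

with t_res the residence time defined exactly as in the measurement: from
half-inhalation to the mid-sample time of the collector.  For nanoparticles
no sedimentation or impaction terms are needed; diffusion dominates
throughout.  The effective airspace radius is the natural subject-level
parameter: it sets the exponential decay time tau ~ r^2/(pi^2 D) of
recovery versus residence time and thereby the spread of time-normalized
recoveries across a cohort.

This simulator is a qualitative stand-in for full multiple-path dosimetry
models: it reproduces the size ordering, the exponential decline with
residence time, and the near-independence of flow rate, and it drives the
synthetic-data generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .physics import (
    BODY_CONDITIONS,
    GasConditions,
    ParticleSpec,
    diffusion_coefficient,
    sphere_remaining_fraction,
    tube_penetration,
)

__all__ = [
    "AirwayGeneration",
    "LungGeometry",
    "SimulatedBreath",
    "simulate_recovery",
    "breath_residence_time",
    "cohort_predictions",
    "default_geometry",
]


@dataclass(frozen=True)
class AirwayGeneration:
    count: int
    length: float  # m
    diameter: float  # m

    def __post_init__(self) -> None:
        if self.count < 1 or self.length <= 0 or self.diameter <= 0:
            raise ValueError(f"invalid airway generation {self}")


# Symmetric Weibel-type conducting path at ~TLC inflation: generation g has
# 2^g tubes; (length, diameter) in cm.
_WEIBEL_TABLE_CM = [
    (12.0, 1.80), (4.76, 1.22), (1.90, 0.83), (0.76, 0.56),
    (1.27, 0.45), (1.07, 0.35), (0.90, 0.28), (0.76, 0.23),
    (0.64, 0.186), (0.54, 0.154), (0.46, 0.130), (0.39, 0.109),
    (0.33, 0.095), (0.27, 0.082), (0.23, 0.074), (0.20, 0.066),
]


@dataclass(frozen=True)
class LungGeometry:
    """Conducting path plus an effective distal airspace."""

    conducting_path: tuple[AirwayGeneration, ...]
    distal_airspace_radius: float  # m
    dead_space: float = 0.3  # L
    functional_residual_fraction: float = 0.0  # residual-air mixing; 0 for RV->TLC

    def __post_init__(self) -> None:
        if self.distal_airspace_radius <= 0:
            raise ValueError("distal airspace radius must be > 0")
        if not self.conducting_path:
            raise ValueError("conducting path must have >= 1 generation")
        counts = [g.count for g in self.conducting_path]
        if any(c2 < c1 for c1, c2 in zip(counts, counts[1:])):
            raise ValueError("generation counts must be ordered proximal -> distal")


def default_geometry(
    airspace_radius: float = 300e-6, dead_space: float = 0.3, n_generations: int = 16
) -> LungGeometry:
    """Weibel-type symmetric geometry with a configurable airspace radius."""
    path = tuple(
        AirwayGeneration(count=2**g, length=l / 100.0, diameter=d / 100.0)
        for g, (l, d) in enumerate(_WEIBEL_TABLE_CM[:n_generations])
    )
    return LungGeometry(
        conducting_path=path, distal_airspace_radius=airspace_radius, dead_space=dead_space
    )


@dataclass(frozen=True)
class SimulatedBreath:
    """Commanded single-breath maneuver for the forward model."""

    particle: ParticleSpec
    inhale_flow: float  # L/s, mean
    exhale_flow: float  # L/s, mean (magnitude)
    breath_hold: float  # s
    inhaled_volume: float = 4.5  # L
    collector_volume: float = 1.2  # L

    def __post_init__(self) -> None:
        for q in (self.inhale_flow, self.exhale_flow):
            if not (0.1 <= q <= 12.0):
                raise ValueError(f"mean flows must lie in [0.1, 12] L/s, got {q}")
        if self.breath_hold < 0:
            raise ValueError("breath hold must be >= 0")
        if self.inhaled_volume <= 0 or self.collector_volume <= 0:
            raise ValueError("volumes must be > 0")


def _tree_penetration(geometry: LungGeometry, D: float, flow_lps: float) -> float:
    """Product of per-generation Gormley-Kennedy penetrations for one leg."""
    q_total = flow_lps * 1e-3  # m^3/s
    p = 1.0
    for gen in geometry.conducting_path:
        p *= tube_penetration(D, gen.length, q_total / gen.count)
    return p


def breath_residence_time(breath: SimulatedBreath) -> float:
    """Residence time implied by the commanded breath.

    Half-inhaled to mid-sample: V_i/(2 Q_in) + hold + (V_collector/2)/Q_ex.
    """
    return (
        breath.inhaled_volume / (2.0 * breath.inhale_flow)
        + breath.breath_hold
        + breath.collector_volume / (2.0 * breath.exhale_flow)
    )


def simulate_recovery(
    geometry: LungGeometry,
    breath: SimulatedBreath,
    conditions: GasConditions | None = None,
) -> tuple[float, float]:
    """Predicted recovery and residence time for one breath.

    Returns ``(R_pred, t_res)`` with R_pred in (0, 1].  In the pure
    breath-hold limit (instantaneous flows, no conducting losses) R_pred
    reduces exactly to the absorbing-sphere kernel at the hold time.
    """
    cond = conditions or BODY_CONDITIONS
    D = float(diffusion_coefficient(breath.particle, cond))
    t_res = breath_residence_time(breath)
    p_in = _tree_penetration(geometry, D, breath.inhale_flow)
    p_ex = _tree_penetration(geometry, D, breath.exhale_flow)
    f_sphere = sphere_remaining_fraction(D, t_res, geometry.distal_airspace_radius)
    return p_in * f_sphere * p_ex, t_res


def cohort_predictions(
    geometries: list[LungGeometry] | dict[str, LungGeometry],
    breaths: list[SimulatedBreath],
    conditions: GasConditions | None = None,
) -> pd.DataFrame:
    """Deterministic prediction table: one row per geometry x breath.

    Columns: subject, size_nm, hold_s, flow_in_Lps, flow_ex_Lps, t_res_s,
    R_pred.  ``geometries`` may be a dict keyed by subject label.
    """
    if not geometries:
        raise ValueError("need >= 1 geometry")
    if isinstance(geometries, dict):
        items = list(geometries.items())
    else:
        items = [(f"S{i + 1}", g) for i, g in enumerate(geometries)]
    rows = []
    for label, geom in items:
        for breath in breaths:
            r_pred, t_res = simulate_recovery(geom, breath, conditions)
            rows.append(
                {
                    "subject": label,
                    "size_nm": breath.particle.diameter_nm,
                    "hold_s": breath.breath_hold,
                    "flow_in_Lps": breath.inhale_flow,
                    "flow_ex_Lps": breath.exhale_flow,
                    "t_res_s": t_res,
                    "R_pred": r_pred,
                }
            )
    return pd.DataFrame(rows)
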