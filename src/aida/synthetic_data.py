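"""Synthetic instrument and cohort: every input the pipeline needs.

This module replaces the physical apparatus and the human volunteers:

* syringe calibration runs (penetration observations on a size x flow grid
  with multiplicative measurement noise),
* subject profiles (vital capacity, dead space, effective distal-airspace
  radius, repeat-to-repeat variability),
* 100 Hz flow traces realizing the I-V single-breath maneuver with
  half-sine flow segments, sensor noise and valve-event jitter, and
* 1 Hz particle-counter traces with Poisson counting noise (1 L/min sample
  flow), tagged reservoir/sample, whose underlying sample-collector mean is
  C_reservoir * R_true * R_instrument_true.

The ground truth behind every generated measurement (true recovery, true
residence time, true instrument penetration) is recorded separately and is
never read by the analysis path — it exists so that tests can close the
loop from raw traces to recovered parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .instrument_loss import (
    CalibrationRecord,
    InstrumentLossModel,
    passage_time_from_flows,
)
from .lung_sim import LungGeometry, SimulatedBreath, default_geometry
from .physics import BODY_CONDITIONS, GasConditions, ParticleSpec
from .traces import (
    CPC_SAMPLE_FLOW_LPM,
    ConcentrationTrace,
    FlowTrace,
    RESERVOIR,
    SAMPLE,
)

__all__ = [
    "SubjectProfile",
    "FlowTruth",
    "MeasurementTruth",
    "SyntheticMeasurement",
    "SyntheticSession",
    "generate_calibration_run",
    "generate_flow_trace",
    "generate_session",
    "default_cohort",
]

#: Flow-sensor noise (L/s, SD) added to generated traces.
FLOW_NOISE_SD = 0.02
#: Valve timing jitter: each event time is off by uniform(+-this) seconds,
#: keeping the overall timing precision around 0.1 s.
VALVE_JITTER_S = 0.05
FLOW_HZ = 100.0

#: Default calibration-syringe mean flows (L/s), spanning the characterized
#: range of the simulated breathing maneuvers.
CALIBRATION_FLOWS_LPS = (0.14, 0.35, 0.80, 1.60, 3.00, 4.58)

#: Breath-hold settings characterized on subjects (s).
STUDY_HOLD_TIMES_S = (3.0, 5.0, 7.0, 10.0, 15.0, 20.0)
#: Nominal particle sizes characterized on subjects (nm).
STUDY_SIZES_NM = (22.0, 50.0, 75.0, 100.0)


@dataclass(frozen=True)
class SubjectProfile:
    """A virtual volunteer.

    ``airspace_radius`` sets the true recovery decay through the forward
    simulator; alternatively ``recovery_curves`` prescribes (R0, tau) per
    particle size directly, bypassing the simulator.
    ``repeat_variability_sd`` is the absolute SD on R between repeats of one
    condition (physiological inconsistency in executing the maneuver).
    """

    subject_id: str = "S1"
    vital_capacity: float = 4.5  # L
    dead_space: float = 0.3  # L
    airspace_radius: float = 300e-6  # m
    repeat_variability_sd: float = 0.005
    recovery_curves: dict[float, tuple[float, float]] | None = None  # size_nm -> (R0, tau)

    def __post_init__(self) -> None:
        if not (2.0 <= self.vital_capacity <= 8.0):
            raise ValueError(f"vital capacity must lie in [2, 8] L, got {self.vital_capacity}")
        if self.repeat_variability_sd < 0:
            raise ValueError("repeat variability must be >= 0")
        if self.airspace_radius <= 0:
            raise ValueError("airspace radius must be > 0")

    def geometry(self) -> LungGeometry:
        return default_geometry(
            airspace_radius=self.airspace_radius, dead_space=self.dead_space
        )

    def true_recovery(
        self,
        particle: ParticleSpec,
        residence_time: float,
        inhale_flow: float,
        exhale_flow: float,
        conditions: GasConditions | None = None,
    ) -> float:
        """True (noise-free) recovery at a realized residence time.

        Uses the prescribed per-size exponential when given, otherwise the
        forward simulator's kernels evaluated on this subject's geometry.
        """
        if self.recovery_curves is not None:
            key = particle.diameter_nm
            if key not in self.recovery_curves:
                raise KeyError(f"no prescribed recovery curve for {key} nm")
            r0, tau = self.recovery_curves[key]
            return r0 * math.exp(-residence_time / tau)
        from .lung_sim import _tree_penetration
        from .physics import diffusion_coefficient, sphere_remaining_fraction

        geom = self.geometry()
        D = float(diffusion_coefficient(particle, conditions or BODY_CONDITIONS))
        return (
            _tree_penetration(geom, D, inhale_flow)
            * sphere_remaining_fraction(D, residence_time, geom.distal_airspace_radius)
            * _tree_penetration(geom, D, exhale_flow)
        )


def default_cohort(n: int = 7, seed: int = 7) -> list[SubjectProfile]:
    """Seven healthy virtual volunteers.

    Airspace radii span 230-470 um (evenly spaced, with a seeded shuffle of
    vital capacities in 3.5-6 L), chosen so that the cohort's 100 nm
    recoveries normalized to 10 s residence time spread over roughly
    0.14-0.44 — the inter-subject range healthy adults show.
    """
    rng = np.random.default_rng(seed)
    radii = np.linspace(230e-6, 470e-6, n)
    vcs = rng.uniform(3.5, 6.0, size=n)
    return [
        SubjectProfile(
            subject_id=f"S{i + 1}",
            vital_capacity=float(vcs[i]),
            airspace_radius=float(radii[i]),
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# calibration runs
# ---------------------------------------------------------------------------

def generate_calibration_run(
    loss: InstrumentLossModel,
    sizes_nm: tuple[float, ...] = STUDY_SIZES_NM,
    flows_lps: tuple[float, ...] = CALIBRATION_FLOWS_LPS,
    noise_cv: float = 0.01,
    seed: int = 0,
    *,
    n_repeats: int = 3,
    dead_volume: float = 0.3,
) -> list[CalibrationRecord]:
    """Syringe maneuvers on a size x flow grid (200 ms hold, equal legs).

    Observed penetration = model prediction x (1 + N(0, noise_cv)).  The
    default grid (4 sizes x 6 flows x 3 repeats) yields 72 records.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[CalibrationRecord] = []
    for size in sizes_nm:
        particle = ParticleSpec.from_nm(size)
        for q in flows_lps:
            t_inst = passage_time_from_flows(q, q, dead_volume)
            truth = loss.penetration(particle, t_inst)
            for _ in range(n_repeats):
                obs = truth * (1.0 + noise_cv * rng.standard_normal())
                obs = min(max(obs, 1e-9), 1.1)
                records.append(
                    CalibrationRecord(
                        particle=particle,
                        mean_flow_inhale=q,
                        mean_flow_exhale=q,
                        t_instrument=t_inst,
                        observed_penetration=obs,
                        conditions=loss.conditions,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# flow traces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowTruth:
    """Generator bookkeeping for one flow trace (analytic, noise-free)."""

    t_I: float
    t_II: float
    t_III: float
    t_IV: float
    t_V: float
    realized_hold: float
    inhaled_volume: float
    exhaled_volume: float
    t_half_inhaled: float
    t_mid_sample: float
    residence_time: float
    mean_flow_inhale: float
    mean_flow_exhale: float


def _half_sine(duration: float, volume: float, dt: float) -> np.ndarray:
    """Half-sine flow segment of given duration integrating to ``volume``."""
    n = max(2, int(round(duration / dt)))
    t = (np.arange(n) + 0.5) * dt
    peak = math.pi * volume / (2.0 * duration)
    return peak * np.sin(math.pi * t / duration)


def generate_flow_trace(
    profile: SubjectProfile,
    breath: SimulatedBreath,
    seed: int = 0,
    *,
    noise_sd: float = FLOW_NOISE_SD,
    valve_jitter: float = VALVE_JITTER_S,
    pre_breathing_s: float = 8.0,
) -> tuple[FlowTrace, FlowTruth]:
    """A 100 Hz flow trace realizing the I-V maneuver.

    Half-sine segments: tidal pre-breathing, exhalation to RV, inhalation to
    TLC (commanded volume realized within 1%), breath hold (commanded
    duration +- valve jitter), and exhalation through the collector to
    waste.  Sensor noise (SD ``noise_sd`` L/s) is superimposed; valve-event
    timestamps are embedded with per-event uniform(+-``valve_jitter``)
    offsets.  Returns the trace together with the generator's analytic
    bookkeeping (the ground-truth residence time oracle).
    """
    if breath.inhaled_volume > profile.vital_capacity:
        raise ValueError(
            f"commanded inhaled volume {breath.inhaled_volume} L exceeds "
            f"vital capacity {profile.vital_capacity} L"
        )
    rng = np.random.default_rng(seed)
    dt = 1.0 / FLOW_HZ

    segments: list[np.ndarray] = []
    # tidal pre-breathing: full sine cycles, 0.5 L half-volumes, 4 s period
    n_tidal = max(1, int(round(pre_breathing_s / 4.0)))
    for _ in range(n_tidal):
        segments.append(_half_sine(2.0, 0.5, dt))
        segments.append(-_half_sine(2.0, 0.5, dt))
    t_I = sum(s.size for s in segments) * dt

    # exhale to RV
    erv = min(1.0, profile.vital_capacity - breath.inhaled_volume + 1.0)
    erv = max(erv, 0.3)
    segments.append(-_half_sine(erv / 0.7, erv, dt))
    t_II = sum(s.size for s in segments) * dt

    # inhale RV -> TLC
    T_in = breath.inhaled_volume / breath.inhale_flow
    segments.append(_half_sine(T_in, breath.inhaled_volume, dt))
    t_III = sum(s.size for s in segments) * dt

    # breath hold (realized duration jittered within valve precision)
    hold = breath.breath_hold + float(rng.uniform(-valve_jitter, valve_jitter))
    hold = max(hold, 0.0)
    segments.append(np.zeros(max(2, int(round(hold / dt)))))
    t_IV = sum(s.size for s in segments) * dt

    # sampled exhalation into collector, continuing to waste
    v_ex = max(0.8 * breath.inhaled_volume, breath.collector_volume * 1.5)
    v_ex = min(v_ex, breath.inhaled_volume)
    T_ex = v_ex / breath.exhale_flow
    segments.append(-_half_sine(T_ex, v_ex, dt))
    t_end_ex = sum(s.size for s in segments) * dt
    segments.append(np.zeros(int(round(2.0 / dt))))

    flow = np.concatenate(segments)
    # realized segment durations (rounded to the grid)
    T_in_real = t_III - t_II
    T_ex_real = t_end_ex - t_IV

    flow = flow + rng.normal(0.0, noise_sd, size=flow.size)
    times = np.arange(flow.size) * dt

    # volume-triggered collector closure (point V), analytic on the half-sine
    frac = 1.0 - 2.0 * breath.collector_volume / v_ex
    if not (-1.0 <= frac < 1.0):
        raise ValueError("exhaled volume does not cover the collector volume")
    t_V = t_IV + (T_ex_real / math.pi) * math.acos(frac)

    jitter = lambda: float(rng.uniform(-valve_jitter, valve_jitter))
    events = {
        "II": t_II + jitter(),
        "III": t_III + jitter(),
        "IV": t_IV + jitter(),
        "V": t_V + jitter(),
    }

    t_half = t_II + T_in_real / 2.0  # half-sine: half volume at half duration
    t_mid = t_IV + (T_ex_real / math.pi) * math.acos(1.0 - breath.collector_volume / v_ex)
    truth = FlowTruth(
        t_I=t_I,
        t_II=t_II,
        t_III=t_III,
        t_IV=t_IV,
        t_V=t_V,
        realized_hold=t_IV - t_III,
        inhaled_volume=breath.inhaled_volume,
        exhaled_volume=v_ex,
        t_half_inhaled=t_half,
        t_mid_sample=t_mid,
        residence_time=t_mid - t_half,
        mean_flow_inhale=breath.inhaled_volume / T_in_real,
        mean_flow_exhale=v_ex / T_ex_real,
    )
    return FlowTrace(times=times, flow=flow, valve_events=events), truth


# ---------------------------------------------------------------------------
# complete sessions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementTruth:
    R_true: float
    residence_time: float
    R_instrument_true: float
    t_instrument_true: float
    seed: int


@dataclass
class SyntheticMeasurement:
    measurement_id: str
    subject_id: str
    particle: ParticleSpec
    hold_s: float
    repeat: int
    flow_trace: FlowTrace
    concentration_trace: ConcentrationTrace


@dataclass
class SyntheticSession:
    subject: SubjectProfile
    measurements: list[SyntheticMeasurement]
    ground_truth: dict[str, MeasurementTruth] = field(default_factory=dict)


def _poisson_concentration(
    rng: np.random.Generator, mean_cm3: np.ndarray, counter_flow_lpm: float
) -> np.ndarray:
    """1 Hz CPC samples: counts ~ Poisson(C * q * 1 s), reported as counts/q."""
    q_cm3 = counter_flow_lpm * 1000.0 / 60.0  # cm^3 per 1 s sample
    return rng.poisson(np.maximum(mean_cm3, 0.0) * q_cm3).astype(float) / q_cm3


def generate_session(
    profile: SubjectProfile,
    conditions_grid: list[tuple[float, float]],
    loss: InstrumentLossModel,
    reservoir_concentration: float = 4000.0,
    seed: int = 0,
    *,
    n_repeats: int = 3,
    inhale_flow: float = 1.8,
    exhale_flow: float = 2.0,
    collector_volume: float = 1.2,
    reservoir_drift_per_s: float = 0.0,
    counting_noise: bool = True,
    gas_conditions: GasConditions | None = None,
) -> SyntheticSession:
    """One measurement session: traces plus separately stored ground truth.

    ``conditions_grid`` lists (size_nm, hold_s) pairs; each is measured
    ``n_repeats`` times.  The exhaled-sample concentration mean is
    C_reservoir x R_true x R_instrument_true, where R_true comes from the
    subject's forward model (or prescribed decay curves) evaluated at the
    realized residence time, times a mean-one lognormal repeat multiplier
    whose absolute SD on R is ``profile.repeat_variability_sd``.
    """
    if not (500.0 <= reservoir_concentration <= 20000.0):
        raise ValueError(
            f"reservoir concentration must lie in [500, 20000] cm^-3, "
            f"got {reservoir_concentration}"
        )
    master = np.random.default_rng(seed)
    session = SyntheticSession(subject=profile, measurements=[])
    inhaled_volume = min(profile.vital_capacity, 4.5)

    for size_nm, hold_s in conditions_grid:
        particle = ParticleSpec.from_nm(size_nm)
        for rep in range(n_repeats):
            m_seed = int(master.integers(0, 2**31 - 1))
            rng = np.random.default_rng(m_seed)
            breath = SimulatedBreath(
                particle=particle,
                inhale_flow=inhale_flow,
                exhale_flow=exhale_flow,
                breath_hold=hold_s,
                inhaled_volume=inhaled_volume,
                collector_volume=collector_volume,
            )
            flow_trace, truth = generate_flow_trace(
                profile, breath, seed=int(rng.integers(0, 2**31 - 1))
            )

            r_base = profile.true_recovery(
                particle,
                truth.residence_time,
                breath.inhale_flow,
                breath.exhale_flow,
                gas_conditions,
            )
            if profile.repeat_variability_sd > 0 and r_base > 0:
                sigma = profile.repeat_variability_sd / r_base
                sigma = min(sigma, 1.0)  # keep the multiplier physical
                ln_sigma = math.sqrt(math.log(1.0 + sigma**2))
                mult = float(rng.lognormal(-0.5 * ln_sigma**2, ln_sigma))
            else:
                mult = 1.0
            r_true = r_base * mult

            t_inst = passage_time_from_flows(
                truth.mean_flow_inhale, truth.mean_flow_exhale, profile.dead_space
            )
            r_inst = loss.penetration(particle, t_inst)

            # CPC timeline: reservoir until 2 s after collector closure,
            # then the exhaled sample for 14 s.
            t_switch = math.ceil(truth.t_V) + 2.0
            n_res = int(t_switch) + 1
            n_smp = 14
            times = np.arange(n_res + n_smp, dtype=float)
            res_mean = reservoir_concentration * (
                1.0 + reservoir_drift_per_s * times[:n_res]
            )
            smp_mean = np.full(n_smp, reservoir_concentration * r_true * r_inst)
            if counting_noise:
                conc = np.concatenate(
                    [
                        _poisson_concentration(rng, res_mean, CPC_SAMPLE_FLOW_LPM),
                        _poisson_concentration(rng, smp_mean, CPC_SAMPLE_FLOW_LPM),
                    ]
                )
            else:
                conc = np.concatenate([res_mean, smp_mean])
            source = np.array([RESERVOIR] * n_res + [SAMPLE] * n_smp, dtype=object)
            conc_trace = ConcentrationTrace(times=times, concentration=conc, source=source)

            mid = f"{profile.subject_id}_{size_nm:g}nm_{hold_s:g}s_r{rep + 1}"
            session.measurements.append(
                SyntheticMeasurement(
                    measurement_id=mid,
                    subject_id=profile.subject_id,
                    particle=particle,
                    hold_s=hold_s,
                    repeat=rep + 1,
                    flow_trace=flow_trace,
                    concentration_trace=conc_trace,
                )
            )
            session.ground_truth[mid] = MeasurementTruth(
                R_true=r_true,
                residence_time=truth.residence_time,
                R_instrument_true=r_inst,
                t_instrument_true=t_inst,
                seed=m_seed,
            )
    return session
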