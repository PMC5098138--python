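"""Session formats, the end-to-end analysis driver, and the command line.

A measurement session on disk is a directory holding, per single-breath
measurement, a flow-trace CSV (time_s, flow_Lps) and a particle-counter CSV
(time_s, concentration_cm3, source), each with a JSON sidecar carrying
units, sampling rate and (for flow) the valve-event timestamps; a
``manifest.json`` ties them to subject and condition metadata.  Synthetic
sessions additionally carry a ``ground_truth.json`` that the analysis path
never reads.

:func:`analyze_session` runs the full pipeline on a session — phase
detection, maneuver metrics, passage time, concentration windows, the
loss-corrected recovery equation, repeat aggregation, and per-size
recovery-versus-residence-time fits with normalization to a reference
residence time — and returns tidy tables (one row per measurement, one per
condition, one per fitted curve).

The ``aida`` command line wraps this: ``simulate``, ``calibrate``,
``analyze`` and ``report``.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import instrument_loss, maneuver, recovery, synthetic_data
from .instrument_loss import InstrumentLossModel
from .physics import ParticleSpec
from .traces import (
    ConcentrationTrace,
    FlowTrace,
    RESERVOIR,
    SAMPLE,
    TraceValidationError,
)

__all__ = [
    "RunConfig",
    "write_flow_trace",
    "read_flow_trace",
    "write_concentration_trace",
    "read_concentration_trace",
    "write_session",
    "read_session",
    "analyze_measurement",
    "analyze_session",
    "cli",
]

log = logging.getLogger("aida")

_FLOAT_FMT = "%.12g"


@dataclass(frozen=True)
class RunConfig:
    """Analysis settings: volumes, windows, QC thresholds, reference time."""

    collector_volume: float = 1.2  # L
    analyzed_volume: float = 0.3  # L
    dead_space: float = 0.3  # L (instrument + anatomical, for depth window)
    instrument_dead_volume: float = 0.3  # L (passage-time estimate)
    reservoir_window_s: float = recovery.RESERVOIR_WINDOW_S
    sample_window_s: float = recovery.SAMPLE_WINDOW_S
    reference_residence_time_s: float = 10.0
    stability_max_cv: float = 0.05
    stability_max_drift: float = 0.05

    def __post_init__(self) -> None:
        if min(self.collector_volume, self.analyzed_volume, self.instrument_dead_volume) <= 0:
            raise ValueError("volumes must be positive")
        if self.reservoir_window_s <= 0 or self.sample_window_s <= 0:
            raise ValueError("averaging windows must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# trace round-tripping
# ---------------------------------------------------------------------------

def write_flow_trace(trace: FlowTrace, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"time_s": trace.times, "flow_Lps": trace.flow}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )
    sidecar = {
        "kind": "flow",
        "sampling_rate_hz": trace.sampling_rate,
        "units": {"time_s": "s", "flow_Lps": "L/s"},
        "sign_convention": "positive = inhalation",
        "valve_events": trace.valve_events,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_flow_trace(path: str | Path) -> FlowTrace:
    path = Path(path)
    frame = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FlowTrace(
        times=frame["time_s"].to_numpy(),
        flow=frame["flow_Lps"].to_numpy(),
        valve_events=sidecar.get("valve_events"),
    )


def write_concentration_trace(trace: ConcentrationTrace, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {
            "time_s": trace.times,
            "concentration_cm3": trace.concentration,
            "source": trace.source,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "kind": "concentration",
        "sampling_rate_hz": 1.0 / trace.dt,
        "counter_flow_lpm": trace.counter_flow_lpm,
        "units": {"time_s": "s", "concentration_cm3": "cm^-3"},
        "source_tags": [RESERVOIR, SAMPLE],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_concentration_trace(path: str | Path) -> ConcentrationTrace:
    path = Path(path)
    frame = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return ConcentrationTrace(
        times=frame["time_s"].to_numpy(),
        concentration=frame["concentration_cm3"].to_numpy(),
        source=frame["source"].to_numpy(dtype=object),
        counter_flow_lpm=sidecar.get("counter_flow_lpm", 1.0),
    )


# ---------------------------------------------------------------------------
# sessions on disk
# ---------------------------------------------------------------------------

def write_session(session: synthetic_data.SyntheticSession, outdir: str | Path) -> Path:
    """Write traces, manifest and (separate) ground truth; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for m in session.measurements:
        flow_path = outdir / f"{m.measurement_id}_flow.csv"
        cpc_path = outdir / f"{m.measurement_id}_cpc.csv"
        write_flow_trace(m.flow_trace, flow_path)
        write_concentration_trace(m.concentration_trace, cpc_path)
        entries.append(
            {
                "measurement_id": m.measurement_id,
                "subject": m.subject_id,
                "size_nm": m.particle.diameter_nm,
                "hold_s": m.hold_s,
                "repeat": m.repeat,
                "flow_trace": flow_path.name,
                "concentration_trace": cpc_path.name,
            }
        )
    manifest = {
        "subject": {
            "subject_id": session.subject.subject_id,
            "vital_capacity_L": session.subject.vital_capacity,
            "dead_space_L": session.subject.dead_space,
        },
        "measurements": entries,
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    if session.ground_truth:
        truth = {
            k: {
                "R_true": v.R_true,
                "residence_time_s": v.residence_time,
                "R_instrument_true": v.R_instrument_true,
                "t_instrument_true": v.t_instrument_true,
                "seed": v.seed,
            }
            for k, v in session.ground_truth.items()
        }
        (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return manifest_path


def read_session(manifest_path: str | Path) -> synthetic_data.SyntheticSession:
    """Load a session from its manifest (ground truth is not loaded)."""
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    subj = manifest["subject"]
    profile = synthetic_data.SubjectProfile(
        subject_id=subj["subject_id"],
        vital_capacity=subj.get("vital_capacity_L", 4.5),
        dead_space=subj.get("dead_space_L", 0.3),
    )
    measurements = []
    for entry in manifest["measurements"]:
        flow_file = base / entry["flow_trace"]
        cpc_file = base / entry["concentration_trace"]
        for f in (flow_file, cpc_file):
            if not f.exists():
                raise FileNotFoundError(f"manifest references missing trace file: {f}")
        measurements.append(
            synthetic_data.SyntheticMeasurement(
                measurement_id=entry["measurement_id"],
                subject_id=entry["subject"],
                particle=ParticleSpec.from_nm(entry["size_nm"]),
                hold_s=entry["hold_s"],
                repeat=entry["repeat"],
                flow_trace=read_flow_trace(flow_file),
                concentration_trace=read_concentration_trace(cpc_file),
            )
        )
    return synthetic_data.SyntheticSession(subject=profile, measurements=measurements)


# ---------------------------------------------------------------------------
# analysis pipeline
# ---------------------------------------------------------------------------

def _source_window(
    trace: ConcentrationTrace, tag: str, length_s: float, anchor: str
) -> tuple[float, float]:
    """A window of the requested length at the start or end of a tagged span."""
    t0, t1 = trace.source_span(tag)
    if anchor == "end":
        return (max(t0, t1 - (length_s - trace.dt)), t1)
    return (t0, min(t1, t0 + (length_s - trace.dt)))


def analyze_measurement(
    flow_trace: FlowTrace,
    conc_trace: ConcentrationTrace,
    particle: ParticleSpec,
    loss: InstrumentLossModel,
    config: RunConfig = RunConfig(),
) -> dict:
    """Run one measurement through the full recovery pipeline.

    Returns a flat dict (one results-table row).  The reservoir mean is
    taken over the last ``reservoir_window_s`` of the reservoir-tagged span
    (i.e. up to the moment sampling switched to the collector); the sample
    mean over the first ``sample_window_s`` of the collector span.
    """
    phases = maneuver.detect_phases(flow_trace)
    metrics = maneuver.compute_metrics(
        flow_trace,
        phases,
        collector_volume=config.collector_volume,
        analyzed_volume=config.analyzed_volume,
        dead_space=config.dead_space,
    )
    t_inst = instrument_loss.passage_time(flow_trace, phases, config.instrument_dead_volume)

    res_window = _source_window(conc_trace, RESERVOIR, config.reservoir_window_s, "end")
    smp_window = _source_window(conc_trace, SAMPLE, config.sample_window_s, "start")
    c_res, sd_res = recovery.window_mean(conc_trace, res_window, source=RESERVOIR)
    c_smp, sd_smp = recovery.window_mean(conc_trace, smp_window, source=SAMPLE)
    stability = recovery.stability_qc(
        conc_trace, max_cv=config.stability_max_cv, max_drift=config.stability_max_drift
    )

    record = recovery.MeasurementRecord(
        C_reservoir=c_res,
        C_sample=c_smp,
        particle=particle,
        metrics=metrics,
        t_instrument=t_inst,
        sd_reservoir=sd_res,
        sd_sample=sd_smp,
        window_definitions={"reservoir": res_window, "sample": smp_window},
        qc_flags=() if stability.passed else ("unstable_reservoir",),
    )
    result = recovery.compute_recovery(record, loss)
    return {
        "size_nm": particle.diameter_nm,
        "hold_s": metrics.breath_hold_time,
        "t_res_s": metrics.residence_time,
        "V_i_L": metrics.V_i,
        "t_instrument_s": t_inst,
        "C_reservoir_cm3": c_res,
        "C_sample_cm3": c_smp,
        "R_raw": result.R_raw,
        "R_instrument": result.R_instrument_applied,
        "R": result.R,
        "sd_R": result.uncertainty,
        "reservoir_cv": stability.cv,
        "reservoir_drift": stability.drift,
        "qc": ";".join(result.qc_flags) if result.qc_flags else "pass",
    }


def analyze_session(
    session: synthetic_data.SyntheticSession,
    loss: InstrumentLossModel,
    config: RunConfig = RunConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Analyze every measurement of a session.

    Returns ``(results, summary, curves)``:

    * ``results`` — one row per measurement (rejected maneuvers appear with
      ``qc`` set to the rejection reason, never silently dropped);
    * ``summary`` — mean/SD/n per (subject, size, commanded hold);
    * ``curves`` — per (subject, size): fitted R0, tau and the recovery
      normalized to the reference residence time.
    """
    rows = []
    for m in session.measurements:
        base = {
            "measurement_id": m.measurement_id,
            "subject": m.subject_id,
            "commanded_hold_s": m.hold_s,
            "repeat": m.repeat,
        }
        try:
            row = analyze_measurement(
                m.flow_trace, m.concentration_trace, m.particle, loss, config
            )
        except (
            maneuver.ManeuverRejectionError,
            recovery.RecoveryError,
            TraceValidationError,
        ) as exc:
            log.warning("measurement %s rejected: %s", m.measurement_id, exc)
            row = {"size_nm": m.particle.diameter_nm, "qc": f"rejected: {exc}"}
        rows.append({**base, **row})
    results = pd.DataFrame(rows)

    ok = results[results["qc"].str.startswith(("pass", "low_confidence"))].copy()
    summaries = []
    for (subject, size, hold), group in ok.groupby(["subject", "size_nm", "commanded_hold_s"]):
        if len(group) >= 2:
            agg = recovery.aggregate_repeats(list(group["R"]))
            summaries.append(
                {
                    "subject": subject,
                    "size_nm": size,
                    "hold_s": hold,
                    "mean_R": agg.mean,
                    "sd_R": agg.sd,
                    "n": agg.n,
                    "t_res_mean_s": float(group["t_res_s"].mean()),
                    "sd_flagged": agg.flagged,
                }
            )
    summary = pd.DataFrame(summaries)

    curves = []
    for (subject, size), group in ok.groupby(["subject", "size_nm"]):
        pts = list(zip(group["t_res_s"], group["R"]))
        weights = np.where(group["sd_R"] > 0, 1.0 / np.maximum(group["sd_R"], 1e-12) ** 2, 1.0)
        try:
            curve = recovery.fit_recovery_curve(pts, weights=weights)
        except recovery.RecoveryError as exc:
            log.warning("curve fit skipped for %s / %g nm: %s", subject, size, exc)
            continue
        curves.append(
            {
                "subject": subject,
                "size_nm": size,
                "R0": curve.R0,
                "tau_s": curve.tau,
                "n_points": curve.n_points,
                "R_at_ref": recovery.normalize_to_time(
                    curve, config.reference_residence_time_s
                ),
                "t_ref_s": config.reference_residence_time_s,
            }
        )
    return results, summary, pd.DataFrame(curves)


# ---------------------------------------------------------------------------
# command line
# ---------------------------------------------------------------------------

@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log debug detail to stderr.")
def cli(verbose: bool) -> None:
    """Single-breath nanoparticle lung-deposition analysis."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


@cli.command()
@click.option("-o", "--outdir", type=click.Path(), required=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--subject-id", default="S1", show_default=True)
@click.option("--sizes", default="22,50,75,100", show_default=True,
              help="Particle sizes (nm), comma-separated.")
@click.option("--holds", default="3,5,7,10,15,20", show_default=True,
              help="Breath-hold times (s), comma-separated.")
@click.option("--repeats", type=int, default=3, show_default=True)
@click.option("--concentration", type=float, default=4000.0, show_default=True,
              help="Reservoir concentration (cm^-3).")
def simulate(outdir, seed, subject_id, sizes, holds, repeats, concentration) -> None:
    """Generate a complete synthetic measurement session on disk."""
    try:
        size_list = [float(s) for s in sizes.split(",")]
        hold_list = [float(h) for h in holds.split(",")]
    except ValueError as exc:
        raise click.ClickException(f"bad --sizes/--holds: {exc}") from exc
    profile = synthetic_data.SubjectProfile(subject_id=subject_id)
    grid = [(s, h) for s in size_list for h in hold_list]
    session = synthetic_data.generate_session(
        profile,
        grid,
        instrument_loss.REFERENCE_LOSS_MODEL,
        reservoir_concentration=concentration,
        seed=seed,
        n_repeats=repeats,
    )
    manifest = write_session(session, outdir)
    click.echo(f"wrote {len(session.measurements)} measurements to {manifest.parent}")


@cli.command()
@click.argument("records_csv", type=click.Path(exists=True))
@click.option("-o", "--out", type=click.Path(), required=True, help="Loss-model JSON path.")
@click.option("--space", type=click.Choice(["linear", "log"]), default="linear",
              show_default=True)
def calibrate(records_csv, out, space) -> None:
    """Fit the instrument loss model to a calibration-record CSV."""
    frame = pd.read_csv(records_csv)
    try:
        records = instrument_loss.records_from_frame(frame)
        model = instrument_loss.fit_loss_model(records, space=space)
    except instrument_loss.CalibrationError as exc:
        raise click.ClickException(f"calibration failed: {exc}") from exc
    Path(out).parent.mkdir(parents=True, exist_ok=True)
    model.to_json(out)
    s = model.calibration_summary or {}
    log.info(
        "fitted A=%.4f b=%.4g m^-2 (n=%d, rms=%.2g, r=%.6f)",
        model.A, model.b, s.get("n", 0), s.get("residual_rms", float("nan")),
        s.get("pearson_r", float("nan")),
    )
    click.echo(f"A={model.A:.6g} b={model.b:.6g} -> {out}")


@cli.command()
@click.argument("manifest", type=click.Path(exists=True))
@click.argument("loss_model", type=click.Path(exists=True))
@click.option("-o", "--outdir", type=click.Path(), required=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="RunConfig YAML.")
def analyze(manifest, loss_model, outdir, config_path) -> None:
    """Analyze a session: per-measurement, per-condition and curve tables."""
    config = RunConfig.from_yaml(config_path) if config_path else RunConfig()
    session = read_session(manifest)
    loss = InstrumentLossModel.from_json(loss_model)
    results, summary, curves = analyze_session(session, loss, config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    results.to_csv(out / "results.csv", index=False, float_format=_FLOAT_FMT)
    summary.to_csv(out / "summary.csv", index=False, float_format=_FLOAT_FMT)
    curves.to_csv(out / "curves.csv", index=False, float_format=_FLOAT_FMT)
    n_rej = int(results["qc"].str.startswith("rejected").sum())
    click.echo(
        f"analyzed {len(results)} measurements ({n_rej} rejected) -> {out}"
    )


@cli.command()
@click.argument("results_dir", type=click.Path(exists=True))
def report(results_dir) -> None:
    """Print the recovery report for an analyzed session."""
    out = Path(results_dir)
    curves_path = out / "curves.csv"
    summary_path = out / "summary.csv"
    if not curves_path.exists() or not summary_path.exists():
        raise click.ClickException(f"{out} does not contain curves.csv/summary.csv")
    curves = pd.read_csv(curves_path)
    summary = pd.read_csv(summary_path)
    click.echo("Recovery vs residence time (per subject and size):")
    for row in curves.itertuples():
        click.echo(
            f"  {row.subject}  {row.size_nm:g} nm: R0={row.R0:.4f} "
            f"tau={row.tau_s:.2f} s  R({row.t_ref_s:g} s)={row.R_at_ref:.4f}"
        )
    if len(summary):
        worst = summary["sd_R"].max()
        click.echo(f"Worst repeat SD: {worst:.4f} "
                   f"({'flagged' if worst > recovery.REPEAT_SD_FLAG else 'within range'})")


if __name__ == "__main__":  # pragma: no cover
    cli()
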