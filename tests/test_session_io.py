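"""On-disk formats, the end-to-end analysis driver and the command line."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from aida.instrument_loss import InstrumentLossModel, records_to_frame
from aida.session_io import (
    RunConfig,
    analyze_measurement,
    analyze_session,
    cli,
    read_concentration_trace,
    read_flow_trace,
    read_session,
    write_concentration_trace,
    write_flow_trace,
    write_session,
)
from aida.synthetic_data import generate_calibration_run
from aida.traces import ConcentrationTrace

IDENTITY_LOSS = InstrumentLossModel(A=1.0, b=1e-30)


class TestTraceRoundTrips:
    def test_flow_trace_lossless(self, tmp_path, flow_trace_with_truth):
        trace, _ = flow_trace_with_truth
        path = tmp_path / "flow.csv"
        write_flow_trace(trace, path)
        back = read_flow_trace(path)
        assert np.allclose(back.times, trace.times, rtol=1e-12, atol=0)
        assert np.allclose(back.flow, trace.flow, rtol=1e-11, atol=1e-14)
        assert back.valve_events.keys() == trace.valve_events.keys()
        for k in trace.valve_events:
            assert back.valve_events[k] == pytest.approx(trace.valve_events[k], rel=1e-12)

    def test_concentration_trace_lossless(self, tmp_path, small_session):
        trace = small_session.measurements[0].concentration_trace
        path = tmp_path / "cpc.csv"
        write_concentration_trace(trace, path)
        back = read_concentration_trace(path)
        assert np.allclose(back.concentration, trace.concentration, rtol=1e-12)
        assert list(back.source) == list(trace.source)
        assert back.counter_flow_lpm == trace.counter_flow_lpm

    def test_sidecar_units_present(self, tmp_path, flow_trace_with_truth):
        trace, _ = flow_trace_with_truth
        path = tmp_path / "flow.csv"
        write_flow_trace(trace, path)
        sidecar = json.loads((tmp_path / "flow.csv.json").read_text())
        assert sidecar["units"]["flow_Lps"] == "L/s"
        assert sidecar["sampling_rate_hz"] == pytest.approx(100.0)


class TestSessionRoundTrip:
    def test_write_read_preserves_measurements(self, tmp_path, small_session):
        manifest = write_session(small_session, tmp_path / "ses")
        loaded = read_session(manifest)
        assert len(loaded.measurements) == len(small_session.measurements)
        a = small_session.measurements[0]
        b = loaded.measurements[0]
        assert b.measurement_id == a.measurement_id
        assert b.particle.diameter_nm == pytest.approx(a.particle.diameter_nm)
        assert np.allclose(b.flow_trace.flow, a.flow_trace.flow, rtol=1e-11, atol=1e-14)

    def test_ground_truth_stored_separately_and_not_loaded(self, tmp_path, small_session):
        manifest = write_session(small_session, tmp_path / "ses")
        assert (tmp_path / "ses" / "ground_truth.json").exists()
        loaded = read_session(manifest)
        assert loaded.ground_truth == {}

    def test_missing_trace_is_a_hard_error_naming_the_file(self, tmp_path, small_session):
        manifest = write_session(small_session, tmp_path / "ses")
        victim = tmp_path / "ses" / small_session.measurements[0].measurement_id
        victim = victim.parent / f"{small_session.measurements[0].measurement_id}_cpc.csv"
        victim.unlink()
        with pytest.raises(FileNotFoundError, match=victim.name):
            read_session(manifest)


class TestAnalysis:
    def test_identity_loss_leaves_raw_ratio(self, small_session):
        m = small_session.measurements[0]
        row = analyze_measurement(
            m.flow_trace, m.concentration_trace, m.particle, IDENTITY_LOSS
        )
        assert row["R"] == pytest.approx(row["R_raw"], rel=1e-9)
        assert row["R_instrument"] == pytest.approx(1.0, rel=1e-9)

    def test_recovers_ground_truth(self, small_session, loss_model):
        for m in small_session.measurements:
            truth = small_session.ground_truth[m.measurement_id]
            row = analyze_measurement(
                m.flow_trace, m.concentration_trace, m.particle, loss_model
            )
            assert row["R"] == pytest.approx(truth.R_true, abs=0.02)
            assert row["t_res_s"] == pytest.approx(truth.residence_time, abs=0.05)
            assert row["qc"] == "pass"

    def test_session_tables_shapes(self, small_session, loss_model):
        results, summary, curves = analyze_session(small_session, loss_model)
        assert len(results) == len(small_session.measurements)
        # two conditions x three repeats -> two summary rows
        assert len(summary) == 2
        assert set(summary["n"]) == {3}
        # one curve per (subject, size); both sizes appear
        assert set(curves["size_nm"]) == {50.0, 100.0}
        assert (curves["tau_s"] > 0).all()

    def test_rejected_measurement_kept_in_results(self, small_session, loss_model):
        import dataclasses

        m0 = small_session.measurements[0]
        flat = ConcentrationTrace(
            times=m0.concentration_trace.times,
            concentration=m0.concentration_trace.concentration,
            source=np.full(m0.concentration_trace.times.shape, "reservoir", dtype=object),
        )
        broken = dataclasses.replace(m0, concentration_trace=flat)
        session = dataclasses.replace(
            small_session, measurements=[broken] + small_session.measurements[1:]
        )
        results, _, _ = analyze_session(session, loss_model)
        assert len(results) == len(small_session.measurements)
        assert results.iloc[0]["qc"].startswith("rejected")

    def test_deterministic_outputs(self, small_session, loss_model):
        a = analyze_session(small_session, loss_model)
        b = analyze_session(small_session, loss_model)
        for fa, fb in zip(a, b):
            pd.testing.assert_frame_equal(fa, fb)

    def test_runconfig_yaml(self, tmp_path):
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text("collector_volume: 1.0\nreference_residence_time_s: 12.0\n")
        cfg = RunConfig.from_yaml(cfg_path)
        assert cfg.collector_volume == 1.0
        assert cfg.reference_residence_time_s == 12.0
        assert cfg.analyzed_volume == 0.3  # defaults preserved

    def test_runconfig_validation(self):
        with pytest.raises(ValueError):
            RunConfig(collector_volume=-1.0)


class TestCli:
    def test_simulate_calibrate_analyze_report_chain(self, tmp_path, loss_model):
        runner = CliRunner()
        ses_dir = tmp_path / "session"
        r = runner.invoke(
            cli,
            ["simulate", "-o", str(ses_dir), "--seed", "5", "--sizes", "100",
             "--holds", "5,10", "--repeats", "2"],
        )
        assert r.exit_code == 0, r.output
        assert "4 measurements" in r.output
        assert (ses_dir / "manifest.json").exists()

        records_csv = tmp_path / "calibration.csv"
        records_to_frame(
            generate_calibration_run(loss_model, noise_cv=0.005, seed=1)
        ).to_csv(records_csv, index=False)
        model_json = tmp_path / "loss.json"
        r = runner.invoke(cli, ["calibrate", str(records_csv), "-o", str(model_json)])
        assert r.exit_code == 0, r.output
        fitted = InstrumentLossModel.from_json(model_json)
        assert fitted.b == pytest.approx(loss_model.b, rel=0.05)

        out_dir = tmp_path / "analysis"
        r = runner.invoke(
            cli,
            ["analyze", str(ses_dir / "manifest.json"), str(model_json),
             "-o", str(out_dir)],
        )
        assert r.exit_code == 0, r.output
        results = pd.read_csv(out_dir / "results.csv")
        assert len(results) == 4
        assert (results["qc"] == "pass").all()

        r = runner.invoke(cli, ["report", str(out_dir)])
        assert r.exit_code == 0, r.output
        assert "Recovery vs residence time" in r.output

    def test_simulate_reproducible_byte_identical(self, tmp_path):
        runner = CliRunner()
        args = ["--seed", "5", "--sizes", "100", "--holds", "10", "--repeats", "1"]
        for d in ("a", "b"):
            r = runner.invoke(cli, ["simulate", "-o", str(tmp_path / d)] + args)
            assert r.exit_code == 0, r.output
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_calibrate_rejects_degenerate_csv(self, tmp_path):
        bad = tmp_path / "bad.csv"
        pd.DataFrame(
            {
                "size_nm": [50.0, 50.0],
                "flow_in_Lps": [1.0, 1.0],
                "flow_ex_Lps": [1.0, 1.0],
                "t_instrument_s": [0.6, 0.6],
                "R_instrument": [0.9, 0.91],
            }
        ).to_csv(bad, index=False)
        r = CliRunner().invoke(cli, ["calibrate", str(bad), "-o", str(tmp_path / "m.json")])
        assert r.exit_code != 0
        assert "calibration failed" in r.output
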