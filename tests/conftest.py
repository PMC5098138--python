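import numpy as np
import pytest

from aida.instrument_loss import REFERENCE_LOSS_MODEL
from aida.lung_sim import SimulatedBreath
from aida.physics import ParticleSpec
from aida.synthetic_data import SubjectProfile, generate_flow_trace, generate_session


@pytest.fixture(scope="session")
def loss_model():
    return REFERENCE_LOSS_MODEL


@pytest.fixture(scope="session")
def subject():
    return SubjectProfile(subject_id="S1", airspace_radius=320e-6)


@pytest.fixture(scope="session")
def standard_breath():
    return SimulatedBreath(
        particle=ParticleSpec.from_nm(100),
        inhale_flow=1.8,
        exhale_flow=2.0,
        breath_hold=10.0,
        inhaled_volume=4.5,
    )


@pytest.fixture(scope="session")
def flow_trace_with_truth(subject, standard_breath):
    return generate_flow_trace(subject, standard_breath, seed=3)


@pytest.fixture(scope="session")
def small_session(subject, loss_model):
    """Two conditions x three repeats at the study's noise levels."""
    grid = [(100.0, 10.0), (50.0, 5.0)]
    return generate_session(subject, grid, loss_model, seed=11)


def make_clean_flow_trace(hold=10.0, q_in=1.5, q_ex=2.0, v_in=4.5, dt=0.01):
    """Noise-free piecewise trace with exactly known phase boundaries.

    Segments: 2 s rest, 2 s exhale to RV (1 L), inhale v_in at constant
    q_in, hold, exhale 3.6 L at constant q_ex, 2 s rest.  Constant-flow
    segments make every derived quantity closed-form.
    """
    t_in = v_in / q_in
    t_ex = 3.6 / q_ex
    segs = [
        np.zeros(int(2 / dt)),
        np.full(int(2 / dt), -0.5),
        np.full(int(round(t_in / dt)), q_in),
        np.zeros(int(round(hold / dt))),
        np.full(int(round(t_ex / dt)), -q_ex),
        np.zeros(int(2 / dt)),
    ]
    flow = np.concatenate(segs)
    times = np.arange(flow.size) * dt
    bounds = np.cumsum([0] + [s.size for s in segs]) * dt
    truth = {"I": bounds[1], "II": bounds[2], "III": bounds[3], "IV": bounds[4], "end_ex": bounds[5]}
    from aida.traces import FlowTrace

    return FlowTrace(times=times, flow=flow), truth
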