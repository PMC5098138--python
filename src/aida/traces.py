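"""Raw time-series containers: breath flow and particle-counter traces.

The (virtual) instrument produces two signals per measurement:

* a pneumotachograph flow trace, signed L/s sampled on a uniform 100 Hz grid
  (positive = inhalation), optionally annotated with valve-event timestamps
  from the computer-controlled four-way valve, and
* a condensation-particle-counter (CPC) concentration trace, cm^-3 at 1 Hz
  and 1 L/min sample flow, with each sample tagged by its source — the
  aerosol reservoir or the exhaled-sample collector.

Both are thin dataclasses over numpy arrays with validation; file
round-tripping (two-column CSV + JSON sidecar) lives in
:mod:`aida.session_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FlowTrace", "ConcentrationTrace", "TraceValidationError",
           "RESERVOIR", "SAMPLE", "CPC_SAMPLE_FLOW_LPM"]

#: Source tags for concentration samples.
RESERVOIR = "reservoir"
SAMPLE = "sample"

#: CPC sample flow (L/min); sets the counting statistics of each 1 s sample.
CPC_SAMPLE_FLOW_LPM = 1.0

FLOW_SAMPLING_HZ = 100.0
MAX_ABS_FLOW = 15.0  # L/s, physiological + sensor ceiling


class TraceValidationError(ValueError):
    """Raised when a trace violates its structural invariants."""


def _check_uniform_grid(times: np.ndarray, context: str) -> float:
    if times.ndim != 1 or times.size < 2:
        raise TraceValidationError(f"{context}: need a 1-D time grid with >= 2 samples")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise TraceValidationError(f"{context}: non-uniform sampling grid")
    return float(dt[0])


@dataclass
class FlowTrace:
    """Signed mouth flow in L/s on a uniform grid (positive = inhalation)."""

    times: np.ndarray  # s
    flow: np.ndarray  # L/s
    valve_events: dict[str, float] | None = None  # labels "I".."V" -> time (s)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)
        if self.times.shape != self.flow.shape:
            raise TraceValidationError("times and flow must have equal length")
        self._dt = _check_uniform_grid(self.times, "FlowTrace")
        if not np.all(np.isfinite(self.flow)):
            raise TraceValidationError("flow contains non-finite values")
        if np.max(np.abs(self.flow)) >= MAX_ABS_FLOW:
            raise TraceValidationError(
                f"|flow| must stay below {MAX_ABS_FLOW} L/s "
                f"(max seen {np.max(np.abs(self.flow)):.2f})"
            )

    @property
    def dt(self) -> float:
        return self._dt

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self._dt

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ConcentrationTrace:
    """Particle number concentration (cm^-3) with a per-sample source tag."""

    times: np.ndarray  # s
    concentration: np.ndarray  # cm^-3
    source: np.ndarray = field(default=None)  # type: ignore[assignment]
    counter_flow_lpm: float = CPC_SAMPLE_FLOW_LPM

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentration = np.asarray(self.concentration, dtype=float)
        if self.source is None:
            self.source = np.full(self.times.shape, RESERVOIR, dtype=object)
        else:
            self.source = np.asarray(self.source, dtype=object)
        if not (self.times.shape == self.concentration.shape == self.source.shape):
            raise TraceValidationError("times, concentration and source must align")
        self._dt = _check_uniform_grid(self.times, "ConcentrationTrace")
        if not np.all(np.isfinite(self.concentration)):
            raise TraceValidationError("concentration contains non-finite values")
        if np.any(self.concentration < 0):
            raise TraceValidationError("concentration must be >= 0")
        if self.counter_flow_lpm <= 0:
            raise TraceValidationError("counter flow must be > 0 L/min")

    @property
    def dt(self) -> float:
        return self._dt

    def source_span(self, tag: str) -> tuple[float, float]:
        """(first, last) sample time carrying the given source tag."""
        mask = self.source == tag
        if not np.any(mask):
            raise TraceValidationError(f"no samples tagged {tag!r}")
        t = self.times[mask]
        return float(t[0]), float(t[-1])

    def __len__(self) -> int:
        return self.times.size
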