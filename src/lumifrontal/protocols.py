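"""Stimulus protocols: intensity steps and bi-phasic intensity ramps.

A step protocol is a sequence of ON epochs (light at a fixed log intensity
for ``on_s`` seconds) each followed by darkness for ``off_s`` seconds, with
the whole block repeated ``n_reps`` times per intensity and intensities
presented in ascending order.  A ramp protocol repeats a bi-phasic
trajectory in which log intensity rises linearly over one phase and falls
symmetrically over the next.

Intensities are expressed throughout as log10 photons cm^-2 s^-1 (melanopsin
quantum catch serving as the intensity proxy).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Epoch",
    "StimulusProtocol",
    "InvalidProtocolError",
    "make_step_protocol",
    "make_ramp_protocol",
    "align_stimulus",
    "write_protocol",
    "read_protocol",
]

#: Mean latency (s) between the LED "turn on" command and light emission.
COMMAND_TO_LIGHT_DELAY_S = 0.116


class InvalidProtocolError(ValueError):
    """Raised when a stimulus protocol violates its construction rules."""


@dataclass(frozen=True)
class Epoch:
    """One light-ON epoch.

    ``onset_s``/``duration_s`` delimit the light pulse; ``log_intensity`` is
    its intensity, and ``rep`` its repetition index within that intensity.
    """

    onset_s: float
    duration_s: float
    log_intensity: float
    rep: int = 0

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class StimulusProtocol:
    """A full stimulation session.

    Parameters
    ----------
    epochs
        ON epochs in chronological order.
    kind
        ``"step"`` or ``"ramp"``.
    ramp
        For ramp protocols, a dict with keys ``start_log``, ``span_log``,
        ``phase_s`` describing the bi-phasic trajectory of every epoch.
    total_duration_s
        Nominal session wall time (stimulation block only; any dark lead-in
        before the first epoch is excluded).
    """

    epochs: list[Epoch]
    kind: str = "step"
    ramp: dict | None = None
    total_duration_s: float = 0.0
    delay_applied: bool = field(default=False)

    @property
    def intensities(self) -> np.ndarray:
        """Distinct step intensities, ascending."""
        return np.unique([e.log_intensity for e in self.epochs])

    def epochs_at(self, log_intensity: float, atol: float = 1e-9) -> list[Epoch]:
        return [e for e in self.epochs if abs(e.log_intensity - log_intensity) <= atol]

    def ramp_intensity(self, t_in_epoch: float | np.ndarray) -> np.ndarray:
        """Instantaneous log intensity ``t_in_epoch`` seconds into a ramp epoch.

        The trajectory is piecewise linear and symmetric about the phase
        transition: ascending over [0, phase_s], descending over
        [phase_s, 2*phase_s].
        """
        if self.ramp is None:
            raise InvalidProtocolError("not a ramp protocol")
        start = self.ramp["start_log"]
        span = self.ramp["span_log"]
        phase = self.ramp["phase_s"]
        t = np.asarray(t_in_epoch, dtype=float)
        up = start + span * t / phase
        down = start + span * (2 - t / phase)
        out = np.where(t <= phase, up, down)
        return np.clip(out, start, start + span)


def make_step_protocol(
    intensities,
    n_reps: int = 20,
    on_s: float = 10.0,
    off_s: float = 10.0,
    t0: float = 10.0,
) -> StimulusProtocol:
    """Build the 7-intensity step protocol (20 reps of 10 s ON / 10 s OFF).

    Intensities must be strictly ascending; they are presented in that order,
    each with ``n_reps`` ON/OFF cycles.  ``t0`` seconds of darkness precede
    the first pulse so that the pre-onset baseline window of the first rep
    falls inside the recording.
    """
    intensities = np.asarray(intensities, dtype=float)
    if intensities.ndim != 1 or len(intensities) < 1:
        raise InvalidProtocolError("need a 1-D, non-empty intensity vector")
    if len(intensities) > 1 and not np.all(np.diff(intensities) > 0):
        raise InvalidProtocolError("intensities must be strictly ascending")
    if n_reps < 1:
        raise InvalidProtocolError("n_reps must be >= 1")
    if on_s <= 0 or off_s <= 0:
        raise InvalidProtocolError("epoch durations must be positive")

    epochs = []
    t = float(t0)
    for e_log in intensities:
        for rep in range(n_reps):
            epochs.append(Epoch(onset_s=t, duration_s=on_s, log_intensity=float(e_log), rep=rep))
            t += on_s + off_s
    total = len(intensities) * n_reps * (on_s + off_s)
    return StimulusProtocol(epochs=epochs, kind="step", total_duration_s=total)


def make_ramp_protocol(
    start_log: float,
    span_log: float = 2.0,
    phase_s: float = 30.0,
    n_reps: int = 20,
    inter_rep_s: float = 10.0,
    t0: float = 10.0,
) -> StimulusProtocol:
    """Build the bi-phasic ramp protocol.

    Each epoch lasts ``2 * phase_s`` seconds: log intensity rises linearly
    from ``start_log`` to ``start_log + span_log`` over the ascending phase,
    then falls symmetrically back during the descending phase.
    """
    if span_log <= 0:
        raise InvalidProtocolError("span_log must be positive")
    if phase_s <= 0:
        raise InvalidProtocolError("phase_s must be positive")
    if n_reps < 1:
        raise InvalidProtocolError("n_reps must be >= 1")
    epochs = []
    t = float(t0)
    for rep in range(n_reps):
        epochs.append(
            Epoch(onset_s=t, duration_s=2 * phase_s, log_intensity=float(start_log + span_log), rep=rep)
        )
        t += 2 * phase_s + inter_rep_s
    ramp = {"start_log": float(start_log), "span_log": float(span_log), "phase_s": float(phase_s)}
    total = n_reps * (2 * phase_s + inter_rep_s)
    return StimulusProtocol(epochs=epochs, kind="ramp", ramp=ramp, total_duration_s=total)


def align_stimulus(protocol: StimulusProtocol, delay_s: float = COMMAND_TO_LIGHT_DELAY_S) -> StimulusProtocol:
    """Shift all epoch onsets later by the command-to-light delay.

    The hardware emits light ``delay_s`` after the command timestamped in the
    protocol; analysis must align to actual light onset.  Guarded so the
    correction cannot be applied twice.
    """
    if delay_s < 0:
        raise ValueError("delay_s must be non-negative")
    if protocol.delay_applied:
        raise RuntimeError("stimulus delay correction already applied to this protocol")
    shifted = [
        Epoch(e.onset_s + delay_s, e.duration_s, e.log_intensity, e.rep) for e in protocol.epochs
    ]
    return StimulusProtocol(
        epochs=shifted,
        kind=protocol.kind,
        ramp=None if protocol.ramp is None else dict(protocol.ramp),
        total_duration_s=protocol.total_duration_s,
        delay_applied=delay_s > 0,
    )


def write_protocol(protocol: StimulusProtocol, path) -> None:
    """Serialize a protocol to JSON."""
    payload = {
        "kind": protocol.kind,
        "ramp": protocol.ramp,
        "total_duration_s": protocol.total_duration_s,
        "delay_applied": protocol.delay_applied,
        "epochs": [
            {
                "onset_s": e.onset_s,
                "duration_s": e.duration_s,
                "log_intensity": e.log_intensity,
                "rep": e.rep,
            }
            for e in protocol.epochs
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_protocol(path) -> StimulusProtocol:
    with open(path) as fh:
        payload = json.load(fh)
    epochs = [
        Epoch(d["onset_s"], d["duration_s"], d["log_intensity"], d.get("rep", 0))
        for d in payload["epochs"]
    ]
    return StimulusProtocol(
        epochs=epochs,
        kind=payload.get("kind", "step"),
        ramp=payload.get("ramp"),
        total_duration_s=payload.get("total_duration_s", 0.0),
        delay_applied=payload.get("delay_applied", False),
    )
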