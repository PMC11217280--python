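"""Spike-train containers, spike-table IO, PSTH construction and analysis windows.

The analysis window around each light pulse spans [-4, +16] s relative to
light onset: 4 s of pre-onset darkness, the 10 s stimulus, and 6 s of
post-offset darkness.  Within it, three time-average firing rates are used
throughout: the baseline FR0 over the 3 s preceding onset, the early-window
FR1 over the first second of the stimulus, and the steady-state FR2 over the
last 6 s of the stimulus.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocols import StimulusProtocol

__all__ = [
    "SpikeTrain",
    "PSTH",
    "WindowRates",
    "read_spike_table",
    "write_spike_table",
    "build_psth",
    "build_ramp_rates",
    "baseline_normalize",
    "window_rates",
    "qc_filter",
    "PRE_S",
    "POST_S",
    "BASELINE_WINDOW",
    "EARLY_WINDOW",
    "STEADY_WINDOW",
]

logger = logging.getLogger(__name__)

PRE_S = 4.0      # seconds of darkness before light onset included in the PSTH
POST_S = 6.0     # seconds after light offset included in the PSTH
BASELINE_WINDOW = (-3.0, 0.0)   # FR0
EARLY_WINDOW = (0.0, 1.0)       # FR1
STEADY_WINDOW = (4.0, 10.0)     # FR2 (last 6 s of a 10 s stimulus)


@dataclass
class SpikeTrain:
    """Spike times (s) of one unit, ascending and non-negative."""

    unit_id: str
    spike_times: np.ndarray
    session_id: str = "s0"

    def __post_init__(self):
        t = np.asarray(self.spike_times, dtype=float)
        if t.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if t.size and (not np.all(np.isfinite(t)) or t.min() < 0):
            raise ValueError("spike times must be finite and non-negative")
        if t.size and np.any(np.diff(t) < 0):
            warnings.warn(f"unit {self.unit_id}: spike times unsorted; sorting", stacklevel=2)
            t = np.sort(t)
        self.spike_times = t

    def __len__(self) -> int:
        return len(self.spike_times)

    def mean_rate(self, duration_s: float | None = None) -> float:
        """Session-wide mean firing rate (spikes/s)."""
        if duration_s is None:
            duration_s = self.spike_times[-1] if len(self) else 0.0
        if duration_s <= 0:
            return 0.0
        return len(self) / duration_s


@dataclass
class PSTH:
    """Peri-stimulus time histogram for one unit at one intensity.

    ``rates`` is reps x bins in spikes/s; bins are half-open [t, t+bin_s)
    with edges aligned to light onset, covering ``window`` = (-4, +16) s.
    """

    rates: np.ndarray
    bin_s: float
    log_intensity: float
    unit_id: str = ""
    window: tuple[float, float] = (-PRE_S, 10.0 + POST_S)
    baseline_subtracted: bool = False
    excluded_reps: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.rates = np.atleast_2d(np.asarray(self.rates, dtype=float))
        span = self.window[1] - self.window[0]
        n_bins = span / self.bin_s
        if abs(n_bins - round(n_bins)) > 1e-9 or self.rates.shape[1] != round(n_bins):
            raise ValueError("bin width must tile the analysis window exactly")

    @property
    def n_reps(self) -> int:
        return self.rates.shape[0]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        return self.window[0] + (np.arange(self.n_bins) + 0.5) * self.bin_s

    @property
    def bin_edges(self) -> np.ndarray:
        return self.window[0] + np.arange(self.n_bins + 1) * self.bin_s

    def mean(self) -> np.ndarray:
        """Across-rep mean rate per bin."""
        return self.rates.mean(axis=0)

    def _bins_in(self, lo: float, hi: float) -> slice:
        i0 = int(round((lo - self.window[0]) / self.bin_s))
        i1 = int(round((hi - self.window[0]) / self.bin_s))
        return slice(i0, i1)

    def window_mean(self, lo: float, hi: float) -> np.ndarray:
        """Per-rep time-average rate over [lo, hi) s relative to onset."""
        return self.rates[:, self._bins_in(lo, hi)].mean(axis=1)


@dataclass
class WindowRates:
    """Per-rep baseline/early/steady-state rates for one unit+intensity."""

    fr0: np.ndarray
    fr1: np.ndarray
    fr2: np.ndarray
    log_intensity: float
    unit_id: str = ""


# ---------------------------------------------------------------------------
# spike table IO

SPIKE_COLUMNS = ["session_id", "unit_id", "spike_time_s"]


def write_spike_table(trains: list[SpikeTrain], path) -> None:
    """Write spike trains as a CSV with one row per spike."""
    frames = [
        pd.DataFrame(
            {"session_id": t.session_id, "unit_id": t.unit_id, "spike_time_s": t.spike_times}
        )
        for t in trains
    ]
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=SPIKE_COLUMNS)
    df.to_csv(path, index=False)


def read_spike_table(path) -> list[SpikeTrain]:
    """Read a spike-table CSV into SpikeTrains (sorted; unsorted input warns).

    Malformed rows raise a parse error carrying the 1-based data line number.
    """
    df = pd.read_csv(path, dtype={"session_id": str, "unit_id": str})
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"spike table missing columns: {missing}")
    times = pd.to_numeric(df["spike_time_s"], errors="coerce")
    bad = np.flatnonzero(times.isna().to_numpy() | (times.to_numpy() < 0))
    if len(bad):
        raise ValueError(f"malformed spike time at line {bad[0] + 2}")
    trains = []
    for (session, unit), sub in df.groupby(["session_id", "unit_id"], sort=True):
        trains.append(SpikeTrain(unit_id=unit, session_id=session,
                                 spike_times=sub["spike_time_s"].to_numpy(float)))
    return trains


# ---------------------------------------------------------------------------
# PSTH construction


def build_psth(
    train: SpikeTrain,
    protocol: StimulusProtocol,
    bin_s: float = 0.1,
    recording_start_s: float = 0.0,
) -> dict[float, PSTH]:
    """Bin spikes around every ON epoch into one PSTH per intensity.

    Bins are half-open [t, t+bin_s) aligned to light onset.  Reps whose
    pre-onset window extends before the recording start are excluded and
    recorded in ``excluded_reps``.  Total spike count over retained windows
    is conserved exactly (rate = count / bin_s).
    """
    out: dict[float, PSTH] = {}
    spikes = train.spike_times
    for e_log in protocol.intensities:
        epochs = protocol.epochs_at(e_log)
        window = (-PRE_S, epochs[0].duration_s + POST_S)
        n_bins = int(round((window[1] - window[0]) / bin_s))
        rows, excluded = [], []
        for ep in epochs:
            if ep.onset_s + window[0] < recording_start_s:
                excluded.append(ep.rep)
                continue
            edges = ep.onset_s + window[0] + np.arange(n_bins + 1) * bin_s
            counts, _ = np.histogram(spikes, bins=edges)
            # np.histogram closes the last bin; drop spikes landing exactly
            # on the final edge to keep every bin half-open
            if counts[-1]:
                counts[-1] -= np.count_nonzero(spikes == edges[-1])
            rows.append(counts / bin_s)
        rates = np.array(rows) if rows else np.zeros((0, n_bins))
        out[float(e_log)] = PSTH(
            rates=rates,
            bin_s=bin_s,
            log_intensity=float(e_log),
            unit_id=train.unit_id,
            window=window,
            excluded_reps=excluded,
        )
    return out


def build_ramp_rates(
    train: SpikeTrain,
    protocol: StimulusProtocol,
    bin_s: float = 1.0,
) -> np.ndarray:
    """Rep x bin firing rates over each full ramp epoch (onset-aligned)."""
    if protocol.ramp is None:
        raise ValueError("protocol is not a ramp protocol")
    dur = 2 * protocol.ramp["phase_s"]
    n_bins = int(round(dur / bin_s))
    rows = []
    for ep in protocol.epochs:
        edges = ep.onset_s + np.arange(n_bins + 1) * bin_s
        counts, _ = np.histogram(train.spike_times, bins=edges)
        rows.append(counts / bin_s)
    return np.asarray(rows, dtype=float)


def baseline_normalize(psth: PSTH) -> PSTH:
    """Subtract each rep's 3 s pre-onset mean rate from all its bins."""
    if psth.window[0] > BASELINE_WINDOW[0]:
        raise ValueError("PSTH window must include at least 3 s pre-onset")
    base = psth.window_mean(*BASELINE_WINDOW)
    return PSTH(
        rates=psth.rates - base[:, None],
        bin_s=psth.bin_s,
        log_intensity=psth.log_intensity,
        unit_id=psth.unit_id,
        window=psth.window,
        baseline_subtracted=True,
        excluded_reps=list(psth.excluded_reps),
    )


def window_rates(psth: PSTH) -> WindowRates:
    """Per-rep FR0 / FR1 / FR2 for one unit and intensity."""
    return WindowRates(
        fr0=psth.window_mean(*BASELINE_WINDOW),
        fr1=psth.window_mean(*EARLY_WINDOW),
        fr2=psth.window_mean(*STEADY_WINDOW),
        log_intensity=psth.log_intensity,
        unit_id=psth.unit_id,
    )


def qc_filter(
    trains: list[SpikeTrain],
    min_rate_hz: float = 0.5,
    duration_s: float | None = None,
) -> list[SpikeTrain]:
    """Drop units whose session-wide mean rate is not higher than 0.5 Hz.

    The inequality is strict ("higher than"): a unit at exactly the
    threshold is removed.  Removals are logged.
    """
    kept = []
    for t in trains:
        rate = t.mean_rate(duration_s)
        if rate > min_rate_hz:
            kept.append(t)
        else:
            logger.info("qc_filter: removed unit %s (%.3f Hz <= %.2f Hz)", t.unit_id, rate, min_rate_hz)
    return kept
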