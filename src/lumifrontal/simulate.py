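"""Synthetic spike trains, waveform metrics and miniature atlas fixtures.

The generator emulates the statistical structure of light-evoked firing in
prefrontal/thalamic units: an inhomogeneous Poisson process whose rate is

    r(t) = max(0, baseline + onPeak(t; E) + offPeak(t; E) + sustained(t; E))

with four response archetypes.  The sustained component's asymptotic
amplitude at log intensity E follows the Naka-Rushton saturating sigmoid
with parameters (Rmax, n, K), signed +1 for 'enhanced' and -1 for
'suppressed' archetypes, and rises toward that asymptote with a first-order
time constant tau.  ON/OFF transients are gamma-shaped bumps whose mode sits
at the peak latency and whose width sets their SD; transient amplitude
scales with a second, more sensitive sigmoid (rod/cone-driven transients
saturate at lower intensities than the melanopsin-driven sustained
component).

Spikes are drawn exactly by thinning against a rate upper bound; every
output is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .encoding import naka_rushton
from .mapping import LabelVolume
from .protocols import StimulusProtocol, make_step_protocol
from .recordings import SpikeTrain

__all__ = [
    "ResponseArchetype",
    "SimulationConfig",
    "DEFAULT_ARCHETYPES",
    "ARCHETYPE_NAMES",
    "rate_function",
    "archetype_template_psth",
    "simulate_unit",
    "simulate_population",
    "simulate_null_responses",
    "simulate_waveform_metrics",
    "make_label_volume",
    "sample_track_points",
]

ARCHETYPE_NAMES = ("E_on_off", "S_on_off", "E_on", "S_on")


@dataclass(frozen=True)
class ResponseArchetype:
    """Rate-model parameters of one functional response archetype.

    Rates in spikes/s, times in seconds, K in log photons cm^-2 s^-1.
    """

    name: str
    baseline_rate: float
    on_peak_amp: float
    on_peak_latency: float = 0.09
    on_peak_width: float = 0.05
    off_peak_amp: float = 0.0
    sustained_Rmax: float = 0.0
    sustained_n: float = 1.0
    sustained_K: float = 13.5
    sustained_sign: int = 1
    sustained_tau: float = 0.5
    # transient amplitude sigmoid (rod/cone-like: more sensitive, shallow)
    transient_n: float = 1.0
    transient_K: float = 12.5
    # gain (spikes/s) of the unit's idiosyncratic response-shape component;
    # suppressed archetypes get smaller gains (firing-floor headroom)
    fingerprint_gain: float = 9.0

    def __post_init__(self):
        if self.baseline_rate < 0 or self.sustained_Rmax < 0:
            raise ValueError("rates must be non-negative")
        if self.sustained_n <= 0:
            raise ValueError("sustained_n must be positive")
        if self.sustained_sign not in (-1, 1):
            raise ValueError("sustained_sign must be +1 or -1")
        if self.name == "NULL" and (
            self.on_peak_amp or self.off_peak_amp or self.sustained_Rmax
            or self.fingerprint_gain
        ):
            raise ValueError("NULL archetype must have zero response amplitudes")

    def sustained_amplitude(self, log_intensity) -> np.ndarray:
        """Signed asymptotic sustained amplitude at a given intensity."""
        return self.sustained_sign * naka_rushton(
            log_intensity, self.sustained_Rmax, self.sustained_n, self.sustained_K
        )

    def transient_gain(self, log_intensity) -> np.ndarray:
        """Unit-max sigmoid scaling the ON/OFF transient amplitude."""
        e = np.asarray(log_intensity, dtype=float)
        return 1.0 / (1.0 + 10.0 ** (self.transient_n * (self.transient_K - e)))


# Defaults: baselines 2 Hz (RS-like) for enhanced and 6-8 Hz (FS-like) for
# suppressed archetypes (suppression needs headroom above the zero floor);
# ON-peak latency 90 ms; sustained K in 13.0-14.0, n in 1.0-2.0, Rmax 3-8 Hz;
# tau 0.5 s for ON-OFF archetypes, 2 s for the slower ON archetypes.
DEFAULT_ARCHETYPES: dict[str, ResponseArchetype] = {
    "E_on_off": ResponseArchetype(
        name="E_on_off", baseline_rate=2.0, on_peak_amp=45.0, off_peak_amp=30.0,
        sustained_Rmax=6.0, sustained_n=1.5, sustained_K=13.2,
        sustained_sign=1, sustained_tau=0.5, fingerprint_gain=9.0,
    ),
    "S_on_off": ResponseArchetype(
        name="S_on_off", baseline_rate=8.0, on_peak_amp=35.0, off_peak_amp=25.0,
        sustained_Rmax=5.0, sustained_n=1.5, sustained_K=13.4,
        sustained_sign=-1, sustained_tau=0.5, fingerprint_gain=2.5,
    ),
    "E_on": ResponseArchetype(
        name="E_on", baseline_rate=2.0, on_peak_amp=6.0, off_peak_amp=0.0,
        sustained_Rmax=8.0, sustained_n=1.2, sustained_K=13.6,
        sustained_sign=1, sustained_tau=2.0, fingerprint_gain=9.0,
    ),
    "S_on": ResponseArchetype(
        name="S_on", baseline_rate=8.0, on_peak_amp=5.0, off_peak_amp=0.0,
        sustained_Rmax=4.0, sustained_n=1.0, sustained_K=13.8,
        sustained_sign=-1, sustained_tau=2.0, fingerprint_gain=3.5,
    ),
    "NULL": ResponseArchetype(name="NULL", baseline_rate=3.0, on_peak_amp=0.0,
                              fingerprint_gain=0.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Population-simulation settings (defaults mirror the step-protocol study)."""

    n_units_per_archetype: int = 60
    archetypes: tuple[str, ...] = ARCHETYPE_NAMES
    intensities: tuple[float, ...] = (9.4, 10.4, 11.4, 12.4, 13.4, 14.4, 15.4)
    n_reps: int = 20
    on_s: float = 10.0
    off_s: float = 10.0
    seed: int = 0
    jitter: bool = True
    n_sessions: int = 1

    def __post_init__(self):
        if not np.all(np.diff(self.intensities) > 0):
            raise ValueError("intensities must be strictly increasing")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


# ---------------------------------------------------------------------------
# rate model


def _transient_kernel(dt: np.ndarray, latency: float, width: float) -> np.ndarray:
    """Gamma-shaped transient, unit peak at ``latency``, SD ``width``, 0 for dt<=0."""
    theta = 0.5 * (-latency + np.sqrt(latency**2 + 4 * width**2))
    k = latency / theta + 1.0
    dt = np.asarray(dt, dtype=float)
    out = np.zeros_like(dt)
    pos = dt > 0
    d = dt[pos]
    out[pos] = (d / latency) ** (k - 1) * np.exp((latency - d) / theta)
    return out


_FINGERPRINT_GRID_DT = 0.1
_FINGERPRINT_T_MAX = 16.0  # stimulus (10 s) + post window (6 s)
_CHOL_CACHE: dict[tuple, np.ndarray] = {}


def sample_fingerprint(
    rng: np.random.Generator,
    sd: float = 0.3,
    length_s: float = 0.8,
    clip: float = 0.75,
) -> np.ndarray:
    """Per-unit idiosyncratic response-shape component (dimensionless).

    A zero-mean Gaussian process (RBF kernel) sampled on a 0.1 s grid over
    [0, 16] s after light onset; it is added to the rate scaled by the
    unit's own sustained response magnitude, is tapered to zero over the
    last second of the window, and carries exactly zero mean over the
    steady-state window [4, 10) s — so it perturbs the response time course
    without moving any steady-state rate.  No two real neurons share an
    identical response kernel; this scatter is what spreads population
    variance over many principal components.
    """
    key = (sd, length_s)
    if key not in _CHOL_CACHE:
        grid = np.arange(0.0, _FINGERPRINT_T_MAX + _FINGERPRINT_GRID_DT, _FINGERPRINT_GRID_DT)
        cov = sd**2 * np.exp(-((grid[:, None] - grid[None, :]) ** 2) / (2 * length_s**2))
        cov += 1e-10 * np.eye(len(grid))
        _CHOL_CACHE[key] = np.linalg.cholesky(cov)
    L = _CHOL_CACHE[key]
    f = L @ rng.standard_normal(L.shape[0])
    grid = np.arange(L.shape[0]) * _FINGERPRINT_GRID_DT
    taper = np.clip((_FINGERPRINT_T_MAX - grid) / 1.0, 0.0, 1.0) * np.clip(grid / 0.5, 0.0, 1.0)
    f = f * taper
    steady = (grid >= 4.0) & (grid < 10.0)
    f[steady] -= f[steady].mean()
    return np.clip(f, -clip, clip)


def _fingerprint_at(fingerprint: np.ndarray | None, dt: np.ndarray) -> np.ndarray:
    if fingerprint is None:
        return np.zeros_like(dt)
    grid = np.arange(len(fingerprint)) * _FINGERPRINT_GRID_DT
    return np.interp(np.clip(dt, 0.0, grid[-1]), grid, fingerprint)


def _step_rate(arch: ResponseArchetype, protocol: StimulusProtocol, t: np.ndarray,
               fingerprint: np.ndarray | None = None) -> np.ndarray:
    """Rate r(t) under a step protocol, vectorized over times."""
    t = np.asarray(t, dtype=float)
    onsets = np.array([e.onset_s for e in protocol.epochs])
    durs = np.array([e.duration_s for e in protocol.epochs])
    elogs = np.array([e.log_intensity for e in protocol.epochs])

    r = np.full_like(t, arch.baseline_rate)
    idx = np.searchsorted(onsets, t, side="right") - 1
    valid = idx >= 0
    if not np.any(valid):
        return np.maximum(r, 0.0)
    iv = idx[valid]
    dt_on = t[valid] - onsets[iv]
    dur = durs[iv]
    gain = arch.transient_gain(elogs[iv])
    amp = arch.sustained_amplitude(elogs[iv])
    tau = arch.sustained_tau

    contrib = np.zeros_like(dt_on)
    if arch.on_peak_amp:
        contrib += arch.on_peak_amp * gain * _transient_kernel(
            dt_on, arch.on_peak_latency, arch.on_peak_width
        )
    during = dt_on < dur
    envelope = np.where(
        during,
        -np.expm1(-dt_on / tau),
        -np.expm1(-dur / tau) * np.exp(-np.maximum(dt_on - dur, 0.0) / tau),
    )
    contrib += amp * envelope
    if fingerprint is not None and arch.fingerprint_gain:
        # fingerprint rides the same rise/decay envelope as the sustained
        # component, so it cannot drive the rate below zero while the
        # response is still building up
        contrib += arch.fingerprint_gain * gain * envelope * _fingerprint_at(fingerprint, dt_on)
    if arch.off_peak_amp:
        contrib += arch.off_peak_amp * gain * _transient_kernel(
            dt_on - dur, arch.on_peak_latency, arch.on_peak_width
        )
    r[valid] += contrib
    return np.maximum(r, 0.0)


def _ramp_rate(arch: ResponseArchetype, protocol: StimulusProtocol, t: np.ndarray,
               grid_dt: float = 0.05) -> np.ndarray:
    """Rate r(t) under a ramp protocol.

    The sustained drive is the Naka-Rushton value of the instantaneous log
    intensity passed through a first-order low-pass with time constant tau
    (exact exponential-integrator stepping on a fine grid); responses to
    gradients carry no ON/OFF transients.
    """
    t = np.asarray(t, dtype=float)
    r = np.full_like(t, arch.baseline_rate)
    dur = 2 * protocol.ramp["phase_s"]
    tau = arch.sustained_tau
    n_grid = int(round(dur / grid_dt))
    tg = np.arange(n_grid + 1) * grid_dt
    drive = arch.sustained_amplitude(protocol.ramp_intensity(tg))
    y = np.empty_like(drive)
    y[0] = 0.0
    decay = np.exp(-grid_dt / tau)
    for i in range(n_grid):
        y[i + 1] = drive[i] + (y[i] - drive[i]) * decay
    for ep in protocol.epochs:
        rel = t - ep.onset_s
        inside = (rel >= 0) & (rel <= dur)
        r[inside] += np.interp(rel[inside], tg, y)
        after = rel > dur
        r[after] += y[-1] * np.exp(-(rel[after] - dur) / tau)
    return np.maximum(r, 0.0)


def rate_function(arch: ResponseArchetype, protocol: StimulusProtocol, t,
                  fingerprint: np.ndarray | None = None) -> np.ndarray:
    """Instantaneous firing rate (spikes/s) of an archetype under a protocol."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if protocol.kind == "ramp":
        return _ramp_rate(arch, protocol, t)
    return _step_rate(arch, protocol, t, fingerprint=fingerprint)


def archetype_template_psth(
    arch: ResponseArchetype,
    log_intensity: float,
    bin_s: float = 0.2,
    on_s: float = 10.0,
) -> np.ndarray:
    """Noiseless baseline-subtracted mean PSTH of an archetype at one intensity.

    Used as the canonical template when naming GMM clusters.  Covers the
    standard [-4, +16] s window; values are bin-centre rates minus baseline.
    """
    proto = make_step_protocol([log_intensity], n_reps=1, on_s=on_s, off_s=10.0, t0=10.0)
    onset = proto.epochs[0].onset_s
    n_bins = int(round((on_s + 10.0) / bin_s))
    centers = onset - 4.0 + (np.arange(n_bins) + 0.5) * bin_s
    return rate_function(arch, proto, centers) - arch.baseline_rate


# ---------------------------------------------------------------------------
# spike generation


def simulate_unit(
    arch: ResponseArchetype,
    protocol: StimulusProtocol,
    seed: int | np.random.Generator = 0,
    unit_id: str = "u0",
    session_id: str = "s0",
    fingerprint: np.ndarray | None = None,
) -> SpikeTrain:
    """Draw one unit's spike train by thinning an inhomogeneous Poisson process.

    Thinning is exact: candidate spikes arrive at a constant upper-bound
    rate and are retained with probability r(t) / bound.  With a
    ``fingerprint`` (see :func:`sample_fingerprint`), the unit's sustained
    time course carries its idiosyncratic smooth modulation.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_end = max(e.offset_s for e in protocol.epochs) + 16.0
    bound = (
        arch.baseline_rate + arch.on_peak_amp + arch.off_peak_amp
        + arch.sustained_Rmax + 0.75 * arch.fingerprint_gain + 1.0
    )
    n_cand = rng.poisson(bound * t_end)
    cand = np.sort(rng.uniform(0.0, t_end, size=n_cand))
    u = rng.uniform(0.0, 1.0, size=n_cand)
    keep = u < rate_function(arch, protocol, cand, fingerprint=fingerprint) / bound
    return SpikeTrain(unit_id=unit_id, session_id=session_id, spike_times=cand[keep])


def _jittered(arch: ResponseArchetype, rng: np.random.Generator) -> ResponseArchetype:
    """Per-unit parameter heterogeneity within an archetype.

    Gaussian scatter (clipped to keep parameters valid): within-type
    variability in real populations is unimodal around the type's centre.
    """
    g = rng.standard_normal(8)
    return replace(
        arch,
        baseline_rate=arch.baseline_rate * max(1.0 + 0.10 * g[0], 0.3),
        sustained_Rmax=arch.sustained_Rmax * max(1.0 + 0.07 * g[1], 0.3),
        sustained_n=arch.sustained_n * max(1.0 + 0.05 * g[2], 0.3),
        sustained_K=arch.sustained_K + 0.12 * g[3],
        on_peak_amp=arch.on_peak_amp * max(1.0 + 0.07 * g[4], 0.0),
        off_peak_amp=arch.off_peak_amp * max(1.0 + 0.07 * g[5], 0.0),
        sustained_tau=arch.sustained_tau * max(1.0 + 0.20 * g[6], 0.25),
        on_peak_latency=arch.on_peak_latency * max(1.0 + 0.10 * g[7], 0.5),
    )


def simulate_population(
    config: SimulationConfig,
) -> tuple[list[SpikeTrain], StimulusProtocol, pd.DataFrame]:
    """Simulate a labelled population under the 7-intensity step protocol.

    Returns (spike trains, protocol, ground-truth table).  The ground truth
    records each unit's archetype and its true (baseline, Rmax, n, K, sign,
    tau) for recovery tests.  Deterministic per seed.
    """
    protocol = make_step_protocol(
        list(config.intensities), n_reps=config.n_reps, on_s=config.on_s, off_s=config.off_s
    )
    master = np.random.default_rng(config.seed)
    trains, rows = [], []
    counter = 0
    for name in config.archetypes:
        base_arch = DEFAULT_ARCHETYPES[name]
        for _ in range(config.n_units_per_archetype):
            unit_rng = np.random.default_rng(master.integers(2**31))
            if config.jitter:
                arch = _jittered(base_arch, unit_rng)
                fingerprint = sample_fingerprint(unit_rng)
            else:
                arch, fingerprint = base_arch, None
            unit_id = f"u{counter:04d}"
            session_id = f"s{counter % config.n_sessions:02d}"
            trains.append(
                simulate_unit(arch, protocol, seed=unit_rng, unit_id=unit_id,
                              session_id=session_id, fingerprint=fingerprint)
            )
            rows.append(
                {
                    "unit_id": unit_id,
                    "session_id": session_id,
                    "archetype": name,
                    "baseline_rate": arch.baseline_rate,
                    "Rmax": arch.sustained_Rmax,
                    "n": arch.sustained_n,
                    "K": arch.sustained_K,
                    "sign": arch.sustained_sign,
                    "tau": arch.sustained_tau,
                }
            )
            counter += 1
    columns = ["unit_id", "session_id", "archetype", "baseline_rate", "Rmax",
               "n", "K", "sign", "tau"]
    return trains, protocol, pd.DataFrame(rows, columns=columns)


def simulate_null_responses(
    n_units: int,
    n_intensities: int = 7,
    seed: int = 0,
    mean_rate: float = 3.0,
) -> np.ndarray:
    """Intensity-independent per-intensity mean steady-state rates.

    Each unit's 7 per-intensity mean FR2 values are drawn i.i.d. from a
    common Gamma distribution (shape 4), i.e. there is no intensity
    dependence whatsoever; used to calibrate the encoding classifier's
    false-positive rate.
    """
    rng = np.random.default_rng(seed)
    shape = 4.0
    return rng.gamma(shape, mean_rate / shape, size=(n_units, n_intensities))


# ---------------------------------------------------------------------------
# waveform metrics

_WAVEFORM_PARAMS = {
    # metric order: spontaneous_fr, trough_to_peak_s, trough_to_peak_ratio,
    #               trough_half_duration_s
    "RS": {"mean": (2.5, 6.8e-4, 1.9, 3.0e-4), "sd": (1.2, 0.8e-4, 0.30, 0.45e-4)},
    "FS": {"mean": (11.0, 2.9e-4, 1.25, 1.5e-4), "sd": (3.5, 0.45e-4, 0.22, 0.28e-4)},
}


def simulate_waveform_metrics(cls: str, n: int, seed: int = 0) -> pd.DataFrame:
    """Draw waveform metrics for n units of one putative class (RS or FS).

    FS units have narrow trough-to-peak durations and high spontaneous
    rates; RS units broad waveforms and low rates.  Durations and rates are
    clipped at small positive floors.
    """
    if cls not in _WAVEFORM_PARAMS:
        raise ValueError("class must be 'RS' or 'FS'")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    p = _WAVEFORM_PARAMS[cls]
    vals = rng.standard_normal((n, 4)) * np.array(p["sd"]) + np.array(p["mean"])
    vals[:, 0] = np.clip(vals[:, 0], 0.05, None)
    vals[:, 1] = np.clip(vals[:, 1], 5e-5, None)
    vals[:, 2] = np.clip(vals[:, 2], 0.1, None)
    vals[:, 3] = np.clip(vals[:, 3], 3e-5, None)
    return pd.DataFrame(
        vals,
        columns=["spontaneous_fr", "trough_to_peak_s", "trough_to_peak_ratio",
                 "trough_half_duration_s"],
    ).assign(label=cls)


# ---------------------------------------------------------------------------
# miniature atlas fixtures


def make_label_volume(
    regions: dict[str, tuple],
    extent_um: tuple[float, float, float],
    voxel_um: float = 10.0,
) -> LabelVolume:
    """Build an integer-labelled volume from named axis-aligned boxes.

    ``regions`` maps name -> (lo, hi) corner pairs in um on (AP, DV, ML).
    Boxes must not overlap.  A synthetic stand-in for a reference atlas
    volume, suitable for testing affiliation arithmetic.
    """
    names = list(regions)
    boxes = {k: (np.asarray(v[0], float), np.asarray(v[1], float)) for k, v in regions.items()}
    for k, (lo, hi) in boxes.items():
        if np.any(hi <= lo):
            raise ValueError(f"region {k}: hi corner must exceed lo corner")
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            lo_a, hi_a = boxes[a]
            lo_b, hi_b = boxes[b]
            if np.all(np.minimum(hi_a, hi_b) > np.maximum(lo_a, lo_b)):
                raise ValueError(f"regions {a} and {b} overlap")
    shape = tuple(int(round(e / voxel_um)) for e in extent_um)
    data = np.zeros(shape, dtype=np.int16)
    labels = {}
    for lab, name in enumerate(names, start=1):
        lo, hi = boxes[name]
        i0 = np.clip(np.floor(lo / voxel_um).astype(int), 0, shape)
        i1 = np.clip(np.ceil(hi / voxel_um).astype(int), 0, shape)
        data[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]] = lab
        labels[name] = lab
    return LabelVolume(data=data, voxel_um=voxel_um, labels=labels)


def sample_track_points(
    point_um,
    direction,
    length_um: float,
    n_points: int = 35,
    jitter_um: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Annotation points along a ground-truth probe line with isotropic jitter."""
    rng = np.random.default_rng(seed)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    s = np.linspace(0.0, length_um, n_points)
    pts = np.asarray(point_um, dtype=float) + s[:, None] * d
    if jitter_um > 0:
        pts = pts + rng.standard_normal(pts.shape) * jitter_um
    return pts
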