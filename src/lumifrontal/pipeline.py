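"""End-to-end orchestration: simulate -> PSTH -> responsiveness -> encoding ->
typing -> cell class -> dynamics -> mapping -> report.

``run_pipeline`` executes the full analysis on a synthetic population (or on
spike tables read from disk), writing per-unit results, summary tables and a
machine-readable manifest under one run directory.  Every stochastic stage
draws its seed deterministically from the run seed, so a rerun with the same
config reproduces every result table byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cellclass, dynamics, functypes, mapping
from .encoding import IntensityResponseModel
from .recordings import build_psth, qc_filter, window_rates
from .responsiveness import classify_responsiveness
from .simulate import (
    DEFAULT_ARCHETYPES,
    SimulationConfig,
    archetype_template_psth,
    make_label_volume,
    sample_track_points,
    simulate_population,
    simulate_waveform_metrics,
)

__all__ = ["RunConfig", "run_pipeline", "round_half_away", "format_percent"]

logger = logging.getLogger(__name__)


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention used in printed tables)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def format_percent(count: int, total: int, decimals: int = 0) -> float:
    """Percentage of ``count``/``total`` at printed precision."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_away(100.0 * count / total, decimals)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (round-trips losslessly via JSON)."""

    n_units_per_archetype: int = 10
    n_null_units: int = 10
    n_reps: int = 20
    intensities: tuple[float, ...] = (9.4, 10.4, 11.4, 12.4, 13.4, 14.4, 15.4)
    bin_s: float = 0.1
    n_perm: int = 2000
    n_shuffles: int = 100
    alpha: float = 0.05
    seed: int = 0
    n_sessions: int = 4
    outdir: str = "run_out"
    spikes_csv: str | None = None
    protocol_json: str | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["intensities"] = tuple(d["intensities"])
        return cls(**d)


def _simulate_inputs(config: RunConfig):
    archetypes = list(DEFAULT_ARCHETYPES)
    archetypes = [a for a in archetypes if a != "NULL"]
    sim = SimulationConfig(
        n_units_per_archetype=config.n_units_per_archetype,
        archetypes=tuple(archetypes),
        intensities=config.intensities,
        n_reps=config.n_reps,
        seed=config.seed,
        n_sessions=config.n_sessions,
    )
    trains, protocol, truth = simulate_population(sim)
    if config.n_null_units:
        null_cfg = SimulationConfig(
            n_units_per_archetype=config.n_null_units,
            archetypes=("NULL",),
            intensities=config.intensities,
            n_reps=config.n_reps,
            seed=config.seed + 1,
            n_sessions=config.n_sessions,
        )
        null_trains, _, null_truth = simulate_population(null_cfg)
        offset = len(trains)
        for i, t in enumerate(null_trains):
            t.unit_id = f"u{offset + i:04d}"
        null_truth["unit_id"] = [f"u{offset + i:04d}" for i in range(len(null_truth))]
        trains += null_trains
        truth = pd.concat([truth, null_truth], ignore_index=True)
    return trains, protocol, truth


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the report bundle (also written to disk).

    Stage failures abort with the stage name; outputs written so far are
    preserved in the run directory.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    t_start = time.time()
    timings: dict[str, float] = {}
    stage = "simulate"
    try:
        if config.spikes_csv is not None:
            from .protocols import read_protocol
            from .recordings import read_spike_table

            trains = read_spike_table(config.spikes_csv)
            protocol = read_protocol(config.protocol_json)
            truth = pd.DataFrame({"unit_id": [t.unit_id for t in trains],
                                  "session_id": [t.session_id for t in trains],
                                  "archetype": "unknown"})
        else:
            trains, protocol, truth = _simulate_inputs(config)
        timings[stage] = time.time() - t_start

        stage = "qc"
        t0 = time.time()
        duration = max(e.offset_s for e in protocol.epochs) + 16.0
        trains = qc_filter(trains, min_rate_hz=0.5, duration_s=duration)
        kept_ids = {t.unit_id for t in trains}
        truth = truth[truth["unit_id"].isin(kept_ids)].reset_index(drop=True)
        timings[stage] = time.time() - t0

        if not trains:
            report = {"units": pd.DataFrame(), "summary": {"n_units": 0}}
            _write_report(report, truth, out, config, timings)
            return report

        stage = "psth"
        t0 = time.time()
        psths = {t.unit_id: build_psth(t, protocol, bin_s=config.bin_s) for t in trains}
        wrates = {
            uid: {e: window_rates(p) for e, p in by_int.items()} for uid, by_int in psths.items()
        }
        timings[stage] = time.time() - t0

        stage = "responsiveness"
        t0 = time.time()
        resp_rows = []
        for i, t in enumerate(trains):
            r = classify_responsiveness(
                wrates[t.unit_id], n_perm=config.n_perm, alpha=config.alpha,
                seed=config.seed + 10_000 + i, unit_id=t.unit_id,
            )
            resp_rows.append(dataclasses.asdict(r))
        resp = pd.DataFrame(resp_rows)
        timings[stage] = time.time() - t0

        stage = "encoding"
        t0 = time.time()
        enc_rows = []
        persistent = set(resp.loc[resp["persistent_flag"], "unit_id"])
        for i, t in enumerate(trains):
            row = {"unit_id": t.unit_id, "encoding_flag": False, "Rmax": np.nan,
                   "n": np.nan, "K": np.nan, "direction": 0, "rmse": np.nan,
                   "p5": np.nan, "threshold_E": np.nan}
            if t.unit_id in persistent:
                model = IntensityResponseModel.from_window_rates(wrates[t.unit_id])
                res = model.fit()
                test = res.encoding_test(n_shuffles=config.n_shuffles,
                                         seed=config.seed + 20_000 + i)
                row.update(
                    encoding_flag=test.encoding_flag, rmse=res.rmse, p5=test.percentile5,
                    direction=res.direction, **res.params,
                )
                if res.converged and res.sigmoid.Rmax > 0.1:
                    row["threshold_E"] = res.threshold_intensity(0.1)
            enc_rows.append(row)
        enc = pd.DataFrame(enc_rows)
        timings[stage] = time.time() - t0

        stage = "typing"
        t0 = time.time()
        e_top = max(config.intensities)
        feats = {}
        for t in trains:
            p = psths[t.unit_id][e_top]
            from .recordings import baseline_normalize

            bn = baseline_normalize(p)
            factor = int(round(0.2 / config.bin_s))
            m = bn.mean()
            feats[t.unit_id] = m.reshape(-1, factor).mean(axis=1) if factor > 1 else m
        enc_units = enc.loc[enc["encoding_flag"], "unit_id"].tolist()
        type_labels = pd.Series("unclassified", index=[t.unit_id for t in trains], name="type")
        if len(enc_units) >= 16:
            X = np.array([feats[u] for u in enc_units])
            tmodel = functypes.build_type_model(X, seed=config.seed + 30_000)
            templates = {
                name: _rebinned_template(name, e_top)
                for name in ("E_on_off", "S_on_off", "E_on", "S_on")
            }
            names = functypes.label_types(tmodel, X, templates)
            clusters = functypes.assign_to_model(tmodel, X)
            for u, c in zip(enc_units, clusters):
                type_labels[u] = names[int(c)]
        timings[stage] = time.time() - t0

        stage = "cellclass"
        t0 = time.time()
        metrics = _unit_waveform_metrics(truth, config.seed + 40_000)
        if len(metrics) >= 4:
            ei = cellclass.classify_ei(metrics)
        else:
            ei = pd.Series("RS", index=metrics.index, name="ei_label")
        timings[stage] = time.time() - t0

        stage = "dynamics"
        t0 = time.time()
        dyn_rows = []
        for t in trains:
            p = psths[t.unit_id][e_top]
            mean_trace = p.mean()
            d = enc.set_index("unit_id").loc[t.unit_id, "direction"]
            d = int(d) if d in (-1, 1) else 1
            lat = dynamics.latency_late(mean_trace, config.bin_s, direction=d)
            decay, censored = dynamics.decay_time(mean_trace, config.bin_s)
            wr = wrates[t.unit_id][e_top]
            fr0 = float(np.mean(wr.fr0))
            dyn_rows.append({
                "unit_id": t.unit_id,
                "latency_late_s": lat,
                "decay_s": decay,
                "decay_censored": censored,
                "m_early_pct": dynamics.relative_change(fr0, float(np.mean(wr.fr1))),
                "m_late_pct": dynamics.relative_change(fr0, float(np.mean(wr.fr2))),
            })
        dyn = pd.DataFrame(dyn_rows)
        timings[stage] = time.time() - t0

        stage = "mapping"
        t0 = time.time()
        volume = make_label_volume(
            {"regionA": ((0, 0, 0), (1000, 2000, 1000)),
             "regionB": ((1000, 0, 0), (2000, 2000, 1000))},
            extent_um=(2000, 2000, 1000), voxel_um=10.0,
        )
        pts = sample_track_points((500, 100, 500), (0.5, 1.0, 0.0), 1500.0,
                                  jitter_um=15.0, seed=config.seed + 50_000)
        track = mapping.fit_track_line(pts)
        offsets = np.arange(32) * 50.0
        unit_channels = np.arange(len(trains)) % 32
        coords, _ = mapping.locate_units(track, offsets, unit_channels)
        affiliations = {}
        for i, t in enumerate(trains):
            affiliations[t.unit_id] = mapping.affiliation_probability(
                coords[i], volume, n_points=10_000, seed=config.seed + 60_000 + i,
                unit_id=t.unit_id,
            )
        timings[stage] = time.time() - t0

        stage = "report"
        t0 = time.time()
        units = (
            truth.merge(resp, on="unit_id")
            .merge(enc, on="unit_id")
            .merge(dyn, on="unit_id")
        )
        units["type"] = units["unit_id"].map(type_labels)
        units["ei_label"] = units["unit_id"].map(ei)
        units["region"] = units["unit_id"].map(
            lambda u: affiliations[u].best()[0] if u in affiliations else "outside"
        )

        n = len(units)
        n_resp = int((units["transient_flag"] | units["persistent_flag"]).sum())
        summary = {
            "n_units": n,
            "n_responsive": n_resp,
            "pct_responsive": format_percent(n_resp, n),
            "n_transient": int(units["transient_flag"].sum()),
            "n_persistent": int(units["persistent_flag"].sum()),
            "n_encoding": int(units["encoding_flag"].sum()),
            "pct_encoding": format_percent(int(units["encoding_flag"].sum()), n),
            "type_counts": units.loc[units["encoding_flag"], "type"]
            .value_counts().to_dict(),
            "type_counts_by_region": {
                r: sub.loc[sub["encoding_flag"], "type"].value_counts().to_dict()
                for r, sub in units.groupby("region")
            },
        }
        incidence = mapping.incidence_per_session(units, "persistent_flag")
        report = {"units": units, "summary": summary, "incidence": incidence,
                  "timings": timings}
        timings[stage] = time.time() - t0
        _write_report(report, truth, out, config, timings)
        return report
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc


def _rebinned_template(name: str, e_top: float) -> np.ndarray:
    return archetype_template_psth(DEFAULT_ARCHETYPES[name], e_top, bin_s=0.2)


def _unit_waveform_metrics(truth: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Per-unit waveform metrics: suppressed (high-baseline) archetypes get
    FS-like waveforms, the rest RS-like; labels kept out of the metrics."""
    rows = []
    rng = np.random.default_rng(seed)
    for _, r in truth.iterrows():
        cls = "FS" if str(r.get("archetype", "")).startswith("S_") else "RS"
        m = simulate_waveform_metrics(cls, 1, seed=int(rng.integers(2**31)))
        m = m.drop(columns=["label"]).assign(unit_id=r["unit_id"])
        rows.append(m)
    if not rows:
        return pd.DataFrame(columns=cellclass.METRIC_COLUMNS + ["unit_id"])
    return pd.concat(rows, ignore_index=True).set_index("unit_id")


def _write_report(report: dict, truth: pd.DataFrame, out: Path, config: RunConfig,
                  timings: dict) -> None:
    units = report.get("units")
    if isinstance(units, pd.DataFrame) and not units.empty:
        units.to_csv(out / "units.csv", index=False)
    else:
        (out / "units.csv").write_text("")
    truth.to_csv(out / "ground_truth.csv", index=False)
    inc = report.get("incidence")
    if isinstance(inc, pd.DataFrame):
        inc.to_csv(out / "incidence_per_session.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(report.get("summary", {}), fh, indent=1, default=str)
    manifest = {
        "config": dataclasses.asdict(config),
        "seeds": {"root": config.seed},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
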