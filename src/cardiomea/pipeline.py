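"""End-to-end orchestration: simulate → filter → QC → beats → map → fit.

A run is described by a single :class:`RunConfig` (JSON on disk), consumes
either a recording file or a simulation preset, and writes its outputs plus
a manifest (config hash, seed, versions, per-stage status) into one run
directory.  All randomness flows from the root seed, split per stage.
"""

from __future__ import annotations

import hashlib
import json
import traceback
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .core import StimulusProtocol, ValidationError
from . import io as cio
from .simulate import PRESETS, PhotoResponseParams, make_fixture, \
    simulate_camp_and_rate, generate_beat_times
from .filtering import FilterSpec, bandpass_filter, channel_metrics, apply_qc
from .beats import (beat_table, cycle_summary, extract_kinetics, fold_series,
                    fold_series_from_recording)
from .mapping import map_recording
from .doseresponse import fit_dose_response


class FilterBlock(BaseModel):
    low_hz: float = 150.0
    high_hz: float = 2500.0
    order: int = 2
    ripple_db: float = 1.0
    zero_phase: bool = True


class QCBlock(BaseModel):
    snr_threshold: float = 2.0
    threshold_k: float = 5.0
    refractory_ms: float = 80.0


class DetectionBlock(BaseModel):
    threshold_k: float = 5.0
    refractory_ms: float = 80.0
    segment_len_s: float = 6.0


class MappingBlock(BaseModel):
    method: str = "extremum"
    grid_step_um: float = 25.0
    speed_cap_mm_s: float = 200.0
    max_beats: int = 10


class FittingBlock(BaseModel):
    fix_hill: bool = True
    n_bootstrap: int = 200


class SimulationBlock(BaseModel):
    sample_rate_hz: float | None = None
    duration_s: float | None = None
    noise_rms_uV: float = 7.0
    jitter_ms: float = 1.0


class RunConfig(BaseModel):
    """Validated configuration for one pipeline run."""

    input_recording: str | None = None
    protocol_path: str | None = None
    preset: str | None = None
    seed: int = 0
    out_dir: str = "run"
    filter: FilterBlock = Field(default_factory=FilterBlock)
    qc: QCBlock = Field(default_factory=QCBlock)
    detection: DetectionBlock = Field(default_factory=DetectionBlock)
    mapping: MappingBlock = Field(default_factory=MappingBlock)
    fitting: FittingBlock = Field(default_factory=FittingBlock)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)

    @model_validator(mode="after")
    def _one_input(self):
        if (self.input_recording is None) == (self.preset is None):
            raise ValueError("exactly one of input_recording or preset "
                             "must be set")
        if self.preset is not None and self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; "
                             f"available: {', '.join(PRESETS)}")
        return self

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        config.model_dump_json().encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis chain described by ``config``.

    Deterministic for a fixed seed; on a stage failure the outputs of
    completed stages are left in place and the manifest records the error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(("simulate", "qc", "beats", "map"),
                                      seeds)}
    manifest = {"config": json.loads(config.model_dump_json()),
                "config_hash": _config_hash(config),
                "seed": config.seed, "stage_seeds": stage_seeds,
                "version": __version__, "stages": {}}

    def _finish():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return out

    def _fail(stage, exc):
        manifest["stages"][stage] = {
            "status": "failed", "error": f"{type(exc).__name__}: {exc}",
            "traceback": traceback.format_exc(limit=5)}

    # ---- input --------------------------------------------------------
    try:
        if config.preset is not None:
            bundle = make_fixture(
                config.preset, seed=stage_seeds["simulate"],
                sample_rate_hz=config.simulation.sample_rate_hz,
                duration_s=config.simulation.duration_s,
                noise_rms_uV=config.simulation.noise_rms_uV,
                jitter_ms=config.simulation.jitter_ms)
            rec, protocol = bundle.recording, bundle.protocol
            truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                     for k, v in bundle.truth.items()}
            (out / "truth.json").write_text(json.dumps(truth, indent=1))
        else:
            rec = cio.read_recording(config.input_recording)
            protocol = (cio.load_protocol(config.protocol_path)
                        if config.protocol_path
                        else StimulusProtocol(((0.0, rec.duration_s, 0.0),)))
        manifest["stages"]["input"] = {"status": "ok",
                                       "n_channels": rec.n_channels,
                                       "duration_s": rec.duration_s}
    except Exception as exc:   # noqa: BLE001 - recorded in manifest
        _fail("input", exc)
        return _finish()

    # ---- filter -------------------------------------------------------
    try:
        spec = FilterSpec(**config.filter.model_dump())
        spec = spec.for_sample_rate(rec.sample_rate_hz)
        filtered = bandpass_filter(rec, spec)
        manifest["stages"]["filter"] = {
            "status": "ok", "low_hz": spec.low_hz, "high_hz": spec.high_hz}
    except Exception as exc:   # noqa: BLE001
        _fail("filter", exc)
        return _finish()

    # ---- QC -----------------------------------------------------------
    try:
        report = channel_metrics(filtered,
                                 threshold_k=config.qc.threshold_k,
                                 refractory_ms=config.qc.refractory_ms,
                                 snr_threshold=config.qc.snr_threshold)
        report.to_frame().to_csv(out / "qc_report.csv", index=False)
        clean = apply_qc(filtered, report)
        manifest["stages"]["qc"] = {"status": "ok",
                                    "n_included": report.n_included,
                                    "n_excluded": report.n_excluded}
    except Exception as exc:   # noqa: BLE001
        _fail("qc", exc)
        return _finish()

    # ---- beats --------------------------------------------------------
    try:
        series = fold_series_from_recording(
            clean, segment_len_s=config.detection.segment_len_s,
            threshold_k=config.detection.threshold_k,
            refractory_ms=config.detection.refractory_ms)
        series.to_frame().to_csv(out / "fold_series.csv", index=False)
        beat_table(clean,
                   threshold_k=config.detection.threshold_k,
                   refractory_ms=config.detection.refractory_ms
                   ).to_csv(out / "beat_table.csv", index=False)
        manifest["stages"]["beats"] = {"status": "ok",
                                       "bps0": series.bps0,
                                       "n_segments": len(series.bps)}
    except Exception as exc:   # noqa: BLE001
        _fail("beats", exc)
        return _finish()

    # ---- kinetics (only when the protocol has a light edge) -----------
    light_epochs = [(a, b, i) for a, b, i in protocol.epochs if i > 0]
    if light_epochs:
        try:
            a, b, _ = light_epochs[0]
            kin = extract_kinetics(series.segment_mid_s, series.fold,
                                   edge_time_s=a, epoch_end_s=min(
                                       b, series.segment_mid_s[-1]))
            (out / "kinetics.json").write_text(json.dumps({
                "baseline_level": kin.baseline_level,
                "plateau_level": kin.plateau_level,
                "t50_min": kin.t50_min, "t90_min": kin.t90_min,
                "direction": kin.direction,
                "no_response": kin.no_response}, indent=1))
            manifest["stages"]["kinetics"] = {"status": "ok"}
        except Exception as exc:   # noqa: BLE001
            _fail("kinetics", exc)
        if len(protocol.epochs) >= 2:
            try:
                cyc = cycle_summary(series.segment_mid_s, series.fold,
                                    protocol)
                cyc.to_csv(out / "cycle_summary.csv", index=False)
                manifest["stages"]["cycles"] = {"status": "ok"}
            except Exception as exc:   # noqa: BLE001
                _fail("cycles", exc)

    # ---- activation mapping ------------------------------------------
    try:
        maps, summary = map_recording(
            clean, method=config.mapping.method,
            grid_step_um=config.mapping.grid_step_um,
            speed_cap_mm_s=config.mapping.speed_cap_mm_s,
            threshold_k=config.detection.threshold_k,
            refractory_ms=config.detection.refractory_ms,
            max_beats=config.mapping.max_beats)
        import pandas as pd

        pd.DataFrame({
            "beat_id": [m.beat_id for m in maps],
            "mean_speed_mm_s": [m.mean_speed_mm_s for m in maps],
            "sem_speed_mm_s": [m.sem_speed_mm_s for m in maps],
            "n_vectors": [m.n_vectors for m in maps],
        }).to_csv(out / "activation_per_beat.csv", index=False)
        pd.DataFrame([{
            "mean_speed_mm_s": summary.mean_speed_mm_s,
            "sem_speed_mm_s": summary.sem_speed_mm_s,
            "n_vectors": summary.n_vectors,
            "n_beats": summary.n_beats,
            "mean_direction_deg": summary.mean_direction_deg,
        }]).to_csv(out / "activation_summary.csv", index=False)
        manifest["stages"]["map"] = {
            "status": "ok", "mean_speed_mm_s": summary.mean_speed_mm_s,
            "n_beats": summary.n_beats}
    except Exception as exc:   # noqa: BLE001
        _fail("map", exc)

    return _finish()


DEFAULT_LADDER = (0.0, 0.03, 0.3, 0.7, 2.7, 7.0, 27.0)


def run_dose_response_experiment(levels=DEFAULT_LADDER,
                                 params: PhotoResponseParams | None = None,
                                 dark_min: float = 5.0,
                                 light_min: float = 30.0,
                                 segment_len_s: float = 10.0,
                                 jitter_ms: float = 0.0,
                                 seed: int = 0,
                                 fix_hill: bool = True,
                                 n_bootstrap: int = 200):
    """Simulate one illumination run per intensity and fit the Hill curve.

    Each level runs ``dark_min`` minutes dark then ``light_min`` minutes at
    that irradiance; the plateau is the mean fold-change over the final 20%
    of the light epoch, computed from beat times through the segment-rate
    estimator.  Requires >= 4 levels.
    """
    levels = tuple(float(x) for x in levels)
    if len(levels) < 4:
        raise ValidationError("need an intensity ladder with >= 4 levels")
    p = params or PhotoResponseParams()
    rng = np.random.default_rng(seed)
    points = []
    failures = []
    for irr in levels:
        try:
            dur = (dark_min + light_min) * 60.0
            protocol = StimulusProtocol((
                (0.0, dark_min * 60.0, 0.0),
                (dark_min * 60.0, dur, irr)))
            t, _, rate = simulate_camp_and_rate(p, protocol, dur, dt_s=0.5)
            beats = generate_beat_times(t, rate, jitter_ms=jitter_ms,
                                        seed=rng)
            series = fold_series([beats], dur, segment_len_s)
            tail = series.segment_mid_s >= dur - 0.2 * light_min * 60.0
            points.append((irr, float(np.mean(series.fold[tail]))))
        except Exception as exc:   # noqa: BLE001
            failures.append((irr, f"{type(exc).__name__}: {exc}"))
    if failures:
        raise ValidationError(f"dose-response levels failed: {failures}")
    irr = np.array([pt[0] for pt in points])
    resp = np.array([pt[1] for pt in points])
    fit = fit_dose_response(irr, resp, fix_hill=fix_hill,
                            n_bootstrap=n_bootstrap, seed=seed)
    return fit
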