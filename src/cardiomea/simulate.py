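"""Forward model of an optogenetically modulated cardiomyocyte monolayer
on a multi-electrode array.

The chronotropic photoresponse is a two-stage first-order cascade:

* light drives the second messenger (cAMP) toward a saturating target,

  .. math:: dc/dt = k_{deg}\\,[c_0 + (c_{max}-c_0)\\,I/(I+K_I)] - k_{deg}\\,c

  so the dose dependence of the steady state is hyperbolic (Michaelis–Menten
  in the irradiance ``I``) with half-saturation ``K_I``;

* the beating rate relaxes toward a cAMP-dependent target,

  .. math:: dR/dt = (R_{target}(c) - R)/\\tau_R,\\qquad
            R_{target}(c) = R_0\\,[1 + \\delta_{max}(c-c_0)/(c_{max}-c_0)]

By construction the steady-state fold change at constant irradiance is
``1 + delta_max * I / (I + K_I)``, exposed in closed form for testing.

Beats are emitted by an integrate-and-fire clock over R(t) (a beat whenever
the accumulated phase advances by one), which tracks rate changes exactly.
Extracellular waveforms are a propagating spike template plus Gaussian
noise; dead channels carry noise only.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import (ElectrodeLayout, MultichannelRecording, StimulusProtocol,
                   ValidationError, default_layout, grid_layout)
from . import io as cio


# --------------------------------------------------------------------------
# photoresponse model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhotoResponseParams:
    """Calibration of the light → cAMP → beating-rate cascade.

    Defaults reproduce the phenomenology this package models: half-maximal
    irradiance 0.56 µW mm⁻², 14% maximal rate elevation, basal/lit cAMP of
    5.36 / 11.04 ng per mg total protein, cAMP half-rise under 2.5 min and
    an overall beat-rate half-rise near 7 min.
    """

    K_I: float = 0.56            # half-saturating irradiance, µW mm⁻²
    delta_max: float = 0.14      # maximal fractional rate elevation
    k_deg_per_min: float = 0.6   # cAMP turnover rate, min⁻¹ (t50 ≈ 1.2 min)
    tau_R_min: float = 6.6       # beat-rate relaxation time, min
    c0: float = 5.36             # basal cAMP, ng mg⁻¹ total protein
    c_max: float = 11.04         # plateau cAMP at saturating light
    R0: float = 4.3              # basal beating rate, beats s⁻¹

    def __post_init__(self) -> None:
        if min(self.K_I, self.k_deg_per_min, self.tau_R_min, self.c0,
               self.c_max, self.R0) <= 0:
            raise ValidationError("photoresponse parameters must be positive")
        if not 0 < self.delta_max < 1:
            raise ValidationError("delta_max must lie in (0, 1)")
        if self.c_max <= self.c0:
            raise ValidationError("c_max must exceed basal cAMP c0")

    def camp_target(self, irradiance) -> np.ndarray:
        """Steady-state cAMP at constant irradiance (hyperbolic drive)."""
        irr = np.asarray(irradiance, dtype=float)
        return self.c0 + (self.c_max - self.c0) * irr / (irr + self.K_I)

    def rate_target(self, camp) -> np.ndarray:
        """Beating-rate set point for a given cAMP level."""
        c = np.asarray(camp, dtype=float)
        return self.R0 * (1.0 + self.delta_max * (c - self.c0)
                          / (self.c_max - self.c0))

    def steady_state_fold(self, irradiance) -> np.ndarray:
        """Closed-form steady-state fold change 1 + δmax·I/(I+K_I)."""
        irr = np.asarray(irradiance, dtype=float)
        return 1.0 + self.delta_max * irr / (irr + self.K_I)


def simulate_camp_and_rate(params: PhotoResponseParams,
                           protocol: StimulusProtocol,
                           duration_s: float,
                           dt_s: float = 1.0,
                           c_init: float | None = None,
                           r_init: float | None = None):
    """Integrate the cascade over a stimulus protocol.

    Uses exact exponential stepping (the drive is piecewise constant over
    each ``dt_s``), so constant-irradiance epochs converge monotonically to
    the closed-form steady state with no discretisation drift.

    Returns
    -------
    t_s, camp, rate : ndarray
        Time grid (s), cAMP (ng mg⁻¹) and beating rate (beats s⁻¹).
    """
    if dt_s <= 0 or dt_s > 1.0:
        raise ValidationError("dt_s must be in (0, 1] s")
    if duration_s <= 0:
        raise ValidationError("duration_s must be positive")
    n = int(round(duration_s / dt_s)) + 1
    t = np.arange(n) * dt_s
    irr = np.asarray(protocol.irradiance_at(t))
    c = np.empty(n)
    r = np.empty(n)
    c[0] = params.c0 if c_init is None else c_init
    r[0] = params.R0 if r_init is None else r_init
    k = params.k_deg_per_min / 60.0          # s⁻¹
    tau = params.tau_R_min * 60.0            # s
    decay_c = math.exp(-k * dt_s)
    decay_r = math.exp(-dt_s / tau)
    c_inf = params.camp_target(irr)
    for i in range(1, n):
        c[i] = c_inf[i - 1] + (c[i - 1] - c_inf[i - 1]) * decay_c
        r_t = params.rate_target(0.5 * (c[i - 1] + c[i]))
        r[i] = r_t + (r[i - 1] - r_t) * decay_r
    return t, c, r


# --------------------------------------------------------------------------
# beat clock
# --------------------------------------------------------------------------

def generate_beat_times(t_s: np.ndarray, rate_bps: np.ndarray,
                        jitter_ms: float = 0.0,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Integrate-and-fire beat clock over a rate series.

    A beat is emitted each time the accumulated phase ``∫R dt`` advances by
    one; the clock starts half a period in so beats sit inside the record.
    Independent Gaussian jitter (σ = ``jitter_ms``) is added per beat.
    """
    t = np.asarray(t_s, dtype=float)
    r = np.asarray(rate_bps, dtype=float)
    if np.any(r <= 0):
        raise ValidationError("rate series must be strictly positive")
    if len(t) != len(r) or len(t) < 2:
        raise ValidationError("need matching time/rate series of length >= 2")
    from scipy.integrate import cumulative_trapezoid

    phase = np.concatenate([[0.0], cumulative_trapezoid(r, t)]) + 0.5
    n_beats = int(np.floor(phase[-1]))
    targets = np.arange(1, n_beats + 1, dtype=float)
    beats = np.interp(targets, phase, t)
    if jitter_ms > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        beats = beats + rng.normal(0.0, jitter_ms / 1000.0, size=len(beats))
        beats = np.sort(np.clip(beats, t[0], t[-1]))
    return beats


def constant_rate_beats(rate_bps: float, duration_s: float,
                        jitter_ms: float = 0.0, seed: int = 0) -> np.ndarray:
    """Beat times for a constant rate over [0, duration)."""
    t = np.array([0.0, duration_s])
    r = np.array([rate_bps, rate_bps])
    return generate_beat_times(t, r, jitter_ms=jitter_ms, seed=seed)


# --------------------------------------------------------------------------
# spike template and wavefront
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeTemplate:
    """Extracellular spike waveform.

    ``morphology`` blends positive-monophasic (+1) through biphasic (0,
    Gaussian first derivative, zero net area) to negative-monophasic (−1);
    the waveform is peak-normalised so its absolute extremum equals
    ``amplitude_uV``.  The default (−0.3) is a biphasic wave whose negative
    lobe dominates, as extracellular field potentials typically show; the
    dominant lobe gives spike detection a unique extremum fiducial (a
    perfectly symmetric biphasic wave has two equal lobes and its extremum
    time is ill-defined at the sample level).
    """

    amplitude_uV: float = 300.0
    width_ms: float = 2.0
    morphology: float = -0.3

    def __post_init__(self) -> None:
        if self.amplitude_uV <= 0 or self.width_ms <= 0:
            raise ValidationError("amplitude and width must be positive")
        if not -1.0 <= self.morphology <= 1.0:
            raise ValidationError("morphology must lie in [-1, 1]")
        fine = np.linspace(-self.half_support_s, self.half_support_s, 2001)
        object.__setattr__(self, "_norm", float(np.max(np.abs(self._raw(fine)))))

    @property
    def sigma_s(self) -> float:
        return self.width_ms / 2.0 / 1000.0

    @property
    def half_support_s(self) -> float:
        return 4.0 * self.sigma_s

    def _raw(self, t: np.ndarray) -> np.ndarray:
        s = self.sigma_s
        g = np.exp(-0.5 * (t / s) ** 2)
        dg = -(t / s) * g * math.exp(0.5)   # Gaussian derivative, |peak| = 1
        m = self.morphology
        return m * g + (1.0 - abs(m)) * dg

    def evaluate(self, t_s) -> np.ndarray:
        """Waveform value at times relative to the spike fiducial (s)."""
        t = np.asarray(t_s, dtype=float)
        return self.amplitude_uV * self._raw(t) / self._norm

    def fiducial_offset_s(self) -> float:
        """Time of the dominant extremum relative to the template origin."""
        fine = np.linspace(-self.half_support_s, self.half_support_s, 4001)
        w = self.evaluate(fine)
        return float(fine[np.argmax(np.abs(w))])


@dataclass(frozen=True)
class WavefrontParams:
    """Geometry of the activation wavefront crossing the array."""

    mode: str = "planar"                 # planar | radial
    speed_mm_s: float = 50.0
    direction_deg: float = 0.0           # planar propagation direction
    origin_um: tuple = (500.0, 500.0)    # radial source
    jitter_ms: float = 0.0               # per-beat wavefront timing jitter

    def __post_init__(self) -> None:
        if self.speed_mm_s <= 0:
            raise ValidationError("wavefront speed must be positive")
        if self.mode not in ("planar", "radial"):
            raise ValidationError("mode must be 'planar' or 'radial'")

    def delays_s(self, layout: ElectrodeLayout,
                 ids: Sequence[int] | None = None) -> np.ndarray:
        """Per-electrode arrival delay (s), shifted so the earliest is 0."""
        pts = layout.positions(ids)
        v_um_s = self.speed_mm_s * 1000.0
        if self.mode == "planar":
            th = math.radians(self.direction_deg)
            u = np.array([math.cos(th), math.sin(th)])
            d = pts @ u / v_um_s
        else:
            d = np.hypot(pts[:, 0] - self.origin_um[0],
                         pts[:, 1] - self.origin_um[1]) / v_um_s
        return d - d.min()


# --------------------------------------------------------------------------
# waveform synthesis
# --------------------------------------------------------------------------

def synthesize_recording(beat_times_s: np.ndarray,
                         wavefront: WavefrontParams,
                         template: SpikeTemplate,
                         layout: ElectrodeLayout,
                         noise_rms_uV: float = 7.0,
                         dead_channels: Sequence[int] = (),
                         sample_rate_hz: float = 25000.0,
                         duration_s: float | None = None,
                         seed: int | np.random.Generator = 0,
                         ) -> MultichannelRecording:
    """Render beats into a multichannel extracellular recording.

    Each live channel receives the spike template at every beat time plus
    that channel's wavefront delay, with sub-sample placement; Gaussian
    noise of the requested RMS is added everywhere. ``dead_channels``
    receive noise only.
    """
    beats = np.asarray(beat_times_s, dtype=float)
    if len(beats) and np.any(np.diff(beats) < 0):
        raise ValidationError("beat times must be sorted")
    dead = np.asarray(sorted(dead_channels), dtype=int)
    if len(dead) and not np.all(np.isin(dead, layout.electrode_ids)):
        raise ValidationError("dead channels must be layout electrode ids")
    if duration_s is None:
        duration_s = (beats[-1] + 0.2) if len(beats) else 1.0
    if len(beats) > 1:
        med_ibi = float(np.median(np.diff(beats)))
        if 2 * template.half_support_s >= med_ibi:
            import warnings

            warnings.warn("spike template wider than the median inter-beat "
                          "interval; waveforms will overlap", stacklevel=2)

    n = int(round(duration_s * sample_rate_hz))
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    ids = layout.electrode_ids
    delays = wavefront.delays_s(layout)
    data = np.zeros((len(ids), n), dtype=np.float32)
    if noise_rms_uV > 0:
        for ci in range(len(ids)):   # per-row to bound peak memory
            data[ci] = rng.standard_normal(n, dtype=np.float32) * noise_rms_uV

    half = template.half_support_s
    half_n = int(math.ceil(half * sample_rate_hz))
    beat_jit = (rng.normal(0.0, wavefront.jitter_ms / 1000.0, size=len(beats))
                if wavefront.jitter_ms > 0 else np.zeros(len(beats)))
    for ci, cid in enumerate(ids):
        if cid in dead:
            continue
        events = beats + delays[ci] + beat_jit
        for ev in events:
            c = int(round(ev * sample_rate_hz))
            lo, hi = max(0, c - half_n), min(n, c + half_n + 1)
            if hi <= lo:
                continue
            tt = np.arange(lo, hi) / sample_rate_hz - ev
            data[ci, lo:hi] += template.evaluate(tt)
    return MultichannelRecording(data=data,
                                 sample_rate_hz=sample_rate_hz,
                                 channel_ids=ids, layout=layout)


# --------------------------------------------------------------------------
# experiment presets
# --------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """A simulated experiment: recording(s), protocol and ground truth."""

    name: str
    protocol: StimulusProtocol
    recording: MultichannelRecording | None
    truth: dict
    recordings: list = field(default_factory=list)   # multiday only

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.recording is not None:
            cio.write_recording(self.recording, outdir / "recording.h5")
        for i, rec in enumerate(self.recordings):
            cio.write_recording(rec, outdir / f"recording_day{i}.h5")
        cio.write_protocol(self.protocol, outdir / "protocol.csv")
        truth = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                 for k, v in self.truth.items()}
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))


PRESETS = ("nt_baseline", "bpac_light_step", "bpac_cycles",
           "bpac_stepwise", "dead_channels", "multiday")

_MIN = 60.0


def make_fixture(name: str, seed: int = 0,
                 sample_rate_hz: float | None = None,
                 duration_s: float | None = None,
                 n_channels: int | None = None,
                 synthesize_waveform: bool = True,
                 params: PhotoResponseParams | None = None,
                 noise_rms_uV: float = 7.0,
                 jitter_ms: float = 1.0) -> FixtureBundle:
    """Build one of the stock simulated experiments.

    Presets mirror the experiment designs this package analyses:
    a dark baseline, a 5-min-dark / 40-min-light step, two 25-min light /
    30-min dark cycles, a stepwise 0 / 0.3 / 27 µW mm⁻² ladder, a chip with
    three dead interfaces, and a four-day series with drifting baseline rate
    and spike morphology. Long protocols default to a reduced 1 kSa/s
    sample rate and a wider template so waveforms stay resolvable.
    """
    if name not in PRESETS:
        raise ValidationError(
            f"unknown preset {name!r}; available: {', '.join(PRESETS)}")
    rng = np.random.default_rng(seed)
    layout = default_layout()
    if n_channels is not None:
        layout = layout.subset(layout.electrode_ids[:n_channels])
    wavefront = WavefrontParams(mode="planar", speed_mm_s=50.0,
                                direction_deg=30.0)
    p = params or PhotoResponseParams()

    def _steady_fixture(rate_bps, dead=(), dur=6.0, fs=25000.0):
        beats = constant_rate_beats(rate_bps, dur, jitter_ms=jitter_ms,
                                    seed=rng)
        protocol = StimulusProtocol(((0.0, dur, 0.0),))
        rec = None
        if synthesize_waveform:
            rec = synthesize_recording(
                beats, wavefront, SpikeTemplate(), layout,
                noise_rms_uV=noise_rms_uV, dead_channels=dead,
                sample_rate_hz=fs, duration_s=dur, seed=rng)
        return beats, protocol, rec

    if name == "nt_baseline":
        dur = duration_s or 6.0
        fs = sample_rate_hz or 25000.0
        beats, protocol, rec = _steady_fixture(5.7, dur=dur, fs=fs)
        truth = {"preset": name, "rate_bps": 5.7, "beat_times_s": beats,
                 "speed_mm_s": wavefront.speed_mm_s,
                 "direction_deg": wavefront.direction_deg}
        return FixtureBundle(name, protocol, rec, truth)

    if name == "dead_channels":
        dur = duration_s or 6.0
        fs = sample_rate_hz or 25000.0
        dead_ids = [int(i) for i in layout.electrode_ids[[5, 13, 21]]] \
            if len(layout) >= 22 else [int(layout.electrode_ids[0])]
        beats, protocol, rec = _steady_fixture(5.7, dead=dead_ids,
                                               dur=dur, fs=fs)
        truth = {"preset": name, "rate_bps": 5.7, "beat_times_s": beats,
                 "dead_channel_ids": dead_ids,
                 "n_live": len(layout) - len(dead_ids)}
        return FixtureBundle(name, protocol, rec, truth)

    if name == "multiday":
        fs = sample_rate_hz or 25000.0
        dur = duration_s or 6.0
        rates = [4.1, 4.0, 5.2, 5.1]
        morphs = [1.0, 0.33, -0.33, -1.0]
        recs = []
        beats_all = []
        protocol = StimulusProtocol(((0.0, dur, 0.0),))
        for r0, m in zip(rates, morphs):
            beats = constant_rate_beats(r0, dur, jitter_ms=jitter_ms,
                                        seed=rng)
            beats_all.append(beats)
            recs.append(synthesize_recording(
                beats, wavefront, SpikeTemplate(morphology=m), layout,
                noise_rms_uV=noise_rms_uV, sample_rate_hz=fs,
                duration_s=dur, seed=rng))
        truth = {"preset": name, "rates_bps": rates, "morphologies": morphs,
                 "beat_times_s": [b.tolist() for b in beats_all]}
        return FixtureBundle(name, protocol, None, truth, recordings=recs)

    # light-driven presets: simulate the cascade, then render
    if name == "bpac_light_step":
        epochs = ((0.0, 5 * _MIN, 0.0), (5 * _MIN, 45 * _MIN, 27.0))
    elif name == "bpac_cycles":
        epochs = ((0.0, 5 * _MIN, 0.0),
                  (5 * _MIN, 30 * _MIN, 27.0),
                  (30 * _MIN, 60 * _MIN, 0.0),
                  (60 * _MIN, 85 * _MIN, 27.0),
                  (85 * _MIN, 115 * _MIN, 0.0))
    else:  # bpac_stepwise
        p = params or replace(PhotoResponseParams(), R0=4.67)
        epochs = ((0.0, 5 * _MIN, 0.0),
                  (5 * _MIN, 35 * _MIN, 0.3),
                  (35 * _MIN, 50 * _MIN, 27.0))
    protocol = StimulusProtocol(epochs)
    dur = duration_s or protocol.duration_s
    protocol = StimulusProtocol(
        tuple((a, min(b, dur), i) for a, b, i in epochs if a < dur))
    fs = sample_rate_hz or 1000.0
    t, camp, rate = simulate_camp_and_rate(p, protocol, dur, dt_s=0.5)
    beats = generate_beat_times(t, rate, jitter_ms=jitter_ms, seed=rng)
    rec = None
    if synthesize_waveform:
        template = SpikeTemplate(width_ms=6.0 if fs < 5000 else 2.0)
        rec = synthesize_recording(beats, wavefront, template, layout,
                                   noise_rms_uV=noise_rms_uV,
                                   sample_rate_hz=fs, duration_s=dur,
                                   seed=rng)
    truth = {"preset": name, "beat_times_s": beats,
             "t_s": t, "camp_ng_mg": camp, "rate_bps": rate,
             "steady_state_fold_at_27": float(p.steady_state_fold(27.0)),
             "params": {"K_I": p.K_I, "delta_max": p.delta_max,
                        "k_deg_per_min": p.k_deg_per_min,
                        "tau_R_min": p.tau_R_min, "R0": p.R0}}
    return FixtureBundle(name, protocol, rec, truth)
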