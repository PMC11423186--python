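# Methods

This note documents the models, estimators and numerical choices behind
`cardiomea`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one reasonable option
existed.

## Photoresponse model

The light → cAMP → beating-rate cascade is modelled as two first-order
stages:

* **cAMP stage.** Intracellular cAMP `c` (ng per mg total protein) turns
  over at rate `k_deg` toward a light-dependent target,
  `dc/dt = k_deg·[c0 + (c_max − c0)·I/(I + K_I)] − k_deg·c`. The drive is
  hyperbolic (Michaelis–Menten) in the irradiance `I`, reflecting
  single-photon-pool saturation of the photoactivated cyclase.
* **Rate stage.** The beating rate `R` (beats s⁻¹) relaxes with time
  constant `tau_R` toward a set point linear in cAMP,
  `R_target(c) = R0·[1 + delta_max·(c − c0)/(c_max − c0)]`.

By construction the steady-state fold change at constant irradiance is
`1 + delta_max·I/(I + K_I)`; this closed form is exposed on
`PhotoResponseParams` so tests can compare the integrated trajectory
against an independent analytic limit. The model is the simplest one that
reproduces the observed phenomenology — a fast cAMP rise, a slower rate
rise, and a saturating dose–response whose EC50 equals `K_I` exactly
(because a linear cascade preserves the hyperbolic dose dependence at
every level).

**Defaults and rationale** (all configurable):

| parameter | default | unit | why |
|---|---|---|---|
| `K_I` | 0.56 | µW mm⁻² | half-saturating irradiance of the measured dose–response |
| `delta_max` | 0.14 | — | 14 % plateau elevation at saturating light (the alternative printed value, 17 %, is supported by overriding `delta_max`) |
| `c0`, `c_max` | 5.36, 11.04 | ng mg⁻¹ | basal and lit-state cAMP plateaus |
| `k_deg` | 0.6 | min⁻¹ | cAMP half-rise `ln2/k_deg ≈ 1.2 min`, inside the < 2.5 min constraint |
| `tau_R` | 6.6 | min | see calibration below |
| `R0` | 4.3 | beats s⁻¹ | basal rate of the transduced cultures (non-transduced baseline is 5.7) |

**Calibration of the time constants.** `k_deg` and `tau_R` were chosen so
that the *measured* kinetics — the fold-change series segmented at 6–10 s,
smoothed with a 5-segment moving average, and read out by the crossing
estimator below — satisfy all of: cAMP half-rise < 2.5 min; beat-rate
half-rise between 6 and 8 min; light-off decay t50 of 6 ± 1 min when the
light is switched off after a 20-min plateau; and time-to-95 %-of-plateau
between 20 and 25 min under continuous illumination. The closed-form
cascade slightly underestimates the measured decay t50 because the rate
still lags cAMP at light-off, so the calibration was finalised against the
measurement operators rather than the asymptotic formulas. A known
limitation: no two-stage linear cascade with t50 ≈ 7 min can produce a
t90 as fast as 13 min (the measured t90 here is ≈ 17 min); capturing that
ratio would need a sigmoidal (cooperative) stage.

## Beat generation and waveform synthesis

Beats come from an **integrate-and-fire clock**: a beat is emitted each
time `∫R dt` advances by one, with the phase initialised at 0.5 so beats
sit strictly inside the record. This tracks rate changes exactly —
unlike a renewal process, the expected count over any window equals the
rate integral — which is what the kinetics tests need. Per-beat Gaussian
timing jitter (default σ = 1 ms) models cycle-to-cycle variability; no
printed variability statistic exists, so the default is a conservative
round number well below the detection refractory period.

The extracellular spike template blends a Gaussian and its first
derivative: morphology +1 is positive-monophasic, 0 is biphasic (exact
zero net area), −1 negative-monophasic; the waveform is peak-normalised
to `amplitude_uV` (default 300 µV, within the > 64 µV operating band).
The default morphology is −0.3 — biphasic with a dominant negative lobe,
as extracellular field potentials typically show. A perfectly symmetric
biphasic wave has two equal-magnitude lobes, so the "largest deflection"
fiducial flips between lobes with sampling phase (±2 ms errors that bias
conduction speeds by ~8 %); a dominant lobe makes the fiducial unique.

Wavefronts are planar (delay = projection onto the propagation direction
divided by speed) or radial (delay = distance from origin over speed).
Spikes are placed with sub-sample precision by evaluating the template at
the exact continuous offsets; Gaussian noise (default RMS 7 µV, inside
the < 10 µV envelope) is added per channel; dead channels receive noise
only. The default 32-electrode layout is a 6×6 grid at 200 µm pitch with
the four corners removed, spanning 1000 µm × 1000 µm; `grid_layout`
builds arbitrary rectangular grids (the mapping fixtures use 4×8).

Long-protocol presets default to a reduced 1 kSa/s sample rate with a
6-ms-wide template so the waveform stays resolvable; at that rate the
filter band is clipped to 0.4·fs (see below).

## Filtering and channel QC

The bandpass is a type-I Chebyshev with prototype order 2 and passband
150–2500 Hz. Two underdetermined choices are documented explicitly:
passband ripple defaults to 1 dB (configurable — Chebyshev-I is not fully
specified without it), and "second order" is read as the analog prototype
order, so the digital bandpass has four poles; application is zero-phase
(forward–backward) by default so activation times carry no group-delay
bias, with a causal single-pass option for strict online equivalence.
For recordings sampled below 2×2500 Hz, `FilterSpec.for_sample_rate`
clips the upper edge to 0.4·fs (and keeps the lower edge below a quarter
of that), preserving the filter family at reduced rates.

Channel metrics: the noise scale is the **median absolute deviation
× 1.4826** — robust to the spikes themselves, unlike a raw standard
deviation; the amplitude is the median absolute extremum over detected
spikes; SNR is their ratio. A channel with no detections — or fewer than
0.5 spikes per second, far below any beating monolayer — scores SNR 0:
isolated threshold crossings on a noise-only channel would otherwise
score SNR ≈ threshold_k and defeat the exclusion rule. Channels with
SNR < 2 (default threshold) are excluded; excluding every channel raises
an error that names the threshold.

## Beat analysis

Spikes are local extrema of |v| above `threshold_k` × noise (default 5),
separated by a refractory period (default 80 ms, below the ~150 ms
interval of the fastest plausible rates). Peak times are refined to
sub-sample precision with a parabolic fit through the extremum and its
neighbours — at 1 kSa/s the raw sample grid would quantise inter-beat
intervals to whole milliseconds and turn the fold-change series into a
staircase.

The per-segment rate is **1/median(inter-beat interval)** (≥ 3 spikes;
with exactly 2, the single interval; fewer, rate 0). A per-segment count
would quantise to 1/6 Hz and could not express rates like 4.67 beats s⁻¹;
the median tolerates a missed beat. Segments default to 6 s; the array
rate is the median across included channels (per-channel series are also
kept); the fold series divides by the first segment's array rate, so
`fold[0] = 1` exactly.

Kinetics: baseline is the mean fold over a settled window just before the
stimulus edge (default the final 20 % of the pre-edge interval — for a
falling edge this references the preceding plateau, not the whole rise);
plateau is the mean over the final 20 % of the epoch. The series is
smoothed with a centred 5-segment moving average, normalised between
baseline and plateau, and t50/t90 are the first linearly interpolated
crossings of 0.5/0.9 after the edge. If the baseline–plateau separation
is under twice the baseline noise, a `no_response` flag replaces a
meaningless t50. Cycle summaries report per-epoch plateaus and each light
epoch against its preceding dark epoch; epochs with fewer than 5 segments
are skipped with a warning.

## Activation mapping

Spike trains are clustered into array-wide beats by pooling all spikes,
splitting at gaps larger than half the median inter-beat interval, and
keeping per channel the spike nearest the beat's median time within ±40 %
of that interval; beats captured by fewer than half the channels are
dropped. Activation times use the dominant-extremum fiducial by default,
with a cross-correlation alternative (lag against the earliest channel,
parabolic sub-sample refinement) that attaches a quality warning when the
two methods disagree by > 2 ms on more than a quarter of the channels.

Times are interpolated with a **thin-plate-spline** (zero smoothing),
which honours the electrode values exactly and reproduces affine
surfaces — hence planar wavefronts — to machine precision, making the
planar-wave tests exact. The grid step is 25 µm (pitch/8), balancing
gradient accuracy against cost. The gradient is taken by central
differences; velocity is `∇T/‖∇T‖²` with speed `1/‖∇T‖`, pointing in the
direction of wave travel (increasing activation time). Vectors outside
the electrode hull or faster than 200 mm s⁻¹ (near-flat gradients) are
excluded; if none survive, a degenerate-map error is raised. Summaries
pool all vectors across beats before averaging (mean ± SEM over vectors);
per-beat means are also reported.

## Dose–response fitting

The Hill model is parameterised on a **linear dose axis** so the
zero-irradiance point enters the fit directly — a deliberate divergence
from log(agonist) conventions, which would need a pseudo-dose for I = 0.
The slope is fixed to 1 by default (the steady state of the cascade is
exactly Michaelis–Menten), with a free-slope option; bottom and top are
fitted. Weighted least squares uses replicate counts as weights (the fit
is invariant to splitting a point's weight across duplicates); EC50 is
bounded positive. At least 4 distinct levels including zero dose are
required; a response span below the noise floor raises an
unidentifiable-EC50 error. Confidence intervals come from a seeded
parametric bootstrap (200 resamples, Gaussian with the fit's RMS error).
On the 7-level single-replicate design the *median* recovered EC50 is
nearly unbiased (≲ 3 % across EC50 ∈ {0.1, 0.56, 3.7} and σ ≤ 0.02), but
individual-draw errors at σ = 0.02 are large (median |error| ~30–40 %) —
an identifiability limit of the design, not of the estimator.

## Pipeline and reproducibility

A run is one JSON `RunConfig` (exactly one of recording path or
simulation preset). All randomness flows from a single root seed split
per stage with `numpy.random.SeedSequence`; the manifest records the
config hash, seed, stage seeds, package version, and per-stage status —
a failing stage leaves completed outputs in place plus an error record.
Fixed-seed runs are byte-identical.

## What the simulator does and does not emulate

Emulated: periodic biphasic spikes with configurable morphology drift,
planar/radial wavefront geometry with per-beat jitter, Gaussian sensor
noise, dead channels, and the dose-dependent, minute-scale chronotropic
photoresponse. Not emulated: biophysical membrane dynamics
(Hodgkin–Huxley-class models), spiral waves / re-entry or multiple
activation centres, cell–electrode junction physics, line noise and
stimulation artifacts, long-term culture drift within a recording, and
non-Gaussian noise. Passing tests therefore demonstrate correctness of
the analysis chain on signals with known ground truth — not robustness
to every pathology of real recordings.

## Problem sizes

The test suite and the acceptance script run the full waveform chain on
6-s, 32-channel recordings at 25 kSa/s; the 45-min illumination
experiment is synthesised at 1 kSa/s (with the clipped filter band and
the wider template); dose–response and kinetics studies run at the
rate-series level, where waveform synthesis adds nothing to the quantity
under test. These sizes keep a full run in tens of seconds while leaving
every estimator on its native path.
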