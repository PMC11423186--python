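# cardiomea

Analysis pipeline for multi-electrode-array (MEA) field-potential
recordings of cardiomyocyte monolayers whose beating rate is modulated
optogenetically, together with a matched forward simulator so that every
stage can be exercised, tested and calibrated without any external data.

## Who this is for

Labs recording extracellular field potentials from beating cardiac
monolayers on planar MEAs (32 channels, 25 kSa/s, 200 µm pitch) while
driving the cells with light — e.g. through a photoactivatable adenylyl
cyclase (bPAC) that raises intracellular cAMP and with it the spontaneous
beating rate. The package turns raw multichannel voltage matrices plus an
irradiance protocol into:

* **channel QC** — per-channel SNR, RMS noise and spike amplitude after a
  second-order type-I Chebyshev bandpass (150–2500 Hz); channels with
  SNR < 2 are excluded;
* **beating-rate series** — spike detection per channel, per-6-s-segment
  rate from the median inter-beat interval, array-median reduction and
  fold-change normalisation *BPS/BPS₀* to the first segment;
* **chronotropic kinetics** — plateau level and t50/t90 of rising and
  falling edges of the fold-change series around stimulus steps;
* **isochronal activation maps** — per-beat activation times across the
  array, thin-plate-spline time surfaces T(x, y), and conduction
  velocities by the inverse-gradient rule **v** = ∇T/‖∇T‖², summarised as
  mean ± SEM over all velocity vectors;
* **dose–response fits** — plateau fold-change versus irradiance fitted
  with a Hill curve on a linear dose axis,
  r(I) = bottom + (top − bottom)·I/(I + EC₅₀), Hill slope fixed to 1.

The simulator generates the matching synthetic experiments: biphasic
extracellular spikes riding on Gaussian noise, a planar or radial
wavefront propagating across the electrode grid, dead channels, and a
light-driven chronotropic response modelled as a two-stage first-order
cascade,

    dc/dt = k_deg·[c₀ + (c_max − c₀)·I/(I + K_I)] − k_deg·c
    dR/dt = (R_target(c) − R)/τ_R,   R_target(c) = R₀·[1 + δ_max·(c − c₀)/(c_max − c₀)]

whose steady-state fold change is 1 + δ_max·I/(I + K_I) by construction
(defaults: K_I = 0.56 µW mm⁻², δ_max = 0.14, i.e. a 14 % elevation at
saturating light). See `docs/methods.md` for the full model description
and parameter rationale.

## Worked example

`examples/` holds one short script per capability. For instance,
`python examples/02_light_step_kinetics.py` simulates a 5-min dark
baseline followed by 40 min at 27 µW mm⁻² and analyses the resulting beat
train:

```
simulated 12734 beats over 45 min; basal rate 4.3 beats/s
BPS0 = 4.30 beats/s
plateau fold = 1.137 (13.7% elevation; closed-form steady state 1.137)
t50 = 6.4 min, t90 = 17.0 min, 95% of plateau at 20.8 min
```

The fold-change series plateaus ~14 % above the dark baseline, reaching
95 % of the plateau in 20–25 min with a half-rise near 7 min — the
operating point of the calibrated cascade. `examples/03_activation_map.py`
maps a noiseless 50 mm s⁻¹ planar wavefront back to
`mean speed = 50.00 mm/s ± 0.000 (SEM), direction = 30.0 deg`, and
`examples/04_dose_response.py` recovers `EC50 = 0.56 uW/mm^2` from a
7-level intensity ladder.

The same stages are scriptable from the shell:

```bash
cardiomea simulate --preset dead_channels --seed 0 --out run/
cardiomea qc run/recording.h5 --out run/qc_report.csv
cardiomea map run/recording.h5 --out-dir run/
cardiomea pipeline config.json        # full chain from one JSON config
```

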