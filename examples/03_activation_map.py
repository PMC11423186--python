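"""Isochronal activation mapping and conduction-velocity estimation.

Synthesizes a noiseless planar wavefront (50 mm/s at 30 degrees) crossing
a 200-um-pitch 4x8 electrode grid, clusters spikes into array-wide beats,
interpolates per-beat activation times with a thin-plate spline and
inverts the gradient into a velocity field.
"""

import cardiomea as cm

layout = cm.grid_layout(8, 4)                      # 4 columns x 8 rows
wavefront = cm.WavefrontParams(mode="planar", speed_mm_s=50.0,
                               direction_deg=30.0)
beats = cm.constant_rate_beats(5.7, 1.84)          # 10 beats
rec = cm.synthesize_recording(beats, wavefront, cm.SpikeTemplate(), layout,
                              noise_rms_uV=0.0, sample_rate_hz=25000.0,
                              duration_s=1.9)

maps, summary = cm.map_recording(cm.bandpass_filter(rec))
print(f"{summary.n_beats} beats mapped, {summary.n_vectors} velocity "
      "vectors pooled")
print(f"mean speed = {summary.mean_speed_mm_s:.2f} mm/s "
      f"+- {summary.sem_speed_mm_s:.3f} (SEM), "
      f"direction = {summary.mean_direction_deg:.1f} deg")

cm.render_isochronal_map(maps[0], "isochronal_map.png")
print("first beat's isochronal map written to isochronal_map.png")
# Speed and direction match the generating wavefront because thin-plate
# interpolation reproduces planar activation surfaces exactly.
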