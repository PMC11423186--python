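"""Isochronal activation mapping and conduction-velocity estimation.

Per array-wide beat, spike fiducials give each electrode an activation time
(earliest electrode = 0).  The times are interpolated with a thin-plate
spline — which reproduces planar wavefronts exactly — onto a regular grid;
the gradient ∇T (ms µm⁻¹) is taken by central differences and inverted,
v = ∇T/‖∇T‖², so that the speed is 1/‖∇T‖ and the vector points in the
direction of wave travel.  Speeds are summarised as mean ± SEM over all
grid vectors inside the electrode hull, after discarding near-flat-gradient
blowups above a speed cap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial import Delaunay, QhullError

from .core import ElectrodeLayout, MultichannelRecording, ValidationError
from .beats import detect_peaks


class DegenerateMapError(ValueError):
    """No valid velocity vectors could be derived from the surface."""


# --------------------------------------------------------------------------
# beat clustering across channels
# --------------------------------------------------------------------------

def beat_cluster(spike_trains: dict,
                 min_channel_fraction: float = 0.5,
                 window_fraction: float = 0.4) -> list:
    """Group per-channel spike times into array-wide beats.

    Spikes are pooled, split at gaps larger than half the median inter-beat
    interval, and each channel contributes its spike nearest the beat's
    median time within ± ``window_fraction`` × IBI.  Beats captured by fewer
    than ``min_channel_fraction`` of the channels are dropped.

    Returns a list of dicts ``{channel_id: spike_time_s}``.
    """
    trains = {cid: np.asarray(t, float) for cid, t in spike_trains.items()
              if len(t) > 0}
    if len(trains) < 4:
        raise ValidationError("need spikes on at least 4 channels")
    ibis = [np.median(np.diff(t)) for t in trains.values() if len(t) >= 2]
    if not ibis:
        warnings.warn("no channel has >= 2 spikes; no clusterable beats",
                      stacklevel=2)
        return []
    ibi = float(np.median(ibis))
    # pool (time, channel) pairs sorted by time
    pairs = sorted((tv, cid) for cid, t in trains.items() for tv in t)
    times = np.array([p[0] for p in pairs])
    breaks = np.flatnonzero(np.diff(times) > 0.5 * ibi) + 1
    groups = np.split(np.arange(len(pairs)), breaks)
    n_channels = len(spike_trains)
    beats = []
    for g in groups:
        med = float(np.median(times[g]))
        best: dict = {}
        for i in g:
            tv, cid = pairs[i]
            if abs(tv - med) > window_fraction * ibi:
                continue
            if cid not in best or abs(tv - med) < abs(best[cid] - med):
                best[cid] = tv
        if len(best) >= min_channel_fraction * n_channels:
            beats.append(best)
    if not beats:
        warnings.warn("no clusterable beats found", stacklevel=2)
    return beats


# --------------------------------------------------------------------------
# activation times
# --------------------------------------------------------------------------

def activation_times(cluster: dict, method: str = "extremum",
                     rec: MultichannelRecording | None = None,
                     window_ms: float = 10.0,
                     disagreement_ms: float = 2.0) -> dict:
    """Per-electrode activation times (ms, earliest = 0) for one beat.

    ``extremum`` takes the detected spike fiducial (time of the largest
    absolute deflection).  ``xcorr`` re-times each channel by the lag
    maximising its cross-correlation against the earliest channel's
    waveform (requires the recording), with parabolic sub-sample
    refinement, and attaches a quality warning when the two methods
    disagree by more than ``disagreement_ms`` on over 25% of channels.
    """
    if len(cluster) < 4:
        raise ValidationError("need a cluster with >= 4 electrodes")
    ids = list(cluster.keys())
    ext = np.array([cluster[c] for c in ids], dtype=float)
    if method == "extremum":
        rel = ext - ext.min()
        return {c: float(r * 1000.0) for c, r in zip(ids, rel)}
    if method != "xcorr":
        raise ValidationError("method must be 'extremum' or 'xcorr'")
    if rec is None:
        raise ValidationError("xcorr method requires the recording")
    fs = rec.sample_rate_hz
    half = int(round(window_ms / 1000.0 * fs))
    ref_id = ids[int(np.argmin(ext))]

    def snippet(cid, t_center):
        x = rec.channel(cid)
        c = int(round((t_center - rec.t0_s) * fs))
        lo, hi = c - half, c + half + 1
        if lo < 0 or hi > len(x):
            return None
        return x[lo:hi].astype(np.float64), c

    ref = snippet(ref_id, cluster[ref_id])
    if ref is None:
        rel = ext - ext.min()
        return {c: float(r * 1000.0) for c, r in zip(ids, rel)}
    ref_w, ref_c = ref
    out = {}
    for cid in ids:
        sn = snippet(cid, cluster[cid])
        if sn is None:
            out[cid] = (cluster[cid] - cluster[ref_id]) * 1000.0
            continue
        w, c = sn
        corr = np.correlate(w - w.mean(), ref_w - ref_w.mean(), mode="full")
        k = int(np.argmax(corr))
        # parabolic sub-sample refinement around the correlation peak
        if 0 < k < len(corr) - 1:
            y0, y1, y2 = corr[k - 1], corr[k], corr[k + 1]
            denom = y0 - 2 * y1 + y2
            k = k + (0.5 * (y0 - y2) / denom if denom != 0 else 0.0)
        lag_samples = k - (len(ref_w) - 1)
        out[cid] = ((c - lag_samples) - ref_c) / fs * 1000.0
    rel = np.array([out[c] for c in ids])
    rel -= rel.min()
    out = {c: float(r) for c, r in zip(ids, rel)}
    ext_rel = (ext - ext.min()) * 1000.0
    diff = np.abs(rel - ext_rel)
    if np.mean(diff > disagreement_ms) > 0.25:
        warnings.warn("extremum and xcorr fiducials disagree by more than "
                      f"{disagreement_ms} ms on >25% of channels",
                      stacklevel=2)
    return out


# --------------------------------------------------------------------------
# surface interpolation and velocity field
# --------------------------------------------------------------------------

def interpolate_surface(times_ms: dict, layout: ElectrodeLayout,
                        grid_step_um: float = 25.0, smoothing: float = 0.0):
    """Thin-plate interpolation of activation times onto a regular grid.

    The interpolant honours the electrode values exactly (smoothing 0) and
    reproduces affine surfaces — hence planar wavefronts — to machine
    precision.  Returns (grid_x, grid_y, T) with T of shape (ny, nx).
    """
    ids = list(times_ms.keys())
    if len(ids) < 4:
        raise ValidationError("need >= 4 electrodes to interpolate")
    pts = layout.positions(ids)
    vals = np.array([times_ms[c] for c in ids], dtype=float)
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-6) < 2:
        raise ValidationError("electrodes are collinear; surface is rank "
                              "deficient")
    interp = RBFInterpolator(pts, vals, kernel="thin_plate_spline",
                             smoothing=smoothing)
    gx = np.arange(pts[:, 0].min(), pts[:, 0].max() + grid_step_um / 2,
                   grid_step_um)
    gy = np.arange(pts[:, 1].min(), pts[:, 1].max() + grid_step_um / 2,
                   grid_step_um)
    xx, yy = np.meshgrid(gx, gy)
    T = interp(np.column_stack([xx.ravel(), yy.ravel()])).reshape(xx.shape)
    return gx, gy, T


@dataclass
class ActivationMap:
    """One beat's activation surface and inverse-gradient velocity field."""

    beat_id: int
    electrode_ids: np.ndarray
    electrode_xy_um: np.ndarray
    times_ms: np.ndarray
    grid_x: np.ndarray
    grid_y: np.ndarray
    surface_ms: np.ndarray
    vx_mm_s: np.ndarray
    vy_mm_s: np.ndarray
    speed_mm_s: np.ndarray
    valid: np.ndarray
    mean_speed_mm_s: float
    sem_speed_mm_s: float
    n_vectors: int
    mean_direction_deg: float


def velocity_field(grid_x: np.ndarray, grid_y: np.ndarray, T: np.ndarray,
                   electrode_points: np.ndarray,
                   speed_cap_mm_s: float = 200.0):
    """Invert the activation-time gradient into a velocity field.

    T is in ms on a µm grid, so ‖∇T‖ is in ms µm⁻¹ and 1/‖∇T‖ is µm ms⁻¹ =
    mm s⁻¹.  Vectors outside the electrode hull or faster than
    ``speed_cap_mm_s`` (near-flat gradient) are excluded.

    Returns (vx, vy, speed, valid_mask, mean, sem, n, mean_direction_deg).
    """
    dTdy, dTdx = np.gradient(T, grid_y, grid_x)
    grad2 = dTdx ** 2 + dTdy ** 2
    gradmag = np.sqrt(grad2)
    with np.errstate(divide="ignore", invalid="ignore"):
        speed = 1.0 / gradmag                    # µm/ms == mm/s
        vx = dTdx / grad2
        vy = dTdy / grad2
    xx, yy = np.meshgrid(grid_x, grid_y)
    try:
        hull = Delaunay(electrode_points)
        inside = hull.find_simplex(
            np.column_stack([xx.ravel(), yy.ravel()])) >= 0
        inside = inside.reshape(xx.shape)
    except QhullError as exc:
        raise ValidationError("electrode hull is degenerate") from exc
    valid = inside & np.isfinite(speed) & (speed <= speed_cap_mm_s)
    if not valid.any():
        raise DegenerateMapError(
            "no valid velocity vectors (flat or out-of-hull surface)")
    sp = speed[valid]
    mean = float(np.mean(sp))
    sem = float(np.std(sp, ddof=1) / np.sqrt(sp.size)) if sp.size > 1 else 0.0
    direction = float(np.degrees(np.arctan2(np.mean(vy[valid]),
                                            np.mean(vx[valid]))))
    return vx, vy, speed, valid, mean, sem, int(sp.size), direction


def activation_map(cluster: dict, layout: ElectrodeLayout,
                   beat_id: int = 0, method: str = "extremum",
                   rec: MultichannelRecording | None = None,
                   grid_step_um: float = 25.0,
                   speed_cap_mm_s: float = 200.0) -> ActivationMap:
    """Build the full activation map for one clustered beat."""
    times = activation_times(cluster, method=method, rec=rec)
    gx, gy, T = interpolate_surface(times, layout, grid_step_um)
    ids = list(times.keys())
    pts = layout.positions(ids)
    vx, vy, speed, valid, mean, sem, n, direction = velocity_field(
        gx, gy, T, pts, speed_cap_mm_s)
    return ActivationMap(beat_id=beat_id,
                         electrode_ids=np.asarray(ids),
                         electrode_xy_um=pts,
                         times_ms=np.array([times[c] for c in ids]),
                         grid_x=gx, grid_y=gy, surface_ms=T,
                         vx_mm_s=vx, vy_mm_s=vy, speed_mm_s=speed,
                         valid=valid, mean_speed_mm_s=mean,
                         sem_speed_mm_s=sem, n_vectors=n,
                         mean_direction_deg=direction)


@dataclass
class SpeedSummary:
    """Speeds pooled over all velocity vectors of all beats on one chip."""

    mean_speed_mm_s: float
    sem_speed_mm_s: float
    n_vectors: int
    n_beats: int
    mean_direction_deg: float
    per_beat_mean_mm_s: np.ndarray


def map_recording(rec: MultichannelRecording, method: str = "extremum",
                  grid_step_um: float = 25.0,
                  speed_cap_mm_s: float = 200.0,
                  threshold_k: float = 5.0,
                  refractory_ms: float = 80.0,
                  max_beats: int | None = None):
    """Detect, cluster, and map every beat of a recording.

    Returns (maps, summary) where the summary pools velocity vectors across
    beats before averaging.
    """
    trains = {}
    for i, cid in enumerate(rec.channel_ids):
        t, _ = detect_peaks(rec.data[i], rec.sample_rate_hz,
                            threshold_k=threshold_k,
                            refractory_ms=refractory_ms)
        trains[int(cid)] = t + rec.t0_s
    clusters = beat_cluster(trains)
    if max_beats is not None:
        clusters = clusters[:max_beats]
    maps = []
    speeds = []
    vx_sum = vy_sum = 0.0
    for b, cl in enumerate(clusters):
        try:
            m = activation_map(cl, rec.layout, beat_id=b, method=method,
                               rec=rec, grid_step_um=grid_step_um,
                               speed_cap_mm_s=speed_cap_mm_s)
        except (DegenerateMapError, ValidationError):
            continue
        maps.append(m)
        speeds.append(m.speed_mm_s[m.valid])
        vx_sum += float(np.sum(m.vx_mm_s[m.valid]))
        vy_sum += float(np.sum(m.vy_mm_s[m.valid]))
    if not speeds:
        raise DegenerateMapError("no beat produced a valid activation map")
    pooled = np.concatenate(speeds)
    summary = SpeedSummary(
        mean_speed_mm_s=float(np.mean(pooled)),
        sem_speed_mm_s=float(np.std(pooled, ddof=1) / np.sqrt(pooled.size))
        if pooled.size > 1 else 0.0,
        n_vectors=int(pooled.size),
        n_beats=len(maps),
        mean_direction_deg=float(np.degrees(np.arctan2(vy_sum, vx_sum))),
        per_beat_mean_mm_s=np.array([m.mean_speed_mm_s for m in maps]),
    )
    return maps, summary


def render_isochronal_map(amap: ActivationMap, path) -> None:
    """Render the activation surface as a filled-contour raster (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 5))
    xx, yy = np.meshgrid(amap.grid_x, amap.grid_y)
    cf = ax.contourf(xx, yy, amap.surface_ms, levels=15, cmap="viridis")
    ax.scatter(amap.electrode_xy_um[:, 0], amap.electrode_xy_um[:, 1],
               s=18, c="k", marker="s", zorder=3)
    fig.colorbar(cf, ax=ax, label="activation time (ms)")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
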