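"""Core domain types shared by every pipeline stage.

Conventions used throughout the package:

* time in seconds, t = 0 at recording start; stimulus protocols share the
  recording clock;
* electrode coordinates in micrometres, origin at the lower-left electrode,
  x rightward, y upward;
* voltages in microvolts, amplifier gain already divided out;
* irradiance in microwatts per square millimetre.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class FormatError(ValueError):
    """A container file is missing required metadata or malformed."""


class ValidationError(ValueError):
    """Inputs violate a documented precondition."""


# --------------------------------------------------------------------------
# electrode layout
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeLayout:
    """Planar electrode positions of a multi-electrode array.

    Parameters
    ----------
    electrode_ids
        Integer electrode labels, unique.
    x_um, y_um
        Positions in micrometres.
    is_reference
        Optional per-electrode reference flag (reference electrodes carry no
        biological signal).
    """

    electrode_ids: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    is_reference: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        ids = np.asarray(self.electrode_ids, dtype=int)
        x = np.asarray(self.x_um, dtype=float)
        y = np.asarray(self.y_um, dtype=float)
        if not (len(ids) == len(x) == len(y)):
            raise ValidationError("layout arrays must have equal length")
        if len(np.unique(ids)) != len(ids):
            raise ValidationError("electrode ids must be unique")
        pts = np.column_stack([x, y])
        if len(pts) > 1:
            from scipy.spatial.distance import pdist

            if pdist(pts).min() < 1.0:
                raise ValidationError("electrode positions closer than 1 µm")
        ref = self.is_reference
        if ref is None:
            ref = np.zeros(len(ids), dtype=bool)
        object.__setattr__(self, "electrode_ids", ids)
        object.__setattr__(self, "x_um", x)
        object.__setattr__(self, "y_um", y)
        object.__setattr__(self, "is_reference", np.asarray(ref, dtype=bool))

    def __len__(self) -> int:
        return len(self.electrode_ids)

    def positions(self, ids: Sequence[int] | None = None) -> np.ndarray:
        """(n, 2) array of x/y positions, optionally for a subset of ids."""
        if ids is None:
            return np.column_stack([self.x_um, self.y_um])
        index = {e: i for i, e in enumerate(self.electrode_ids)}
        rows = [index[i] for i in ids]
        return np.column_stack([self.x_um[rows], self.y_um[rows]])

    def subset(self, ids: Sequence[int]) -> "ElectrodeLayout":
        keep = np.isin(self.electrode_ids, np.asarray(ids, dtype=int))
        return ElectrodeLayout(
            self.electrode_ids[keep], self.x_um[keep], self.y_um[keep],
            self.is_reference[keep],
        )


def grid_layout(n_rows: int, n_cols: int, pitch_um: float = 200.0,
                start_id: int = 0) -> ElectrodeLayout:
    """Rectangular electrode grid, row-major ids, lower-left at the origin."""
    jj, ii = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    return ElectrodeLayout(
        electrode_ids=start_id + np.arange(n_rows * n_cols),
        x_um=(jj.ravel() * pitch_um).astype(float),
        y_um=(ii.ravel() * pitch_um).astype(float),
    )


def default_layout(pitch_um: float = 200.0) -> ElectrodeLayout:
    """Default 32-electrode layout: 6×6 grid minus corners, 200 µm pitch.

    Spans 1000 µm × 1000 µm, the interrogation area of the device this
    package models.
    """
    full = grid_layout(6, 6, pitch_um)
    corners = []
    for cx in (0.0, 5 * pitch_um):
        for cy in (0.0, 5 * pitch_um):
            hit = np.flatnonzero((full.x_um == cx) & (full.y_um == cy))
            corners.append(full.electrode_ids[hit[0]])
    keep = ~np.isin(full.electrode_ids, corners)
    ids = np.arange(int(keep.sum()))
    return ElectrodeLayout(ids, full.x_um[keep], full.y_um[keep])


# --------------------------------------------------------------------------
# recording container
# --------------------------------------------------------------------------

@dataclass
class MultichannelRecording:
    """Channels × samples extracellular voltage matrix.

    ``data`` holds microvolts; rows are aligned with ``channel_ids`` which in
    turn must be a subset of ``layout.electrode_ids``.
    """

    data: np.ndarray
    sample_rate_hz: float
    channel_ids: np.ndarray
    layout: ElectrodeLayout
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=np.float32))
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("recording must contain data")
        if self.data.shape[0] != len(self.channel_ids):
            raise ValidationError(
                f"data has {self.data.shape[0]} channels but "
                f"{len(self.channel_ids)} channel ids were given")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        missing = set(self.channel_ids) - set(self.layout.electrode_ids)
        if missing:
            raise ValidationError(
                f"channel ids {sorted(missing)} are not in the layout")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.sample_rate_hz

    def channel(self, channel_id: int) -> np.ndarray:
        idx = np.flatnonzero(self.channel_ids == channel_id)
        if len(idx) == 0:
            raise KeyError(f"no channel {channel_id}")
        return self.data[idx[0]]

    def subset(self, ids: Sequence[int]) -> "MultichannelRecording":
        ids = np.asarray(ids, dtype=int)
        keep = np.isin(self.channel_ids, ids)
        if not keep.any():
            raise ValidationError("subset would leave no channels")
        return MultichannelRecording(
            data=self.data[keep],
            sample_rate_hz=self.sample_rate_hz,
            channel_ids=self.channel_ids[keep],
            layout=self.layout.subset(self.channel_ids[keep]),
            t0_s=self.t0_s,
        )


# --------------------------------------------------------------------------
# stimulus protocol
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StimulusProtocol:
    """Piecewise-constant irradiance schedule.

    Epochs are (t_start_s, t_end_s, irradiance_uW_mm2) triples; outside every
    epoch the irradiance is zero.  ``irradiance_at`` is right-continuous.
    """

    epochs: tuple

    def __post_init__(self) -> None:
        eps = sorted((float(a), float(b), float(i)) for a, b, i in self.epochs)
        for a, b, i in eps:
            if b <= a:
                raise ValidationError(f"epoch ({a}, {b}) has non-positive length")
            if i < 0:
                raise ValidationError("irradiance must be non-negative")
        for (a0, b0, _), (a1, _, _) in zip(eps, eps[1:]):
            if a1 < b0:
                raise ValidationError(
                    f"epochs overlap at t = {a1} s (previous ends {b0} s)")
        object.__setattr__(self, "epochs", tuple(eps))

    @property
    def duration_s(self) -> float:
        return self.epochs[-1][1] if self.epochs else 0.0

    def irradiance_at(self, t_s) -> np.ndarray:
        """Irradiance I(t), right-continuous, 0 outside all epochs."""
        t = np.asarray(t_s, dtype=float)
        out = np.zeros_like(t)
        for a, b, irr in self.epochs:
            out[(t >= a) & (t < b)] = irr
        return out if out.ndim else float(out)

    def boundaries(self) -> np.ndarray:
        """Sorted unique epoch boundary times."""
        pts = set()
        for a, b, _ in self.epochs:
            pts.add(a)
            pts.add(b)
        return np.array(sorted(pts))

    @staticmethod
    def constant(irradiance: float, duration_s: float) -> "StimulusProtocol":
        return StimulusProtocol(((0.0, duration_s, irradiance),))


# --------------------------------------------------------------------------
# QC report
# --------------------------------------------------------------------------

@dataclass
class QCReport:
    """Per-channel signal-quality metrics and the inclusion decision.

    ``included`` is True iff snr >= snr_threshold (default 2, the exclusion
    rule applied to every filtered recording before analysis).
    """

    channel_ids: np.ndarray
    snr: np.ndarray
    rms_noise_uV: np.ndarray
    peak_amplitude_uV: np.ndarray
    n_spikes: np.ndarray
    snr_threshold: float = 2.0
    included: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        self.snr = np.asarray(self.snr, dtype=float)
        self.rms_noise_uV = np.asarray(self.rms_noise_uV, dtype=float)
        self.peak_amplitude_uV = np.asarray(self.peak_amplitude_uV, dtype=float)
        self.n_spikes = np.asarray(self.n_spikes, dtype=int)
        if self.included is None:
            self.included = self.snr >= self.snr_threshold
        self.included = np.asarray(self.included, dtype=bool)

    @property
    def n_included(self) -> int:
        return int(self.included.sum())

    @property
    def n_excluded(self) -> int:
        return int((~self.included).sum())

    def included_ids(self) -> np.ndarray:
        return self.channel_ids[self.included]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "channel_id": self.channel_ids,
            "snr": self.snr,
            "rms_noise_uV": self.rms_noise_uV,
            "peak_amplitude_uV": self.peak_amplitude_uV,
            "n_spikes": self.n_spikes,
            "included": self.included,
        })
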