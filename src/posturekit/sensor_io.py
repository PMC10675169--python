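"""Ingestion and synchronization of per-sensor IMU streams.

Each body-worn sensor reports a six-component sample stream: three-axis
acceleration in g and three-axis angular velocity in deg/s.  Seven sensors
(sternum, both wrists, both thighs, both lower legs) at 50 Hz make up a full
recording; this module reads per-sensor CSV files, clips values to the
configured measuring ranges (+/-8 g, +/-1000 deg/s -- saturation, not
rejection), resamples each stream onto a uniform grid and intersects the
seven time spans into a single synchronized recording.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

SAMPLE_RATE_HZ = 50.0
ACC_RANGE_G = 8.0
GYR_RANGE_DPS = 1000.0

#: Gaps longer than this (seconds) are not bridged by interpolation.
MAX_INTERPOLATED_GAP_S = 0.5

CSV_COLUMNS = ("timestamp", "acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")


class SensorLocation(enum.Enum):
    """The seven body placements, in canonical row order."""

    STERNUM = 0
    LEFT_WRIST = 1
    RIGHT_WRIST = 2
    LEFT_THIGH = 3
    RIGHT_THIGH = 4
    LEFT_LOWER_LEG = 5
    RIGHT_LOWER_LEG = 6


#: Canonical sensor order used for frame rows and stacked arrays.
SENSOR_ORDER: tuple[SensorLocation, ...] = tuple(SensorLocation)


class SensorIOError(Exception):
    """Base class for ingestion and synchronization failures."""


class FormatError(SensorIOError):
    pass


class InsufficientDataError(SensorIOError):
    pass


class ConfigurationError(SensorIOError):
    pass


@dataclass
class SampleSeries:
    """One sensor's time-stamped stream of 6-component samples.

    ``acc`` is (n, 3) in g, ``gyr`` is (n, 3) in deg/s, ``timestamps`` is
    (n,) seconds, strictly increasing.
    """

    location: SensorLocation
    timestamps: np.ndarray
    acc: np.ndarray
    gyr: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.acc = np.asarray(self.acc, dtype=np.float64)
        self.gyr = np.asarray(self.gyr, dtype=np.float64)
        n = self.timestamps.shape[0]
        if self.acc.shape != (n, 3) or self.gyr.shape != (n, 3):
            raise FormatError(
                f"component arrays must be ({n}, 3); got acc {self.acc.shape}, gyr {self.gyr.shape}"
            )
        if n > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise FormatError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return self.timestamps.shape[0]

    @property
    def values(self) -> np.ndarray:
        """(n, 6) array: acc x/y/z then gyr x/y/z."""
        return np.concatenate([self.acc, self.gyr], axis=1)


@dataclass
class SynchronizedRecording:
    """All seven sensors resampled onto one shared uniform grid.

    ``data`` has shape (7, n, 6) with sensors in :data:`SENSOR_ORDER` and
    components ordered acc x/y/z, gyr x/y/z.
    """

    start_time: float
    rate: float
    data: np.ndarray
    locations: tuple[SensorLocation, ...] = field(default=SENSOR_ORDER)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.locations) or self.data.shape[2] != 6:
            raise FormatError(f"data must be ({len(self.locations)}, n, 6); got {self.data.shape}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    @property
    def timestamps(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.rate

    def series(self, location: SensorLocation) -> SampleSeries:
        idx = self.locations.index(location)
        block = self.data[idx]
        return SampleSeries(location, self.timestamps, block[:, :3], block[:, 3:])


def clip_to_range(acc: np.ndarray, gyr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Saturate values at the configured full-scale ranges."""
    return (
        np.clip(acc, -ACC_RANGE_G, ACC_RANGE_G),
        np.clip(gyr, -GYR_RANGE_DPS, GYR_RANGE_DPS),
    )


def _normalize_timestamps(ts: np.ndarray) -> np.ndarray:
    # Vendors export either epoch milliseconds or seconds; tell them apart
    # by magnitude (epoch ms are > 1e10 for any modern date).
    if ts.size and np.nanmax(np.abs(ts)) > 1e10:
        return ts / 1000.0
    return ts


def load_sensor_csv(path: str | Path, location: SensorLocation) -> SampleSeries:
    """Read one sensor's CSV stream, clip to range, drop duplicate timestamps.

    The file must carry a header with a ``timestamp`` column and the six
    component columns ``acc_x .. gyr_z``.  Out-of-range values are clipped
    (sensor saturation); rows sharing a timestamp keep the first occurrence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise InsufficientDataError(f"{path}: empty sensor file") from None
    if df.empty:
        raise InsufficientDataError(f"{path}: no samples")
    for col in CSV_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    values = np.empty((len(df), len(CSV_COLUMNS)), dtype=np.float64)
    for j, col in enumerate(CSV_COLUMNS):
        converted = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=np.float64)
        bad = np.nonzero(np.isnan(converted) & ~pd.isna(df[col]).to_numpy())[0]
        if bad.size:
            # +2: one for the header line, one for 0-based indexing
            raise FormatError(f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}")
        if np.any(np.isnan(converted)):
            raise FormatError(f"{path}: missing value in column {col!r}")
        values[:, j] = converted

    ts = _normalize_timestamps(values[:, 0])
    order = np.argsort(ts, kind="stable")
    ts, comps = ts[order], values[order, 1:]
    keep = np.ones(len(ts), dtype=bool)
    keep[1:] = np.diff(ts) > 0  # collapse duplicates, first kept
    ts, comps = ts[keep], comps[keep]
    acc, gyr = clip_to_range(comps[:, :3], comps[:, 3:])
    return SampleSeries(location, ts, acc, gyr)


def resample_to_grid(series: SampleSeries, rate: float = SAMPLE_RATE_HZ) -> SampleSeries:
    """Linearly interpolate a stream onto a uniform 1/rate grid.

    The grid spans the input range only -- no extrapolation.  Grid points are
    placed at ``ceil(t0*rate)/rate .. floor(t1*rate)/rate`` so that two
    streams resampled at the same rate share phase-aligned timestamps.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if len(series) < 2:
        raise InsufficientDataError("resampling needs at least 2 samples")
    t0, t1 = series.timestamps[0], series.timestamps[-1]
    k0 = int(np.ceil(t0 * rate - 1e-9))
    k1 = int(np.floor(t1 * rate + 1e-9))
    if k1 < k0:
        raise InsufficientDataError("input span contains no grid point")
    grid = np.arange(k0, k1 + 1) / rate
    out = np.empty((grid.size, 6))
    vals = series.values
    for j in range(6):
        out[:, j] = np.interp(grid, series.timestamps, vals[:, j])
    return SampleSeries(series.location, grid, out[:, :3], out[:, 3:])


def split_on_gaps(series: SampleSeries, max_gap: float = MAX_INTERPOLATED_GAP_S) -> list[SampleSeries]:
    """Split a stream wherever consecutive samples are more than ``max_gap``
    seconds apart; gaps at or under the threshold are left for interpolation."""
    if len(series) == 0:
        return []
    breaks = np.nonzero(np.diff(series.timestamps) > max_gap)[0] + 1
    segments = []
    for lo, hi in zip(np.r_[0, breaks], np.r_[breaks, len(series)]):
        segments.append(
            SampleSeries(series.location, series.timestamps[lo:hi], series.acc[lo:hi], series.gyr[lo:hi])
        )
    return segments


def gap_list(series: SampleSeries, max_gap: float = MAX_INTERPOLATED_GAP_S) -> list[tuple[float, float]]:
    """(start, length) of every inter-sample gap exceeding ``max_gap`` seconds."""
    d = np.diff(series.timestamps)
    idx = np.nonzero(d > max_gap)[0]
    return [(float(series.timestamps[i]), float(d[i])) for i in idx]


def synchronize(series_set: list[SampleSeries] | dict[SensorLocation, SampleSeries],
                rate: float = SAMPLE_RATE_HZ) -> SynchronizedRecording:
    """Resample all seven streams onto the 50 Hz grid over their common span.

    Requires each of the seven locations exactly once and at least one second
    of overlap.  The order the series are supplied in does not matter; the
    output always follows :data:`SENSOR_ORDER`.
    """
    if isinstance(series_set, dict):
        series_list = list(series_set.values())
    else:
        series_list = list(series_set)
    by_loc: dict[SensorLocation, SampleSeries] = {}
    for s in series_list:
        if s.location in by_loc:
            raise ConfigurationError(f"duplicate sensor location: {s.location.name}")
        by_loc[s.location] = s
    missing = [loc.name for loc in SENSOR_ORDER if loc not in by_loc]
    if missing:
        raise ConfigurationError(f"missing sensor locations: {', '.join(missing)}")

    t_start = max(s.timestamps[0] for s in by_loc.values())
    t_end = min(s.timestamps[-1] for s in by_loc.values())
    if t_end - t_start < 1.0:
        raise InsufficientDataError(
            f"overlapping span is {max(t_end - t_start, 0):.3f} s; need >= 1 s"
        )
    k0 = int(np.ceil(t_start * rate - 1e-9))
    k1 = int(np.floor(t_end * rate + 1e-9))
    grid = np.arange(k0, k1 + 1) / rate
    data = np.empty((len(SENSOR_ORDER), grid.size, 6))
    for i, loc in enumerate(SENSOR_ORDER):
        s = by_loc[loc]
        vals = s.values
        for j in range(6):
            data[i, :, j] = np.interp(grid, s.timestamps, vals[:, j])
    return SynchronizedRecording(start_time=grid[0], rate=rate, data=data)


def save_recording(recording: SynchronizedRecording, path: str | Path) -> None:
    """Write a synchronized recording to a chunked HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data, chunks=True, compression="gzip")
        f.attrs["start_time"] = recording.start_time
        f.attrs["rate"] = recording.rate
        f.attrs["locations"] = [loc.name for loc in recording.locations]


def load_recording(path: str | Path) -> SynchronizedRecording:
    with h5py.File(path, "r") as f:
        locations = tuple(SensorLocation[name] for name in f.attrs["locations"])
        return SynchronizedRecording(
            start_time=float(f.attrs["start_time"]),
            rate=float(f.attrs["rate"]),
            data=f["data"][...],
            locations=locations,
        )
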