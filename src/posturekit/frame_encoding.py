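"""Two-channel image encoding of one-second sensor windows.

One second of a synchronized 7-sensor recording at 50 Hz becomes a
2 x 21 x 50 value grid: channel 0 holds the accelerometer components,
channel 1 the gyroscope components; row ``3*sensor + component`` holds one
component (x, y, z) of one sensor in canonical order; each column is one
sample.  Values are normalized by the full-scale ranges (+/-8 g,
+/-1000 deg/s) into [-1, 1].  Presented as an image this is resolution
50 x 21 x 2 in column x row x channel order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .labels import LABELS
from .sensor_io import (
    ACC_RANGE_G,
    GYR_RANGE_DPS,
    SAMPLE_RATE_HZ,
    SENSOR_ORDER,
    FormatError,
    SynchronizedRecording,
)

N_CHANNELS = 2
N_ROWS = 3 * len(SENSOR_ORDER)  # 21
N_COLUMNS = int(SAMPLE_RATE_HZ)  # 50
FRAME_SHAPE = (N_CHANNELS, N_ROWS, N_COLUMNS)

#: Recorded in frame/dataset metadata so a model checkpoint can refuse
#: frames built under a different row convention.
SENSOR_ORDER_NAMES: tuple[str, ...] = tuple(loc.name for loc in SENSOR_ORDER)


@dataclass
class EncodedFrame:
    """One-second window as a normalized 2-channel value grid."""

    values: np.ndarray
    start_time: float
    sensor_order: tuple[str, ...] = field(default=SENSOR_ORDER_NAMES)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != FRAME_SHAPE:
            raise FormatError(f"frame must have shape {FRAME_SHAPE}; got {self.values.shape}")


def encode_window(recording: SynchronizedRecording, start: float) -> EncodedFrame:
    """Encode the one-second window beginning at ``start`` (seconds).

    Accelerometer values are divided by 8 g, gyroscope values by 1000 deg/s;
    an input at exactly full scale maps to exactly +/-1.
    """
    offset = (start - recording.start_time) * recording.rate
    i0 = int(round(offset))
    if abs(offset - i0) > 1e-6:
        raise ValueError(f"window start {start} is not on the sample grid")
    if i0 < 0 or i0 + N_COLUMNS > recording.n_samples:
        raise ValueError(
            f"window [{start}, {start + 1}) extends outside the recording"
        )
    block = recording.data[:, i0 : i0 + N_COLUMNS, :]  # (7, 50, 6)
    values = np.empty(FRAME_SHAPE)
    # (7, 50, 3) -> rows 3*sensor + component, columns = samples
    values[0] = (block[:, :, :3] / ACC_RANGE_G).transpose(0, 2, 1).reshape(N_ROWS, N_COLUMNS)
    values[1] = (block[:, :, 3:] / GYR_RANGE_DPS).transpose(0, 2, 1).reshape(N_ROWS, N_COLUMNS)
    order = tuple(loc.name for loc in recording.locations)
    return EncodedFrame(values, start_time=float(start), sensor_order=order)


def window_stream(recording: SynchronizedRecording, hop: float = 1.0) -> list[EncodedFrame]:
    """All full one-second windows at starts 0, hop, 2*hop, ... from the
    recording start; a trailing partial window is dropped."""
    if hop <= 0:
        raise ValueError("hop must be positive")
    if recording.duration < 1.0:
        raise ValueError(f"recording of {recording.duration:.2f} s is shorter than one window")
    n = int(np.floor((recording.duration - 1.0) / hop + 1e-9)) + 1
    return [encode_window(recording, recording.start_time + k * hop) for k in range(n)]


def decode_frame(frame: EncodedFrame) -> np.ndarray:
    """Invert the encoding: (7, 50, 6) raw sample block in g and deg/s."""
    vals = np.asarray(frame.values, dtype=np.float64)
    if vals.shape != FRAME_SHAPE:
        raise FormatError(f"frame must have shape {FRAME_SHAPE}; got {vals.shape}")
    n_sensors = len(SENSOR_ORDER)
    acc = (vals[0] * ACC_RANGE_G).reshape(n_sensors, 3, N_COLUMNS).transpose(0, 2, 1)
    gyr = (vals[1] * GYR_RANGE_DPS).reshape(n_sensors, 3, N_COLUMNS).transpose(0, 2, 1)
    return np.concatenate([acc, gyr], axis=2)


@dataclass
class FrameDataset:
    """Encoded frames paired with ground-truth label vectors."""

    frames: np.ndarray  # (n, 2, 21, 50) float32
    labels: np.ndarray  # (n, 8) uint8
    sensor_order: tuple[str, ...] = field(default=SENSOR_ORDER_NAMES)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.frames.ndim != 4 or self.frames.shape[1:] != FRAME_SHAPE:
            raise FormatError(f"frames must be (n,) + {FRAME_SHAPE}; got {self.frames.shape}")
        if self.labels.shape != (self.frames.shape[0], len(LABELS)):
            raise FormatError(
                f"labels must be ({self.frames.shape[0]}, {len(LABELS)}); got {self.labels.shape}"
            )

    def __len__(self) -> int:
        return self.frames.shape[0]


def save_frame_dataset(dataset: FrameDataset, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=dataset.frames, chunks=True, compression="gzip")
        f.create_dataset("labels", data=dataset.labels, chunks=True)
        f.attrs["sensor_order"] = list(dataset.sensor_order)
        f.attrs["labels_order"] = list(LABELS)
        f.attrs["acc_range_g"] = ACC_RANGE_G
        f.attrs["gyr_range_dps"] = GYR_RANGE_DPS
        f.attrs["rate_hz"] = SAMPLE_RATE_HZ


def load_frame_dataset(path: str | Path) -> FrameDataset:
    with h5py.File(path, "r") as f:
        return FrameDataset(
            frames=f["frames"][...],
            labels=f["labels"][...],
            sensor_order=tuple(f.attrs["sensor_order"]),
        )
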