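"""Scripted multi-sensor IMU session simulator with ground-truth labels.

The supervised dataset this package trains on is built from scripted,
timestamped movement: a script lists whole-second segments, each a posture
or walking plus a set of moving extremities, and the simulator renders the
seven 50 Hz sensor streams that a wearer following the script would produce.
Because the script *is* the annotation, no manual labelling is needed.

The kinematic model is deliberately simple but physically grounded:

* the accelerometer of every sensor reads a posture-specific gravity unit
  vector (thigh long-axis vertical when standing, horizontal when sitting or
  lying; the sternum separates lying from upright postures), plus activity
  oscillation, plus white noise;
* the gyroscope reads activity oscillation plus white noise;
* walking adds antiphase periodic gait components on the left/right thigh
  and lower-leg sensors and a small vertical bob on the sternum;
* a moving extremity adds a band-limited (2-5 Hz) multi-sine burst on its
  wrist or leg sensors.

All amplitudes sit comfortably inside the +/-8 g / +/-1000 deg/s measuring
ranges, so no clipping occurs.  Everything is driven by one seeded
generator: the same script and seed reproduce bit-identical streams.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotation import AnnotationTrack
from .frame_encoding import FRAME_SHAPE, FrameDataset, SENSOR_ORDER_NAMES
from .labels import (
    EXTREMITY_LABELS,
    LABEL_INDEX,
    N_LABELS,
    POSTURE_LABELS,
    admissible_combinations,
    label_vector,
)
from .sensor_io import (
    ACC_RANGE_G,
    GYR_RANGE_DPS,
    SAMPLE_RATE_HZ,
    SENSOR_ORDER,
    SampleSeries,
    SensorLocation,
    SynchronizedRecording,
)


class ScriptError(ValueError):
    """A script segment violates the label scheme."""


@dataclass(frozen=True)
class ScriptSegment:
    """A whole-second stretch of one posture/walk state and moving extremities."""

    duration: int
    posture: str
    extremities: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not isinstance(self.duration, int) or self.duration < 1:
            raise ScriptError(f"segment duration must be an integer >= 1; got {self.duration!r}")
        if self.posture not in POSTURE_LABELS:
            raise ScriptError(f"unknown posture/walk state: {self.posture!r}")
        object.__setattr__(self, "extremities", frozenset(self.extremities))
        unknown = self.extremities - set(EXTREMITY_LABELS)
        if unknown:
            raise ScriptError(f"unknown extremity labels: {sorted(unknown)}")
        if self.posture == "WA" and not {"RL", "LL"} <= self.extremities:
            raise ScriptError("walking segments must include both lower extremities (RL and LL)")

    def label_row(self) -> np.ndarray:
        return label_vector(self.posture, tuple(self.extremities))


@dataclass(frozen=True)
class MotionModelConfig:
    """Kinematic and noise parameters of the simulator.

    Defaults are physiologically plausible magnitudes, well separated from
    the noise floor: a comfortable gait cadence of 1.8 Hz with 200 deg/s leg
    swing, voluntary extremity movement as 2-5 Hz bursts, and sensor noise
    two orders of magnitude below the activity signals.
    """

    gait_freq_hz: float = 1.8
    gait_gyro_amp_dps: float = 200.0
    gait_acc_amp_g: float = 0.4
    sternum_bob_amp_g: float = 0.1
    burst_band_hz: tuple[float, float] = (2.0, 5.0)
    burst_n_sines: int = 3
    burst_gyro_amp_dps: float = 120.0
    burst_acc_amp_g: float = 0.3
    noise_sigma_acc_g: float = 0.02
    noise_sigma_gyr_dps: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma_acc_g < 0 or self.noise_sigma_gyr_dps < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not (0 < self.gait_gyro_amp_dps + self.burst_gyro_amp_dps < GYR_RANGE_DPS):
            raise ValueError("gyro amplitudes must stay within the measuring range")
        if not (0 < 1.0 + self.gait_acc_amp_g + self.burst_acc_amp_g < ACC_RANGE_G):
            raise ValueError("accelerometer amplitudes must stay within the measuring range")


# Gravity direction (unit vector in the sensor frame) per placement category
# and posture.  The x axis is the sensor's long/anterior axis, z the axis
# aligned with gravity when the wearer stands.  These orientations are what
# make postures separable: thighs discriminate sitting from standing, the
# sternum discriminates lying from everything upright.
_CATEGORY: dict[SensorLocation, str] = {
    SensorLocation.STERNUM: "sternum",
    SensorLocation.LEFT_WRIST: "wrist",
    SensorLocation.RIGHT_WRIST: "wrist",
    SensorLocation.LEFT_THIGH: "thigh",
    SensorLocation.RIGHT_THIGH: "thigh",
    SensorLocation.LEFT_LOWER_LEG: "lower_leg",
    SensorLocation.RIGHT_LOWER_LEG: "lower_leg",
}

_X = np.array([1.0, 0.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])

GRAVITY_TABLE: dict[tuple[str, str], np.ndarray] = {
    # lying: every sensor sees gravity along its anterior axis
    ("sternum", "LY"): _X, ("wrist", "LY"): _X, ("thigh", "LY"): _X, ("lower_leg", "LY"): _X,
    # sitting: trunk and shanks vertical, thighs and forearms horizontal
    ("sternum", "SI"): _Z, ("wrist", "SI"): _X, ("thigh", "SI"): _X, ("lower_leg", "SI"): _Z,
    # standing and walking: everything vertical
    ("sternum", "ST"): _Z, ("wrist", "ST"): _Z, ("thigh", "ST"): _Z, ("lower_leg", "ST"): _Z,
    ("sternum", "WA"): _Z, ("wrist", "WA"): _Z, ("thigh", "WA"): _Z, ("lower_leg", "WA"): _Z,
}

#: Which sensors an extremity-movement label drives.
EXTREMITY_SENSORS: dict[str, tuple[SensorLocation, ...]] = {
    "RH": (SensorLocation.RIGHT_WRIST,),
    "LH": (SensorLocation.LEFT_WRIST,),
    "RL": (SensorLocation.RIGHT_THIGH, SensorLocation.RIGHT_LOWER_LEG),
    "LL": (SensorLocation.LEFT_THIGH, SensorLocation.LEFT_LOWER_LEG),
}

_LEFT_LEGS = (SensorLocation.LEFT_THIGH, SensorLocation.LEFT_LOWER_LEG)
_RIGHT_LEGS = (SensorLocation.RIGHT_THIGH, SensorLocation.RIGHT_LOWER_LEG)

_RATE = int(SAMPLE_RATE_HZ)


def validate_script(script: list[ScriptSegment]) -> None:
    if not script:
        raise ScriptError("script must contain at least one segment")


def _burst(t: np.ndarray, rng: np.random.Generator, amp: float,
           band: tuple[float, float], n_sines: int) -> np.ndarray:
    """Band-limited multi-sine burst with peak amplitude bounded by ``amp``."""
    freqs = rng.uniform(band[0], band[1], size=n_sines)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_sines)
    out = np.zeros_like(t)
    for f, p in zip(freqs, phases):
        out += np.sin(2.0 * np.pi * f * t + p)
    return (amp / n_sines) * out


def _simulate_arrays(script: list[ScriptSegment], config: MotionModelConfig,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Render a script into a (7, n, 6) sample block and per-second labels."""
    validate_script(script)
    total_s = sum(seg.duration for seg in script)
    n = total_s * _RATE
    data = np.zeros((len(SENSOR_ORDER), n, 6))
    labels = np.zeros((total_s, N_LABELS), dtype=np.uint8)

    loc_index = {loc: i for i, loc in enumerate(SENSOR_ORDER)}
    sec = 0
    offset = 0
    for seg in script:
        m = seg.duration * _RATE
        t = np.arange(m) / SAMPLE_RATE_HZ
        sl = slice(offset, offset + m)
        labels[sec : sec + seg.duration] = seg.label_row()

        for loc in SENSOR_ORDER:
            g = GRAVITY_TABLE[(_CATEGORY[loc], seg.posture)]
            data[loc_index[loc], sl, :3] += g  # gravity, in g

        if seg.posture == "WA":
            w = 2.0 * np.pi * config.gait_freq_hz
            for phase, legs in ((0.0, _LEFT_LEGS), (np.pi, _RIGHT_LEGS)):
                swing = np.sin(w * t + phase)
                for loc in legs:
                    i = loc_index[loc]
                    data[i, sl, 4] += config.gait_gyro_amp_dps * swing  # gyr y: sagittal swing
                    data[i, sl, 3] += config.gait_acc_amp_g * swing     # fore-aft acceleration
            i = loc_index[SensorLocation.STERNUM]
            data[i, sl, 5] += config.sternum_bob_amp_g * np.sin(2.0 * w * t)  # vertical bob at 2x cadence

        # Draw bursts in canonical extremity order so the draw sequence is
        # invariant under a left/right mirror of the script.
        for ext in EXTREMITY_LABELS:
            if ext not in seg.extremities:
                continue
            for loc in EXTREMITY_SENSORS[ext]:
                i = loc_index[loc]
                for axis in range(3):
                    data[i, sl, 3 + axis] += _burst(
                        t, rng, config.burst_gyro_amp_dps, config.burst_band_hz, config.burst_n_sines
                    )
                    data[i, sl, axis] += _burst(
                        t, rng, config.burst_acc_amp_g, config.burst_band_hz, config.burst_n_sines
                    )
        sec += seg.duration
        offset += m

    if config.noise_sigma_acc_g > 0:
        data[:, :, :3] += rng.normal(0.0, config.noise_sigma_acc_g, size=data[:, :, :3].shape)
    if config.noise_sigma_gyr_dps > 0:
        data[:, :, 3:] += rng.normal(0.0, config.noise_sigma_gyr_dps, size=data[:, :, 3:].shape)
    return data, labels


def simulate_session(script: list[ScriptSegment], config: MotionModelConfig
                     ) -> tuple[dict[SensorLocation, SampleSeries], AnnotationTrack]:
    """Render a script into seven 50 Hz sample streams plus the truth track."""
    rng = np.random.default_rng(config.seed)
    data, labels = _simulate_arrays(script, config, rng)
    timestamps = np.arange(data.shape[1]) / SAMPLE_RATE_HZ
    streams = {
        loc: SampleSeries(loc, timestamps, data[i, :, :3], data[i, :, 3:])
        for i, loc in enumerate(SENSOR_ORDER)
    }
    track = AnnotationTrack.from_labels(labels, start_time=0.0, annotator_id="script")
    return streams, track


def session_recording(streams: dict[SensorLocation, SampleSeries]) -> SynchronizedRecording:
    """Stack already-aligned simulator streams into a recording."""
    data = np.stack([streams[loc].values for loc in SENSOR_ORDER])
    return SynchronizedRecording(
        start_time=float(streams[SENSOR_ORDER[0]].timestamps[0]),
        rate=SAMPLE_RATE_HZ,
        data=data,
    )


def _encode_block(data: np.ndarray, n_seconds: int) -> np.ndarray:
    """Vectorized equivalent of encode_window over consecutive seconds."""
    acc = data[:, : n_seconds * _RATE, :3].reshape(len(SENSOR_ORDER), n_seconds, _RATE, 3)
    gyr = data[:, : n_seconds * _RATE, 3:].reshape(len(SENSOR_ORDER), n_seconds, _RATE, 3)
    ch0 = (acc / ACC_RANGE_G).transpose(1, 0, 3, 2).reshape(n_seconds, FRAME_SHAPE[1], _RATE)
    ch1 = (gyr / GYR_RANGE_DPS).transpose(1, 0, 3, 2).reshape(n_seconds, FRAME_SHAPE[1], _RATE)
    return np.stack([ch0, ch1], axis=1).astype(np.float32)


def generate_balanced_dataset(config: MotionModelConfig | None = None,
                              n_windows: int = 10_000) -> FrameDataset:
    """Simulate and encode a balanced labeled dataset of one-second frames.

    Windows are allocated as evenly as possible (counts differ by at most
    one) over the 52 admissible label combinations; each combination is
    rendered as its own scripted segment.
    """
    config = config or MotionModelConfig()
    combos = admissible_combinations()
    if n_windows < len(combos):
        raise ValueError(
            f"n_windows must be >= {len(combos)} (one per admissible combination); got {n_windows}"
        )
    base, extra = divmod(n_windows, len(combos))
    rng = np.random.default_rng(config.seed)

    frames = np.empty((n_windows,) + FRAME_SHAPE, dtype=np.float32)
    labels = np.empty((n_windows, N_LABELS), dtype=np.uint8)
    row = 0
    for k, combo in enumerate(combos):
        count = base + (1 if k < extra else 0)
        posture = POSTURE_LABELS[int(np.argmax(combo[:4]))]
        extremities = frozenset(
            name for name in EXTREMITY_LABELS if combo[LABEL_INDEX[name]]
        )
        seg = ScriptSegment(duration=count, posture=posture, extremities=extremities)
        data, seg_labels = _simulate_arrays([seg], config, rng)
        frames[row : row + count] = _encode_block(data, count)
        labels[row : row + count] = seg_labels
        row += count
    return FrameDataset(frames=frames, labels=labels, sensor_order=SENSOR_ORDER_NAMES)


#: Posture priority used when random flips leave several posture bits set:
#: the most specific/active state wins.
_POSTURE_PRIORITY = ("WA", "ST", "SI", "LY")


def simulate_annotator(truth: AnnotationTrack, flip_rate: float, seed: int) -> AnnotationTrack:
    """A noisy virtual annotator: flips each per-second label independently.

    After flipping, posture exclusivity is re-imposed by keeping the
    highest-priority surviving posture (walking > standing > sitting >
    lying); a second may end up with no posture at all, as real human tracks
    can.  Unlabelled seconds stay unlabelled.
    """
    if not 0.0 <= flip_rate <= 1.0:
        raise ValueError("flip_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = truth.labels.copy()
    flips = rng.random(labels.shape) < flip_rate
    flips[truth.unlabelled] = False
    labels = labels ^ flips.astype(np.uint8)
    # re-impose posture exclusivity: highest-priority surviving posture wins
    priority_idx = [LABEL_INDEX[name] for name in _POSTURE_PRIORITY]
    postures = labels[:, :4]
    keep = np.zeros_like(postures)
    remaining = np.ones(labels.shape[0], dtype=bool)
    for idx in priority_idx:
        sel = remaining & (postures[:, idx] == 1)
        keep[sel, idx] = 1
        remaining &= ~sel
    labels[:, :4] = keep
    return AnnotationTrack(labels, truth.unlabelled.copy(),
                           start_time=truth.start_time, annotator_id=f"sim-flip{flip_rate}")


def load_script(path: str | Path) -> list[ScriptSegment]:
    """Read a script from a JSON list of {duration, posture, extremities}."""
    entries = json.loads(Path(path).read_text())
    if not isinstance(entries, list):
        raise ScriptError("script file must contain a JSON list of segments")
    return [
        ScriptSegment(
            duration=int(e["duration"]),
            posture=str(e["posture"]).upper(),
            extremities=frozenset(str(x).upper() for x in e.get("extremities", [])),
        )
        for e in entries
    ]


def save_script(script: list[ScriptSegment], path: str | Path) -> None:
    entries = [
        {"duration": seg.duration, "posture": seg.posture,
         "extremities": sorted(seg.extremities, key=EXTREMITY_LABELS.index)}
        for seg in script
    ]
    Path(path).write_text(json.dumps(entries, indent=2) + "\n")
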