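"""Credibility checking and 24-h behavior summaries.

Credible label sequences satisfy two per-second rules: at most one of
lying / sitting / standing / walking is set, and a walking second carries
both lower-extremity labels.  Summaries aggregate a per-second track into
posture durations and percentages, a 4x4 posture-transition matrix,
run-length timelines and left/right extremity-usage ratios; a wear-time
report judges whether a recording meets the continuous >=24 h target.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import AnnotationTrack
from .labels import EXTREMITY_LABELS, POSTURE_LABELS

RULE_POSTURE_EXCLUSIVE = "posture-exclusivity"
RULE_WALKING_LEGS = "walking-lower-extremities"

#: Gaps longer than this many seconds break the continuity requirement.
DEFAULT_CONTINUITY_GAP_S = 60.0
FULL_DAY_S = 24 * 3600.0

#: State code for seconds carrying no posture/walk label (or unlabelled).
UNLABELLED_STATE = "UNLABELLED"


@dataclass
class CredibilityReport:
    total_seconds: int
    violations: list[tuple[int, str, str]] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations


def check_credibility(track: AnnotationTrack) -> CredibilityReport:
    """Scan a track for per-second rule violations, in second order."""
    if len(track) == 0:
        raise ValueError("cannot check an empty track")
    labels = track.labels
    violations: list[tuple[int, str, str]] = []
    posture_count = labels[:, :4].sum(axis=1)
    for sec in range(len(track)):
        if track.unlabelled[sec]:
            continue
        if posture_count[sec] > 1:
            names = [POSTURE_LABELS[j] for j in range(4) if labels[sec, j]]
            violations.append(
                (sec, RULE_POSTURE_EXCLUSIVE, f"{'+'.join(names)} set simultaneously")
            )
        if labels[sec, 3] == 1 and not (labels[sec, 6] == 1 and labels[sec, 7] == 1):
            missing = [n for n, j in (("RL", 6), ("LL", 7)) if labels[sec, j] == 0]
            violations.append(
                (sec, RULE_WALKING_LEGS, f"walking without {'/'.join(missing)}")
            )
    return CredibilityReport(total_seconds=len(track), violations=violations)


@dataclass
class TimelineRun:
    start: int   # seconds, inclusive
    end: int     # seconds, exclusive
    state: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class BehaviorSummary:
    total_seconds: int
    labeled_seconds: int          # seconds carrying exactly one posture/walk state
    unlabelled_seconds: int
    durations: dict[str, int]                 # per posture/walk state, seconds
    percentages: dict[str, float]             # of labeled seconds
    transition_matrix: np.ndarray             # (4, 4) counts, rows=from, cols=to
    transitions: dict[tuple[str, str], int]   # nonzero entries by name
    runs: list[TimelineRun]
    extremity_seconds: dict[str, int]
    extremity_percent: dict[str, float]       # of labeled seconds
    upper_relative: dict[str, float]          # RH/LH share of upper-limb activity
    lower_relative: dict[str, float]


def _state_sequence(track: AnnotationTrack) -> np.ndarray:
    """Per-second state index 0..3, or -1 for unlabelled / no-posture seconds."""
    labels = track.labels
    counts = labels[:, :4].sum(axis=1)
    states = np.where(counts == 1, np.argmax(labels[:, :4], axis=1), -1)
    states[track.unlabelled] = -1
    return states


def summarize(track: AnnotationTrack) -> BehaviorSummary:
    """Aggregate a per-second track into durations, transitions and timelines.

    Seconds with no posture/walk label count as unlabelled time and are
    excluded from every percentage denominator.  Transitions are counted
    between adjacent labeled seconds only (an unlabelled stretch breaks the
    contiguous segment).
    """
    if len(track) == 0:
        raise ValueError("cannot summarize an empty track")
    states = _state_sequence(track)
    labeled = states >= 0
    labeled_seconds = int(labeled.sum())

    durations = {name: int((states == j).sum()) for j, name in enumerate(POSTURE_LABELS)}
    denom = max(labeled_seconds, 1)
    percentages = {name: 100.0 * durations[name] / denom for name in POSTURE_LABELS}

    # run-length encoding of the full state sequence (incl. unlabelled runs)
    runs: list[TimelineRun] = []
    start = 0
    for sec in range(1, len(states) + 1):
        if sec == len(states) or states[sec] != states[start]:
            name = POSTURE_LABELS[states[start]] if states[start] >= 0 else UNLABELLED_STATE
            runs.append(TimelineRun(start=start, end=sec, state=name))
            start = sec

    matrix = np.zeros((4, 4), dtype=np.int64)
    prev, cur = states[:-1], states[1:]
    change = (prev >= 0) & (cur >= 0) & (prev != cur)
    for a, b in zip(prev[change], cur[change]):
        matrix[a, b] += 1
    transitions = {
        (POSTURE_LABELS[a], POSTURE_LABELS[b]): int(matrix[a, b])
        for a in range(4) for b in range(4) if matrix[a, b]
    }

    ext_cols = track.labels[:, 4:]
    ext_seconds = {
        name: int((ext_cols[:, j] == 1)[labeled].sum())
        for j, name in enumerate(EXTREMITY_LABELS)
    }
    ext_percent = {name: 100.0 * ext_seconds[name] / denom for name in EXTREMITY_LABELS}

    def relative(right: str, left: str) -> dict[str, float]:
        total = ext_seconds[right] + ext_seconds[left]
        if total == 0:
            return {right: float("nan"), left: float("nan")}
        return {right: 100.0 * ext_seconds[right] / total,
                left: 100.0 * ext_seconds[left] / total}

    return BehaviorSummary(
        total_seconds=len(track),
        labeled_seconds=labeled_seconds,
        unlabelled_seconds=len(track) - labeled_seconds,
        durations=durations,
        percentages=percentages,
        transition_matrix=matrix,
        transitions=transitions,
        runs=runs,
        extremity_seconds=ext_seconds,
        extremity_percent=ext_percent,
        upper_relative=relative("RH", "LH"),
        lower_relative=relative("RL", "LL"),
    )


@dataclass
class RecordingMeta:
    """Start/stop (seconds) and the list of (gap start, gap length) holes."""

    start: float
    stop: float
    gaps: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class WearTimeReport:
    duration_s: float
    continuous: bool
    meets_24h: bool
    feasible: bool
    max_gap_s: float


def wear_time_report(meta: RecordingMeta, track: AnnotationTrack | None = None,
                     gap_threshold_s: float = DEFAULT_CONTINUITY_GAP_S,
                     target_s: float = FULL_DAY_S) -> WearTimeReport:
    """Judge a recording against the continuous full-wear-time target.

    Feasible means data collection was continuous (no gap above the
    threshold) and the recording spans at least the 24-h target.
    """
    duration = meta.stop - meta.start
    max_gap = max((g for _, g in meta.gaps), default=0.0)
    continuous = max_gap <= gap_threshold_s
    meets = duration >= target_s
    return WearTimeReport(
        duration_s=float(duration),
        continuous=continuous,
        meets_24h=meets,
        feasible=continuous and meets,
        max_gap_s=float(max_gap),
    )
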