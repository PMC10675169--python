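"""Per-second annotation tracks and the text coding scheme.

A code is one posture/walk token (LY, SI, ST, WA), optionally followed by a
forward slash and space-separated extremity tokens (RH, LH, RL, LL), e.g.
``SI/RH`` or ``WA/RL LL``.  A question mark marks a second whose activity is
outside the scheme; such seconds are excluded from analysis.  Parsing is
case-insensitive, whitespace-tolerant and order-independent in the
extremity list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .labels import (
    EXTREMITY_LABELS,
    LABEL_INDEX,
    LABELS,
    N_LABELS,
    POSTURE_LABELS,
)

UNLABELLED_CODE = "?"


class AnnotationError(Exception):
    pass


class ParseError(AnnotationError):
    pass


class ProtocolViolationError(AnnotationError):
    pass


class AlignmentError(AnnotationError):
    pass


@dataclass
class AnnotationTrack:
    """One entry per second: an 8-label vector or an unlabelled marker.

    ``labels`` is (n, 8) uint8; ``unlabelled`` is a (n,) boolean mask (label
    rows under the mask are all-zero and carry no meaning).
    """

    labels: np.ndarray
    unlabelled: np.ndarray
    start_time: float = 0.0
    annotator_id: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        self.unlabelled = np.asarray(self.unlabelled, dtype=bool)
        if self.labels.ndim != 2 or self.labels.shape[1] != N_LABELS:
            raise AnnotationError(f"labels must be (n, {N_LABELS}); got {self.labels.shape}")
        if self.unlabelled.shape != (self.labels.shape[0],):
            raise AnnotationError("unlabelled mask length must match labels")

    def __len__(self) -> int:
        return self.labels.shape[0]

    @classmethod
    def from_labels(cls, labels: np.ndarray, start_time: float = 0.0,
                    annotator_id: str = "") -> "AnnotationTrack":
        labels = np.asarray(labels, dtype=np.uint8)
        return cls(labels, np.zeros(labels.shape[0], dtype=bool), start_time, annotator_id)

    def codes(self) -> list[str]:
        return [
            UNLABELLED_CODE if self.unlabelled[i] else format_code(self.labels[i])
            for i in range(len(self))
        ]


def parse_code(code: str) -> np.ndarray | None:
    """Parse one per-second code into an 8-label vector; ``?`` gives None."""
    text = code.strip()
    if not text:
        raise ParseError("empty annotation code")
    if text == UNLABELLED_CODE:
        return None
    head, _, tail = text.partition("/")
    vec = np.zeros(N_LABELS, dtype=np.uint8)
    posture = head.strip().upper()
    if posture not in POSTURE_LABELS:
        raise ParseError(f"unknown posture/walk token: {head.strip()!r}")
    vec[LABEL_INDEX[posture]] = 1
    for token in tail.split():
        name = token.strip().upper()
        if name in POSTURE_LABELS:
            raise ProtocolViolationError(
                f"second posture/walk token {token!r} in code {code!r}"
            )
        if name not in EXTREMITY_LABELS:
            raise ParseError(f"unknown extremity token: {token!r}")
        vec[LABEL_INDEX[name]] = 1
    return vec


def format_code(vec: np.ndarray) -> str:
    """Render a label vector back into scheme text (inverse of parse_code)."""
    vec = np.asarray(vec)
    postures = [name for name in POSTURE_LABELS if vec[LABEL_INDEX[name]]]
    if len(postures) != 1:
        raise ProtocolViolationError(
            f"cannot format a vector with {len(postures)} posture/walk labels"
        )
    extremities = [name for name in EXTREMITY_LABELS if vec[LABEL_INDEX[name]]]
    if extremities:
        return f"{postures[0]}/{' '.join(extremities)}"
    return postures[0]


def load_annotation_file(path: str | Path, annotator_id: str = "") -> AnnotationTrack:
    """Read a flat ``second,code`` CSV export into a track.

    Second indices are 0-based and must be strictly increasing; seconds
    absent from the file become unlabelled entries.  An optional header line
    ``second,code`` is skipped.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    entries: list[tuple[int, str]] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if lineno == 1 and line.lower().replace(" ", "") in ("second,code", "second_index,code"):
            continue
        sec_text, _, code = line.partition(",")
        try:
            sec = int(sec_text.strip())
        except ValueError:
            raise ParseError(f"{path}:{lineno}: bad second index {sec_text!r}") from None
        entries.append((sec, code.strip()))
    if not entries:
        raise AnnotationError(f"{path}: no annotation entries")
    seconds = np.array([s for s, _ in entries])
    if np.any(np.diff(seconds) < 0):
        raise AnnotationError(f"{path}: second indices are not monotonically increasing")
    if np.any(np.diff(seconds) == 0):
        dup = int(seconds[np.nonzero(np.diff(seconds) == 0)[0][0]])
        raise AnnotationError(f"{path}: duplicate entry for second {dup}")
    n = int(seconds[-1]) + 1
    labels = np.zeros((n, N_LABELS), dtype=np.uint8)
    unlabelled = np.ones(n, dtype=bool)
    for sec, code in entries:
        vec = parse_code(code)
        if vec is None:
            continue
        labels[sec] = vec
        unlabelled[sec] = False
    return AnnotationTrack(labels, unlabelled, start_time=0.0, annotator_id=annotator_id)


def save_annotation_file(track: AnnotationTrack, path: str | Path) -> None:
    path = Path(path)
    lines = ["second,code"]
    lines += [f"{i},{code}" for i, code in enumerate(track.codes())]
    path.write_text("\n".join(lines) + "\n")


@dataclass
class AlignedTracks:
    """Per-second pairing of two tracks over their overlapping span."""

    start_time: float
    labels_a: np.ndarray  # (n, 8)
    labels_b: np.ndarray
    excluded: np.ndarray  # (n,) True where either side is unlabelled

    def __len__(self) -> int:
        return self.labels_a.shape[0]

    @property
    def n_compared(self) -> int:
        return int((~self.excluded).sum())


def align_tracks(a: AnnotationTrack, b: AnnotationTrack) -> AlignedTracks:
    """Pair two tracks second-by-second over the overlap of their spans.

    Seconds unlabelled in either track are flagged excluded (kept in the
    arrays so callers can report exclusion counts).
    """
    start = max(a.start_time, b.start_time)
    end = min(a.start_time + len(a), b.start_time + len(b))
    if end - start < 1:
        raise AlignmentError("tracks do not overlap")
    ia = int(round(start - a.start_time))
    ib = int(round(start - b.start_time))
    n = int(round(end - start))
    return AlignedTracks(
        start_time=float(start),
        labels_a=a.labels[ia : ia + n],
        labels_b=b.labels[ib : ib + n],
        excluded=a.unlabelled[ia : ia + n] | b.unlabelled[ib : ib + n],
    )
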