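"""Label taxonomy for movement-behavior recognition.

Eight binary labels describe one second of movement: a posture or the
walking activity (lying LY, sitting SI, standing ST, walking WA -- at most
one active at a time in credible output) plus four extremity-movement
indicators (right hand RH, left hand LH, right leg RL, left leg LL).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

#: Canonical label order used everywhere (arrays of shape (..., 8)).
LABELS: tuple[str, ...] = ("LY", "SI", "ST", "WA", "RH", "LH", "RL", "LL")

#: Posture/walking states, mutually exclusive in credible output.
POSTURE_LABELS: tuple[str, ...] = ("LY", "SI", "ST", "WA")
POSTURE_SLICE = slice(0, 4)

#: Extremity-movement indicators; all four may co-occur.
EXTREMITY_LABELS: tuple[str, ...] = ("RH", "LH", "RL", "LL")
EXTREMITY_SLICE = slice(4, 8)

LABEL_INDEX: dict[str, int] = {name: i for i, name in enumerate(LABELS)}

N_LABELS = len(LABELS)


def label_vector(posture: str, extremities: tuple[str, ...] | frozenset[str] = ()) -> np.ndarray:
    """Build an 8-vector with one posture/walk state and a set of extremities."""
    if posture not in POSTURE_LABELS:
        raise ValueError(f"unknown posture/walk label: {posture!r}")
    vec = np.zeros(N_LABELS, dtype=np.uint8)
    vec[LABEL_INDEX[posture]] = 1
    for ext in extremities:
        if ext not in EXTREMITY_LABELS:
            raise ValueError(f"unknown extremity label: {ext!r}")
        vec[LABEL_INDEX[ext]] = 1
    return vec


def admissible_combinations() -> list[np.ndarray]:
    """All label vectors a credible one-second window can carry.

    Lying, sitting and standing combine freely with any subset of the four
    extremity indicators (3 x 2^4 = 48 combinations).  Walking requires both
    lower extremities to move, leaving only the two hand indicators free
    (2^2 = 4 combinations) -- 52 in total.
    """
    combos: list[np.ndarray] = []
    for posture in ("LY", "SI", "ST"):
        for r in range(len(EXTREMITY_LABELS) + 1):
            for subset in combinations(EXTREMITY_LABELS, r):
                combos.append(label_vector(posture, subset))
    for r in range(3):
        for subset in combinations(("RH", "LH"), r):
            combos.append(label_vector("WA", ("RL", "LL") + subset))
    return combos


def is_credible(vec: np.ndarray) -> bool:
    """True when a label vector satisfies the per-second credibility rules."""
    vec = np.asarray(vec)
    if int(vec[POSTURE_SLICE].sum()) > 1:
        return False
    if vec[LABEL_INDEX["WA"]] and not (vec[LABEL_INDEX["RL"]] and vec[LABEL_INDEX["LL"]]):
        return False
    return True
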