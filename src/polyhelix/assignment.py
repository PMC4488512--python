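"""Sequential π → 3₁₀ → α helix assignment from per-residue profiles.

Assignment works on one chain segment at a time and keeps a per-residue
assigned flag ``b`` that, once set, is never cleared within a pass cascade
(discarded sub-minimal runs return their residues to the unassigned pool).
π-helices are assigned first, then 3₁₀, then α; α-helices additionally go
through a merge step (two adjacent α-helices separated by fewer than four
residues merge when every intermediate residue bends and fits mildly
enough) and a C-terminal extension step.  The left-handed pass repeats the
three assignments on mirrored coordinates for residues still unassigned.

Score/angle/RMSD values are compared strictly against the thresholds; any
undefined quantity is ``inf`` and therefore fails every ``< threshold``
test, which keeps all window logic safely inside the segment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .curve_fitting import GridSpec, ResidueProfile, profile_segment
from .scoring import (
    ALPHA,
    PI,
    THREE_TEN,
    HelixClassParams,
    ScoreTriple,
    ThresholdConfig,
    helix_scores,
)

__all__ = [
    "HelixAnnotation",
    "AssignmentState",
    "assign_pi",
    "assign_310",
    "assign_alpha",
    "merge_alpha",
    "extend_alpha",
    "assign_segment",
    "MIN_LENGTH",
]

# Minimum helix lengths (residues) enforced after each pass.
MIN_LENGTH = {ALPHA: 4, THREE_TEN: 3, PI: 5}


@dataclass(frozen=True)
class HelixAnnotation:
    """An assigned helix over an inclusive residue range.

    ``start``/``end`` are residue identifiers — segment indices while
    assigning, (residue_number, insertion_code) pairs once mapped onto a
    chain by the pipeline.
    """

    chain_id: str
    start: object
    end: object
    helix_type: str
    handedness: str = "right"

    def __post_init__(self) -> None:
        if self.helix_type not in MIN_LENGTH:
            raise ValueError(f"unknown helix type {self.helix_type!r}")
        if self.handedness not in ("right", "left"):
            raise ValueError("handedness must be 'right' or 'left'")


@dataclass
class AssignmentState:
    """Per-residue assigned flags for one segment (0 = free, 1 = assigned)."""

    b: np.ndarray

    @classmethod
    def for_length(cls, n: int) -> "AssignmentState":
        return cls(b=np.zeros(n, dtype=np.int8))


class _View:
    """Threshold-test view over profiles + scores; out-of-range is inf."""

    def __init__(self, profiles: Sequence[ResidueProfile], scores: Sequence[ScoreTriple]):
        self.n = len(profiles)
        self.profiles = profiles
        self.scores = scores

    def h(self, i: int) -> float:
        return self.scores[i].h if 0 <= i < self.n else math.inf

    def g(self, i: int) -> float:
        return self.scores[i].g if 0 <= i < self.n else math.inf

    def pi(self, i: int) -> float:
        return self.scores[i].pi if 0 <= i < self.n else math.inf

    def a(self, i: int) -> float:
        return self.profiles[i].a if 0 <= i < self.n else math.inf

    def sd(self, i: int) -> float:
        return self.profiles[i].small_delta if 0 <= i < self.n else math.inf


def _filter_min_length(
    runs: list[tuple[int, int]], helix_type: str, b: np.ndarray
) -> list[tuple[int, int]]:
    kept = []
    for s, e in runs:
        if e - s + 1 >= MIN_LENGTH[helix_type]:
            kept.append((s, e))
        else:
            b[s : e + 1] = 0  # sub-minimal run returns to the unassigned pool
    return kept


def _to_annotations(
    runs: list[tuple[int, int]], helix_type: str, handedness: str
) -> list[HelixAnnotation]:
    return [
        HelixAnnotation(
            chain_id="", start=s, end=e, helix_type=helix_type, handedness=handedness
        )
        for s, e in runs
    ]


def assign_pi(
    profiles: Sequence[ResidueProfile],
    scores: Sequence[ScoreTriple],
    thresholds: ThresholdConfig,
    state: AssignmentState,
    handedness: str = "right",
) -> list[HelixAnnotation]:
    """π-helix pass: start on a low π score with three consecutive small axis
    angles, grow while the score stays low, then take four trailing residues
    (clipped to the segment and to unassigned residues); runs shorter than 5
    are discarded."""
    v = _View(profiles, scores)
    b = state.b
    n = v.n
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if (
            b[i] == 0
            and v.pi(i) < thresholds.pi_T
            and v.a(i) < thresholds.a_I
            and v.a(i + 1) < thresholds.a_I
            and v.a(i + 2) < thresholds.a_I
        ):
            start = i
            b[i] = 1
            i += 1
            while i < n - 3 and b[i] == 0 and v.pi(i) < thresholds.pi_T:
                b[i] = 1
                i += 1
            taken = 0
            while i < n and taken < 4 and b[i] == 0:
                b[i] = 1
                i += 1
                taken += 1
            runs.append((start, i - 1))
        else:
            i += 1
    return _to_annotations(_filter_min_length(runs, PI, b), PI, handedness)


def assign_310(
    profiles: Sequence[ResidueProfile],
    scores: Sequence[ScoreTriple],
    thresholds: ThresholdConfig,
    state: AssignmentState,
    handedness: str = "right",
) -> list[HelixAnnotation]:
    """3₁₀ pass: start on a low g score with a small axis angle, grow while
    the score stays low, then extend the C-terminus by two residues when the
    seven-residue RMSD δ stays below δ_G at both; runs shorter than 3 are
    discarded."""
    v = _View(profiles, scores)
    b = state.b
    n = v.n
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if b[i] == 0 and v.g(i) < thresholds.g_T and v.a(i) < thresholds.a_G:
            start = i
            b[i] = 1
            i += 1
            while i < n and b[i] == 0 and v.g(i) < thresholds.g_T:
                b[i] = 1
                i += 1
            if v.sd(i) < thresholds.delta_G and v.sd(i + 1) < thresholds.delta_G:
                taken = 0
                while i < n and taken < 2 and b[i] == 0:
                    b[i] = 1
                    i += 1
                    taken += 1
            runs.append((start, i - 1))
        else:
            i += 1
    return _to_annotations(_filter_min_length(runs, THREE_TEN, b), THREE_TEN, handedness)


def assign_alpha(
    profiles: Sequence[ResidueProfile],
    scores: Sequence[ScoreTriple],
    thresholds: ThresholdConfig,
    state: AssignmentState,
    handedness: str = "right",
) -> list[HelixAnnotation]:
    """α pass: start on two consecutive low h scores with a small axis angle,
    grow while the score stays low; raw runs then go through the merge and
    C-terminal extension steps, and final helices shorter than 4 residues are
    discarded."""
    v = _View(profiles, scores)
    b = state.b
    n = v.n
    runs: list[tuple[int, int]] = []
    i = 0
    while i < n:
        if (
            b[i] == 0
            and v.h(i) < thresholds.h_T
            and v.a(i) < thresholds.a_T
            and v.h(i + 1) < thresholds.h_T
        ):
            start = i
            b[i] = 1
            i += 1
            while i < n and b[i] == 0 and v.h(i) < thresholds.h_T:
                b[i] = 1
                i += 1
            runs.append((start, i - 1))
        else:
            i += 1
    runs = merge_alpha(runs, profiles, scores, thresholds, state)
    runs = extend_alpha(runs, profiles, scores, thresholds, state)
    return _to_annotations(_filter_min_length(runs, ALPHA, b), ALPHA, handedness)


def merge_alpha(
    runs: list[tuple[int, int]],
    profiles: Sequence[ResidueProfile],
    scores: Sequence[ScoreTriple],
    thresholds: ThresholdConfig,
    state: AssignmentState,
) -> list[tuple[int, int]]:
    """Merge adjacent α runs separated by fewer than four residues when every
    intermediate residue has a ≤ a_max, h < h_max and δ < δ_max.

    Applied left-to-right; merges cascade.  Intermediate residues of a merge
    become assigned.  Residues already assigned to another helix block the
    merge (assigned flags are final)."""
    v = _View(profiles, scores)
    b = state.b
    merged: list[tuple[int, int]] = []
    for run in sorted(runs):
        if not merged:
            merged.append(run)
            continue
        s_prev, e_prev = merged[-1]
        s, e = run
        gap = range(e_prev + 1, s)
        if s - e_prev - 1 < 4 and all(
            b[i] == 0
            and v.a(i) <= thresholds.a_max
            and v.h(i) < thresholds.h_max
            and v.sd(i) < thresholds.delta_max
            for i in gap
        ):
            b[e_prev + 1 : s] = 1
            merged[-1] = (s_prev, e)
        else:
            merged.append(run)
    return merged


def extend_alpha(
    runs: list[tuple[int, int]],
    profiles: Sequence[ResidueProfile],
    scores: Sequence[ScoreTriple],
    thresholds: ThresholdConfig,
    state: AssignmentState,
) -> list[tuple[int, int]]:
    """Extend the C-terminus of each α run by two residues when the first
    residue past the run is unassigned with h < h_max and a < a_max (clipped
    to the segment end and to unassigned residues)."""
    v = _View(profiles, scores)
    b = state.b
    out: list[tuple[int, int]] = []
    for s, e in runs:
        j = e + 1
        if (
            j < v.n
            and b[j] == 0
            and v.h(j) < thresholds.h_max
            and v.a(j) < thresholds.a_max
        ):
            taken = 0
            while j < v.n and taken < 2 and b[j] == 0:
                b[j] = 1
                j += 1
                taken += 1
            e = j - 1
        out.append((s, e))
    return out


def assign_segment(
    coords: np.ndarray,
    grid: GridSpec | None = None,
    classes: tuple[HelixClassParams, HelixClassParams, HelixClassParams] | None = None,
    thresholds: ThresholdConfig | None = None,
    chain_id: str = "",
    combiner: str = "sum",
    left_handed: bool = True,
    return_details: bool = False,
):
    """Full assignment of one contiguous Cα segment.

    Runs the right-handed profile through the π, 3₁₀ and α passes, then (if
    ``left_handed``) mirrors the coordinates, re-profiles, and repeats the
    three passes on still-unassigned residues, emitting left-handed
    annotations.  Annotations never overlap; output is sorted by start.
    ``start``/``end`` of the returned annotations are segment indices.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    details: dict[str, tuple[list[ResidueProfile], list[ScoreTriple]]] = {}
    if n < 4:
        return ([], details) if return_details else []
    grid = grid or GridSpec()
    thresholds = thresholds or ThresholdConfig()
    state = AssignmentState.for_length(n)

    annotations: list[HelixAnnotation] = []
    passes = ["right", "left"] if left_handed else ["right"]
    for handedness in passes:
        profiles = profile_segment(coords, grid, handedness=handedness)
        scores = [helix_scores(p.fit, classes, combiner) for p in profiles]
        details[handedness] = (profiles, scores)
        for assigner in (assign_pi, assign_310, assign_alpha):
            annotations.extend(
                replace(ann, chain_id=chain_id)
                for ann in assigner(profiles, scores, thresholds, state, handedness)
            )
    annotations = sorted(annotations, key=lambda ann: ann.start)
    return (annotations, details) if return_details else annotations
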