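"""Assignment-pass tests, anchored on an independent hand-trace of the
sequential threshold pseudocode (π → 3₁₀ → α with merge/extension)."""

import math

import numpy as np
import pytest

from polyhelix.assignment import (
    AssignmentState,
    HelixAnnotation,
    assign_310,
    assign_alpha,
    assign_pi,
    assign_segment,
    extend_alpha,
    merge_alpha,
)
from polyhelix.curve_fitting import (
    ResidueProfile,
    initial_estimates,
    kabsch_superpose,
    profile_segment,
)
from polyhelix.helix_model import (
    HelicalCurve,
    closest_point_distance,
    curve_points,
    helix_in_coil_trace,
    kinked_pair_trace,
    mirror_coordinates,
    turn_angle_from_rp,
)
from polyhelix.scoring import ScoreTriple, ThresholdConfig, helix_scores, standard_curve

from conftest import ideal_trace

INF = math.inf
THR = ThresholdConfig()


# ---------------------------------------------------------------------------
# Independent hand-trace of the assignment pseudocode over plain lists.


def _get(xs, i):
    return xs[i] if 0 <= i < len(xs) else INF


def trace_pi(pi, a, thr, b):
    runs = []
    n = len(pi)
    i = 0
    while i < n:
        if b[i] == 0 and _get(pi, i) < thr.pi_T and all(
            _get(a, i + k) < thr.a_I for k in (0, 1, 2)
        ):
            s = i
            b[i] = 1
            i += 1
            while i < n - 3 and b[i] == 0 and _get(pi, i) < thr.pi_T:
                b[i] = 1
                i += 1
            extra = 0
            while i < n and extra < 4 and b[i] == 0:
                b[i] = 1
                i += 1
                extra += 1
            runs.append((s, i - 1))
        else:
            i += 1
    return _drop_short(runs, 5, b)


def trace_310(g, a, sd, thr, b):
    runs = []
    n = len(g)
    i = 0
    while i < n:
        if b[i] == 0 and _get(g, i) < thr.g_T and _get(a, i) < thr.a_G:
            s = i
            b[i] = 1
            i += 1
            while i < n and b[i] == 0 and _get(g, i) < thr.g_T:
                b[i] = 1
                i += 1
            if _get(sd, i) < thr.delta_G and _get(sd, i + 1) < thr.delta_G:
                extra = 0
                while i < n and extra < 2 and b[i] == 0:
                    b[i] = 1
                    i += 1
                    extra += 1
            runs.append((s, i - 1))
        else:
            i += 1
    return _drop_short(runs, 3, b)


def trace_alpha(h, a, sd, thr, b):
    runs = []
    n = len(h)
    i = 0
    while i < n:
        if (
            b[i] == 0
            and _get(h, i) < thr.h_T
            and _get(a, i) < thr.a_T
            and _get(h, i + 1) < thr.h_T
        ):
            s = i
            b[i] = 1
            i += 1
            while i < n and b[i] == 0 and _get(h, i) < thr.h_T:
                b[i] = 1
                i += 1
            runs.append((s, i - 1))
        else:
            i += 1
    # merge adjacent pairs, left to right, cascading
    merged = []
    for run in runs:
        if merged:
            ps, pe = merged[-1]
            s, e = run
            if s - pe - 1 < 4 and all(
                b[k] == 0
                and _get(a, k) <= thr.a_max
                and _get(h, k) < thr.h_max
                and _get(sd, k) < thr.delta_max
                for k in range(pe + 1, s)
            ):
                for k in range(pe + 1, s):
                    b[k] = 1
                merged[-1] = (ps, e)
                continue
        merged.append(run)
    # extend C-termini by two residues
    final = []
    for s, e in merged:
        j = e + 1
        if j < n and b[j] == 0 and _get(h, j) < thr.h_max and _get(a, j) < thr.a_max:
            extra = 0
            while j < n and extra < 2 and b[j] == 0:
                b[j] = 1
                j += 1
                extra += 1
            e = j - 1
        final.append((s, e))
    return _drop_short(final, 4, b)


def _drop_short(runs, min_len, b):
    kept = []
    for s, e in runs:
        if e - s + 1 >= min_len:
            kept.append((s, e))
        else:
            for k in range(s, e + 1):
                b[k] = 0
    return kept


def hand_trace(profiles, scores, thr=THR, b=None):
    n = len(profiles)
    b = list(b) if b is not None else [0] * n
    h = [s.h for s in scores]
    g = [s.g for s in scores]
    pi = [s.pi for s in scores]
    a = [p.a for p in profiles]
    sd = [p.small_delta for p in profiles]
    return {
        "pi": trace_pi(pi, a, thr, b),
        "310": trace_310(g, a, sd, thr, b),
        "alpha": trace_alpha(h, a, sd, thr, b),
    }, b


def spans(annotations, helix_type=None, handedness=None):
    return [
        (ann.start, ann.end)
        for ann in annotations
        if (helix_type is None or ann.helix_type == helix_type)
        and (handedness is None or ann.handedness == handedness)
    ]


# ---------------------------------------------------------------------------


class TestPlantedFixtures:
    @pytest.mark.parametrize(
        "label,n_helix", [("alpha", 12), ("310", 7), ("pi", 8)]
    )
    def test_planted_helix_recovered_with_pseudocode_boundaries(self, label, n_helix):
        coords, planted = helix_in_coil_trace(standard_curve(label), n_helix)
        annotations = assign_segment(coords)
        assert len(annotations) == 1
        ann = annotations[0]
        assert ann.helix_type == label
        assert ann.handedness == "right"
        # planted core is covered (up to the windowed boundary behaviour)
        assert ann.start <= planted[0] + 1
        assert ann.end >= planted[1] - 3
        # boundaries agree with the independent hand-trace
        profiles = profile_segment(coords)
        scores = [helix_scores(p.fit) for p in profiles]
        expected, _ = hand_trace(profiles, scores)
        assert spans(annotations, label) == expected[label]
        for other in expected:
            if other != label:
                assert expected[other] == []

    def test_mirrored_alpha_assigned_left_handed(self):
        coords, planted = helix_in_coil_trace(standard_curve("alpha"), 12)
        annotations = assign_segment(mirror_coordinates(coords))
        assert len(annotations) == 1
        ann = annotations[0]
        assert (ann.helix_type, ann.handedness) == ("alpha", "left")
        # same boundaries as the right-handed assignment of the unmirrored trace
        unmirrored = assign_segment(coords)
        assert (ann.start, ann.end) == (unmirrored[0].start, unmirrored[0].end)

    def test_extended_strand_gets_no_annotation(self, strand_curve):
        assert assign_segment(ideal_trace(strand_curve, 15)) == []

    def test_pi_precedence_blocks_alpha(self):
        coords, planted = helix_in_coil_trace(standard_curve("pi"), 8)
        annotations = assign_segment(coords)
        pi_spans = spans(annotations, "pi")
        assert pi_spans
        covered = {i for s, e in pi_spans for i in range(s, e + 1)}
        for s, e in spans(annotations, "alpha"):
            assert not covered & set(range(s, e + 1))

    def test_kinked_pair_never_merged(self, class_curves):
        coords = kinked_pair_trace(class_curves["alpha"], 10, 60.0)
        annotations = assign_segment(coords)
        alpha_spans = spans(annotations, "alpha")
        assert len(alpha_spans) == 2
        gap_start = alpha_spans[0][1] + 1
        gap_end = alpha_spans[1][0] - 1
        assert gap_end >= gap_start  # a genuine break at the kink

    def test_tiny_segments_yield_nothing(self, class_curves):
        assert assign_segment(ideal_trace(class_curves["pi"], 4)) == []
        assert assign_segment(np.zeros((0, 3))) == []
        assert assign_segment(ideal_trace(class_curves["alpha"], 3)) == []


class TestInvariants:
    @pytest.mark.parametrize("seed", range(5))
    def test_no_overlap_and_min_lengths_on_noisy_traces(self, seed, class_curves):
        coords = ideal_trace(class_curves["alpha"], 16, noise=0.15, seed=seed)
        annotations = assign_segment(coords)
        minima = {"alpha": 4, "310": 3, "pi": 5}
        claimed = set()
        for ann in annotations:
            length = ann.end - ann.start + 1
            assert length >= minima[ann.helix_type]
            span = set(range(ann.start, ann.end + 1))
            assert not span & claimed
            claimed |= span

    def test_deterministic(self, class_curves):
        coords = ideal_trace(class_curves["310"], 12, noise=0.1, seed=2)
        assert assign_segment(coords) == assign_segment(coords)

    def test_assignment_matches_hand_trace_on_noisy_trace(self, class_curves):
        coords = ideal_trace(class_curves["alpha"], 18, noise=0.12, seed=9)
        annotations, details = assign_segment(coords, return_details=True, left_handed=False)
        profiles, scores = details["right"]
        expected, _ = hand_trace(profiles, scores)
        for helix_type in ("pi", "310", "alpha"):
            assert spans(annotations, helix_type) == expected[helix_type]

    def test_raising_h_threshold_grows_alpha_set(self, class_curves):
        coords = ideal_trace(class_curves["alpha"], 16, noise=0.2, seed=4)
        profiles = profile_segment(coords)
        scores = [helix_scores(p.fit) for p in profiles]

        def alpha_set(h_T):
            state = AssignmentState.for_length(len(profiles))
            anns = assign_alpha(
                profiles, scores, ThresholdConfig(h_T=h_T), state
            )
            return {i for ann in anns for i in range(ann.start, ann.end + 1)}

        assert alpha_set(20.0) <= alpha_set(60.0) <= alpha_set(120.0)

    def test_emitted_alpha_helices_fit_single_curve(self, class_curves):
        coords = ideal_trace(class_curves["alpha"], 14, noise=0.1, seed=1)
        for ann in assign_segment(coords):
            if ann.helix_type != "alpha" or ann.end - ann.start + 1 > 12:
                continue
            sub = coords[ann.start : ann.end + 1]
            assert _single_curve_rmsd(sub) < 0.5


def _single_curve_rmsd(coords: np.ndarray) -> float:
    """Best closest-point RMSD of one helical curve fit to a whole trace."""
    n = len(coords)
    mid = max((n - 4) // 2, 0)
    r_m, p_m, _ = initial_estimates(coords[mid : mid + 4])
    d = float(np.linalg.norm(np.diff(coords, axis=0), axis=1).mean())
    best = INF
    for r in np.arange(r_m - 0.2, r_m + 0.21, 0.02):
        for p in np.arange(max(p_m - 0.2, 0.0), p_m + 0.21, 0.02):
            if r <= 0 or d <= p:
                continue
            try:
                t = turn_angle_from_rp(r, p, d)
            except Exception:
                continue
            model = HelicalCurve(radius=r, rise=p, turn=t)
            canonical = curve_points(model, np.arange(float(n)))
            rot, trans, _ = kabsch_superpose(canonical, coords)
            curve = HelicalCurve(radius=r, rise=p, turn=t, origin=trans, rotation=rot)
            sq = [
                closest_point_distance(curve, coords[k], (k - 1.0, k + 1.0)) ** 2
                for k in range(n)
            ]
            best = min(best, math.sqrt(sum(sq) / n))
    return best


# ---------------------------------------------------------------------------
# Rule-level unit tests on fabricated profiles (no geometry involved).


def fabricate(n, a=0.0, sd=0.01, h=INF, g=INF, pi=INF):
    profiles = [ResidueProfile(index=i, a=a, small_delta=sd) for i in range(n)]
    scores = [ScoreTriple(h=h, g=g, pi=pi) for _ in range(n)]
    return profiles, scores


def set_scores(scores, idx, **kw):
    for i in idx:
        scores[i] = ScoreTriple(**{**scores[i].__dict__, **kw})


class TestMergeRule:
    def _runs_after_merge(self, gap, a_mid=20.0, h_mid=50.0, sd_mid=0.1):
        n = 20 + gap
        profiles, scores = fabricate(n)
        for i in range(10, 10 + gap):
            profiles[i] = ResidueProfile(index=i, a=a_mid, small_delta=sd_mid)
            scores[i] = ScoreTriple(h=h_mid)
        runs = [(2, 9), (10 + gap, 15 + gap)]
        state = AssignmentState.for_length(n)
        for s, e in runs:
            state.b[s : e + 1] = 1
        return merge_alpha(runs, profiles, scores, THR, state)

    def test_gentle_bend_merges(self):
        assert self._runs_after_merge(gap=2) == [(2, 17)]

    def test_sharp_bend_blocks_merge(self):
        assert self._runs_after_merge(gap=2, a_mid=85.0) == [(2, 9), (12, 17)]

    def test_wide_gap_never_merges(self):
        assert self._runs_after_merge(gap=5) == [(2, 9), (15, 20)]

    def test_merge_cascades(self):
        n = 24
        profiles, scores = fabricate(n, a=10.0, h=50.0)
        runs = [(0, 4), (6, 10), (12, 16)]
        state = AssignmentState.for_length(n)
        for s, e in runs:
            state.b[s : e + 1] = 1
        assert merge_alpha(runs, profiles, scores, THR, state) == [(0, 16)]


class TestExtendRule:
    def test_loose_continuation_extends_by_two(self):
        profiles, scores = fabricate(14, a=30.0, h=100.0)
        state = AssignmentState.for_length(14)
        state.b[2:9] = 1
        assert extend_alpha([(2, 8)], profiles, scores, THR, state) == [(2, 10)]
        assert list(state.b[9:11]) == [1, 1]

    def test_assigned_neighbour_blocks_extension(self):
        profiles, scores = fabricate(14, a=30.0, h=100.0)
        state = AssignmentState.for_length(14)
        state.b[2:9] = 1
        state.b[9] = 1  # e.g. claimed by a 3_10 helix
        assert extend_alpha([(2, 8)], profiles, scores, THR, state) == [(2, 8)]

    def test_extension_clipped_at_segment_end(self):
        profiles, scores = fabricate(10, a=30.0, h=100.0)
        state = AssignmentState.for_length(10)
        state.b[2:9] = 1
        assert extend_alpha([(2, 8)], profiles, scores, THR, state) == [(2, 9)]

    def test_large_bend_blocks_extension(self):
        profiles, scores = fabricate(14, a=50.0, h=100.0)
        state = AssignmentState.for_length(14)
        state.b[2:9] = 1
        assert extend_alpha([(2, 8)], profiles, scores, THR, state) == [(2, 8)]


class TestThreeTenRule:
    def test_single_passing_residue_with_delta_extension_reaches_minimum(self):
        profiles, scores = fabricate(12, a=0.0, sd=0.01)
        set_scores(scores, [5], g=1.0)
        state = AssignmentState.for_length(12)
        anns = assign_310(profiles, scores, THR, state)
        assert spans(anns, "310") == [(5, 7)]

    def test_single_passing_residue_without_delta_support_discarded(self):
        profiles, scores = fabricate(12, a=0.0, sd=0.5)
        set_scores(scores, [5], g=1.0)
        state = AssignmentState.for_length(12)
        assert assign_310(profiles, scores, THR, state) == []
        assert not state.b.any()


class TestPiRule:
    def test_four_residue_segment_cannot_reach_minimum_length(self, class_curves):
        profiles, scores = fabricate(4, a=0.0)
        set_scores(scores, [0], pi=1.0)
        state = AssignmentState.for_length(4)
        assert assign_pi(profiles, scores, THR, state) == []

    def test_ideal_alpha_scores_block_pi(self, class_curves):
        profiles = profile_segment(ideal_trace(class_curves["alpha"], 12))
        scores = [helix_scores(p.fit) for p in profiles]
        state = AssignmentState.for_length(12)
        assert assign_pi(profiles, scores, THR, state) == []


class TestAnnotationType:
    def test_rejects_unknown_type(self):
        with pytest.raises(ValueError):
            HelixAnnotation(chain_id="A", start=0, end=5, helix_type="beta")

    def test_rejects_bad_handedness(self):
        with pytest.raises(ValueError):
            HelixAnnotation(
                chain_id="A", start=0, end=5, helix_type="alpha", handedness="both"
            )
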