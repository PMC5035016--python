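"""The five-task connection recognizer and violation detection."""

import numpy as np
import pytest

from ruffscore.board import design_id, enumerate_connections
from ruffscore.ingest import CellInk
from ruffscore.recognize import (
    ActiveDotSet,
    PixelAssignment,
    RecognitionConfig,
    assign_pixels,
    candidate_connections,
    check_line_compatibility,
    detect_violations,
    identify_active_dots,
    recognize_cell,
    reject_false_positives,
)
from ruffscore.render import StrokeNoiseModel, moderate_noise, zero_noise


def make_cell(mask, dot_centers):
    return CellInk(cell_index=0, part_number=1, red_mask=mask,
                   dot_centers_px=np.asarray(dot_centers, float))


def draw_segment(mask, p, q, width=3):
    """Paint a straight stroke into a boolean mask (test-local rasterizer)."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    n = int(np.hypot(*(q - p))) * 2 + 1
    for t in np.linspace(0, 1, n):
        x, y = p + t * (q - p)
        r = width // 2
        mask[int(y) - r:int(y) + r + 1, int(x) - r:int(x) + r + 1] = True
    return mask


#: An easy synthetic geometry: near-collinear chain 0-1-2 plus two far dots.
CHAIN_DOTS = [(50.0, 200.0), (200.0, 200.0), (350.0, 200.0),
              (80.0, 60.0), (320.0, 60.0)]


class TestActiveDots:
    def test_empty_mask_no_active_dots(self, layout, config):
        cell = make_cell(np.zeros((400, 450), bool), layout.dot_centers_cell(1))
        active = identify_active_dots(cell, config)
        assert not any(active.active)

    def test_strokes_touching_three_dots(self, cell_factory, config):
        # design with connections 0-1 and 1-2 only: dots 0, 1, 2 active,
        # dots 3 and 4 inactive
        design = design_id([(0, 1), (1, 2)])
        cell, _ = cell_factory(design)
        active = identify_active_dots(cell, config)
        assert active.indices == (0, 1, 2)

    def test_complete_design_all_active(self, cell_factory, config):
        cell, _ = cell_factory(1023)
        active = identify_active_dots(cell, config)
        assert active.indices == (0, 1, 2, 3, 4)


class TestCandidateConnections:
    def test_three_active_dots_three_candidates(self):
        active = ActiveDotSet(active=(True, True, True, False, False),
                              evidence=(9, 9, 9, 0, 0))
        cands = candidate_connections(active)
        assert [(c.dot_a, c.dot_b) for c in cands] == [(0, 1), (0, 2), (1, 2)]

    @pytest.mark.parametrize("flags", [(False,) * 5,
                                       (False, True, False, False, False)])
    def test_fewer_than_two_active_no_candidates(self, flags):
        active = ActiveDotSet(active=flags, evidence=(0,) * 5)
        assert candidate_connections(active) == []

    def test_five_active_gives_all_ten(self):
        active = ActiveDotSet(active=(True,) * 5, evidence=(9,) * 5)
        assert len(candidate_connections(active)) == 10


class TestAssignPixels:
    def test_on_line_pixels_go_to_their_candidate(self, config):
        mask = np.zeros((400, 450), bool)
        draw_segment(mask, CHAIN_DOTS[0], CHAIN_DOTS[1])
        cell = make_cell(mask, CHAIN_DOTS)
        cands = [c for c in enumerate_connections(5)
                 if (c.dot_a, c.dot_b) == (0, 1)]
        assignment = assign_pixels(cell, cands, config)
        assert (assignment.candidate_of == 0).all()

    def test_far_pixels_stay_unassigned(self, config):
        mask = np.zeros((400, 450), bool)
        mask[390:395, 430:435] = True  # a blob far from every candidate
        cell = make_cell(mask, CHAIN_DOTS)
        cands = [c for c in enumerate_connections(5)
                 if (c.dot_a, c.dot_b) in {(0, 1), (3, 4)}]
        assignment = assign_pixels(cell, cands, config)
        assert (assignment.candidate_of == -1).all()
        assert assignment.unassigned_fraction == 1.0

    def test_rendered_design_pixels_mostly_assigned(self, cell_factory, config):
        design = design_id([(0, 1), (1, 2)])
        cell, _ = cell_factory(design)
        active = identify_active_dots(cell, config)
        assignment = assign_pixels(cell, candidate_connections(active), config)
        assert assignment.unassigned_fraction < 0.01

    def test_distance_ties_prefer_shorter_segment(self, config):
        # a pixel exactly between collinear dots 0 and 1 ties candidates
        # 0-1 (length 150) and 0-2 (length 300): the shorter must win
        mask = np.zeros((400, 450), bool)
        mask[200, 125] = True
        cell = make_cell(mask, CHAIN_DOTS)
        cands = [c for c in enumerate_connections(5)
                 if (c.dot_a, c.dot_b) in {(0, 1), (0, 2)}]
        assignment = assign_pixels(cell, cands, config)
        chosen = assignment.candidates[assignment.candidate_of[0]]
        assert (chosen.dot_a, chosen.dot_b) == (0, 1)


class TestLineCompatibility:
    def conn(self, a, b):
        return next(c for c in enumerate_connections(5)
                    if (c.dot_a, c.dot_b) == (a, b))

    def pixels_of(self, mask):
        ys, xs = np.nonzero(mask)
        return np.column_stack([xs, ys]).astype(float)

    def test_full_straight_stroke_accepted(self, config):
        mask = np.zeros((400, 450), bool)
        draw_segment(mask, CHAIN_DOTS[0], CHAIN_DOTS[1])
        result = check_line_compatibility(
            self.conn(0, 1), self.pixels_of(mask),
            np.asarray(CHAIN_DOTS), config)
        assert result.accepted
        assert result.coverage > 0.95

    def test_short_partial_mark_rejected_for_coverage(self, config):
        # ink covering only ~30% of the segment near dot 0
        p = np.asarray(CHAIN_DOTS[0])
        q = np.asarray(CHAIN_DOTS[1])
        mask = np.zeros((400, 450), bool)
        draw_segment(mask, p, p + 0.3 * (q - p))
        result = check_line_compatibility(
            self.conn(0, 1), self.pixels_of(mask), np.asarray(CHAIN_DOTS),
            config)
        assert not result.accepted
        assert result.reason == "coverage"

    def test_central_gap_rejected(self, config):
        # two stubs with a 40% hole in the middle: coverage 60% < 75%
        # fails first, and the gap alone would also reject it
        p = np.asarray(CHAIN_DOTS[0])
        q = np.asarray(CHAIN_DOTS[1])
        mask = np.zeros((400, 450), bool)
        draw_segment(mask, p, p + 0.3 * (q - p))
        draw_segment(mask, p + 0.7 * (q - p), q)
        result = check_line_compatibility(
            self.conn(0, 1), self.pixels_of(mask), np.asarray(CHAIN_DOTS),
            config)
        assert not result.accepted
        gap_config = RecognitionConfig(coverage_threshold=0.5)
        result = check_line_compatibility(
            self.conn(0, 1), self.pixels_of(mask), np.asarray(CHAIN_DOTS),
            gap_config)
        assert not result.accepted
        assert result.reason == "gap"
        assert result.max_gap_fraction == pytest.approx(0.4, abs=0.05)

    def test_coverage_monotone_under_added_corridor_pixels(self, config):
        # adding ink along an accepted candidate can never un-accept it
        p = np.asarray(CHAIN_DOTS[0])
        q = np.asarray(CHAIN_DOTS[1])
        mask = np.zeros((400, 450), bool)
        draw_segment(mask, p, q, width=1)
        base = check_line_compatibility(self.conn(0, 1), self.pixels_of(mask),
                                        np.asarray(CHAIN_DOTS), config)
        assert base.accepted
        rng = np.random.default_rng(0)
        for _ in range(20):
            t = rng.uniform(0, 1)
            x, y = p + t * (q - p)
            mask[int(y) + rng.integers(-3, 4), int(x) + rng.integers(-3, 4)] = True
            again = check_line_compatibility(
                self.conn(0, 1), self.pixels_of(mask), np.asarray(CHAIN_DOTS),
                config)
            assert again.accepted
            assert again.coverage >= base.coverage - 1e-12


class TestFalsePositiveRejection:
    def setup_assignment(self, long_pixels):
        conns = {(a, b): c for c in enumerate_connections(5)
                 for a, b in [(c.dot_a, c.dot_b)]}
        cands = [conns[(0, 1)], conns[(0, 2)], conns[(1, 2)]]
        pixels = np.asarray(long_pixels, float)
        assignment = PixelAssignment(
            pixels_xy=pixels,
            candidate_of=np.full(len(pixels), 1, dtype=int),  # all on 0-2
            candidates=cands,
        )
        active = ActiveDotSet(active=(True, True, True, False, False),
                              evidence=(9, 9, 9, 0, 0))
        return conns, cands, assignment, active

    def test_collinear_long_candidate_removed(self, config):
        # 0-2 passes through active dot 1 and both shorts are accepted:
        # without independent ink, 0-2 is a false positive
        pixels = [(x, 200.0) for x in range(60, 340, 3)]
        conns, cands, assignment, active = self.setup_assignment(pixels)
        true_set, notes = reject_false_positives(
            [conns[(0, 1)], conns[(0, 2)], conns[(1, 2)]], active, assignment,
            np.asarray(CHAIN_DOTS), config)
        assert conns[(0, 2)] not in true_set
        assert {(c.dot_a, c.dot_b) for c in true_set} == {(0, 1), (1, 2)}

    def test_independent_support_retains_long_candidate(self, config):
        # same geometry, but the long line owns ink far outside both
        # short corridors (e.g. a wide detour): it was genuinely drawn
        pixels = [(x, 200.0) for x in range(60, 340, 3)]
        pixels += [(x, 230.0) for x in range(150, 250, 2)]  # 30 px off-chain
        conns, cands, assignment, active = self.setup_assignment(pixels)
        true_set, _ = reject_false_positives(
            [conns[(0, 1)], conns[(0, 2)], conns[(1, 2)]], active, assignment,
            np.asarray(CHAIN_DOTS), config)
        assert conns[(0, 2)] in true_set

    def test_isolated_stroke_untouched(self, config):
        conns = {(c.dot_a, c.dot_b): c for c in enumerate_connections(5)}
        pixels = np.asarray([(x, 200.0) for x in range(60, 190, 3)], float)
        assignment = PixelAssignment(pixels, np.zeros(len(pixels), int),
                                     [conns[(0, 1)]])
        active = ActiveDotSet(active=(True, True, False, False, False),
                              evidence=(9, 9, 0, 0, 0))
        true_set, _ = reject_false_positives([conns[(0, 1)]], active,
                                             assignment,
                                             np.asarray(CHAIN_DOTS), config)
        assert true_set == {conns[(0, 1)]}


class TestViolations:
    def test_compliant_render_no_violations(self, cell_factory, config):
        cell, _ = cell_factory(design_id([(0, 1), (2, 3)]))
        rec = recognize_cell(cell, config)
        assert rec.violations == 0

    @pytest.mark.parametrize("design", [1, design_id([(0, 1), (1, 2)]), 1023])
    def test_violation_mode_strokes_counted_and_excluded(
            self, cell_factory, config, design):
        cell, violating = cell_factory(design, violation=True)
        rec = recognize_cell(cell, config)
        assert rec.violations == len(violating) == bin(design).count("1")
        assert rec.design == 0

    def test_overshoot_below_threshold_ignored(self, cell_factory, config):
        # strokes poking 4 px past the dot centers: under the 10 px
        # threshold, not a violation
        noise = StrokeNoiseModel(overshoot_px=4.0)
        cell, _ = cell_factory(design_id([(0, 2)]), noise=noise, violation=True)
        rec = recognize_cell(cell, config)
        assert rec.violations == 0
        assert rec.design == design_id([(0, 2)])

    def test_violations_can_count_as_designs_when_configured(
            self, cell_factory, layout):
        liberal = RecognitionConfig(dot_radius_px=layout.dot_radius_px,
                                    count_violations_as_designs=True)
        design = design_id([(0, 1), (1, 2)])
        cell, _ = cell_factory(design, violation=True)
        rec = recognize_cell(cell, liberal)
        assert rec.violations == 2
        assert rec.design == design


class TestRecognizeCell:
    def test_empty_cell(self, layout, config):
        cell = make_cell(np.zeros((400, 450), bool), layout.dot_centers_cell(1))
        rec = recognize_cell(cell, config)
        assert rec.design == 0
        assert rec.violations == 0
        assert not rec.unscorable

    def test_no_hallucination_from_stray_ink(self, layout, config):
        # a red smudge touching no dots must not produce a design
        mask = np.zeros((400, 450), bool)
        mask[10:14, 10:14] = True
        cell = make_cell(mask, layout.dot_centers_cell(1))
        rec = recognize_cell(cell, config)
        assert rec.design == 0
        assert rec.unscorable

    @pytest.mark.parametrize("part", [1, 2, 3, 4, 5])
    def test_sampled_zero_noise_round_trip_all_parts(self, cell_factory,
                                                     config, part):
        rng = np.random.default_rng(100 + part)
        for mask in rng.integers(1, 1024, size=12):
            cell, _ = cell_factory(int(mask), part=part)
            rec = recognize_cell(cell, config)
            assert rec.design == int(mask)

    def test_moderate_noise_recovery_rate(self, cell_factory, config):
        # >= 99% exact design recovery over 1,000 random noisy cells
        rng = np.random.default_rng(7)
        noise = moderate_noise()
        hits = 0
        n = 1000
        for _ in range(n):
            mask = int(rng.integers(1, 1024))
            part = int(rng.integers(1, 6))
            cell, _ = cell_factory(mask, part=part, noise=noise, rng=rng,
                                   via="alpha")
            hits += recognize_cell(cell, config).design == mask
        assert hits >= 0.99 * n

    def test_diagnostics_cover_all_candidates(self, cell_factory, config):
        design = design_id([(0, 1), (1, 2)])
        cell, _ = cell_factory(design)
        rec = recognize_cell(cell, config)
        pairs = {(c.dot_a, c.dot_b) for c in rec.diagnostics}
        assert pairs == {(0, 1), (0, 2), (1, 2)}
        assert rec.diagnostics[next(c for c in rec.diagnostics
                                    if (c.dot_a, c.dot_b) == (0, 2))].startswith(
            "rejected")


class TestConfigScaling:
    def test_thresholds_scale_with_dpi(self):
        base = RecognitionConfig()
        half = base.scaled(150)
        assert half.activation_radius_px == pytest.approx(
            base.activation_radius_px / 2)
        assert half.corridor_halfwidth_px == pytest.approx(
            base.corridor_halfwidth_px / 2)
        assert half.overshoot_threshold_px == pytest.approx(
            base.overshoot_threshold_px / 2)
        assert half.coverage_threshold == base.coverage_threshold
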