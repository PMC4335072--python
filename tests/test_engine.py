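import math

import pytest

from cellregen import (
    Kernel,
    NoAdmissibleCandidate,
    RegenerationConfig,
    SignalField,
    StateError,
    amputate,
    candidate_set,
    admissible,
    detect_violations,
    make_ellipse,
    make_glyph,
    make_rectangle,
    neighbors8,
    new_field,
    old_field,
    run,
    select_3a,
    select_3b,
)
from cellregen.errors import InvalidArgumentError

from _oracle import field_at, kern, naive_run


class TestConfig:
    def test_defaults_valid(self):
        cfg = RegenerationConfig()
        assert cfg.rule == "3b" and cfg.epsilon == 1e-14

    def test_roundtrip(self):
        cfg = RegenerationConfig(rule="3a", epsilon=1e-10, search_margin=3)
        assert RegenerationConfig.from_dict(cfg.to_dict()) == cfg

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"rule": "3c"},
            {"epsilon": 0.0},
            {"max_steps": 0},
            {"search_margin": -1},
            {"tie_break": "zigzag"},
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(InvalidArgumentError):
            RegenerationConfig(**kwargs)

    def test_unknown_key(self):
        with pytest.raises(InvalidArgumentError):
            RegenerationConfig.from_dict({"ruleX": "3a"})


class TestCandidateSet:
    def test_straight_cut_initial_candidates(self, square_3x3_cut_top):
        cands = candidate_set(square_3x3_cut_top, search_margin=5)
        # empty 8-neighbours of the middle-row blastema
        expected = set()
        for b in square_3x3_cut_top.blastema:
            expected |= neighbors8(b)
        expected -= square_3x3_cut_top.control
        assert cands == expected

    def test_new_cell_extends_candidates(self, rect_12x8_cut4):
        base = candidate_set(rect_12x8_cut4, 5)
        grown = rect_12x8_cut4.copy()
        grown.add_new((5, 4))
        extended = candidate_set(grown, 5)
        assert (5, 5) in extended
        assert (5, 4) not in extended  # now occupied
        assert extended >= (base - {(5, 4)})

    def test_window_bounds(self, square_3x3_cut_top):
        cands = candidate_set(square_3x3_cut_top, search_margin=0)
        assert all(0 <= x <= 2 and 0 <= y <= 2 for x, y in cands)

    def test_requires_blastema(self, poly2):
        with pytest.raises(StateError):
            candidate_set(make_rectangle(3, 3))


class TestAdmissible:
    def test_wound_candidate_admissible(self, square_3x3_cut_top, poly2):
        old = old_field(square_3x3_cut_top, poly2)
        new = new_field(square_3x3_cut_top, poly2)
        assert admissible((1, 2), old, new, poly2, 1e-14)

    def test_far_outside_inadmissible_on_intact_side(self, poly2):
        """A cell hugging the untouched boundary overshoots a nearby control."""
        rect = make_rectangle(12, 8)
        cut = amputate(rect, lambda n: n[1] >= 7)  # shallow cut, small deficits
        old = old_field(cut, poly2)
        new = new_field(cut, poly2)
        assert not admissible((5, -1), old, new, poly2, 1e-14)

    def test_toggle_disables_check(self, poly2):
        old = SignalField({(0, 0): 1.0})
        new = SignalField({(0, 0): 1.0})
        assert admissible((1, 0), old, new, poly2, 1e-14, enforce_condition2=False)
        assert not admissible((1, 0), old, new, poly2, 1e-14)


class TestSelectionRules:
    def test_two_control_illustration(self, poly2):
        """With two controls, 3a picks the position adding the largest f(dA)+f(dB)."""
        old = SignalField({(0, 0): 10.0, (4, 0): 10.0})
        new = SignalField({(0, 0): 1.0, (4, 0): 1.0})
        candidates = [(1, 1), (2, 1), (3, 1)]
        chosen = select_3a(candidates, old, new, poly2)
        scores = {
            c: math.fsum(kern("polynomial", 2.0, (c[0] - p[0]) ** 2 + (c[1] - p[1]) ** 2)
                         for p in old)
            for c in candidates
        }
        assert chosen == max(candidates, key=lambda c: scores[c])

    def test_single_candidate(self, poly2):
        old = SignalField({(0, 0): 10.0})
        new = SignalField({(0, 0): 1.0})
        assert select_3b([(2, 0)], old, new, poly2) == (2, 0)

    def test_symmetric_tie_resolved_by_order(self, poly2):
        old = SignalField({(0, 0): 10.0})
        new = SignalField({(0, 0): 1.0})
        # (-1,0) and (1,0) are equidistant: the (y,x)-smallest wins
        assert select_3b([(1, 0), (-1, 0)], old, new, poly2) == (-1, 0)

    def test_stall_signal(self, poly2):
        old = SignalField({(0, 0): 1.0})
        new = SignalField({(0, 0): 1.0})  # zero deficit: everything overshoots
        with pytest.raises(NoAdmissibleCandidate):
            select_3a([(1, 0)], old, new, poly2)

    @pytest.mark.parametrize("rule", ["3a", "3b"])
    def test_brute_force_argmax_small_fixture(self, poly2, rule):
        """Engine choice equals exhaustive naive argmax on a <=40 cell fixture."""
        cut = amputate(make_rectangle(6, 5), lambda n: n[1] >= 3)
        nodes = cut.control | cut.removed
        status, placements = naive_run(nodes, cut.removed, rule=rule, max_steps=50)
        result = run(cut, poly2, RegenerationConfig(rule=rule, max_steps=50))
        assert [t.node for t in result.trace] == placements
        assert result.status == status


class TestRun:
    @pytest.mark.parametrize("rule", ["3a", "3b"])
    def test_rectangle_roundtrip(self, rect_12x8_cut4, poly2, rule):
        res = run(rect_12x8_cut4, poly2, RegenerationConfig(rule=rule))
        assert res.status == "exact"
        assert res.structure.new == rect_12x8_cut4.removed

    def test_without_condition2_violates_outside(self, rect_12x8_cut4, poly2):
        cfg = RegenerationConfig(rule="3a", enforce_condition2=False, max_steps=300)
        res = run(rect_12x8_cut4, poly2, cfg)
        assert res.status == "violation"
        assert res.structure.new - rect_12x8_cut4.removed
        assert res.worst_violation is not None

    def test_single_cell_restored_in_one_step(self, poly2):
        cut = amputate(make_rectangle(4, 4), [(1, 1)])
        res = run(cut, poly2, RegenerationConfig())
        assert res.status == "exact" and res.steps_taken == 1
        assert res.trace[0].node == (1, 1)

    def test_long_thin_failure(self):
        """A slowly decaying kernel cannot regenerate a long amputation."""
        rect = make_rectangle(30, 4)
        cut = amputate(rect, lambda n: n[0] >= 18)
        res = run(cut, Kernel("polynomial", 1.0), RegenerationConfig(max_steps=200))
        assert res.status != "exact"

    def test_trace_consistency(self, rect_12x8_cut4, poly2):
        res = run(rect_12x8_cut4, poly2, RegenerationConfig())
        assert len(res.trace) == res.steps_taken
        s_values = [t.S_t for t in res.trace]
        assert all(a < b for a, b in zip(s_values, s_values[1:]))

    def test_determinism(self, rect_12x8_cut4, poly2):
        a = run(rect_12x8_cut4, poly2, RegenerationConfig())
        b = run(rect_12x8_cut4, poly2, RegenerationConfig())
        assert [t.node for t in a.trace] == [t.node for t in b.trace]
        assert [t.S_t for t in a.trace] == [t.S_t for t in b.trace]

    def test_new_cells_connected_to_blastema(self, rect_12x8_cut4, poly2):
        res = run(rect_12x8_cut4, poly2, RegenerationConfig())
        region = set(res.structure.new) | set(rect_12x8_cut4.blastema)
        seen = set(rect_12x8_cut4.blastema)
        frontier = list(seen)
        while frontier:
            p = frontier.pop()
            for q in neighbors8(p) & region:
                if q not in seen:
                    seen.add(q)
                    frontier.append(q)
        assert seen == region

    def test_empty_blastema_rejected(self, poly2):
        with pytest.raises(StateError):
            run(make_rectangle(3, 3), poly2)

    def test_step_limit(self, rect_12x8_cut4, poly2):
        res = run(rect_12x8_cut4, poly2, RegenerationConfig(max_steps=3))
        assert res.status == "step_limit" and res.steps_taken == 3

    def test_literal_mode_stalls_on_deep_cut(self, rect_12x8_cut4, poly2):
        """Without memory inheritance the greedy wraps the intact boundary."""
        cfg = RegenerationConfig(new_cell_memory=False, max_steps=300)
        res = run(rect_12x8_cut4, poly2, cfg)
        assert res.status != "exact"

    def test_ellipse_roundtrip(self, poly2):
        cut = amputate(make_ellipse((5.0, 3.0)), lambda n: n[0] >= 3)
        for rule in ("3a", "3b"):
            res = run(cut, poly2, RegenerationConfig(rule=rule))
            assert res.status == "exact"
            assert res.structure.new == cut.removed

    def test_glyph_roundtrip(self, poly2):
        cut = amputate(make_glyph("L"), lambda n: n[1] >= 8)
        res = run(cut, poly2, RegenerationConfig())
        assert res.status == "exact"
        assert res.structure.new == cut.removed

    def test_exponential_kernel_roundtrip(self, exp11):
        cut = amputate(make_rectangle(12, 6), lambda n: n[1] >= 4)
        res = run(cut, exp11, RegenerationConfig())
        assert res.status == "exact"
        assert res.structure.new == cut.removed


class TestDetectViolations:
    def test_no_violation(self):
        old = SignalField({(0, 0): 1.0, (1, 0): 2.0})
        new = SignalField({(0, 0): 0.9, (1, 0): 2.0})
        violations, worst = detect_violations(old, new, 1e-14)
        assert violations == {} and worst is None

    def test_single_violation_is_worst(self):
        old = SignalField({(0, 0): 1.0, (1, 0): 2.0})
        new = SignalField({(0, 0): 1.1, (1, 0): 1.0})
        violations, worst = detect_violations(old, new, 1e-14)
        assert set(violations) == {(0, 0)} and worst == (0, 0)

    def test_worst_by_absolute_difference(self):
        # relative violation larger at (0,0), absolute larger at (1,0)
        old = SignalField({(0, 0): 1.0, (1, 0): 10.0})
        new = SignalField({(0, 0): 1.5, (1, 0): 11.0})
        violations, worst = detect_violations(old, new, 1e-14)
        assert set(violations) == {(0, 0), (1, 0)}
        assert worst == (1, 0)
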