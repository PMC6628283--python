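"""Membership evaluation, rule firing, inference and defuzzification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mamfis as m
from mamfis.fuzzy_core import ZeroAggregateError, _fire_strengths


def oracle_centroid(agg: m.AggregatedOutput, refine: int = 10) -> float:
    """Midpoint Riemann centroid of the linear interpolant at 10x resolution."""
    n_fine = (len(agg.grid) - 1) * refine
    edges = np.linspace(agg.grid[0], agg.grid[-1], n_fine + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    mu = np.interp(mids, agg.grid, agg.mu)
    return float((mu * mids).sum() / mu.sum())


class TestMembershipDegree:
    @pytest.mark.parametrize(
        "mf, x, expected",
        [
            (m.MembershipFunction("t", "trapezoidal", 0, 1, 2, 3), 1.5, 1.0),
            (m.MembershipFunction("t", "trapezoidal", 0, 1, 2, 3), 0.5, 0.5),
            (m.MembershipFunction("t", "trapezoidal", 0, 1, 2, 3), 2.5, 0.5),
            (m.MembershipFunction("t", "triangular", 0, 1, 2), 2.5, 0.0),
            (m.MembershipFunction("t", "triangular", 0, 1, 2), -0.1, 0.0),
            (m.MembershipFunction("t", "triangular", 0, 1, 2), 1.0, 1.0),
            # zero-width ramps: degree 1 at the vertical edge
            (m.MembershipFunction("t", "triangular", 1, 1, 2), 1.0, 1.0),
            (m.MembershipFunction("t", "trapezoidal", 0, 1, 2, 2), 2.0, 1.0),
        ],
    )
    def test_piecewise_linear_examples(self, mf, x, expected):
        assert m.membership_degree(mf, x) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=100)
    @given(
        bp=st.lists(st.floats(-100, 100), min_size=4, max_size=4),
        x=st.floats(-150, 150),
    )
    def test_degree_bounded_and_peak_is_one(self, bp, x):
        a, b, c, d = sorted(bp)
        mf = m.MembershipFunction("t", "trapezoidal", a, b, c, d)
        assert 0.0 <= mf.degree(x) <= 1.0
        assert mf.degree(b) == 1.0

    def test_invalid_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            m.MembershipFunction("t", "triangular", 2, 1, 0)
        with pytest.raises(ValueError):
            m.MembershipFunction("t", "trapezoidal", 0, 2, 1, 3)


class TestRuleFiring:
    def _system(self, weight=1.0, connector="AND", n_inputs=3):
        mfs = lambda: (  # noqa: E731
            m.MembershipFunction("m1", "trapezoidal", 0, 0, 1, 2),
            m.MembershipFunction("m2", "trapezoidal", 1, 2, 3, 3),
        )
        inputs = [m.FuzzyVariable(f"x{i}", 0, 3, mfs()) for i in range(n_inputs)]
        out = m.FuzzyVariable("z", 0, 3, mfs())
        rule = m.FuzzyRule((1,) * n_inputs, (1,), weight, connector)
        return m.FuzzySystem("s", inputs, [out], [rule]), rule

    @pytest.mark.parametrize(
        "connector, weight, expected",
        [("AND", 1.0, 0.3), ("OR", 1.0, 1.0), ("AND", 0.5, 0.15)],
    )
    def test_min_max_and_weight(self, connector, weight, expected):
        # degrees at x=(0.8, 1.7, 1.0) for MF1 are (1.0, 0.3, 1.0)
        system, rule = self._system(weight, connector)
        x = [0.8, 1.7, 1.0]
        degs = [system.inputs[j].mfs[0].degree(x[j]) for j in range(3)]
        assert degs == pytest.approx([1.0, 0.3, 1.0])
        got = m.rule_fire_strength(system, rule, x)
        assert got == pytest.approx(expected)

    def test_dimension_mismatch_raises(self):
        system, rule = self._system()
        with pytest.raises(ValueError):
            m.rule_fire_strength(system, rule, [0.5, 0.5])


class TestDefuzzify:
    def test_symmetric_triangle_centroid_is_center(self):
        grid = np.linspace(0, 2, 101)
        mu = np.maximum(0, 1 - abs(grid - 1))
        assert m.defuzzify(m.AggregatedOutput(grid, mu)) == pytest.approx(1.0)

    def test_constant_plateau_all_methods(self):
        agg = m.AggregatedOutput(np.linspace(0, 4, 5), np.ones(5))
        assert m.defuzzify(agg, "centroid") == pytest.approx(2.0)
        assert m.defuzzify(agg, "som") == 0.0
        assert m.defuzzify(agg, "lom") == 4.0
        assert m.defuzzify(agg, "mom") == pytest.approx(2.0)

    def test_right_ramp_closed_form(self):
        # mu(x) = x on [0,1]: centroid = int x^2 / int x = 2/3
        grid = np.linspace(0, 1, 1001)
        got = m.defuzzify(m.AggregatedOutput(grid, grid.copy()))
        assert got == pytest.approx(2 / 3, abs=1e-6)

    def test_zero_aggregate_signals_no_rule_fired(self):
        agg = m.AggregatedOutput(np.linspace(0, 1, 11), np.zeros(11))
        with pytest.raises(ZeroAggregateError):
            m.defuzzify(agg, "centroid")
        with pytest.raises(ZeroAggregateError):
            m.defuzzify(agg, "mom")

    def test_centroid_matches_riemann_oracle_on_random_aggregates(self):
        rng = np.random.default_rng(42)
        span = 0.0
        # grids at the resolutions the engine actually uses; much coarser
        # grids make the refined oracle's own cubic-order error dominate
        for _ in range(200):
            lo = rng.uniform(-50, 50)
            hi = lo + rng.uniform(0.1, 100)
            n = int(rng.integers(201, 1002))
            grid = np.linspace(lo, hi, n)
            mu = rng.uniform(0, 1, n)
            agg = m.AggregatedOutput(grid, mu)
            got = m.defuzzify(agg)
            exp = oracle_centroid(agg)
            assert abs(got - exp) <= 1e-6 * (hi - lo)


class TestInfer:
    def _single_rule_system(self, consequent_center=1.0, resolution=1001):
        inp = m.FuzzyVariable(
            "x", 0, 2, (m.MembershipFunction("any", "trapezoidal", 0, 0, 2, 2),)
        )
        out_mfs = (
            m.MembershipFunction(
                "c", "triangular",
                consequent_center - 1, consequent_center, consequent_center + 1,
            ),
        )
        out = m.FuzzyVariable(
            "z", consequent_center - 1, consequent_center + 1, out_mfs
        )
        return m.FuzzySystem(
            "s", [inp], [out], [m.FuzzyRule((1,), (1,))], resolution=resolution
        )

    def test_single_always_firing_rule_returns_consequent_centroid(self):
        system = self._single_rule_system(consequent_center=1.0)
        assert m.infer(system, [0.7])[0] == pytest.approx(1.0)

    def test_two_equal_rules_symmetric_about_two(self):
        inp = m.FuzzyVariable(
            "x", 0, 2, (m.MembershipFunction("any", "trapezoidal", 0, 0, 2, 2),)
        )
        out = m.FuzzyVariable(
            "z", 0, 4,
            (
                m.MembershipFunction("lo", "triangular", 0, 1, 2),
                m.MembershipFunction("hi", "triangular", 2, 3, 4),
            ),
        )
        system = m.FuzzySystem(
            "s", [inp], [out], [m.FuzzyRule((1,), (1,)), m.FuzzyRule((1,), (2,))]
        )
        assert m.infer(system, [1.0])[0] == pytest.approx(2.0)

    def test_mixed_strength_aggregate_matches_midpoint_oracle(self, staggered_system):
        system = staggered_system
        var = system.outputs[0]
        span = var.range_hi - var.range_lo
        n_fine = (system.resolution - 1) * 10
        edges = np.linspace(var.range_lo, var.range_hi, n_fine + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        for x in np.linspace(0, 10, 23):
            strengths = _fire_strengths(system, np.array([[x]]))[:, 0]
            mu = np.zeros_like(mids)
            for s, rule in zip(strengths, system.rules):
                mf = var.mfs[rule.consequent[0] - 1]
                mu = np.maximum(mu, np.minimum(s, mf.degree(mids)))
            expected = (mu * mids).sum() / mu.sum()
            assert abs(m.infer(system, [x])[0] - expected) <= 1e-6 * span

    def test_deterministic_bit_for_bit(self, staggered_system):
        X = np.linspace(0, 10, 50).reshape(-1, 1)
        a, _ = m.infer_batch(staggered_system, X)
        b, _ = m.infer_batch(staggered_system, X)
        assert np.array_equal(a, b)

    def test_translation_shifts_centroid_exactly(self, staggered_system):
        import dataclasses

        delta = 13.25
        sys0 = staggered_system
        shifted_out = m.FuzzyVariable(
            "z",
            sys0.outputs[0].range_lo + delta,
            sys0.outputs[0].range_hi + delta,
            tuple(
                m.MembershipFunction(
                    mf.label, mf.shape, mf.a + delta, mf.b + delta,
                    mf.c + delta, None if mf.d is None else mf.d + delta,
                )
                for mf in sys0.outputs[0].mfs
            ),
        )
        sys1 = dataclasses.replace(sys0, outputs=[shifted_out])
        for x in (0.5, 3.0, 6.5, 9.0):
            a = m.infer(sys0, [x])[0]
            b = m.infer(sys1, [x])[0]
            assert b - a == pytest.approx(delta, abs=1e-9)

    def test_no_rule_fired_midpoint_and_flag(self):
        # input MF only covers [0,1]; rules cannot fire beyond it
        inp = m.FuzzyVariable(
            "x", 0, 4,
            (
                m.MembershipFunction("lo", "triangular", 0, 0.5, 1),
                m.MembershipFunction("hi", "triangular", 3, 3.5, 4),
            ),
        )
        out = m.FuzzyVariable(
            "z", 0, 2, (m.MembershipFunction("c", "triangular", 0, 1, 2),)
        )
        system = m.FuzzySystem("s", [inp], [out], [m.FuzzyRule((1,), (1,))])
        with pytest.warns(m.fuzzy_core.NoRuleFiredWarning):
            crisp, flags = m.infer_batch(system, [[3.5]])
        assert flags[0, 0]
        assert crisp[0, 0] == pytest.approx(1.0)  # midpoint of [0, 2]
        assert system.diagnostics["no_rule_fired"] == 1

    def test_empty_rule_base_rejected(self):
        inp = m.FuzzyVariable(
            "x", 0, 1, (m.MembershipFunction("a", "trapezoidal", 0, 0, 1, 1),)
        )
        out = m.FuzzyVariable(
            "z", 0, 1, (m.MembershipFunction("a", "trapezoidal", 0, 0, 1, 1),)
        )
        system = m.FuzzySystem("s", [inp], [out], [])
        with pytest.raises(ValueError):
            m.infer(system, [0.5])


class TestClassify:
    def _outvar(self):
        return m.FuzzyVariable(
            "z", 0, 3,
            (
                m.MembershipFunction("c1", "triangular", 0, 1, 2),
                m.MembershipFunction("c2", "triangular", 1, 2, 3),
            ),
        )

    def test_nearer_peak_wins(self):
        assert m.classify(self._outvar(), 1.1, [1, 2]) == 1

    def test_exact_tie_breaks_to_lower_index(self):
        assert m.classify(self._outvar(), 1.5, [1, 2]) == 1

    def test_plateau_membership_dominates(self):
        var = m.FuzzyVariable(
            "z", 0, 3,
            (
                m.MembershipFunction("c1", "triangular", 0, 1, 2),
                m.MembershipFunction("c2", "trapezoidal", 1, 1.8, 2.2, 3),
            ),
        )
        assert m.classify(var, 1.9, [1, 2]) == 2

    def test_batch_agrees_with_scalar(self):
        var = self._outvar()
        xs = np.linspace(0, 3, 31)
        batch = m.classify_batch(var, xs, [1, 2])
        scalar = [m.classify(var, x, [1, 2]) for x in xs]
        assert np.array_equal(batch, scalar)
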