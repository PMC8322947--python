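"""Forward arcs, operating-point solutions, and loop-gain algebra."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from baroloop import (
    MNArcParams,
    NMArcParams,
    attenuation_factor,
    gain_from_attenuation,
    mn_arc_response,
    nm_arc_response,
    open_loop_gain,
    parallel_shift_counterfactual,
    solve_operating_point,
    solve_operating_point_numeric,
    tilt_disturbance_report,
)
from baroloop.exceptions import InvalidArgumentError, NoRootError, UndefinedRatioError

# randomized-grid strategies spanning physiological parameter ranges
gains_mn = st.floats(min_value=0.5, max_value=20.0)
gains_nm = st.floats(min_value=0.05, max_value=2.0)
intercepts_nm = st.floats(min_value=20.0, max_value=60.0)
setpoints = st.floats(min_value=80.0, max_value=130.0)


class TestArcResponses:
    @pytest.mark.parametrize(
        "ap, expected",
        [
            (103.0, 0.0),  # at the set point the drive is silent
            (92.303, 8.92 * (103.0 - 92.303)),  # ~95.42 below it
            (120.0, 0.0),  # above the set point: no response, clamped at floor
        ],
    )
    def test_mn_response(self, mn_mean, ap, expected):
        assert mn_arc_response(ap, mn_mean) == pytest.approx(expected, abs=1e-12)

    def test_mn_response_nonincreasing_and_continuous_at_setpoint(self, mn_mean):
        eps = 1e-9
        assert mn_arc_response(103.0 - eps, mn_mean) == pytest.approx(0.0, abs=1e-6)
        aps = [60 + i for i in range(60)]
        vals = [mn_arc_response(a, mn_mean) for a in aps]
        assert all(x >= y for x, y in zip(vals, vals[1:]))

    def test_mn_respects_nonzero_floor(self):
        mn = MNArcParams(g_mn=8.92, ap_mn0=103.0, pne_floor=20.0)
        assert mn_arc_response(120.0, mn) == 20.0

    @pytest.mark.parametrize(
        "pne, g_nm, ap_nm0, expected",
        [
            (0.0, 0.61, 34.1, 34.1),  # null-PNE offset by definition
            (95.42, 0.36, 33.4, 0.36 * 95.42 + 33.4),  # ~67.75
            (47.0, 0.5778, 33.84, 0.5778 * 47 + 33.84),  # ~61.0, the blockade mean
        ],
    )
    def test_nm_response(self, pne, g_nm, ap_nm0, expected):
        nm = NMArcParams(g_nm=g_nm, ap_nm0=ap_nm0)
        assert nm_arc_response(pne, nm) == pytest.approx(expected, abs=1e-12)

    def test_invalid_inputs_rejected(self, mn_mean, nm_supine):
        with pytest.raises(InvalidArgumentError):
            mn_arc_response(float("nan"), mn_mean)
        with pytest.raises(InvalidArgumentError):
            nm_arc_response(-1.0, nm_supine)
        with pytest.raises(InvalidArgumentError):
            MNArcParams(g_mn=-1.0, ap_mn0=100.0)
        with pytest.raises(InvalidArgumentError):
            NMArcParams(g_nm=-0.1, ap_nm0=30.0)


class TestGainAlgebra:
    def test_open_loop_gain_is_product(self, mn_mean, nm_supine, nm_hut15):
        assert open_loop_gain(mn_mean, nm_supine) == pytest.approx(5.4412)
        assert open_loop_gain(mn_mean, nm_hut15) == pytest.approx(3.2112)
        assert open_loop_gain(MNArcParams(0.0, 103.0), nm_supine) == 0.0

    @pytest.mark.parametrize(
        "g_l, expected",
        [(0.0, 1.0), (3.0, 0.25), (5.4412, 1 / 6.4412)],
    )
    def test_attenuation_factor(self, g_l, expected):
        assert attenuation_factor(g_l) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("ratio, expected", [(0.25, 3.0), (1.0, 0.0)])
    def test_gain_from_attenuation(self, ratio, expected):
        assert gain_from_attenuation(ratio) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [-0.5, 0.0, 1.5])
    def test_gain_from_attenuation_domain(self, bad):
        with pytest.raises(InvalidArgumentError):
            gain_from_attenuation(bad)

    @settings(max_examples=200, derandomize=True)
    @given(g=st.floats(min_value=0.0, max_value=100.0))
    def test_attenuation_roundtrip(self, g):
        assert gain_from_attenuation(attenuation_factor(g)) == pytest.approx(
            g, rel=1e-12, abs=1e-12
        )


class TestOperatingPoint:
    def test_group_mean_equilibria(self, mn_mean, nm_supine, nm_hut15):
        op0 = solve_operating_point(mn_mean, nm_supine)
        assert op0.ap == pytest.approx(92.3032354, abs=1e-6)
        assert op0.pne == pytest.approx(95.4151400, abs=1e-6)
        assert not op0.boundary
        op15 = solve_operating_point(mn_mean, nm_hut15)
        assert op15.ap == pytest.approx(86.4726444, abs=1e-6)
        assert op15.pne == pytest.approx(147.4240122, abs=1e-6)

    def test_point_satisfies_both_arcs(self, mn_mean, nm_supine):
        op = solve_operating_point(mn_mean, nm_supine)
        assert abs(nm_arc_response(op.pne, nm_supine) - op.ap) <= 1e-9
        assert abs(mn_arc_response(op.ap, mn_mean) - op.pne) <= 1e-9

    def test_arcs_meeting_at_setpoint(self, mn_mean):
        op = solve_operating_point(mn_mean, NMArcParams(g_nm=0.61, ap_nm0=103.0))
        assert op.ap == pytest.approx(103.0)
        assert op.pne == pytest.approx(0.0, abs=1e-12)

    def test_boundary_when_plant_pressure_exceeds_setpoint(self, mn_mean):
        # NM line already above the set point at zero PNE: reflex saturates
        op = solve_operating_point(mn_mean, NMArcParams(g_nm=0.5, ap_nm0=120.0))
        assert op.boundary
        assert op.pne == 0.0
        assert op.ap == pytest.approx(120.0)

    def test_degenerate_both_gains_zero(self):
        op = solve_operating_point(
            MNArcParams(0.0, 103.0), NMArcParams(0.0, 34.1)
        )
        assert op.boundary and op.ap == pytest.approx(34.1) and op.pne == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(g_mn=gains_mn, g_nm=gains_nm, ap_nm0=intercepts_nm, ap_mn0=setpoints)
    def test_convex_combination_bound(self, g_mn, g_nm, ap_nm0, ap_mn0):
        """AP* lies strictly between the plant offset and the set point."""
        op = solve_operating_point(
            MNArcParams(g_mn, ap_mn0), NMArcParams(g_nm, ap_nm0)
        )
        assert ap_nm0 < op.ap < ap_mn0

    @settings(max_examples=100, derandomize=True)
    @given(
        g_mn=gains_mn, g_nm=gains_nm, ap_nm0=intercepts_nm, ap_mn0=setpoints,
        delta=st.floats(min_value=1.0, max_value=30.0),
    )
    def test_ap_star_increasing_in_plant_offset(self, g_mn, g_nm, ap_nm0, ap_mn0, delta):
        mn = MNArcParams(g_mn, ap_mn0)
        lo = solve_operating_point(mn, NMArcParams(g_nm, ap_nm0 - delta))
        hi = solve_operating_point(mn, NMArcParams(g_nm, ap_nm0))
        assert hi.ap > lo.ap


class TestNumericSolver:
    @settings(max_examples=150, derandomize=True)
    @given(g_mn=gains_mn, g_nm=gains_nm, ap_nm0=intercepts_nm, ap_mn0=setpoints)
    def test_agrees_with_closed_form(self, g_mn, g_nm, ap_nm0, ap_mn0):
        mn = MNArcParams(g_mn, ap_mn0)
        nm = NMArcParams(g_nm, ap_nm0)
        closed = solve_operating_point(mn, nm)
        numeric = solve_operating_point_numeric(
            lambda ap: mn_arc_response(ap, mn),
            lambda pne: nm_arc_response(pne, nm),
            ap_bracket=(0.0, 200.0),
        )
        assert abs(numeric.ap - closed.ap) <= 1e-6

    def test_sigmoidal_controller_fixed_point(self, nm_hut15):
        """A logistic (saturating) controller curve has a self-consistent root."""
        mn_curve = lambda ap: 300.0 / (1.0 + math.exp(0.1 * (ap - 90.0)))
        nm_curve = lambda pne: 0.36 * pne + 33.4
        op = solve_operating_point_numeric(mn_curve, nm_curve, (0.0, 200.0))
        assert abs(nm_curve(mn_curve(op.ap)) - op.ap) <= 1e-9
        assert op.pne == pytest.approx(mn_curve(op.ap))

    def test_no_sign_change_raises(self, mn_mean, nm_supine):
        with pytest.raises(NoRootError):
            solve_operating_point_numeric(
                lambda ap: mn_arc_response(ap, mn_mean),
                lambda pne: nm_arc_response(pne, nm_supine),
                ap_bracket=(150.0, 200.0),
            )


class TestDisturbanceDecomposition:
    def test_group_mean_tilt_decomposition(self, mn_mean, nm_supine, nm_hut15):
        rep = tilt_disturbance_report(mn_mean, nm_supine, nm_hut15)
        assert rep.closed_loop_delta_ap == pytest.approx(5.8306, abs=1e-3)
        assert rep.open_loop_delta_ap == pytest.approx(24.5538, abs=1e-3)
        assert rep.attenuation_ratio == pytest.approx(0.23746, abs=1e-4)
        assert rep.implied_gl == pytest.approx(3.2112, abs=1e-3)
        assert round(rep.closed_loop_delta_ap) == 6
        assert round(rep.implied_gl) == 3

    def test_zero_disturbance_rejected(self, mn_mean, nm_supine):
        with pytest.raises(UndefinedRatioError):
            tilt_disturbance_report(mn_mean, nm_supine, nm_supine)
        with pytest.raises(UndefinedRatioError):
            parallel_shift_counterfactual(mn_mean, nm_supine, nm_supine)

    def test_pure_parallel_shift_attenuation(self, mn_mean, nm_supine):
        """Lowering only the plant offset is attenuated by exactly 1/(1+G_L)."""
        shifted = NMArcParams(g_nm=0.61, ap_nm0=34.1 - 10.0)
        rep = tilt_disturbance_report(mn_mean, nm_supine, shifted)
        g_l = open_loop_gain(mn_mean, nm_supine)
        assert rep.closed_loop_delta_ap == pytest.approx(10.0 / (1 + g_l), rel=1e-9)
        assert rep.attenuation_ratio == pytest.approx(1.0 / (1 + g_l), rel=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(
        g_mn=gains_mn, g_nm=gains_nm, ap_nm0=intercepts_nm, ap_mn0=setpoints,
        delta=st.floats(min_value=0.5, max_value=15.0),
    )
    def test_parallel_shift_law_randomized(self, g_mn, g_nm, ap_nm0, ap_mn0, delta):
        mn = MNArcParams(g_mn, ap_mn0)
        pre = NMArcParams(g_nm, ap_nm0)
        rep = tilt_disturbance_report(mn, pre, NMArcParams(g_nm, ap_nm0 - delta))
        g_l = g_mn * g_nm
        assert rep.closed_loop_delta_ap == pytest.approx(delta / (1 + g_l), rel=1e-9)

    @settings(max_examples=60, derandomize=True)
    @given(
        g_nm=gains_nm, ap_nm0=intercepts_nm, ap_mn0=setpoints,
        g_lo=st.floats(min_value=0.5, max_value=9.0),
        bump=st.floats(min_value=0.5, max_value=10.0),
    )
    def test_closed_loop_fall_decreases_with_controller_gain(
        self, g_nm, ap_nm0, ap_mn0, g_lo, bump
    ):
        """A stronger controller buffers the same plant shift more."""
        pre = NMArcParams(g_nm, ap_nm0)
        post = NMArcParams(g_nm, ap_nm0 - 8.0)
        weak = tilt_disturbance_report(MNArcParams(g_lo, ap_mn0), pre, post)
        strong = tilt_disturbance_report(MNArcParams(g_lo + bump, ap_mn0), pre, post)
        assert strong.closed_loop_delta_ap < weak.closed_loop_delta_ap


class TestParallelShiftCounterfactual:
    def test_group_mean_counterfactual(self, mn_mean, nm_supine, nm_hut15):
        rep = parallel_shift_counterfactual(mn_mean, nm_supine, nm_hut15)
        assert rep.closed_loop_delta_ap == pytest.approx(3.8120, abs=1e-3)
        assert rep.closed_loop_delta_ap < 4.0
        assert rep.implied_gl == pytest.approx(5.4412, rel=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(
        g_mn=gains_mn, g_nm=gains_nm, ap_mn0=setpoints,
        ap_nm0=intercepts_nm,
        g_post=gains_nm, drop=st.floats(min_value=0.5, max_value=15.0),
    )
    def test_counterfactual_identity_randomized(
        self, g_mn, g_nm, ap_mn0, ap_nm0, g_post, drop
    ):
        """Implied loop gain equals G_MN*G_NM(pre) exactly, for any post line."""
        mn = MNArcParams(g_mn, ap_mn0)
        pre = NMArcParams(g_nm, ap_nm0)
        post = NMArcParams(g_post, ap_nm0 - drop)
        before = solve_operating_point(mn, pre)
        open_loop_ap = nm_arc_response(before.pne, post)
        if open_loop_ap >= before.ap - 1e-6:
            # not a pressure-lowering disturbance: outside the identity's
            # domain (the reflex may saturate at the set point)
            return
        rep = parallel_shift_counterfactual(mn, pre, post)
        assert rep.implied_gl == pytest.approx(g_mn * g_nm, rel=1e-9)
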