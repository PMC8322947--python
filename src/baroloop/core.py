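"""Static closed-loop model of the sympathetic arterial baroreflex.

The reflex is split into two arcs sharing the same pair of variables,
arterial pressure (AP, mmHg) and plasma norepinephrine (PNE, pg/ml, a
surrogate for sympathetic nerve activity):

* the **mechanoneural (MN) arc** — the controller: baroreceptors sense AP
  and drive sympathetic outflow, ``PNE = max(floor, G_MN * (AP_MN,0 - AP))``;
* the **neuromechanical (NM) arc** — the plant: sympathetic outflow raises
  pressure, ``AP = G_NM(phi) * PNE + AP_NM,0(phi)``, with both parameters
  depending on the tilt angle ``phi``.

Superimposing the two curves on one PNE-AP plane gives the equilibrium
diagram; the closed-loop operating point is their intersection.  The
open-loop gain ``G_L = G_MN * G_NM`` measures how well the loop buffers a
disturbance: a pure parallel drop of the NM curve by ``D`` mmHg moves the
operating pressure by only ``D / (1 + G_L)``.

Everything here is static (equilibria only) and purely in-memory; file I/O
lives in :mod:`baroloop.io`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Tuple

from .exceptions import InvalidArgumentError, NoRootError, UndefinedRatioError

#: Residual tolerance (mmHg) for equilibrium solutions.
RESIDUAL_TOL = 1e-9


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise InvalidArgumentError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class MNArcParams:
    """Mechanoneural (controller) line: pressure in, norepinephrine out.

    Parameters
    ----------
    g_mn:
        Arc gain, pg·ml⁻¹·mmHg⁻¹; the PNE released per mmHg of pressure fall
        below the set point.  Stored positive; the slope of the line on the
        PNE-vs-AP plane is ``-g_mn``.
    ap_mn0:
        AP-axis intercept, mmHg.  Approximates the set point: above it the
        sympathetic drive is silent.
    pne_floor:
        Minimal PNE when the reflex is silent, pg·ml⁻¹.  Zero by default;
        a positive value models a non-neural residual release.
    """

    g_mn: float
    ap_mn0: float
    pne_floor: float = 0.0

    def __post_init__(self) -> None:
        _require_finite("g_mn", self.g_mn)
        _require_finite("ap_mn0", self.ap_mn0)
        _require_finite("pne_floor", self.pne_floor)
        if self.g_mn < 0:
            raise InvalidArgumentError(f"g_mn must be >= 0, got {self.g_mn}")
        if self.pne_floor < 0:
            raise InvalidArgumentError(f"pne_floor must be >= 0, got {self.pne_floor}")


@dataclass(frozen=True)
class NMArcParams:
    """Neuromechanical (plant) line at one tilt angle: PNE in, pressure out.

    Parameters
    ----------
    g_nm:
        Arc gain, mmHg·ml·pg⁻¹; pressure produced per unit PNE.
    ap_nm0:
        AP generated at null PNE, mmHg (the intercept of the plant line).
    angle_deg:
        Optional annotation: the tilt angle this parameterization belongs to.
    """

    g_nm: float
    ap_nm0: float
    angle_deg: float | None = None

    def __post_init__(self) -> None:
        _require_finite("g_nm", self.g_nm)
        _require_finite("ap_nm0", self.ap_nm0)
        if self.g_nm < 0:
            raise InvalidArgumentError(f"g_nm must be >= 0, got {self.g_nm}")


@dataclass(frozen=True)
class OperatingPoint:
    """Closed-loop equilibrium: the (AP, PNE) pair satisfying both arcs.

    ``boundary`` is True when the unconstrained line intersection would
    demand PNE below the floor, so the point sits on the NM line at the
    floor instead (the loop cannot command negative norepinephrine).
    """

    ap: float
    pne: float
    boundary: bool = False


@dataclass(frozen=True)
class DisturbanceReport:
    """Decomposition of a tilt disturbance into closed- and open-loop falls.

    ``closed_loop_delta_ap`` is the actual equilibrium pressure fall;
    ``open_loop_delta_ap`` is the fall that would occur if the reflex did
    not respond (PNE frozen at its pre-disturbance value).  Their ratio is
    the attenuation achieved by the loop, and ``1/ratio - 1`` recovers an
    implied open-loop gain.
    """

    ap_before: float
    ap_after: float
    pne_before: float
    closed_loop_delta_ap: float
    open_loop_delta_ap: float
    attenuation_ratio: float
    implied_gl: float


def mn_arc_response(ap: float, mn: MNArcParams) -> float:
    """Norepinephrine commanded by the controller at arterial pressure ``ap``.

    Rectified-linear: ``max(pne_floor, g_mn * (ap_mn0 - ap))``.  Above the
    set point the reflex is silent and the floor value is returned.
    """
    ap = _require_finite("ap", ap)
    return max(mn.pne_floor, mn.g_mn * (mn.ap_mn0 - ap))


def nm_arc_response(pne: float, nm: NMArcParams) -> float:
    """Arterial pressure produced by the plant at norepinephrine level ``pne``."""
    pne = _require_finite("pne", pne)
    if pne < 0:
        raise InvalidArgumentError(f"pne must be >= 0, got {pne}")
    return nm.g_nm * pne + nm.ap_nm0


def open_loop_gain(mn: MNArcParams, nm: NMArcParams) -> float:
    """Open-loop gain G_L = G_MN * G_NM, the product of the two arc gains."""
    return mn.g_mn * nm.g_nm


def attenuation_factor(g_l: float) -> float:
    """Fraction 1/(1 + G_L) of a disturbance surviving closed-loop feedback."""
    g_l = _require_finite("g_l", g_l)
    if g_l < 0:
        raise InvalidArgumentError(f"g_l must be >= 0, got {g_l}")
    return 1.0 / (1.0 + g_l)


def gain_from_attenuation(ratio: float) -> float:
    """Invert the attenuation relation: G_L = 1/ratio - 1 for ratio in (0, 1]."""
    ratio = _require_finite("ratio", ratio)
    if not 0.0 < ratio <= 1.0:
        raise InvalidArgumentError(f"attenuation ratio must be in (0, 1], got {ratio}")
    return 1.0 / ratio - 1.0


def solve_operating_point(mn: MNArcParams, nm: NMArcParams) -> OperatingPoint:
    """Closed-form equilibrium of the two linear arcs.

    The unconstrained intersection is

    ``AP* = (G_L * AP_MN,0 + AP_NM,0) / (1 + G_L)``,
    ``PNE* = G_MN * (AP_MN,0 - AP*)``.

    If ``PNE*`` falls below the MN floor the loop saturates: the point is
    placed on the NM line at the floor and flagged ``boundary=True``.  The
    degenerate case ``G_MN = G_NM = 0`` lands there too, at ``AP = AP_NM,0``.
    """
    g_l = open_loop_gain(mn, nm)
    if not math.isfinite(g_l):
        raise InvalidArgumentError("open-loop gain must be finite")
    ap_star = (g_l * mn.ap_mn0 + nm.ap_nm0) / (1.0 + g_l)
    pne_star = mn.g_mn * (mn.ap_mn0 - ap_star)
    if pne_star < mn.pne_floor or (mn.g_mn == 0.0 and nm.g_nm == 0.0):
        pne = mn.pne_floor
        return OperatingPoint(ap=nm_arc_response(pne, nm), pne=pne, boundary=True)
    return OperatingPoint(ap=ap_star, pne=pne_star, boundary=False)


def solve_operating_point_numeric(
    mn_curve: Callable[[float], float],
    nm_curve: Callable[[float], float],
    ap_bracket: Tuple[float, float],
    tol: float = RESIDUAL_TOL,
) -> OperatingPoint:
    """Bisection solver for arbitrary monotone arc curves.

    ``mn_curve`` maps AP to PNE (non-increasing), ``nm_curve`` maps PNE to
    AP (non-decreasing).  The fixed-point residual
    ``r(ap) = nm_curve(mn_curve(ap)) - ap`` must change sign over
    ``ap_bracket``; monotonicity of the inputs is the caller's
    responsibility and is not verified.  Bisects until ``|r| <= tol``.

    Serves as an independent check on :func:`solve_operating_point` for
    linear arcs and supports nonlinear (e.g. sigmoidal) arcs directly.
    """
    lo, hi = (float(ap_bracket[0]), float(ap_bracket[1]))
    if lo > hi:
        lo, hi = hi, lo

    def residual(ap: float) -> float:
        return nm_curve(mn_curve(ap)) - ap

    r_lo, r_hi = residual(lo), residual(hi)
    for r, ap in ((r_lo, lo), (r_hi, hi)):
        if abs(r) <= tol:
            return OperatingPoint(ap=ap, pne=mn_curve(ap), boundary=False)
    if r_lo * r_hi > 0:
        raise NoRootError(
            f"fixed-point residual does not change sign over [{lo}, {hi}] "
            f"(r(lo)={r_lo:.6g}, r(hi)={r_hi:.6g})"
        )
    # plain bisection: robust for the monotone residuals this supports
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        r_mid = residual(mid)
        if abs(r_mid) <= tol:
            break
        if r_lo * r_mid <= 0:
            hi = mid
        else:
            lo, r_lo = mid, r_mid
    else:
        mid = 0.5 * (lo + hi)
    return OperatingPoint(ap=mid, pne=mn_curve(mid), boundary=False)


def _decompose(
    mn: MNArcParams,
    nm_pre: NMArcParams,
    nm_post: NMArcParams,
) -> DisturbanceReport:
    before = solve_operating_point(mn, nm_pre)
    after = solve_operating_point(mn, nm_post)
    open_loop_ap = nm_arc_response(before.pne, nm_post)
    closed_delta = before.ap - after.ap
    open_delta = before.ap - open_loop_ap
    if abs(open_delta) <= RESIDUAL_TOL:
        raise UndefinedRatioError(
            "open-loop pressure change is zero: the pre- and post-disturbance "
            "NM lines coincide at the operating norepinephrine level"
        )
    ratio = closed_delta / open_delta
    return DisturbanceReport(
        ap_before=before.ap,
        ap_after=after.ap,
        pne_before=before.pne,
        closed_loop_delta_ap=closed_delta,
        open_loop_delta_ap=open_delta,
        attenuation_ratio=ratio,
        implied_gl=gain_from_attenuation(ratio),
    )


def tilt_disturbance_report(
    mn: MNArcParams,
    nm_pre: NMArcParams,
    nm_post: NMArcParams,
) -> DisturbanceReport:
    """Decompose a tilt disturbance (NM line moving from ``nm_pre`` to ``nm_post``).

    The closed-loop fall is the distance between the two equilibria along
    the MN curve; the open-loop fall is the vertical drop obtained by
    freezing PNE at its pre-tilt value and evaluating the post-tilt NM
    line.  Because head-up tilt changes the NM *gain* as well as its
    intercept, the implied loop gain from this construction generally
    understates ``G_MN * G_NM(pre)``; see
    :func:`parallel_shift_counterfactual`.
    """
    return _decompose(mn, nm_pre, nm_post)


def parallel_shift_counterfactual(
    mn: MNArcParams,
    nm_pre: NMArcParams,
    nm_post: NMArcParams,
) -> DisturbanceReport:
    """Re-run the decomposition with a slope-preserving post-tilt NM line.

    The counterfactual line keeps the pre-disturbance gain and passes
    through the open-loop point (pre-tilt PNE, post-tilt NM response), i.e.
    the disturbance is reduced to a pure parallel shift.  For such a shift
    the attenuation is exactly ``1/(1 + G_L)``, so the implied loop gain
    equals ``G_MN * G_NM(pre)`` identically.
    """
    before = solve_operating_point(mn, nm_pre)
    open_loop_ap = nm_arc_response(before.pne, nm_post)
    intercept = open_loop_ap - nm_pre.g_nm * before.pne
    counterfactual = NMArcParams(
        g_nm=nm_pre.g_nm, ap_nm0=intercept, angle_deg=nm_post.angle_deg
    )
    return _decompose(mn, nm_pre, counterfactual)
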