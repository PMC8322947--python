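"""Per-subject arc estimation and group summaries for tilt studies.

The estimation protocol mirrors the study design the package models:

* the **MN arc** is fitted by ordinary least squares of PNE on AP across
  the baseline tilt positions (head-down, supine, and head-up angles);
  the gain is minus the slope and the set-point estimate is the AP-axis
  intercept (where the fitted PNE reaches zero);
* each **NM arc** is the line through exactly two points at one angle:
  the closed-loop baseline point and the ganglionic-blockade point, whose
  norepinephrine is a non-neural residual;
* per-subject **open-loop gains** are exact products ``G_MN * G_NM(angle)``;
* group statistics are arithmetic means and sample SDs (n-1 denominator),
  with the group open-loop gain the *mean of per-subject products*, not
  the product of group means — the two differ whenever gains covary;
* paired contrasts use an exact Wilcoxon signed-rank test (full sign-flip
  enumeration up to n = 20).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .core import MNArcParams, NMArcParams
from .exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    NoReflexResponseError,
    SchemaError,
    UndefinedTestError,
)

BASELINE = "baseline"
BLOCKADE = "blockade"

#: Angles (degrees) at which blockade measurements are required for NM fits.
NM_FIT_ANGLES = (0.0, 15.0)


@dataclass(frozen=True)
class MNArcFit:
    """An MN-arc least-squares fit with its quality diagnostics."""

    params: MNArcParams
    r: float  # Pearson correlation of the fitted PNE-vs-AP points
    n_points: int


@dataclass(frozen=True)
class MeasurementRow:
    """One (condition, angle) measurement for a subject."""

    condition: str  # BASELINE or BLOCKADE
    angle_deg: float
    ap: float  # arterial pressure, mmHg
    pne: float  # plasma norepinephrine, pg/ml
    hr: float | None = None  # heart rate, beats/min; passthrough only

    def __post_init__(self) -> None:
        if self.condition not in (BASELINE, BLOCKADE):
            raise SchemaError(
                f"condition must be '{BASELINE}' or '{BLOCKADE}', got {self.condition!r}"
            )
        if not self.ap > 0:
            raise SchemaError(f"ap must be > 0 mmHg, got {self.ap}")
        if self.pne < 0:
            raise SchemaError(f"pne must be >= 0 pg/ml, got {self.pne}")


@dataclass(frozen=True)
class SubjectRecord:
    """All measurements for one subject."""

    subject_id: str
    rows: tuple[MeasurementRow, ...]

    def baseline_rows(self) -> list[MeasurementRow]:
        return [r for r in self.rows if r.condition == BASELINE]

    def row_at(self, condition: str, angle_deg: float) -> MeasurementRow:
        for r in self.rows:
            if r.condition == condition and math.isclose(r.angle_deg, angle_deg):
                return r
        raise SchemaError(
            f"subject {self.subject_id!r}: missing ({condition}, {angle_deg:g} deg) row"
        )


@dataclass(frozen=True)
class SubjectEstimates:
    """Fitted arc parameters and open-loop gains for one subject."""

    subject_id: str
    mn_fit: MNArcFit
    nm_0: NMArcParams
    nm_15: NMArcParams
    g_l_0: float
    g_l_15: float
    flags: tuple[str, ...] = ()  # quality flags, e.g. non-positive NM slope


@dataclass(frozen=True)
class ParameterSummary:
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float  # W: rank sum of positive differences
    p_two_sided: float
    n: int  # pairs remaining after dropping zero differences


@dataclass(frozen=True)
class GroupSummary:
    """Group means ± SD of every estimated parameter plus paired contrasts.

    ``g_l_0``/``g_l_15`` follow the mean-of-products convention;
    ``g_l_0_product_of_means``/``g_l_15_product_of_means`` are reported as
    diagnostics of how much the two conventions disagree.
    """

    n_subjects: int
    parameters: dict[str, ParameterSummary]
    test_g_nm: PairedTestResult
    test_g_l: PairedTestResult
    g_l_0_product_of_means: float
    g_l_15_product_of_means: float
    excluded_subjects: tuple[str, ...] = ()
    sd_convention: str = field(default="sample (n-1)", repr=False)


def fit_mn_arc(points: Sequence[tuple[float, float]]) -> MNArcFit:
    """Least-squares MN line through baseline (AP, PNE) points.

    Ordinary unweighted OLS with AP as regressor and PNE as response:
    ``pne = m*ap + b``.  The arc gain is ``-m`` (must be positive for a
    functioning reflex) and the set-point estimate is the AP-axis
    intercept ``-b/m`` where the fitted PNE vanishes.
    """
    if len(points) < 3:
        raise InsufficientDataError(
            f"MN-arc fit needs >= 3 points, got {len(points)}"
        )
    ap = np.asarray([p[0] for p in points], dtype=float)
    pne = np.asarray([p[1] for p in points], dtype=float)
    if np.ptp(ap) == 0:
        raise DegenerateDesignError("all AP values equal: slope is unidentifiable")
    res = stats.linregress(ap, pne)
    if res.slope >= 0:
        raise NoReflexResponseError(
            f"fitted PNE-vs-AP slope is {res.slope:.4g} >= 0: "
            "no reflex response detectable"
        )
    g_mn = -res.slope
    ap_mn0 = -res.intercept / res.slope
    return MNArcFit(
        params=MNArcParams(g_mn=g_mn, ap_mn0=ap_mn0),
        r=float(res.rvalue),
        n_points=len(points),
    )


def fit_nm_arc(
    baseline_point: tuple[float, float],
    blockade_point: tuple[float, float],
    angle_deg: float | None = None,
) -> NMArcParams:
    """NM line through the baseline and blockade (PNE, AP) points at one angle.

    Slope with respect to the PNE axis is the arc gain; the intercept is
    the pressure at null norepinephrine.  Coincident PNE values are
    degenerate; a negative slope raises a typed error that the per-subject
    pipeline converts into a quality flag rather than dropping the subject.
    """
    (pne_base, ap_base), (pne_block, ap_block) = baseline_point, blockade_point
    if pne_base == pne_block:
        raise DegenerateDesignError(
            "baseline and blockade PNE coincide: NM line is undefined"
        )
    g_nm = (ap_base - ap_block) / (pne_base - pne_block)
    ap_nm0 = ap_block - g_nm * pne_block
    if g_nm < 0:
        # preserve the two-point geometry in an annotated plain record;
        # NMArcParams enforces g_nm >= 0 so it cannot carry this case
        raise NoReflexResponseError(
            f"two-point NM slope is negative ({g_nm:.4g} mmHg·ml/pg)"
        )
    return NMArcParams(g_nm=g_nm, ap_nm0=ap_nm0, angle_deg=angle_deg)


def estimate_subject(record: SubjectRecord) -> SubjectEstimates:
    """Full per-subject pipeline: MN fit, both NM fits, open-loop gains."""
    baseline = record.baseline_rows()
    angles = {r.angle_deg for r in baseline}
    if len(angles) < 3:
        raise SchemaError(
            f"subject {record.subject_id!r}: baseline rows at only "
            f"{len(angles)} distinct angles (need >= 3)"
        )
    mn_fit = fit_mn_arc([(r.ap, r.pne) for r in baseline])

    flags: list[str] = []
    nm_arcs: dict[float, NMArcParams] = {}
    for angle in NM_FIT_ANGLES:
        base = record.row_at(BASELINE, angle)
        block = record.row_at(BLOCKADE, angle)
        try:
            nm_arcs[angle] = fit_nm_arc(
                (base.pne, base.ap), (block.pne, block.ap), angle_deg=angle
            )
        except NoReflexResponseError as err:
            flags.append(f"nm_{angle:g}: {err}")
            nm_arcs[angle] = NMArcParams(g_nm=0.0, ap_nm0=base.ap, angle_deg=angle)

    g_mn = mn_fit.params.g_mn
    return SubjectEstimates(
        subject_id=record.subject_id,
        mn_fit=mn_fit,
        nm_0=nm_arcs[0.0],
        nm_15=nm_arcs[15.0],
        g_l_0=g_mn * nm_arcs[0.0].g_nm,
        g_l_15=g_mn * nm_arcs[15.0].g_nm,
        flags=tuple(flags),
    )


def wilcoxon_signed_rank_exact(
    differences: Iterable[float],
) -> PairedTestResult:
    """Exact two-sided Wilcoxon signed-rank test by sign-flip enumeration.

    Zero differences are dropped; tied magnitudes get mid-ranks.  For
    n <= 20 the null distribution of W (rank sum of positive differences)
    is built by enumerating all 2^n sign assignments and the two-sided p
    is ``min(1, 2 * min(P(W' <= W), P(W' >= W)))``.  Beyond n = 20 a
    normal approximation with tie correction is used.
    """
    d = np.asarray([x for x in differences if x != 0], dtype=float)
    n = d.size
    if n == 0:
        raise UndefinedTestError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))  # mid-ranks for ties
    w = float(ranks[d > 0].sum())
    if n <= 20:
        # distribution of W over all sign patterns; 2^20 is ~1e6 sums
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        p_le = np.mean(totals <= w + 1e-12)
        p_ge = np.mean(totals >= w - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        p = float(stats.wilcoxon(d, correction=False, mode="approx").pvalue)
    return PairedTestResult(statistic=w, p_two_sided=p, n=n)


def _summary(values: Sequence[float]) -> ParameterSummary:
    arr = np.asarray(values, dtype=float)
    return ParameterSummary(
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)),
        n=arr.size,
    )


def summarize_group(
    estimates: Sequence[SubjectEstimates],
    exclude_flagged: bool = False,
) -> GroupSummary:
    """Group means ± sample SD plus the paired 0-vs-15-degree contrasts.

    ``exclude_flagged`` drops subjects carrying quality flags (e.g. a
    negative NM slope) from the summary; they are listed, never silently
    lost.
    """
    excluded = tuple(e.subject_id for e in estimates if exclude_flagged and e.flags)
    kept = [e for e in estimates if e.subject_id not in excluded]
    if len(kept) < 2:
        raise InsufficientDataError(
            f"group summary needs >= 2 subjects, got {len(kept)}"
        )
    params = {
        "g_mn": _summary([e.mn_fit.params.g_mn for e in kept]),
        "ap_mn0": _summary([e.mn_fit.params.ap_mn0 for e in kept]),
        "r": _summary([e.mn_fit.r for e in kept]),
        "g_nm_0": _summary([e.nm_0.g_nm for e in kept]),
        "ap_nm0_0": _summary([e.nm_0.ap_nm0 for e in kept]),
        "g_nm_15": _summary([e.nm_15.g_nm for e in kept]),
        "ap_nm0_15": _summary([e.nm_15.ap_nm0 for e in kept]),
        "g_l_0": _summary([e.g_l_0 for e in kept]),
        "g_l_15": _summary([e.g_l_15 for e in kept]),
    }

    def paired(a: list[float], b: list[float]) -> PairedTestResult:
        diffs = [x - y for x, y in zip(a, b)]
        try:
            return wilcoxon_signed_rank_exact(diffs)
        except UndefinedTestError:
            return PairedTestResult(statistic=math.nan, p_two_sided=math.nan, n=0)

    return GroupSummary(
        n_subjects=len(kept),
        parameters=params,
        test_g_nm=paired([e.nm_0.g_nm for e in kept], [e.nm_15.g_nm for e in kept]),
        test_g_l=paired([e.g_l_0 for e in kept], [e.g_l_15 for e in kept]),
        g_l_0_product_of_means=params["g_mn"].mean * params["g_nm_0"].mean,
        g_l_15_product_of_means=params["g_mn"].mean * params["g_nm_15"].mean,
        excluded_subjects=excluded,
    )
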