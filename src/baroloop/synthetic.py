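"""Synthetic tilt-study cohorts with known ground truth.

The generator reproduces the structure of a graded head-up tilt study in
vagally blocked subjects: baseline closed-loop measurements at -7, 0, 15
and 60 degrees, plus ganglionic-blockade measurements at 0 and 15 degrees
where the reflex loop is opened and the measured point falls on the NM
line at a residual, non-neural norepinephrine level.

Each subject is a draw from a truncated-normal population over the arc
parameters (truncation at zero keeps gains physiological); the defaults
are the group means and SDs of a seven-subject study of healthy young
men.  Baseline rows are exact closed-loop equilibria of the subject's own
arcs, corrupted by additive Gaussian pressure noise and multiplicative
lognormal norepinephrine noise; with both noise scales at zero the data
are exactly model-consistent and the estimation pipeline recovers the
truth to machine precision.

The NM parameters are anchored at 0 and 15 degrees; between and beyond the
anchors the gain is interpolated log-linearly in sin(phi) (which keeps it
positive out to 60 degrees) and the intercept linearly in sin(phi).  This
angle law is a generator assumption, not an estimated quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .core import MNArcParams, NMArcParams, nm_arc_response, solve_operating_point
from .estimation import BASELINE, BLOCKADE, MeasurementRow, SubjectRecord
from .exceptions import InvalidArgumentError

GENERATOR_VERSION = "1.0"

ANGLE_MIN_DEG = -7.0
ANGLE_MAX_DEG = 60.0


@dataclass(frozen=True)
class SubjectTruth:
    """Generative arc parameters for one synthetic subject."""

    mn: MNArcParams
    g_nm_0: float
    ap_nm0_0: float
    g_nm_15: float
    ap_nm0_15: float
    pne_residual: float  # post-blockade non-neural PNE, pg/ml

    def __post_init__(self) -> None:
        for name in ("g_nm_0", "g_nm_15"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be > 0")
        if self.pne_residual < 0:
            raise InvalidArgumentError("pne_residual must be >= 0")


class ParamDist(BaseModel):
    """Population mean and SD of one truth parameter."""

    mean: float
    sd: float = Field(ge=0.0)


class CohortConfig(BaseModel):
    """Study design and population model for a synthetic cohort.

    Defaults match the emulated study: seven subjects, baseline tilt
    angles -7/0/15/60 degrees, blockade at 0 and 15 degrees, group-level
    parameter means and SDs from its published summary, residual
    post-blockade norepinephrine around 45 pg/ml, 2 mmHg pressure noise
    and an 8% fractional norepinephrine assay noise.
    """

    n_subjects: int = Field(default=7, ge=1)
    g_mn: ParamDist = ParamDist(mean=8.92, sd=3.07)
    ap_mn0: ParamDist = ParamDist(mean=103.0, sd=9.5)
    g_nm_0: ParamDist = ParamDist(mean=0.61, sd=0.08)
    ap_nm0_0: ParamDist = ParamDist(mean=34.1, sd=4.9)
    g_nm_15: ParamDist = ParamDist(mean=0.36, sd=0.05)
    ap_nm0_15: ParamDist = ParamDist(mean=33.4, sd=8.6)
    pne_residual: ParamDist = ParamDist(mean=45.0, sd=10.0)
    baseline_angles_deg: tuple[float, ...] = (-7.0, 0.0, 15.0, 60.0)
    blockade_angles_deg: tuple[float, ...] = (0.0, 15.0)
    ap_noise_sd: float = Field(default=2.0, ge=0.0)  # mmHg, additive
    pne_fractional_sd: float = Field(default=0.08, ge=0.0)  # lognormal CV
    seed: int = 0

    @model_validator(mode="after")
    def _check_angles(self) -> "CohortConfig":
        for name in ("baseline_angles_deg", "blockade_angles_deg"):
            angles = getattr(self, name)
            if len(set(angles)) != len(angles):
                raise ValueError(f"{name} contains duplicate angles: {angles}")
            for a in angles:
                if not ANGLE_MIN_DEG <= a <= ANGLE_MAX_DEG:
                    raise ValueError(
                        f"{name}: angle {a} outside supported "
                        f"[{ANGLE_MIN_DEG}, {ANGLE_MAX_DEG}] degrees"
                    )
        if len(self.baseline_angles_deg) < 3:
            raise ValueError("need >= 3 baseline angles for the MN-arc fit")
        return self

    _PARAM_FIELDS = (
        "g_mn", "ap_mn0", "g_nm_0", "ap_nm0_0", "g_nm_15", "ap_nm0_15", "pne_residual",
    )

    def zeroed_noise(self) -> "CohortConfig":
        """Copy of the config with both measurement-noise scales at zero."""
        return self.model_copy(update={"ap_noise_sd": 0.0, "pne_fractional_sd": 0.0})

    def zeroed_population_sds(self) -> "CohortConfig":
        """Copy with all population SDs zero: every subject equals the means."""
        update = {
            name: ParamDist(mean=getattr(self, name).mean, sd=0.0)
            for name in self._PARAM_FIELDS
        }
        return self.model_copy(update=update)


@dataclass(frozen=True)
class StudyDataset:
    """A simulated cohort plus the provenance needed to regenerate it."""

    subjects: tuple[SubjectRecord, ...]
    truths: tuple[SubjectTruth, ...]
    config: CohortConfig
    generator_version: str = GENERATOR_VERSION


def _truncnorm_draw(rng: np.random.Generator, dist: ParamDist, lower: float) -> float:
    """One draw from Normal(mean, sd) truncated below at ``lower``."""
    if dist.sd == 0.0:
        return dist.mean
    a = (lower - dist.mean) / dist.sd
    u = rng.uniform()
    return float(stats.truncnorm.ppf(u, a, np.inf, loc=dist.mean, scale=dist.sd))


def draw_population(config: CohortConfig) -> list[SubjectTruth]:
    """Draw per-subject truths from the configured population.

    Gains and the residual PNE are truncated at zero; intercepts are
    unconstrained.  Parameters are drawn independently (no covariance
    structure is modelled).  Reproducible: the cohort seed spawns one
    deterministic substream per subject.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_subjects)
    truths = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        truths.append(
            SubjectTruth(
                mn=MNArcParams(
                    g_mn=_truncnorm_draw(rng, config.g_mn, 0.0),
                    ap_mn0=_truncnorm_draw(rng, config.ap_mn0, -np.inf),
                ),
                g_nm_0=_truncnorm_draw(rng, config.g_nm_0, 0.0),
                ap_nm0_0=_truncnorm_draw(rng, config.ap_nm0_0, -np.inf),
                g_nm_15=_truncnorm_draw(rng, config.g_nm_15, 0.0),
                ap_nm0_15=_truncnorm_draw(rng, config.ap_nm0_15, -np.inf),
                pne_residual=_truncnorm_draw(rng, config.pne_residual, 0.0),
            )
        )
    return truths


def nm_params_at_angle(truth: SubjectTruth, angle_deg: float) -> NMArcParams:
    """NM-arc line at tilt angle ``angle_deg`` for one subject.

    The gain interpolates log-linearly in sin(phi) between the 0- and
    15-degree anchors, ``g(phi) = g0 * (g15/g0)**(sin phi / sin 15deg)``,
    and the intercept linearly in sin(phi); both anchors are reproduced
    exactly.  Angles outside [-7, 60] degrees are out of the generator's
    supported range.
    """
    if not ANGLE_MIN_DEG <= angle_deg <= ANGLE_MAX_DEG:
        raise InvalidArgumentError(
            f"angle {angle_deg} deg outside supported "
            f"[{ANGLE_MIN_DEG}, {ANGLE_MAX_DEG}]"
        )
    t = math.sin(math.radians(angle_deg)) / math.sin(math.radians(15.0))
    g_nm = truth.g_nm_0 * (truth.g_nm_15 / truth.g_nm_0) ** t
    ap_nm0 = truth.ap_nm0_0 + (truth.ap_nm0_15 - truth.ap_nm0_0) * t
    return NMArcParams(g_nm=g_nm, ap_nm0=ap_nm0, angle_deg=angle_deg)


def _plausible_hr(angle_deg: float, blocked: bool, rng: np.random.Generator) -> float:
    """Heart-rate passthrough column; not used by any downstream fit."""
    base = 88.0 if blocked else 97.0
    orthostatic = 0.0 if blocked else 24.0 * math.sin(math.radians(max(angle_deg, 0.0)))
    return round(base + orthostatic + rng.normal(0.0, 2.0), 1)


def simulate_subject(
    truth: SubjectTruth,
    config: CohortConfig,
    rng: np.random.Generator,
    subject_id: str,
) -> SubjectRecord:
    """Simulate all rows for one subject given its truth and an RNG stream."""

    def pne_noise() -> float:
        if config.pne_fractional_sd == 0.0:
            return 1.0
        # lognormal with unit mean and fractional SD sigma_f
        s2 = math.log(1.0 + config.pne_fractional_sd**2)
        return float(rng.lognormal(mean=-0.5 * s2, sigma=math.sqrt(s2)))

    def ap_noise() -> float:
        return float(rng.normal(0.0, config.ap_noise_sd)) if config.ap_noise_sd else 0.0

    rows: list[MeasurementRow] = []
    for angle in config.baseline_angles_deg:
        op = solve_operating_point(truth.mn, nm_params_at_angle(truth, angle))
        rows.append(
            MeasurementRow(
                condition=BASELINE,
                angle_deg=angle,
                ap=op.ap + ap_noise(),
                pne=op.pne * pne_noise(),
                hr=_plausible_hr(angle, blocked=False, rng=rng),
            )
        )
    for angle in config.blockade_angles_deg:
        # loop opened: PNE is the angle-independent non-neural residual,
        # pressure falls on the NM line at that residual
        pne = truth.pne_residual * pne_noise()
        ap = nm_arc_response(pne, nm_params_at_angle(truth, angle)) + ap_noise()
        rows.append(
            MeasurementRow(
                condition=BLOCKADE,
                angle_deg=angle,
                ap=ap,
                pne=pne,
                hr=_plausible_hr(angle, blocked=True, rng=rng),
            )
        )
    return SubjectRecord(subject_id=subject_id, rows=tuple(rows))


def simulate_study(config: CohortConfig) -> StudyDataset:
    """Simulate a full cohort: population draw, then per-subject measurements.

    One cohort seed drives everything; per-subject measurement streams are
    spawned deterministically from it, so a fixed seed yields an identical
    dataset on every run.
    """
    truths = draw_population(config)
    noise_seeds = np.random.SeedSequence(config.seed).spawn(
        config.n_subjects + 1
    )[-1].spawn(config.n_subjects)
    subjects = tuple(
        simulate_subject(
            truth,
            config,
            np.random.default_rng(ss),
            subject_id=f"S{i + 1:02d}",
        )
        for i, (truth, ss) in enumerate(zip(truths, noise_seeds))
    )
    return StudyDataset(subjects=subjects, truths=tuple(truths), config=config)
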