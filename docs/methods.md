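# Methods

## Model

The sympathetic arterial baroreflex is treated as a static negative-feedback
loop over two shared variables: arterial pressure AP (mmHg) and plasma
norepinephrine PNE (pg/ml), the latter standing in for sympathetic nerve
activity. Two assumptions frame everything else:

1. **PNE is a direct surrogate for sympathetic outflow.** Spillover and
   clearance kinetics are not modelled; consequently between-subject
   comparisons of single arc gains should be made cautiously, while the
   dimensionless loop gain is comparable across subjects.
2. **Both arcs are linear near the operating point.** The full arc
   characteristics are sigmoidal over wide pressure ranges, but within the
   narrow span reachable by postural tilt a line is adequate. The numeric
   solver (below) accepts arbitrary monotone curves for users who want the
   saturating form.

The mechanoneural (controller) arc is rectified-linear,

    PNE(AP) = max(pne_floor, G_MN · (AP_MN,0 − AP)),

silent above the set point AP_MN,0. Whether the silent state means zero
PNE or a small non-neural residual is not empirically settled; the floor
is therefore a parameter (default 0 pg/ml). The neuromechanical (plant)
arc at tilt angle φ is

    AP(PNE) = G_NM(φ) · PNE + AP_NM,0(φ).

Head-up tilt acts as the external disturbance: it lowers both the NM gain
and its offset, which is exactly why the naive attenuation-ratio estimate
of loop gain disagrees with G_MN·G_NM(0) (see the counterfactual below).

## Operating point

For linear arcs the equilibrium is closed-form:

    AP* = (G_L·AP_MN,0 + AP_NM,0) / (1 + G_L),   PNE* = G_MN·(AP_MN,0 − AP*),

with G_L = G_MN·G_NM. AP* is a convex combination of the set point and
the null-PNE pressure with weight G_L/(1+G_L). When the intersection
would require PNE below the floor, the loop saturates: the returned point
sits on the NM line at the floor and carries a `boundary` flag (the loop
cannot command negative norepinephrine). The degenerate case of both
gains zero lands on (AP_NM,0, floor), also flagged.

`solve_operating_point_numeric` bisects the fixed-point residual
r(AP) = NM(MN(AP)) − AP to |r| ≤ 1e−9 mmHg (the same residual tolerance
the closed form satisfies identically). It doubles as an independent
oracle for the closed form in the test suite and as the entry point for
nonlinear arcs; monotonicity of the supplied curves is the caller's
responsibility. Test comparisons between the two routes use 1e−6 mmHg.

## Disturbance decomposition

For a tilt moving the NM line from `pre` to `post`:

- closed-loop fall: difference between the two equilibrium pressures
  (the operating point slides along the MN line);
- open-loop fall: freeze PNE at its pre-tilt value and drop vertically
  onto the post-tilt NM line;
- attenuation ratio: closed/open; implied loop gain: 1/ratio − 1.

Because tilt changes the NM slope, the implied gain from the real tilt
undershoots G_MN·G_NM(0). The **parallel-shift counterfactual** replaces
the post-tilt line with one of pre-tilt slope through the open-loop
point; for that pure shift the attenuation is exactly 1/(1+G_L) and the
implied gain equals G_MN·G_NM(pre) to machine precision — an identity the
suite asserts at 1e−9 relative over randomized parameter grids. A
disturbance whose open-loop pressure change is below the residual
tolerance is reported as undefined rather than as a 0/0 ratio. The
identity is only claimed for pressure-lowering disturbances with an
interior equilibrium; a rise pushing the system above the set point
saturates the reflex and leaves the identity's domain.

## Estimation pipeline

Mirroring the tilt-study protocol (vagal blockade throughout; baseline
measurements at −7°, 0°, +15°, +60°; trimethaphan ganglionic blockade at
0° and +15°):

- **MN arc:** ordinary unweighted least squares of PNE on AP over the
  baseline points (≥3 distinct angles required). Gain = −slope, set
  point = AP-axis intercept, quality = Pearson r. The regression
  direction is deliberate (PNE regressed on AP, not orthogonal or
  geometric-mean regression), matching the definition of the gain as the
  slope with respect to the AP axis. Intercept-constrained or weighted
  variants are not offered.
- **NM arcs:** the exact line through the (baseline, blockade) point pair
  at each of 0° and 15°. Coincident PNE values are an error; a negative
  slope raises a typed error that the per-subject pipeline converts into
  a quality flag plus a zero-gain placeholder, so flagged subjects are
  visible and optionally excludable from group summaries, never silently
  clamped or dropped.
- **Open-loop gains:** exact per-subject products G_MN·G_NM(φ).
- **Group summary:** arithmetic mean and *sample* SD (n−1; the choice is
  material at n = 7 and is recorded in the output metadata). The group
  loop gain is the **mean of per-subject products**; the product of group
  means is also reported as a diagnostic because the two differ whenever
  gains covary across subjects — with the reference group means,
  8.92 × 0.61 = 5.44, a different number from a mean-of-products group
  value.
- **Paired contrast** (G_NM and G_L, 0° vs 15°): exact two-sided Wilcoxon
  signed-rank test. Zeros dropped, tied magnitudes mid-ranked, the null
  distribution of W enumerated over all 2ⁿ sign assignments for n ≤ 20
  (two-sided p = 2·min(P(W′≤W), P(W′≥W)), capped at 1); a tie-corrected
  normal approximation takes over beyond n = 20. At n = 7 with all
  differences of one sign the exact p is 2/128 = 0.015625.

## Synthetic cohorts

The generator emulates the study design so the whole pipeline is testable
without data access: per-subject truths are independent truncated-normal
draws (truncation at zero for gains and the residual PNE) around
configurable population means/SDs, defaulting to the reference group
values (G_MN 8.92 ± 3.07, AP_MN,0 103.0 ± 9.5, G_NM(0) 0.61 ± 0.08,
AP_NM,0(0) 34.1 ± 4.9, G_NM(15) 0.36 ± 0.05, AP_NM,0(15) 33.4 ± 8.6);
no between-parameter covariance is modelled because none is identifiable
from group summaries — which is also why a published group mean-of-products
loop gain is not a generator target. The post-blockade residual PNE is a
constant per subject (population 45 ± 10 pg/ml, between the reported 47
and 40 at the two angles, whose slight decline is treated as noise, not
structure) and does not respond to tilt, reflecting the opened loop.

Baseline rows are exact closed-loop equilibria of the subject's own arcs;
blockade rows lie exactly on the subject's NM line at the residual PNE.
Measurement noise is additive Gaussian on AP (default SD 2 mmHg, typical
of averaged tonometric pressure) and multiplicative lognormal on PNE
(default fractional SD 8%, typical of catecholamine assay CVs); both are
zeroable, and the zero-noise mode is exactly model-consistent, giving the
suite its machine-precision recovery checks.

**Angle law (generator assumption).** Only the 0° and 15° NM anchors are
measured quantities. Between −7° and 60° the gain interpolates
log-linearly in sin φ, `g(φ) = g₀·(g₁₅/g₀)^(sin φ/sin 15°)` — chosen to
guarantee positivity at steep angles — and the offset linearly in sin φ;
both anchors are reproduced exactly. sin φ is the natural abscissa
because the orthostatic stimulus scales with the vertical hydrostatic
component. With mean-truth parameters this law puts the 60° closed-loop
pressure near 66 mmHg, the same range as observed steep-tilt pressures;
that is a consequence of the assumption, not a fit. Angles outside
[−7°, 60°] are refused.

Seeding: one cohort seed; per-subject truth streams are SeedSequence
children 0…n−1 and measurement-noise streams are children of spawn index
n, so truth and noise never share a stream and a fixed seed reproduces
the dataset byte-for-byte.

Passing tests on these cohorts shows the pipeline is correct *given the
model*: real tilt data add assay drift, within-period nonstationarity,
hydrostatic reference error and arc nonlinearity that the generator does
not emulate, so recovery precision reported here is an upper bound on
what field data would give.

## Pipeline and formats

Study tables are CSV with header
`subject_id,condition,angle_deg,ap_mmHg,hr_bpm,pne_pg_ml`; heart rate is
an optional passthrough (the vagally blocked heart-rate reflex is out of
scope), pressures are assumed referenced to clavicle/baroreceptor level
(recorded in the provenance sidecar, not corrected). Floats are written
as shortest round-trip reprs and read with round-trip parsing, so
write-then-read is lossless. Reports are JSON at full precision with
non-finite values explicitly flagged; rounding happens only at the
presentation layer. The equilibrium-diagram export tags the three lines
and three marked points with stable SVG ids so figure structure is
testable.

## Problem sizes in tests

Monte-Carlo checks use 200 replicate single-subject cohorts per noise
level (noise-monotonicity and recovery calibration: median relative error
of G_MN < 10% and of G_L(0) < 15% at default noise), 300 seven-subject
cohorts for the population-mean check, and ≤ 200 hypothesis examples per
property; the full suite runs in a few seconds on one core.

## Known limitations

- Static equilibria only: no beat-to-beat dynamics, no tilt-transition
  kinetics, no pharmacokinetics of atropine or trimethaphan.
- Sigmoidal arc *parameter estimation* is not implemented; nonlinear arcs
  are supported only through the numeric solver with user-supplied curves.
- The group-level population model is independent-marginal; real cohorts
  presumably have correlated gains (their mean-of-products loop gain says
  as much), so group loop-gain distributions from the generator are not
  calibrated to any published group value.
- The angle law beyond the two anchors is an assumption; treat 60°
  predictions as illustrative.
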