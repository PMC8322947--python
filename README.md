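# baroloop

Equilibrium-diagram analysis of the human sympathetic arterial baroreflex.

The arterial baroreflex is the negative-feedback loop that stabilizes
arterial pressure (AP): baroreceptors sense AP, the vasomotor center
adjusts sympathetic outflow, and sympathetic outflow in turn raises AP.
Splitting the loop into its two halves — the **mechanoneural (MN) arc**
(pressure in, sympathetic activity out, read out as plasma norepinephrine,
PNE) and the **neuromechanical (NM) arc** (norepinephrine in, pressure
out) — puts both on one PNE–AP plane:

    MN arc:  PNE = max(0, G_MN · (AP_MN,0 − AP))
    NM arc:  AP  = G_NM(φ) · PNE + AP_NM,0(φ)        (φ = tilt angle)

The closed-loop **operating point** is the intersection of the two lines.
The **open-loop gain** `G_L = G_MN · G_NM` measures how well the loop
buffers disturbances: a pure parallel drop of the NM line by Δ mmHg moves
the operating pressure by only `Δ / (1 + G_L)`.

`baroloop` is aimed at cardiovascular-autonomic physiologists and modelers.
It provides:

- the forward model and operating-point algebra, including a bisection
  solver for nonlinear (e.g. sigmoidal) arc curves
  (`baroloop.core`);
- the estimation pipeline for graded head-up-tilt studies under vagal
  blockade with ganglionic-blockade (trimethaphan) trials: per-subject
  MN regression across tilt angles, two-point NM lines at 0° and 15°,
  open-loop gains, group means ± SD, and an exact Wilcoxon signed-rank
  contrast (`baroloop.estimation`);
- a synthetic cohort generator with known ground truth emulating the
  seven-subject study design, for end-to-end validation without any
  download (`baroloop.synthetic`);
- a CLI (`baroloop simulate | fit | report`) with a CSV study-table
  schema, YAML configs, JSON reports and an SVG equilibrium diagram.

## Worked example

Using the group-mean arc parameters of a seven-subject tilt study in
healthy young men (`G_MN = 8.92 pg·ml⁻¹·mmHg⁻¹`, `AP_MN,0 = 103.0 mmHg`;
supine NM arc `G_NM(0) = 0.61 mmHg·ml·pg⁻¹`, `AP_NM,0(0) = 34.1 mmHg`;
15° NM arc `G_NM(15) = 0.36`, `AP_NM,0(15) = 33.4`):

```python
>>> from baroloop import solve_operating_point, tilt_disturbance_report
>>> from baroloop.reference import (MN_GROUP_MEAN,
...     NM_SUPINE_GROUP_MEAN, NM_HUT15_GROUP_MEAN)
>>> solve_operating_point(MN_GROUP_MEAN, NM_SUPINE_GROUP_MEAN)
OperatingPoint(ap=92.30323542197107, pne=95.41514003601809, boundary=False)
>>> rep = tilt_disturbance_report(MN_GROUP_MEAN, NM_SUPINE_GROUP_MEAN,
...                               NM_HUT15_GROUP_MEAN)
>>> round(rep.closed_loop_delta_ap, 2), round(rep.open_loop_delta_ap, 2)
(5.83, 24.55)
>>> round(rep.attenuation_ratio, 3), round(rep.implied_gl, 2)
(0.237, 3.21)
```

Read: tilting from supine to 15° head-up lowers the equilibrium pressure
by only ≈5.8 mmHg, while with the reflex frozen (PNE held at its supine
value of ≈95 pg/ml) the same disturbance would drop pressure by
≈24.6 mmHg — the loop attenuates the disturbance to about one quarter.
Inverting the attenuation (`G_L = 1/ratio − 1 ≈ 3.2`) understates the
true supine loop gain `8.92 × 0.61 = 5.44` because head-up tilt reduces
the NM *gain* as well as its offset; the slope-preserving counterfactual
(`parallel_shift_counterfactual`) restores the identity exactly and
predicts a fall below 4 mmHg.

The same numbers from the shell:

```bash
baroloop report --out report.json --plot diagram.svg
baroloop simulate --out study.csv --seed 17
baroloop fit --data study.csv --out estimates.json
```

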