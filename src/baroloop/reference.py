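"""Reference group-level parameters of the emulated tilt study.

These are the published group means (± SD where used) of a seven-subject
head-up tilt study in healthy young men under vagal blockade, used
throughout the package as the default generative truth and as the worked
example for the equilibrium-diagram decomposition.  They are inputs to
the model, not outputs of this package.
"""

from __future__ import annotations

from .core import MNArcParams, NMArcParams

#: MN (controller) arc, group means: gain pg·ml⁻¹·mmHg⁻¹, set point mmHg.
MN_GROUP_MEAN = MNArcParams(g_mn=8.92, ap_mn0=103.0)

#: NM (plant) arc at supine (0°), group means.
NM_SUPINE_GROUP_MEAN = NMArcParams(g_nm=0.61, ap_nm0=34.1, angle_deg=0.0)

#: NM (plant) arc at 15° head-up tilt, group means.
NM_HUT15_GROUP_MEAN = NMArcParams(g_nm=0.36, ap_nm0=33.4, angle_deg=15.0)

#: Group-mean baseline (angle_deg, AP mmHg, PNE pg/ml) under vagal blockade.
TILT_TABLE_BASELINE = (
    (-7.0, 91.0, 83.0),
    (0.0, 87.0, 92.0),
    (15.0, 79.0, 129.0),
    (60.0, 59.0, 278.0),
)

#: Group-mean ganglionic-blockade (angle_deg, AP mmHg, PNE pg/ml).
TILT_TABLE_BLOCKADE = (
    (0.0, 61.0, 47.0),
    (15.0, 46.0, 40.0),
)
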