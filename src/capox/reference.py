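"""Published cohort-level reference values used by the reproduction report.

These are the printed group means from the awake-mouse barrel-cortex
study this pipeline reimplements: layer-wise arteriolar/venular
saturations, surface and first-order-capillary saturations, and
branch-order group means.  They serve as *inputs* to the closed-form
worked quantities (DOEF, extraction partition, branch ratios) that the
report recomputes; saturations are stored as fractions.
"""

from __future__ import annotations

from .oximetry import HillParams

# Diving-arteriole / surfacing-venule SO2 layer means (fractions).
LAYER_SO2_ARTERIOLE = {"I": 0.909, "V": 0.871}
LAYER_SO2_VENULE = {"I": 0.618, "V": 0.535}

# Pial-surface saturations and the first-order (A1) capillary mean.
SURFACE_SO2_ARTERIOLE = 0.910
SURFACE_SO2_VENULE = 0.620
A1_SO2 = 0.810

# Branch-order group means in layers I-III.
BRANCH_FLUX_RBC_PER_S = {"A1-A3": 97.0, "V1-V3": 36.0}
BRANCH_SPEED_MM_PER_S = {"A1-A3": 1.9, "V1-V3": 0.6}

# Mouse (C57BL/6) hemoglobin dissociation parameters.
MOUSE_HILL = HillParams(h=2.59, p50=40.2)
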