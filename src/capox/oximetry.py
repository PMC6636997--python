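"""Hill-equation oximetry and oxygen extraction fractions.

Hemoglobin saturation is computed from PO2 with the Hill equation

    SO2 = PO2^h / (PO2^h + P50^h)

using dissociation parameters for C57BL/6 mouse blood (h = 2.59,
P50 = 40.2 mmHg).  Saturations are carried as fractions in [0, 1]
throughout; render as percent only at the reporting boundary.

The depth-dependent oxygen extraction fraction (DOEF) for a cortical layer
is (SO2_A - SO2_V)/SO2_A from the layer-specific diving-arteriole and
surfacing-venule saturations; DOEF in layer I is the global extraction
fraction of the interrogated territory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HillParams",
    "hill_so2",
    "capillary_so2",
    "doef",
    "arteriolar_extraction_fraction",
]


@dataclass(frozen=True)
class HillParams:
    """Hill dissociation-curve parameters (C57BL/6 mouse defaults)."""

    h: float = 2.59
    p50: float = 40.2

    def __post_init__(self) -> None:
        if self.h <= 0 or self.p50 <= 0:
            raise ValueError("Hill coefficient and P50 must be positive")


def hill_so2(po2, params: HillParams = HillParams()):
    """Hemoglobin saturation (fraction in [0, 1)) at PO2 [mmHg]."""
    p = np.asarray(po2, dtype=float)
    if np.any(p < 0):
        raise ValueError("PO2 must be non-negative")
    ph = p**params.h
    so2 = ph / (ph + params.p50**params.h)
    return float(so2) if np.isscalar(po2) else so2


def capillary_so2(metrics, params: HillParams = HillParams()):
    """Capillary saturation from RBC-PO2 (not Mean-PO2).

    Capillary SO2 reflects the hemoglobin inside erythrocytes, so it is
    computed from the PO2 fitted during RBC passages; arterioles and
    venules use their Mean-PO2 directly via :func:`hill_so2`.
    Returns NaN when RBC-PO2 is missing (rejected segmentation or fit).
    """
    rbc_po2 = getattr(metrics, "rbc_po2", metrics)
    if rbc_po2 is None or not np.all(np.isfinite(np.asarray(rbc_po2, float))):
        return np.nan
    return hill_so2(rbc_po2, params)


def doef(so2_a: float, so2_v: float) -> float:
    """Oxygen extraction fraction (SO2_A - SO2_V)/SO2_A for one layer.

    Both saturations are fractions in (0, 1].  A venular saturation above
    the arteriolar one yields a negative DOEF, reported as-is with a
    warning (possible in noisy cohorts), never clipped.
    """
    if not 0 < so2_a <= 1:
        raise ValueError("arteriolar SO2 must be in (0, 1]")
    if not 0 <= so2_v <= 1:
        raise ValueError("venular SO2 must be in [0, 1]")
    value = (so2_a - so2_v) / so2_a
    if value < 0:
        warnings.warn("venular SO2 exceeds arteriolar SO2: negative DOEF", stacklevel=2)
    return value


def arteriolar_extraction_fraction(
    so2_pial_a: float, so2_a1: float, so2_pial_v: float
) -> float:
    """Fraction of total oxygen extraction occurring before the A1 capillaries.

    (SO2_pial_A - SO2_A1) / (SO2_pial_A - SO2_pial_V): the saturation drop
    from pial arterioles to first-order capillaries, normalized by the
    total surface arterio-venous drop.  The complement is the fraction
    extracted at and after the capillary bed.
    """
    if so2_pial_a <= so2_pial_v:
        raise ValueError("arteriolar SO2 must exceed venular SO2")
    return (so2_pial_a - so2_a1) / (so2_pial_a - so2_pial_v)
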