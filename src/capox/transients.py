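"""Gated capillary PO2: Mean-PO2, RBC-PO2, InterRBC-PO2, EAT and gradients.

Decay histograms from a capillary acquisition are pooled by their timing
relative to RBC passages before lifetime fitting:

* Mean-PO2      — all cycles, regardless of position;
* RBC-PO2       — cycles inside intensity valleys (RBC passages);
* InterRBC-PO2  — cycles in the central 40% of each plasma peak;
* EAT           — RBC-PO2 minus InterRBC-PO2 (erythrocyte-associated
  transient, a proxy for intracapillary resistance to oxygen delivery).

Intracapillary gradients pool cycles by the time to the nearest RBC
center (2-ms bins) or by the equivalent distance ``v * dt'`` (1-um bins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decay import CalibrationCurve, LifetimeFit, fit_lifetime
from .segmentation import SegmentationResult
from .trace import PhotonTrace

__all__ = [
    "GatedPools",
    "PooledPo2",
    "CapillaryPO2Metrics",
    "Po2Gradient",
    "gate_cycles",
    "pooled_po2",
    "capillary_po2_metrics",
    "eat",
    "time_gradient",
    "distance_gradient",
]

MIN_POOL_CYCLES = 50


@dataclass
class GatedPools:
    """Cycle index pools and per-cycle proximity to the nearest RBC."""

    all_cycles: np.ndarray
    valley_cycles: np.ndarray
    peak_central_cycles: np.ndarray
    dt_to_rbc_ms: np.ndarray
    dist_to_rbc_um: np.ndarray | None


@dataclass(frozen=True)
class PooledPo2:
    """PO2 from one pooled-decay fit; ``valid`` guards small/failed pools."""

    po2_mmhg: float
    fit: LifetimeFit | None
    n_cycles: int
    valid: bool


@dataclass
class CapillaryPO2Metrics:
    """Gated PO2 quantities for one capillary [mmHg]."""

    mean_po2: PooledPo2
    rbc_po2: PooledPo2
    interrbc_po2: PooledPo2

    @property
    def eat_mmhg(self) -> float:
        return eat(self)


@dataclass
class Po2Gradient:
    """PO2 versus time (or distance) from the nearest RBC center.

    Bins with no pooled cycles or failed fits carry NaN PO2 and are
    flagged by their zero/low counts, never interpolated.
    """

    bin_centers: np.ndarray
    po2_per_bin: np.ndarray
    counts_per_bin: np.ndarray
    axis: str = "time_ms"


def _central_window(start: int, stop: int, fraction: float = 0.4) -> np.ndarray:
    """Indices of the central `fraction` of a run, >= 1 cycle, symmetric."""
    n = stop - start
    k = max(1, int(np.floor(fraction * n)))
    lead = (n - k) // 2
    return np.arange(start + lead, start + lead + k)


def gate_cycles(seg: SegmentationResult, speed_mm_per_s: float | None = None) -> GatedPools:
    """Pool cycle indices by position relative to RBC passages.

    The valley pool is every cycle inside a valley; the peak-central pool
    is the central 40% of each plasma peak (symmetric about the peak
    midpoint, rounded inward, minimum one cycle).  ``dt'`` is the time
    from each cycle midpoint to the nearest valley center; the distance
    axis ``v * dt'`` requires a positive speed.
    """
    if not seg.accepted:
        raise ValueError("cannot gate an unaccepted segmentation")
    n = len(seg.labels)
    all_cycles = np.arange(n)
    valley_cycles = np.flatnonzero(seg.labels)
    if seg.peaks:
        peak_central = np.concatenate(
            [_central_window(start, stop) for start, stop, _ in seg.peaks]
        )
    else:
        peak_central = np.empty(0, dtype=int)

    period_s = seg.cycle_period_us * 1e-6
    mid_s = (all_cycles + 0.5) * period_s
    centers_s = seg.valley_center_times_s()
    if len(centers_s):
        idx = np.clip(np.searchsorted(centers_s, mid_s), 0, len(centers_s) - 1)
        lo = np.clip(idx - 1, 0, len(centers_s) - 1)
        dt_s = np.minimum(np.abs(mid_s - centers_s[idx]), np.abs(mid_s - centers_s[lo]))
    else:
        dt_s = np.full(n, np.inf)
    dt_ms = dt_s * 1e3
    dist_um = None
    if speed_mm_per_s is not None:
        if not speed_mm_per_s > 0:
            raise ValueError("speed must be positive for distance gating")
        dist_um = speed_mm_per_s * dt_ms  # mm/s * ms = um
    return GatedPools(all_cycles, valley_cycles, peak_central, dt_ms, dist_um)


def pooled_po2(
    trace: PhotonTrace,
    pool: np.ndarray,
    calib: CalibrationCurve,
    discard_head_us: float = 5.0,
    min_cycles: int = MIN_POOL_CYCLES,
) -> PooledPo2:
    """Sum the decays of a cycle pool, fit the lifetime, convert to PO2.

    Pools smaller than ``min_cycles`` (default 50) or with failed fits
    are flagged invalid rather than reported.
    """
    pool = np.asarray(pool, dtype=int)
    if pool.size < max(min_cycles, 1):
        return PooledPo2(np.nan, None, int(pool.size), False)
    hist = trace.pooled_histogram(pool)
    if hist.counts.sum() <= 0:
        return PooledPo2(np.nan, None, int(pool.size), False)
    fit = fit_lifetime(hist, discard_head_us=discard_head_us)
    if not fit.converged or fit.tau_us > 1.01 * calib.tau_zero_us:
        return PooledPo2(np.nan, fit, int(pool.size), False)
    return PooledPo2(float(calib.to_po2(fit.tau_us)), fit, int(pool.size), True)


def capillary_po2_metrics(
    trace: PhotonTrace,
    pools: GatedPools,
    calib: CalibrationCurve,
    discard_head_us: float = 5.0,
) -> CapillaryPO2Metrics:
    """Mean-, RBC- and InterRBC-PO2 with identical fit settings per gate."""
    return CapillaryPO2Metrics(
        mean_po2=pooled_po2(trace, pools.all_cycles, calib, discard_head_us),
        rbc_po2=pooled_po2(trace, pools.valley_cycles, calib, discard_head_us),
        interrbc_po2=pooled_po2(trace, pools.peak_central_cycles, calib, discard_head_us),
    )


def eat(metrics: CapillaryPO2Metrics) -> float:
    """EAT = RBC-PO2 - InterRBC-PO2 [mmHg]; NaN when either gate is missing.

    May legitimately be negative in noisy data and is reported as-is.
    """
    if not (metrics.rbc_po2.valid and metrics.interrbc_po2.valid):
        return np.nan
    return metrics.rbc_po2.po2_mmhg - metrics.interrbc_po2.po2_mmhg


def _gradient(
    trace: PhotonTrace,
    values: np.ndarray,
    calib: CalibrationCurve,
    bin_width: float,
    max_value: float | None,
    axis: str,
    min_cycles: int,
) -> Po2Gradient:
    finite = np.isfinite(values)
    if max_value is None:
        max_value = float(values[finite].max()) if finite.any() else bin_width
    n_bins = max(1, int(np.ceil(max_value / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    which = np.clip(np.floor(values / bin_width).astype(int), 0, None)
    po2 = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        pool = np.flatnonzero(finite & (which == b))
        counts[b] = len(pool)
        if len(pool) >= max(min_cycles, 1):
            res = pooled_po2(trace, pool, calib, min_cycles=1)
            if res.valid:
                po2[b] = res.po2_mmhg
    return Po2Gradient(0.5 * (edges[:-1] + edges[1:]), po2, counts, axis=axis)


def time_gradient(
    trace: PhotonTrace,
    pools: GatedPools,
    calib: CalibrationCurve,
    bin_width_ms: float = 2.0,
    max_time_ms: float | None = None,
    min_cycles: int = 1,
) -> Po2Gradient:
    """PO2 in 2-ms bins of time from the nearest RBC center."""
    return _gradient(
        trace, pools.dt_to_rbc_ms, calib, bin_width_ms, max_time_ms,
        "time_ms", min_cycles,
    )


def distance_gradient(
    trace: PhotonTrace,
    pools: GatedPools,
    calib: CalibrationCurve,
    bin_width_um: float = 1.0,
    max_dist_um: float | None = None,
    min_cycles: int = 1,
) -> Po2Gradient:
    """PO2 in 1-um bins of distance ``v * dt'`` from the nearest RBC center."""
    if pools.dist_to_rbc_um is None:
        raise ValueError("distance gating requires pools built with a speed")
    return _gradient(
        trace, pools.dist_to_rbc_um, calib, bin_width_um, max_dist_um,
        "distance_um", min_cycles,
    )
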