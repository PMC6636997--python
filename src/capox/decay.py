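"""Phosphorescence decay fitting and Stern-Volmer oxygen calibration.

The oxygen probe's triplet-state phosphorescence decays single-exponentially,
with a lifetime quenched by molecular oxygen.  A pooled decay histogram
(photon counts per time bin, summed over many excitation/decay cycles) is fit
to ``A*exp(-t/tau) + B`` by nonlinear least squares; the lifetime ``tau`` maps
to absolute PO2 through the linear Stern-Volmer relation

    1/tau = 1/tau0 + kq * PO2

where ``tau0`` is the zero-oxygen lifetime and ``kq`` the quenching constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

__all__ = [
    "DecayHistogram",
    "LifetimeFit",
    "CalibrationCurve",
    "fit_lifetime",
    "lifetime_to_po2",
    "po2_to_lifetime",
    "calibrate",
]


@dataclass(frozen=True)
class DecayHistogram:
    """Photon counts binned over the decay window, pooled over cycles.

    Parameters
    ----------
    bin_edges
        Bin edges in microseconds, measured from the start of the decay
        window (i.e. immediately after the excitation gate closes).
        Strictly increasing, length ``len(counts) + 1``.
    counts
        Non-negative photon counts per bin.
    n_cycles_pooled
        Number of excitation/decay cycles summed into this histogram.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_cycles_pooled: int = 1

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if edges.ndim != 1 or counts.ndim != 1 or len(edges) != len(counts) + 1:
            raise ValueError("bin_edges must have length len(counts) + 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def window_us(self) -> float:
        return float(self.bin_edges[-1] - self.bin_edges[0])


@dataclass(frozen=True)
class LifetimeFit:
    """Result of a single-exponential fit ``A*exp(-t/tau) + B``."""

    tau_us: float
    amplitude: float
    offset: float
    r_squared: float
    converged: bool


@dataclass(frozen=True)
class CalibrationCurve:
    """Stern-Volmer lifetime <-> PO2 map: ``1/tau = 1/tau0 + kq*PO2``.

    tau_zero_us : zero-oxygen lifetime [us]
    kq : quenching constant [1/(s*mmHg)]

    Defaults (tau0 = 40 us, kq = 250 s^-1 mmHg^-1, so tau = 20 us at
    100 mmHg) are plausible placeholders for a two-photon phosphorescent
    probe and must be replaced by a titration-derived curve for real data.
    """

    tau_zero_us: float = 40.0
    kq: float = 250.0

    def __post_init__(self) -> None:
        if self.tau_zero_us <= 0:
            raise ValueError("tau_zero_us must be positive")
        if self.kq <= 0:
            raise ValueError("kq must be positive")

    def to_po2(self, tau_us):
        return lifetime_to_po2(tau_us, self)

    def to_lifetime(self, po2):
        return po2_to_lifetime(po2, self)


def lifetime_to_po2(tau_us, calib: CalibrationCurve):
    """Convert lifetime [us] to PO2 [mmHg] via the Stern-Volmer relation.

    PO2 = (1/tau - 1/tau0) / kq, floored at 0.  Lifetimes up to 1% above
    tau0 (fit noise at zero oxygen) clamp to 0; larger values violate the
    calibration and raise.
    """
    tau = np.asarray(tau_us, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("lifetime must be positive")
    if np.any(tau > 1.01 * calib.tau_zero_us):
        raise ValueError(
            f"lifetime {np.max(tau):.3g} us exceeds the zero-oxygen lifetime "
            f"{calib.tau_zero_us:.3g} us by more than 1% - calibration violated"
        )
    po2 = (1.0 / (tau * 1e-6) - 1.0 / (calib.tau_zero_us * 1e-6)) / calib.kq
    po2 = np.maximum(po2, 0.0)
    return float(po2) if np.isscalar(tau_us) else po2


def po2_to_lifetime(po2, calib: CalibrationCurve):
    """Convert PO2 [mmHg] to phosphorescence lifetime [us]."""
    p = np.asarray(po2, dtype=float)
    if np.any(p < 0):
        raise ValueError("PO2 must be non-negative")
    tau_s = 1.0 / (1.0 / (calib.tau_zero_us * 1e-6) + calib.kq * p)
    tau = tau_s * 1e6
    return float(tau) if np.isscalar(po2) else tau


def calibrate(titration_points) -> CalibrationCurve:
    """Fit a Stern-Volmer line to oxygen-titration points.

    Parameters
    ----------
    titration_points
        Sequence of ``(po2_mmhg, tau_us)`` pairs from an independent
        titration experiment; at least two distinct PO2 values.

    Returns
    -------
    CalibrationCurve with kq = slope and tau0 = 1/intercept of the
    least-squares line of 1/tau against PO2.
    """
    pts = np.asarray(titration_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least two (po2, tau) titration points")
    po2, tau_us = pts[:, 0], pts[:, 1]
    if len(np.unique(po2)) < 2:
        raise ValueError("titration points must span at least two PO2 values")
    if np.any(tau_us <= 0):
        raise ValueError("titration lifetimes must be positive")
    res = stats.linregress(po2, 1.0 / (tau_us * 1e-6))
    if res.slope <= 0 or res.intercept <= 0:
        raise ValueError("bad titration: fitted kq or tau0 is non-positive")
    return CalibrationCurve(tau_zero_us=1e6 / res.intercept, kq=res.slope)


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    # Offset from the histogram tail, then log-linear regression on the
    # background-subtracted counts where they are safely above the offset.
    n_tail = max(1, len(y) // 10)
    b0 = float(np.mean(y[-n_tail:]))
    z = y - b0
    mask = z > max(1e-12, 0.02 * np.max(z)) if np.max(z) > 0 else np.zeros_like(z, bool)
    if mask.sum() >= 3:
        slope, intercept, *_ = stats.linregress(t[mask], np.log(z[mask]))
        if slope < 0:
            return float(np.exp(intercept)), -1.0 / slope, b0
    # fallback: 1/e crossing heuristic
    a0 = max(float(y[0] - b0), 1e-6)
    tau0 = max((t[-1] - t[0]) / 3.0, 1e-3)
    return a0, tau0, b0


def fit_lifetime(
    decay: DecayHistogram,
    discard_head_us: float = 5.0,
    weighted: bool = False,
) -> LifetimeFit:
    """Fit a single-exponential decay ``A*exp(-t/tau) + B`` to a histogram.

    The first ``discard_head_us`` of the decay window is rejected (residual
    excitation-gate contamination) and the remainder fit by unweighted
    nonlinear least squares; ``weighted=True`` applies Poisson weights
    (sigma = sqrt(max(counts, 1))).

    Never raises on degenerate or noisy data: failures (optimizer error,
    all-zero counts, lifetime outside (0.1 us, 10x window)) return
    ``converged=False`` and are rejected downstream.
    """
    t_all = decay.bin_centers
    keep = t_all >= decay.bin_edges[0] + discard_head_us
    t = t_all[keep]
    y = decay.counts[keep]
    if len(t) < 4 or (decay.bin_edges[-1] - (decay.bin_edges[0] + discard_head_us)) < 20:
        raise ValueError("decay window after head discard is too short (< 20 us)")
    if np.sum(y) <= 0:
        return LifetimeFit(np.nan, np.nan, np.nan, np.nan, False)

    a0, tau0, b0 = _initial_guess(t, y)
    window = decay.window_us
    sigma = np.sqrt(np.maximum(y, 1.0)) if weighted else None
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, a, tau, b: a * np.exp(-tt / tau) + b,
            t,
            y,
            p0=(a0, min(max(tau0, 0.2), 5 * window), b0),
            sigma=sigma,
            bounds=([0.0, 1e-3, -np.inf], [np.inf, 100.0 * window, np.inf]),
            maxfev=5000,
        )
    except (RuntimeError, ValueError):
        return LifetimeFit(np.nan, np.nan, np.nan, np.nan, False)

    a_hat, tau_hat, b_hat = (float(v) for v in popt)
    resid = y - (a_hat * np.exp(-t / tau_hat) + b_hat)
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
    ok = bool(0.1 < tau_hat < 10.0 * window and a_hat > 0 and np.isfinite(r2))
    return LifetimeFit(tau_hat, a_hat, b_hat, r2, ok)
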