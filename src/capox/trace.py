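"""Per-location photon-count traces: the raw measurement unit.

A measurement at one vascular location is a sequence of excitation/decay
cycles (default 300 us each: 10 us excitation gate, 290 us decay window).
Each cycle yields a histogram of photon arrival times over the decay
window; the full trace is an ``(n_cycles, n_bins)`` integer array.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decay import DecayHistogram

__all__ = ["PhotonTrace"]


@dataclass
class PhotonTrace:
    """Photon counts per decay bin for every excitation/decay cycle.

    counts : (n_cycles, n_bins) non-negative integers
    bin_edges_us : decay-bin edges [us] from the start of the decay window
    cycle_period_us : full cycle duration [us] (gate + decay window)
    segment_id : identifier of the vascular location
    """

    counts: np.ndarray
    bin_edges_us: np.ndarray
    cycle_period_us: float = 300.0
    segment_id: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.bin_edges_us = np.asarray(self.bin_edges_us, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D (n_cycles, n_bins) array")
        if len(self.bin_edges_us) != self.counts.shape[1] + 1:
            raise ValueError("bin_edges_us must have length n_bins + 1")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be non-negative")

    @property
    def n_cycles(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_cycles * self.cycle_period_us * 1e-6

    def cycle_midtimes_s(self) -> np.ndarray:
        """Midpoint time [s] of each excitation/decay cycle."""
        return (np.arange(self.n_cycles) + 0.5) * self.cycle_period_us * 1e-6

    def pooled_histogram(self, pool=None) -> DecayHistogram:
        """Sum decay histograms over a set of cycles (all cycles if None)."""
        if pool is None:
            summed = self.counts.sum(axis=0)
            n = self.n_cycles
        else:
            pool = np.asarray(pool, dtype=int)
            if pool.size == 0:
                raise ValueError("cannot pool an empty cycle set")
            summed = self.counts[pool].sum(axis=0)
            n = len(pool)
        return DecayHistogram(self.bin_edges_us, summed, n_cycles_pooled=n)
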