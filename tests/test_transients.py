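"""Gated PO2 pools, EAT and intracapillary gradients."""

from dataclasses import dataclass

import numpy as np
import pytest

from capox.decay import DecayHistogram, fit_lifetime
from capox.segmentation import IntensityTrace, build_intensity_trace, compute_flow_metrics, segment_trace
from capox.simulate import (
    Po2Waveform,
    SimulationConfig,
    expected_pooled_decay,
    sample_rbc_schedule,
    synthesize_trace,
)
from capox.transients import (
    _central_window,
    capillary_po2_metrics,
    distance_gradient,
    eat,
    gate_cycles,
    pooled_po2,
    time_gradient,
)


@dataclass(frozen=True)
class LinearWaveform:
    """PO2 falling linearly with time from the nearest RBC center."""

    peak: float = 60.0
    slope_per_ms: float = 0.6

    def evaluate(self, times_s, schedule):
        dt_ms = schedule.time_to_nearest_center(np.asarray(times_s)) * 1e3
        return np.maximum(self.peak - self.slope_per_ms * dt_ms, 0.0)


def _segmented_synthetic(calib, config, flux=40.0, speed=1.0, waveform=None, seed=0):
    duration = config.n_cycles * config.cycle_period_us * 1e-6
    sch = sample_rbc_schedule(flux, speed, duration, gap_cv=0.0, rng_seed=seed)
    wf = waveform or Po2Waveform(50.0, 36.0)
    trace = synthesize_trace(sch, wf, calib, config, rng_seed=seed + 1)
    seg = segment_trace(build_intensity_trace(trace))
    assert seg.accepted
    return sch, wf, trace, seg


class TestGateCycles:
    def test_central_window_of_ten_is_four(self):
        assert _central_window(0, 10).tolist() == [3, 4, 5, 6]

    @pytest.mark.parametrize("n,expected", [(1, 1), (2, 1), (3, 1), (5, 2), (25, 10)])
    def test_central_window_sizes(self, n, expected):
        assert len(_central_window(0, n)) == expected

    def test_pools_partition_consistently(self, calib, short_config):
        _, _, _, seg = _segmented_synthetic(calib, short_config)
        pools = gate_cycles(seg, speed_mm_per_s=1.0)
        assert set(pools.valley_cycles) <= set(pools.all_cycles)
        assert set(pools.peak_central_cycles) <= set(pools.all_cycles)
        assert not set(pools.valley_cycles) & set(pools.peak_central_cycles)
        assert np.array_equal(np.flatnonzero(seg.labels), pools.valley_cycles)

    def test_distance_is_speed_times_dt(self, calib, short_config):
        _, _, _, seg = _segmented_synthetic(calib, short_config)
        pools = gate_cycles(seg, speed_mm_per_s=2.0)
        assert np.allclose(pools.dist_to_rbc_um, 2.0 * pools.dt_to_rbc_ms)

    def test_dt_zero_at_valley_centers(self, calib, short_config):
        _, _, _, seg = _segmented_synthetic(calib, short_config)
        pools = gate_cycles(seg)
        # cycles nearest to each valley center sit within half a cycle period
        for _, _, center in seg.valleys:
            assert pools.dt_to_rbc_ms[int(round(center))] <= 0.3

    def test_unaccepted_segmentation_rejected(self):
        seg = segment_trace(IntensityTrace(np.full(500, 5.0)))
        with pytest.raises(ValueError):
            gate_cycles(seg)


class TestPooledPo2:
    def test_constant_po2_recovered_in_every_gate(self, calib):
        """Noiseless trace at constant PO2: every gate reads 50 mmHg."""
        from capox.simulate import expected_decay_matrix
        from capox.trace import PhotonTrace

        config = SimulationConfig(n_cycles=2000)
        duration = config.n_cycles * config.cycle_period_us * 1e-6
        sch = sample_rbc_schedule(40.0, 1.0, duration, gap_cv=0.0, rng_seed=0)
        wf = Po2Waveform(50.0, 50.0)
        lam = expected_decay_matrix(sch, wf, calib, config)
        # scale up before rounding so integer quantization is negligible
        trace = PhotonTrace(
            np.rint(lam * 2e4).astype(np.int64), config.bin_edges_us,
            config.cycle_period_us,
        )
        seg = segment_trace(build_intensity_trace(trace))
        assert seg.accepted
        pools = gate_cycles(seg)
        metrics = capillary_po2_metrics(trace, pools, calib)
        for pooled in (metrics.mean_po2, metrics.rbc_po2, metrics.interrbc_po2):
            assert pooled.valid
            assert pooled.po2_mmhg == pytest.approx(50.0, abs=0.05)
        assert metrics.eat_mmhg == pytest.approx(0.0, abs=0.05)

    def test_small_pool_flagged(self, calib, short_config):
        _, _, trace, _ = _segmented_synthetic(calib, short_config)
        res = pooled_po2(trace, np.arange(10), calib)
        assert not res.valid and np.isnan(res.po2_mmhg)

    def test_empty_pool_flagged(self, calib, short_config):
        _, _, trace, _ = _segmented_synthetic(calib, short_config)
        res = pooled_po2(trace, np.empty(0, dtype=int), calib)
        assert not res.valid

    def test_gated_po2_matches_noiseless_pool_oracle(self, calib):
        """Stochastic gated fits agree with fits of the exact expected
        pooled decay over the same cycle pools (9-s trace, EAT waveform)."""
        config = SimulationConfig(n_cycles=30000)
        sch, wf, trace, seg = _segmented_synthetic(calib, config)
        pools = gate_cycles(seg)
        metrics = capillary_po2_metrics(trace, pools, calib)
        for pooled, pool in (
            (metrics.mean_po2, pools.all_cycles),
            (metrics.rbc_po2, pools.valley_cycles),
            (metrics.interrbc_po2, pools.peak_central_cycles),
        ):
            expected = expected_pooled_decay(sch, wf, calib, config, pool=pool)
            oracle_fit = fit_lifetime(DecayHistogram(config.bin_edges_us, expected))
            oracle = calib.to_po2(oracle_fit.tau_us)
            assert pooled.valid
            assert pooled.po2_mmhg == pytest.approx(oracle, abs=2.0)
        # valley cycles span the +-3 ms transit over which the waveform has
        # already relaxed, so RBC-PO2 sits a little below the 50 mmHg crest;
        # InterRBC-PO2 lies between the floor and the crest
        assert 45.0 < metrics.rbc_po2.po2_mmhg <= 50.5
        assert 36.0 < metrics.interrbc_po2.po2_mmhg < metrics.rbc_po2.po2_mmhg
        # Mean-PO2 bracketed by the gated values
        assert (
            metrics.interrbc_po2.po2_mmhg - 2.0
            < metrics.mean_po2.po2_mmhg
            < metrics.rbc_po2.po2_mmhg + 2.0
        )


class TestEat:
    def test_difference_and_missing_flags(self, calib):
        config = SimulationConfig(n_cycles=2000, photon_rate_plasma=500.0)
        _, _, trace, seg = _segmented_synthetic(calib, config)
        pools = gate_cycles(seg)
        metrics = capillary_po2_metrics(trace, pools, calib)
        assert eat(metrics) == pytest.approx(
            metrics.rbc_po2.po2_mmhg - metrics.interrbc_po2.po2_mmhg
        )
        from capox.transients import PooledPo2

        metrics.rbc_po2 = PooledPo2(np.nan, None, 0, False)
        assert np.isnan(eat(metrics))


class TestGradients:
    def test_linear_waveform_gradient(self, calib):
        """With PO2 = 60 - 0.6*dt [ms], the 4-6 ms bin reads ~57 mmHg."""
        config = SimulationConfig(n_cycles=30000, photon_rate_plasma=100.0)
        _, _, trace, seg = _segmented_synthetic(
            calib, config, flux=20.0, waveform=LinearWaveform()
        )
        pools = gate_cycles(seg)
        grad = time_gradient(trace, pools, calib, min_cycles=50)
        bin5 = np.argmin(np.abs(grad.bin_centers - 5.0))
        assert grad.counts_per_bin[bin5] > 0
        assert grad.po2_per_bin[bin5] == pytest.approx(57.0, abs=1.0)

    def test_constant_po2_flat_gradient(self, calib):
        config = SimulationConfig(n_cycles=2000, photon_rate_plasma=500.0)
        _, _, trace, seg = _segmented_synthetic(
            calib, config, waveform=Po2Waveform(45.0, 45.0)
        )
        pools = gate_cycles(seg)
        grad = time_gradient(trace, pools, calib, min_cycles=50)
        ok = np.isfinite(grad.po2_per_bin)
        assert ok.sum() >= 3
        assert np.all(np.abs(grad.po2_per_bin[ok] - 45.0) < 2.0)

    def test_monotone_waveform_monotone_oracle_profile(self, calib):
        """Noiseless per-bin pooled fits fall monotonically with dt."""
        config = SimulationConfig(n_cycles=30000)
        sch, wf, trace, seg = _segmented_synthetic(calib, config, flux=30.0)
        pools = gate_cycles(seg)
        vals = []
        for lo in (0.0, 2.0, 4.0, 6.0, 8.0):
            pool = np.flatnonzero(
                (pools.dt_to_rbc_ms >= lo) & (pools.dt_to_rbc_ms < lo + 2.0)
            )
            expected = expected_pooled_decay(sch, wf, calib, config, pool=pool)
            fit = fit_lifetime(DecayHistogram(config.bin_edges_us, expected))
            vals.append(calib.to_po2(fit.tau_us))
        assert np.all(np.diff(vals) < 0)

    def test_empty_far_bins_flagged(self, calib):
        config = SimulationConfig(n_cycles=2000, photon_rate_plasma=500.0)
        _, _, trace, seg = _segmented_synthetic(calib, config)
        pools = gate_cycles(seg)
        grad = time_gradient(trace, pools, calib, max_time_ms=60.0, min_cycles=1)
        # the periodic 40 RBC/s schedule has no dt beyond half a 25-ms gap
        far = grad.bin_centers > 15.0
        assert np.all(grad.counts_per_bin[far] == 0)
        assert np.all(np.isnan(grad.po2_per_bin[far]))

    def test_distance_gradient_is_rescaled_time_gradient(self, calib):
        """At v = 1 mm/s, distance [um] and time [ms] axes coincide."""
        config = SimulationConfig(n_cycles=2000, photon_rate_plasma=200.0)
        _, _, trace, seg = _segmented_synthetic(calib, config)
        pools = gate_cycles(seg, speed_mm_per_s=1.0)
        g_time = time_gradient(trace, pools, calib, bin_width_ms=2.0, min_cycles=50)
        g_dist = distance_gradient(trace, pools, calib, bin_width_um=2.0, min_cycles=50)
        n = min(len(g_time.po2_per_bin), len(g_dist.po2_per_bin))
        np.testing.assert_allclose(
            g_time.po2_per_bin[:n], g_dist.po2_per_bin[:n], equal_nan=True
        )

    def test_distance_gradient_requires_speed(self, calib, short_config):
        _, _, trace, seg = _segmented_synthetic(calib, short_config)
        pools = gate_cycles(seg)  # no speed
        with pytest.raises(ValueError):
            distance_gradient(trace, pools, calib)
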