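# Methods

This note documents the models, estimators and numerical choices behind
`capox`, and what the synthetic-data tests do and do not demonstrate.

## Measurement model

A measurement at one vascular location is a sequence of excitation/decay
cycles: a 10-µs two-photon excitation gate followed by a 290-µs collection
window (300 µs per cycle; 2000 cycles = 0.6 s for routine PO2/flow, 30000
cycles = 9 s for EAT, gradients and temporal fluctuations). Photon arrival
times within the window are histogrammed at 1 µs (290 bins) — the probe's
emission is single-exponential, so finer binning adds nothing at these
photon budgets.

**Lifetime fitting.** Pooled histograms are fit to `A·exp(−t/τ) + B` by
unweighted nonlinear least squares (`scipy.optimize.curve_fit`), after
discarding the first 5 µs of the decay (residual gate contamination).
Initial values come from a log-linear regression on tail-offset-subtracted
counts. The offset `B` is estimated rather than fixed at zero because real
detectors have dark counts and the synthetic default background is nonzero
(0.02 counts/bin/cycle ≈ 10% of the signal). Poisson weighting
(`weighted=True`) is available but off by default; at ≥10⁴ pooled photons
the difference is negligible. Fitting never raises on noisy data: optimizer
failure, all-zero counts, non-positive amplitude, or a lifetime outside
(0.1 µs, 10× window) set `converged=False` and the segment's metric is
dropped downstream — the same rejection philosophy as the R² < 0.5 rule for
segmentations.

**Stern-Volmer calibration.** `1/τ = 1/τ₀ + k_q·PO2`, fit as a straight
line of `1/τ` against PO2 through titration points. The defaults
(τ₀ = 40 µs, k_q = 250 s⁻¹·mmHg⁻¹, so τ = 20 µs at 100 mmHg) are plausible
placeholders for a two-photon phosphorescent oxygen probe; real analyses
must supply probe-specific titration data. Lifetimes up to 1% above τ₀
clamp to PO2 = 0 (fit noise at zero oxygen); larger violations raise.

## RBC segmentation and flow

The per-cycle photon sum is the intensity time course. A 3-cycle (0.9 ms)
moving average suppresses shot noise before Otsu thresholding
(`skimage.filters.threshold_otsu`); runs below threshold shorter than 2
cycles (0.6 ms) are treated as shot-noise dips and relabeled plasma. R² is
computed on the *raw* trace against its two-level per-class-mean
reconstruction; traces with R² < 0.5 (or degenerate unimodal histograms)
are rejected, never raised on.

Flux = valleys / duration; line-density = fraction of cycles labeled RBC;
speed = 6 µm / valley duration, averaged over passages. Valleys touching a
trace boundary count toward flux and line-density but not speed (their
transit time is unknown). Merged valleys (RBCs separated by less than the
smoothing scale) count once — a deliberate reproduction of the known
few-percent undercount of threshold methods; no de-merging heuristic is
attempted.

## Gated PO2 and EAT

With an accepted segmentation: Mean-PO2 pools all cycles; RBC-PO2 pools
valley cycles; InterRBC-PO2 pools the central 40% of each plasma peak,
taken symmetrically about the peak midpoint and rounded inward (minimum one
cycle) so cycles adjacent to RBCs are trimmed. All gates reuse the same fit
settings (5-µs head discard). A gate under 50 cycles is flagged missing
rather than fit. EAT = RBC-PO2 − InterRBC-PO2, reported as-is (possibly
negative under noise).

Each cycle's `Δt′` is the time from its midpoint to the nearest valley
center; cycles before the first/after the last valley use the single
nearest center. Time gradients pool cycles into 2-ms bins of `Δt′`,
distance gradients into 1-µm bins of `v·Δt′`; empty bins carry NaN with a
zero count and are never interpolated. Gradients are computed per capillary
and averaged across capillaries afterwards.

## Oximetry

`SO2 = PO2^h/(PO2^h + P50^h)` with h = 2.59, P50 = 40.2 mmHg (C57BL/6
mouse blood). Saturations are fractions in [0, 1] internally and become
percent only at reporting boundaries. Capillary SO2 uses RBC-PO2 (the
relevant hemoglobin compartment); arterioles and venules use Mean-PO2.
`DOEF = (SO2_A − SO2_V)/SO2_A` per layer from two-stage (animal-first)
saturation means; negative DOEF warns but is not clipped. The
arterio-venous partition `(SO2_pialA − SO2_A1)/(SO2_pialA − SO2_pialV)`
quantifies the share of extraction upstream of first-order capillaries.
Note the partition is computed from the raw saturations; with the
published surface values (0.910/0.620) and A1 = 0.810 it evaluates to
34.5% and is reported at whole-percent precision (34%), the total surface
A–V difference being 29–30% depending on rounding.

## Synthetic-data generator

The generator emulates the statistical structure of the study's raw
measurements; segments are statistically independent (no vascular network
topology, no motion artifacts, no depth-dependent SNR loss).

**Passages.** Inter-center gaps are dead-time + gamma:
`gap = d + X`, `d = transit + 2 ms` minimum plasma gap, with X gamma
distributed, scaled so the total gap has mean exactly `1/flux` and the
requested CV (default 0.5). This keeps passages non-overlapping and
resolvable, the expected count unbiased (`flux·duration`, via an
equilibrium burn-in start), and spans regular (`CV→0`, exactly periodic)
to irregular flow with one parameter. Infeasible flux/speed combinations
(line density ≥ 1, or no room for the dead time) are rejected with an
explicit message.

**PO2 waveform.** PO2 equals a crest value at each RBC center and relaxes
exponentially (default time constant 10 ms) toward an inter-RBC floor —
the monotone intracapillary gradient shape. Slow physiology is emulated by
piecewise-constant modulation over 0.6-s blocks: per-block flux
multipliers are lognormal with the layer's temporal CV, and the PO2 level
shares a latent normal with correlation ρ = 0.7, so flux and Mean-PO2
co-fluctuate as observed in awake animals (where the flux–PO2 correlation
is the strongest of the pairwise set).

**Measurement-scale calibration.** The layer profiles state RBC-PO2 and
EAT on the *measurement* scale — they are gated-estimator outputs, not
waveform amplitudes. Because the valley gate averages the waveform over
the RBC transit and the central-peak gate sits ~10 ms from the nearest
center, gated estimators attenuate the crest-to-floor amplitude by a
flux-dependent factor of roughly 2–4. The generator therefore inverts an
analytic attenuation factor (mean of `exp(−|t′|/τ_relax)` over each gate,
periodic-gap approximation) to choose crest and floor such that the
pipeline's RBC-PO2 and EAT estimators are centered on the profile values.
Waveform crest/floor are stored alongside the targets in the ground-truth
table. The approximation is exact for periodic gaps; with gap CV 0.5 the
recovered layer means run ~15% above target, uniformly across layers, so
orderings and contrasts are preserved.

**Photon synthesis.** Expected counts in bin t of cycle i are
`A_i·m_i·exp(−t/τ_i) + background`, with τ_i the Stern-Volmer lifetime at
the waveform PO2 at the cycle midpoint (PO2 is frozen within each 300-µs
cycle), `m_i = 1 − rbc_contrast = 0.15` while an RBC occupies the focus,
and `A_i` normalized so plasma cycles integrate to `photon_rate_plasma`
(default 50 counts/cycle). Counts are drawn by sampling each photon's
arrival time from the window-truncated exponential — exactly Poisson with
the stated means, but costing O(photons) rather than O(cycles × bins).
Every stochastic step is seeded; cohorts are bit-for-bit reproducible, and
per-segment seeds derive deterministically from the master seed.

**Layer profiles.** Defaults use the published layer means verbatim:
arteriolar PO2 99/94/88/84 mmHg (II/III and IV interpolated between the
printed endpoints), venular 49/47/45/43, capillary flux 41/41/36/38 RBC/s,
EAT 13.4/13.3/9.9/11.0 mmHg. Quantities reported only as trends were fixed
once at realistic values consistent with those trends: spatial flux CV
0.60/0.55/0.40/0.45 (dispersion shrinking with depth), RBC-PO2 means
50/48/44/42 with CV 0.30/0.28/0.22/0.24, speed 1.0 mm/s (CV 0.25),
temporal flux CV 0.15 (0.10 in layer V), temporal PO2 CV 0.06 (0.04 in
IV–V). Branch-ordered capillaries (30% of those above 300 µm) draw from
upstream (97 RBC/s, 1.9 mm/s, RBC-PO2 66) or downstream (36 RBC/s,
0.6 mm/s, 43) distributions matching the published group means.

## Cohort statistics

Layers are half-open depth bins [0,100) → I, [100,320) → II/III,
[320,450) → IV, [450,600] → V (the upper bin closed; the 450–600 µm range
covers mainly the upper part of layer V). Aggregation is two-stage —
within-animal means (with spatial STD/CV across capillaries), then
cross-animal means with SEM — which equals the pooled mean only under
equal per-animal counts. Missing metrics are excluded listwise per metric
with dropped animal-layer cells logged. Temporal fluctuations use 15-point
series (0.6-s bins of a 9-s trace, each re-segmented and re-fit
independently); capillaries with any missing bin are excluded.
Correlations are Pearson on the 15-point series, compared on the Fisher-z
scale (|r| = 1 flagged, excluded from group tests). Group contrasts:
one-way ANOVA with Tukey HSD (Tukey–Kramer under unequal n, via
statsmodels) or Welch t-tests, α = 0.05. No hierarchical models and no
multiplicity control beyond Tukey within a family, matching the two-stage
design.

## Validation sizes and what they show

The test suite validates by parameter recovery on synthetic cohorts:
lifetime-fit calibration at the standard budget (2000 cycles ×
50 counts/cycle; 500 seeds: bias < 1%, spread < 5%); end-to-end recovery
on 50 capillaries with 9-s traces (Mean-PO2 within 2 mmHg of the
noiseless pooled-decay estimand, flux within 5% of the realized passage
count); EAT layer ordering (generating 13.4 vs 9.9 mmHg in layers I/IV)
preserved in ≥ 95 of 100 seeded cohorts at a scaled-down design of 10
capillaries per layer and 3.6-s traces, sized for adequate ordering power
from a pilot effect estimate; and ANOVA/Tukey family-wise type-I error
≈ 0.05 under the null over 1000 simulations.

Passing these shows the estimators are correctly implemented and
well-calibrated *under the generator's assumptions* — independent
segments, single-file flow, exponential PO2 relaxation, stationary
dead-time-gamma passages, pure Poisson noise. It does not certify
performance against motion artifacts, multi-file flow, probe
photobleaching, depth-dependent SNR loss, or non-exponential decay
kinetics, none of which are modeled. The Mean-PO2 "truth" is itself
defined as the fit of the noiseless expected pooled decay (the estimand of
the pooled estimator), not the time-average of the waveform — the two
differ slightly because pooling mixes lifetimes nonlinearly.

## Known limitations

* Within-valley PO2 variation is not modeled (RBC-PO2 is a single gated
  value per capillary).
* The Stern-Volmer defaults are placeholders; absolute PO2 accuracy on
  real data is entirely calibration-limited.
* No temperature/pH (Bohr) correction of the dissociation curve.
* The gate-attenuation inversion is a periodic-gap approximation; under
  irregular flow the recovered EAT is biased slightly upward (uniformly
  across layers).
* Line-scan cross-validation of flow metrics and RBC-size estimation are
  out of scope; the RBC diameter is a fixed 6-µm parameter.
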