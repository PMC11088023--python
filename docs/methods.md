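# Methods

## Scope and data model

The package quantifies dynamic FDG-PET of lung lesions. Time is handled in
seconds at the I/O boundary (`FrameSchedule`, BIDS-PET style JSON sidecars
with `FrameTimesStart`/`FrameDuration`) and converted once to minutes for
all kinetic mathematics, so rate constants are in min⁻¹ and Ki in
ml/g/min. Images are assumed decay-corrected to injection time with voxel
values in kBq/ml — the standard output of clinical reconstruction; the
package performs no decay, scatter or motion handling. Frame values are
treated throughout as *time averages* over the frame interval, not point
samples; several numerical choices below follow from taking this
seriously.

## Arterial input

Two sources of Cp(t):

* **Parametric** (`feng_aif`): the classic tri-exponential bolus
  Cp(t) = (A1·u − A2 − A3)e^{λ1 u} + A2 e^{λ2 u} + A3 e^{λ3 u}, u = t − τ,
  with the standard decay constants (λ1 = −4.1339, λ2 = −0.1191,
  λ3 = −0.0104 min⁻¹), an appearance delay τ = 0.5 min, and amplitudes
  scaled so the peak is ≈ 45 kBq/ml — a realistic ascending-aorta peak for
  a ~265 MBq injection on a modern digital scanner. Evaluated on a 1-s
  grid over 65 min.
* **Image-derived** (`extract_idif`): unweighted per-frame mean over
  10-mm-diameter discs on six consecutive axial slices. When no centre is
  supplied, the ROI is auto-placed at the centre of mass of the ≥90%-of-max
  region of the 0–60 s composite (robust to ties and noise; a plain argmax
  lands on an arbitrary edge voxel of a uniform vessel). Plasma is taken
  equal to whole blood; no partial-volume or spill-over correction.

**Input reconstruction.** IDIF samples are frame averages, and during the
6×10 s bolus frames the curve is far from linear: placing the raw means at
frame midpoints flattens the peak and was measured to bias K1 and Ki
upward by ~35–45% on noiseless phantoms. The default
`integral-preserving` mode therefore exploits that the running integral
∫Cp at every frame edge is *exactly* cumsum(mean·duration): a monotone
shape-preserving cubic (PCHIP) is threaded through those integral knots
and its derivative, sampled at 0.2 s, becomes Cp. This restores the fit to
within ~0.02% of the truth on noiseless phantoms. The `midpoint` mode is
retained for comparison.

## Forward model and simulation

C1 is the exponential convolution K1·[Cp ⊛ e^{−(k2+k3)t}], computed with
an exact piecewise-linear exponential integrator expressed as an IIR
filter (`scipy.signal.lfilter`) — stable for arbitrarily stiff k2+k3, with
a series fallback as k2+k3 → 0. C2 = k3·∫C1 and frame values are
trapezoidal time-averages of CT on a 0.2-s grid. Convergence is second
order in the step; at the default step every frame agrees with a stiff
LSODA reference to better than 0.1% for typical lung kinetics.

## Estimators

**Linearized NNLS (production path).** Double-integrating the ODEs gives
CT = θ1∫Cp + θ2∫∫Cp − θ3∫CT with θ1 = K1, θ2 = K1k3, θ3 = k2+k3, all
non-negative. Because the data are frame averages, the *equation is
averaged over each frame*: the design columns are exact frame averages of
∫Cp and ∫∫Cp (difference quotients of the next-higher cumulative
integral at the frame edges), and the ∫CT regressor uses the exact edge
integrals of the measured averages with a PCHIP antiderivative for the
within-frame part. Midpoint evaluation was tried first and left 3–4%
errors in K1/k2 on noiseless data; the frame-averaged design reduces them
to ≲0.1%. Weighted (w ∝ frame duration, the inverse-variance choice for
frame means; `uniform` available) Lawson–Hanson NNLS then yields θ.

*Errors-in-variables refinement.* The measured TAC appears inside its own
regressor ∫CT, so voxel-level noise attenuates the fit (measured −10%
median Ki on moderate-noise phantoms). Two generalized-least-squares style
iterations replace ∫CT with the model-implied integral (CT′ = θ1Cp +
θ2∫Cp − θ3CT solved by the same exponential integrator) and refit,
reducing the median bias to ≈ −2%. On noiseless data the first solution is
already the fixed point.

*Degenerate mapping* (flags, never exceptions): θ1 < 10⁻⁶ → all rates 0;
θ3 < 10⁻⁶ with θ2 > 0 → K1 = θ1, k2 = k3 = 0, Ki = 0; implied
k2 = θ3 − θ2/θ1 < 0 → k2 clamped to 0, k3 = θ3. For non-degenerate fits
Ki = θ2/θ3 = K1k3/(k2+k3) to machine precision.

**Nonlinear reference** (`fit_2tci_nls`): bound-constrained weighted least
squares through the forward model, 5 starts log-spaced (≈0.4–2.5×) around
the NNLS warm start, bounds [0, 5] on each rate; non-convergence of all
starts is flagged. Kept as an independent oracle, not the production path.

**Patlak** (`patlak_ki`): OLS of CT/Cp against ∫Cp/Cp for frames with
midpoint ≥ t* (default 20 min), using frame-averaged Cp and ∫Cp for
consistency with the frame-averaged TAC (midpoint ratios left ~5% slope
errors when the intercept term dominates, i.e. small Ki with large V).

**Voxel-wise maps** (`fit_voxelwise`): the NNLS path applied per voxel
with shared design columns; identical to the scalar fit voxel for voxel.

## Lesion quantification

Body-weight SUV = activity·(weight·1000 g)/(dose·1000 kBq). Segmentation:
the 26-connected component containing the local maximum among voxels
≥ 40% of that maximum (the max located inside a seed box or bbox, ties to
the lowest linear index); components touching an interior search-box
boundary are flagged, not rejected. VOI summaries report the mean of each
parametric map (primary) and the median (in `extras`); note the VOI mean
of a Ki map does not satisfy Ki = K1k3/(k2+k3) exactly, since a mean of
ratios is not a ratio of means. CT-derived lesion diameters are cohort
covariates only, never computed from images.

## Synthetic phantom

A 32×32×16 grid at 4 mm isotropic: background tissue (K1 = 0.05,
k2 = 0.40, k3 = 0.005 — low-trapping lung-like), a 10-mm-radius spherical
lesion (K1 = 0.12, k2 = 0.25, k3 = 0.06, Ki = 0.0232 ml/g/min — a typical
malignant value), and a 15-mm-radius aortic cylinder carrying the
frame-averaged blood curve (the ascending aorta is ~30 mm across, which
is what makes a 10-mm ROI sit safely inside the vessel). Noise is
zero-mean Gaussian, post-reconstruction style, with
σᵢ = α·√(max(Cᵢ, 0.1)/Δtᵢ); α = 0.77 for the `moderate` level, computed
once as 0.1·√(C̄·Δt) from the default lesion's late-frame mean
(11.9 kBq/ml, 5-min frames) so that moderate ≈ 10% late-frame CoV
(measured 10.5%); `low`/`high` are α/2 and 2α. The phantom emulates
kinetics, frame timing and count-limited noise — not anatomy, scanner
resolution, motion or Poisson statistics — so a green phantom test
establishes estimator correctness, not clinical performance.

## Synthetic cohorts

Group marginals are calibrated to printed clinical summaries: log-normal
for median [IQR] parameters (location ln median, scale ln(q3/q1)/(2·
0.6745)) and zero-truncated normal for mean ± SD parameters, with the
parent (loc, scale) moment-matched so the *truncated* distribution
reproduces the printed mean and SD exactly (naively using the printed
values as parent moments inflates the post-truncation mean by ~4%).
A log-normal anchored at the printed median can match the IQR ratio but
not both endpoints unless the median is their geometric mean; endpoints
land within ~4% for the malignant Ki row. SUVmax, K1, k2, k3 are drawn
independently by default (an equicorrelated Gaussian-copula knob exists);
Ki is first formed as the macro function of the drawn rates, then
rank-preservingly quantile-mapped onto its own printed marginal, so the
Ki column matches its calibration while remaining a monotone function of
the drawn kinetics. Cohorts match printed *marginals* only — the true
joint distribution is unknown — so cross-parameter comparisons (which
parameter "wins" an ROC contest) are illustrative. Default designs: 23
benign / 124 malignant; 93 AC / 17 SCC; 31 EGFR+ / 17 EGFR− (K1, and k2
where unreported, reuse the malignant/AC marginals). A deterministic
benign stand-in (`benign_ki_range_cohort`) spans the printed benign Ki
range [0.0002, 0.0246] ml/g/min.

## Statistics

Two-group comparisons are gated by per-group Shapiro–Wilk at α = 0.05:
both pass → Welch's t (mean ± SD summaries), otherwise Wilcoxon rank-sum
(median [IQR]); the variant is recorded next to the summaries it implies.
ROC analysis auto-orients so AUC ≥ 0.5, uses the midrank Mann–Whitney
AUC, candidate cut-offs at midpoints between adjacent observed unique
scores (±∞ at the ends, so reported sensitivity/specificity are invariant
to infinitesimal cut-off perturbation), Youden-maximal with ties to the
lowest cut-off, and a seeded class-stratified percentile bootstrap
(default 2000 reps) for the AUC CI, expanded if needed to contain the
point estimate. Fixed-threshold classification uses the strictly-greater
convention. No multiple-testing correction is applied (per-comparison
α = 0.05, matching field practice).

## Known limitations

* No motion, partial-volume or spill-over handling; vB is simulator-only.
* The linearized fit's noise behaviour is characterised at the phantom's
  Gaussian noise level; Poisson/count-domain noise is not modelled.
* Patlak inherits its usual small negative transient bias for slowly
  equilibrating tissue at finite t*.
* Reversible (k4 > 0) kinetics are out of scope by design.
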