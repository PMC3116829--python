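# Methods

## The pseudo-3D landscape and the blanket estimator

A segmented nucleus image is interpreted as a surface: the x and y
coordinates are the pixel position and z is the 8-bit gray level
(0–255). The Minkowski–Bouligand (blanket) fractal dimension of that
surface is estimated from how the volume between a dilated upper and an
eroded lower envelope scales with the radius *e* of a non-planar,
ball-shaped structuring element:

* for each *e* = 1…30 pixels, the upper envelope at pixel *p* is
  max over offsets (dx, dy) with dx²+dy² ≤ e² of
  gray(p+(dx,dy)) + √(e²−dx²−dy²); the lower envelope is the analogous
  minimum with the height subtracted;
* the fractal area is A(e) = Σ(upper − lower)/2e over the mask;
* A(e) ∝ e^(2−D) for a fractal surface, so an ordinary least-squares fit
  of ln A against ln(1/e) over the 30 radii gives **FD = 2 + slope**,
  in [2, 3] for surface textures.

Implementation notes:

* **Mask-restricted support.** The structuring support is intersected
  with the nucleus mask: gray values outside the nucleus are never read.
  This avoids contaminating chromatin texture with background and keeps
  a constant surface exactly at FD = 2 whatever the mask shape.
* **Direct (non-iterative) morphology.** Each radius uses its own ball
  element applied to the original surface; the iterative unit-step
  blanket construction is *not* used (it corresponds to a different,
  flat-top element).
* **Real-valued ball heights.** Heights √(e²−dx²−dy²) are kept as reals;
  rounding them introduces a systematic slope bias at small *e*.
* **Shared-scan kernel.** Production code collects, per pixel, the
  max/min gray level on each concentric squared-radius shell once, and
  assembles every radius's envelope from the shells. This is
  algebraically identical to direct enumeration (asserted bit-exactly
  against a brute-force oracle in the tests) and roughly an order of
  magnitude faster. Natural logarithms are used throughout (the base
  cancels in slope and R²).
* A warning is emitted when the nucleus bounding box is smaller than
  2·e_max+1 in either dimension, where large-e areas become
  support-limited; `e_max` is configurable (default 30).

## Goodness of fit ("fractal quality")

The R² of the log-log regression is reported after normalizing for the
slope: the point cloud is rotated **about its centroid** by
π/4 − arctan(slope) so the fitted line sits at 45°, the regression is
refit on the rotated points, and its coefficient of determination is
returned. An ideal fractal gives exactly 1.0 (colinear points stay
colinear under rotation); degenerate zero-variance input is defined as
1.0. The rotation center is a design choice — the centroid keeps the
residual geometry well-defined and scale-free — and the implemented
semantics are pinned by a step-by-step hand-computed fixture in the
tests.

## Morphometry

Nuclear area is the mask pixel count, scaled by the square of the
pixel calibration (µm/pixel). The calibration is a **required** input
with no default — µm² areas are meaningless without it; FD and R² are
pixel-unit computations and ignore it. The circular form factor is
FF = 2√(πA)/P, the perimeter of the equal-area circle over the actual
perimeter. Digital perimeters are estimator-dependent; the default is
the 4-direction Crofton formula (low bias on smooth shapes, within 2 %
of 2πr on digital disks of radius ≥ 20), with `crofton2` and
`boundary8` available and the choice recorded in the output.

## Per-case aggregation

Per-case features are arithmetic means over the acquired nuclei in
acquisition order, with the cumulative-mean FD trace retained. A
stabilization diagnostic reports the earliest index from which a
5-value window of cumulative means stays within 0.005 of the final
value; both knobs are explicit because the original sufficiency
criterion was visual. Cases with fewer than 40 nuclei are flagged. No
nuclei are excluded before averaging.

## Survival chain

* **Kaplan–Meier / log-rank** via lifelines; cohorts with no events are
  flagged rather than tested.
* **Cox regression**: partial-likelihood maximization (lifelines) with
  Wald p-values; optional stratification of the baseline hazard (e.g.
  by ISS stage). ISS enters as indicator contrasts with **stage III as
  the reference** (its coefficient is identically 0). Ties are handled
  by Efron's approximation, which coincides with Breslow's when all
  event times are distinct — always the case for the continuous-time
  synthetic cohorts here. Newton tolerances are tightened
  (precision 1e-12) because the library's default stopping rule leaves
  a final unapplied step of ~1e-6 in the coefficients.
* **Backward stepwise selection** (entry p < 0.05, removal p > 0.10):
  start from the full model, repeatedly remove the term with the
  largest likelihood-ratio p above the removal threshold, re-test
  excluded terms for re-entry after each removal, stop at a fixed
  point. Multi-column terms (ISS) are removed/entered as a unit with
  the matching degrees of freedom. The likelihood-ratio statistic
  stands in for SPSS's "conditional" statistic, which it closely
  approximates. If the full model cannot be fit, the selection falls
  back to a forward build from the strongest single term.
* **Bootstrap stability**: resamples of size n drawn with replacement;
  the full stepwise selection is re-run per resample and each
  candidate's inclusion frequency reported. Failed resamples (e.g. no
  events) are redrawn so the denominator stays at n_boot, with the
  retry count logged; a master seed spawns per-resample substreams for
  exact replay.
* **Ward cut-point**: the two-cluster Ward objective on 1-D data is
  solved exactly — an exhaustive scan of contiguous splits of the
  sorted values for minimal total within-cluster sum of squares — and
  the cut is the midpoint between the flanking values. (Greedy
  agglomeration can miss the optimum on adversarial inputs; the exact
  solution is asserted against brute force and cross-checked against
  scipy's Ward linkage on separated data.)
* **ANOVA + Fisher LSD**: one-way F-test, then pairwise t-tests on the
  pooled within-group variance with N−k degrees of freedom, each
  compared to α = 0.05 without multiplicity correction (that is what
  LSD specifies).

## Synthetic data

The generator produces everything the analysis consumes, with known
ground truth.

**Fractional Brownian surfaces.** Spectral synthesis: complex Gaussian
spectrum with amplitude ∝ f^−(H+1) (power f^−(2H+2)), inverse FFT,
affine rescale to the target gray range, rounding to integers. The
field is synthesized on a 4× finer grid and subsampled: band-limited
synthesis at the target resolution truncates the spectrum at Nyquist
and measurably flattens the increment scaling at 1–4-pixel lags —
exactly the scales the blanket estimator probes. The graph of such a
surface has nominal dimension 3 − H.

**Estimator bias and the calibration family.** The blanket estimator on
8-bit, mask-restricted textures is biased toward 2 for rough surfaces:
the texture relief σ·e^H is bounded by the 8-bit range while the ball
contribution 2e grows with the radius, so the log-log slope is
compressed (the classical self-affinity crossover of blanket/box
estimators; at full contrast the estimate caps near 2.49 for a nominal
2.8, and no rendering at full contrast measures below ≈2.16). Rather
than pretending the nominal dimension is recovered, the generator maps
a **target estimated FD** to a rendering along a one-parameter family
that couples roughness and contrast,

    H(t) = 0.95 − 0.75·t,   gray range 128 ± (40 + 70·t),   t ∈ [0, 1],

calibrated once at the default rendering (96×96 canvas, 42×34 px
ellipse, e_max = 30, 30 seeds per point) and frozen. The family spans
estimated FD 2.09–2.49 nearly linearly and mirrors chromatin biology:
mature chromatin is smooth and uniform, aggressive chromatin is rough
with many dark and light spots. Per-nucleus estimator spread at the
default rendering is ≈0.03–0.04, so 10–40 nuclei give stable case
means.

**Nuclei.** Elliptical masks (default semi-axes 42×34 px at 0.12
µm/px ≈ 64 µm², the scale of myeloma plasma-cell nuclei) filled with
fBm texture; background holds a constant flag value the estimator never
reads. Four archetype presets emulate the classical maturity classes —
mature (target FD 2.08), immature (2.15), blastic (2.18, plus a bright
nucleolus disk), irregular (2.16).

**Cohorts.** Defaults mirror the modelled study: 67 patients, ISS
distribution 14/39/47 %, ≥40 nuclei per case, per-case latent mean FD ~
N(2.113, 0.045) clipped to [2.07, 2.28], latent R² ~ N(0.99875,
0.0008). Survival is exponential with hazard

    h = h₀ · exp(b_fd·(FD−2.113) + b_r2·(R²−0.99875) + b_iss[stage]
                 + b_cyto·n_abnormalities + b_vpg·very_poor),

with coefficient defaults from the modelled final multivariate model
(b_fd = 14.39, b_r2 = −935.12, ISS I/II/III = −2.13/−1.75/0,
b_cyto = 0.8862) and h₀ = ln2/24.9 per month so a median stage-III
patient has ≈25-month median survival. The very-poor-group indicator
(prevalence 0.46) carries b = 0 by design — it is the null covariate
against which selection stability is judged. Censoring: independent
exponential loss to follow-up (rate 0.015/month) plus censoring at
autologous transplantation for a random 30 % of patients (transplant at
6–12 months). Nucleus images per case are rendered from the latent FD
(with per-nucleus jitter sd 0.05) through the calibration family, so
the image→FD→Cox chain is exercisable end to end. All generators are
bit-reproducible given (spec, seed).

What the generator does **not** emulate: irregular nuclear outlines
(masks are ellipses, so synthetic form factors sit near 1 rather than
the ≈0.52 of real nuclei), stain and illumination variation, touching
or overlapping nuclei, segmentation error, and any coupling between the
latent goodness-of-fit R² and the rendered texture (the R² hazard term
acts as latent frailty; only the FD effect is recoverable from the
images). Passing tests therefore demonstrate the correctness of the
estimator and the statistical chain, not performance on stained smears.

## Validation scales and known limitations

Simulation sizes in the test suite are chosen for a routine CI budget:
fBm dimension recovery uses 8 seeds per H at 256×256; the end-to-end
cohort recovery uses 150 patients × 12 nuclei at 64×64 px (e_max = 12)
over 10 seeds; stepwise selection behavior uses 100 seeds at n = 300;
bootstrap separation uses 20 meta-replicates of 25 resamples; the
acceptance script runs a 67-patient cohort at 10 nuclei per case.

Two honest limitations surface in the strictest checks:

* **Absolute fBm dimension recovery.** Estimated FD orders strictly
  with H and stays in (2, 3), but the blanket estimator's compression
  means the nominal 3 − H is recovered within 0.2 only for smooth
  surfaces (H ≈ 0.8); at H = 0.2 the shortfall is ≈0.33 and is
  intrinsic to the method (verified against an independent
  morphological implementation and with unbounded continuous
  amplitude), not to this implementation. The working range of the
  method — and of the chromatin application — is the smooth regime.
* **Stepwise type-I retention.** With removal threshold p_out = 0.10, an
  independent null covariate is retained in ≈10 % of runs by
  construction (its LR p falls below 0.10 that often). Selection
  frequencies, not single runs, are the reliable stability readout —
  which is precisely what the bootstrap inclusion-frequency analysis
  provides.
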