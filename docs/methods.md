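# Methods note

This note records the generative model behind the synthetic data, the
parameter defaults and why they were chosen, and the numerical decisions in
the segmentation and statistics layers. All numbers quoted here are either
definitions of the package's own defaults or quantities computed by the test
suite / `scripts/acceptance.py`.

## 1. Synthetic cohort model

Each subject carries a latent tau **severity** drawn, by default, from a
two-component lognormal mixture: a low mode (median 0.06, log-sd 1.0, weight
0.55) for control/PART-like subjects and a heavy tail (median 2.5, log-sd
0.8) for AD-like subjects. Regional **burden** (% AT8-positive area) is
severity times a fixed regional susceptibility that decreases from
entorhinal cortex (1.0) through neocortical association regions to primary
motor cortex (0.10), mimicking the canonical spread gradient. Off-target
regions (midbrain, basal ganglia, choroid plexus) have zero susceptibility
and an independent small burden, uniform on [0, 0.02] %.

**Braak stage** is assigned by a threshold rule: stage k is reached when the
k-th anchor region (transentorhinal → neocortical sequence) exceeds its
burden threshold; because burden is severity × susceptibility, this reduces
to cutpoints on the latent severity. Thal phase, neuritic plaque score and
ADNC derive from a correlated amyloid latent, TDP-43 from age; a
configurable fraction of subjects (default 0.20) is forced into a PART
profile (Thal ≤ 2, Braak I–IV). Braak stages are stored as integers 0–6;
the table loader also accepts Roman numerals I–VI.

**SUVR** for on-target regions is

```
suvr = (intercept + slope * burden_pct + covariate terms) * noise
```

with intercept 1.02, slope 0.40, an age effect of −0.001 SUVR/year (centered
at 80), a male offset of −0.02, and multiplicative gamma noise with mean 1
and shape 625 (coefficient of variation 4 %, in the range of published
flortaucipir test–retest variability). The intercept/slope pair is chosen so
that the temporal composite crosses its 1.36 positivity cut-off at a burden
of (1.36 − 1.02)/0.40 = 0.85 % — the planted detection change point that the
Youden analysis is expected to recover. Off-target SUVR is drawn
independently of local burden (normal, mean 1.30, sd 0.15), so off-target
burden–SUVR correlations are null by construction. The reference region
(inferior cerebellar cortex) has SUVR ≈ 1 by definition; `roi_mean` and
`ref_mean` columns are generated so that `compute_suvr` reproduces the `suvr`
column exactly.

### Linearity-demo configuration

`CohortConfig.linearity_demo()` sets up the stage-coding vs sextile-coding
comparison: severity is uniform (so sextile means of burden are linear in
sextile rank), all six Braak anchors are entorhinal with geometrically spaced
thresholds (0.05, 0.15, 0.4, 1.0, 2.2, 4.0 %), making burden an
exponential-like function of the stage code, and SUVR noise shape is 25
(CV ≈ 20 %, matching the substantial between-subject heterogeneity of real
cohorts). The CV matters: sextile group means inherit the quantile noise of
the particular burden sample, a wiggle whose size relative to the residual
standard error does **not** shrink with n. With CV 4 % that wiggle dominates
and the sextile F test rejects spuriously; with CV 20 % it is subdominant.
Because single replicates remain borderline (as in the borderline published
sextile comparison), the direction checks evaluate the **median over
replicate cohorts** — 11 seeds in the acceptance test (runtime budget), 25 in
`scripts/acceptance.py`.

## 2. Histology image generation

A field is rendered on a white-matter-free background of hematoxylin color
(default RGB (165, 150, 200)) scaled per subject by an intensity factor in
[0.8, 1.3]. Pathology is drawn as elliptical tangles plus curvilinear
neurites in DAB color, then the mask is trimmed or grown at its boundary so
the planted positive-pixel count **exactly** equals round(fraction × H × W);
Gaussian pixel noise (sd 2.5) is added last. The truth mask is returned with
the image.

**DAB color default (88, 34, 24).** A classic DAB brown such as
(120, 72, 40) has a red channel above 100, so the red > 100 whitening step of
the graph-cut preprocessing (below) would erase the foreground itself. The
default is therefore a darker DAB with red < 100, still satisfying
R > G > B; its stain score R − G = 54 clears the fitted per-subject
thresholds with margin across the intensity-scale range. Lighter stains
remain available through `StainModel`.

## 3. % AT8-positive area quantification

**Stain score.** s = max(0, R − G) per pixel: high for DAB brown, near zero
for the hematoxylin counterstain (red ≈ green) and for white background.

**Per-subject threshold (background-tail rule).** Otsu's criterion on the
pooled score histogram fails here: with realistic ≤ 1–2 % foreground the
histogram is effectively unimodal and Otsu splits the background mode (the
between-class variance of halving the background exceeds w₁w₂Δ² of the true
split), so a clamp always fires and the threshold stops tracking staining
intensity. The default rule instead models the dominant background mode
robustly: t = mean + 4 × sd of the scores below median + 4·s₀, where
s₀ = 1.4826·MAD + 0.5. The +0.5 half-bin guard corrects the underestimate of
MAD on 8-bit-quantized narrow modes. The result is clamped to [25, 240];
the floor of 25 sits above the counterstain score of the default stain model
(15) at all intensity scales. Otsu remains available as
`strategy="otsu"`. Measured relative errors on default-SNR 512×512 fixtures
are within ±3 % of truth at planted fractions from 0.1 % to 10 %
(`scripts/acceptance.py`).

**Graph-cut route.** Following the whitening convention for erythrocytes and
bright debris, pixels with red strictly above 100 are set to white, the image
is converted to integer luma grayscale (0.299R + 0.587G + 0.114B, rounded),
and the binary labeling minimizes

```
E(L) = Σ_p U_p(L_p) + λ Σ_(p,q) exp(−(I_p − I_q)² / 2σ²) · [L_p ≠ L_q]
```

with U the negative log-likelihood of a two-class Gaussian intensity model
(initialized from an Otsu split of the grayscale histogram, darker class =
foreground, sd floored at 0.5 gray levels, clamped at 10⁴) on a 4-connected
grid (8-connectivity available). Defaults λ = 2 and σ = mean absolute
neighbor difference give mild smoothing that removes single-pixel noise
without eroding the thin neurites at the package's field sizes (tested at
128–512 px). The energy is submodular, so the global optimum is found by one
s–t min cut.

**Solver numerics.** The max-flow backend computes in 32-bit integers and
silently wraps larger capacities, so `solve_binary_mrf` (a) shifts each
pixel's unary pair by its minimum — a constant per labeling, (b) caps the
remaining unary at the sum of the pixel's incident pairwise weights + 1
(any larger value already forces that pixel's label in every optimal
labeling, so the set of optima is unchanged), and (c) scales to integers
adaptively so the total capacity stays below 2³¹. The acceptance suite
checks the resulting labeling and energy against exhaustive enumeration of
all 2^(H·W) labelings on images up to 4×4.

Regional % positive area is the arithmetic mean over the 1–3 fields of a
subject × region; per-subject thresholds are fitted on the pooled scores of
all of that subject's fields.

## 4. PET layer

SUVR = ROI mean / reference mean, with a non-positive reference an error.
Meta-ROIs are unweighted means of member-region SUVRs: temporal composite
(4 members, cut-off 1.36) and cortical composite (13 members, cut-off 1.19),
shipped as `tauconcord/data/meta_rois.json`. Positivity uses the
**inclusive** convention suvr ≥ cut-off (a measured SUVR exactly at the
published cut-off is called positive); an exclusive option exists.

## 5. Statistics

- **Spearman correlation**: Pearson correlation of mid-ranks. Exact
  permutation p-value (all n! permutations, chunked) for n ≤ 10; the
  t-approximation t = ρ√((n−2)/(1−ρ²)) otherwise.
- **Youden detection threshold**: candidate cutpoints are midpoints between
  consecutive sorted unique pathology values; rule pathology ≥ t predicts
  PET-positive; ties in J break toward the smallest threshold (the most
  sensitive detection claim).
- **Clopper–Pearson**: exact interval from beta quantiles,
  [B(α/2; k, n−k+1), B(1−α/2; k+1, n−k)], with closed boundaries at k = 0
  and k = n. Chosen over Wald/Wilson because the validation cohorts are
  small (n ≈ 63) and the exact interval's coverage never falls below
  nominal; measured coverage over 2,000 simulated binomials (n = 63,
  p = 0.85) is reported by `scripts/acceptance.py` (≥ 0.94).
- **Linear vs polynomial**: OLS via Vandermonde least squares;
  F = ((RSS₁ − RSS₂)/(d−1)) / (RSS₂/(n−d−1)); AIC uses the full Gaussian
  log-likelihood, AIC = n ln 2π + n ln(RSS/n) + n + 2(k+1), counting the
  error variance as a parameter; ΔAIC = AIC(poly) − AIC(linear), so
  negative values favor the polynomial. Models with residuals at round-off
  level raise instead of reporting a meaningless p. A worked 8-point
  example used by the tests: x = 1..8,
  y = (1.61, 4.12, 7.42, 11.87, 17.55, 24.10, 31.45, 40.02) gives, by direct
  normal equations, RSS₁ = 43.3793, RSS₂ = 0.048940, F = 4426.8,
  p = 1.45e-8, ΔAIC = −52.30 (quadratic preferred).
- **Sextiles**: rank-based six-way split by stable argsort; group sizes are
  ⌈n/6⌉ for the first n mod 6 groups and ⌊n/6⌋ otherwise; ties keep input
  order.
- **Gamma GLM**: `statsmodels` GLM with Gamma family and log link (identity
  available for sensitivity analyses), i.e. IRLS; dispersion from Pearson
  residuals; the test suite verifies the fit against a hand-rolled IRLS
  implementation to 10⁻⁶ and checks 95 % Wald coverage of planted
  coefficients.
- **PART**: definite = Thal 0 with Braak I–IV; possible = Thal 1–2 with
  Braak I–IV; anything else not PART.

## 6. Problem sizes and budgets

Defaults are the package's own choices: 512×512 fields (exhaustive-oracle
tests use ≤ 4×4 where 2^(H·W) enumeration is feasible), cohorts of 63
(matching the motivating validation-study scale) to 500 subjects, 1,000–
2,000 replicates for calibration rates. The full test suite runs in well
under its budget on one CPU; `scripts/acceptance.py` completes in seconds.

## 7. Limitations

- The image generator plants idealized tangle/neurite geometry with
  stationary Gaussian noise; it does not model tissue folds, uneven
  illumination, erythrocytes (the red > 100 whitening step is exercised only
  lightly), or out-of-focus fields.
- Burden–SUVR coupling is linear with multiplicative noise; real
  flortaucipir binding shows regional off-target effects and nonlinearity at
  high burden that the generator does not attempt to reproduce.
- The cohort staging model reduces Braak assignment to anchor-region
  thresholds on a scalar severity; real staging is a spatial pattern
  judgment.
- Statistical conventions (inclusive cut-offs, midpoint cutpoint candidates,
  smallest-threshold tie-breaking, AIC constant) are stated choices; other
  conventions shift third-decimal results.
- Published cohort-level effect sizes depend on an unavailable 63-subject
  dataset; the package checks directions and calibration on synthetic
  cohorts, not those effect sizes.
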