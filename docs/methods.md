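# Methods

This note records the models implemented by `phenopine`, the default
parameter choices and their rationale, what the synthetic generator
does and does not emulate, and the numerical decisions that a
maintainer would otherwise have to reverse-engineer.

## Spectral model and background correction

The measurement scene is a single seedling in front of a non-reflective
black box, observed by a bare fibre optic with a conical field of view.
The footprint on the target plane at distance *d* is a circle of radius
*d·tan(θ/2)*; with the study geometry (24 cm, 25°) this is 5.32 cm,
reported to one decimal as 5.3 cm. Within that circle the recorded
signal is modelled as an area-weighted linear mixture of exactly two
surfaces — seedling and background — which is appropriate because the
background is spatially homogeneous and the optic integrates radiance
over the footprint. Inverting the mixture requires the seedling
coverage C₁; the estimate comes from pixel-level two-class kNN
classification of an RGB photograph, counting classes among pixels
whose centres fall strictly inside the footprint circle
(centre-sampling convention; the discretisation error is one pixel out
of the few thousand in a circle).

Choices the measurement description leaves open, and the defaults
taken here:

* **k of the classifier** — unspecified; default k = 5 (odd, so the
  two-class vote cannot tie), Euclidean distance on RGB scaled to
  [0, 1], no illumination normalisation. All configurable. Residual
  distance ties at the k-th neighbour are broken deterministically
  (class-name order via the probability argmax), so predictions are
  invariant to training-set order.
* **Coverage floor** — the correction divides by C₁, amplifying noise
  by 1/C₁; spectra with C₁ < 0.10 are refused rather than corrected
  (configurable `min_coverage`). The floor value bounds the
  amplification at 10× and is not derived from data.
* **Order of operations** — white-panel normalisation (R = raw/white ×
  0.99) happens before unmixing. Because the mixture is linear and the
  white reference is common to both terms, the result equals the
  radiance-domain correction; normalising first makes the roles of the
  stored spectra unambiguous.
* **Index bands** — nearest-band lookup on the 1-nm instrument grid,
  ties to the lower wavelength; no interpolation, smoothing or
  detector-splice correction.
* Corrected reflectances can leave [0, 1] under noise; they are
  flagged in metadata, never clipped, so downstream code decides.

## Quenching-protocol model

The 192-s protocol is represented as an explicit phase schedule: one
initial dark phase, five actinic light phases, three dark relaxation
phases, every phase closed by a saturation pulse. Exact phase durations
are an instrument configuration not part of the public record; the
default schedule (32 s dark + 5×20 s light + 3×20 s dark) reproduces
the total length and phase counts and is fully configurable. Window
conventions follow standard quenching analysis: F₀ is the mean of the
dark segment before the first pulse, F_M the maximum inside the first
pulse, F_P the induction maximum of the first light phase outside
pulses, F_t the mean of the last 10 % of a phase before its pulse, and
steady state is the final light phase. F₀′ in the light-adapted steady
state (F₀_Lss) is measured by instruments with a dedicated far-red
routine; the model provides an annotated far-red window at the start of
the first relaxation phase, and when a protocol lacks one the package
substitutes the standard approximation F₀·F_M^Lss/F_M and flags the
result. All nine derived parameters are ratios of these levels and are
therefore scale-invariant, which the tests exploit.

## Traits and soil water

Water content is relative mass loss on drying; LMA converts dry mass
per projected area from g cm⁻² to g m⁻². The sensor calibration is an
ordinary least-squares polynomial (default degree 1; a quadratic is
available but must remain monotone over the calibrated range — a
non-monotone calibration is rejected rather than silently accepted).
Converted readings are reported as fractions, clipped to [0, 1] only
with an explicit flag, and flagged when the raw value lies outside the
calibrated range. The permanent wilting point is the VWC linearly
interpolated at the first crossing of −1.5 MPa in the paired
(VWC, potential) series. The reference value "0.204 % VWC" is
ambiguous between a fraction of 0.00204 and 20.4 %; a peat-based
substrate cannot wilt at 0.2 % volumetric water, so the package treats
0.204 as a fraction (20.4 %) and keeps percentages at the I/O boundary
only.

## Mixed model

Per trait, the model is a full ecotype × treatment × DAT factorial
(sum-to-zero contrasts, so the intercept is the grand mean in balanced
designs) with a block × DAT random intercept and per-seedling
heterogeneous-AR1 residuals: corr(e_i, e_j) = ρ^|i−j| scaled by one SD
per DAT. T is a free parameter (the motivating design has T = 19
spectral/fluorescence dates; the recovery study uses T = 6).

Estimation is REML with the fixed effects profiled out (GLS at each
candidate), optimising over atanh ρ and the log SDs with L-BFGS-B and
three fixed-seed restarts on failure. For balanced data (every seedling
at every DAT) the likelihood is evaluated after an orthogonal rotation
in the seedling dimension of each block: the block-mean component has
covariance R + m·σ²_bd·I and the m−1 orthogonal components have
covariance R, reducing every evaluation to T×T Cholesky factorisations
of (at most) a handful of distinct matrices. A dense-covariance
fallback handles unbalanced data and doubles as an internal oracle: the
two paths agree to 1e−9 on balanced inputs, and the dense marginal
covariance matches a brute-force Kronecker construction on a three-tree
toy.

Inference choices: Wald chi-square tests are marginal per term (no
Kenward–Roger or Satterthwaite denominator corrections — with 200
observations per variance parameter in the intended designs the
chi-square reference is adequate, and the recovery study measures the
actual type-I error); predicted means average estimable cell means
over omitted factors with normal 95 % intervals (multiplier 1.96);
pairwise contrasts form one BH family per call (the family definition
is the caller's: per trait × table by default); Cohen's d divides a
contrast by the model's residual SD at that DAT, or the
root-mean-square residual SD when DAT is averaged over, since no
variant of the pooling is canonical for model-based contrasts.

## Redundancy analysis

Responses are z-scored (sample SD), predictors dummy-coded and
centred; the constrained variance fraction R² is the squared norm of
the projection of the response matrix onto the predictor column space
over the total, and the constrained axes come from the SVD of the
fitted matrix. Significance uses free row permutations of the response
(default 999, seeded), with per-predictor marginal statistics as the
extra sum of squares given the other predictors. Under the null,
E[R²] = q/(n−1) for q predictor df — the tests check this, and that
P(p ≤ α) respects the permutation granularity bound α + 1/(n_perm+1).

## Synthetic generator

The generator produces every input with known truth and is
deterministic given its seed (explicit seeds everywhere; no global
state):

* **Scenes** — exact pixel-count coverage inside the footprint circle
  (a raster-order cap of the disk), well-separated colour
  distributions for seedling and background so a pixel classifier can
  be exact. It emulates coverage geometry, not crown architecture.
* **Endmember spectra** — a piecewise parametric curve (green-peak
  Gaussian, chlorophyll absorption well, logistic red-edge sigmoid,
  NIR plateau, SWIR water bands). Only the qualitative responses are
  contractual: more chlorophyll moves the red-edge inflection to
  longer wavelengths (REP up), de-epoxidation depresses 531 nm
  relative to 570 nm (PRI down). No radiative-transfer fidelity is
  attempted and no quantitative match to real pine spectra is claimed;
  passing tests therefore validate the pipeline's algebra and
  statistics, not spectroscopic realism. The background is a low flat
  spectrum (~0.02) mimicking the black coating.
* **Fluorescence traces** — piecewise-linear induction curves whose
  annotated windows equal the truth levels exactly; sample times
  include the anchor points so the zero-noise round trip is exact.
* **Trait tables** — the mixed model itself, with sum-to-zero effect
  vectors (validated, so injected effects are identifiable), seedlings
  assigned round-robin to blocks within each cell.
* **Soil drying** — exponential drying from saturation (VWC 0.60 →
  0.04, time constant 18 days — a realistic pot-scale dry-down), a
  linear sensor with known gain/offset, and a log-linear retention
  curve pinned to −1.5 MPa at VWC 0.204.

What the generator does not emulate: real crown self-shadowing and
specular effects, instrument drift between white references, pixel
bleed at the seedling silhouette, fluorescence heterogeneity across the
imaged needle area, non-Gaussian trait errors, missing data and
mortality. Results on synthetic data bound the method's correctness,
not its field accuracy.

## Problem sizes and numerics

The recovery study runs 200 simulated datasets of 120 seedlings × 6
DATs (and 200 more under the null for the Wald type-I error), a scale
chosen so the full study completes in a few minutes on one CPU while
keeping Monte-Carlo error on a coverage proportion near 1.5 %. The
demo pipeline mirrors the motivating design (2 ecotypes × 3 treatments
× 15 seedlings, 12 spectral dates) at 64×64-pixel scene resolution.
Degenerate inputs fail loudly by design: empty grids, single-class
training sets, constant response columns (named in the error),
non-crossing potential series, zero denominators in index and
fluorescence formulas (the parameter is named), rank-deficient designs
and non-monotone calibrations all raise instead of returning flagged
numbers, except where a flag is the documented behaviour (coverage
extrapolation, out-of-range reflectance).

## Known limitations

* Wald tests use the asymptotic chi-square reference; small-block
  designs (few blocks, many variance parameters) will show mild CI
  undercoverage for DAT-level effects, visible in the recovery study's
  lower coverage bound (~0.92).
* The REML surface for heterogeneous AR1 can be flat when T is small
  and ρ near ±1; the restarts mitigate but do not eliminate local
  optima.
* F₀_Lss without a far-red window is an approximation and is flagged
  as such; parameters built on it (FvFm_Ln, FvFm_Lss, FvFm_Dn) inherit
  the bias.
* The RDA permutation scheme is free row permutation; it does not
  restrict permutations within blocks.
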