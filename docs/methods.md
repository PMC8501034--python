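# Methods

This note documents the models, conventions and numerical choices behind
`ramangt`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Spectral preprocessing

All analysis windows are preprocessed by `preprocess_normalize`: the
ordinary-least-squares straight line over the channel index is subtracted
and the residual scaled to unit Euclidean norm. This makes the reference
family scale-free — `P(a·v + c·ramp + d) = P(v)` for a > 0 — and is
idempotent. The free amplitude α in the unmixing model absorbs any global
scale, so the only requirement is that references and measurements are
treated consistently. A side effect is that normalized spectra sum to ≈ 0
across channels; the per-pixel signal-intensity image is therefore defined
as ‖α·y_x‖₂ (equal to α for unit-norm references), which is proportional
to the channel sum of the corresponding raw, positive spectra.

Window conventions: channels with lo ≤ ν ≤ hi (inclusive). The synthetic
axis is anchored at 2000 cm⁻¹ with spacing 300/209 ≈ 1.435 cm⁻¹, so the
2000-2300 cm⁻¹ analysis window holds exactly 210 channels and each flank
(1800-2000, 2300-2500 cm⁻¹) exactly 140.

## Reference regression

Each channel's normalized intensity versus mixing ratio x is a
shape-preserving piecewise cubic Hermite interpolant of five free knot
values at x̃ = [0, 2, 4, 6, 8]:

* interior knot derivatives: 0 where the adjacent differences change sign
  or vanish, otherwise the PCHIP weighted harmonic mean of the adjacent
  secant slopes (the plain harmonic mean for these equally spaced knots);
* endpoint derivatives: the one-sided three-point estimate
  ((2h₁+h₂)Δ₁ − h₁Δ₂)/(h₁+h₂) *without* the monotonicity clipping some
  library implementations add. On interior segments the interpolant is
  identical (≤ 1e-10 in tests) to `scipy.interpolate.PchipInterpolator`;
  endpoint segments can differ when the boundary slope estimate would be
  clipped.

The five knot values per channel minimize RSS₁ over all replicates at the
17 measured ratio levels. The derivative rule's conditionals make the
objective piecewise-smooth, so a Nelder-Mead search (xatol 1e-10) is run
from a data-driven start — the mean of observations at the levels nearest
each knot — plus two ±5 % perturbed restarts (fixed internal seed), keeping
the lowest RSS₁. At the default 1 % noise the recovered knot values sit
well within three standard errors of the generator truth. The model's
domain is hard-bounded to [0, 8]; extrapolation raises.

No bounds are imposed on the knot values themselves: nothing in the
normalized-intensity scale requires them, and the restart strategy guards
the only failure mode observed (flat channels with sign-ambiguous
derivatives).

## Constrained unmixing

At fixed x the amplitude problem min ‖m − (α·y_x + β·b + γ·s + δ·1)‖²
subject to α, β ≥ 0 is solved exactly by enumerating the four sign
patterns of the two inequality constraints (each an unconstrained least
squares over the remaining columns) and keeping the feasible solution with
the lowest RSS; exact ties prefer the fully unconstrained pattern.
Rank-deficient designs (e.g. b parallel to the offset column) fall back to
the minimum-norm solution and are flagged. The profiled objective
g(x) = min RSS₂ is minimized by a coarse 0.05-step grid over [0, 8]
followed by local refinement — a bounded scalar search for single-pixel
fits, a shared 0.002-step local fine grid for whole cubes — which matches
an exhaustive 0.001-step brute force to well under 0.005 in the
cross-check. Refinement can only improve on the coarse solution by
construction.

SNR₂ = ‖α·y_x‖²/RSS₂, with the conventions 0 when α = 0 and +∞ when the
fit is exact with nonzero signal. A pixel is "identifiable" when α > 0 and
SNR₂ exceeds the masking threshold (default 100).

The flank background subtraction (display only) fits (β, γ, δ) by
unconstrained least squares on the two concatenated 140-channel flanks;
the ramp regressor is the concatenated index 1…280. For subtraction over a
display window the ramp is continued across the 2000-2300 cm⁻¹ gap by
linear interpolation between the flank endpoints (140 → 141), the only
continuous extension consistent with the flank-space fit. Flanks with
fewer than three channels on the given axis are rejected.

## Kinetic saturation model

g/t(x) = p + r·xⁿ/(q + xⁿ) with baseline p, half-saturation q > 0 and
plateau p + r. The equilibrium argument fixes only that the two reaction
orders are equal; their common value n is not determined, so n = 1 by
default, with optional co-fitting. Fitting is trust-region least squares
in the parametrization (p, p + r, q[, n]) with box bounds
p, p + r ∈ [0, 1.5] (saturated-chain gauche/trans ratios stay well below
1.5 even in disordered bilayers) and q ≥ 1e-8. Flat point sets fit r ≈ 0
and are flagged non-identifiable in q. Noiseless points at the 12 tabulated
bilayer compositions are recovered to ≤ 1e-4.

The 12 bilayer composition tables (mixing ratio → molecule counts, e.g.
8.0 → 192:24) are tabulated study inputs; their count ratios equal the
nominal mixing ratios exactly.

## Dihedral conformer analysis

Signed dihedrals use the standard two-plane convention, range (−180°, 180°]
with anti-periplanar at 180°; the angle is invariant under rigid motion and
flips sign under mirror reflection. Classification: gauche iff |φ| ≤ 120°
(the symmetric rotamer boundary between the 180° and ±60° minima; the
boundary itself counts as gauche; configurable). All consecutive backbone
carbon quadruples are evaluated — 13 positions for a 16-carbon chain.
Ensemble ratios pool gauche and trans counts over all chains and frames
(ratio of sums, not mean of ratios), since the kinetic model's
concentrations are counts of dihedral positions. Chains are built from
internal coordinates (bond 1.54 Å, angle 111°) with the out-of-plane sign
chosen so builder and analyzer round-trip to ≤ 1e-6 degrees.

## Image quantification

* **Scan-line artifacts (HLA).** Cosine similarity between each pixel's
  3-row × 31-column neighbourhood of the intensity image and a template
  with ones in the middle row; reflect padding; flag > 0.7 (a uniform
  image scores exactly 1/√3 ≈ 0.577, safely below); flagged pixels dilated
  by 10 px in both horizontal directions. Flagging is invariant under
  positive rescaling of the image.
* **Valid mask.** SNR₂ > 100 and not artifact-extended.
* **LD segmentation.** Median-filter background (kernel 21, reflect)
  subtraction; convolution with the fixed 5×5 center-surround kernel
  (center 24, twenty −1 neighbours); Gaussian annular Fourier bandpass
  with half-power cutoffs at structure sizes 5 px (high-pass arm) and 2 px
  (low-pass arm), mirror-padded FFT; min-max rescale to [0, 255]; threshold
  at 5 × the modal intensity (fullest of 256 unit bins); LD = above
  threshold ∧ valid; non-LD = valid ∖ (LD dilated by a radius-2 disc).

  Every stage uses *non-negative arithmetic*: differences and filter
  responses below zero clamp to zero, matching the 8-bit display-pipeline
  semantics of the image tools this procedure mirrors. This choice is
  load-bearing: with signed arithmetic the center-surround kernel carves
  negative moats around bright puncta as deep as the peaks, the rescaled
  modal intensity then sits near mid-range, and 5× it exceeds the maximum
  — no threshold could ever fire. With clamping, the modal intensity
  measures the small offset of the background bulk above zero and the rule
  behaves as intended. A structureless image (filtered maximum ≤ 1e-8 of
  the intensity scale) yields an empty LD mask rather than rescaled
  numerical ripple.
* **Region statistics.** Mean/median/SD of the mixing-ratio and
  gauche/trans images per region, pixel counts, and LD area fraction
  |LD|/(|LD|+|non-LD|). Empty regions report missing values with a
  warning; images without detected LDs complete with a note that such
  data are analyzed manually.

## Synthetic data: what it emulates, what it does not

* **Reference family**: pseudo-Voigt C-D bands whose center right-shifts
  and width grows linearly with the mixing ratio (the qualitative
  behaviour of the ~2100 cm⁻¹ band); 17 levels × 10 replicates; replicate
  nuisance = amplitude jitter, affine baseline, i.i.d. Gaussian channel
  noise (1 % of peak by default). The noise-free channel functions are
  constructed to be exactly representable by the 5-knot regression, so
  fitting accuracy can be separated from model misspecification. Real
  band shapes, Poisson shot noise, wavenumber miscalibration and cosmic
  rays are not emulated.
* **Phantom cubes** (default 64×64×210, 0.3 µm/px): cytosol at x = 3.0
  with unit signal amplitude; three droplet discs of radius 2 px (≈1.2 µm,
  inside the 2-5 px band the droplet filter retains) at x = 0.5/0.8 with
  8× amplitude; smooth broad background with per-pixel amplitude, ramp and
  offset nuisance; Gaussian channel noise (0.002). Scan-line rows are
  modelled as a ×3 *gain* artifact on the signal amplitude — a spectrally
  flat additive stripe would be absorbed exactly by the free offset δ and
  never reach the intensity image, so a gain artifact is the minimal model
  that reproduces the stripes the detector actually leaves there.
* **Kinetic points**: forward curve at the 12 tabulated compositions plus
  Gaussian noise.
* **Chains**: prescribed or Bernoulli-sampled dihedral sequences realized
  as 3-D coordinates.

All generators are pure functions of (spec, seed).

## Problem sizes and runtimes

The test suite builds one 210-channel reference model (≈30 s), unmixes one
64×64×210 phantom (≈10 s) and cross-checks the minimizer on 100 random
pixels against a 0.001-step exhaustive grid; the whole suite runs in about
three minutes on one CPU. `scripts/acceptance.py` repeats the study from
scratch in about a minute, using 50 pixels for the brute-force cross-check
and 800 chains (10 400 dihedrals) for the conformer-statistics check.

## Known limitations

* The background regressor is a single measured pixel, as in the original
  crosshair procedure. Its noise is shared by every pixel's fit and
  induces a common-mode signed bias in the recovered mixing ratio — at the
  generator's default noise level, up to ~0.2 ratio units depending on the
  background-pixel noise draw (verified to vanish when the true background
  is supplied). Averaging several background pixels would reduce it;
  faithfulness to the single-pixel procedure was preferred.
* The kinetic order n is not identifiable from the equilibrium argument;
  results for n ≠ 1 require co-fitting and more informative data.
* The LD threshold rule assumes puncta within the 2-5 px band; larger
  droplets are attenuated by the bandpass and would need different filter
  sizes.
* Passing tests on phantoms demonstrates correctness of the mathematics
  and the pipeline plumbing, not performance on real instrument data —
  real spectra carry shot noise, baseline structure and band-shape
  variation the generator does not model.
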