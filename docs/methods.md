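# Methods

## Model

A discrete linear imaging system maps an object coefficient vector
θ ∈ C^N (a 2D pixel image) to measurements g = Hθ + n.  The SVD
H = Σ_n σ_n v_n u_n† splits object space into a *measurement space*
(span of u_1 … u_P) that the data determine stably and a *generalized null
space* (the orthogonal complement) that they do not.  The truncation index P
is set by a stability tolerance ε through the rule μ_P > 1/ε² ≥ μ_{P+1},
stated on the squared singular values μ_n = σ_n²; internally the package
stores σ_n and converts when applying the rule, so no silent factor sneaks
into the threshold.  A mode whose μ equals 1/ε² exactly is excluded
(the inequality is strict).  When P = R and H has exact zero modes, the
generalized null space is the literal kernel of H.

The truncated pseudoinverse H_P⁺ = Σ_{n≤P} (1/σ_n) u_n v_n† is the stable
linear estimator; it is 1/σ_P-Lipschitz in the data.  The projectors are
P_meas = H_P⁺H and P_null = I − P_meas.

Every reconstruction θ̂ then splits as θ̂ = θ̂_meas + θ̂_null, and the errors
attributable solely to the reconstruction prior are isolated as

* **measurement-space hallucination map**: θ̂_meas − θ̂_tp, where
  θ̂_tp = H_P⁺g.  Requires no knowledge of the true object.
* **null-space hallucination map**: 1(θ̂_null) ⊙ (θ̂_null − θ_null), where
  1(·) is the pixelwise exact-zero indicator.  The indicator makes the map
  identically zero for any estimator that never invents null-space content
  (in particular θ̂_tp), while a prior-driven null component is compared
  against the truth's null component.
* **error map**: θ̂ − θ (all error sources mixed).
* **bias map**: E[θ̂] − θ over repeated Gaussian noise realizations with the
  model-error phase perturbation held fixed (default 100 realizations).

## Numerical zero and the indicator

Floating-point projections of a generic estimate are never exactly zero, so
a literal exact-zero indicator would be vacuous without care.  The null
projectors therefore snap outputs whose magnitude falls below a relative
floor (default 1e-12, the same order as the rank floor used when counting
nonzero singular values) to exact zero.  An estimate whose null component is
zero *by construction* — any zero-filled pseudoinverse image, whose
unsampled k-space coefficients are FFT round-trip dust of order 1e-16 —
then projects to a bitwise-zero array, and the indicator behaves exactly as
defined.  Genuine null content sits many orders of magnitude above the
floor and is untouched.  The indicator additionally accepts an absolute
tolerance (default 0) for studying near-zero cases.

## Stylized MRI system

The forward operator is H = M F with F the *unitary* 2D DFT (normalization
1/√(rows·cols) both ways, DC at the grid center under the shifted
convention) and M a binary Cartesian mask.  Consequences used throughout:

* every nonzero singular value equals 1, so the zero-filled inverse FFT is
  exactly the Moore–Penrose pseudoinverse and no truncation is needed — the
  generalized null space *is* the true null space (dimension = number of
  unsampled k-space points);
* P_meas = F⁻¹MF and P_null = F⁻¹(1−M)F are analytic and O(N log N).

The uniform Cartesian mask samples every accel-th phase-encode row:
rows r with r ≡ offset (mod accel).  With offset 0 exactly ⌈rows/accel⌉
rows are kept; the default offset aligns the comb with the DC row, which is
the sensible physical choice (the bulk of object energy lives at DC).  The
exact line layout of the reference undersampling pattern is not published;
this layout is the package's documented choice and both parameters are
recorded in every output.

Measurement corruption at sampled locations is a multiplicative per-sample
uniform phase perturbation g·e^{iφ}, φ ~ U(−a, a) (model error), applied
*before* additive iid Gaussian noise on the real and imaginary channels
(σ per channel).  The order is a documented convention.  Defaults used by
the experiment pipeline: σ = 0.01 and a = 0.1 rad on unit-intensity
objects — visible but not dominant corruption; both are configuration
parameters, as the reference study does not print its values.

## Phantoms

The generator emulates two object populations with a genuine distribution
shift, standing in for in-distribution vs out-of-distribution anatomy:
family A (few large smooth ellipses, low-frequency texture) and family B
(many small ellipses, high-frequency texture).  Each phantom is a sum of
constant ellipses rescaled to peak 0.8, plus band-limited zero-mean texture
(RMS = `texture_amp`, default 0.03) restricted to the support, plus an
optional additive circular lesion of known contrast; values are clipped to
[0, 1] and the support stays strictly inside the field of view.  Identical
specs are bit-reproducible.  The families separate cleanly in high-frequency
energy fraction (`texture_power`), which the tests verify.

What the phantoms do *not* emulate: realistic brain anatomy, scanner
statistics, coil effects, or the texture spectra of real MRI datasets.
Passing tests therefore demonstrate the *mathematical* behavior of the maps
and estimators, not clinical performance.

Default size is 64×64 for tests and the demo pipeline (the reference
configuration is 320×320); size is a parameter, and every dense-oracle
comparison is done at ≤16×16 where materializing H is cheap.

## PLS-TV solver

recon_plstv minimizes ½‖g − Hθ‖² + λ·TV(θ) with isotropic total variation
(forward differences, reflective boundary; complex images contribute real
and imaginary channels separately).  The solver is a monotone accelerated
proximal-gradient scheme (MFISTA): step size 1 is the exact Lipschitz step
because ‖H†H‖ = 1; the TV proximal map is an inner Chambolle dual iteration
(default 30 iterations, τ = 0.249) written against the package's own TV
discretization so the monotonicity contract is meaningful; accelerated
candidates that would increase the objective are rejected (keeping the
previous iterate and restarting momentum), so the objective trace is
nonincreasing by construction even with an inexact prox.  A candidate that
overshoots the current objective by more than 1% repeatedly (default
patience 30) raises a divergence error naming the step size.  Convergence:
relative objective change below `tol` (default 1e-6) on an accepted step;
default `max_iter` 500 (the demo pipeline uses fewer at 64×64).  λ is
problem-scale dependent; the demo uses λ = 0.005 at 64×64 on [0, 1]
phantoms, and the null-recovery analyses use λ = 0.002 with 300 iterations.
The reference study's own hyperparameters are not published; these are the
package's choices.

U-Net and deep-image-prior reconstructions are deliberately out of scope;
any externally produced estimate can be analyzed by passing a callable
`(g, mask) -> estimate` (or its output) to the map functions.

## Transform T (specific maps)

Pipeline, deterministic end to end: absolute value → zero outside the
object support (Otsu's threshold on the true object, 256 bins, when no mask
is supplied) → histogram equalization over in-support pixels (256 bins) →
Gaussian smoothing → binarize strictly above the `percentile`-th percentile
(default 95) of in-support processed values → drop connected components
smaller than `min_component_px`.  Choices where the reference is silent or
ambiguous, all configurable:

* "kernel width 7" is realized as a 7×7 truncated Gaussian with
  σ = 7/4 (radius 3);
* the percentile is computed over in-support pixels only (outside-support
  zeros would otherwise dominate the low tail);
* absolute value first, so positive and negative structures are detected
  symmetrically;
* connectivity default 8-neighbor;
* a map that is constant within the support (e.g. identically zero) has no
  structure to localize and yields an empty map.

The pipeline is scale-free: T(c·map) = T(map) for any c > 0, since abs,
equalization, smoothing and percentile thresholding are all invariant to a
positive scale.  `min_component_px` defaults to 100 (≈0.1% of a 320×320
grid); the 64×64 demo pipeline uses 20.

## Region-restricted SSIM

Per-pixel SSIM uses a Gaussian-weighted 7×7 window (σ = 1.5), stabilizers
K1 = 0.01, K2 = 0.03, reflect boundary handling, computed on real parts
with the truth's peak-to-peak range as the data range.  Tests pin the map
to a direct per-window evaluation of the definition and cross-check against
an independent library implementation under matched settings.  Ensemble
records average the SSIM map separately over the specific-map support and
over the remaining in-support background (disjoint sets covering the
support); per-method summaries report medians and 30-bin histograms.
Records with empty region support are excluded and counted — notably the
pseudoinverse method, whose null hallucination map is identically zero,
never produces regions.

## Problem sizes and reproducibility

Default experiment: 3 phantoms × 2 methods at 64×64, ×3 undersampling;
bias maps at up to 400 realizations; dense oracles at ≤16×16; the
projector-algebra sweeps use 100 random objects over 10 masks between 8×8
and 32×32.  Every stochastic step is seeded; re-running a persisted
configuration byte-reproduces all numeric artifacts (`.npz` archives carry
no timestamps), which the tests assert.

## Known limitations

* Desk-scale only: dense SVDs materialize H (fine to ~32×32); large-scale
  iterative/randomized projector computation is out of scope.
* The pixel basis is the only expansion basis: coefficient maps and
  object-space maps coincide by construction.
* Single-coil, no coil sensitivities, bias fields, or non-Cartesian
  trajectories.
* The specific-map transform is one simple localization recipe, not a
  task-optimal design; its output depends on the configured percentile and
  component floor.
* Classifying detected structures as false positives/negatives is out of
  scope.
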