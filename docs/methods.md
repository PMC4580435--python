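# Methods

This note records the models, numerical conventions and design choices
behind `tvpet`, in the spirit of a package methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Imaging model and coordinates

Images are square `N×N` arrays of non-negative activity; array axis 0 is
`x`, axis 1 is `y`, the centre sits at index `((N−1)/2, (N−1)/2)`, and the
default length unit is one pixel.  A line of response (LOR) is
parameterised by its signed transaxial offset `s ∈ [−r_f, r_f]`, azimuth
`φ ∈ [0, π)`, axial midpoint `z` and axial tangent `δ = tan θ`.  The datum
is

```
p(s, φ, z, δ) = ∫ dl f(s cosφ − l sinφ, s sinφ + l cosφ, z + l δ)
```

with `l` the transaxial path parameter; integrating in `l` rather than arc
length absorbs the conventional `1/(1+δ²)` normalisation, so for an axially
constant object the oblique sinogram is independent of `δ` (a tested
invariant).  The full-turn convention is folded to a half turn using
`p(s, φ+π) = p(−s, φ)`; 2D reconstruction only needs `[0, π)`.

The axial grid of a rebinned stack has `2·n_rings − 1` slices (direct
planes on the rings, cross planes between them), spacing `L / (2·n_rings)`.

## Synthetic data

Phantoms are additive compositions of ellipses; a pixel's activity is the
sum of the activities of shapes covering its centre.  Two stylised presets
emulate common test objects:

* `brain_like` (default 64×64): a white-matter base (0.25), two gray-matter
  lobes (total 1.0, i.e. a 4:1 gray:white FDG-like ratio) and two small hot
  lesions (total 2.0) that sit entirely inside gray matter, so each ROI has
  constant truth.  The white-matter-only area is the contrast-recovery
  background.
* `thorax_like` (128×128): body, two lung fields, spine, mediastinum and
  five small hot lesions.  Additive composition cannot express activity
  *below* the body base, so the lungs are distinct (slightly raised)
  regions rather than cold ones; the preset emulates the region layout of a
  thorax, not its attenuation physics.

Activity values are arbitrary units of order 1; all downstream calibrations
assume this scale (see *Fidelity scale* below).

The projector samples each LOR at half-pixel spacing with bilinear
interpolation and sums (validated against the analytic chord length of a
uniform disc, ≤3% interior error); the oblique projector samples
trilinearly through the slice stack and truncates where lines leave the
axial extent (it warns when a `δ` implies truncation everywhere).

Counting noise: bins are scaled so their sum equals the expected total
event count and replaced by independent Poisson draws.  The experiment
drivers rescale the draws back to line-integral units (`preserve_scale`),
i.e. data are treated as pre-corrected and calibrated, with the count
budget setting only the relative noise level (≈ `1/√(counts per bin)`).
"Counting rate" means expected total counts per 2D sinogram.  All
randomness flows through explicit integer seeds; there is no global state.

## Fourier rebinning

`rebin_fore` extends each oblique sinogram to a full turn, takes its 2D FFT
over `(s, φ)`, and shifts the component at radial frequency `ω` (radians
per length) and integer harmonic `k` axially by `−δ·k/ω` — the
frequency–distance relation: that component originates at transaxial
distance `−k/ω` along the LOR, hence at axial offset `−δ·k/ω` from the
midpoint.  Shifted components are accumulated into the two bracketing
slices with linear weights and each frequency bin is normalised by its
accumulated weight, so every output slice estimates the *average* direct
sinogram (total stack mass equals the accepted oblique mass divided by the
number of accepted `δ` planes; this average convention is forced by the
requirement that an axially uniform object rebin to its own direct
sinogram).

Components where the relation degenerates keep the single-slice (midpoint)
assignment: `|ω|` index below `omega_limit` (at least the `ω = 0` row),
`|k|` below `k_limit`, Nyquist rows/columns (no Hermitian partner — shifting
them would leave an imaginary residue), and components implying a source
distance `|k/ω| > r_f` (physically impossible; leakage).  Out-of-grid
targets are clamped to the edge slices, which keeps the mass identity
exact.  Default `omega_limit = k_limit = 1`, the smallest cutoffs at which
the axially uniform cylinder phantom rebins to its direct sinograms within
a few percent at desk scale.  `rebin_ssrb` is the degenerate case (all
shifts zero) and doubles as the test oracle; with the limits covering the
whole transform, `rebin_fore` reproduces it exactly.

## Direct Fourier reconstruction

The three steps: (1) unitary 1D FFT of each radial profile, zero-padded by
`pad_factor` (default 4) to oversample the radial frequency axis, with the
phase appropriate for profiles centred on `s = 0`; (2) bilinear
interpolation in `(radial frequency, angle)` of the polar samples onto the
`N×N` Cartesian frequency grid — each in-disk bin takes the
distance-weighted average of its 4 nearest polar samples; the DC bin takes
the mean of the per-angle DC values, bins beyond the maximum radial
frequency are flagged unsampled, and Hermitian symmetry is enforced; (3)
real part of the inverse unitary centred 2D FFT with unsampled bins at
zero (the minimum-norm completion).

One subtlety: mirroring `P(ν, π) = P(−ν, 0)` on an fftshifted even-length
frequency axis is a flip *plus a one-bin roll*; a plain flip is off by one
frequency bin.

Accuracy at the reference protocol (64×64, 96 angles, pad 4): the polar
samples themselves are accurate to ~1%; the dominant error is angular —
at 1.5·N angles the outer frequency rings are angularly undersampled and
bilinear averaging of decorrelated phases attenuates them, which acts as a
mild low-pass.  This error is protocol-inherent (denser angular sampling,
not a different kernel, would remove it); `pad_factor` controls only the
(already small) radial interpolation error.

## The TV solver

The objective is `J(u) = ½‖F u − f‖² + α‖u‖_TV` with isotropic TV built
from periodic forward differences (`D_i u` has the two axis differences at
pixel `i`).  Periodic boundaries are required so `DᵀD` is diagonal in the
Fourier basis; phantoms vanish near the border, so the wrap term is inert.

**Fidelity scale.**  The balance between `‖Fu − f‖²` and `α‖u‖_TV` depends
on the squared operator norm assigned to `F` relative to the unitary
transform (`fidelity_scale`, default 4).  The default is calibrated once so
that the default TV weight `α = 1.5` sits at the joint bias/variance
optimum for the reference brain phantom at 10⁶ counts — the calibration
minimising bias alone (~2) and the one minimising variance and relative
error (~8) bracket it, and the composite is flat in between.  This mirrors
how the TV weight is chosen in practice: scanning `α` at fixed scale, the
bias and variance of the reconstruction fall and then rise, and the default
is placed at the knee.  The Lipschitz constant of `∇G`,
`G = ‖Fu − f‖²/(2α)`, is then `L = fidelity_scale/α`.

**Iteration.**  With splitting variables `w_i = D_i u` and multiplier `λ`
(both initialised, with `u`, at zero):

1. `u` update: minimise the quadratic surrogate
   `G(u_k) + ⟨∇G(u_k), u−u_k⟩ + ‖u−u_k‖²/(2δ) + (β/2)‖Du − w + λ/β‖²`
   exactly via the FFT-diagonalised normal equations
   `((1/δ)I + βDᵀD)u = (1/δ)(u_k − δ∇G(u_k)) + βDᵀ(w − λ/β)`
   (the residual of which is checked to 1e−8 in the tests).  The step size
   `δ` is the Barzilai–Borwein value `1/δ = ⟨Δg, Δu⟩/‖Δu‖²` (reciprocal
   clamped to `[1e−12, 1e12]`; non-positive curvature falls back to the
   previous `δ`; the first iteration uses `delta_init`), halved by a line
   search until the surrogate majorises `G` *and* the objective `J` does
   not increase.
2. `w` update: per-pixel shrinkage `w_i = shrink(D_i u + λ_i/β, 1/β)` with
   `shrink(b, μ) = max(‖b‖−μ, 0)·b/‖b‖`.
3. `λ` update: `λ ← λ − β(w − Du)`.

`β` (default 10) only affects the convergence path, not the optimum; at the
default scale it balances the subproblems (splitting residual
`‖w − Du‖/‖Du‖` reaches ~5×10⁻⁴ within 100 iterations) and the result is
insensitive to it over two orders of magnitude.

**Stopping.**  Iterations stop at `max_iter` (default 100) or when the line
search drives `δ` below `delta_stop` (default 1e−5) without finding a step
that decreases `J` — i.e. when no monotone progress is possible, which is
the practical meaning of a step-size-based stopping rule here: since the BB
reciprocal is a Rayleigh quotient of `∇²G`, `δ` is bounded below by
`α/fidelity_scale` in exact arithmetic and can only collapse through
line-search rejections.  A divergence guard aborts if the objective grows
more than tenfold over five iterations (unreachable with the monotone line
search; it protects modified configurations).  An optional non-negativity
clamp exists but is off by default.

The `α → 0` limit reproduces the DF reconstruction (tested at `α = 1e−6`,
<1% relative difference): the fidelity term then forces the sampled bins to
the data and the unsampled bins stay at the TV-preferred (near-zero)
completion.  Final images are insensitive to `delta_init` over
`{0.08, 0.8, 8}` (<1% pairwise difference; in the tested noiseless runs
they agree to ~4×10⁻⁵), though the noiseless solve reaches its stall only
beyond the 100-iteration cap.

## Metrics

`bias` and `variance` follow the regional definitions above; because both
divide by the true pixel value, regions are restricted to strictly positive
truth, and the "all region" summary uses every such pixel.  For *variance*
the regional mean `ū_n` is only meaningful within a homogeneous region, so
the all-region variance is pooled over constant-truth sub-regions
(`pooled_variance`); on a homogeneous ROI it coincides with the plain
definition.  Without pooling, anatomical contrast dominates the statistic
(≈1.6 for any decent reconstruction of the brain phantom) and it stops
measuring noise.  CRC uses the phantom's exclusive-background region and
the true S/B ratio as the theory value.

`count_rate_sweep` runs levels × methods × replicates with per-replicate
seeds derived from one base seed (`SeedSequence([seed, level, rep])`), so
the full table is bit-reproducible.

## Problem sizes and known limitations

* The reference experiments use a 64×64 brain phantom, 64 radial bins, 96
  angles, five replicates at each count level — sizes at which the full
  sweep runs in seconds on one CPU while leaving the Poisson-noise regime
  of interest intact.
* The simulator is geometric: no positron range, scatter, randoms,
  attenuation or detector blur.  Consequently the reconstruction error at
  moderate counts contains a *systematic* component shared by both methods
  (band-limit ringing plus the gridding low-pass, amplified by the `1/û`
  weighting over the low-uptake base), of the order of +0.013 in all-region
  bias for DF.  TV removes part of it (≈+0.008 for BOSVS) and most of the
  noise variance, but method contrasts driven by *physics* noise in real
  acquisitions are compressed here.  Passing tests therefore demonstrate
  correctness of the operators and the direction and stability of the
  method contrasts, not the exact ratios obtainable on scanner data.
* TV shrinks small-lesion contrast (visible in the ROI bias of the worked
  example); the contrast-recovery coefficient of the regularised method is
  below the DF baseline at the default weight.
* The noiseless TV solve converges linearly with a slow tail
  (ratio ≈0.97/iteration at the default calibration); within the
  100-iteration cap it reaches image differences far below the noise level
  but not its monotone-progress stall.
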