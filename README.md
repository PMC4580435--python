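# tvpet

Total-variation constrained direct Fourier reconstruction for 3D PET.

In fully 3D positron emission tomography the scanner records line integrals
of the tracer distribution along oblique lines of response,
`p(s, φ, z, δ)`, where `s` and `φ` are the usual sinogram coordinates, `z`
the axial midpoint and `δ = tan θ` the axial tangent of the line.  This
package implements a two-stage reconstruction of such data:

1. **Fourier rebinning (FORE).**  Each oblique sinogram is transformed over
   `(s, φ)`; by the frequency–distance relation the component at radial
   frequency `ω` and angular harmonic `k` originates from activity at axial
   position `z − δ·k/ω`, so shifting each component by that offset and
   accumulating produces a stack of ordinary direct sinograms
   (`N` direct + `N−1` cross slices for an `N`-ring scanner).  Single-slice
   rebinning (SSRB) is included as a fallback and oracle.
2. **2D reconstruction.**  Each direct sinogram is reconstructed either by
   the classic three-step direct Fourier (DF) method — per-angle radial
   FFT, polar→Cartesian gridding, inverse 2D FFT — or by solving the
   TV-regularised problem

   ```
   min_u  ½‖F u − f‖² + α‖u‖_TV ,    ‖u‖_TV = Σ_i ‖D_i u‖₂
   ```

   where `f` is the gridded frequency-plane data and `F` the Fourier
   transform restricted to the sampled bins.  The solver is the Bregman
   operator splitting method with variable Barzilai–Borwein step size
   (BOSVS): the TV term is split with auxiliary gradients `w_i = D_i u` and
   a multiplier `λ`, and each iteration performs a BB-stepped, line-searched
   quadratic-surrogate `u` update (solved exactly in two FFTs), a
   closed-form shrinkage `w` update and the multiplier update
   `λ ← λ − β(w − Du)`.

Because PET images are locally piecewise constant, the TV prior suppresses
streak/ringing artifacts and Poisson noise that plain DF passes through,
while preserving edges.

A synthetic module provides piecewise-constant phantoms (stylised brain and
thorax presets, discs), a line-integral projector for direct and oblique
sinograms, and Poisson counting noise at a chosen expected event count, so
the whole chain is testable without any external data.  Quantitative
evaluation uses the standard region metrics

```
bias     = (1/n) Σ (u_i − û_i)/û_i
variance = (1/n) Σ ((u_i − ū_n)/û_i)²
CRC      = ((S/B)_measured − 1)/((S/B)_theory − 1)
```

with `û` the ground truth and `ū_n` the regional mean of the estimate.

## Worked example

Simulate a noisy brain-like sinogram (10⁶ expected counts), reconstruct it
with both methods and score against the ground truth:

```
tvpet simulate --phantom brain_like --counts 1e6 --seed 1 \
      --out brain.sino --truth-out brain_truth.img
tvpet reconstruct --in brain.sino --out recon_bosvs.img --method bosvs
tvpet reconstruct --in brain.sino --out recon_df.img    --method df
tvpet evaluate --recon recon_bosvs.img --truth brain_truth.img --out report_bosvs.csv
tvpet evaluate --recon recon_df.img    --truth brain_truth.img --out report_df.csv
```

`report_bosvs.csv`:

```
region,bias,variance
all,0.01690039066351015,0.08051272782908046
1,-0.1910917682514499,0.00236927812965193
2,-0.20673677978272303,0.0020625160382351025
```

`report_df.csv`:

```
region,bias,variance
all,0.020384132252498438,0.21798223535996153
1,-0.07044753058898724,0.013845615539170039
2,-0.03421452239151842,0.013044172993495133
```

Reading the numbers: over all pixels with positive true activity, the
TV-regularised reconstruction has both lower bias (0.0169 vs 0.0204, the
mean relative deviation from the truth) and much lower variance (0.081 vs
0.218, the truth-normalised fluctuation within homogeneous regions — TV
removes most of the Poisson noise that DF passes through).  Inside the two
small hot lesions (regions 1 and 2) the TV prior trades a stronger negative
bias (contrast shrinkage, −0.19 vs −0.07) for a ~6× lower variance — the
classic regularisation trade-off at this count level.

The same chain works for oblique 3D data (`tvpet simulate
--deltas 0,-0.1,0.1 ...` then `tvpet rebin --method fore ...`), for count-
rate sweeps (`tvpet sweep --phantom brain_like --levels 5e5,1e6,3e6,6e6,9e6
--reps 5 --seed 7 --out sweep.csv`), and as a single configured run
(`tvpet pipeline --config cfg.json --outdir out/`).

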