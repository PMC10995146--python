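# Methods

## The fusion model

`dmif` fuses two registered, same-size medical images (CT/MRI, MR-T1/T2,
or grayscale MRI with a pseudo-color PET/SPECT map) in three stages.

**1. Latent low-rank decomposition.** Each single-channel source
`X` (intensities rescaled to [0, 1]) is split by the latent low-rank
representation

```
min_{Z,L,E}  ||Z||_* + ||L||_* + λ ||E||_1   s.t.  X = XZ + LX + E
```

into a *structural* part `XZ` (global structure and brightness), a
*salient* part `LX` (local detail) and sparse noise `E`.  The data
matrix is the raw image matrix itself — no patch extraction — which
keeps every SVD at image size.  The program is solved by inexact
augmented Lagrange multipliers: auxiliary splittings `J = Z`, `S = L`
take singular-value-thresholding steps at level `1/μ`, the quadratic
subproblems in `Z` and `L` are solved exactly against the constant
factors `(I + XᵀX)⁻¹` and `(I + XXᵀ)⁻¹`, `E` is soft-thresholded at
`λ/μ`, and the penalty grows as `μ ← min(ρμ, μ_max)`.

Solver parameters (all exposed): `λ = 0.8` (the conventional choice for
LatLRR on natural images; intensities must be on [0, 1] for the
thresholds to be meaningful, hence the internal rescaling), `μ₀ =
10⁻²/‖X‖₂`, `ρ = 1.1`, `μ_max = 10¹⁰`, `tol = 10⁻⁶` on the relative
equality residual `‖X − XZ − LX − E‖_F/‖X‖_F`, `max_iter = 500`.  On
[0, 1]-scaled 64–128 px phantoms the solver converges in roughly 200
iterations.  Non-convergence is a warning carried on the result, not an
exception; a zero input short-circuits to the zero solution.  The
default SVD driver occasionally fails on near-singular iterates, in
which case the slower QR-based driver is used for that step.

**2. Structural-part fusion by convolutional feature weights.** Both
structural parts go through a frozen convolutional backbone tapped at
three depths `k = 1, 2, 3` with downsampling factors `2^(k−1)`.  At
each tap the channel ℓ1 norm is box-averaged over a 3×3 window with
fixed divisor 9 (zero padding, so border activities are attenuated);
the two sources' activities are ratio-normalized per pixel into weights
that sum to 1 (an all-zero pixel falls back to ½/½); the weights are
upsampled to image resolution by block replication (odd sizes use
ceiling tap sizes and final cropping).  Per layer, the candidate fusion
is the per-pixel weighted average of the two structural parts; the
fused structural image `G` is the pixel-wise maximum over the three
candidates.  Each candidate is a convex combination, so `G` is bounded
by the pixel-wise min/max of its inputs, and every stage is symmetric
in the source order.

Two backbones satisfy the same contract.  The default is a tiny seeded
random CNN — three stages of {3×3 conv, stride 1, zero pad, no bias,
ReLU}, stages 2–3 preceded by 2×2 max pooling, channels (4, 8, 16),
weights drawn once from a seeded standard normal and frozen — which is
fully deterministic and needs no downloads.  Random frozen filters are
not feature detectors of VGG quality, but the weight maps only need a
*relative* activity comparison between two images of the same scene,
for which random projections of local contrast suffice.  An optional
adapter taps a pretrained VGG-16 (last activation of conv blocks 1–3,
post-ReLU, channels 64/128/256) when torch and torchvision are
installed; nothing in the package or tests requires it.

**3. Salient-part fusion and reconstruction.** The salient parts carry
complementary local detail, so they are fused by a plain sum
`H = I₁ˢ + I₂ˢ` with no clipping at that stage.  The fused image is
`R = clip(G + H)` into [0, 255].  The noise parts `E` are deliberately
dropped from the reconstruction (implicit denoising); they remain
available on the result object.  Clipping rather than rescaling was
chosen for the output range: rescaling would couple the output contrast
to outlier pixels.  One consequence worth knowing: fusing an image with
itself returns `clip(XZ + 2·LX)`, not the original image — the sum rule
doubles the shared salient part and the noise part is gone.

**Color handling.** When one source is RGB (PET/SPECT pseudo-color),
its BT.601 full-range luma is fused with the grayscale source and its
chroma (Cb, Cr) is re-attached to the fused luma.  This is the standard
chroma pass-through mechanism and preserves the functional image's
color semantics exactly.  Fusing two color sources is not supported.

## Quality indexes

* **SD** — population standard deviation of the fused intensities.
* **EN** — Shannon entropy of the 256-bin histogram on [0, 255]
  (values clipped in), in bits; at most 8.
* **Q_MI** — the entropy-normalized mutual-information index
  `2·[MI(a,f)/(H(a)+H(f)) + MI(b,f)/(H(b)+H(f))]`, range [0, 2].
  Joint histograms are dense 256×256; terms with a zero entropy
  denominator contribute 0.  Several normalizations of MI circulate in
  the fusion literature; this package states and tests this one.
* **Q_PC** — the phase-congruency index `P_p·P_M·P_m`: the product of
  the Pearson correlations between the fused image's phase-congruency
  map / maximum-moment map / minimum-moment map and the element-wise
  maximum of the corresponding source maps.  Correlations are global
  (whole image); a zero-variance map zeroes its factor with a warning.

Phase congruency uses a frequency-domain log-Gabor bank: 4 scales,
6 orientations, minimum wavelength 3 px, scale multiplier 2.1,
`σ_onf = 0.55`, angular spread `π/6/1.5`, a high-order low-pass at
0.45 cycles/px, noise compensation at `k = 2` Rayleigh standard
deviations above the noise-energy mean estimated from the median
smallest-scale amplitude, and a sigmoidal frequency-spread weighting
(cut-off 0.5, gain 10).  The combined map is total weighted energy over
total amplitude, clipped to [0, 1]; the moment maps come from the
classical covariance analysis of the per-orientation congruency.  For
color results all indexes are computed on the BT.601 luma.

A caveat the test suite makes explicit: with 256×256 joint-histogram
bins and a 256×256 image there is one sample per bin, so MI carries a
Miller–Madow finite-sample bias of ≈ 0.7 bits and Q_MI of *independent*
images sits near 0.2 rather than 0.  The tests assert against the
derived bias floor, and against ≈ 0 only at a coarser binning where the
bias is negligible.

## Synthetic phantoms

The phantom generator produces registered pairs sharing one elliptical
head geometry, built so the two members carry complementary content:
the structural member (CT/T1-like) has a bright rim (230) over a
piecewise-constant interior (55 with a few constant blobs at 90–190);
the soft-tissue member (MRI/T2-like) has a dark rim (20), a smooth
band-limited interior texture (Gaussian-filtered noise, ±90 around
120), and a bright lesion-like focus absent from the other member.
Functional pairs replace the second member by a hot-colormap rendering
of a smooth activity field.  Additive Gaussian acquisition noise
defaults to σ = 2 intensity levels (mild scanner noise).  Default
problem sizes in the tests and the acceptance script are 64–128 px
(the package's own desk-scale choice); the pipeline runs unchanged at
256 px.

What the phantoms do *not* emulate: anatomical detail, MR physics,
partial-volume effects, registration error, or the intensity statistics
of real scanners.  Passing tests therefore demonstrate the pipeline's
contracts (feasibility, normalization, symmetry, determinism, metric
behavior) on controlled complementary structure — not clinical fusion
quality.

## Observed behavior of the indexes on phantoms

On the default complementary phantoms the fused result clearly exceeds
both sources in SD and EN (it holds the rim, the texture and the
lesion at once) and scores Q_MI ≈ 0.86 at 128 px.  A naive 0.5/0.5
average scores *higher* on Q_MI (≈ 1.04) while being visibly worse —
half-contrast rim and texture.  This is a known bias of MI-based
indexes: the average is a deterministic function of the sources and so
retains maximal joint-histogram dependence, while the sum rule raises
the fused entropy that normalizes Q_MI.  The package reports the
baseline value alongside its own so the comparison is always visible,
and the corresponding gain assertion in the acceptance suite is left
failing rather than weakened.

## Numerical and design choices

* Equal specs ⇒ bit-identical phantoms; equal inputs/config ⇒
  bit-identical fusion output (the solver and backbone are
  deterministic).  CLI reruns are byte-identical; files are written
  8-bit with half-to-even rounding.
* Weight normalization is a ratio (no exponential); ties and dead
  pixels give ½/½, preserving the sum-to-one invariant exactly.
* The layer-candidate maximum is taken in image space after the
  weighted average, never on feature maps — feature maps live at the
  wrong resolution and scale for image-space reconstruction.
* The solver's equality residual is allowed tiny non-monotonicity
  (factor 1.01 per step) in tests to absorb ALM oscillation.
* Degenerate inputs: zero images decompose to zero parts; flat images
  have zero entropy and undefined correlations, handled by the declared
  fallbacks (Q_MI term → 0, Q_PC factor → 0 with a warning).

## Limitations

* Two sources only; no registration; 2-D slices only.
* The LatLRR solve is O(iterations × image²·³); 256 px pairs take tens
  of seconds on one core, which is the practical desk-scale ceiling.
* With both sources color, or bit depths beyond 16, the tool refuses
  rather than guessing.
* Absolute index values on real clinical pairs depend on acquisition
  and registration quality; the phantom numbers calibrate the pipeline,
  not clinical expectations.
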