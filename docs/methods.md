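# Methods

## Problem

Sparse-view CT reduces patient dose by measuring far fewer projection
angles than a standard scan.  Filtered back-projection (FBP) of such data
is dominated by streak artifacts, and the clinically hard part is not
removing the streaks but recovering fine, high-frequency structure while
doing so.  `svct` implements a learned reconstruction pipeline for 2-D
fan-beam data that addresses exactly this trade-off.

## Reconstruction model

The pipeline is a progressive dual-domain cascade

    y' = IENet( FBP_180( SINet(x) ) ),        y_g = HENet( [y', b] ),

where `x` is the sparse sinogram, `SINet` expands it to the intermediate
view set (projection domain), the differentiable FBP layer maps it into the
image domain, `IENet` predicts the residual toward the standard-view
reference `y_L`, `b = |y' * s_H| + |y' * s_W|` is the Sobel edge map of the
stage-1 output, and `HENet` is an adversarially trained refinement
generator conditioned on both the image and its edges.

Phase 1 trains SINet and IENet jointly with

    L = l1·L1(x', x_L) + l2·L1(y', y_L) + l3·L_cons + R_HF(y', y_L),

where `L_cons = mean |P' y' − x_L|` re-projects the enhanced image onto the
intermediate view set (`P'`) and compares it with the sinogram-domain
label, coupling the two domains.  All weights default to 1.

Phase 2 freezes the cascade and trains `HENet` against a convolutional
critic `D` with the WGAN-GP objective

    min_G max_D  E[D(G)] − E[D(y_L)] + mu·E[(||grad D(yhat)||−1)^2]

plus MSE, `R_HF` and consistency regularisers on the generator
(`mu = 10`, interpolates `yhat` uniformly between real and generated
samples).  The critic has no normalisation layers, a requirement for a
well-defined gradient penalty.

## Direction-weighted high-frequency regulariser

On the residual `z = y' − y_L` we compute backward differences `g_h, g_w`
(replicate boundary: first row/column zero), magnitude
`nor = sqrt(g_h² + g_w²)` and direction `theta = atan2(g_h, g_w)`.  The
magnitude is resampled bilinearly at the two unit-pixel offsets
perpendicular to `theta` and averaged into `ver`; the descriptor
`alpha = nor / (ver + 1e-8)`, clipped to [0, 10], measures directional
consistency — isotropic noise has similar gradient magnitude along and
across its gradient direction, oriented texture does not.  The penalty is

    R_HF = mean( alpha · nor ),

a direction-weighted total variation.  Three numerical choices matter:

* `alpha` is a stop-gradient weight, recomputed each step but never
  differentiated — differentiating the ratio is fragile where `ver -> 0`
  and would change the penalty from a weighted TV into something harder to
  control.
* The epsilon and clip bound keep flat regions (where `nor = ver = 0`)
  from producing exploding weights; with exact-zero gradients `alpha = 0`,
  so constant residuals incur exactly zero penalty.
* Which function of `alpha` should weight the TV term is genuinely
  ambiguous — the descriptor marks `alpha ≈ 1` as noise-like, yet the
  penalty as written weights *by* `alpha`.  We implement the literal form
  as the default and expose `hf_weight_mode ∈ {alpha, inverse, min}` so the
  alternative readings can be tested; the choice does not affect any
  identity or homogeneity property of the term.

## Geometry and operators

Flat equally spaced detector (pitch in mm implies a flat array), source
645 mm from the detector and 322.5 mm from the rotation centre, 736
elements of 0.3 mm, full `[0, 2pi)` rotation with views at `k·2pi/n`.
Sparse view sets are even decimations of the standard set, so sparse
angles are literal subsets — row-subsampling a dense sinogram is exactly
the sparse acquisition.

The forward projector integrates the bilinearly interpolated image along
each ray (Joseph-style) with step = half a pixel; its adjoint scatters with
the same weights, so the pair satisfies `<Au, v> = <u, A'v>` to machine
precision — this is what makes gradient flow through the reconstruction
layer exact rather than approximate.  FBP applies cosine weighting, a
band-limited ramp filter along the detector axis (spatial-domain Ram-Lak
impulse response, apodised by a raised-cosine rolloff to zero at Nyquist —
`cosine` default, `ramlak` and `hann` available), and distance-weighted
(`1/U²`) back-projection.  The image grid is centred on the rotation
centre with pixel size chosen so the field of view is the inscribed circle
covered by the detector at iso-centre magnification (0.42 mm at 256 px).

Small systems (desk scale) are assembled once as sparse matrices with
exactly the same weights as the streaming path, making training steps a
matvec; large systems stream view by view to bound memory.

## Networks

Both domain networks are a modified U-Net in which *every* scale change is
attention-guided (the AGD/AGU blocks replace pooling and up-convolution
entirely): the channel branch is a squeeze-excite bottleneck (reduction
16) whose sigmoid weights multiply a fixed resampling (bilinear x2 up, 2x2
average pool down); the spatial branch pools the feature map into M
learned visual primitives through an attention map `P` (1x1 convolution,
softmax over positions per primitive) and redistributes them over the
rescaled grid through a scaling map `D` (3x3 convolution to `M·s²`
channels + channel-to-space rearrangement for upscale, strided 3x3
convolution for downscale, softmax over primitives per position).  The two
branches are summed.  `P` and `D` are derived from the feature map alone.
M defaults to 96 at paper scale.

SINet pre-upsamples the sparse sinogram by periodic linear interpolation
along the view axis before the U-Net and adds the interpolation through a
skip, so a zero-weight network is exactly the linear interpolation; IENet
and HENet are residual.  Final 1x1 convolutions are zero-initialised, so
freshly built residual networks are identities — training starts from the
analytically sensible point (FBP of the interpolated sinogram) instead of
noise, and the adversarial stage cannot degrade the stage-1 output before
it has learned anything.

The critic is a strided conv stack (LeakyReLU 0.2, stride 2 on every other
layer), global average pooling and a linear head.  Its input gradient —
needed inside the gradient penalty — is constructed explicitly as a
vector-Jacobian chain of autodiff primitives with activation masks held
constant, which is exact almost everywhere for a piecewise-linear network
and makes the penalty differentiable w.r.t. the critic weights.

## Training

Adam with betas (0.9, 0.999) in phase 1 and (0.5, 0.9) in phase 2;
learning rate decays exponentially from 1e-3 to 1e-5 across the configured
epochs (endpoints fixed, schedule shape our choice); batch size 2; 5
critic updates per generator update (standard WGAN-GP practice).  Phase 2
freezes the dual-domain cascade and precomputes its outputs (a config
switch allows fine-tuning instead).  One master seed fans out — via
`numpy.random.SeedSequence` — to parameter initialisation, batch shuffling
and the gradient-penalty draws, so (config, seed, dataset) determine every
logged number.  The best-validation parameter set (a split carved from the
training phantoms, 10 % by default) is restored at the end of phase 1.

All computation is numpy; the package includes a small reverse-mode
autodiff engine (`svct.autodiff`) with exactly the primitives the model
needs.  Training uses float32 parameters; gradient-check tests run the
same code in float64.

## Synthetic data

The phantom generator emulates what matters for this problem: a
piecewise-smooth body (nested random ellipses with soft-tissue contrast, a
low-frequency texture field) plus deliberately dense fine structure — thin
high-contrast rods 1–2 px wide and discs of 1–4 px — so both streak
artifacts and detail loss are visible and measurable at 64–256 px.  The
reference image `y_L` is the FBP of the standard-view sinogram, not the
phantom itself: that is the reference a full-dose scan would give, and it
keeps the learning target consistent with what a real system could ever
provide (the noiseless phantom is stored alongside as an extra oracle).
Optional Gaussian/Poisson noise toggles exist but default to off.

What the generator does *not* emulate: real anatomy, beam hardening,
scatter, detector physics, or the intensity statistics of patient CT.
Passing tests therefore demonstrate that the method's mechanics work —
operators are exact, losses behave as derived, training improves over the
FBP baseline under controlled conditions — not that clinical image quality
is reproduced.

## Scale presets and problem sizes

`paper` preserves the published acquisition (736 detectors, 720/180/60 or
30 views, 256 px images, M = 96, depth-4/width-64 U-Nets).  `desk` is the
configuration the tests and the acceptance script exercise end to end:
180 detectors, 180/60/20 views, 64 px images, depth-2/width-16 U-Nets with
M = 16, and a 4-layer critic.  The shipped end-to-end runs use 200
training phantoms, 200 phase-1 steps and 5 adversarial generator updates —
sizes chosen so a complete two-phase run finishes in minutes on one CPU
core while the dual-domain stage still clears the sparse-FBP baseline by
several dB (most of the margin comes from the learned sinogram
interpolation; the remaining steps refine it).

## Degenerate inputs and tie-breaks

Angles live in the half-open `[0, 2pi)`; a sinogram whose angle list
touches `2pi` is rejected.  FBP requires at least 2 views; the projector
requires a square image whose field of view the detector covers.  PSNR of
an exact match is reported as the capped sentinel 999 dB.  VIF is the
pixel-domain multi-scale approximation (no steerable pyramid); its dyadic
decimation makes flip symmetry approximate rather than exact.  `data_range`
is always explicit in metric calls since the intensity unit of normalised
attenuation images is a convention.

## Known limitations

2-D fan-beam only (no cone-beam or helical geometry); no photon-physics
simulation; the numpy engine is single-threaded apart from BLAS, so paper-
scale training, while configured, is not practical on one CPU; the
adversarial stage at desk scale is run long enough to demonstrate
stability and non-degradation, not convergence of the Wasserstein
estimate.
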