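# Methods

This note documents the models, parameter choices and numerical decisions
behind `vesselfd`, and what the synthetic phantoms do and do not emulate.

## Fractal dimension estimation

All three dimensions come from one multiscale box-counting scan of the
binary vessel map inside a region of interest. The ROI's bounding box is
tiled by square boxes of side `r` drawn from a geometric schedule
(default: powers of 2 from 2 px up to a quarter of the ROI diameter, at
least 4 scales or the measurement is refused). For each box,
`n_i` is the number of vessel pixels it contains inside the ROI, `M` the
total vessel mass and `p_i = n_i/M`. The estimators are ordinary
least-squares slopes with natural logarithms:

- box dimension `D_B`: `log N(r)` against `log(1/r)`, `N(r)` the number of
  boxes with `n_i > 0`;
- information dimension `D_I`: Shannon entropy `H(r) = −Σ p_i log p_i`
  against `log(1/r)`;
- correlation dimension `D_C`: `log C(r)` with `C(r) = Σ p_i²` against
  `log r`.

Design points:

- *Measured on the full binary map, not its skeleton.* A `skeletonize`
  flag exists but defaults off.
- *Entropy sign convention.* `D_I` uses the positive entropy `H`; the
  alternative sign (slope of `Σ p log p`) would produce a negative number
  and is a known notational slip in parts of the literature.
- *Pair counting.* `C(r)` is the standard box approximation of the
  pair-correlation integral; an exact O(n²) Heaviside pair counter is
  provided (`pairwise_correlation_sum`) as a cross-check oracle for small
  inputs only.
- *Boundary handling.* Boxes straddling the ROI boundary contribute only
  their inside-ROI pixels; `N` counts occupied boxes only.
- *Offset averaging.* Optionally the scan averages `N`, `H`, `C` over the
  four half-box-shifted grid placements. It is off by default (a single
  anchored grid) and on in the ROI-size study, where the 5×-vs-6×ODr
  contrast (~0.01 in `D_B`) would otherwise be dominated by grid-placement
  noise. Both modes are deterministic.
- *Scale range for space-filling fixtures.* For sets with interior (the
  filled disc), perimeter boxes inflate coarse counts and depress the
  slope; convergence tests on such fixtures cap the schedule at 1/16 of
  the diameter instead of 1/4.
- Estimates are never clamped; values outside [0, 2] are flagged in the
  result's `out_of_range` list.

**Known estimator behaviour on finite-caliber maps.** On a *binary* vessel
raster the occupancy measure becomes uniform once boxes shrink below the
vessel caliber (every box inside a vessel is completely filled), so the
entropy deficit `log N − H` shrinks as `r → 0` — the opposite trend of a
true multifractal. The regression slope for `D_I` therefore sits
systematically *above* `D_B` by ~0.05–0.15 at desk scales, on phantoms and
on any finite-width vessel raster; the Rényi ordering
`log N ≥ H ≥ −log C` still holds exactly at every scale and is asserted as
a test invariant. On uniform-mass analytic constructions (`H = log N`)
`D_I` equals `D_B` to machine precision.

## Vessel segmentation

The vesselness of a pixel at scale σ uses the magnitude-ordered
eigenvalues `λ₁ ≥ λ₂ ≥ 0` of the γ-normalized (γ = 2) Gaussian Hessian:

    v = exp(−R_A²/2α²) · (1 − exp(−S²/2β²)),  R_A = λ₂/λ₁,  S = λ₁ + λ₂

gated to zero where the dominant curvature's sign contradicts the
requested polarity (dark vessels curve upward), maximized over scales
σ ∈ {1, 2, 4, 8} px, and rescaled to [0, 1] by the map's own maximum.
`R_A` at `λ₁ = 0` is defined as 0 (the response is 0 through the `S` term
anyway). A variant with the Frobenius-norm structure term
(`--variant original-frangi`) is provided for comparison.

Defaults `α = 0.5`, `β = 5.0` are calibrated against the normalization
stage: on background-normalized images the structure term on vessel
centrelines measures a few units, and setting β to roughly half its
typical maximum places the dataset-optimal threshold near 0.24 — interior
to the canonical 0.15–0.35 sweep, with mean MCC ≈ 0.82 on phantom
ensembles. Thresholding applies `value ≥ t` with **no post-processing**, so
quality numbers are properties of the raw map.

Binary maps are scored with the Matthews correlation coefficient
restricted to an evaluation mask. MCC is computed from exact integer
confusion counts with a single square root, so perfect (and inverted)
segmentations score exactly ±1; a zero denominator factor yields MCC = 0
with a `degenerate` flag. MCC equals the Pearson correlation of the two
pixel indicator vectors — a test asserts this to 1e−12.

## Preprocessing

Images are resampled to a reference pixel pitch (bilinear for
intensities, nearest-neighbour for masks) and normalized against
estimated background fields: tentative background pixels are those that
are neither tubular (coarse single-scale vesselness above 3 robust sigmas)
nor intensity outliers (beyond 4 robust sigmas — this catches the bright
disc and dark fovea). Per-window (default width/8, min 8 px) medians and
scaled MADs (×1.4826) over background pixels are interpolated to
full-resolution luminosity and contrast fields `L̂`, `Ĉ`, and the image
becomes `(I − L̂)/max(Ĉ, ε)`. All classification thresholds are in MAD
units, so the transform is equivariant under affine intensity rescaling up
to the truncated-derivative-kernel residual (~0.5% RMS), and
re-normalizing an already-normalized phantom changes values by < 5% RMS.
A constant image returns all zeros with a `degenerate` flag.

## Optic disc, fovea and ROI geometry

The disc is segmented in a patch around a seed point (ground-truth centre
for phantoms; a user-supplied point or bright-region centroid for real
images — template-based disc *detection* is out of scope). The patch is
mapped through the opponent-colour transform

    (e, e_λ, e_λλ)ᵀ = [[0.06, 0.63, 0.31], [0.19, 0.18, −0.37], [0.22, −0.44, 0.06]] · (R, G, B)ᵀ

and enhanced as `√(e_λ² + e_λλ²)/(|e| + ε)` with ε = 1 — the large floor
keeps dark vessel pixels from dominating the chromatic magnitude. The
disc boundary is traced as Laplacian zero-crossings of the smoothed
enhanced patch (σ = halfwidth/6), gated by gradient strength and masked
away from the void outside the camera field of view. An ellipse is fitted
by direct least squares (with a radial pre-trim and three
worst-quartile-refit rounds to reject vessel-edge arcs; a degenerate fit
raises rather than falling back), and the fitted radii are corrected for
the scale-space displacement of a convex edge's zero-crossing
(`r_fit ≈ R + σ²/R`, inverted in closed form — verified on clean discs to
< 1%). ODr is the mean of the corrected radii; recovery error on the
phantom ensemble is ~3% mean.

The fovea is the minimum of the heavily blurred (σ = 0.5 × ODr,
mask-normalized so the extra-FOV void cannot bleed darkness inward)
intensity in the 4–6×ODr ring around the disc, after inpainting vessels
by iterative Laplacian diffusion (200 iterations or 1e−4 relative
change). The search excludes a 0.5×ODr margin at the field rim, where
vignetting is darkest. ROIs are circular masks at k×ODr (canonically
k = 4, 5, 6) anchored at the fovea or the disc centre, clipped at image
borders; pixel centres within the radius belong to the mask.

## Synthetic phantoms

The phantom generator produces, from a seed alone, a colour fundus-like
image plus exact ground truth (vessel map, disc geometry, fovea, field
mask). The geometry is DRIVE-scale: 512 px images, ODr = 36 px, fovea at
the image centre and the disc 5×ODr nasally — so the canonical 4/5/6×ODr
ROIs mean the same thing as on real fovea-centred images.

The vessel model mirrors documented fundus anatomy:

- trunks emerge at the nerve-head centre, cross the disc and leave the rim
  (initial caliber ~6 px);
- bifurcations follow an asymmetric Murray rule — child calibers
  `w·0.794·(2f)^{1/3}` with flow split `f ~ U(0.25, 0.75)` — and their
  probability decays with generation (`0.6 × 0.85^depth`), concentrating
  branching peripapillary; between branch events vessels taper slowly
  (×0.93) and elongate (×1.05), giving long arcades;
- 1-px side twigs leave thicker vessels along their whole course, so the
  thinnest vessels are interleaved with retained ones rather than
  clustered at tree tips (this is what makes "observers miss thin
  vessels" *lower* the measured FD, as on real annotations);
- a macular avascular zone: headings steer away from the fovea inside
  3×ODr, vessels arc around the macula;
- ~20 short radial peripapillary stub vessels at the rim;
- subjects differ coherently: one per-seed factor (±30%) modulates branch
  probability, caliber and stub count together, emulating global
  vascular-density differences between individuals (this is what makes
  FDs measured in different ROIs of the same subject correlate).

Rendering is dark-on-bright in a three-channel image whose green channel
carries the vessel contrast, with a yellow disc, a dark macula, a lateral
illumination gradient, mild vignetting and Gaussian sensor noise. All
randomness flows from named per-seed streams (tree, stubs, subject
factors, noise), so identical seeds give bit-identical bundles.

What the phantoms do *not* emulate: pathology (microaneurysms,
hemorrhages, neovascularization), vessel reflexes and central light
streaks, arteriole/venule distinction, photoreceptor texture, and real
camera optics. Passing studies therefore demonstrate the *measurement
chain's* sensitivities under controlled conditions, not clinical effect
sizes; study 1's "group" axis (branching complexity) is an analogy for
disease grading, not a claim about retinopathy.

Observer emulation removes every vessel whose local caliber (read off the
Euclidean distance transform, `2d − 1`) falls below a threshold; the
surviving map is the union of the remaining core pixels' maximal
inscribed discs clipped to the input, which keeps thick vessels at full
width, vanishes thin twigs, and is monotone in the threshold. Camera
emulation resamples by a resolution factor, applies contrast gain and
gamma, then a per-acquisition integer pointing jitter and sensor noise,
with geometry transformed consistently; a neutral profile is the
identity.

## The six studies

Each study is a pure function of `(config, seed)` writing deterministic
CSV/JSON reports. Desk-scale defaults (sizes chosen so the whole harness
runs in about a minute): study 1 — 3 branching-complexity groups × 6
phantoms, full-FOV and 5×ODr ROIs, per-group mean/SD/RSD and Tukey HSD
pairwise comparisons (Tukey so the simultaneous intervals agree with the
family-corrected p-values); study 2 — 12 phantoms, truth vs emulated
observer (caliber 2 px), per-subject relative errors and Pearson tests
for all three dimensions; study 3 — 8 phantoms × 3 vesselness
parameterizations, each thresholded at its dataset-optimal MCC (the
"different methods" axis is emulated by parameterizations, since the
other published segmentation algorithms are out of scope); study 4 — 20
phantoms × ROIs at 4/5/6×ODr with 6× as reference, offset-averaged
scans; study 5 — 5 phantoms × the 0.15–0.35 (step 0.01) threshold sweep,
per-threshold mean MCC and mean FD relative error vs truth-FD; study 6 —
3 camera profiles × 6 subjects × 5 acquisitions, per-subject
repeatability (RSD over acquisitions) and between-camera mean relative
differences. Sample standard deviations (n−1) throughout; per-image
pairing for all Pearson tests; references: phantom truth (studies 2, 3,
5), the 6×ODr ROI (study 4).

Observed directions on the phantom ensembles match the qualitative
pattern expected of the real measurement chain: FD falls monotonically as
the threshold prunes the map; segmentation quality and FD error
anti-correlate strongly (the exact coincidence of the MCC optimum with
the FD-error minimum on a 0.01 grid does not hold — the best-MCC map
retains halo false positives around wide trunks, leaving it slightly
FD-oversegmented, so zero FD error occurs a few hundredths higher);
smaller fovea-anchored ROIs yield lower mean FD with strong inter-ROI
association; dropping sub-2-px vessels lowers `D_B` on a significant
majority of phantoms; and zero-jitter zero-noise acquisition repeats give
exactly zero repeatability RSD.

## Limitations

- The measurement chain is calibrated and validated on phantoms; absolute
  FD values and error magnitudes on clinical images will differ.
- The box schedule, grid anchoring and regression range materially affect
  FD — the instability the studies quantify. All are explicit
  configuration with declared defaults, not inferred per image.
- `D_I > D_B` on finite-caliber binary maps is an intrinsic property of
  the estimator at measurable scales (see above), not an implementation
  artifact.
- Disc segmentation needs a seed point near the disc; it is not a
  detector.
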