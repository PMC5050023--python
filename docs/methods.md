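# Methods

`ktswivel` measures the internal geometry of human sister-kinetochore pairs
from two-colour 3D fluorescence data: the intra-kinetochore distance Δ
between an inner (centromere-proximal, e.g. CENP-A) and an outer
(microtubule-binding, e.g. Ndc80 C-terminus) marker, and the *swivel* angle
ϑ of the inner-to-outer axis about the sister–sister axis. Because no raw
cell data ships with the package, a first-class synthetic-data generator
produces ensembles with known truth for every downstream stage; all
quantitative claims in the test suite are statements about this generative
model, validated against closed-form or brute-force oracles.

## Coordinate frame and observables

All positions are in nanometres in a right-handed *plate frame*: x̂ normal
to the metaphase plate, ŷ and ẑ in-plane. `fit_plate_frame` recovers this
frame from a cloud of inner-marker positions as the minimal-spread
principal direction (x̂), with deterministic sign fixing.

Per kinetochore (sisters indexed 1, 2 within a pair):

- **Δ3D** — Euclidean inner→outer distance; **Δ2D** its xy-projection;
  **Δx, Δy, Δz** the plate-frame components. Measurements with
  |Δz| > 100 nm (half the axial pixel size) carry a failed z-filter flag
  and are excluded from Δ summaries.
- **d3D / d2D** — inter-sister inner–inner distances; εy is the xy distance
  from one sister's outer marker to the other sister's inner marker.
- **Δ1D** — ½(outer–outer − inner–inner) xy distances; signed, and negative
  when the outer domains have rotated inside the inner markers.
- **ϑ3D** — angle between the intra-kinetochore axis and the
  away-from-sister direction (0° = pointing at the attached pole).
- **ϑy (y-swivel)** — magnitude from the cosine rule on the triangle
  (d_y, Δy, εy) with the 180° complement,
  ϑy = 180° − cos⁻¹((d² + Δy² − εy²) / (2 d Δy));
  this equals the xy dot-product angle between the away direction and the
  intra-kinetochore vector (a tested invariant). The *sign* is not defined
  by the triangle; we take ϑy > 0 when the intra-kinetochore vector falls on
  the right-handed-perpendicular side of the away direction in xy, giving
  the signed range (−180°, 180°].
- **ϑz** — the analogous construction in the xz-plane.
- **ϑtwist** — tilt of the sister–sister axis from the plate normal
  (0° = pair aligned with the spindle axis). Descriptions of twist relative
  to "the plate" are the complement of this angle.
- **ϑkMT** — angle the k-fibre axis tends on the sister axis, measured in xy
  exactly like y-swivel; when the k-fibre is collinear with the
  intra-kinetochore axis, ϑkMT ≡ ϑy (tested exactly).

Cosine arguments are clamped to [−1, 1] with tolerance 10⁻⁶; a larger
excess raises. Angles are computed in radians, reported in degrees.

## 1D projection theory

With both sisters' geometry projected to xy and decomposed along the sister
axis, Pythagoras gives the outer–outer distance

d_y2² = (d_y1 + Δy1·cos ϑ1 + Δy2·cos ϑ2)² + (Δy1·sin ϑ1 + Δy2·sin ϑ2)²,

and Δ1D = ½(d_y2 − d_y1) rearranges to a closed form whose first term is the
mean sister-axis projection scaled by d_y1/(d_y1+d_y2) and whose second term
collects the quadratic Δ contributions (`delta1d_exact`). To first order in
Δ/d̄ this is the pure projection ½(Δy1 cos ϑ1 + Δy2 cos ϑ2)
(`delta1d_first_order`). At Δ/d̄ = 0.1 (the realistic regime: Δ ≈ 98 nm,
d ≈ 950 nm) the worst-case discrepancy between exact and first-order forms,
over all swivel combinations, is exactly 10% of Δ: along the diagonal
ϑ1 = ϑ2 = ϑ the error is |(√(1.04·10⁶ + 4·10⁵ cos ϑ) − 1000)/2 − 100 cos ϑ|
(nm), stationary where the square root equals d_y1, i.e. cos ϑ = −0.1, where
it evaluates to 10 nm. A 1° grid sweep attains 9.9998%. The closed form is
verified against coordinate-level brute force to < 10⁻⁹ nm on 10⁴ random
configurations.

This is the quantitative core of the package's scientific point: Δ1D (and
to a lesser degree Δ2D) conflates distance with rotation. An ensemble whose
Δ3D is fixed but whose swivel dispersion broadens shows a strongly reduced
median Δ1D with an unchanged median Δ3D — the pipeline's two-condition
report demonstrates this on synthetic "untreated" (σ_ϑy = 56.4°) versus
"microtubule-depolymerised" (σ_ϑy = 89.5°) ensembles.

## Synthetic-data generator

`simulate_pairs` draws, per pair:

- centre: x ~ N(0, plate_thickness_sd), (y, z) uniform in the plate ellipse
  (defaults: thickness sd 550 nm, half-widths 5 µm — a mid-metaphase plate);
- inter-sister distance d ~ N(950, 150) nm (median matches the live-cell
  value; the spread is a realistic choice, the distribution is not reported);
- sister axis: plate normal tilted by |N(0, twist_sd)| (default 20°) at a
  uniform azimuth; sister 1 faces the −x pole, sister 2 the +x pole;
- Δ per kinetochore ~ N(delta_magnitude, delta_dispersion), default
  98 nm with zero dispersion (the population dispersion of Δ3D about its
  median is not reported, so the default adds none; the value used is echoed
  in the output metadata);
- outer-marker direction: under `gaussian_y`, a signed y-swivel
  ~ N(0, swivel_sd) (stored unwrapped) applied as an xy rotation of the
  away-from-sister direction, plus an independent z-elevation draw folded
  into [−90°, 90°] (an elevation beyond ±90° would silently flip the xy
  azimuth, breaking the identity between the drawn and measured y-swivel);
  under `isotropic`, a uniform direction on the hemisphere facing the
  attached pole;
- observations: green = inner + noise, red = outer + chromatic shift +
  noise (per-axis Gaussian localization error, same for both channels).

Identical configurations are bit-identical (single `default_rng(seed)`).
Noiseless observations measured back through the geometry module reproduce
the generative Δ3D and swivels to < 10⁻⁶ (tested).

Because the measured signed y-swivel lives on (−180°, 180°], generative
dispersions large enough to put mass beyond ±180° are recovered as the
*wrapped*-normal sd: at σ = 89.5° the expected recovered sd is ≈ 83.5°
(quadrature oracle in the tests). The acceptance script reports the measured
value without un-wrapping.

`simulate_trajectory` produces triangle-wave ("sawtooth") oscillations of
the pair centre along x with amplitude 300 nm, direction reversals every
35 s, sampled at 7.5 s, plus optional white positional jitter. Frames are
labelled P (poleward) / AP per sister by the sign of the frame-to-frame
displacement relative to that sister's pole. The displacement
autocorrelation of this motion is most negative at the sampled lag nearest
the half-period (37.5 s on the 7.5 s grid); note that white *positional*
noise alone differences to an MA(1) with lag-1 autocorrelation −0.5.

`render_stack` rasterises spots into 69.4 × 69.4 × 100 nm voxel stacks as
integrated anisotropic 3D Gaussians (default PSF σ = 120 nm lateral, 300 nm
axial), with constant background and optional Poisson resampling. Stacks are
written/read as OME-TIFF.

## Spot localization

`detect_candidates` finds local maxima on a lightly smoothed copy of the
stack (σ = 1 voxel; shot noise otherwise fragments one spot into several
maxima), over a PSF-sized footprint and above a robust noise floor
(median + 4·MAD·1.4826). Exact-tie plateaus from noiseless renders are
collapsed to their centroid. Survivors then pass, in order, the intensity
filter (amplitude > 25% of the brightest candidate, per stack) and pairwise
isolation (any candidate within 750 nm of another is dropped — both members
of a close pair). The filters are idempotent.

`fit_mixture` jointly fits clusters of nearby seeds by least squares on an
ROI: shared background and PSF widths (lateral/axial, bounded to 0.3–3× the
initial guess), per-spot total amplitude and centre; tolerance 10⁻⁶,
iteration cap 200. Failures (no signal, non-convergence) are flagged, not
raised. On noiseless input the fit is unbiased to < 1 nm; at a 10⁴-photon
budget the per-axis scatter is a few nm, far inside the 30 nm bound used in
the tests.

`masked_partner_search` fits the partner channel using only voxels inside a
sphere (static imaging, 300 nm) or hemisphere (dynamic imaging, directed
along the plate normal away from the pair centre) around a shift-corrected
anchor. A partner is *absent* when there is no signal above the noise floor,
the fit fails, or the fitted centre falls outside the mask (this is what
rejects a true spot 400 nm away whose PSF tail leaks into a 300 nm mask).

## Chromatic registration

`estimate_shift` takes row-matched dual-label single-epitope spot tables and
returns the per-axis **median** green→red displacement (robust to gross
mismatches) with per-axis sds; the same 25% / 750 nm quality filters apply,
and fewer than 3 surviving spots is an error. `apply_correction` subtracts ζ
from red positions; when a dual-camera interphase calibration is applied to
mitotic data, ζz is first incremented by the focal-depth offset (+78.2 nm,
a stored default, not hard-coded), never in single-camera mode. Estimate
then apply is a projector: re-estimating on corrected data yields a null
shift. `validate_geometry` summarises plate-frame Δ components
(median ± bootstrap SE) and flags Δx sign-symmetry — a bioriented ensemble
must be bimodal in Δx and centred in Δy, Δz, so a residual shift shows up
additively in these medians.

## Statistics

- `summarize_median`: median ± seeded bootstrap SE (default B = 10⁴);
  approaches 1.2533·σ/√n for Gaussian data.
- `mann_whitney`: exact tie-aware enumeration when the smaller sample has
  ≤ 8 observations and the enumeration is affordable (≤ 2·10⁵ arrangements),
  otherwise the tie-corrected normal approximation without continuity
  correction (so identical samples give p = 1; complete ties give p = 1
  rather than 0/0). Two-sided by default.
- `variance_f_test`: two-sided F on sample variances.
- `permutation_correlation`: Monte-Carlo permutation null of Pearson's r
  (default 10⁶ permutations, seeded, vectorised in chunks). The p-value is
  the add-one estimator (1 + #extreme)/(1 + B), an upper bound of 1/(B+1)
  when no permutation is as extreme; the null's sample mean/sd provide a
  Gaussian-tail extrapolated p and z-score in the result's `extra` (sample
  moments, not histogram fitting). `absolute=True` folds both variables to
  [0°, 90°] for angle pairs; the signed range is the alternative.
- `gaussian_tail_p`: upper-tail standard-normal probability, exponentiated
  from log-space beyond z = 6 (at z = 8.9: 2.8 × 10⁻¹⁹).
- `fit_swivel_surface`: least-squares degree-3 polynomial of swivel against
  in-plane position; with plate thickness, the separable degree-3 × degree-1
  tensor sheet. Returns coefficients and R²; rank-deficient designs raise.
- `displacement_autocorrelation`: per-lag Pearson correlation of the
  differenced series (not the biased single-variance ACF estimator, which
  cannot reach −1 on alternating displacements).
- `angular_histogram`: 18 × 20° bins over (−180°, 180°] (rose-plot data as
  CSV-ready tables).

Type-I error of the two-sample tests is verified at 0.05 ± 0.01 under
simulated nulls (5000 runs, n = 50 per group).

## Pipeline, pairing, problem sizes

`run_pipeline` chains simulate → shift-correct → measure → summarise/test
per named condition, deterministically in the seed (byte-identical summary
JSON), logging kept/dropped counts for each filter. The optional rendered
route (`localize_rendered_pairs`) renders each pair into a local two-channel
stack, re-detects and mixture-fits the green spots, masked-searches the red
partner and shift-corrects it, recovering the generative Δ3D median within
3 combined SE (tested at 35–40 pairs, 5·10⁴ photons, Poisson noise).

`pair_sisters` is a deliberate simplification of the original temporal
tracking/manual pairing: with ground-truth IDs it is exact; without, it
pairs mutual nearest neighbours *across the plate* — candidates must be
500–2000 nm apart with the pair axis within 60° of the plate normal, and
proximity is ranked by in-plane distance. Known limitation: at realistic
plate occupancies the in-plane nearest-stranger distance (≈ 0.4–0.7 µm) is
comparable to the in-plane sister offset, so a few percent of assembled
pairs are chance neighbours (~10% wrong at 45 pairs per plate, worse at
100); applications needing exact pairing must supply IDs or tracking.

Test and acceptance problem sizes (1000–2000 pairs for ensemble medians,
649 for the dispersion-recovery replicates, 35–45 pairs for rendered-image
routes, 5000 null simulations, 10³–2·10⁵ permutations in tests) were chosen
so each check resolves its claim within sampling error while the whole suite
stays desk-scale.

## What passing tests do and do not show

The generator emulates plate geometry, fixed-magnitude Δ with configurable
swivel laws, session-level chromatic shift, Gaussian localization error and
Poisson-limited imaging. It does not model chromosome bodies or background
structure, spectral bleed-through, camera gain/offset, spatially varying
aberration (a single ζ per session), kinetochore–kinetochore exclusion, or
deconvolution artefacts. Passing tests therefore validate the measurement
mathematics, the estimators and the pipeline plumbing under this model —
not performance on raw microscope data. Headline live-cell numbers
(Δ3D = 98.0 nm, Δ1D 57.9 → 17.8 nm, swivel medians 51.6°/73.8°) enter only
as generative parameters or qualitative orderings, never as values the
package claims to reproduce from data.
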