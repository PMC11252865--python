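# Methods

This note documents the models, algorithmic choices and limitations behind
`aortamech`. It is written for users who need to judge whether the
procedures match their own experimental protocol, and for maintainers who
need to know why each default is what it is.

## Scope and data model

The package analyses the passive biomechanics and histomorphometry of
arterial wall tissue, organised around the measurements typically taken
from one excised aorta per animal:

- a uniaxial tensile record per region (descending thoracic, DTA; distal
  abdominal, DAA) and loading direction (longitudinal, circumferential);
- closed-ring perimeters and opened-ring landmark coordinates per region;
- six in-vivo/ex-vivo mark positions along the whole vessel;
- Masson's-trichrome sections of the DTA;
- group structure: one control and several treatment groups, one value per
  animal and variable.

Landmark and mark *detection* is out of scope: coordinates and arc-length
positions are consumed as numbers, as produced by standard image
digitisation tools.

## Tensile stress–stretch parameterization

**Kinematics and stress.** Stretch is λ = (l₀+d)/l₀ from crosshead
displacement d and gauge length l₀. Cauchy stress assumes incompressibility
(standard for arterial tissue): σ = Fλ/(w₀t₀). With N and mm inputs the
natural unit is MPa; results are reported in kPa, the scale on which
arterial moduli are conventionally quoted. The recorded force is exactly
recoverable as σ·w₀t₀/λ (tested to machine precision).

**Rupture truncation.** The retained range ends at the global stress
maximum. Samples beyond it are discarded only when stress subsequently
falls below (1 − `drop_fraction`)·σ_max (default `drop_fraction` 0.2),
which distinguishes a genuine rupture from terminal noise; a curve with no
interior maximum is kept whole and flagged `no_rupture`.

**Bilinear model.** Arterial σ–λ curves show a compliant low-stretch
regime (modulus E1, elastin-dominated), a stiff high-stretch regime
(modulus E2, collagen recruitment), and a transition point (λt, σt). The
extraction is:

1. *Anchored window search.* The longest contiguous window anchored at the
   first sample whose OLS fit of σ on λ reaches R² ≥ `r2_min` gives the
   low-stretch line; the longest window anchored at the last pre-rupture
   sample gives the high-stretch line. `r2_min` defaults to 0.999, the
   compliance level practitioners use when hand-selecting bounds. If no
   window of at least `min_points` (default 5) complies — common on noisy
   records — the window maximising R² is used and the fit is flagged
   `r2_relaxed`.
2. *Overlap resolution.* If the two windows overlap (sharp corners,
   low noise), they are split at the overlap midpoint and re-fit, flagged
   `window_overlap`.
3. *Transition point.* (λt, σt) is the intersection of the two fitted
   lines: λt = (b₂−b₁)/(E1−E2), σt = E1·λt + b₁. The intersection is the
   only definition that is unique, reproducible, and consistent with the
   transition being the boundary between the two regimes. Parallel lines
   (a single linear regime) raise a degenerate-transition error.
4. *Window refinement.* The windows are re-fit on λ ≤ λt and λ > λt
   respectively and the intersection recomputed, iterating to stability
   (`refine_iters`, default 3). Without this step the compliant windows
   admit a handful of transition-zone samples past the corner, which biases
   the moduli by order 10⁻³ relative even on noise-free curves; with it,
   recovery on noise-free smoothed-bilinear curves is exact to well below
   10⁻³ relative. If refinement would shrink a window below `min_points`
   (transition close to a domain end) it stops and flags `refine_truncated`;
   if λt falls outside the gap between the final windows the fit is flagged
   `transition_outside_gap` — in practice the signature of a curve whose
   low-stretch regime is too short to identify E1 reliably.

No toe-region offset is applied: the extractor only uses slopes and the
line intersection, so a non-zero stress at λ = 1 does not affect recovery.
The displacement rate is metadata; no rate dependence is modelled.

**What the windows are not.** The search is restricted to windows anchored
at the curve ends. Interior windows could fit transient linear stretches of
a noisy curve; anchoring reproduces the practitioner's convention (the low
modulus starts at the origin of loading, the high modulus ends at rupture)
and makes the search exhaustively verifiable: the incremental running-sums
scan is tested against a brute-force fit of every anchored window.

## Residual-strain geometry

**Closed-ring morphometry.** Assuming a circular cross-section, the inner
radius is IR = P_in/2π and the wall thickness T = P_out/2π − IR. The
assumption is applied to both perimeters.

**Opening angle.** After a radial cut the ring springs open; the opening
angle α is measured at the vertex (midpoint of the inner-perimeter arc)
between rays to the mid-thickness points of the two cut ends. α is computed
with the atan2 form of the vector angle — exact range [0°, 180°], stable
near 0° and 180° — and is invariant under rigid motion and uniform scaling.
Reported arterial opening angles stay well below 180°; an `allow_reflex`
option extends the range to [0°, 360°) using the signed orientation for
tissues that curl past collinearity, but is off by default.

**Axial pre-stretch.** Six marks define five segments; each segment's
pre-stretch is λ_Z = l_in-vivo/l_ex-vivo. Segments are labelled by the
in-vivo relative position of their midpoint (0–20% … 80–100% of the mark
span, proximal to distal); with the nearly equidistant marks the protocol
prescribes this is the identity ordering, and the implementation falls back
to ordinal ordering if irregular spacing would make midpoint bins collide.
The whole-vessel ratio always lies between the smallest and largest segment
value (tested).

## Trichrome histomorphometry

**Colour deconvolution.** Per-pixel optical density OD = −log((I+1)/256)
is linear in stain concentration (Beer–Lambert). With a 3×3 matrix M of
unit stain OD vectors (rows: collagen blue, cytoplasm red, nuclei dark),
per-pixel densities are OD·M⁻¹, clipped at zero.

The default matrix uses widely published colour-deconvolution vectors for
methyl-blue/ponceau-fuchsin trichrome, with the nuclear (Weigert iron
hematoxylin) component modelled as near-neutral blue-black
([0.55, 0.58, 0.60] before normalisation). Two cautions, both learned the
hard way and now tested:

- The matrix must be well conditioned. A classic alum-hematoxylin vector
  lies almost in the plane of the other two stains (determinant ≈ 0.01);
  8-bit quantization noise then explodes into cross-channel talk.
  The shipped matrix has determinant ≈ 0.19. Deconvolution output depends
  entirely on this matrix; for quantitative work on real slides it should
  be calibrated per staining batch and passed in explicitly.
- Otsu thresholds on spike-like histograms have a plateau of equally
  optimal thresholds, and implementations that return the plateau's first
  bin can land exactly on a mode. The package uses a histogram Otsu with a
  plateau-centre tie-break; on continuous histograms it coincides with the
  standard answer.

**Measurements.** Tissue is defined as total OD above `od_threshold`
(default 0.15, roughly one-quarter of a typical stained-pixel OD).
Percentages are relative to the tissue mask — collagen fraction is
"fraction of the sectioned wall", not of the frame. Nuclei are counted as
8-connected components of the thresholded nuclei channel with pixel area
in `nuclei_area_range_px` (default 10–400 px, sized for ≈1 µm pixels);
density is count per mm² of tissue. Touching nuclei merge into one
component — no watershed splitting is attempted, a declared limitation that
biases counts downward on densely packed real tissue. Per-animal values are
the mean over that animal's available images. The whole pipeline is
deterministic: identical image and config give bit-identical results.

## Group statistics

Values are summarised as mean ± SEM (SD with n−1 denominator over √n).
Pairwise comparisons use a decision tree:

1. Normality of each group by a Kolmogorov–Smirnov-type test. Because the
   normal parameters are estimated from the sample, the plain KS test is
   anticonservative; the default uses Lilliefors critical values
   (`ks_variant="lilliefors"`, requiring n ≥ 4), with the plain variant
   available for strict protocol replication.
2. If both groups are normal: a two-sided F-test (larger over smaller
   sample variance, matching degrees of freedom, doubled upper tail).
   Equal variances → unpaired Student t-test; unequal → Welch t-test.
3. Otherwise: two-sided Mann–Whitney U — exact when both n ≤ 8 with no
   ties, normal approximation with tie correction otherwise.

All tests are two-sided; significance is p ≤ α (default 0.05). No
multiplicity correction is applied by default, matching common practice in
this literature; Holm adjustment is available (`adjust="holm"`). The
composite procedure's type-I error at n = 8 vs 5 was measured at 0.048 over
20 000 null replicates, and the test suite checks 2000 replicates against
the 99% binomial band around 0.05. Branch selection is exclusive and always
justified by the recorded normality/variance p-values (property-tested).

## Synthetic data: what it emulates, what it does not

Generators exist so every stage can be validated by parameter recovery;
their defaults encode the study conditions the package targets (three
groups of N = 8/5/5 animals; the published group means for tensile
parameters, ring geometry, opening angles, pre-stretch profiles, collagen
fraction and nuclei density).

- **Tensile curves** follow a smoothed-bilinear law
  σ(λ) = σt + E1(λ−λt) + (E2−E1)·s·log(1+e^((λ−λt)/s)) on a uniform λ grid,
  converted to force and displacement through the specimen geometry. The
  log-sum-exp blend (rather than a hard corner) gives the window search a
  finite transition zone to contend with, as in real data; corner sharpness
  s defaults to 0.01 in λ units, with s = 10⁻⁴ used for exactness tests.
  Noise is Gaussian on force, default SD 0.5% of peak force — the order of
  a 10 N load cell's resolution relative to soft-tissue peak loads. The
  published parameter sets can imply σ(1) > 0; no zero-stress toe is forced
  (the extractor is toe-agnostic). An exponential-toe generator
  σ = a(e^{b(λ−1)}−1) with closed-form tangent truths is provided for
  realism checks. Curves that would be non-positive everywhere are
  rejected as infeasible.
- **Opened rings** place the cut-end landmarks on rays of known half-angle
  about a seeded random orientation and offset, so recovery must be
  rigid-motion invariant.
- **Pre-stretch marks** are equidistant in vivo, with ex-vivo segments
  shortened by the per-segment profile; optional jitter bounds are tested
  by error propagation.
- **Trichrome slides** are painted through the forward Beer–Lambert model
  with disjoint classes: non-touching elliptical nuclei (a ≥ 1 px
  8-connectivity-safe gap enforced by dilated-footprint rejection
  sampling), exactly the target fraction of remaining tissue pixels as
  collagen, cytoplasm elsewhere, on a tissue rectangle inside a white
  border. Ground truth (painted collagen %, nucleus count, tissue area) is
  returned alongside the image.

What the generators do *not* emulate — and hence what passing recovery
tests do not demonstrate about real data: preconditioning hysteresis and
viscoelastic relaxation in tensile records; curved, layered or damaged
wall geometry; staining variability, uneven illumination, out-of-focus
blur and overlapping nuclei in histology; inter-animal correlation
structure beyond independent draws around group means. Recovery results
validate the *estimators*, not the biology.

All generators are pure functions of (config, seed); identical inputs give
identical outputs, to the byte for images.

## Pipeline and reproducibility

`run_pipeline` chains simulate → analyze → compare → report. A bad
specimen (malformed record, degenerate geometry) is logged and skipped,
never fatal. Every output file carries the configuration hash and seed in
`# key=value` header lines; the run manifest records the full
configuration. Re-running with the same configuration reproduces every
table byte-identically (tested). Group tables mark treatment-vs-control
significance with `(*)`, the convention of the field's tables and figures.

The cohort simulator reconstructs per-animal spread as SD = SEM·√N from
published group summaries, truncating non-physical draws (E2 > E1 > 0,
transition inside the tested stretch range, feasible stress at λ = 1).
Draws whose transition lands near λ = 1 produce curves whose low-stretch
regime is only a few samples long; E1 is then poorly identified and the
fit is flagged — the pipeline tests assert that large recovery errors
occur only on flagged fits. One group mean absent from the published
record (sildenafil distal opening angle) is set to 48°, inside the
reported distal range.

Default problem sizes — 200-point tensile curves, 512 px simulation
images with 1024 px used for the histology recovery checks, 2000-replicate
null calibration — were chosen so the whole validation suite runs in
seconds to minutes on a laptop while keeping every estimate's Monte-Carlo
error well inside the tolerances being asserted.

## Numerical details

- Window statistics use cumulative sums (O(1) per window); a window with
  zero stress variance is treated as perfectly fit (R² = 1), and a window
  with zero stretch variance is skipped as degenerate.
- Lines are intersected only when |E1−E2| exceeds 10⁻⁹ of the larger
  modulus; otherwise the transition is reported as degenerate.
- Angle and pre-stretch computations are scale-invariant to machine
  precision; tests assert mm→cm invariance and sub-nanodegree angle
  round-trips.
- Constant samples short-circuit the statistics (normality degenerate-flag
  with p = 0; F-test degenerate-unequal) rather than dividing by zero.
- Group comparison requires n ≥ 4 per group (the Lilliefors table's lower
  limit); the pipeline silently omits smaller groups from comparisons but
  still summarises them.

## Known limitations

- E1/λt are unidentifiable when the true transition sits near the start of
  the stretch range; flagged, not repaired.
- Nuclei counting has no split step for touching nuclei.
- The stain matrix default is generic, not calibrated to any scanner.
- The opening-angle vertex definition (arc vs chord midpoint) is the
  caller's responsibility; the generator uses the arc midpoint convention.
- The decision tree inherits the usual caveat of adaptive testing: the
  pre-tests and the final test are computed on the same data, so the
  nominal α is approximate (measured 0.048 at the study's group sizes).
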