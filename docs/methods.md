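# Methods

`lightzones` is an in-silico pipeline for studying *light zones* — parts of
a scene whose first-order light field (direction, intensity, diffuseness)
has a consistent structure that differs from neighboring parts — and for
analyzing how well probe-setting observers distinguish them. This note
documents the models, the parameters that matter, the numerical choices,
and the limits of what the synthetic pipeline can show.

## Radiometric scene model

Scenes consist of point-like spherical sources, luminous rectangular
panels, planar rectangular shades, and a constant isotropic ambient term.
Illuminance on a sensor face is direct-only:

    E = E_ambient + sum_sources I * max(0, cos theta) * V / d^2

with `V` a binary visibility term (open-segment ray–rectangle
intersection) and panels expanded into `subdivision^2` point patches
(default 4 x 4) of intensity `I / subdivision^2`. There is no global
illumination: the ambient term stands in for interreflections, and an
explicit upward-pointing secondary source can be added in a scene config
where floor scatter matters. This keeps the simulator analytic,
deterministic and fast while preserving exactly the zone structure the
analysis needs. Occlusion is binary (no penumbra): the sources of
interest are small relative to their distance, and penumbrae are
irrelevant to first-order zone structure.

Coordinates are right-handed with +z up; the viewer of a rendered image
looks along +y (picture plane = xz); azimuth runs counterclockwise from
+x, elevation up from the horizontal plane; light direction vectors point
from the measurement position toward the source. Scene units are
desk-scale by convention: scene content within radius ~1, sources at
distance ~10, so inverse-square variation across a scene is mild (a few
percent), emulating distant lamps.

An endpoint lying exactly on a shade plane does not count as occluded
(tolerance 1e-9 on the segment parameter). This makes the zone border
well-defined: a probe standing on the border sees both sources, and its
veridical light vector points straight up — the physically correct limit.

## First-order light field from cubic illuminance

A cubic illuminance meter records six face illuminances `E+`, `E-` along
each axis. The first-order description follows in closed form:

* light-vector component per axis: `E_a = E_a+ - E_a-`
* vector magnitude: `E_vector = |(E_x, E_y, E_z)|`
* symmetric part per axis: `~E_a = (E_a+ + E_a- - |E_a|) / 2`
* symmetric illuminance: `E_sym = (~E_x + ~E_y + ~E_z) / 3`
* scalar illuminance: `E_scalar = E_vector / 4 + E_sym`
* diffuseness: `D = 1 - (E_vector / E_scalar) / 4`, in [0, 1]

`D = 0` is a fully collimated beam (all light on one face), `D = 1` a
Ganzfeld. The `|E_a|` entering the per-axis symmetric part is the
magnitude of that axis's vector component. Internally the six inputs are
max-normalized before the arithmetic: `D` is scale invariant, the linear
quantities are rescaled afterwards, and the normalization guarantees the
denominator `E_scalar >= max(faces)/4`, so the computation cannot
underflow or divide by zero for any admissible input. A genuinely dark
point (all six faces zero) is an error; `D` is undefined there.

Caveat on precision: the symmetric part is a difference of nearly equal
numbers for near-collimated fields, so it carries the cancellation error
of the overall illuminance level, not of its own (tiny) magnitude. Tests
of scale invariance anchor tolerances accordingly.

## Grid interpolation and light tubes

Fields are sampled on rectilinear lattices (at least 2 nodes per axis).
Interpolation is component-wise trilinear (`scipy.interpolate
.RegularGridInterpolator`), chosen because it is deterministic and
reproduces any field linear in position exactly; a smoothed tricubic mode
is available behind a flag (needs 4+ nodes per axis). Light tubes are
streamlines of the normalized light-vector field: fixed-step Euler
integration, bidirectional from each seed, default step a quarter of the
minimum grid spacing, terminating at the volume boundary, at a stagnation
point (|vector| < 1e-12), or after `max_steps` per direction. Tube
radius is `c / E_scalar` — thick where the light is dim — with `c` set so
the median radius over the traced set equals a configurable display
value (the underlying convention fixes only the inverse proportionality).
Tube shapes are a visual product: a fixed-step Euler polyline through a
trilinearly interpolated field is not a numerical claim about the exact
field lines.

## Probe settings

An observer setting is a direction (azimuth/elevation in the view frame),
a directed intensity and an ambient intensity, both display-normalized to
[0, 1]. Directed and ambient intensities are read as `E_vector` and
`E_sym` of the inferred field; `E_scalar` and `D` then follow from the
same equations as for physical measurements. A Lambertian probe renders
as `L = I_ambient + I_directed * max(0, n . d)`; any setting whose peak
luminance exceeds 1 is flagged `clipped` but not numerically corrected —
synthetic settings are generated pre-clipping on the physical scale, and
analysis proceeds on the unclipped values with the flag preserved for
auditing. Display normalization per condition uses a single gain chosen
so the brightest veridical probe peaks at 0.8, leaving headroom for
intensity noise.

## The two-zone experiment designs

**Two-zone probing design (10 images).** A rotationally symmetric
desk-scale scene with two identical point sources at exactly 45 degrees
elevation (conditions 1–3) or one source (condition 4):

* Condition 1 — a partial divider shade in the zone-border plane: each
  source lights only its closer half; zones lit from opposite sides,
  perpendicular to the border.
* Condition 2 — full shades beside each source: each source lights one
  lateral half; zones lit along the border, in opposite senses. The
  full-shade sources carry a 0.1-unit lateral offset from the shade plane
  so the ray–rectangle test is well-posed.
* Condition 3 — the combination (one divider-type, one full-type shade),
  with the two sources on perpendicular sides: the front zone is lit from
  the front, the back zone laterally.
* Condition 4 — a single unshaded source, viewed from four sides
  (F/R/B/L).

Each two-zone condition is viewed by two cameras, one putting the zones
left–right (LR) and one front–back (FB); the physical scene is identical
across views. The camera assignment reproduces the canonical zone
correspondence: the left zone of the LR view is the front zone of the FB
view for condition 1 but the *back* zone for conditions 2 and 3. Each
image carries 5 probes (one per scene quadrant at (±0.5, ±0.5, 0.25) plus
the center) with 3 repetitions: 10 x 5 x 3 = 150 trials per observer.
Probes group into zone1 (left/front pair), middle, zone2 (right/back
pair) by their view-frame coordinate along the border normal.

Per-probe veridical light fields are *measured*, not asserted: a cubic
meter is evaluated at each probe position in the actual scene and reduced
by the first-order equations.

**Grid-probing design.** The same machinery on a 5 x 5 x 3 lattice
(x, y in [-1, 1], z in [0.2, 1.0]; 75 nodes) over an LR-zoned scene
(condition-1 geometry) and an FB-zoned scene (condition-3 geometry). One
setting per node plus two extra repetitions on five designated repeat
probes (two per zone, one central). Analysis slices the lattice into the
five planes parallel to the zone border (along x for LR, along y for FB).

The absolute geometry of the original apparatus is not recoverable (the
published schematic is explicitly not to scale), so distances, shade
sizes and probe heights here are package conventions, configurable
through the scene-config YAML.

## Synthetic observers

Each observer is a parameter bundle:

* `kappa_dir` (default 20) — von Mises–Fisher concentration of
  directional noise about the target direction; angular SD roughly
  `1/sqrt(kappa)` rad ≈ 13 degrees at the default, a realistic precision
  for probe adjustment.
* `sd_intensity` (default 0.05) and `sd_diffuseness` (default 0.10) —
  truncated-Gaussian noise applied on the normalized `E_scalar` and `D`
  scales and mapped back to `(I_directed, I_ambient)` holding the
  perturbed `E_scalar` fixed (`I_dir = 4 E_s (1 - D)`, `I_amb = E_s D`),
  clipped to [0, 1]. The defaults sit at the lower end of the intensity
  and diffuseness spreads reported for human observers in this paradigm.
* `zone_confusion_p` (default 0) — probability that a setting on a
  *back*-zone probe of an FB-oriented two-zone image is made about the
  *front* zone's veridical direction instead of its own. This emulates
  the idiosyncratic behavior observed for depth-oriented zone borders;
  it applies to FB views only, because that is the asymmetry the
  analysis must be able to detect (LR views must stay symmetric). The
  fraction of confused settings has no published value; it is a free
  simulation parameter, and the default demonstration cohort mixes
  observers with p = 0 and p = 0.5.

vMF sampling inverts the CDF of `cos(theta)` about the mean direction
(`w = 1 + log(u + (1-u) exp(-2 kappa)) / kappa`, uniform azimuth);
concentration is estimated by the standard spherical approximation
`kappa_hat = R(3 - R^2)/(1 - R^2)`. For pooled recovery across probes
with different veridical directions, the estimator uses each setting's
cosine with its own probe's veridical direction (a known-mean estimate,
unbiased under the generator). All randomness flows from one master seed
through `numpy` `SeedSequence` spawning per observer; identical seeds
give byte-identical settings tables.

What the generator does **not** emulate: systematic per-observer biases,
learning or order effects across trials, cue-visibility differences
between views (the hypothesized *cause* of the back-zone confusion), the
interreflection-driven downward light vector in occluded scene centers,
and clipping-corrected intensities. Passing tests therefore show that the
analysis machinery detects the statistical structure the generator
encodes — not that human observers behave this way.

## Directional statistics

* Mean direction and resultant length: `R = |sum v| / n`; dispersion
  `1/R` in [1, inf], reported as infinity (with an undefined mean) when
  the resultant vanishes exactly.
* SD ellipse: orthographic projection onto the tangent plane at the mean
  direction, 2 x 2 covariance eigendecomposition; axes are the
  eigenvalue square roots, orientation the major-axis angle.
* Deviation from veridical: both the full 3-D angle between setting and
  veridical light vector and the top-view azimuthal difference are
  reported — all sources sit at one elevation, so zone differences live
  in the top view, but the 3-D angle is what a light-vector comparison
  uses. Middle probes whose veridical vector points straight up have no
  meaningful top-view azimuth; their large top-view deviations are
  expected and flagged by context.
* Intensity and diffuseness spreads: standard deviations of the implied
  `E_scalar` and `D` per group.
* Circular histograms: 24 bins of 15 degrees by default.
* Paired t tests: classical difference-score t with `df = n - 1`, coded
  from the textbook formula (only the t-distribution tail probability
  comes from scipy); cross-validated against an independent
  implementation in the tests.
* No multiple-testing correction is applied to the comparison table
  (raw p values, matching standard practice for this analysis); a
  Bonferroni adjustment is a one-liner on the emitted CSV if wanted.

### Two-sample Watson U² and its p-value

The statistic is the rotation-invariant two-sample Cramér–von Mises form
on the circle: with pooled order statistics and cumulative fractions
`d_k = F_n(x_k) - G_m(x_k)`,

    U2 = nm/N^2 * [ sum d_k^2 - (sum d_k)^2 / N ].

Two p-value modes exist. `permutation` draws a seeded pooled-relabeling
null — the package's internal oracle. `asymptotic` uses the limiting
null series `P(U2 > u) = 2 sum_k (-1)^(k-1) exp(-2 k^2 pi^2 u)` after a
finite-sample moment correction: writing U² as a quadratic form in the
centered sample-membership indicators over the pooled ranks, its exact
permutation-null mean and variance follow in closed form from the joint
moments of sampling without replacement (the derivation is verified in
the test suite against exhaustive enumeration over all C(N, n)
assignments). The statistic is mapped affinely to match the limiting
mean (1/12) and variance (1/360) before the series is applied. Without
this correction the series misestimates mid-range p-values by up to ~0.09
at n ≈ 10 even though its 5% tail is accurate; with it, agreement with
the permutation oracle is at Monte-Carlo resolution (median |Δp| ≈ 0.001
at 999 permutations) and the nominal 5% level is held within simulation
error. Ties are broken by pooled sort order; the correction assumes
tie-free data, which holds for continuous azimuths.

## Pipeline conventions and problem sizes

Cross-view comparisons rotate one view's azimuths by the 90-degree view
difference before testing (settings live in view frames); single-source
pairs are compared after a left–right (`az -> 180 - az`) or front–back
(`az -> -az`) mirror. The comparison table pairs zones by physical
identity, matched through the scene-frame zone directions.

Default problem sizes keep every stage interactive: cohorts of 10
observers (1,500 two-zone trials), 34 observers where confusion-rate
recovery needs 600+ back-zone trials, 999 permutations for the oracle,
1,000 simulations for the type-I calibration check. All reports are CSV;
figures (dispersion bars, polar histograms) are side effects only and
never inputs. Every run directory carries a JSON manifest with the
master seed and stage parameters; re-running with the same seed
reproduces byte-identical CSVs.

## Known limitations

* Direct illumination only: phenomena driven by interreflection (e.g. a
  downward mid-scene light vector under floor scatter) appear only if
  modeled explicitly as a secondary source.
* The noise-free dispersion floor is not exactly 1: the two probes of a
  zone see the distant source a few degrees apart, so pooled zone
  dispersions bottom out near 1.0014 rather than 1.
* Tube geometry is qualitative (interpolation and integration choices),
  suitable for visual comparison, not for quantitative field-line
  claims.
* Human-derived numbers from the probing literature (zone separations in
  degrees, specific t and p values) are not reproduction targets: the
  underlying observer data are unpublished, and the synthetic cohorts
  demonstrate the direction of the effects, not their magnitudes.
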