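# Methods

This note records the models, conventions and design choices behind
`chewsim`, in the order the pipeline uses them.

## Colour difference

Colours are CIE L\*a\*b\* triples as measured by a chromameter; the
difference is the CIE76 Euclidean distance
ΔE = √(ΔL\*² + Δa\*² + Δb\*²).  The visibility decision uses the strict
rule ΔE > 5 CIELAB units (a difference of exactly 5 is judged not
distinct).  Reported values are rounded half-even to 2 decimals; full
precision is kept internally.  ΔE2000/ΔE94 and calibrated RGB↔Lab
conversion are out of scope.

## Bolus homogeneity by image analysis

**Intensity scale.** Pixels are normalised to [0, 1] (8-bit values / 255).
Bolus red-channel variances of order 10⁻³–10⁻⁴, the magnitudes this
statistic takes on real boli, only arise on the normalised scale, so the
convention is load-bearing and fixed here.

**Variance convention.** The homogeneity score is the *population*
variance (divide by N) of one channel's intensities restricted to the ROI.
At realistic ROI sizes (~10⁶ px) the N vs N−1 distinction is negligible,
but a fixed convention makes exact tests possible.  The score is invariant
to pixel permutation within the ROI and to padding with excluded pixels,
and is bounded by 0.25 (a half/half binary image).

**ROI extraction.** The photographs have a green background chosen to
contrast with the purple/white product.  No segmentation algorithm is
canonical for this task, so the package fixes a deterministic one:
chroma-key in HSV (background = circular hue distance ≤ tolerance *and*
saturation ≥ a floor, so near-grey product pixels are never keyed), then
the largest connected foreground component (discards specks), then an
optional binary erosion of configurable radius to trim shadow fringes.
Defaults: hue 1/3, tolerance 0.10, saturation floor 0.15, erosion 0.

**Channel selection.** Among red/green/blue, the analysis channel is the
one whose per-image ROI variances maximise the one-way between-group
(child/adult) F statistic; ties — including all-degenerate designs, where
F = +∞ by convention — resolve in the fixed order red > green > blue.  On
the purple-on-white product the red channel wins, which is why the
homogeneity statistic is called the red-channel variance throughout.

**Replicates.** Variance is computed per image; replicate images are
averaged afterwards for stage summaries.  The order (score, then average)
is fixed.

## Hardness by texture analysis

The endpoint is the *final charge*: the force at the last (largest)
displacement sample, optionally tail-smoothed over a configurable window
(default: none) and tare-corrected (default 0).  The term denotes the
endpoint load, not the maximum force — the back-extrusion protocol
compresses until the bolus covers the dish, so the travel end *is* the
measurement point.  Penetration (3 mm probe, 7 mm travel, 0.5 mm/s; intact
cheese, ~1 N) and back-extrusion (35 mm plate, 0.2 mm/s; boli, ~50–110 N)
are different instrumental scales; the package never compares hardness
across modes.

## In vivo masticatory parameters

Per subject: mouth volume (mL), quantity naturally consumed (g),
mastication time (s), number of tongue–palate compressions, and the
saliva assay.  Derived quantities: chewing frequency n/t; saliva content
(%) = (bolus WC / bolus DM) × cheese DM − cheese WC; saliva volume (mL) =
content × 10⁻² × consumed mass (4.5 g pieces; saliva ≈ water, so g ≡ mL);
saliva rate = volume / time; and the three ratios (mouth/quantity,
saliva/mouth, saliva/quantity).  Negative saliva content — possible when
the bolus assays drier than the cheese through evaporation or assay error
— is clamped to 0 with a warning, since a physical volume cannot be
negative.  Stage times are 0.33 t, 0.66 t, 0.99 t of each subject's own
mastication time (99 % ≈ swallowing).

"Pearson standard deviation" in summaries means the population SD
(divide by N).  Triplicate raw measurements are averaged per subject
before group summaries.  Overall means pool subjects across groups; with
equal group sizes this equals the mean of group means.  Printed panel
summary values are treated as generating targets, not recomputable
outputs: group-mean frequencies are means of per-subject ratios, which
cannot be recovered from the summary table alone.

## Transposition to the masticator

Masticator constants: 375.00 mL container, 36 ± 1 °C, plunger palate of
63.62 cm², 7 cheese pieces of 4.5 g.  The cheese mass to load is
container volume / (mouth volume per quantity ratio); with the pooled
11.47 mL/g this is 32.69 g.  The computed target (32.69 g) and the mass
actually loadable as whole pieces (7 × 4.5 = 31.5 g) are kept as separate
quantities, with a warning when they diverge beyond a configurable
tolerance (default 1.5 g).

Saliva is added before the run as a precomputed total, linear in the
planned compressions: rate × pieces × compressions, i.e. 0.35 mL at 1
compression up to 6.30 mL at 18 with the pooled 0.05 mL/s rate.  The
pooled (not per-group) ratio and rate are the defaults because the group
differences on these quantities are not significant; per-group
transposition is available but off by default.

The experimental grid is the Cartesian product of compression counts
{1, 2, 6, 8, 10, 14, 18} and rotation speeds {4, 15} rpm — 14 settings —
ordered ascending by compressions then speed.

## Nearest-value matching

For each group × stage × metric, the selected setting minimises
|in vivo − in vitro|.  Equidistant candidates resolve by *minimal
intervention*: fewer compressions first, then lower rpm (this reproduces
the published choices in the two genuinely tied rows).  Gaps within a
10⁻⁹ relative tolerance count as tied, which keeps decimal table values
(e.g. |0.0024 − 0.0026| vs |0.0024 − 0.0022|) exactly tied despite binary
floating point.  The per-group final recommendation is the 99 %-stage
match under the image metric: the bolus mixing state is judged more
informative than hardness, whose in vitro decline is confounded by the
fixed 36 °C vessel temperature (see Limitations).  Selection is invariant
to candidate order, and enlarging the candidate set can never increase
the selected gap.

## Statistical inference

All ANOVAs use Type III sums of squares from a full-rank sum-to-zero
contrast parameterisation: the SS of an effect is the increase in residual
SS when its columns are dropped from the full model.  The mixed designs
treat subject-nested-in-group as a random stratum (split-plot):

* group (between-subject) is tested against the subject-within-group mean
  square;
* mastication progress and the group × progress interaction are tested
  against the pooled within-subject residual.

Degenerate zero-denominator cases report F = +∞ with p = 0 (or F = 0,
p = 1 when the numerator is also null) instead of erroring.  Requesting
the interaction with a single observation per subject × stage cell is
rejected, as the interaction would not be separable from the
subject × stage error.  Independent oracles cross-check the
implementation in the test suite: brute-force SS decompositions,
`scipy.stats.f_oneway`, closed-form balanced mean-square formulas, and
the balanced-design identity that the between-subject F equals a one-way
ANOVA on per-subject means.  The split-plot error strata are implemented
here because generic OLS ANOVA tables test every effect against the
single residual.

The triangle test is the exact one-sided binomial with null success
probability 1/3: p = P(X ≥ k), and the minimum significant count is the
smallest k whose tail is ≤ α.  At n = 30 and α = 0.05 the exact minimum
is 15 correct answers; printed session tables sometimes quote 16, which
is conservative — the package reports the exact value.  Observed session
counts of 5 and 9 out of 30 are far from significant either way.

## Synthetic data

The raw study data are not public, so the generators reproduce the study
conditions:

* **Panels.**  Truncated-at-zero normal draws per subject, defaults equal
  to the published child/adult means ± SDs (30 subjects per group);
  compression counts rounded with floor 1; triplicates simulated with 3 %
  relative within-subject noise and averaged.  Sampling is by rejection;
  all generators are bit-reproducible under a fixed seed.
* **Mixing images.**  The initial bolus is a disk on a green background;
  the coloured phase is an *annular sector* — a surface-layer ring
  restricted to an angular wedge, trimmed to the exact pixel-area fraction
  f (default 0.30).  A full annulus was rejected: it is rotationally
  symmetric, so the stirring operator below would leave it invariant and
  the rotation-speed knob would be inert.  At zero compressions and zero
  noise the red-channel variance is exactly the two-point closed form
  f(1 − f)(r₁ − r₀)².  Mixing applies (i) a differential rotation of
  total twist shear_rate × rpm × n (zero at the rim, maximal at the
  centre), which shears the wedge into a spiral and lengthens the phase
  interface, then (ii) a fold blur of scale σ_c √n confined to the ROI by
  normalised convolution, then additive Gaussian pixel noise (SD 0.01)
  clipped to [0, 1].  The √n single blur is the exact composition of n
  successive σ_c folds and keeps full-study synthesis (388 images) to a
  few seconds.  Variance is thereby decreasing in compressions at fixed
  rpm and lower at 15 rpm than 4 rpm — the orderings real boli show.
  Child boli are generated with a smaller fold scale (σ_c 1.2 vs 2.0)
  than adults, encoding their less efficient mixing, so child variance
  exceeds adult variance at every stage.  Stage → mixing intensity uses
  round(stage fraction × subject compressions), floor 0.  Default image
  size is 128 × 128; the statistic is scale-free, so small rasters trade
  nothing but pixel-quantisation noise for speed.  The images are
  two-phase cartoons: no illumination gradients, camera noise beyond the
  Gaussian term, specular highlights or 3-D relief — passing tests show
  the *statistic and pipeline* behave correctly, not that the forward
  model renders real cheese.
* **Force curves.**  Saturating ramp F(x) = H(1 − e^{−kx})/(1 − e^{−k}),
  x = d/d_max, k = 3, plus i.i.d. Gaussian noise; at zero noise the
  final charge is exactly H.  In vitro mean hardness follows
  H_floor + (H₀ − H_floor) e^{−rate·n(1 + gain·rpm)} (defaults 40, 120,
  0.08, 0.03), decreasing in both knobs.
* **Triangle sessions.**  Each panelist answers correctly with
  probability p_d + (1 − p_d)/3.

## Problem sizes

The default synthetic study is the full design: 30 + 30 subjects, 3
stages × 2 replicates (360 in vivo images), 14 grid settings × 2
replicates (28 in vitro images), at 128 × 128 px.  The test suite uses
48–96 px rasters, 4–8 subjects per group, 20-seed monotonicity sweeps and
200-replicate ANOVA calibrations — sizes at which every distributional
check is stable while the whole suite runs in seconds.

## Known limitations

* The ROI algorithm and the intensity normalisation are package
  conventions; the originating instrumentation did not specify either.
* Whether published stage-level variances are means over all
  subjects × duplicates is not stated; the package fixes
  score-then-average and treats printed values as inputs.
* The in vitro hardness decline is confounded by vessel temperature
  (cheese loaded at 4 °C into a 36 °C vessel softens faster than
  in-mouth), which is why image and texture metrics can disagree on the
  adult swallowing stage; the final recommendation policy resolves this
  in favour of the image metric.
* No multi-objective matching or interpolation between grid points; no
  multiple-swallow modelling; no photometric camera calibration.
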