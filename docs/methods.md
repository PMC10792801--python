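# Methods

## Measurement model

All geometry is planar, in millimetres, with +x anatomically anterior
and +y superior (mathematical y-up). Readers of pixel-space (y-down)
files must pass `y_down=True` / `--y-down`, which negates y; all
downstream code assumes the y-up frame. A traced "plane" is always the
*infinite* line through its two defining landmarks — perpendicular feet
routinely fall outside the short traced borders, and a
distance-to-segment would kink at the endpoints.

Per vertebra (C3/C4; C2 carries only the lower border and its deepest
point):

- **SWIA** = angle at `up` between the rays toward `ua` (superior
  border) and `lp` (posterior border). The two borders intersect at
  `up` by construction, so "the angle between the borders" is the
  interior angle at that shared corner. Values are confined to the
  open interval (0°, 180°); rays within 1e-9° of collinear raise a
  degeneracy error rather than returning a boundary value, since such
  configurations are anatomically impossible and indicate corrupt
  input.
- **CD** = signed perpendicular distance of `d` from the line
  `la`–`lp`, oriented so global +y (anatomical superior) is positive,
  then clamped at 0 with a convexity flag (`cd_raw` keeps the signed
  value). The clamp matches the construct: concavity depth is
  undefined for a convex border, and every published per-stage range
  starts at 0. Orientation by global +y rather than by a local rule is
  forced by C2, which has no superior landmarks to define "interior"
  locally; it fails loudly if the lower border is vertical (a frame
  error).
- **BW**, **BH** = unsigned distances from `um` to the posterior-border
  line and the lower-border line; **BS** = BW/BH.

SWIA and BS are similarity-invariant; CD/BW/BH are rigid-motion
invariant and scale linearly. These invariances are property-tested
under random similarity transforms.

The mid-anterior point `am` and the anterior border are part of the
landmark scheme and are parsed, stored and round-tripped, but no
outcome consumes them.

Magnification: the reference acquisition magnifies by 1.4, yet the
published measurements are taken from 1:1 prints of those films and are
not explicitly corrected to anatomical size. The package therefore
treats the reference values as being in the measurement frame and
never auto-applies a correction; `apply_scale` / `--scale 1.4` is
available when the user knows their frame. Scaling is multiplicative
and recorded in `scale_factor`.

## Stage reference and classifier

The built-in `StageReference` carries, for each stage, the published
group size, mean/SD for the eight normal outcomes and median/range for
the three CDs. Overrides must be complete and are validated cell by
cell (SD > 0, min ≤ median ≤ max, n > 0); JSON round-trips, TOML is
read via stdlib `tomllib`.

No classification rule is published, so two are provided, both
functions of the summary statistics only (there is no training data):

- **gaussian** (default): per-stage score = Σ normal log-densities
  (mean, SD) over the eight normal outcomes + Σ triangular
  log-densities on (min, mode = median, max) for the CDs, with equal
  stage priors. The triangular form is the simplest density pinned
  down by exactly the three published numbers. Two numerical guards:
  the density is floored at 1e-6 so boundary/out-of-range values stay
  finite, and a degenerate published range (pre-pubertal CD3/CD4
  "0 (0–0)") is widened to a ±0.25 mm triangle about the median —
  half the 0.5 mm reporting step of the source measurements — so that
  a jittered near-zero CD still scores sensibly.
- **centroid**: per-stage score = −Σ |value − location| / scale with
  location = mean (median for CD) and scale = SD (half-range + 0.25 mm
  for CD; the same resolution floor keeps degenerate ranges usable).

Highest score wins; a score gap below 1e-9 sets `ambiguous=True` and
resolves deterministically to the developmentally earlier stage.
Priors are equal despite n = 59/220/115: the study's stage mix
reflects its sampling window, not the prior for a new patient. Scores
and per-outcome z-diagnostics are exposed; probabilistic
interpretation is left to the user.

Both rules satisfy the fixed-point property (each stage's published
location profile classifies as that stage) and, on synthetic cohorts
drawn from the reference itself, the gaussian rule reaches ~98–99%
three-class accuracy (the centroid rule ~94%) — the eleven outcomes
are individually well separated (e.g. BH C3 moves almost 5.4 mm
against SDs near 1.2 mm) and combine multiplicatively.

One deliberate looseness: the published BS means are means of
per-subject ratios, so they differ slightly from the ratio of the BW
and BH means (1.69 vs 12.39/7.47 = 1.66 pre-pubertally).
`MeasurementProfile` therefore stores whatever was measured or
specified; the identity BS = BW/BH holds exactly for measured and
sampled profiles (where it is enforced by construction and by test)
but is not a hard dataclass invariant, which lets the published
location profile be represented verbatim.

## Synthetic cohorts

The stages are characterised at the measurement level, so the
generator samples *profiles* first and then builds landmarks to match
— not the reverse (landmark-level population shape statistics are
unpublished). Per stage:

- SWIA, BW, BH (C3 and C4) ~ Normal(mean, SD), independent by default;
  an optional correlation matrix over these six drawn outcomes is
  accepted for sensitivity studies (identity by default — the
  reference publishes no covariances, and independence is an explicit
  simplification). BS is derived as BW/BH, not drawn, preserving the
  profile identity.
- CD ~ Triangular(min, mode = median, max); a degenerate range is a
  point mass (the flat pre-pubertal border), as forced by the printed
  "0 (0–0)".

Landmark construction places `lp` at the local origin with the lower
border horizontal: `la` at the template CL length (default 14 mm,
a typical traced lower border), `d` at the CL midpoint raised by CD,
`up` at height BH + BW/tan(SWIA) so that the superior border leaving
`up` at the SWIA angle carries its midpoint `um` at exactly BW from
the posterior line and BH from the lower line, `ua` mirror-extending
the superior border, and `am` at the anterior-border midpoint.
Vertebrae stack C4→C2 with a 4 mm gap. Template parameters (CL
length, gap, CL tilt) provably do not affect any measured outcome —
the round-trip `profile(profile_to_landmarks(p)) == p` holds to 1e-9
(observed: ~1e-14) and is the module's core contract. Profiles whose
parameters put the posterosuperior corner at or below the lower border
(possible only far outside the reference ranges) raise an
infeasibility error; cohort generation resamples up to a retry cap.

Optional realism layers: per-coordinate Gaussian landmark jitter
(hand-tracing noise; at 0.5 mm it perturbs recovered SWIA with an SD
of ~3.3° on the pubertal template, leaving stage separation intact)
and a random rigid motion with rotation confined to ±20° — the
plausible head-tilt range, which keeps the global +y axis anatomically
superior as the CD sign convention requires.

What the generator does *not* emulate: inter-outcome correlation within
a subject (real SWIA/BS/CD co-develop), sex differences (the reference
pools sexes), digitisation quantisation, and any landmark-level shape
variation beyond what the 11 outcomes pin down. Passing tests
therefore demonstrate internal consistency of measurement, reference
and statistics — not field performance on real radiographs.

## Statistical pipeline

Per outcome, per group: Shapiro–Wilk and Lilliefors (Kolmogorov–
Smirnov with estimated parameters, matching normality screening with
estimated moments) at α = 0.05; one rejection in any group — or a
degenerate constant group, like the pre-pubertal CD point mass —
routes the outcome non-parametrically (the conservative OR reading of
a single published per-outcome verdict).

- Parametric route: one-way ANOVA from explicit sums of squares
  (zero within-group variance handled: F = ∞, P = 0 when means
  differ), eta² = SS_between/SS_total, and Bonferroni-adjusted
  pairwise t tests on the pooled error term (df = N − k).
- Non-parametric route: Kruskal–Wallis with eta²_H =
  (H − k + 1)/(n − k) clipped to [0, 1] (the standard rank-based
  analogue, used so the effect-size column is comparable across
  routes), and Dunn's z tests with the tie-corrected rank variance,
  Bonferroni-adjusted.

Bonferroni spans the three pairwise comparisons within an outcome
only; no cross-outcome correction is applied, as none is used in the
reference protocol. Pairwise significance condenses to a compact
letter display by the insert-and-absorb sweep (A = highest location;
non-transitive chains resolve without error, e.g. the published
B/AB/A pattern for CD C2 and B/A/B for BW C3).

ICC: two-way single-rater forms from the ANOVA mean squares —
absolute agreement ICC(2,1) by default (the conventional model for
inter-observer agreement across a fixed panel) and consistency
ICC(3,1) — with 95% CIs by the F-distribution method (Satterthwaite
df for the absolute form). The reference reliability table does not
state which ICC form it used, and the underlying rating data are
unavailable, so exact reproduction of those values is not attempted;
both forms are exposed, and the implementation is cross-checked in the
test suite against an independent reference implementation
(pingouin) to 1e-9 on values and to rounding on CIs.

## Problem sizes and numerical choices

Simulation-based checks run at the reference group sizes (59/220/115)
with 200 replicates for effect-size recovery, 1,000 profiles for the
inverse-geometry contract, 200 subjects per stage for classifier
accuracy, and 20 fixed seeds for the qualitative-structure sweep —
sizes at which Monte-Carlo error is well below the tolerances being
asserted while the whole suite stays fast. File outputs round to
0.01 mm / 0.01°, the reporting granularity of the source protocol;
the library computes in full double precision throughout.

## Known limitations

- The expectation that simulated default-size cohorts reproduce the
  published BW C3 letter pattern (B/A/B) in ≥95% of seeds is not
  attainable under the published parameters themselves: the
  pre-pubertal vs post-pubertal BW C3 contrast (0.26 mm against a
  pooled SD of ~1.25 at n = 59/115) sits near the Bonferroni
  significance boundary, so the non-significance that produces B/A/B
  recurs in only ~86% of simulated cohorts (observed 18/20 fixed
  seeds; the other patterns and the P < 0.001 omnibus results
  reproduce in 20/20). The corresponding acceptance test reports this
  honestly rather than relaxing the bound.
- Reference values are treated as being in the published measurement
  frame; whether they are corrected for the 1.4 acquisition
  magnification is not stated at the source, so users comparing
  absolute linear measurements must establish their own frame.
- No sex-specific references, no six-stage (CS1–CS6) output, and no
  landmark detection from images: input is coordinates.
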