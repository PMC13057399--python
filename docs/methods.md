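# Methods

## Task geometry

The roadway is a chain of identical-length trials: a 20 m straight lead-in, a
100 m circular arc (radius 35, 55 or 75 m; left or right), and a 20 m
straight tail — 140 m per trial, 4 m lane width (half-width 2 m). A session
is 144 trials: 8 repeats of each cell of the radius × direction ×
flow-density factorial, uniformly shuffled per seed. Plan-view coordinates
are right-handed (x east, y north), heading counterclockwise from +x, and a
left turn carries positive signed curvature, which keeps the signed-offset
algebra unambiguous. The first trial starts at the origin heading +y so the
road frame agrees with the gaze module's body-forward reference.

Polylines are discretized at a uniform 0.25 m arc-length spacing
(configurable, capped at 1 m). At 0.25 m the chord–sagitta error is below
0.3 mm even at radius 35 m. Consecutive trials share the junction pose
exactly, and a windowed accessor exposes the current trial plus the two
upcoming ones, mirroring how the task streams turns into the scene. The two
20 m straights meeting between bends are kept as distinct segments so
per-trial windows fall at exact arc-length offsets.

## Lane position

ρ(t) is the distance from the head to the inner road edge. Per sample the
nearest centre-line vertex is located (k-d tree), and the *lateral component*
of the head offset — the cross product of the vertex tangent with the offset
vector — is taken, signed by side, then converted as ρ = 2 − (offset toward
the inner edge). Using the tangent-orthogonal component rather than the raw
Euclidean nearest-vertex distance matters: the raw distance to a discrete
vertex set overestimates by up to (Δs/2)²/(2d) (millimetres at 0.25 m
spacing), while the lateral component's error is bounded by Δs²·κ/8
(≈ 0.06 mm at radius 35), which the test suite verifies against a 1 mm
brute-force polyline. d_center = ρ − 2 is positive toward the outer edge;
the maximum departure statistic is max |d_center|.

Series are linearly resampled to an exact 90 Hz base over the trial's time
span (the resampler is the identity on already-uniform input). Traces whose
nearest-centre distance everywhere exceeds 10 m are rejected as corrupt.

All per-trial statistics are averaged over the **middle 40% of the trial's
traversal time**, including the straights: for a 140 m trial at 19 m/s the
window is 2.21–5.16 s, which is where the driver negotiates the central part
of the bend. The same window is applied to gaze summaries and to maximum
departure (whose window the task description leaves open; using one window
keeps the summaries comparable, and the fraction is a config knob).

The per-participant flow-sensitivity contrast is
Δρ = 0.5·((ρ_l − ρ_m) + (ρ_l − ρ_h)) on the per-density mean lane positions.
Mean trajectories across trials/participants carry pointwise t-distribution
95% confidence bands.

## Gaze chain

Processing starts from per-eye unit gaze directions in the head frame with
tracker confidence; pupil detection and 3D eye-model fitting are upstream and
out of scope.

1. **Gating**: confidence strictly below 0.75 → null. Nulls are never
   replaced downstream; every stage propagates them.
2. **Cyclopean merge**: the two 120 Hz streams are interleaved on the union
   of their timestamps (240 Hz effective). At each output time the
   temporally nearest valid sample of each eye within half an eye frame
   (≈4.17 ms) contributes; the mean vector is renormalized; both-null → null.
   The explicit pairing window is the contract that makes asynchronous
   streams well-defined; one consequence is that an isolated single-eye
   dropout is absorbed by the partner eye.
3. **World transform**: head orientation (90 Hz quaternions) is spherically
   interpolated (Slerp) to the gaze timestamps and applied to the cyclopean
   direction; translation is ignored.
4. **Angles**: azimuth is the signed angle of the ground-plane projection
   from body-forward (positive rightward); elevation the angle above the
   ground plane. Gaze parallel to the ground normal has no defined azimuth
   and becomes null. Reconstructing a direction from (az, el) and re-deriving
   the angles is the identity to 1e-9 away from the poles.
5. **Velocity**: finite differences per component — central where both
   neighbours are valid, one-sided at boundaries or next to nulls — then a
   rolling mean and a rolling median, kernel 5 each (~20 ms at 240 Hz),
   windows truncated at series edges (no padding), nulls kept null. Speed is
   γ̇ = √(aż² + ėl²).
6. **Threshold**: per participant, 1.3 × the 95th percentile of the speed
   distribution, clamped to [15, 60]°/s. The bulk of samples are
   inter-saccadic, so the upper quantile tracks the velocity noise floor;
   the multiplier is calibrated so the default synthetic participant lands
   near 25°/s (measured ≈26°/s). A fixed-threshold policy (e.g. 60°/s for a
   participant with a known high noise floor) is available in the run
   configuration.
7. **Detection**: maximal runs of speed above threshold lasting ≥ 25 ms;
   sampling gaps longer than 3 nominal intervals split runs. A property test
   checks exact agreement with a naive run scanner on random series.
8. **Trial summaries**: over the middle-40% window, mean azimuth (negated on
   left turns so that looking into the bend is positive on both directions),
   mean elevation, and saccade count. Trials whose saccade count falls
   outside the participant's mean ± 3 SD are dropped.

## Perimetry

Monocular 24-2 (6° spacing, ±27°×±21°) and 10-2 (2° spacing, central ±9°)
sensitivity grids are interpolated onto a common 1°-step cell-centre grid:
piecewise linear on the test-point triangulation, with nearest-value
extrapolation to the edges for the 24-2 tests only — the 10-2 contributes
only inside its own extent — then averaged cellwise across the four inputs.

Cells are blind when sensitivity falls below a criterion, 10 dB by default;
the criterion is a required user choice, not a property of the data. Areas
are in squared degrees with cos(elevation) solid-angle weights (these match
exact lat-long spherical cell areas to <0.1%; flat counting differs by ~2%
over this field extent). "Central 10°" is a 10°-radius disk around fixation;
"central 24°" the ±24° square clipped to the grid; both are config options
since the regions' shapes are conventions. Deficit-area measures correlate
with Δρ via Pearson's r.

## Synthetic data

The generator's job is the statistical structure the analysis assumes, not
cognitive fidelity; its defaults are the study conditions, and the free
parameters below are documented as free.

**Driver** (lookahead lane-offset tracker): the head follows the centre line
offset toward the inner edge by a per-density cut gain inside arcs (zero on
straights), smoothed by a centred moving average over a 1 s lookahead and a
first-order lag (rate 2 s⁻¹), plus smooth lateral Gaussian noise (SD 0.12 m,
0.1 s correlation scale — across trials the lane position at a fixed time
has exactly this SD, which the CI-width test uses). Samples at a nominal
90 Hz with 0.5 ms timestamp jitter. Cut gains default to 0.15/0.45/0.50 m
for low/medium/high density: corner cutting grows from low to medium and
saturates, the direction of effect the analysis is designed to detect.
Parameter sets whose reference path leaves the 4 m roadway are rejected.

**Gaze**: the latent azimuth points toward the inside of the upcoming bend
with eccentricity (400 deg·m) × curvature — 11.4° at radius 35 down to 5.3°
at 75 — ramped over ~1 s. Optokinetic nystagmus rides on top: a slow phase
at 0.25 × the vehicle yaw rate with 1.5° quick-phase resets executed at
10°/s. The quick phases are deliberately slow enough to stay below the
saccade threshold so that the detector's ground truth is exactly the
injected saccades: 6 per trial (within the 5–6.5/trial range typical of such
tasks), 4° amplitude, 40 ms raised-cosine profile (peak ≈157°/s, ~4× the
threshold), placed in equal slots within each trial with recorded intervals.
No quantitative nystagmus amplitude is available to match, so these are free
parameters. Elevation is constant at −7.5°. Per-eye streams sample the
latent signal at 120 Hz with a fixed half-frame phase offset (240 Hz
effective), 0.10° angular noise per sample (the scale of the tracker
precision such systems report), confidence ~N(0.95, 0.03) with 2% dropouts
to below 0.75. Head yaw is 0.3 × the latent eccentricity about body-forward:
gaze is generated in the seated lab frame (body-forward +y), where azimuth
stays centred near zero as in recordings from a fixed driving seat —
accumulated vehicle heading over 144 chained turns is unbounded and cannot
be that frame.

**Perimetry**: one hemifield below criterion (≈0.5 dB) except a spared
central disk, intact cells ≈30 ± 1.5 dB, independent noise per eye and test.
The test-point lattices are simplified rectangular versions of the clinical
patterns (6°/2° spacing at half-offsets), which preserves extent and spacing
but not the exact clinical point count.

**Cohorts**: for group-level statistics, condition-cell tables are generated
directly — subject random intercept (SD 0.25 m) plus independent cell noise
(SD 0.15 m) plus optional additive group/density effects around a 1.9 m
baseline. This is the scale the ANOVA operates on; per-sample simulation
adds nothing to its calibration.

What passing tests on synthetic data do *not* show: the generator has no
blinks, no slippage-induced drift, no pursuit, no systematic calibration
error, no correlation between steering difficulty and gaze noise, and its
driver has no dynamics beyond a first-order lag. Results on real recordings
depend on those properties; the pipeline's contracts (null propagation,
windowing, detector behaviour, statistics) are what the suite establishes.

## Statistics

The mixed ANOVA is the classical univariate split-plot decomposition: one
between-subjects factor and fully crossed within-subject factors. Each
within effect is carried by an orthonormal contrast set over its cells
(Kronecker products of per-factor contrasts); per-subject contrast scores
are analysed against the group design with Type III (unweighted group means)
sums of squares, so modestly unequal group sizes are handled. Per effect:
Mauchly's test at α = 0.05 gates the Greenhouse–Geisser correction, and the
corrected dfs/p are always reported alongside the uncorrected ones, with
partial η² as SS_effect/(SS_effect+SS_error). A constant dependent variable
yields F = 0 throughout. The implementation is cross-checked against an
independent routine on single-within designs and against a hand-computed
toy decomposition; missing cells abort with a message rather than being
imputed, as no imputation rule is defensible here.

Two-sample comparisons use Levene's test to select the pooled vs Welch
branch; a natural-log transform is applied when requested, or automatically
when a Shapiro check fails in either group and all values are positive, and
the decision is recorded in the result. Kruskal–Wallis uses midranks; the
all-tied degenerate case returns H = 0, p = 1 by convention. Bonferroni
adjustment multiplies by the number of tests and caps at 1.
N_eff = 4n₁n₂/(n₁+n₂) quantifies the power of an unbalanced two-group
design: 9 vs 21 behaves like ≈25 balanced subjects.

## Problem sizes and numerical choices

The validation suite and the acceptance script use: 100 seeds for schedule
balance; 10⁴ random head positions against a 1 mm-resampled polyline oracle
(observed error < 0.5 mm, bound 1 mm); 200 simulated trials for
saccade-count recovery (±1 tolerance) and 1000 random series for detector
equivalence; 20 cohorts for density-ordering recovery plus one
flow-insensitive driver (|Δρ| below twice its standard error); 500 null
cohorts of 10 subjects per group for the type-I calibration (rate within
[0.03, 0.07] at α = 0.05). These sizes make the checks stable at the few-
percent level while keeping a full run in the tens of seconds.

Ties and degenerate inputs: a head sample exactly on the centre line has
d_center = 0; gaze exactly along the ground normal has null azimuth;
rotations are validated orthonormal to 1e-6 before use; merged gaze vectors
are renormalized after averaging; filter windows shrink at series edges
rather than padding.

## Known limitations

- The within-trial window and the detector minimum duration interact: a
  saccade straddling a trial boundary or window edge can be counted on
  either side.
- The adaptive threshold assumes saccades are rare in the speed
  distribution; a participant saccading continuously would inflate their own
  threshold.
- Compositing averages dB values across tests and eyes directly; no
  age-normalisation or test-reliability weighting is applied.
- The ANOVA requires complete cells; designs with structurally missing cells
  need a mixed-model approach outside this package's scope.
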