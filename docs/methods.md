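# Methods

## Scoring model

The engine scores each status-bearing goal (a leaf of the goal tree;
subgoals where a goal has them) per region and year on [0, 1], reported
×100. Five quantities are assembled per leaf:

1. **Status** *x*: current benefit over a reference point, capped at 1.
   Exceeding a reference never scores above 100 — reference targets are
   "at or above" targets.
2. **Trend** *T*: OLS slope of status on year over the window ending at
   the assessment year (default 5 years), multiplied by the window
   length and divided by the status at the window start — a proportional
   change — clipped to [−1, 1]. The trend is computed from the status
   series the engine itself produces, not supplied as a layer. In the
   first assessment years the window is truncated; with at least two
   in-window values the regression is run on what exists, with fewer the
   trend is set to 0 (a flat, not missing, outlook). A window-start
   status of exactly 0 also gives a trend of 0 (the proportional change
   is undefined).
3. **Pressures** *p*: each bound pressure layer is already rescaled to
   [0, 1] upstream (1 = maximum negative impact). Within the ecological
   and social categories layers combine by their sensitivity-rank
   weights; *p* is the unweighted mean of the categories present.
4. **Resilience** *r*: regulatory, ecological-integrity and social
   categories, weighted within and averaged across the categories
   present, then **capped at *p***: once a pressure is adequately
   addressed, further resilience must not inflate the outlook.
5. **Likely future status** and **score**:
   *x̂*F = (1/(1+δ))(1 + β*T* + (1−β)(*r*′−*p*))*x*, clipped to [0, 1]
   (the raw formula can exceed 1 at high status with positive trend);
   *I* = (*x* + *x̂*F)/2.

Defaults: β = 0.67 (trend twice as predictive as pressures/resilience),
δ = 0 (future valued equally), ω_g = 1 for every goal. Subgoals average
(unweighted) into goals, goals into the region index, and regions into
study-area scores weighted by marine area over the regions flagged
`in_study_aggregate` — a study may assess more regions than it
aggregates. The study-area index is the area-weighted mean of region
indices (the alternative — aggregating each goal first and averaging
the rollups — differs only when goals are missing in some regions and
is available through `study_area_score` on goal columns).

**Missing data.** Missing is NaN everywhere, never zero. A missing
status yields missing trend, future and score for that leaf; every mean
renormalizes over what is present; Clean Waters is the exception — its
geometric mean is deliberately not renormalized, because a missing
contamination component makes the product meaningless.

## Goal models

* **Wild-capture fisheries** — each assessed stock scores on a
  harvest-control-rule curve over *B*/*B*<sub>MSY</sub>: 0 at 0.05,
  rising linearly to 1 at 0.8, a plateau to 1.5, declining to an
  underexploitation floor of 0.25 at 3.0. With *F*/*F*<sub>MSY</sub>
  present the score is multiplied by a mortality factor: 1 up to 1.2,
  linearly to 0 at 2.4. The published curve is specified only
  qualitatively (penalize both over- and under-exploitation, target at
  *B*/*B*<sub>MSY</sub> = 1), so every breakpoint is configurable.
  Region status is the catch-weighted mean over assessed stocks times an
  unassessed-stock penalty — the assessed fraction of catch raised to γ
  (default 1), the simplest multiplier consistent with the verbal
  definition. Stocks managed sustainably without an MSY reference
  (herring-like) are exempt: excluded from both the mean and the
  penalty. A region whose catch is entirely unassessed gets no score.
* **Aquaculture** — production over a tenure-based potential; regions
  without tenures are unscored, and the goal renormalizes.
* **Wild-capture salmon** — indicator fisheries scored
  max(0, 1 − |catch − target|/target) and averaged study-wide; overshoot
  is treated as unsustainable like undershoot (symmetric by design,
  configurable).
* **Resource-access components** — herring (3-year running mean of the
  spawn index over a historic reference), shellfish (1 − area-weighted
  closed fraction), salmon escapement (mean of min(ratio, 1) over
  indicator stocks, study-wide), licenses (license share over
  max(population share, 0.15)); unweighted mean of present components.
* **Livelihoods** — employment-rate and wage no-net-loss components
  (current over the prior-five-year mean, capped), averaged; computed
  separately for First Nations and non-First Nations communities.
* **Tourism** — a single no-net-loss component on visitation. Because
  carried-back extension fills the years before a truncated series
  begins, the first data year always scores exactly 100.
* **Protected places** — min(fraction/0.30, 1) averaged over the
  coastal-marine and coastal-watershed zones.
* **Species / iconic species** — 1 − area-weighted mean extinction risk
  with LC→0, NT→0.2, VU→0.4, EN→0.6, CR→0.8, EX→1 (configurable);
  national (COSEWIC) assessments supersede global (IUCN) for the same
  species. The plain 1 − mean form is used, with no extinction-floor
  rescaling.
* **Habitat services** — service-weighted current over reference
  extents, min(Σw·C / Σw·R, 1); carbon-storage and coastal-protection
  subgoals differ only in their weights. The biodiversity habitats
  subgoal averages the extent component with 1 − intensity condition
  components for trawl-pressure layers.
* **Clean waters** — geometric mean of nutrient, chemical, pathogen and
  debris components (1 = pristine); a zero annihilates the goal.

## Gapfilling

Interpolate linearly inside the observed span first, then extend with
LOCF/NOCB beyond it — matching the separate treatment of periodic and
truncated series; the composition is idempotent and never alters an
observed value. Layers are filled over the study grid plus a five-year
lookback so rolling baselines and early trends are defined. Gapfilled
values are propagated as ordinary values (no downweighting); the filled
grid is auditable through the validation report.

## Sensitivity analysis

Two fixed-effects panel regressions per goal, lag λ ∈ {1..6}:

* (p_ecol,t+λ − p_ecol,t)/p_ecol,t = α + β₁·r_reg,t + β₃·r_soc,t
* (x_t+λ − x_t)/x_t = α + β·p_t, run for p = p_ecol and p_ecol + p_soc

Region and year enter as full indicator sets with one reference level
each. Ecological resilience is excluded from the first model (its layer
is near-constant over a study window, making the design singular) and
social pressures from the response (they share source data with social
resilience). Zero-denominator observations are dropped and counted, not
offset. Fits go through statsmodels OLS; the LOOCV RMSE uses the exact
PRESS identity (residual over 1 − leverage), which for least squares
equals the literal leave-one-out refit loop — the tests verify the
equality to 1e−10. Model selection minimizes LOOCV RMSE over
(λ, component-subset) candidates including intercept-only; ties break
deterministically to fewer parameters, then smaller λ. Trend tables are
simple per-scope OLS of score (0–100) on year — region terms are not
included in the study-area fit, which operates on the already-aggregated
series. Significance stars use 0.001/0.01/0.05/0.1.

## Synthetic studies

`ohibc.synth` generates the full input surface from one master seed
(split deterministically per layer via `numpy` seed sequences — byte-
identical bundles per (spec, seed)). The default spec mirrors the shape
of the motivating study: 8 regions of 5,000–60,000 km² with one excluded
from the study aggregate; years 2001–2016; annual layers; census-like
5-year periodic layers; decadal habitat extents observed 1990/2000/2010;
a visitation series truncated to 2007 (so the first-year-equals-100
behavior is exercised); a static debris layer; one region whose catch is
entirely unassessed (so a missing subgoal flows through every rollup);
per-region stochastic stock sets plus an exempt stock; study-wide salmon
indicator stocks; species risk tables with deliberate COSEWIC/IUCN
duplicates. Noise is applied before [0, 1] clipping so bound enforcement
is exercised. Baselines, trends and noise levels are set to produce
high-and-rising scores of the magnitude a healthy temperate coast
reports; they are structural placeholders — the generator emulates
shape (sampling patterns, truncation, bounds, missingness), not the
statistical distributions of any real dataset, so passing tests
demonstrate correctness of the machinery, not realism of the scores.

Alongside each bundle the generator writes an expectations table
computed by an independent plain-loop transcription of the scoring
equations (`synth/expected.py`) that shares no code with the engine;
engine-versus-expectations agreement (to 1e−9 over all ~12,000 values)
is the pipeline's primary oracle. Targeted generators construct stock
sets hitting prescribed HCR scores by inverting the rising limb of the
curve, and regression panels whose proportional-change responses follow
known coefficients with the same reference-level convention as the
fitted design, so noise-free fits recover truth exactly (≤1e−8) and
noisy fits are testable for CI coverage and type-I calibration.
Simulated panels use 8 regions × 16 years (≈112–120 usable
observations per fit), and the seeded suites use 100 replicates for
coverage/calibration and 50 for selection consistency — sizes chosen so
the binomial acceptance bounds are sharp while the whole simulation
suite runs in well under a minute.

## Numerical choices and limitations

* Internal scale is [0, 1]; the reporting layer multiplies by 100 and
  rounds for display only. CSV round-trips use full-precision float
  parsing.
* Proportional-change responses are not winsorized; heavy-tailed
  responses from near-zero denominators are visible in the dropped-
  observation count instead.
* LOOCV leaves out one (region, year) observation at a time; block
  (region-level) cross-validation is not implemented.
* No spatial processing, no stock-assessment estimation, no inflation
  adjustment: layers arrive prepared. No autocorrelation-robust or
  mixed-effects variants of the panel models — the regressions are
  deliberately the simple ones, and their causal interpretation is
  correspondingly weak.
* Province-wide resilience layers (identical across regions) are
  collinear with year effects; such coefficients are reported as fitted
  (minimum-norm pseudoinverse) and model selection typically discards
  them — mirroring the data limitation rather than hiding it.
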