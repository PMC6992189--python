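# ohibc

A tested, reusable implementation of an Ocean Health Index (OHI)
assessment engine for regional, multi-year coastal studies of the kind
run for British Columbia's coast: eight goals scored annually per region
from prepared data layers, combined with pressures and resilience into
composite 0–100 index scores, plus the downstream time-series analyses
(score trends and lagged management-sensitivity regressions).

It is written for analysts who already have their raw data prepared into
"data layers" — long-format tables of `(layer_id, region_id, year,
value)` — and want a transparent, configurable, fully testable scoring
pipeline rather than a one-off script. A seeded synthetic-study
generator with independently computed expected values makes every stage
testable without any external data.

## The model

The present **status** of goal *g* in a region is the benefit delivered
relative to a reference point, capped at 1:

&nbsp;&nbsp;&nbsp;&nbsp;*x* = *X* / *X*<sub>ref</sub>

References include MSY-based stock targets (*B*/*B*<sub>MSY</sub>,
*F*/*F*<sub>MSY</sub> under a harvest-control-rule curve with an
unassessed-catch penalty), rolling "no net loss" baselines (mean of the
prior five years), policy targets (30% protected area), historic habitat
extents, and zero contamination (Clean Waters is a geometric mean of
four components). **Likely future status** projects five years ahead
from the recent trend *T* (proportional change in status over the
previous five years), pressures *p* and resilience *r*:

&nbsp;&nbsp;&nbsp;&nbsp;*x̂*<sub>F</sub> = (1/(1+δ)) · (1 + β*T* + (1−β)(*r*−*p*)) · *x*

with β = 0.67 and δ = 0 by default, and resilience capped so that
*r* ≤ *p* — once a pressure is adequately addressed, additional
resilience cannot inflate the outlook. Each goal scores
*I* = (*x* + *x̂*<sub>F</sub>)/2; a region's index is the ω-weighted
mean over its scored goals; study-area scores are marine-area-weighted
means over participating regions. Missing values propagate and every
aggregation renormalizes — nothing is imputed.

Incomplete layers are gapfilled transparently: linear interpolation
between observed years for periodic series, last-observation-carried-
forward / next-observation-carried-back extension for truncated ones.

The analysis layer fits OLS score-on-year trends (points per year) and
the management-sensitivity regressions: proportional change in
ecological pressure at *t*+λ on resilience components at *t*, and
proportional change in status at *t*+λ on pressures at *t*, with region
and year fixed effects, λ ∈ 1..6, and candidate models compared by
leave-one-out cross-validation RMSE (exact PRESS identity).

## A worked example

```sh
python examples/run_synthetic_assessment.py
```

```
Study-area scores, 2016 (area-weighted over the 7 aggregate regions):
  HAB      99
  FP       80
  FNA      88
  LIV     100
  TR      100
  SP       75
  BD       91
  CW       80
  Index    89

Region Index scores, 2016: 87 (lowest) to 90 (highest)
```

Each number is a 0–100 score: 100 means that goal's benefits are at
their reference point (e.g. all stocks at *B*/*B*<sub>MSY</sub> = 1, 30%
of coast protected, zero contamination) with an equally healthy outlook;
the Index row averages the eight goals. `examples/` holds three more
short scripts: stock scoring under the harvest control rule, gapfilling
and no-net-loss scoring, and recovery of a known management effect from
a simulated panel.

The same pipeline is scriptable from the shell:

```sh
ohibc synth --out study --seed 42        # synthetic input bundle
ohibc validate --config study/config.yaml
ohibc calc --config study/config.yaml --out study/out
ohibc trends --scores study/out/scores_raw.csv --out study/out
ohibc sensitivity --panel study/out/panel.csv --out study/out
```

Every default — β, δ, the trend window, the HCR breakpoints, risk-
category weights, the protection target, goal→layer bindings — is
overridable in `config.yaml`; unknown keys are rejected.

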