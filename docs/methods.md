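# Methods

## Scope and model

The package assesses riverine ecosystem health from a panel of 16
indicators observed at monitoring stations over several years. Ten
indicators describe natural functions (flow deviation C1, ecological flow
satisfaction C2, riparian status C3, river connectivity C4, wetland
retention C5, dissolved oxygen C6, nutrient concentration C7, heavy metals
C8, biodiversity C9, fish C10) and six describe social functions (flood
control C11, water function zone compliance C12, water-resource utilization
C13, water supply C14, hydropower development C15, public satisfaction
C16). The pipeline has five stages: threshold scoring, entropy weighting,
the coordination model per evaluation unit (station-year), length-weighted
whole-river aggregation, and grade classification.

## Threshold scoring

Each indicator's scoring criteria form a ladder of (score anchor,
threshold) breakpoints on the anchor set {0, 0.2, 0.3, 0.4, 0.6, 0.8, 1};
criteria rows may omit anchors, in which case interpolation simply runs
between the nearest defined anchors. Benefit ladders (e.g. dissolved
oxygen) clamp to 1 at or above the optimal threshold and to 0 at or below
the worst; cost ladders (e.g. pollutant concentrations) mirror this.
Numerical choices:

- **Anchor exactness.** A value exactly at a threshold returns that
  anchor's score exactly (no float interpolation error at breakpoints).
- **Steps.** Equal adjacent thresholds encode a discontinuity (the C2
  flow-guarantee criteria step from 0.2 to 0 at the lowest threshold). A
  value at the shared threshold takes the *higher* score — ties break
  optimistic, consistent with reading the interpolation intervals as
  half-open on the left. Scores strictly inside a step have no raw
  preimage; the generator snaps them to the nearest attainable score with
  a warning.
- **Validation.** Ladders whose thresholds reverse against their
  orientation are rejected at config-load time with the indicator named.
  The shipped connectivity (C4) criteria keep only the monotone prefix of
  the published row, whose tail is internally inconsistent as printed; C4
  scores therefore clamp at 0.4 on the unhealthy side.
- **Units.** All percentages are fractions in [0, 1] internally; config
  blocks may declare `units: percent` and their thresholds are divided by
  100 on load.

Composite indicators score each component on its own ladder and combine
with the **minimum** (C2 flow periods; C7 nutrient and C8 metal
concentrations — one bad constituent compromises the indicator) or the
**mean** (C9/C10 biological sampling points). The combination rule for C2
is not fixed by the published criteria; the minimum was chosen as the
conservative reading (both spawning- and normal-period flows must be
satisfied). C3 and C16 arrive pre-scored (guide-based riparian composite,
questionnaire mean) and are only range-validated.

Water-resource utilization (C13) uses a parabola
`score = (a·r² + b·r)/100` with a = −1111.11, b = 666.67: the vertex at
r = 0.30 scores 1 (a 30–40% utilization rate is the recognized healthy
band) and the score is defined as exactly 0 for r ≥ 0.6, the cap beyond
which exploitation is considered unhealthy. The coefficient magnitudes
follow the published criteria; the quadratic coefficient must be negative
for an interior maximum, and the explicit cutoff absorbs the ~2·10⁻⁵
residual the printed coefficients leave at r = 0.6.

## Entropy weighting

Weights are computed over all station-years jointly (a single basin-level
weight set); computing them per station is possible by subsetting the
score matrix before calling `entropy_weights`. `0·ln 0 := 0` (the standard
limit) rather than epsilon-flooring, so results are exactly reproducible;
all-zero columns and matrices with fewer than two units are rejected, as
are score values outside [0, 1] (no silent clipping). A column with no
variation has entropy 1 and weight 0; if *every* column is uniform the
weights are undefined and an error is raised.

## Coordination model

For one unit, f and g are the subsystem-weighted mean scores, *normalized
by the subsystem weight sums* so they live on the same [0, 1] scale as the
scores; the subsystem weights re-enter through T = W_natural·f +
W_social·g. This normalization is the only reading under which T lies
between f and g and the published whole-river statistics re-derive
consistently. The chain is C_fg = √(1 − fg/((f+g)/2)²), C = 1 − C_fg²
(algebraically fg/((f+g)/2)², verified to 1e-12 in tests), D = √(C·T),
E = f/g. Closed-form limit used as a test: f = g ⟹ C = 1, T = f, D = √f,
E = 1. Degenerate inputs (f + g = 0, g = 0) raise rather than return
sentinels. A tiny negative under the C_fg square root from float
cancellation is truncated to 0.

## Whole-river aggregation

F = Σ f_i·L_i/L and G = Σ g_j·L_j/L over the stations' observed segment
lengths, then the same chain on (F, G). The segment partition is a
required input (`ReachLayout`); where it is unknown,
`ReachLayout.equal_segments` provides the documented equal-split default
used for the packaged three-station example. Aggregation is applied per
year; multi-year averaging is deliberately not provided, since assessments
report years separately.

## Grades

T and D grade on five uniform bins over [0, 1], half-open [lower, upper)
with the top bin closed — so 0.799 is "moderately coordinated" and 0.800
"highly coordinated", matching the published gradings either side of the
boundary. E grades on <0.8 (natural functions lag), [0.8, 1.2] closed at
both ends (synchronized; the published band is written inclusively), >1.2
(social functions lag). Alternative bins can be supplied as YAML.

## Synthetic data

The generator emulates the study layout — three main-stem stations
(upstream, midstream, downstream) × four years × 16 indicators — by
drawing a target score per cell and inverting the indicator's scoring rule
to emit raw values that re-score to the target within 1e-9 (flat preimage
regions invert to the region boundary; the ascending parabola branch is
used for C13). Defaults, chosen once to mirror the reported per-indicator
levels of such a basin: means of 0.30/0.29 for the poor hydrology
indicators, 0.98/0.90/0.93 for the excellent water-quality indicators,
0.54/0.71 for biology, 0.30 for utilization, 0.71–0.90 for the social
indicators; truncated-normal spread 0.05 (a Beta alternative is available);
no station gradient unless requested. Per-indicator random substreams are
derived from (seed, CRC32 of the indicator id), so adding or removing an
indicator never shifts the other draws and identical scenarios are
byte-identical.

What the generator does **not** emulate: temporal autocorrelation, cross-
indicator correlation (e.g. discharge driving both flow deviation and
nutrient dilution), measurement error in the raw units, and within-year
sampling variation. Passing tests therefore demonstrate the pipeline's
correctness and invariances, not distributional realism of any specific
basin.

## Published reference values

A packaged fixture transcribes the published whole-river statistics of the
Lhasa River (2011–2014; Pangduo/Tanggya/Lhasa stations; 551 km main stem):
per-year g and E, per-station f and E, the printed T and D, and the
0.67/0.33 subsystem split. The published per-indicator weight table is not
reproducible from the text (it lives in an appendix, and the raw score
matrix is only available as a figure), so tests validate the weighting
stage by its mathematical properties instead. Since the printed inputs are
rounded to 3 decimals, re-derived statistics are compared at ±0.005.

## Problem sizes

Tests and the acceptance script run on the 3 × 4 × 16 study-scale panel
(plus a 1000-unit panel for the distributional check); the reference
re-derivations are closed-form and instantaneous.

## Known limitations

- Only a single main-stem chain of stations is supported; no tributary
  topology.
- Exactly two subsystems; no multi-subsystem coupling generalization.
- Subjective (e.g. AHP) weighting and subjective–objective combination are
  out of scope.
- The carry-forward missing-data policy reuses the last earlier year of
  the same station; it never extrapolates backwards or across stations.
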