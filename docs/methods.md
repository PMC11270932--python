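# Methods

## The model

`agingccd` evaluates how well three interacting systems develop *together*:
the elderly population (U1), the demand for healthcare resources (U2) and
the supply of healthcare resources (U3). Each system is summarized by a
composite score built from observed indicators, and the joint behaviour of
the three scores is summarized by a coupling coordination degree.

### Entropy-weight composite scores

For indicator *j* observed on samples *i* (here: years of a region's series,
or regions within a year), with polarity reflecting whether growth improves
the subsystem:

1. **Min–max normalization**
   x′ = (x − min)/(max − min) for positive indicators,
   x′ = (max − x)/(max − min) for negative indicators, so x′ ∈ [0, 1] with
   1 always meaning "best".
2. **Proportions** Y = x′ / Σᵢ x′.
3. **Information entropy** e = −k Σᵢ Y ln Y with k = 1/ln m (m samples) and
   0·ln 0 := 0, implemented by masking zero proportions rather than adding
   an epsilon (an epsilon perturbs e in the fourth decimal, which the
   reproduction checks resolve).
4. **Redundancy** d = 1 − e; an indicator whose values are concentrated on
   few samples has low entropy, high redundancy, and therefore high
   discriminating power.
5. **Weights** w = d / Σ d, renormalized *within each subsystem* so each
   subsystem's weights sum to 1 (the published weight table for the national
   analysis sums to ≈1 per subsystem, which pins down this convention).
6. **Composite score** U = Σⱼ wⱼ x′ⱼ per region-year. With weights summing
   to one and x′ ∈ [0, 1], U ∈ [0, 1], reaching 1 exactly when every
   indicator in the subsystem is at its best value over the window.

A configuration switch `score_base="proportion"` instead computes
U = Σ wⱼ Yⱼ. This variant is retained because some formulations write the
composite score against Y; it caps U far below 1 (shares over m samples sum
to one), which is inconsistent with composite scores that are reported to
reach 1, so the normalized base is the default.

### Coupling coordination

With β = (1/3, 1/3, 1/3) by default (the three systems treated as equally
important):

- **Coupling degree** C = [U1·U2·U3 / ((U1+U2+U3)/3)³]^(1/3) ∈ [0, 1] — a
  pure balance statistic (an AM–GM ratio), equal to 1 iff U1 = U2 = U3 > 0.
  The all-zero triple is a 0/0; it is defined as C = 0 (the "disorderly
  development" point class) with a warning.
- **Comprehensive level** T = β1·U1 + β2·U2 + β3·U3.
- **Coordination degree** D = √(C·T), so D² = C·T holds to 1e−12 by
  construction and is asserted in the tests.

Classification: C is labelled by a six-stage scheme with point classes at
0 and 1 and left-closed intervals [0, 0.3), [0.3, 0.5), [0.5, 0.8),
[0.8, 1); D by a five-class scheme (<0.20, [0.20, 0.40), [0.40, 0.60),
[0.60, 0.80), [0.80, 1]) with an associated coordination type; and a series
of T values by the objective quartile method: empirical quartiles with
linear interpolation (the common "type 7" rule), classes below Q1 / [Q1, Q2)
/ [Q2, Q3) / ≥ Q3, ties deterministically assigned to the higher class. The
quartile rule is recorded in the run metadata so the classification can be
re-checked under alternatives.

## Sample axis and normalization window

For a single-region time series the samples are the years (m = number of
years). For multi-region panels the default is per-year cross-sections over
regions, with weights averaged across years; pooled region-years is
available. Normalization min/max is taken over the same sample grouping.

Min–max normalization over the panel's own span forces every indicator to
hit 0 (and 1) somewhere in the window. When all indicators of a subsystem
trend monotonically, the boundary year collapses to U = 0, and C and D
degenerate there. The `window=(first, last)` option widens the min/max
window beyond the observed span, with the boundary years synthesized by
linear extrapolation of each series' edge slope (clipped at zero, since
yearbook-style quantities are nonnegative). These synthetic boundary years
participate in min/max **only** — never in proportions, entropy, weights or
scores. This mirrors a study design whose normalization window extends one
year beyond the reporting window at each end precisely to avoid boundary
zeros; since true boundary values are generally unpublished, extrapolation
makes the mechanism reproducible from the printed data alone. Both the
strict and the widened computation are worth reporting when boundary years
matter: for the national panel, U1(2012) is exactly 0 under the strict
window and ≈0.055 under the widened one.

## Degenerate inputs and numerical choices

- A constant indicator (max = min over its sample group) is normalized to
  0, excluded from the entropy sum, given weight 0, and reported with a
  warning; no division by zero can occur.
- A subsystem whose indicators all have zero redundancy admits no weighting
  and raises ("no discriminating indicators").
- Entropy needs m ≥ 2 samples (k = 1/ln m is undefined at m = 1); m = 1
  raises.
- e is clamped to [0, 1] against floating-point drift; weights are
  renormalized within subsystem after averaging across groups.
- Missing cells are a hard construction-time error, never imputed — the
  method has no imputation step. Units are metadata; no conversion is ever
  applied (min–max normalization is scale invariant, asserted by a property
  test).
- All reporting is at full precision in CSV/JSON; published-value
  comparisons in the tests use stated tolerances, never rounded values.

## The synthetic generator

`generate_panel` emulates a provincial-style panel: each indicator follows
`base · (1 + slope · τ^γ)` (declining analogue for negative polarity) over
the year fraction τ, plus Gaussian noise on the raw scale truncated at zero.
Defaults are chosen to resemble the national analysis: 31 regions, years
2012–2022, the national polarity mix (7 positive elderly indicators; 4
positive + 3 negative demand indicators; 6 positive supply indicators),
relative noise 3%, and whole-span relative growth of 45%/60%/70% for the
elderly/demand/supply subsystems (the order of magnitude of the national
series' 2012→2022 growth). Region heterogeneity (a development level in
[0.5, 1.5] and an imbalance tilt) is drawn once per region from the seed,
a stylized east–west development gradient. The `imbalance` knob scales the
curvature exponent γ apart across subsystems; at `imbalance = 0` and zero
noise all indicators share a single normalized trajectory, so C = 1 in
every region-year — a sharp oracle used in the tests (evaluated with a
widened window so the boundary year keeps positive scores).

What the generator does *not* emulate: spatial autocorrelation between
regions, structural breaks (e.g. pandemic-era utilization drops), reporting
artifacts, or correlated noise across indicators. Passing tests on
synthetic panels therefore demonstrate algorithmic correctness, not
robustness to real-data pathologies.

`generate_coordinated_panel` inverts the model for recovery tests: a target
profile D_t ∈ (0, 1] is realized by making the three subsystems identical
(C = 1, hence U = D²) and pinning normalization with two anchor years just
outside the target span carrying the subsystem minimum and maximum. At zero
noise the evaluated D equals the target exactly; the tests assert ±0.02.

## Reproduction of the published national analysis

The packaged national panel (Tables of elderly-population, supply and
demand indicators, 2012–2022) reproduces, via the strict-window chain, the
published elderly- and supply-subsystem weights to four decimals and the
positive demand weights within 0.01 — strong evidence that the published
weighting used exactly this method on exactly these series. The three
negative cost indicators' published weights are not derivable from the
printed series under any polarity assignment (verified exhaustively), and
the published 2022 endpoint triple (C, D, U1) is mutually infeasible under
the model's own algebra; the corresponding reproduction checks are left
failing by design, with full precision output, rather than being loosened.

## Problem sizes

All computations run in well under a second: the national analysis is
11 years × 20 indicators; synthetic panels default to 31 regions × 11
years × 20 indicators; property grids use 10⁴ random score triples.

## Known limitations

- Three-subsystem coupling only (the k-system generalization is out of
  scope), no spatial statistics, no map rendering.
- The window extrapolation is linear from the two edge years; series with
  strong curvature at the boundary will be extrapolated imperfectly.
- Quartile classification requires at least 4 values and is computed per
  region; cross-region level comparisons should use a pooled series
  explicitly if desired.
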