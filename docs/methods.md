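# Methods

## The analysis model

The feasible set Ω is the 12 treatments of a 3 cultivar ('Dalgona', 'Hero',
'Kingstar') × 2 substrate-volume (10, 20 L/slab) × 2 planting-density (3, 4
plants/slab) factorial, grown in a randomized complete block design with three
blocks and one fruit retained per plant. The pipeline maps per-fruit
measurements to per-treatment objectives and extracts the Pareto-optimal
strategies:

1. **Aggregation.** Total yield per 10 a (1,000 m²) is mean fruit weight ×
   projected plants per 10 a; the stand follows from planting geometry
   (density = 1/(distance × row spacing), projected stand = round(1000 ×
   density)). Water productivity is WP = Y / V_ir with V_ir the irrigation
   volume in m³/10a.
2. **Quality scoring.** Treatment-mean Brix is min–max normalized to 0–100
   over the trial; the panel net score (1 excellent … 5 bad) is
   reverse-normalized; the composite is α·sugar + β·netting with market
   channel weights (premium 0.7/0.3, public 0.8/0.2). Bounds are always taken
   jointly over the comparison set, so the score is a within-trial ranking,
   not an absolute scale.
3. **Economics.** Production is split over Brix grade tiers (Premium ≥ 14 °Bx,
   Superior ≥ 12, Medium ≥ 10, Inferior below; lower bounds inclusive) and
   priced per kg from the packaged wholesale price table (USD, converted at
   1,382 KRW/USD). ROI = 100 × (revenue − cost)/cost: the cost base, not the
   revenue base, is the definition consistent with the reference
   revenue/profit/ROI triple (29,127; 21,213; 268.0%).
4. **Dominance.** With all objectives oriented to maximize (minimize-sense
   columns are negated, never inverted), a dominates b iff a ≥ b in every
   objective with at least one strict inequality. The frontier is computed by
   an exact O(n²) all-pairs scan; at n = 12 (and anything up to thousands of
   candidates) nothing faster is warranted, and any faster algorithm would be
   required to match it exactly. Rows with identical objective vectors are
   all retained (strictness means neither dominates). The frontier is
   invariant under strictly increasing per-column transforms, so running it
   on raw or 0–100-normalized values is equivalent; the normalized matrix is
   kept for reporting only.

## Synthetic-trial generator

Real per-fruit data for the trial are not deposited, so the generator stands
in for them. Each response r of fruit f in treatment t, block b is drawn as

    y = μ_t(r) + β_b(r) + ε,   ε ~ N(0, σ_r²)

with μ_t the cell-mean surface encoded as an exact factorial decomposition
(grand mean + main effects + all interactions) of the packaged calibration
table, and β_b optional Gaussian block effects (default sd 0 — no block
variance is reported for the trial).

Calibration sources, per treatment:

- **weight** = total yield / plants per 10 a, an identity that reproduces the
  reported extremes (e.g. Kingstar 10 L: 1.68 kg at 3 plants/slab, 1.40 kg at
  4) and keeps the simulated yield reconstruction consistent with the
  reference yield table;
- **length, diameter, flesh thickness, net score**: transcribed reference
  means;
- **Brix**: only the extremes are reported (14.5 °Bx peak for Dalgona 10 L/3
  plants; ~10.1–10.3 °Bx floor for Kingstar at 20 L). The packaged per-
  treatment Brix means are therefore calibrated estimates, chosen once,
  constrained by those extremes, by the consistent 10 L > 20 L pattern within
  every cultivar, by a small negative density effect, and by the requirement
  that Dalgona 10 L/3 plants carries the top composite quality score (it is
  the labelled quality-optimal strategy). They are estimates of the study
  conditions, not measurements;
- **irrigation volume** = yield / WP, so the WP identity recovers the
  reference values exactly (per-treatment irrigation is never reported
  directly; all WP checks are self-consistency checks, and are documented as
  such).

Residual sds are free parameters (within-treatment variances are not
reported): weight 0.12 kg, length 0.45 cm, diameter 0.35 cm, flesh thickness
1.8 mm, Brix 0.40 °Bx, net score 0.12. The net-score sd reflects that the
recorded value is the mean of an 8-member panel; it also keeps the [1, 5]
clamp's truncation bias an order of magnitude below the sampling error of a
treatment mean, so mean-recovery checks are meaningful. Net scores are
generated continuous and clamped; integer panel rounding is available
(`round_net=True`) but off by default because reference treatment means (1.25)
are non-integer.

Default design size is 503 fruits allocated as evenly as possible over the 12
treatments (eleven treatments of 42, one of 41) and over blocks within a
treatment. The default seed, 20200129, is the trial's sowing date — a
documented constant, nothing more.

**What the generator does and does not emulate.** It matches treatment means,
the factorial effect structure, and the RCBD layout. It does not model
correlated responses (weight and diameter are drawn independently), skewed or
heavy-tailed residuals, or within-block spatial structure, and it does not
reproduce every reported distributional claim — e.g. grade-percentage figures
that are mutually inconsistent with any Gaussian residual around plausible
means. Passing tests therefore validate the analysis machinery under the
stated effect structure, not distributional fidelity to the real orchard data.

## Supporting statistics

- **ANOVA**: classical balanced three-way decomposition fitted by OLS
  (`statsmodels`); with balance, type I/II/III sums of squares coincide and
  SS additivity holds to 1e-8 relative (asserted in tests against an
  independent cell-means oracle). Unbalanced input is rejected; the pipeline
  first aggregates fruits to block means (one row per treatment × block),
  which is balanced by construction even when per-treatment fruit counts
  differ by one fruit. Shapiro–Wilk and Levene pre-checks are advisory log
  lines.
- **Tukey HSD**: studentized-range pairwise tests (`scipy.stats.tukey_hsd`);
  compact letters by the insert-and-absorb algorithm, so two groups share no
  letter exactly when they differ at α. Letter scope is a flag: across all 12
  treatments or within cultivar.
- **Correlations**: plain Pearson over the 12 treatment summaries —
  descriptive only, no p-values at n = 12; constant metrics yield NaN with a
  warning, never a silent 0.

## Numerical conventions and degenerate inputs

- Internal computation at full precision; rounding (yields to integers, WP and
  percentages to 1 decimal) happens only at the reporting layer.
- Planting distances that are truncated decimals of exact fractions are stored
  as fractions (100/3 cm, not 33.3 cm): the projected stand of 2,000 plants is
  only reproduced exactly.
- Scalar normalization with max = min raises; in matrix/means context a
  degenerate column scores 0 with a logged warning (one constant objective
  should not abort a report). Observations outside supplied bounds are clamped
  with a warning.
- Tier intervals are closed at the lower Brix bound (14.0 → Premium, 12.0 →
  Superior, 10.0 → Medium). The net-score tier mapping (rounded panel level
  1 → Premium, 2 → Superior, 3 → Medium, ≥ 4 → Inferior) is a configurable
  package default; no reference definition exists.
- The composite quality-score recipe (normalization of treatment means with
  premium-channel weights) is likewise a documented package choice; published
  composite values computed by unknown recipes are treated as
  non-reproducible and never asserted.

## Cost model

Seven components, USD per 10 a. Substrate depends on slab volume (1085.4 at
10 L, 1392.9 at 20 L, a 28.3% step); fertilizer (804.8 / 1085.4) and seedlings
(1306.2 / 1741.6, exactly +33.3%) depend on density. The remaining block
(labor 2000, maintenance 600, energy 800, fixed 601.6; 4001.6 in total) is
system-invariant; its internal split is arbitrary — only component-level
substrate/fertilizer/seedling values and system totals are anchored — and the
four anchored totals are 7198 (10 L/3), 7914 (10 L/4), 7505.5 (20 L/3) and
8221.5 (20 L/4), spanning the reported 14.2% system cost difference.

## Problem sizes in tests

The test suite simulates at the design size (503 fruits) for pipeline and
distribution checks, 10,000 fruits for parameter recovery (≥95% of the 72
treatment × response cells within 3 standard errors), and random matrices up
to 200 × 6 for frontier–oracle equivalence; the whole suite runs in well under
a minute.

## Known limitations

- Prices, costs, and calibration targets describe one trial, one site, one
  season, one market month; the package generalizes the machinery, not the
  numbers.
- Revenue assumes the full crop sells at the tier-mean wholesale price;
  no price-volume feedback, discounting, or multi-season amortization.
- Only 12 candidate strategies: the frontier is exact but sparse; no
  interpolation between factor levels is attempted (the 3-D wireframe style of
  presentation is visual, not a fitted surface).
- Per-cultivar frontier extraction is available, but reported per-cultivar
  optimum counts are presentation choices and are checked only as a 1–2 band.
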