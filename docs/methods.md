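# Methods

## Data model and preprocessing

A lactation is a sparse map DIM → daily yield (litres), DIM 0 = calving.
All analysis happens on the fixed grid DIM 10..280 (N = 271 daily
points): records before DIM 10 and after DIM 280 are the most error-prone
in commercial practice (variable management around calving and dry-off),
and the peak — the most informative part of the curve — falls well inside
this window.

Three exclusion rules run in a fixed order, and a rejected lactation
carries exactly the first reason that fires:

1. **Type I** — no observation at any DIM ≤ 10. Interpreted as "recording
   does not reach back to the window start": a lactation first seen at
   DIM 25 is a late start (Type I), not an early-window gap (Type II),
   which keeps the per-rule counts disjoint.
2. **Type II** — any missing day in DIM 10..70. The peak usually occurs
   in this window, and an interpolated peak would bias the very features
   the analysis extracts, so this window is never interpolated.
3. **Type III** — more than 10 consecutive missing days in DIM 70..280.
   A lactation whose last record precedes DIM 270 necessarily fails.

Kept records are gap-filled by linear interpolation between flanking
observations; a trailing gap (≤ 10 days, guaranteed by rule 3) is filled
by carrying the last observation forward — the minimal-assumption fill
where interpolation has no right anchor. Smoothing is a 10-day moving
average, centred on offsets −4..+5 and truncated at the grid edges:
centring avoids phase-shifting the peak, truncation keeps all 271 points.
Finally each curve is Z-normalized (per lactation, population SD). The
Z-step makes the clustering distance compare curve *shape* rather than
production level; per-lactation (not per-DIM-across-animals)
normalization is what that goal requires. Population SD (divide by N) is
an arbitrary but fixed convention. Constant curves cannot be Z-scored and
are dropped with a warning.

Model fitting always uses original-unit (litre) curves; only clustering
uses the Z-form. Pipeline order is interpolate → smooth → normalize.

## Distance and clustering

The dissimilarity is the RMS Euclidean distance
`d(A,B) = sqrt((1/N) Σ (m_A,i − m_B,i)²)` — Euclidean distance scaled by
1/√N, hence a metric; the scaling makes values comparable across grid
lengths (units: Z-units/day on normalized curves).

k-medoids is run as Voronoi-style alternation: assign every curve to its
nearest medoid, then replace each medoid by the cluster member minimizing
the summed distance to its cluster, until the medoid set is stable. This
variant was chosen over PAM swap search for simplicity and speed; on
small instances (n ≤ 8, k ≤ 3) the test suite verifies that the best
result over all possible initializations equals the exhaustive minimum
over every C(n,k) medoid subset, bounding the optimality loss of the
alternation itself. In routine use, initialization is
squared-distance-weighted sampling (k-means++ scheme: first centre
uniform, then P(x) ∝ D(x)² to the nearest chosen centre) with 10 random
restarts, best objective wins. All ties — assignment, medoid update, best
restart — break to the lowest index, so a seed fully determines the
result. An emptied cluster is re-seeded with the point farthest from its
current medoid (logged via the suspended monotonicity assertion: a
re-seed may raise the objective for that iteration; otherwise the
objective is asserted non-increasing at every step).

The number of clusters comes from the elbow of the best-objective
profile J(k): both axes are min-max scaled and the chosen k maximizes the
perpendicular distance to the chord joining the profile's endpoints
(kneedle-style). A curvature-free profile (J linear in k) falls back to
the smallest k. The automation replaces a visual judgement; the profile
is always written out and `--k` overrides it.

## Lactation-curve models and features

Wood `y = a t^b e^{−ct}`; Wilmink `y = a + b e^{−kt} + c t`;
Dijkstra `y = a exp(b(1 − e^{−ct})/c − dt)`. Sign constraints: all
parameters strictly positive, except Wilmink `b, c` strictly negative.
In the Wood model `a` sets the production level and `b`/`c` the rise and
decline; in Dijkstra `a` is theoretical initial production, `b` cell
proliferation at calving, `c` its decay, `d` the cell death rate.

Fitting minimizes the residual sum of squares with
`scipy.optimize.least_squares` (trust-region reflective) under bounds
that implement the open sign constraints as closed bounds at ±1e−8.
Standard errors are `sqrt(diag(σ̂² (JᵀJ)⁻¹))`, `σ̂² = RSS/(N − p)`, with a
pseudo-inverse so near-singular Jacobians (degenerate fits) yield large
SEs instead of exceptions. Initial values (Wood: mean yield, 0.2, 0.003;
Wilmink: max yield, −25, −0.05, 0.05; Dijkstra: first-day yield, 0.03,
0.05, 0.002) have the magnitudes of typical Holstein fits; a 16-point
Latin-hypercube multi-start runs if the first solve fails. A fit never
raises on a hard curve: a solver stall or a parameter on a sign bound is
reported as `converged=False` with the parameters as-is — flat no-peak
curves drive Wood's `b, c` to their bounds, and reporting that is more
informative than failing.

Closed-form features (peak DIM, peak yield, persistency) exist for Wood
and Dijkstra (table in README). Persistency — the relative rate of
decline at `t_h = (peak_dim + tf)/2`, halfway between the peak and the
end of lactation — uses tf = 280 d, the analysis-window end. Features
are flagged *not computable* (rather than returning misleading numbers)
when the parameter regime has no interior peak: `b ≤ 0` (Wood), `b ≤ d`
(Dijkstra), or a nominal peak before DIM 1 or after tf — the `b → 0⁺`
limit places the "peak" at t → 0, which is the no-peak regime, hence the
1-day floor. Wilmink features are not computed; its fitted curve still
enters the fit-error comparison. An internal-consistency identity —
the model evaluated at the closed-form peak DIM equals the closed-form
peak yield exactly — holds algebraically for both families and is tested
at 1e−9 on random valid parameter sets, cross-checking both
implementations at once.

## Cluster evaluation and statistics

The representative curve of a cluster is the pointwise mean of member
smoothed curves (litres). Two errors compare a fitted model against a
cluster: ε_f, the RMSE between the fitted curve and the representative
(litres); and ε_c, the mean over members of the RMSE between the
Z-normalized member and the Z-normalized fitted curve (unitless).
Z-transforming *both* sides of ε_c keeps it dimensionally consistent and
makes it invariant to positive affine rescaling of a member — it is a
pure shape error. Observed (non-parametric) peaks are taken from the
smoothed curves — smoothing exists precisely to stabilize the daily
maximum — with ties resolved to the earliest DIM.

Group comparisons: one-way fixed-effects ANOVA (computed from the sum-of-
squares decomposition, so the degenerate conventions are explicit: zero
within-group variance with unequal means → p = 0; all values identical →
F = 0, p = 1), then Fisher's LSD at α = 0.05 with a compact letter
display built by insert-and-absorb over groups sorted by descending mean
— groups share a letter iff their pairwise test is non-significant
(property-tested by reconstruction). P-values in [0.05, 0.1) are flagged
as trends. No multiple-testing protection beyond the LSD is applied —
unprotected LSD is anti-conservative, a deliberate caveat. "Total milk
yield DIM 10–280" is the plain sum of the 271 interpolated daily values
(no finer integration rule is warranted for daily data). Per-cluster SE
is sample SD/√n; the "pooled SE" column is `sqrt(MS_within · mean(1/nᵢ))`,
a balanced-design-style summary chosen here as the package's convention.
Clusters of size 1 are reported without SE-based tests.

## Synthetic herds

`default_archetypes()` provides four shape families whose parameter
magnitudes are typical of commercial Holstein fits: a typical multiparous
Wood curve (peak ≈ 47 L at DIM 55), a flat primiparous Dijkstra curve
(peak ≈ 37 L at DIM 141), an undulating curve (high flat Wood base ×
Gaussian dip, depth 0.25, centre DIM 150, width 30 d) and a flat no-peak
curve (36 L, −0.01 L/d trend). Parity is drawn per archetype — flat
archetypes skew primiparous, peaked ones multiparous — matching the
field observation that first-lactation cows have flatter, more
persistent curves. Noise is multiplicative by default
(`y·(1+ε), ε ~ N(0, cv²)`, default cv = 0.02), mimicking the
heteroscedastic look of raw milking data; additive noise is available.
Lactation length is uniform on last-DIM ± 30 d around a default of 360 d,
typical of recorded lactations. Structured missingness injects, with
configurable probabilities, a late start (first DIM 11–30), a 1–5-day
gap inside DIM 10–70, and an 11–25-day gap inside DIM 70–280 — one
designed trigger per exclusion rule — plus i.i.d. daily dropouts. Every
lactation carries its archetype and injected-missingness tags in a truth
table. Within-archetype daily-yield variance in real herds is not known
with any precision; the defaults are set for clear test separability, not
calibrated biology.

What the generator does *not* emulate: milk-component dynamics, health
events, pregnancy and seasonality effects, herd-level management shifts,
serial correlation of noise within a lactation, and between-cow variation
in curve parameters *within* an archetype (all members of an archetype
share one base curve). Passing the recovery tests therefore shows the
machinery is correct under the stated generative model — not that real
herds contain exactly these archetypes.

## Problem sizes and determinism

Default analyses run at herd sizes of tens to low hundreds of lactations
(the recovery tests use 90 curves × 271 days; statistical calibration
uses 1000 null replicates), where the full pipeline completes in seconds
on one core; the pairwise distance matrix is O(n²·N) and k-medoids
O(n²·k) per iteration, so thousands of lactations remain practical. One
integer seed determines the herd draw, all restarts and hence every
output byte; `manifest.json` records seed, resolved configuration and
library versions for bit-identical re-runs.

## Known limitations

- The Voronoi alternation can end in a local optimum on large instances;
  restarts mitigate but do not eliminate this (the exhaustive check only
  covers small instances).
- Unprotected LSD inflates the family-wise error rate across many
  pairwise comparisons.
- Carry-forward of a trailing gap biases the last ≤ 10 days flat.
- Asymptotic SEs from (JᵀJ)⁻¹ are unreliable exactly where fits are
  flagged degenerate; treat SEs of non-converged fits qualitatively.
- Residuals of daily milking data are heavy-tailed and serially
  correlated; the least-squares point estimates are fine for curve
  description, but no inferential use of the residual distribution is
  made beyond the SEs.
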