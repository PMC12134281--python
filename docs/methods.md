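# Methods

## Community model

The package treats a culture-based endophyte survey as a set of
*morphospecies records*: a taxon (identified to genus where possible,
otherwise carried as an "unclassified" sterile mycelium) observed in one
tissue (flower, leaf, stem or root) of one host plant, with a colony
count. Segment tallies — segments plated vs segments yielding at least
one endophyte — are stored separately per (plant, tissue) and feed the
colonization-frequency percentage CF% = 100 · colonized / examined.

All per-plant diversity statistics are computed from the plant's
abundance vector n₁ ≥ n₂ ≥ … ≥ n_S (colony counts per morphospecies,
zeros dropped; records with count 0 are allowed in the table but never
contribute to richness):

- Shannon–Wiener H′ = −Σ pᵢ ln pᵢ with pᵢ = nᵢ/N. The **natural**
  logarithm is used throughout: with S = 8 it gives
  E = 1.79/ln 8 = 0.861, matching the evenness conventionally reported
  alongside these tables, whereas log₁₀ would not.
- Simpson's complement 1 − Σ pᵢ². The complement-of-concentration form is
  computed and labelled `simpson_complement` to avoid the recurring
  notational clash between "D" as concentration and "D" as diversity.
- Camargo's index implemented literally as 1/S (the reciprocal-richness
  form used in endophyte survey tables), not Camargo's original
  evenness statistic.
- Berger–Parker dominance N_max/N.
- Evenness E = H′/ln S, *undefined* (typed `None`, not zero) when S < 2.

Hard bounds (H′ ≤ ln S, 1 − D ≤ 1 − 1/S, BP ≥ 1/S, each with equality
exactly at perfect evenness) are enforced as invariants in the test suite
by exhaustive enumeration of every abundance vector with S ≤ 5, N ≤ 12,
and are applied as *validation checks* on user-supplied published index
rows by the report pipeline: inconsistent printed rows are flagged as
warnings, never silently corrected.

Plants that yielded no isolates produce a typed "no data" profile
(mirroring the dashes of published tables), never zero-valued indices —
a zero Shannon index asserts a monoculture, which is a different claim
from "nothing grew".

### Rounding

Published index tables mix 2- and 3-decimal rounding and occasionally
truncate (1/6 printed as 0.16). Profiles therefore store full precision
and apply per-index decimals only when formatting; `round_value` exposes
explicit `half_up` and `truncate` modes. The selectivity index formatter
truncates to 2 decimals (196.2/41.75 = 4.6994 reported as 4.69), keeping
the full-precision value alongside.

### Reconstructing abundance vectors from printed rows

`reconstruct_abundances` enumerates all non-increasing positive integer
vectors of length S with total N in a bounded range (default 1–30, which
keeps the exhaustive search in the millisecond range) and keeps those
whose indices, rounded to the decimals implied by each printed target,
equal every target. This turns a rounded published row into the exact
set of integer communities consistent with it. Audit results on the
packaged nine-plant table:

- Six of eight non-empty rows are exactly reproducible; the recovered
  vectors ship as the `reconstructed_abundances` fixture. For the most
  diverse plant the solution is unique: (6,4,2,1,1,1,1,1), N = 17.
- One row prints H′ = 1.46 for a 4-species community, above the
  mathematical maximum ln 4 ≈ 1.386, and its Simpson/dominance pair is
  likewise jointly infeasible; a second row's Simpson value is
  infeasible given its dominance and richness, and its printed 1/S
  implies a richness that contradicts its own species list. No vector
  exists for either; both rows are flagged by the validation checks and
  excluded from the reconstructed fixture.
- Two near-misses are documented rather than forced: one printed Shannon
  value (1.041) differs by ~0.001 from the value of the vector pinned
  down by the row's other indices (1.0397 → 1.04), and one printed
  Simpson value (0.82) differs by 0.01 from the vector matching the
  row's Shannon and dominance (0.8148 → 0.81). Matching that Simpson
  value exactly would require N = 23, contradicting the survey's own
  abundance ranking, so the N = 9 vector is kept.

### Fixture conventions

The isolate inventory fixture stores colony_count = 1 per record (the
published table lists species, not per-species counts); the
reconstructed fixture carries the index-consistent counts above. Tissue
assignments in both fixtures are a deterministic labeling convention
(round-robin over each plant's tissues with nonzero CF%), since the
source table does not print per-species tissues; no diversity index
depends on this choice, only the illustrative overlap/ordination outputs.
Segment denominators behind published CF% values are likewise not
printed, so the CF table ships as data and is never recomputed.

## Overlaps and ordination

Tissue overlaps are exclusive Venn regions: the region keyed by a tissue
subset T counts species occurring in *exactly* the tissues of T, so the
2⁴ − 1 regions partition the union (asserted in tests against a direct
membership-check oracle). Ordination is PCA of the genus × tissue
colony-count matrix with genera as observations: columns are
mean-centered but not scaled (all entries share colony-count units), and
component signs are fixed by making the largest-magnitude loading
positive, so figures are reproducible run to run. Scores and explained
variance are cross-checked in tests against an independent
eigendecomposition of the covariance matrix.

## Bioassay statistics

**DPPH.** Scavenging % = 100 · (C − T)/C is applied per replicate and
then summarized (mean ± sd); transforming averaged absorbances would
understate the replicate spread. Negative values (sample more absorbing
than the DPPH control) are preserved and flagged `pro_oxidant`, not
clipped.

**4PL dose–response.** v(c) = lower + (upper − lower)/(1 + (c/mid)^hill),
fitted by bounded least squares with the midpoint parameterised on the
log scale for conditioning; initialisation lower = min(v),
upper = max(v), hill = ±1 by the sign of a log-linear trend,
log-midpoint = mean log-concentration; convergence tolerance 1e-8. The
fit is canonically oriented so `upper_` is the response as c → 0.
IC50/CC50 are solved analytically from the fitted parameters and
reported only when 50% lies strictly between the fitted asymptotes;
otherwise a typed "undefined" result is returned. The same routine
serves tumor-line IC50 and normal-line CC50. Tests verify exact
recovery (≤ 1e-6 relative) on noise-free curves, scale equivariance in
concentration, and < 5% median relative IC50 error across 200 seeded
experiments with 5% multiplicative noise.

**ANOVA + Duncan.** One-way ANOVA uses the classical sum-of-squares
decomposition (cross-checked against an independent implementation in
tests); all-equal inputs give F = 0, p = 1 rather than NaN. Duncan's
multiple range test ranks means descending and compares the range of
each p-consecutive span with R_p = q(1 − (1 − α)^(p−1); p, df_within) ·
√(MS_within/n_h), with studentized-range quantiles computed numerically
(no α = 0.05-only table lookup) and harmonic-mean replication n_h for
unequal group sizes. Spans are tested widest-first; a span inside one
already declared homogeneous is never subdivided (the protection rule).
Letters are the maximal homogeneous spans; the display is invariant to
input order, and tests compare it against an independent oracle that
enumerates every contiguous span. With zero within-group variance the
standardized distance between unequal means is infinite, so any
difference separates groups.

**Zone summaries.** Per pathogen, extracts are ranked by mean zone
diameter (reported diameter; whether a well bore is included is the
caller's convention), with solvent-control rows retained in the output
but excluded from ranking and letters; ties are broken lexicographically
and flagged.

## Synthetic data

Generators are pure functions of a parameter record carrying the seed,
each with its own `numpy.random.Generator` stream. The community
generator plates a fixed number of segments per plant tissue (default
12 — chosen so CF% moves in steps of a few percent, typical of small
surveys; published tables rarely print the denominator, so this is a
convention, not an inference), colonizes each independently with a
per-tissue probability, and assigns species to colonized segments from
an even, geometric or log-series abundance model. The dose–response
generator evaluates the 4PL and applies multiplicative Gaussian noise to
viability, back-computing absorbances against a fixed untreated
absorbance so the viability transform round-trips exactly at zero noise;
the DPPH generator inverts the scavenging formula the same way.

What the generators do **not** emulate: between-replicate correlation,
plate-position or batch effects, heteroscedastic absorbance error,
species co-occurrence structure, or tissue-specific host filtering.
Passing tests therefore demonstrate correctness of the estimators under
the stated sampling models, not robustness to every artifact of real
assay data.

## Problem sizes

Default verification sizes: exhaustive index-bound checks over all
abundance vectors with S ≤ 5, N ≤ 12; 200 seeded 4PL experiments
(7 concentrations × 3 replicates) for noisy IC50 recovery; 5000 null
simulations (3 groups × 5 replicates) for ANOVA type-I calibration; 50
random 3–5-group datasets for the Duncan oracle comparison. These sizes
give Monte-Carlo standard errors comfortably below the acceptance bands
while keeping the whole suite in the tens of seconds.

## Known limitations

- Camargo's index here is 1/S by design; users expecting Camargo (1993)
  evenness should not compare values across conventions.
- No rarefaction, richness estimators (Chao1/ACE), beta-diversity
  distances or sequence-based diversity: the scope is culture-based
  inventories.
- Duncan's MRT is provided because it remains the standard post-hoc in
  this assay literature; its per-comparison protection level is liberal
  relative to Tukey's HSD, and the letter display inherits that.
- The 4PL uncertainty of a single fit is summarized by residual RMSE
  only; published "±" values on IC50/CC50 without a stated error model
  are carried as-reported, not re-derived.
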