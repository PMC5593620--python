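# Methods

## Study design and unit of observation

The package implements a case/non-case (disproportionality) design on
spontaneous adverse-event reports.  Within a cohort defined by a drug
indication (e.g. reports whose drugs carry the indication ATRIAL
FIBRILLATION), each report is classified by exposure to an index drug and
by whether it lists an index reaction, giving one 2×2 table per receipt
year.  Because spontaneous-reporting databases contain no unexposed healthy
controls, "unexposed" means *reports of other drugs in the same cohort*;
the reporting odds ratio therefore measures disproportionate reporting, not
incidence risk.

Conventions that the input data do not force and that we fixed once:

- **Term matching** is exact and case-insensitive on preferred-term strings
  (reaction, indication, product name).  No terminology-hierarchy expansion
  is attempted: term dictionaries are licensed, and the analysis this
  package supports queried literal preferred terms.
- **Cohort membership** requires the indication on *any* drug entry of the
  report, not only the index drug.
- **Exposure** is membership of the index drug anywhere in the report's
  drug list; co-medicated reports count as exposed.
- **Year assignment** uses the leading four digits of the receipt date.
- **Deduplication** keeps, per report id, the version with the latest
  receipt year (ties: last in input order).  Versioned case reports are a
  fact of life in these databases and a case must count once; the database
  itself does not prescribe a collapse rule, so this one is a declared
  convention.

## Per-stratum effect and cohort tests

`ROR = ad/bc`, log-scale CI `exp(ln ROR ± z·√(1/a+1/b+1/c+1/d))` (Woolf),
z = 1.959964 at the default 95% level.  A zero cell triggers the
Haldane–Anscombe correction (+0.5 on all four cells, flagged in the
output); the correction is a strict no-op on positive tables.  Cohort-level
association on the cell-wise sum of the yearly tables uses Pearson's χ²
without Yates correction (closed form `n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`)
and the G-test `2ΣO·ln(O/E)`, both against χ² with 1 df.

## Heterogeneity, pooling and model selection

Cochran's Q uses inverse-variance weights `w_i = 1/v_i` around the
weighted mean, `I² = 100·(Q − df)/Q` floored at 0, and the
DerSimonian–Laird moments estimator
`τ² = max(0, (Q − df)/(Σw − Σw²/Σw))`.  Both truncations are standard; the
raw formulas can go negative.

The selection rule is the conventional two-step: random effects
(DerSimonian–Laird, weights `1/(v_i + τ²)`) when the Q test is significant
at `alpha_model` (default 0.05), fixed effects otherwise.  The fixed-effects
point estimate is Mantel–Haenszel on the raw stratified counts,
`ΣR_i/ΣS_i` with `R_i = a_i d_i/n_i`, `S_i = b_i c_i/n_i`, and the
Robins–Breslow–Greenland estimator for the variance of its log.  RBG is our
declared choice of fixed-effects variance: it is the standard companion to
MH and is what `statsmodels.StratifiedTable` computes, which we use as an
independent cross-check in the tests.  Pooled p-values are two-sided Wald
z-tests on the log scale.  With τ² = 0 the DL estimator collapses to
inverse-variance fixed pooling exactly (tested to 1e-12); we do not expose
inverse-variance fixed pooling as a separate reporting model.

The two-step selection rule is itself a known source of mild
miscalibration (the model is random exactly when Q was extreme), which is
why calibration is asserted as a band: under a null truth the selected
model's rejection rate stays within 0.05 ± 0.02 and coverage within
93–97% (500 replicates, 12 years × 20,000 reports/year).

## Bias diagnostics

**Egger's test** is the classical variant: OLS of the standardized effect
`y_i/se_i` on precision `1/se_i`, two-sided Student-t test of the intercept
at k−2 df.  Degenerate geometry is handled explicitly: fewer than 3 strata
or precisions with no variation are errors; an exact fit (zero residual)
with a zero intercept reports t = 0, p = 1 rather than 0/0.

**Leave-one-out** re-pools each k−1 subset *under the model selected on
the full data* — the point of the diagnostic is the influence of a year on
the reported estimate, so the estimator is held fixed while τ² is
re-estimated per subset.  The summary carries min/max pooled ROR and the
smallest lower CI bound.

## Drug–gene network and enrichment

The network has exactly one drug node, a layer of *direct* genes (curated
drug–gene pairs) and a layer of *indirect* genes (partners of direct genes
in gene–gene interaction evidence).  A gene appearing in both layers is
classified direct; gene–gene edges between two direct genes are kept as
edges; gene–gene edges touching no direct gene are dropped with a warning;
self-loops and duplicate unordered pairs are collapsed.  Node bookkeeping
is enforced as an invariant: `|nodes| = 1 + #direct + #indirect`, every
indirect gene adjacent to ≥1 direct gene.  Exports: SIF, GraphML (roles as
node attributes) and a lossless role-annotated edge TSV.

Over-representation of a query list against a GMT collection uses the
upper-tail hypergeometric probability `P(X ≥ k)` with background size N,
annotated-in-background K, query-in-background n and overlap k; the
enrichment rate is `(k/n)/(K/N)`.  The background defaults to the union of
all collection members ("annotated genes"); a genome-wide background can be
passed explicitly — web enrichment tools differ on this operational default
and both are supported.  Adjustment is Benjamini–Hochberg step-up,
implemented directly (sort, scale by m/rank, reverse cumulative minimum,
cap at 1) and cross-checked against `statsmodels.multipletests` in the
tests.  Note the step-up map is *not* idempotent in general — e.g.
(0.02, 0.9, 0.95) → (0.06, 0.95, 0.95) → (0.18, 0.95, 0.95) — only
constant adjusted vectors are fixed points; the tests assert the true
properties (monotone on sorted input, capped, fixed-point on constants).
Significance filtering uses strict `p_adj < alpha`.

## Synthetic data: what it emulates and what it does not

`SimulationTruth` encodes the generative model the random-effects analysis
assumes: per year *i*, `θ_i ~ Normal(θ, τ²)`; each of `n_per_year` reports
is exposed with probability `p_exposed`; event probability is `p_event0`
unexposed and `expit(logit(p_event0) + θ_i)` exposed.  Counts are drawn as
nested binomials, and the report-level generator expands exactly those
counts into case reports (same seed → identical tables, verified
cell-for-cell across 50 seeds).

Defaults mirror the shape of a 12-year atrial-fibrillation cohort:
years 2004–2015, `p_exposed = 0.108` (8,142 exposed of 75,618 reports),
`θ = ln 1.38`, `n_per_year = 6,300` (≈75,600 reports total).  Two values
are not derivable from that shape and were chosen once: `p_event0 = 0.02`
(a few percent of cohort reports listing the event, typical for a
moderately common reaction in spontaneous data) and `τ² = 0.05` (between-
year RORs spanning roughly ×0.64–×1.55 around the pooled value at ±2σ,
consistent with a cohort where the Q test is expected to matter).

Features of real spontaneous-report data the generator deliberately does
**not** model: duplicate case versions, co-medication confounding,
stimulated-reporting dynamics, within-report correlation of multiple drugs
and reactions, and — importantly — **varying yearly report volumes**.  The
last one has a visible consequence: with equal volumes, a year's log-ROR
and its standard error are both driven by the same exposed-event count
(`y_i ≈ log a_i + const`, `se_i ≈ a_i^{-1/2}` when `a` is the smallest
cell), so the Egger regression sees points on a near-deterministic curve
and rejects "symmetry" essentially always, with no bias present.  This is
the known anti-conservatism of Egger's test for log-ORs taken to its
degenerate extreme, not an implementation fault: on effects with
independently drawn standard errors the implementation's null p-values are
uniform (Kolmogorov distance < 0.1 over 1,000 replicates) and rejection at
0.05 is rare.  Consequently, passing simulation tests validate estimation,
calibration and model selection, but say nothing about Egger's behaviour on
real data, where yearly volumes vary by an order of magnitude and supply
genuine precision variation.

## Numerical choices and problem sizes

- Natural logarithms throughout; normal quantile 1.959964 at 95%.
- τ² and I² truncated at zero; `I² = 0` when `Q = 0`.
- Heterogeneity always uses inverse-variance weights, also when MH is the
  reporting model (Cochran's convention).
- MH requires both `Σa_i d_i/n_i > 0` and `Σb_i c_i/n_i > 0`; zero-weight
  strata are tolerated, all-zero margins are errors.
- Monte-Carlo checks run at 12 years × 20,000 reports/year × 500
  replicates (calibration), 100–200 replicates for selection/power
  properties, and 50 seeds for round-trips — sizes at which the asserted
  bands are comfortably resolved while the whole suite stays fast.
- Report JSON is serialized with sorted keys at full float precision;
  human-readable summaries round to 2 decimals.

## Known limitations

- File-based ingestion only; no HTTP clients for the upstream databases.
- Exact preferred-term matching may under-count events coded under sibling
  terms.
- The LOO analysis does not re-select the pooling model per subset (by
  design, see above); users wanting per-subset selection can call
  `select_model` on each subset themselves.
- Network edge counting treats evidence lists as unweighted undirected
  pairs; interaction direction, evidence type and multiplicity are ignored.
- Enrichment p-values are conditional on the chosen background; with the
  annotated-gene default, sparsely annotated queries can look more enriched
  than under a genome-wide background.
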