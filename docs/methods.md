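# Methods

## Scope and model

`faersig` screens a spontaneous-report database for drug–event
disproportionality. The unit of analysis is the deduplicated case report: a
report contributes 0 or 1 to every cell of every 2×2 table, at every MedDRA
level, however many reaction rows it carries. The background for each
(drug, term) table is the entire cleaned database of professional-reporter
cases — including the other target drugs' reports — not a drug-restricted
subset; this mirrors standard practice, where the expected count
`E = (a+b)(a+c)/N` is taken against everything retrievable after cleaning.
Tables are crude (no age/sex/period stratification of E).

## Cleaning

Cases arrive in versions (same CASEID, multiple PRIMARYIDs across
quarters). Per CASEID the survivor is the version with the maximum FDA_DT,
ties broken by the maximum PRIMARYID; PRIMARYIDs compare numerically when
both parse as integers, non-numeric ids compare below all numeric ids and
lexicographically among themselves — a total order that the vectorised sort
and the brute-force test oracle implement independently. Cases on deletion
lists are removed entirely. The pipeline order is dedup → reporter filter →
primary-suspect selection, so the *latest* version's reporter occupation
governs whether a case survives the professional filter. The default
exclusion drops consumers (CN), lawyers (LW), and missing/unknown
occupations, keeping MD/PH/OT/HP.

Drug matching is exact on upper-cased, trimmed names against a synonym
table (the bundled default covers the eight checkpoint inhibitors' generic
and main trade names). No fuzzy matching: reproducibility is preferred over
recall, and any recall loss applies symmetrically to numerator and
background. A case whose primary-suspect rows match several target drugs is
kept once and annotated to each (one case in each drug's margin).

## Hierarchy roll-up

MedDRA is licensed, so the hierarchy is supplied as plain TSV extracts
(PT→primary SOC; SMQ membership with narrow/broad scope). SMQ roll-up
defaults to narrow scope. SOC assignment uses the primary SOC only (no
multi-axiality): the analysis partitions events into disjoint organ
classes. Because the exclusion rule behind a curated SMQ analysis set is a
modelling choice, `roll_up` exposes an SMQ include-list rather than
hard-coding one.

## Engines and numerical choices

- **ROR**: Haldane–Anscombe +0.5 on all four cells, applied only when some
  cell is zero. CI is Wald on the log scale with z = 1.959964.
- **PRR**: computed on uncorrected counts; c = 0 yields an +inf sentinel.
  The χ² is the Yates-corrected Pearson statistic (clamped at 0 when the
  continuity correction exceeds |ad − bc|), verified in tests against an
  independent library implementation.
- **BCPNN**: the gamma-posterior ("shrunk observed count") formulation —
  IC = log2((a+0.5)/(E+0.5)), IC025 from the 2.5% quantile of
  Gamma(a+0.5, rate 1) — is the default because it is exactly testable
  against quantile oracles; the closed-form approximation
  IC − 3.3(a+0.5)^(−1/2) − 2(a+0.5)^(−3/2) sits behind `variant="approx"`
  and agrees within 0.1 for a ≥ 10. The original Dirichlet
  variance-approximation variant is out of scope.
- **MGPS**: the five hyperparameters (two gamma shape/rate pairs and a
  mixture weight) are fitted by direct L-BFGS-B maximisation of the
  negative-binomial-mixture marginal log-likelihood over log-transformed
  shapes/rates and a logit-transformed weight, starting from the
  conventional values (0.2, 0.1, 2.0, 4.0, 1/3), iteration cap 500,
  relative tolerance 1e-8. Direct maximisation was chosen over EM as it is
  faster here and no less accurate; the optimizer result is guarded so the
  returned point never has lower likelihood than the start, and
  non-convergence returns the best iterate with a warning rather than
  raising. Fitting is skipped (default prior used) below 100 (a, E) pairs,
  where a five-parameter likelihood is too flat. EBGM is evaluated through
  the digamma function; EBGM05 by Brent root-finding on the posterior
  mixture CDF to absolute tolerance 1e-6, bracketed by the component
  quantiles.
- **Screening**: minimum of three target reports for every method; ROR025
  > 1, IC025 > 0, EBGM05 > 2 (strict), PRR ≥ 2 with χ² ≥ 4 (inclusive, per
  the MHRA convention). IC bands are closed on the upper end: weak
  (0, 1.5], moderate (1.5, 3.0], strong (3.0, ∞).

## Dates, ages, onset

Dates carry explicit precision (8/6/4-digit day/month/year). Any
computation requiring day resolution — time to onset in particular —
treats lower-precision dates as missing. Onset is event date minus the
earliest day-precise therapy start of the annotated primary-suspect drug;
negative differences are dropped and counted. "Monthly" onset bins are
30-day bins. Ages normalise to years through the FAERS unit codes
(DEC×10, MON/12, WK/52, DY/365.25; HR → missing; a missing unit with a
numeric age is read as years).

## Aggregation

Cumulative metrics sum a term's lower-bound statistic over exactly the
drugs flagged positive by the matching method — negative-signal drugs
contribute zero. This is the only reading consistent with heatmap-style
summaries that print "—" for negatives while their column sums match the
cumulative values. Percentage arithmetic (`share_of_total`, `ratio`) uses
decimal half-up rounding to 2 places, matching display conventions; the
conservation identity Σ per-term C-values = total over positive rows is
asserted in tests.

## Synthetic data: what it emulates, what it does not

The generator emulates, at desk scale, the features of a real quarterly
extract that the pipeline consumes: versioned duplicate cases (default
15% of cases carry 1–3 superseded versions — comparable to the share of
raw records discarded as duplicates in large extracts), a 50%
non-professional reporter fraction, one primary-suspect drug per case
drawn from a marginal where three of the eight target drugs carry ~80% of
target cases, a power-law PT frequency spectrum, multiplicative planted
relative-rate tilts renormalised per drug, PT-dependent death
probabilities (elevated for cardio-respiratory and hepatic-failure terms;
overall death share ≈ 0.2), sex M/F/missing at 0.53/0.34/0.13, ages
centred at 67 ± 12 years with 25% missing (≈57% of known ages above 65),
exponential onset times with per-drug medians spanning 28–50 days, and
date missingness leaving onset computable for roughly 40% of reports.
Target drugs take 20% of cases overall — far above their share in the real
database — so that desk-scale runs have usable per-drug counts.

It does not emulate drug-name noise, multi-drug cases (one PS drug per
case keeps ground truth exact; multi-target behaviour is exercised by
hand-built fixtures), indication fields, country-specific reporting
cultures, or reporting-rate drift over calendar time. Because the planted
tilt is renormalised per drug, the realised report-level relative rate
only approximates the configured rr; recovery tests therefore assert
detection, ordering and calibration properties rather than exact rr
equality. Passing tests show the machinery is correct under these
conditions — not that any particular real-world signal is true.

The standard recovery benchmark plants 20 (drug, PT) pairs at rr = 10,
round-robin across the eight targets with uniform target shares and on
mid-frequency PTs (baseline ≈ 0.5%), so that detection power is a property
of the method rather than of a drug's market share. Null calibration uses
the same 640-PT vocabulary with all rates at 1.

## Problem sizes

Unit tests run on 150–4,000-case extracts; the statistical acceptance
checks use 1,000 cases for the deduplication oracle, 50,000 cases for null
calibration and planted-signal recovery, and 50,000 (a, E) pairs for the
MGPS fit — sizes at which the binomial standard errors of the checked
fractions are a small fraction of the asserted margins.

## Known limitations

- No probabilistic record linkage: duplicates are collapsed by CASEID only.
- No stratified expected counts, no higher-order (drug–drug–event)
  interaction scans, no sequence-symmetry or onset-time signal tests.
- PRR's +inf sentinel for c = 0 is deliberate; downstream screening treats
  it as a (flagged) positive numerator condition only if χ² and count rules
  also pass.
- The bundled hierarchy is a small synthetic stand-in for the licensed
  vocabulary; analyses of real extracts must supply real PT→SOC and SMQ
  extracts in the documented TSV formats.
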