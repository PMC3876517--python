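# Methods

## Scope and model

`trisscore` implements the TRISS (Trauma and Injury Severity Score)
audit pipeline used in trauma-registry research to ask a single question:
*did a cohort's patients die more or less often than a reference logistic
model says they should have?*

Three layers sit on top of each other:

1. **Severity scoring.** The Injury Severity Score (ISS) summarises
   anatomy: each of six body regions (head/neck, face, chest, abdomen,
   extremities, external) carries the worst Abbreviated Injury Scale
   grade (AIS, 0–6) sustained there; the three highest grades are squared
   and summed, giving 0–75, and any AIS 6 (unsurvivable) forces 75.
   The Revised Trauma Score (RTS) summarises physiology: Glasgow Coma
   Scale, systolic blood pressure and respiratory rate are each coded to
   an ordinal 0–4, and RTS = 0.9368·GCSc + 0.7328·SBPc + 0.2908·RRc,
   range 0–7.8416. The unweighted code sum (0–12) is exposed separately
   as the triage RTS; the two quantities are distinct and are never
   reconciled.
2. **Survival prediction.** Per patient,
   `logit = b0 + b1·RTS + b2·ISS + b3·A` with A = 1(age ≥ cutoff), and
   `Ps = 1/(1 + exp(−logit))`. Coefficients are published data, not code:
   each `CoefficientSet` carries a blunt and a penetrating vector plus the
   age cutoff (default 55 years, the Major Trauma Outcome Study
   convention). Two sets ship built in (`table2`, the default, and
   `mtos_formulaAB`); arbitrary sets load from flat JSON. The type system
   enforces b1 > 0, b2 < 0, b3 < 0, so Ps is guaranteed monotone —
   increasing in RTS, decreasing in ISS and in the age indicator.
   Transcriptions of these models sometimes circulate with the ISS/age
   signs or the exponent sign flipped; such forms predict *rising*
   survival with worsening injury and are rejected at construction.
   Penetrating trauma below age 15 is scored with the blunt vector, since
   the penetrating fits exclude children.
3. **Cohort audit.** With observed outcomes O_i ∈ {lived, died} and
   predictions Ps_i:
   * expected deaths `E = Σ(1 − Ps_i)` (probability scale), reported
     alongside the threshold-classified count `#{Ps_i ≤ 0.5}` — both are
     conventional, and they answer different questions;
   * `SMR = O_deaths / E`;
   * `W = (O_survivors − Σ Ps_i)/(n/100)`, excess survivors per 100
     patients;
   * Flora's `Z = (O_survivors − Σ Ps_i)/√(Σ Ps_i(1 − Ps_i))`,
     approximately N(0,1) when outcomes are Bernoulli(Ps_i);
   * the case-mix match `M = Σ_bands min(f_cohort, f_ref)` over six
     survival-probability bands. The reference band distribution is a
     required input — there is no defensible silent default — so `M` is
     simply omitted when none is supplied.

A patient is an *expected survivor* iff Ps > 0.5; the tie at exactly 0.5
classifies as an expected death. Ps bands use the conventional labels
0.96–1.00, 0.91–0.95, 0.76–0.90, 0.51–0.75, 0.26–0.50, 0.00–0.25, binned
on the unrounded Ps with edges [0, 0.255), [0.255, 0.505), [0.505, 0.755),
[0.755, 0.905), [0.905, 0.955), [0.955, 1]; the upper edge is closed.
This exact convention makes band counts bit-reproducible.

## Numerical and interface choices

* **Coding gaps.** The physiological coding table is stated over
  integers and leaves gaps for real-valued inputs (e.g. a respiratory
  rate of 9.5). Raw SBP/RR are rounded to the nearest integer, halves
  away from zero, before coding. GCS must already be an integer in 3–15.
* **RTS weights** are configurable (`ScoreWeights`); 0.7328 for SBP is
  the package default even though 0.7326 also circulates in the
  literature — both are accepted by supplying weights explicitly.
* **Registry dialect.** UTF-8 CSV, fixed canonical header. Validation is
  total: a row is either accepted or attributed a named (row, field)
  violation; strict mode raises on the first, non-strict drops and
  tallies. Missing physiology is an error — no imputation. Fractional
  ages floor to whole years on read.
* **Determinism.** All randomness flows through one
  `numpy.random.Generator` seeded from the spec; identical spec + seed
  gives byte-identical CSV output, and the end-to-end pipeline is
  byte-deterministic under a fixed config.

## The synthetic cohort generator

No public trauma registry ships with this package; the generator exists
so that every stage, and especially the *distributional* claims about the
audit statistics, are testable. Its defaults describe a 1000-patient
single-centre multiple-trauma cohort: 71.4% male, 4.5% penetrating, a
fixed joint age-group × cause frequency table (eight age bins 2–82 years,
four causes dominated by vehicle accidents at 67%), ISS mean 15.50 / SD
11.31, RTS mean 7.49 / SD 0.79, length of stay 7.4 ± 3.2 days.

Sampling works backwards from the scores so the score moments can be hit
exactly in population:

* **Anatomy.** Per-region AIS grades are i.i.d. from a zero-inflated,
  geometrically tilted categorical over grades 0–5: P(0) = z,
  P(g) ∝ θ^(g−1). For any (z, θ) the distribution of "sum of squares of
  the top three of six draws" is enumerated exactly over the 462
  multinomial count vectors, and (z, θ) is solved by a two-stage grid
  search matching the target ISS mean/SD. The fit is rejected
  (`UnsatisfiableSpecError`) if the best achievable mean misses by > 2%
  or the SD by > 10% of scale — this is how impossible targets such as
  SD 0 surface. Grade 6 (ISS 75) is excluded unless
  `allow_unsurvivable=True`.
* **Physiology.** The coded (GCS, SBP, RR) triple is sampled first, from
  a two-component mixture: an intact (4,4,4) state with probability π,
  else each code independently 4 − D with D truncated-geometric(ρ).
  (π, ρ) are grid-solved against the exact 125-triple RTS distribution,
  same rejection thresholds. Raw values are then drawn uniformly inside
  the chosen code's defining range, so raw and coded physiology can never
  disagree. With the default targets the solved populations give ISS
  (15.51, 11.34) and RTS (7.495, 0.790).
* **Outcomes.** Each patient dies with probability q where
  odds(q) = `excess_mortality` × odds(1 − Ps), Ps computed from the true
  TRISS model (default `table2`). With the knob at 1 the cohort is
  calibrated *by construction*: E[SMR] = 1, E[W] = 0 and Z is
  asymptotically standard normal — and the test suite verifies exactly
  that by simulation (200 replicates of n = 1000), plus a monotone SMR
  dose-response over excess-mortality 1.0/1.2/1.5.

What the generator deliberately does **not** emulate: correlation between
cause and severity, between anatomy and physiology (ISS and RTS are
independent given the spec), injury co-location across regions, and any
time-to-event structure. One visible consequence: with both score
distributions at their marginal targets, the model-expected mortality is
≈ 3.6%, lower than the ≈ 8.5% a real cohort with the same marginals shows
— real registries concentrate low RTS and high ISS in the same patients.
Passing calibration tests therefore demonstrates the correctness of the
audit arithmetic and the generator's self-consistency, not fidelity of
any particular real cohort's joint distribution.

## Test and simulation sizes

The suite runs the exhaustive ISS oracle over all 7^6 = 117,649 AIS
profiles, the null-calibration simulation at n = 1000 × 200 replicates,
and dose-response at 20 replicates per excess-mortality level; the whole
suite completes in a few seconds. Monte-Carlo tolerances are fixed from
the CLT (e.g. |mean Z| < 3/√200, SD(Z) ∈ (0.8, 1.2)).

## Known limitations

* AIS-revision agnostic: grades are taken as given; no AIS-90/AIS-2005
  conversion, no NISS.
* Coefficients are inputs; there is no refitting of the logistic model on
  a user registry.
* Records with unmeasurable physiology (intubated patients, untestable
  GCS) are rejected rather than imputed.
* No bootstrap confidence intervals for W/Z/M.
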