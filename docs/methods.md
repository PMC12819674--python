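# Methods

## Scope and data model

The package analyses spontaneous adverse-event reports in the FAERS
quarterly dialect: four `$`-delimited ASCII tables per quarter (DEMO,
DRUG, REAC, THER) keyed by PRIMARYID, where a clinical case (CASEID)
may appear as several report versions. The in-memory unit is the
`ReportRecord`: one deduplicated report with demographics in canonical
units (age in years, weight in kg), its drug list with role codes, its
set of MedDRA preferred terms, and the earliest therapy start date.

## Ingestion and deduplication

Age and weight are converted at parse time (AGE_COD: YR ×1, DEC ×10,
MON ×1/12, WK ×1/52.18, DY ×1/365.25, HR ×1/8766; WT_COD: LBS
×0.453592, GMS ×0.001). Empty fields are missing, matching the dialect.

Deduplication keeps, per CASEID, the version with the latest FDA
receipt date, ties broken by the highest PRIMARYID. Two choices were
genuinely open and are fixed as follows:

- PRIMARYIDs are compared numerically when both parse as integers
  (real PRIMARYIDs are numeric); lexicographic comparison is the
  fallback for non-numeric test identifiers.
- A version without an FDA date loses to any dated version: dated
  versions are the more complete submissions.
- Deduplication runs on the full corpus *before* target-drug
  selection, the order a corpus-wide cleaning pass naturally has. The
  alternative (select first, dedup after) gives the same kept set
  whenever the duplicate versions agree on the suspect drug, which is
  the generated-data regime; on real data the orders can differ and
  the pipeline logs per-stage counts so the effect is visible.

Target reports are those with a primary-suspect drug whose normalized
name (uppercase, whitespace collapsed) contains any configured
pattern; substring matching is deliberate because DRUGNAME is free
text with brand/strength suffixes. `assemble_reports` returns the full
labelled corpus rather than the target subset: disproportionality
needs the background arm, and a labelled corpus keeps the two arms
consistent by construction.

## Disproportionality statistics

Counting is report-level: a report contributes at most one to cell
`a` for a term however many of its PTs match; at SOC level a report
matches a SOC when any PT maps to it (primary SOC only — multi-axial
assignment is out of scope, and each PT carries exactly one primary
SOC). The four statistics and default thresholds are the standard
published formulations (see README); all thresholds are parameters of
`Thresholds`. Statistics are kept at full precision internally;
rounding to two decimals happens only when writing CSVs.

Degenerate inputs: a zero cell triggers the Haldane +0.5 correction
for the ROR only; a zero margin makes the PRR/χ² pair not evaluable
(NaN, flag false) rather than an exception; E = 0 makes EBGM not
evaluable.

### MGPS prior fit

The prior on the relative reporting rate λ is
`w·Gamma(α₁,β₁) + (1−w)·Gamma(α₂,β₂)` (shape/rate). Each observed
count is marginally a two-component negative-binomial mixture given
its E, and the five hyperparameters are estimated by maximising the
summed marginal log-likelihood over all drug–event pairs of the corpus
(unstratified E — no covariate stratification scheme is imposed). The
optimiser is L-BFGS-B on unconstrained transforms (logit w, log of the
rest) with bounds wide enough to be inert in practice. The documented
default start is w=0.2, α₁=0.2, β₁=0.1, α₂=2, β₂=4; because a mixture
component the data barely use is only weakly identified, the fit
always also tries two fixed alternate starts and returns the best
final likelihood, making the result insensitive to the start point. A
fit that ends below its own start likelihood, or terminates abnormally
with a gradient large relative to the likelihood magnitude, raises
with the best iterate attached.

EBGM is `exp(Σⱼ Qⱼ(ψ(αⱼ+a) − ln(βⱼ+E)))` with posterior weights Qⱼ
proportional to prior weight × negative-binomial marginal; EBGM05
solves the posterior mixture CDF at 0.05 by Brent root-finding
bracketed by the component quantiles (widened geometrically when
floating-point slack puts the root outside). Note the geometric mean
sits below the posterior arithmetic mean by at most a factor
`exp(−1/shape)`, so EBGM can fall marginally below `min(1, a/E)` even
under a mean-1 prior; tests assert the sandwich with that correction.

## Subgroups and sensitivity

Strata: sex (F/M), age (<18, 18–65, 65–85, >85 years), weight (<50,
50–100, >100 kg), reporter type (healthcare = MD/PH/HP vs
non-healthcare = CN/LW/OT). Bin edges are left-closed, right-open
([18, 65)), a convention that has to be chosen because shared
endpoints are otherwise ambiguous; it is configurable. Reports missing
the stratifying variable form an implicit "missing" bin that is
counted but not signal-tested by default. Both arms (target and
background) are restricted to the stratum, so each stratum is a
self-contained corpus with its own prior fit.

The sensitivity analysis drops reports carrying a listed co-medication
in a non-PS role or as an additional PS drug; the default list is the
five commonly co-reported products named for immunoglobulin therapy
(Hizentra, Diphenhydramine, Acetaminophen, Gammagard liquid, Human
immunoglobulin G). The retained subset re-enters the unchanged
pipeline.

## Time-to-onset model

Onset is event date minus earliest therapy start date, in days — a
clinical latency, deliberately not the FDA receipt date (which measures
reporting delay). Reports missing either date are skipped; negative
intervals are excluded and counted; zero-day intervals become 0.5 day
so same-day infusion reactions are retained (dropping them would bias
the shape upward). No censoring model is used: only complete pairs
contribute.

The Weibull MLE solves the profile score in β by Brent's method on an
adaptively expanded bracket (the score is monotone in β), then
`α = (mean(xᵝ))^(1/β)`. Wald CIs are computed on (ln β, ln α) from a
central-difference observed information matrix and back-transformed,
guaranteeing positive bounds. Samples below 30 values or with zero
spread are rejected (the MLE diverges on constant data). Hazard
classification uses the shape CI: entirely below 1 → early failure,
entirely above → wear-out, otherwise random. The empirical median/IQR
are reported alongside the fit because with shape ≈ 0.5 the fitted and
empirical medians differ materially and both are informative.
Histogram bins for the onset distribution are 0–7, 8–30, 31–90,
91–180, 181–365, >365 days.

## Synthetic corpus generator

The generator emulates exactly the structures the pipeline must
handle: a target-drug fraction of reports (default 0.3, giving both
arms thousands of reports at the default 5,000 cases), 1–3 drugs per
report with one PS role, per-PT Bernoulli events at a background rate
of 0.04 (independent across PTs given the drug, capped at one
reaction row per PT), injected pairs at `min(1, ρ·background)`,
case-version duplicates (each sampled case gains 1–3 versions with
later-or-equal FDA dates), demographic missingness matching the
large-corpus reality the defaults encode (44.3% age, 60.1% weight,
9.2% sex), optional co-medication tagging, and onset times drawn from
Weibull(0.47, 189.41) days — the early-failure regime the onset model
targets — encoded as start/event date pairs. Every report is forced to
carry at least one reaction (a uniform PT when no Bernoulli fires),
which inflates per-PT rates by at most `(1−p)^k/k`; tests account for
that term. Fixed config + seed gives byte-identical files.

What the generator does *not* emulate — and what green tests therefore
do not establish about real data: free-text drug-name noise, secular
reporting trends, correlated event clusters (real PTs co-occur within
syndromes), reporting-delay dynamics, country fields, and
duplicate versions that disagree on content. Conclusions about
algorithm behaviour under those features require real extracts.

## Problem sizes

Default analysis-scale runs use 5,000-case corpora (≈1,500 target
reports), 20-seed replications for stochastic claims, and
10,000-draw samples for parameter-recovery checks — sizes at which the
binomial/Wald error bands in the tests are a few percent, so the
checks are informative rather than vacuous, while a full suite run
stays comfortably in minutes on a single CPU.

## Known limitations

- The MGPS fit is unstratified; confounding by age/sex that would be
  absorbed by stratified expected counts is not modelled.
- The BCPNN IC uses the closed-form shrinkage formulation; the original
  beta-prior formulation is a possible extension and differs slightly
  at very small counts.
- Substring drug matching can over-match (e.g. a pattern contained in
  an unrelated brand name); patterns are user-supplied and should be
  reviewed against the corpus's DRUGNAME inventory.
- The bundled PT→SOC table is a ~70-term subset for testing and
  examples; real analyses need a licensed MedDRA table in the same
  format.
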