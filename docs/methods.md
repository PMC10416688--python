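# Methods

This note records what the package computes, the assumptions behind it,
and the choices made where the design was genuinely open.

## Margin status

A margin is **clear** at >= 1 mm histological clearance and **involved**
at 0 mm — the binary audit definition.  That definition leaves the open
interval (0, 1) mm unaddressed, so distances there are a distinct
**close** category.  Close margins are reported separately and are *not*
counted as incomplete excisions: the incomplete definition is
involvement, and folding close margins into it would inflate every rate
downstream.  "Less than X mm" mentions are stored as an inexact upper
bound; with X <= 1 mm the margin is classed close (not clear, not
involved).  Contradictory wording for the same margin ("clear" and
"involved") resolves pessimistically to involved and is flagged for
audit — in a patient-safety context a false alarm is cheaper than a
missed involved margin.

## Risk stratification

The low/high rule table follows the BAD adaptation of the NCCN
treatment guidance.  High-risk triggers: aggressive growth pattern
(infiltrative, morphoeic, micronodular, basosquamous); perineural or
lymphovascular invasion; a site in the facial "mask area" (nose, lips,
eyelids, ears, chin, temple, periorbital — high risk at any size); size
>= 10 mm on cheek/forehead/scalp/neck or >= 20 mm on trunk and
extremities; recurrence.  The published criteria admit local
modifications, so the table ships as an editable YAML data file rather
than code constants.

Unknowns use three-valued logic: a lesion is low risk only when every
trigger field is known and negative; if nothing triggers but a relevant
field is unknown the label is *unknown*, never silently low.  Defaulting
unknowns to low would bias the risk-stratified rates invisibly.

## Extraction conventions

All patterns and lexicons are data (`data/extraction_rules.yaml`);
margin patterns run most-specific-first and a later pattern cannot
re-claim matched text, so "nearest peripheral margin 1.2 mm" shadows the
generic "margins ... mm" phrasing in the same sentence.  Negation uses
NegEx-style clause scoping: a cue ("no", "not", "without", "absent",
"no evidence of") negates trigger terms up to a clause terminator
("but", "however", ";", sentence end).  The conclusion section outranks
the clinical details for diagnosis — a clinical "?BCC" is a suspicion,
not a diagnosis, and never counts.

Perineural invasion, lymphovascular invasion and recurrence follow the
**absence-as-negative** convention: when a report was successfully
sectioned but never mentions the finding, it is recorded as absent (and
listed in `assumed_absent`, with no evidence span) rather than unknown.
Pathologists state these findings when present; treating silence as
unknown would mark most real reports unclassifiable for risk.  A report
with no recognisable structure at all still yields unknown.  Generic
margin phrasing ("margins clear by 2 mm") applies to both margins only
when neither has a specific mention.  Specialty is read from the
requesting-clinician header, not the report body; an unmatched non-empty
header maps to "other", an empty one to unknown.

## Cohort and rates

The cohort excludes diagnostic biopsies and non-BCC reports (counts per
reason are logged); primary, recurrent and re-excision lesions are
analysed together.  Records with unknown risk or an unknown margin
status leave the denominator and are tallied as unassessable.  Every
rate-table percentage uses the whole assessable cohort as denominator,
which is what makes the low + high = total row identity exact on counts;
both-margins-involved lesions count in both margin columns and once
overall, so max(peripheral, deep) <= overall <= peripheral + deep.
Rounding to one decimal happens only at presentation.

## Logistic model

`fit_margin_model` fits a binomial GLM (logit link) of the
uninvolved-margin indicator on specialty dummies (reference: plastic
surgery, configurable) plus a binary high-risk covariate, via
statsmodels; Wald CIs are formed on the log-odds scale and
exponentiated.  A specialty with zero outcome variation is *completely
separated*: its ML coefficient is unbounded and any printed OR (0.00 or
otherwise) is an optimisation artefact.  The default fit therefore
excludes separated specialties' rows, flags them, and refuses rate
conversion for them; `method="firth"` keeps them in with a
Jeffreys-prior penalised fit (Newton iterations on the Firth-adjusted
score, hat-diagonal correction) for users who want finite estimates.

Log odds convert to adjusted incomplete rates as
100·(1 − logit⁻¹(η)) only for coefficients significant at a two-sided
Wald threshold (default α = 0.05, configurable); both a fixed-risk-level
and a cohort-risk-mix-weighted conversion are provided, labelled
accordingly, since either is a defensible way to report an adjusted
rate.

## Agreement statistics

Percentage agreement carries a Wilson score interval (exact limits at
boundary counts).  Cohen's kappa uses the marginal-product chance
agreement; its default CI uses the Fleiss–Cohen–Everitt large-sample
variance (cross-checked to machine precision against statsmodels), with
a seeded 2,000-resample multinomial bootstrap available by flag, and the
kappa-vs-zero p-value uses the null variance.  Degenerate tables
(chance agreement 1) raise an explicit undefined-kappa error rather
than returning a number.  Multi-class endpoints use unweighted kappa.
Unknown labels form an explicit category and are never dropped.

## Synthetic corpus

The generator emulates the structure of UK BCC histopathology reports:
three template dialects (classic uppercase headings, compact
mixed-case, and a run-on dictated paragraph with inline headings), a
requesting-clinician header carrying the specialty (full names or
abbreviations — OMFS, ENT, GP, Plastics...), and sections encoding one
lesion per report.  Noise dials control dialect mix, abbreviation,
hedged margin wording ("appears completely excised ... approximately"),
explicit-negation probability for absent invasion findings, and
"mm"/"millimetres".  `NoiseConfig.none()` is the fully explicit
single-dialect rendering used for strict round-trip checks.

Default rates are chosen to emulate the published audit conditions:

- per-margin involvement probabilities conditional on risk
  (low: 1.5%/2.0% peripheral/deep; high: 4.25%/4.25%), which with the
  default feature rates (~42% high-risk prevalence) put the whole-cohort
  stratified percentages near 0.9/1.2 (low), 1.7/1.7 (high) and ~5.5%
  overall;
- ~2.25 lesions per patient; 10% diagnostic biopsies; 5% non-BCC decoy
  reports; 8% of clear margins in the close (0, 1) mm band;
- clear-margin distances log-uniform on [1, 10] mm (close margins
  log-uniform on [0.1, 0.9] mm), rounded to 0.1 mm so the rendered text
  encodes the truth exactly and the >= 1 mm threshold is exercised from
  both sides;
- specialty mix dominated by plastic surgery (40%) and dermatology
  (20%), with the remaining six categories sharing the rest.

The truth risk label is produced by calling the classification module's
own rule table on the generated features — one source of truth, so
generator and classifier cannot drift apart.

What the generator does **not** emulate: real margin involvement does
vary by specialty in observational data, but the generator draws
involvement from risk alone, so specialty odds ratios on default corpora
are ~1; specialty effects are instead exercised by a direct outcome
simulator with known coefficients (`simulate_margin_cohort`).  It also
omits misspellings, OCR artefacts, multi-specimen reports, free-text
idiosyncrasies beyond the three dialects, and realistic demographics.
Perfect extraction accuracy on these corpora therefore demonstrates
rule coverage of the modelled phrasing inventory, not performance on
arbitrary real-world reports.

## Problem sizes and numerics

The test suite runs corpora of ~1,100 lesions per fixture and ~5,000
lesions for the end-to-end checks; the acceptance script uses the full
study scale (15,657 patients, ~35,000 lesions), a ~6,200-report
validation corpus, 200 simulation replicates of n = 20,000 for CI
coverage, and 1,000 random tables for the statistic oracles.  GLM
fitting uses statsmodels defaults (IRLS, iteration cap 100) with
non-convergence raised as an error carrying the deviance trace; the
Firth fit iterates Newton steps to 1e-8 with a cap of 100.  Segment
offsets are 0-based half-open, and segmentation is lossless by
construction (spans plus residue reconstruct the input exactly), which
is what the fuzz tests assert.

## Known limitations

- The extraction rules implement the *described behaviour* of
  rule-based margin extraction systems, not any specific proprietary
  rule set; recurrence detection from clinical wording is best-effort.
- Risk agreement treats the three-valued label (low/high/unknown)
  directly; a binary comparison would need a stance on unknowns.
- The logistic model is lesion-level; repeated lesions within a patient
  are not given a clustering correction.
- The heading lexicon covers common UK surface forms; laboratories with
  exotic headings should extend the YAML file.
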