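# Methods

This note documents the model and conventions behind `acuitybench`, the
defaults of the synthetic-data generator, and the numerical and design
choices made where the problem left them open.

## Care-days, provision windows and attribution

The unit of acuity classification is the **care-day**: a 24 h period
anchored at 07:00 local time, so the day labelled *d* runs
[*d* 07:00, *d*+1 07:00). Each care-day is partitioned into three
**provision windows**: day [07:00, 14:00) (7 h), evening [14:00, 21:00)
(7 h) and night [21:00, 07:00) (10 h). The night window is attributed to
the date it starts; hours between 00:00 and 06:59 therefore belong to the
previous date's night shift automatically — including the hours of an
infant admitted at, say, 03:00. Weekend status (Saturday/Sunday) follows
the attributed date.

All intervals are **half-open** `[start, end)`. The source data do not fix
boundary semantics; half-open intervals make the three windows tile the
care-day exactly and charge each instant to exactly one window (a discharge
at exactly 14:00 contributes nothing to the evening window). Arithmetic is
carried in integer seconds and converted to hours only at the edge, so
infant-hour totals are conserved exactly: summed over windows that span the
cohort, charged seconds equal presence seconds minus home-leave seconds.

Raw rostered shifts (e.g. 07:00–15:30, 21:00–07:15) are longer than the
windows; staff hours are truncated to the windows, so overlap periods
(13:30–14:00, 21:00–21:30, 07:00–07:15) are charged to exactly one window
and no staff hour is double-counted. Nonclinical activity (administration,
education, introduction) is excluded entirely. Agency records count like
employed staff. Overlapping duplicate records for one person on one unit
are merged by interval union with a warning — double-counting a person is
never physically meaningful. Home-leave intervals subtract from presence in
full; whether an infant on leave still books nursing time is unknowable
from the data, and the conservative choice (full subtraction) lowers
recommended hours rather than inflating them. Acuity is still recorded for
leave days, so classification coverage is unaffected.

## Acuity classification

Classification is a top-down, first-match-wins rule table over daily
boolean intervention flags, shipped as data (YAML), not code: the exact
predicate list in use at any site is contestable, so the default table is a
**reconstruction** of the BAPM three-category definitions for the six named
register interventions, and every run manifest records the rule file's
SHA-256. Default table:

* IC — invasive or mechanical respiratory support; chest drain
* HDC — parenteral nutrition (adapted variant), noninvasive respiratory
  support, umbilical line
* SC — no qualifying flag (the default category)

The **adapted/original toggle** changes exactly one rule: parenteral
nutrition with no respiratory-support flag is HDC under the adapted
variant and IC under the original table. The adapted variant is the
default, on the rationale that classifying those infants downward avoids
inflating recommended hours (and hence falsely low provision ratios).
Under the adapted default the table is severity-monotone: adding a flag to
a record never lowers its category. The original variant is intrinsically
non-monotone (adding noninvasive support to a PN-only day moves IC→HDC),
which is why the monotonicity property is stated for the adapted table.

Missing intervention records for an admitted care-day default to SC with a
warning and a count in the run report (configurable to a hard error) — the
same conservative direction as above. Whether "mechanical" and "invasive"
respiratory support are distinct register fields or synonyms is unknown;
both flags exist and either triggers IC.

## Benchmark definitions

Recommended RN hours per window: `R = 1.0·IC + 0.5·HDC + 0.25·SC`
(infant-hours per category; the weights are the BAPM 1:1 / 1:2 / 1:4
ratios and are validated to be strictly decreasing in (0, 1]). The
recommended RN *count* divides by the window duration (7 or 10 h). The
provision ratio `ρ` divides provided clinical RN + specialist-RN hours by
`R`; nursing assistants are excluded, and coordinator hours are excluded
by default (`include_coordinator=False`) since coordinators are accounted
separately; a config switch adds them. `ρ < 1.0` flags understaffing.
When `R = 0` (no admitted infants) the ratio is undefined: the row is kept
in counts but excluded from ratio summaries.

Summaries report mean (SD) with a normal-approximation 95 % CI
(mean ± 1.96·SD/√n) and median with IQR = Q3 − Q1 under the
linear-interpolation quantile convention. Skill-mix proportions (RN share
of staff hours; specialist share of RN hours) are computed per shift first
and then summarized. No multiple-testing correction is applied; p-values
are reported raw at α = 0.05.

### Rank tests

Group contrasts are Kruskal–Wallis (specialist share across shift types
within units) and two-sided Mann–Whitney U (provision ratio, weekday vs
weekend per shift type — reported both pooled across units and per unit,
since either pooling is defensible). Numerical choices:

* Mann–Whitney: exact null distribution when the smaller group has ≤ 8
  observations and there are no ties; tie-corrected normal approximation
  with continuity correction otherwise.
* Kruskal–Wallis: tie-corrected H; **exact permutation p when the pooled
  sample has ≤ 10 observations and no ties**, chi-square (df = k−1)
  otherwise. The chi-square approximation is materially off at such sizes
  (e.g. three groups of two with complete separation: χ² p ≈ 0.102 vs
  permutation p ≈ 0.067), so small samples get the exact method, matching
  the Mann–Whitney design.
* Degenerate all-tied samples (tie correction divides by zero): reported
  as H = 0 / U = n_a·n_b/2 with p = 1 and a degenerate flag.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes, with
ground truth exported for every recoverable quantity.

**Cohort.** Admissions arrive per unit-week as Poisson counts (default
12.7/unit/week ≈ 609 admissions over 16 weeks and three units) with
admission instants uniform over the week — the real time-of-day pattern is
unknown, so uniform is the exposed default. Gestational-age strata
{23–28, 28–32, 32–37, >37} weeks have probabilities
(0.064, 0.082, 0.286, 0.568); length of stay is log-normal matched to
per-stratum mean/SD of (52.6/33.6, 27.2/18.6, 9.5/7.9, 3.8/3.9) days,
truncated below at 1 day — reproducing the strongly right-skewed stay
distribution (cohort median ≈ 4 days, mean ≈ 10). 5 % of stays of ≥ 5 days
include one 1–2 day home-leave interval.

**Acuity dynamics.** Each stay's care-day categories follow a first-order
Markov chain: with probability 0.75 the category persists, otherwise it is
redrawn from a service-wide equilibrium mix (IC 0.17, HDC 0.41, SC 0.42).
Initial categories depend on GA stratum (sicker at lower GA), and each
unit applies a multiplicative tilt emulating level-4/3/2 case mixes
(unit 1 IC-heavy, unit 3 SC-heavy). These dynamics are minimal-parameter
plumbing: they reproduce realistic day-to-day fluctuation and the
published three-level acuity mix, not any particular unit's history.

**Flags.** Intervention flags are emitted as the *minimal* set implying
the day's true category under the adapted default table (IC days always
carry invasive respiratory support; HDC days carry parenteral nutrition
and/or noninvasive support or an umbilical line, never an IC flag; SC days
carry no qualifying flag), plus non-qualifying noise flags (phototherapy,
tube feeding, antibiotics) with probability 0.15. Classification therefore
round-trips exactly, and the PN-only share of HDC days (0.18) yields an
IC-share increase of several points when the original table is applied —
the direction and order of magnitude of the adapted-vs-original contrast.

**Roster.** Rosters are generated backwards from acuity-implied demand.
Per window, provided RN hours = target ratio × recommended hours, rounded
**up** to the 0.25 h scheduling quantum (real rosters are quarter-hour
granular; rounding up guarantees a roster calibrated at 1.0 is never
flagged understaffed by quantization, at the cost of a ≤ 0.25 h upward
bias). Optional per-shift Gaussian dispersion of the target
(`ratio_dispersion_sd`, default 0 — dispersion is an explicit knob) makes
realistic spread. Hours are packed into full-window records plus at most
one shorter fill-in fragment per category, confined to the window so the
calibration never spills into the adjacent window; `shift_length_range`
([4, 15] h) is validated and bounds full records, while fill-in fragments
model staff leaving early. The specialist/assistant split is deterministic
per shift (specialist share of RN hours, RN share of total staff hours),
so the mix parameters are exactly recoverable as medians. Coordinators
appear with per-shift-type probabilities (defaults 0.854 day / 0.012
evening / 0 night), nonclinical records at 5 % of records, agency flags at
5 %.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: admission/discharge churn and transfer workload,
parental-support load, within-day acuity changes, correlated staffing
shortfalls (sickness waves), seasonal census trends, and real rosters'
person-level continuity (generated "persons" are window-slot identities).
The generator demonstrates that the *pipeline* recovers known quantities
under the assumed structure, not that any particular hospital is
understaffed.

## Problem sizes and determinism

Default analyses run a 16-week, three-unit service: 1008 provision
windows, ≈ 600 admissions, ≈ 6500 care-days — the scale the pipeline is
intended for; the packaged demo uses 4 weeks (252 windows) for a fast
worked example. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical parameters give byte-identical CSV
outputs (floats are written with 6 significant digits, timestamps as
timezone-naive local time).

## Known limitations

* The default rule table is a reconstruction; sites should review and
  version their own YAML (the manifest hash makes runs auditable).
* Staffing *requirements* beyond the acuity weights (layout, churn,
  parental support) are out of scope by design.
* The ratio's undefined-when-`R=0` convention means empty unit-shifts do
  not count toward understaffing rates.
* The normal-approximation CI is symmetric and can cross natural bounds
  for proportions near 0 or 1 in small groups.
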