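# Methods

## Setting and design

`hsb` implements a cross-sectional analysis of markers of health-seeking
behaviour and healthcare access in linked UK-style electronic health
records: a primary-care event stream ("medcode" clinical events,
prescriptions, consultation records) linked to hospital admitted-patient
data (positioned ICD-10-style diagnoses and OPCS-style procedures).  The
cohort is anchored at a single index date (default 1 September 2019) and
contains everyone aged 66 or over at index with a GP registration start
at least one year earlier, so that every marker has a minimum pre-index
ascertainment period.

Because primary-care records carry only the year of birth, age is
computed as `index year − birth year`, and the earliest possible date of
attaining an age is taken to be 1 January of the corresponding year.
The extra slack year built into age-eligibility lookbacks (below)
absorbs the within-year uncertainty this creates.  Exact age-band
boundaries may therefore differ from a data source that records full
birth dates; this is inherent to the recording convention, not a bug.

All date intervals are half-open `[start, end)`.  This is applied
uniformly: an event on the window start date counts, one on the end
date does not, and the influenza season "1 September 2018 to 31 March
2019" is stored as `[2018-09-01, 2019-04-01)`.

## Marker ascertainment

A patient is flagged for a marker iff at least one qualifying event
falls in their ascertainment window.  Qualification requires the right
source, a code in the marker's codelist (narrow by default), a date in
the window, and — for the hospital ACS marker — diagnosis position 1.
GP visits are identified from consultation records by type (GP and
nurse visits, excluding out-of-hours) rather than a codelist, which
abstracts the source-identifier logic of real consultation tables.
Same-day duplicate records collapse; for the GP-visit *count*, distinct
(date, type) pairs are counted.

Windows by lookback kind:

* **ever** — `[1900-01-01, index)`.  "Ever" is bounded only by the
  data, because records transferred from previous practices predate the
  current registration.
* **fixed k years** — `[index − k years, index)`.
* **season** — the configured absolute interval.
* **eligibility** — let `E = min(index, 1 Jan of the year the patient
  turns upper_age + 1)` (a person counts as eligible throughout the
  year they have the upper eligible age) and
  `S = max(E − k years, 1 Jan of the year they turn lower_age)`.
  Standard mode returns `[S, index)`, extending past the eligible ages
  to allow for delayed recording; **restricted** mode returns `[S, E)`.
  Only the end moves between modes — the start `S` is identical — so
  restricted windows are always subsets of standard windows, and the
  two coincide exactly for patients still age-eligible at index.  The
  window is empty if the patient was never age-eligible before index.

Two sensitivity axes form a 2×2 grid: lookback mode
(standard/restricted) and codelist variant (narrow/broad; broad lists
exist for the AAA, breast and cervical screening markers, whose
diagnostic procedures can be coded without screening terminology).
Broad lists always contain the narrow lists, so per patient and marker
`flag(restricted) ≤ flag(standard)` and `flag(narrow) ≤ flag(broad)` —
these orderings are enforced by construction and verified by tests.

A patient's sex never zeroes a flag: opposite-sex records for
sex-targeted programmes occur in real data and are counted as recorded.
Programme sex is used only by the generator and for reporting.

The shipped codelists are synthetic placeholders with the structure of
real lists (marker, source, narrow/broad variant, code); real published
codelists in the same CSV format can be dropped in.  The union rule for
the influenza marker (clinical OR prescription records, same-day
duplicates collapsing) is an approximation to vaccine-algorithm logic
that full coding dictionaries would refine.

## Prevalence

The denominator for every marker is the full cohort, including
sex-specific markers; the numerator is the flag count.  Stratification
is by sex and 5-year age band (`[65,70) … [90,95), [95,∞)`, labelled
"65-69" … "90-95", "95+"; the cohort contains no one under 66, so the
first band is effectively 66–69).  Comparison against user-supplied
national reference estimates is a plain observed/reference percentage
ratio; no confidence intervals, weighting or testing, since the design
is purely descriptive.

## Correlation structure

Marker flags are correlated with the phi coefficient — the Pearson
correlation specialised to binary variables, computed from each pair's
2×2 table.  Zero-variance markers (e.g. a female-programme marker
within a male subset at zero leak) have undefined phi and are excluded
with a logged warning rather than imputed.

Markers are clustered on `d = 1 − phi` by complete-linkage
agglomeration.  Negative phi gives `d ∈ (1, 2]`, which complete linkage
accepts unchanged, preserving weak negative between-group correlations
instead of truncating them.  Determinism is pinned down by two
documented contracts: tied minimal distances merge the pair with the
lexicographically smallest cluster ids (leaves numbered 0..n−1 in input
order, merged clusters n, n+1, …), and at each merge the subtree
containing the smaller minimum original index goes left in the leaf
order.  The implementation is a direct O(n³) agglomeration — trivial at
n ≤ 15 markers — cross-checked in tests against an independent
from-scratch agglomerator and against `scipy.cluster.hierarchy` on
tie-free instances.

Cutting the tree at `k` clusters (undoing the last `k − 1` merges)
yields a partition that is compared with the theoretical grouping of
markers under the updated Theory of Planned Behaviour model —
psychological (vaccinations), contextual (screening programmes and NHS
health checks), physically determined with active access (PSA, bone
density, GP visits, low-value care, blood pressure) and physically
determined with lack of access (missed appointments, ACS admissions) —
using the adjusted Rand index (`sklearn.metrics.adjusted_rand_score`;
a brute-force contingency-table implementation serves as the test
oracle).

## Synthetic cohort generator

The generator exists to make every stage testable without access to
real records.  It is a stand-in with planted, interpretable structure —
its parameters are not estimates of any real population.

* **Patients.** Ages are drawn from a 5-year-band mixture
  (24/26/21/15/9/4/1 % over 66–69 … 95–99, mean ≈ 75.9), sex is female
  with probability 0.54, and registration start is uniform 2–30 years
  pre-index, so every generated patient satisfies the inclusion rules.
* **Latent determinants.** Each patient carries four standard-normal
  factor scores, one per TPB group, with a configurable 4×4 correlation
  (default: identity).  Each marker's effective latent is
  `z_m = √ρ·F_group(m) + √(1−ρ)·ε_m` with within-group correlation
  ρ = 0.8 by default; `z_m` is marginally standard normal, so the
  attenuation changes dependence without touching marginal prevalence.
* **Occurrence.** One flag per patient × marker from
  `p = logistic(α_m + λ_m z_m + β_m (age − 75)/10)`, multiplied by
  `cross_sex_leak` (default 0.003, emulating the small opposite-sex
  recording seen in real data) when the patient is not the programme's
  target sex, and set to 0 when the patient has no non-empty standard
  window.  Default loadings are λ = 1.0; default age slopes plant the
  qualitative patterns of screening-era and vaccination data
  (recently introduced programmes decline with age, vaccinations and
  ACS admissions rise).  Occurrence-then-date factorisation is used
  deliberately: the analysis consumes ≥1-occurrence flags and GP-visit
  counts only, so longitudinal visit processes would add nothing
  testable.
* **Calibration.** α_m is found by bracketed root-finding on a
  fixed-seed Monte-Carlo estimate (400 000 draws) of the population
  mean of `p` under the configured age/sex/latent distribution, to
  within 0.002 of the target prevalence; unreachable targets (e.g. a
  target above the achievable maximum for a sex-restricted marker)
  raise a calibration error.  Calibrations are cached per parameter
  set.  Default targets are realistic overall prevalences for an
  English 66+ cohort, ranging from 0.011 % (low-value glucosamine
  prescriptions) to 92.6 % (GP visits).
* **Dates and codes.** A flagged marker emits one event uniform on the
  patient's *standard* window (so restricted-mode ascertainment can
  genuinely miss late events), coded uniformly from the narrow list,
  with configurable probability of a broad-only code (default 0, so
  narrow ascertainment recovers the truth exactly).
* **GP visits.** The flag uses the same latent mechanism (so GP visits
  participate in planted correlation structure); conditional on the
  flag, a zero-truncated negative binomial NB(r = 3, mean = 8.5) count
  is emitted as that many gp/nurse consultation events.  These
  parameters make the unconditional count distribution's quartiles
  exactly 4 / 7 / 11 with P(0) = 7.4 % matching the 92.6 % flag target,
  and about 1 % of patients exceed 25 visits/year.
* **Nuisance records.** Poisson noise events with codes disjoint from
  every codelist, out-of-hours consultations, and ACS-coded hospital
  diagnoses in secondary position — all constructed so they can never
  change a flag, which is what the noise-robustness tests verify.
* **Determinism.** All randomness flows from `SeedSequence(seed)` split
  into separate patient, latent and event streams, so changing event
  parameters never reshuffles the cohort, and identical configs
  reproduce outputs byte-for-byte.

### Planted-structure configuration

Block-structure recovery runs use a dedicated configuration: uniform
target prevalence 0.30, λ = 1.5 for every marker, ρ = 0.8 within group,
independent factors between groups, no age effects, and
`cross_sex_leak = 1` (sex masks off).  Each choice isolates the planted
dependence: heterogeneous near-zero prevalences would turn rare-marker
phi into pure noise, and active sex masks make mutually exclusive
opposite-sex markers within the contextual group strongly *negatively*
correlated (phi ≈ −0.4) for reasons unrelated to the latent structure.
Under this configuration the complete-linkage tree cut at k = 4
recovers the four theoretical groups essentially always at n = 50 000
(ARI = 1), and with λ = 0 the mean |phi| falls below 3/√n with
chance-level ARI.

### What the generator does not emulate

Real record volumes and coding dialects, practice-level clustering,
deprivation and region, death or deregistration, repeat screening
cycles, and confounding of markers by underlying health need.  Passing
tests therefore demonstrate that the *pipeline* is correct (window
algebra, flag logic, estimators, clustering) and that planted structure
is recoverable — not that real UK marker prevalences or correlations
take any particular value.

## Numerical and degenerate-input choices

* Quartiles use the linear-interpolation definition (numpy default);
  the counts {1..9} therefore give median 5, IQR (3, 7).
* Year arithmetic on dates maps 29 February to 28 February when the
  target year is not a leap year.
* Empty cohorts warn rather than fail; empty strata yield no summary
  row; a zero reference percentage yields an absent ratio with a
  warning; a requested broad variant for a marker without one falls
  back to narrow with a logged warning.
* Cluster labels after cutting are ordered by each cluster's smallest
  original leaf index, making partition CSVs stable across runs.

## Problem sizes used by the test suite

Oracle-equivalence checks run on 50 cohorts of 120–200 patients against
a per-patient brute-force double loop; monotonicity properties run over
20 seeds at n = 2 000; parameter recovery and planted-structure
recovery run at n = 50 000 (10 seeds for the recovery count).  These
sizes give binomial/clustering checks comfortable margins (3 binomial
SE at n = 50 000 is ±0.6 percentage points at p = 0.5) while keeping
the default suite fast on a laptop.

## Known limitations

* The age convention can shift patients across band boundaries relative
  to full-birth-date data.
* The restricted-lookback sensitivity moves only the window *end*; a
  variant that also re-anchors the start would be a different, equally
  defensible reading of "stopping the lookback at the upper age of
  eligibility".
* Reference-estimate comparison is a ratio of percentages with no
  uncertainty quantification.
* The shipped codelists are structural placeholders; all prevalence
  content in examples comes from the generator.
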