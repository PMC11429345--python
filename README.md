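# hsb — markers of health-seeking behaviour and healthcare access in EHR

Health-seeking behaviour (what a person does to prevent or detect
disease while believing themselves healthy) and healthcare access are
rarely recorded directly in electronic health records, yet both drive
healthcare utilisation and confound observational studies — famously
inflating estimates of influenza-vaccine effectiveness against
all-cause mortality.  `hsb` is a tested, reusable pipeline for
identifying *proxy markers* of these constructs in linked UK-style EHR
(primary-care coded events, prescriptions and consultations linked to
positioned hospital diagnoses and procedures), aimed at
epidemiologists who want to quantify such markers or adjust for them.

The pipeline has four stages, each usable on its own:

1. **Ascertainment** — 15 marker flags per patient from codelists and
   lookback windows anchored at an index date.  A patient is flagged
   iff ≥1 qualifying event falls in their half-open window
   `[start, end)`.  Markers with an upper age of programme eligibility
   (screening, NHS health checks) use windows anchored to the end of
   eligibility: with `E = min(index, 1 Jan of the year of turning
   upper_age + 1)` and `S = max(E − k, 1 Jan of the year of turning
   lower_age)`, the standard window is `[S, index)` and the restricted
   sensitivity variant is `[S, E)`.  Narrow vs broad codelists form the
   second sensitivity axis.
2. **Prevalence** — exact counts and proportions per marker, overall
   and by sex and 5-year age band, with observed/reference ratios
   against user-supplied national estimates.
3. **Correlation structure** — the phi coefficient
   `φ = (n11·n00 − n10·n01)/√(n1·n0·n·1·n·0)` for every marker pair
   (Pearson correlation on binary data), complete-linkage hierarchical
   clustering on `d = 1 − φ` with a deterministic tie rule, tree
   cutting, and adjusted-Rand agreement with the four-group theoretical
   classification of markers from the updated Theory of Planned
   Behaviour model (psychological / contextual / physical-active /
   physical-lack determinants).
4. **Synthetic cohort generator** — CPRD/HES-like patients and events
   with known structure: correlated latent determinant factors, a
   calibrated latent-factor logistic occurrence model
   `p = logistic(α_m + λ_m z_m + β_m (age−75)/10)`, planted age trends,
   sex-programme masking, GP-visit count distributions and nuisance
   records.  Real patient-level data of this kind are access-restricted,
   so the generator is what makes every downstream stage testable;
   its outputs include a `truth.csv` oracle of planted flags.

See `docs/methods.md` for the full model description, conventions and
limitations.

## Worked example

```python
import hsb
from hsb.simulate import SimulationConfig, simulate

cfg = SimulationConfig(n_patients=10_000, seed=7)
res = simulate(cfg)
cohort = hsb.build_cohort(res.patients)
flags = hsb.flag_all(cohort, res.events, hsb.default_catalogue(), hsb.toy_codelists())
prev = hsb.compare_to_reference(
    hsb.prevalence_table(flags, cohort, ("overall",)),
    hsb.default_reference_estimates())
```

which prints, formatted:

```
cohort: 10000 patients, mean age 75.9, 54.5% female
aaa_screen                  11.3%   ref  76.1
breast_screen               17.8%   ref  71.1
cervical_screen             20.5%   ref  76.2
bowel_screen                72.1%   ref  60.5
nhs_health_check            19.6%   ref  40.0
influenza_vaccination       73.0%   ref  72.4
pneumococcal_vaccination    62.9%   ref  69.0
psa_test                    17.2%   ref  53.0
bone_density_scan            5.2%   ref     -
gp_visits                   92.8%   ref     -
dna_primary_care            30.3%   ref     -
low_value_procedure         18.3%   ref     -
low_value_prescription       0.0%   ref     -
acs_hospital_visit           9.6%   ref     -
blood_pressure              73.8%   ref  84.6
GP visits: median 7 (IQR 4-11)
```

Each line is a marker's overall prevalence in the synthetic cohort (the
numerator is patients with ≥1 qualifying event in their window, the
denominator the whole cohort) next to the configured national reference
percentage.  Screening markers sit far below their references because
the whole-cohort denominator includes ages no longer eligible for the
programme — the same denominator effect seen in real data — while the
influenza-vaccination estimate (73.0% vs reference 72.4%) shows a
marker whose window covers everyone.  The GP-visit quartiles come from
the generator's planted count distribution.

The same run from a shell:

```sh
hsb simulate --out-dir data --seed 7 --n-patients 10000
hsb ascertain --patients data/patients.csv --events data/events.csv --out flags.csv
hsb prevalence --flags flags.csv --patients data/patients.csv --out prevalence.csv
hsb correlate --flags flags.csv --patients data/patients.csv --subset all --k 4 --out-dir corr
```

or as one reproducible run with a manifest:
`hsb run --config pipeline.yaml --out-dir out` (any subset of
`seed`, `n_patients`, `modes`, `variants`, `subsets`, `k`, `strata`,
`codelists`, `references`, `simulation` keys; defaults cover the rest).

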