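# dentage

Dental age (DA) estimation from tooth maturation on panoramic radiographs,
and the statistics used to evaluate such methods — for pediatric
dentists/orthodontists working with developmental timing, and for
biostatisticians comparing age-estimation methods.

## What it does

Clinicians need a child's *developmental* (dental) age, not just the calendar
(chronological) age CA, to time orthodontic treatment, extractions and space
management; forensic work uses the same quantity in reverse. `dentage`
implements two radiographic estimators and the full method-comparison
toolkit around them:

* **Stepwise apexification ladder (Becker method).** Tooth groups are ordered
  by eruption timing; since a root apex closes ~3 years after functional
  eruption and is the most reliably read radiographic landmark, DA is simply
  the DA value of the *last* group whose members all show closed apices:

  | step | group (FDI) | DA (y) |
  |---|---|---|
  | 1 | mandibular central incisors 31, 41 | 9 |
  | 2 | first permanent molars 16, 26, 36, 46 | 9–9.5 |
  | 3 | mandibular lateral incisors 32, 42 | 9.5 |
  | 4 | maxillary central incisors 11, 21 | 10 |
  | – | maxillary lateral incisors 12, 22 — *excluded (too variable)* | 10.5–11 |
  | 5 | mandibular canines + first premolars 33, 43, 34, 44 | 12–13 |
  | 6 | maxillary first premolars 14, 24 | 13–14 |
  | – | mandibular second premolars 35, 45 — *excluded (too variable)* | — |
  | 7 | maxillary canines 13, 23 | 14–15 |
  | 8 | second permanent molars 17, 27, 37, 47 | 15 |

  Below DA ≈ 9 no permanent tooth has apexified, so the estimator falls back
  to interpolating observed root fractions f between per-tooth root-onset
  and apex-closure ages: `age = root_start + f · (apex − root_start)`.

* **Demirjian staging engine.** The seven left-mandibular teeth 31–37 are
  staged A–H; stages map to sex-specific weighted scores summing to a
  maturity score S ∈ [0, 100], converted to DA on a sex-specific curve by
  piecewise-linear interpolation. The numeric standards are external
  configuration (published tables are population-specific); a clearly
  labelled *synthetic* table ships for testing.

* **Method-agreement statistics.** Age×sex bias tables (mean DA − CA per
  stratum), Wilcoxon signed-rank tests (exact tie-aware enumeration for
  n ≤ 25, tie/continuity-corrected normal approximation above), Pearson r,
  OLS with a slope-equality interaction test, and the six-form
  Shrout–Fleiss ICC panel (via `pingouin`) for intra/inter-rater
  reliability.

* **Cohort simulator.** Generates radiograph-free test cohorts: per-subject
  latent maturation tempo, per-tooth closure-age noise, sex-specific timing,
  a configurable population advancement Δ, and boundary-window rater
  misreads — with a 377-subject, ages 8–15 age×sex design as the default.

## Worked example

```python
from dentage import ApexRecord, ApexStatus, estimate_becker, parse_fdi

closed = ["31", "41", "16", "26", "36", "46", "32", "42"]
open_ = ["11", "21", "33", "43", "34", "44", "14", "24", "13", "23",
         "17", "27", "37", "47"]
records = [ApexRecord(parse_fdi(t), ApexStatus.CLOSED) for t in closed] + \
          [ApexRecord(parse_fdi(t), ApexStatus.OPEN) for t in open_]
print(estimate_becker(records))
```

```
DAEstimate(method='becker', point=9.5, low=9.5, high=9.5, flags=frozenset())
```

The last fully apexified group is the mandibular lateral incisors (step 3),
so the dental age is 9.5 years — the molars below it are also closed, the
maxillary incisors above it are not.

End to end from the shell:

```bash
dentage simulate --seed 1 --output cohort.csv          # 377-subject design
dentage estimate --method both --input cohort.csv --output est.csv
dentage compare --input est.csv --output bias.csv
```

`compare` prints a per-sex bias table (mean CA, mean DA per method with SDs,
DA − CA differences, and Wilcoxon p-values per age group), e.g. the `total`
row reports each method's overall over/underestimation of CA in years.

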