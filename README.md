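# audioscreen

Audiometric eligibility screening for clinical trials on acute hearing loss.

Trials on idiopathic sudden sensorineural hearing loss (ISSHL) admit patients
by audiological criteria: the acute pure-tone audiogram must show a minimum
overall severity, and a minimum incident-related hearing loss relative to a
baseline. Screening is tedious by hand — it involves pure-tone averages,
picking the most affected consecutive frequencies, and comparing against
whichever baseline exists for the patient. `audioscreen` automates the whole
decision for single patients and batch cohorts, and estimates the recruitment
rate a planned trial can expect from retrospective screening data.

## The decision model

For a patient with acute audiogram $A(f)$ (thresholds in dB HL on the grid
0.125, 0.25, 0.5, 1, 2, 3, 4, 6, 8 kHz; unmeasurable thresholds above
115 dB HL are dummy coded as 120), two criteria are evaluated:

1. **Minimum severity.** The four-frequency pure-tone average
   $\mathrm{4PTA} = \tfrac14\sum_{f\in\{0.5,1,2,4\}} A(f)$
   must reach a configured level (e.g. 50 dB HL). Setting the level to 0
   disables the criterion.
2. **Minimum hearing-loss difference.** Against a baseline audiogram $B(f)$,
   the maximum over all windows of three consecutive grid frequencies of the
   mean difference $\tfrac13\sum_{f\in w}(A(f)-B(f))$ must reach a configured
   level (e.g. 30 dB). Again 0 disables it.

Three baseline variants are supported, each yielding its own recommendation:
a previous audiogram of the affected ear, the contralateral ear, and the
ISO 7029 age/sex normative median audiogram
($\text{shift}(a, s, f) = \alpha_{s,f}\,(a-18)^2$ for age $a \ge 18$).
A patient is recommended for inclusion against a baseline iff both criteria
are met. WHO and EU impairment grades of every audiogram's 4PTA are attached
for qualitative information (grading formally applies to the better ear).
The cohort recruitment rate counts a patient as eligible iff the first
computable baseline in a configurable preference order (previous →
contralateral → normative) recommends inclusion.

Variant designs — a single most affected frequency, a 3PTA, other frequency
ranges — are expressed through the `window_size` and `pta_frequencies`
configuration fields.

## Worked example

A 65-year-old female screening candidate with only a contralateral-ear
baseline, under criteria 50 dB HL severity / 30 dB window difference:

```python
from audioscreen import Audiogram, PatientRecord, evaluate

acute = Audiogram({0.125: 40, 0.25: 45, 0.5: 50, 1: 50, 2: 55,
                   3: 55, 4: 60, 6: 50, 8: 45}, ear="affected", role="acute")
contra = Audiogram({0.125: 10, 0.25: 10, 0.5: 10, 1: 5, 2: 0,
                    3: 20, 4: 30, 6: 40, 8: 40},
                   ear="contralateral", role="baseline_contralateral")
record = PatientRecord(acute=acute, id="P1", age=65, sex="female",
                       baseline_contralateral=contra)
report = evaluate(record)
```

The report prints:

```
4PTA: 53.75 met: True
WHO grade: (2, 'moderate impairment')
contralateral  max: ('0.5-2 kHz', 46.67)
  qualifying: ['0.125-0.5 kHz', '0.25-1 kHz', '0.5-2 kHz', '1-3 kHz', '2-4 kHz']
  -> include
normative      max: ('0.5-2 kHz', 41.73)  -> include
previous       -> not_computable
```

The severity of 53.75 dB HL exceeds the 50 dB HL minimum and grades as WHO
grade 2, moderate impairment. Against the contralateral ear, five windows of
three consecutive frequencies show a mean incident-related loss of at least
30 dB, the largest (46.67 dB) at 0.5–2 kHz — so the patient is recommended
for inclusion. No previous audiogram exists, so that comparison is flagged
not computable rather than decided.

The same engine is scriptable from the shell:

```sh
audioscreen classify --in cohort.csv --criteria criteria.yaml --out report.json
audioscreen recruitment --in cohort.csv
audioscreen simulate --n 100 --seed 7 --target-eligible-fraction 0.4 --out sim.csv
audioscreen normative --age 65 --sex female
audioscreen plot --in patient.json --out chart.png
```

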